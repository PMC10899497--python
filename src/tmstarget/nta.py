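"""Stimulation networks, network targeting accuracy (NTA) scores and maps.

The stimulation network of a coil placement is the E-field-weighted average
of the placement's voxel-wise functional-connectivity seed maps.  Its NTA
against a pathological network map P is the negative spatial Pearson
correlation, so placements whose predicted network engagement opposes the
pathological pattern score high.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import BrainMap, TimeSeries, weighted_seed_map
from .efield import EFieldParams, EFieldWeights, GrayMatterMask, search_space_fields
from .headgeom import HeadModel, SearchSpace

__all__ = [
    "NTAMap",
    "stimulation_network",
    "stimulation_networks",
    "nta_score",
    "compute_nta_map",
    "nta_map_from_networks",
]


@dataclass
class NTAMap:
    """NTA score per search-space node (NaN at excluded/invalid nodes)."""

    space: SearchSpace
    values: np.ndarray
    valid: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.space.shape or self.valid.shape != self.space.shape:
            raise ValueError("NTA map shape must match the search-space grid")
        finite = self.values[self.valid]
        if finite.size and (np.any(~np.isfinite(finite))
                            or np.any(np.abs(finite) > 1.0 + 1e-9)):
            raise ValueError("valid NTA values must be finite and lie in [-1, 1]")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, j, cpc, flag in self.space.nodes():
            rows.append({"i": i, "j": j, "p_nz": cpc.p_nz, "p_al": cpc.p_al,
                         "nta": self.values[i, j] if self.valid[i, j] else np.nan,
                         "valid": bool(self.valid[i, j])})
        return pd.DataFrame(rows)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def stimulation_network(ts_standardized: TimeSeries, efw: EFieldWeights) -> BrainMap:
    """Stimulation network of one placement (a tagged weighted seed map)."""
    return weighted_seed_map(ts_standardized, efw, tag="stimulation-network")


def stimulation_networks(ts_standardized: TimeSeries,
                         fields: dict[tuple[int, int], EFieldWeights]
                         ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Stimulation networks for many placements in one pass.

    Stacks the sum-normalized weights into a V x N matrix W and evaluates
    S = Z (Z^T W) / T, identical per column to :func:`stimulation_network`.
    Returns (V x N network matrix, node keys in column order).
    """
    Z = ts_standardized.data
    keys = sorted(fields)
    W = np.zeros((Z.shape[0], len(keys)))
    for col, key in enumerate(keys):
        efw = fields[key]
        W[efw.support, col] = efw.values
    W /= W.sum(axis=0, keepdims=True)
    S = Z @ (Z.T @ W) / Z.shape[1]
    return S, keys


def nta_score(S: BrainMap | np.ndarray, P: BrainMap | np.ndarray,
              exclude: np.ndarray | set | None = None) -> float:
    """NTA = negative spatial Pearson correlation of S and P.

    ``exclude`` removes voxels (mask-order positions) from the correlation;
    at least 3 voxels must remain and neither map may be constant.
    """
    s = np.asarray(S.values if isinstance(S, BrainMap) else S, dtype=float)
    p = np.asarray(P.values if isinstance(P, BrainMap) else P, dtype=float)
    if s.shape != p.shape:
        raise ValueError("maps must share the same voxel support")
    keep = np.ones(len(s), dtype=bool)
    if exclude is not None:
        keep[np.asarray(sorted(exclude), dtype=int)] = False
    s, p = s[keep], p[keep]
    if len(s) < 3:
        raise ValueError("fewer than 3 voxels remain after exclusion")
    s = s - s.mean()
    p = p - p.mean()
    ns, npn = np.linalg.norm(s), np.linalg.norm(p)
    if ns < 1e-14 or npn < 1e-14:
        raise ValueError("spatial correlation undefined for a constant map")
    return float(np.clip(-(s @ p) / (ns * npn), -1.0, 1.0))


def nta_map_from_networks(S: np.ndarray, keys: list[tuple[int, int]],
                          space: SearchSpace, P: BrainMap | np.ndarray,
                          exclude=None, provenance: dict | None = None) -> NTAMap:
    """Score a stack of stimulation networks (columns of S) against P."""
    values = np.full(space.shape, np.nan)
    valid = np.zeros(space.shape, dtype=bool)
    errors = {}
    for col, (i, j) in enumerate(keys):
        try:
            values[i, j] = nta_score(S[:, col], P, exclude=exclude)
            valid[i, j] = True
        except ValueError as exc:  # node flagged invalid, not fatal
            errors[(i, j)] = str(exc)
    if not valid.any():
        raise ValueError(f"every search-space node failed NTA scoring: {errors}")
    prov = dict(provenance or {})
    if errors:
        prov["node_errors"] = {f"{i},{j}": msg for (i, j), msg in errors.items()}
    return NTAMap(space=space, values=values, valid=valid, provenance=prov)


def compute_nta_map(head: HeadModel, mask: GrayMatterMask, ts_standardized: TimeSeries,
                    space: SearchSpace, P: BrainMap,
                    efield_params: EFieldParams = EFieldParams(),
                    orientation_deg: float = 45.0,
                    fields: dict[tuple[int, int], EFieldWeights] | None = None,
                    exclude=None, provenance: dict | None = None) -> NTAMap:
    """NTA map over a search space for one subject/session.

    Per included node: scalp site -> coil placement -> surrogate E-field ->
    stimulation network -> NTA score.  Precomputed ``fields`` (which depend
    only on head and grid) may be passed to amortize geometry across sessions
    and durations.  Deterministic for fixed inputs.
    """
    if space.n_included < 1:
        raise ValueError("search space has no included nodes")
    if fields is None:
        fields = search_space_fields(head, mask, space, efield_params, orientation_deg)
    S, keys = stimulation_networks(ts_standardized, fields)
    prov = {"orientation_deg": orientation_deg,
            "sigma_mm": efield_params.sigma_mm,
            "lambda_mm": efield_params.lambda_mm,
            "floor_frac": efield_params.floor_frac}
    prov.update(provenance or {})
    return nta_map_from_networks(S, keys, space, P, exclude=exclude, provenance=prov)
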