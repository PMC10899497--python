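"""Optimal scalp-site selection from an NTA map.

Two selection rules are provided: the classic method takes the argmax node of
the map; the cluster method thresholds the map at the top x% of values,
labels connected components under a six-neighborhood on the CPC grid, and
returns the center-of-gravity of the largest cluster.  Rank-based
thresholding makes the cluster labeling invariant to any strictly increasing
transform of the NTA values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .headgeom import CPCCoordinate, HeadModel, cpc_to_scalp, project_to_cortex, to_mni
from .nta import NTAMap

__all__ = [
    "TargetResult",
    "classic_target",
    "label_clusters",
    "cluster_target",
    "SIX_NEIGHBORHOOD",
]

# hexagonal stencil on the (i, j) grid
SIX_NEIGHBORHOOD = ((-1, 0), (1, 0), (0, -1), (0, 1), (-1, 1), (1, -1))
FOUR_NEIGHBORHOOD = ((-1, 0), (1, 0), (0, -1), (0, 1))
EIGHT_NEIGHBORHOOD = ((-1, 0), (1, 0), (0, -1), (0, 1),
                      (-1, -1), (-1, 1), (1, -1), (1, 1))
_STENCILS = {"six": SIX_NEIGHBORHOOD, "four": FOUR_NEIGHBORHOOD,
             "eight": EIGHT_NEIGHBORHOOD}


@dataclass
class TargetResult:
    """A selected stimulation site with scalp, cortical and MNI coordinates."""

    cpc: CPCCoordinate
    scalp_xyz: np.ndarray
    cortex_xyz: np.ndarray
    mni_xyz: np.ndarray
    method: str
    nta: float
    top_percent: float | None = None
    cluster_size: int | None = None
    cortex_fallback: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("scalp_xyz", "cortex_xyz", "mni_xyz"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def to_dict(self) -> dict:
        return {
            "p_nz": self.cpc.p_nz, "p_al": self.cpc.p_al,
            "scalp_xyz": self.scalp_xyz.tolist(),
            "cortex_xyz": self.cortex_xyz.tolist(),
            "mni_xyz": self.mni_xyz.tolist(),
            "method": self.method, "nta": self.nta,
            "top_percent": self.top_percent, "cluster_size": self.cluster_size,
            "cortex_fallback": self.cortex_fallback,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_row(self) -> pd.DataFrame:
        d = self.to_dict()
        for axis, v in zip("xyz", d.pop("mni_xyz")):
            d[f"mni_{axis}"] = v
        d.pop("scalp_xyz"), d.pop("cortex_xyz")
        return pd.DataFrame([d])


def _attach_projections(head: HeadModel, cpc: CPCCoordinate, method: str,
                        nta: float, **kw) -> TargetResult:
    site = cpc_to_scalp(head, cpc)
    cortex, fallback = project_to_cortex(head, site)
    return TargetResult(cpc=cpc, scalp_xyz=site.position, cortex_xyz=cortex,
                        mni_xyz=to_mni(head, cortex), method=method, nta=nta,
                        cortex_fallback=fallback, **kw)


def classic_target(nta_map: NTAMap, head: HeadModel) -> TargetResult:
    """Argmax of the NTA map; ties broken by lowest (i, j) lexicographically."""
    if nta_map.n_valid < 1:
        raise ValueError("NTA map has no valid nodes")
    best = np.nanmax(np.where(nta_map.valid, nta_map.values, -np.inf))
    ties = np.argwhere(nta_map.valid & (nta_map.values == best))
    i, j = min(map(tuple, ties))
    return _attach_projections(head, nta_map.space.cpc(i, j), "classic", float(best))


def _threshold_value(nta_map: NTAMap, top_percent: float) -> float:
    if not (0.0 < top_percent <= 100.0):
        raise ValueError("top_percent must lie in (0, 100]")
    vals = nta_map.values[nta_map.valid]
    if vals.size == 0:
        raise ValueError("NTA map has no valid nodes")
    return float(np.percentile(vals, 100.0 - top_percent))


def label_clusters(nta_map: NTAMap, top_percent: float,
                   neighborhood: str = "six") -> np.ndarray:
    """Connected components of the supra-threshold node set.

    The threshold is the (100 - top_percent) percentile of valid-node NTA
    values (linear interpolation); nodes with NTA >= threshold are labeled by
    flood fill under the chosen stencil.  Returns an int grid: -1 below
    threshold / invalid, otherwise a 0-based cluster id.
    """
    offsets = _STENCILS[neighborhood]
    thr = _threshold_value(nta_map, top_percent)
    supra = nta_map.valid & (nta_map.values >= thr)
    if not supra.any():
        raise ValueError("supra-threshold node set is empty")
    labels = np.full(nta_map.space.shape, -1, dtype=int)
    next_id = 0
    for seed in map(tuple, np.argwhere(supra)):
        if labels[seed] != -1:
            continue
        stack = [seed]
        labels[seed] = next_id
        while stack:
            ci, cj = stack.pop()
            for di, dj in offsets:
                ni, nj = ci + di, cj + dj
                if (0 <= ni < labels.shape[0] and 0 <= nj < labels.shape[1]
                        and supra[ni, nj] and labels[ni, nj] == -1):
                    labels[ni, nj] = next_id
                    stack.append((ni, nj))
        next_id += 1
    return labels


def cluster_target(nta_map: NTAMap, head: HeadModel, top_percent: float = 5.0,
                   neighborhood: str = "six",
                   weighted_centroid: bool = True) -> TargetResult:
    """Center-of-gravity of the largest supra-threshold cluster.

    The largest cluster is chosen by node count (ties: larger NTA sum, then
    lowest lexicographic minimum node).  The target CPC is the NTA-weighted
    mean of member CPC coordinates, with weights the members' NTA excess over
    the threshold (uniform weights if all excesses vanish or
    ``weighted_centroid=False``); it need not be a grid node.
    """
    labels = label_clusters(nta_map, top_percent, neighborhood)
    thr = _threshold_value(nta_map, top_percent)
    best_key, best_members = None, None
    for cid in range(labels.max() + 1):
        members = np.argwhere(labels == cid)
        nta_sum = float(nta_map.values[labels == cid].sum())
        key = (len(members), nta_sum,
               tuple(-m for m in min(map(tuple, members))))
        if best_key is None or key > best_key:
            best_key, best_members = key, members
    members = best_members
    nta_vals = nta_map.values[members[:, 0], members[:, 1]]
    w = np.maximum(nta_vals - thr, 0.0) if weighted_centroid else np.ones(len(members))
    if w.sum() <= 0:
        w = np.ones(len(members))
    w = w / w.sum()
    p_nz = float(w @ nta_map.space.nz_values[members[:, 0]])
    p_al = float(w @ nta_map.space.al_values[members[:, 1]])
    return _attach_projections(
        head, CPCCoordinate(p_nz, p_al), "cluster", float(nta_vals.max()),
        top_percent=top_percent, cluster_size=len(members))
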