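"""Test–retest stability of the personalized targeting model.

Three instability indices are computed between two sessions of the same
person: the correlation of per-placement stimulation networks, the
correlation of NTA maps, and the intraindividual distance (MNI mm) between
the cortical projections of the two selected targets.  Across people, the
interindividual distance and the inter/intra distance ratio quantify whether
personalization preserves between-subject spread while suppressing
within-subject noise; a target is called stable when its intraindividual
distance falls below the ~1 cm spatial sensitivity of TMS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .connectivity import BrainMap, TimeSeries, bandpass, concatenate_runs, \
    crop_duration, standardize
from .efield import EFieldParams, GrayMatterMask, search_space_fields
from .headgeom import HeadModel, SearchSpace
from .nta import NTAMap, nta_map_from_networks, stimulation_networks
from .targeting import TargetResult, classic_target, cluster_target

__all__ = [
    "SubjectRecord",
    "StabilityReport",
    "pattern_similarity",
    "intra_distance",
    "inter_distance",
    "distance_ratio",
    "duration_stability_curve",
    "STABILITY_THRESHOLD_MM",
]

log = logging.getLogger(__name__)

STABILITY_THRESHOLD_MM = 10.0  # "~1 cm" spatial sensitivity of TMS
DEFAULT_DURATIONS_MIN = (7.0, 14.0, 21.0, 28.0)


@dataclass
class SubjectRecord:
    """One subject's inputs for stability evaluation.

    ``sessions`` holds, per session (e.g. day 1 / day 2), the list of runs to
    be temporally concatenated.
    """

    subject_id: str
    head: HeadModel
    mask: GrayMatterMask
    sessions: list[list[TimeSeries]]
    patho: BrainMap


def _as_vector(m: BrainMap | NTAMap | np.ndarray) -> np.ndarray:
    if isinstance(m, BrainMap):
        return m.values
    if isinstance(m, NTAMap):
        return m.values[m.valid]
    return np.asarray(m, dtype=float)


def pattern_similarity(a, b) -> float:
    """Pearson correlation between two maps over their common valid entries."""
    if isinstance(a, NTAMap) and isinstance(b, NTAMap):
        common = a.valid & b.valid
        va, vb = a.values[common], b.values[common]
    else:
        va, vb = _as_vector(a), _as_vector(b)
    if va.shape != vb.shape:
        raise ValueError("maps must share the same support")
    if len(va) < 3:
        raise ValueError("fewer than 3 common entries")
    va = va - va.mean()
    vb = vb - vb.mean()
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na < 1e-14 or nb < 1e-14:
        raise ValueError("similarity undefined for a constant map")
    return float(np.clip((va @ vb) / (na * nb), -1.0, 1.0))


def intra_distance(head: HeadModel, t1: TargetResult, t2: TargetResult) -> float:
    """Distance (mm) between two sessions' targets in MNI space."""
    for t in (t1, t2):
        if t.mni_xyz is None or len(np.atleast_1d(t.mni_xyz)) != 3:
            raise ValueError("target is missing its MNI projection")
    return float(np.linalg.norm(t1.mni_xyz - t2.mni_xyz))


def inter_distance(targets: Sequence[TargetResult], to_centroid: bool = False) -> float:
    """Across-subject target spread in MNI space (mm).

    Default: mean Euclidean distance over all unordered subject pairs;
    ``to_centroid=True`` gives the mean distance to the cohort centroid.
    """
    if len(targets) < 2:
        raise ValueError("interindividual distance needs at least 2 subjects")
    pts = np.array([t.mni_xyz for t in targets])
    if to_centroid:
        return float(np.mean(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
    return float(np.mean([np.linalg.norm(p - q) for p, q in combinations(pts, 2)]))


def distance_ratio(inter_mm: float, intra_mm_mean: float) -> float:
    """Ratio of interindividual to mean intraindividual distance."""
    if intra_mm_mean <= 0:
        raise ValueError("intraindividual distance mean must be positive "
                         "(degenerate case; report separately)")
    return inter_mm / intra_mm_mean


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


@dataclass
class StabilityReport:
    """Tidy per-subject indices plus duration x method summary."""

    per_subject: pd.DataFrame
    summary: pd.DataFrame
    threshold_mm: float = STABILITY_THRESHOLD_MM

    def save(self, directory: str | Path, prefix: str = "stability") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.per_subject.to_csv(directory / f"{prefix}_per_subject.csv", index=False)
        self.summary.to_csv(directory / f"{prefix}_summary.csv", index=False)


def _select_target(nta_map: NTAMap, head: HeadModel, method: str,
                   top_percent: float) -> TargetResult:
    if method == "classic":
        return classic_target(nta_map, head)
    if method == "cluster":
        return cluster_target(nta_map, head, top_percent=top_percent)
    raise ValueError(f"unknown targeting method: {method}")


def duration_stability_curve(
    cohort: Iterable[SubjectRecord],
    space: SearchSpace,
    durations_min: Sequence[float] = DEFAULT_DURATIONS_MIN,
    methods: Sequence[str] = ("classic", "cluster"),
    efield_params: EFieldParams = EFieldParams(),
    orientation_deg: float = 45.0,
    top_percent: float = 5.0,
    apply_bandpass: bool = True,
    threshold_mm: float = STABILITY_THRESHOLD_MM,
    preprocess: Callable[[TimeSeries], TimeSeries] | None = None,
) -> StabilityReport:
    """Stability indices as a function of scan duration and targeting method.

    Per subject and duration, each session's runs are concatenated, cropped
    to the duration, band-passed (0.01-0.1 Hz) and standardized; stimulation
    networks and NTA maps are computed for both sessions, the three
    instability indices derived, and targets selected with every method.
    Per duration x method the interindividual distance (per session,
    averaged), the inter/intra ratio, mean +/- SEM of each index and the
    stable/unstable counts at ``threshold_mm`` are summarized.

    Subjects with fewer than two usable sessions are skipped with a log
    entry; if all subjects are skipped an error is raised.
    """
    rows = []
    # MNI targets per (duration, method, session) for interindividual spread
    mni_targets: dict[tuple[float, str, int], list[np.ndarray]] = {}
    fields_cache: dict[int, dict] = {}
    n_seen = 0
    for rec in cohort:
        n_seen += 1
        if len(rec.sessions) < 2:
            log.warning("subject %s skipped: %d session(s), need 2",
                        rec.subject_id, len(rec.sessions))
            continue
        key = id(rec.head)
        if key not in fields_cache:
            fields_cache[key] = search_space_fields(
                rec.head, rec.mask, space, efield_params, orientation_deg)
        fields = fields_cache[key]
        subj_rows: list[dict] = []
        subj_targets: dict[tuple[float, str, int], np.ndarray] = {}
        try:
            sessions = [concatenate_runs(runs) for runs in rec.sessions[:2]]
            for dur in durations_min:
                nets, maps, targets = [], [], {m: [] for m in methods}
                for sess_idx, sess_ts in enumerate(sessions):
                    ts = crop_duration(sess_ts, dur)
                    if preprocess is not None:
                        ts = preprocess(ts)
                    if apply_bandpass:
                        ts = bandpass(ts)
                    ts_std, _ = standardize(ts)
                    S, keys = stimulation_networks(ts_std, fields)
                    nets.append(S)
                    maps.append(nta_map_from_networks(S, keys, space, rec.patho))
                    for m in methods:
                        tgt = _select_target(maps[-1], rec.head, m, top_percent)
                        targets[m].append(tgt)
                        subj_targets[(dur, m, sess_idx)] = tgt.mni_xyz
                net_sim = float(np.mean([
                    pattern_similarity(nets[0][:, k], nets[1][:, k])
                    for k in range(nets[0].shape[1])]))
                map_sim = pattern_similarity(maps[0], maps[1])
                for m in methods:
                    subj_rows.append({
                        "subject": rec.subject_id, "duration_min": dur, "method": m,
                        "network_similarity": net_sim, "map_similarity": map_sim,
                        "intra_mm": intra_distance(rec.head, *targets[m]),
                    })
        except ValueError as exc:
            log.warning("subject %s skipped: %s", rec.subject_id, exc)
            continue
        rows.extend(subj_rows)
        for key2, mni in subj_targets.items():
            mni_targets.setdefault(key2, []).append(mni)
    per_subject = pd.DataFrame(rows)
    if per_subject.empty:
        raise ValueError(f"no usable subjects (saw {n_seen})")

    summary_rows = []
    for dur in durations_min:
        for m in methods:
            sub = per_subject[(per_subject.duration_min == dur) & (per_subject.method == m)]
            subjects_kept = set(sub.subject)
            inter_vals = []
            for sess_idx in (0, 1):
                pts = mni_targets.get((dur, m, sess_idx), [])
                if len(pts) >= 2:
                    inter_vals.append(float(np.mean([
                        np.linalg.norm(p - q) for p, q in combinations(pts, 2)])))
            inter = float(np.mean(inter_vals)) if inter_vals else float("nan")
            intra_mean = float(sub.intra_mm.mean())
            summary_rows.append({
                "duration_min": dur, "method": m, "n_subjects": len(subjects_kept),
                "network_similarity_mean": float(sub.network_similarity.mean()),
                "network_similarity_sem": _sem(sub.network_similarity.to_numpy()),
                "map_similarity_mean": float(sub.map_similarity.mean()),
                "map_similarity_sem": _sem(sub.map_similarity.to_numpy()),
                "intra_mm_mean": intra_mean,
                "intra_mm_sem": _sem(sub.intra_mm.to_numpy()),
                "inter_mm": inter,
                "ratio": (inter / intra_mean) if intra_mean > 0 else float("nan"),
                "n_stable": int((sub.intra_mm < threshold_mm).sum()),
                "n_unstable": int((sub.intra_mm >= threshold_mm).sum()),
            })
    return StabilityReport(per_subject=per_subject,
                           summary=pd.DataFrame(summary_rows),
                           threshold_mm=threshold_mm)


def plot_duration_curves(report: StabilityReport, path: str | Path) -> None:
    """Similarity and intra-distance versus scan duration, one panel each."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    s = report.summary
    for m, sub in s.groupby("method"):
        axes[0].errorbar(sub.duration_min, sub.network_similarity_mean,
                         yerr=sub.network_similarity_sem, label=m, marker="o")
        axes[1].errorbar(sub.duration_min, sub.map_similarity_mean,
                         yerr=sub.map_similarity_sem, label=m, marker="o")
        axes[2].errorbar(sub.duration_min, sub.intra_mm_mean,
                         yerr=sub.intra_mm_sem, label=m, marker="o")
    axes[2].axhline(report.threshold_mm, ls="--", c="gray", lw=1)
    for ax, ylab in zip(axes, ["network similarity (r)", "NTA-map similarity (r)",
                               "intraindividual distance (mm)"]):
        ax.set_xlabel("scan duration (min)")
        ax.set_ylabel(ylab)
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
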