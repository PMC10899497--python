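"""Synthetic cohorts with known ground truth.

A latent-factor Gaussian model generates resting-state BOLD with controlled
network structure: K network topographies (von Mises–Fisher-like bumps on a
spherical cortex) load a K-dimensional latent signal with covariance C, plus
a spatially smooth local field and voxel-wise noise.  The implied
voxel-voxel covariance A C A^T + local_sd^2 G G^T + diag(v) is available in
closed form, so seed maps, pathological maps and ground-truth
targets can be computed exactly and compared with what the estimation
pipeline recovers from finite scans.  Latent signals and noise are filtered
to the 0.01-0.1 Hz band so that sample correlations carry the realistic
autocorrelation that makes scan duration matter.

Inter-individual variability is injected by jittering each subject's network
centers on the sphere by a configurable angular sd; a planted pathology
network is anti-correlated (negative entry of C) with the target network, so
the NTA-optimal placement sits over the target network by construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import trimesh
import yaml
from scipy import signal as sp_signal

from .connectivity import BrainMap, TimeSeries, _band_sos, load_run
from .efield import GrayMatterMask
from .headgeom import HeadModel, SearchSpace, closest_point, load_head_model, \
    save_head_model
from .stability import SubjectRecord
from .targeting import TargetResult, classic_target

__all__ = [
    "SyntheticCohortConfig",
    "LatentFCModel",
    "make_spherical_head",
    "build_smoother",
    "sample_subject_model",
    "patho_map",
    "implied_seed_maps",
    "ground_truth_target",
    "noiseless_nta_map",
    "simulate_bold",
    "cohort_records",
    "generate_cohort",
    "load_cohort",
]

# canonical CPC positions of the network-bump centers; index 0 is the target
# network (under the default frontal search space), the last is the planted
# pathology source
_NETWORK_CPC = [(0.29, 0.35), (0.29, 0.65), (0.72, 0.35), (0.55, 0.50),
                (0.10, 0.50), (0.85, 0.50), (0.45, 0.15)]
# the pathology network is multi-focal, like meta-analytic disorder maps
_PATHO_FOCI_CPC = [(0.75, 0.68), (0.62, 0.75), (0.85, 0.60), (0.70, 0.55),
                   (0.60, 0.62)]


@dataclass
class SyntheticCohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate a two-day, two-runs-per-day HCP-style retest design:
    1200-volume runs at TR 0.72 s, concatenating to 28 minutes per session.
    ``noise_sd`` is the band-limited voxel noise sd relative to unit-amplitude
    network bumps; ``jitter_deg`` the angular sd of subject-specific network
    topography on the sphere.
    """

    n_subjects: int = 12
    n_networks: int = 5
    scalp_radius_mm: float = 92.0
    cortex_radius_mm: float = 78.0
    subdiv: int = 4
    grid_mm: float = 6.0
    shell_mm: float = 2.0
    jitter_deg: float = 6.0
    neg_coupling: float = -0.9
    bump_kappa: float = 200.0
    patho_kappa: float = 30.0
    local_sd: float = 0.25
    local_smooth_mm: float = 12.0
    sessions_per_subject: int = 2
    runs_per_session: int = 2
    run_volumes: int = 1200
    tr_seconds: float = 0.72
    noise_sd: float = 3.0
    base_seed: int = 1234

    def __post_init__(self) -> None:
        counts = (self.n_subjects, self.n_networks, self.sessions_per_subject,
                  self.runs_per_session, self.run_volumes, self.subdiv)
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be positive")
        if self.tr_seconds <= 0 or self.jitter_deg < 0:
            raise ValueError("tr_seconds must be positive and jitter_deg >= 0")
        if self.cortex_radius_mm >= self.scalp_radius_mm:
            raise ValueError("cortex must lie inside the scalp")
        if not (-1.0 < self.neg_coupling < 0.0):
            raise ValueError("neg_coupling must lie in (-1, 0)")


@dataclass
class LatentFCModel:
    """Latent-factor ground truth for one subject's functional connectivity.

    The implied voxel covariance is

        Sigma = A C A^T + local_sd^2 G G^T + diag(noise_var)

    with A the network loadings, C the network covariance, G a sparse
    row-unit-norm spatial smoother realizing a local "background connectome"
    (short-range FC that travels with the seed), and ``noise_var`` the
    observation-noise variance.  ``smoother`` columns refer to the full-mask
    voxel set even when the model is restricted to a subset of rows.
    """

    loadings: np.ndarray        # V x K network topographies
    network_cov: np.ndarray     # K x K positive definite
    noise_var: np.ndarray       # per-voxel observation-noise variance
    pathology_index: int
    centers: np.ndarray         # K x 3 unit directions of bump centers
    local_sd: float = 0.0
    smoother: object | None = None  # scipy.sparse V x V_full

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.network_cov = np.asarray(self.network_cov, dtype=float)
        self.noise_var = np.asarray(self.noise_var, dtype=float)
        if np.any(np.linalg.eigvalsh(self.network_cov) <= 0):
            raise ValueError("network covariance must be positive definite")
        if np.any(self.noise_var < 0):
            raise ValueError("noise variances must be nonnegative")
        if self.local_sd > 0 and self.smoother is None:
            raise ValueError("local_sd > 0 requires a spatial smoother")

    @property
    def n_voxels(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_networks(self) -> int:
        return self.loadings.shape[1]

    def implied_variance(self) -> np.ndarray:
        """Diagonal of the implied voxel covariance."""
        d = np.einsum("vk,kl,vl->v", self.loadings, self.network_cov,
                      self.loadings) + self.noise_var
        if self.local_sd > 0:
            d = d + self.local_sd**2  # smoother rows have unit norm
        return d

    def implied_covariance(self) -> np.ndarray:
        """Full implied V x V covariance matrix (small V only)."""
        cov = self.loadings @ self.network_cov @ self.loadings.T + np.diag(self.noise_var)
        if self.local_sd > 0:
            G = self.smoother
            cov = cov + self.local_sd**2 * np.asarray((G @ G.T).todense())
        return cov

    def implied_correlation(self) -> np.ndarray:
        """Full implied V x V correlation matrix (small V only)."""
        cov = self.implied_covariance()
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def subset(self, voxel_idx: np.ndarray) -> "LatentFCModel":
        """Restrict the model to a subset of voxels (same latent structure)."""
        idx = np.asarray(voxel_idx, dtype=int)
        return LatentFCModel(loadings=self.loadings[idx],
                             network_cov=self.network_cov,
                             noise_var=self.noise_var[idx],
                             pathology_index=self.pathology_index,
                             centers=self.centers,
                             local_sd=self.local_sd,
                             smoother=None if self.smoother is None
                             else self.smoother[idx])


def _sphere_cpc_direction(p_nz: float, p_al: float) -> np.ndarray:
    """Closed-form CPC-to-unit-direction on a fiducial-aligned sphere."""
    theta, phi = np.pi * p_nz, np.pi * p_al
    sagittal = np.array([0.0, np.cos(theta), np.sin(theta)])
    return np.cos(phi) * np.array([-1.0, 0.0, 0.0]) + np.sin(phi) * sagittal


def make_spherical_head(scalp_r: float = 92.0, cortex_r: float = 78.0,
                        subdiv: int = 4, grid_mm: float = 6.0,
                        shell_mm: float = 2.0,
                        mni_affine: np.ndarray | None = None
                        ) -> tuple[HeadModel, GrayMatterMask]:
    """Concentric icosphere head with canonical fiducials and a shell mask.

    Fiducials sit at the equatorial axis points (NZ +y, IZ -y, AL -x, AR +x),
    snapped onto the scalp mesh.  The gray-matter mask holds voxels of a
    regular ``grid_mm`` grid whose centers lie within ``shell_mm`` of the
    cortex sphere.
    """
    if subdiv < 1:
        raise ValueError("subdiv must be >= 1")
    if cortex_r >= scalp_r:
        raise ValueError("cortex radius must be smaller than scalp radius")
    scalp = trimesh.creation.icosphere(subdivisions=subdiv, radius=scalp_r)
    cortex = trimesh.creation.icosphere(subdivisions=subdiv, radius=cortex_r)
    canon = {"NZ": [0.0, scalp_r, 0.0], "IZ": [0.0, -scalp_r, 0.0],
             "AL": [-scalp_r, 0.0, 0.0], "AR": [scalp_r, 0.0, 0.0]}
    snapped, _, _ = closest_point(scalp, np.array(list(canon.values())))
    fiducials = dict(zip(canon, snapped))

    extent = cortex_r + shell_mm + grid_mm
    n = int(np.ceil(2 * extent / grid_mm)) + 1
    affine = np.eye(4)
    affine[:3, :3] *= grid_mm
    affine[:3, 3] = -grid_mm * (n - 1) / 2.0
    ax = affine[0, 3] + grid_mm * np.arange(n)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    radius = np.sqrt(X**2 + Y**2 + Z**2)
    inside = np.abs(radius - cortex_r) <= shell_mm
    mask = GrayMatterMask(shape=(n, n, n), affine=affine,
                          indices=np.flatnonzero(inside.reshape(-1)))
    head = HeadModel(scalp=scalp, cortex=cortex, fiducials=fiducials,
                     mni_affine=np.eye(4) if mni_affine is None else mni_affine)
    return head, mask


def _network_cov(config: SyntheticCohortConfig) -> np.ndarray:
    C = np.eye(config.n_networks)
    if config.n_networks >= 2:
        C[0, -1] = C[-1, 0] = config.neg_coupling
    return C


def _jitter_direction(c: np.ndarray, rng: np.random.Generator,
                      sd_rad: float) -> np.ndarray:
    """Rotate a unit direction by a Gaussian angle about a random tangent."""
    t = rng.standard_normal(3)
    t -= (t @ c) * c
    t /= max(np.linalg.norm(t), 1e-12)
    angle = rng.normal(0.0, sd_rad)
    return np.cos(angle) * c + np.sin(angle) * t


def build_smoother(mask: GrayMatterMask, length_mm: float):
    """Sparse Gaussian spatial smoother over mask voxels, unit row norms.

    Row u holds exp(-d(u, v)^2 / (2 length^2)) for voxels within 2.5 lengths,
    normalized so that the implied local covariance G G^T has unit diagonal.
    """
    from scipy import sparse
    from scipy.spatial import cKDTree

    pos = mask.world_coords()
    tree = cKDTree(pos)
    pairs = tree.query_ball_tree(tree, 2.5 * length_mm)
    rows, cols, vals = [], [], []
    for u, nbrs in enumerate(pairs):
        nbrs = np.asarray(nbrs)
        d2 = np.einsum("ij,ij->i", pos[nbrs] - pos[u], pos[nbrs] - pos[u])
        w = np.exp(-d2 / (2.0 * length_mm**2))
        w /= np.linalg.norm(w)
        rows.extend([u] * len(nbrs))
        cols.extend(nbrs)
        vals.extend(w)
    return sparse.csr_matrix((vals, (rows, cols)),
                             shape=(mask.n_voxels, mask.n_voxels))


def sample_subject_model(config: SyntheticCohortConfig, subject_id: int,
                         head: HeadModel | None = None,
                         mask: GrayMatterMask | None = None,
                         smoother=None) -> LatentFCModel:
    """Subject-specific latent FC model: jittered bump centers on the cortex.

    Seeded by ``(base_seed, subject_id)``; zero jitter makes all subjects
    share identical loadings.
    """
    if head is None or mask is None:
        head, mask = make_spherical_head(
            config.scalp_radius_mm, config.cortex_radius_mm, config.subdiv,
            config.grid_mm, config.shell_mm)
    if smoother is None and config.local_sd > 0:
        smoother = build_smoother(mask, config.local_smooth_mm)
    rng = np.random.default_rng([config.base_seed, subject_id])
    jitter = np.deg2rad(config.jitter_deg)

    k = config.n_networks
    if k - 1 > len(_NETWORK_CPC):
        raise ValueError(f"at most {len(_NETWORK_CPC) + 1} networks supported")
    focal = [np.array(_sphere_cpc_direction(*c)) for c in _NETWORK_CPC[:k - 1]]
    centers = np.array([_jitter_direction(c, rng, jitter) for c in focal]
                       + [np.zeros(3)])[:k]

    dirs = mask.world_coords()
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    loadings = np.empty((mask.n_voxels, k))
    for col, c in enumerate(centers[:k - 1] if k > 1 else []):
        cosg = np.clip(dirs @ c, -1.0, 1.0)
        loadings[:, col] = np.exp(config.bump_kappa * (cosg - 1.0))
    # multi-focal pathology topography, one jittered bump per focus
    patho = np.zeros(mask.n_voxels)
    for cpc in _PATHO_FOCI_CPC:
        d = _jitter_direction(_sphere_cpc_direction(*cpc), rng, jitter)
        patho += np.exp(config.patho_kappa * (np.clip(dirs @ d, -1.0, 1.0) - 1.0))
    loadings[:, k - 1] = patho / patho.max()
    centers[k - 1] = _sphere_cpc_direction(*_PATHO_FOCI_CPC[0])
    return LatentFCModel(loadings=loadings, network_cov=_network_cov(config),
                         noise_var=np.full(mask.n_voxels, config.noise_sd**2),
                         pathology_index=config.n_networks - 1,
                         centers=centers, local_sd=config.local_sd,
                         smoother=smoother)


def patho_map(model: LatentFCModel) -> BrainMap:
    """Pathological network map: noiseless seed map of the pathology peak.

    P is the signal-level implied-correlation row of the voxel with the
    strongest pathology-network loading; remote anti-correlation arises from
    the negative network-covariance entry.  Observation noise is excluded —
    the map stands for a meta-analytic group map, not a noisy subject-level
    estimate — so P is invariant to the scan-noise settings.
    """
    clean = replace(model, noise_var=np.zeros(model.n_voxels))
    v_star = int(np.argmax(model.loadings[:, model.pathology_index]))
    w = np.zeros(model.n_voxels)
    w[v_star] = 1.0
    return BrainMap(values=implied_seed_maps(clean, w[:, None])[:, 0],
                    tag="pathological")


def implied_seed_maps(model: LatentFCModel, W: np.ndarray) -> np.ndarray:
    """Weighted averages of implied-correlation rows, one column per weight set.

    Columns of W are sum-normalized; the result equals R @ w~ with R the
    implied correlation matrix, computed without materializing it.
    """
    W = np.asarray(W, dtype=float)
    W = W / W.sum(axis=0, keepdims=True)
    d = np.sqrt(model.implied_variance())
    X = W / d[:, None]
    cov_x = model.loadings @ (model.network_cov @ (model.loadings.T @ X)) \
        + model.noise_var[:, None] * X
    if model.local_sd > 0:
        cov_x = cov_x + model.local_sd**2 * (model.smoother @ (model.smoother.T @ X))
    return cov_x / d[:, None]


def noiseless_nta_map(model: LatentFCModel, space: SearchSpace,
                      fields: dict, P: BrainMap):
    """NTA map computed from the model's implied (noiseless) correlation."""
    from .nta import nta_map_from_networks
    keys = sorted(fields)
    W = np.zeros((model.n_voxels, len(keys)))
    for col, key in enumerate(keys):
        efw = fields[key]
        W[efw.support, col] = efw.values
    S = implied_seed_maps(model, W)
    return nta_map_from_networks(S, keys, space, P,
                                 provenance={"source": "implied-correlation"})


def ground_truth_target(model: LatentFCModel, head: HeadModel,
                        space: SearchSpace, fields: dict,
                        P: BrainMap) -> TargetResult:
    """Planted truth: classic target of the noiseless NTA map."""
    return classic_target(noiseless_nta_map(model, space, fields, P), head)


_GAIN_CACHE: dict[tuple, float] = {}


def _band_gain(tr: float, low: float, high: float) -> float:
    """RMS gain of the zero-phase band-pass on white noise (analytic)."""
    key = (round(tr, 9), low, high)
    if key not in _GAIN_CACHE:
        sos = _band_sos(low, high, tr)
        _, h = sp_signal.sosfreqz(sos, worN=8192, fs=1.0 / tr)
        # filtfilt applies |H|^2; mean power of filtered white noise
        _GAIN_CACHE[key] = float(np.sqrt(np.mean(np.abs(h) ** 4)))
    return _GAIN_CACHE[key]


def _band_limit_rows(rows: np.ndarray, tr: float,
                     low: float = 0.01, high: float = 0.1) -> np.ndarray:
    """Filter rows to the band and rescale to unit stationary variance.

    The rescaling uses the filter's analytic white-noise gain, not each row's
    realized sd: pinning realized variances would make full runs statistically
    special relative to partial-run crops downstream.
    """
    sos = _band_sos(low, high, tr)
    padlen = min(rows.shape[1] - 2, int(round(3.0 / (low * tr))))
    out = sp_signal.sosfiltfilt(sos, rows, axis=1, padlen=max(padlen, 0))
    return out / _band_gain(tr, low, high)


def simulate_bold(model: LatentFCModel, n_volumes: int, tr: float = 0.72,
                  noise_sd: float | None = None, run_seed=0) -> TimeSeries:
    """One synthetic BOLD run: x(t) = A s(t) + e(t).

    The run realizes every model component: network latents s (covariance
    ``network_cov``), the local smooth field, and observation noise scaled to
    ``noise_sd`` (default: the model's own noise sd).  All stochastic terms
    are band-limited to 0.01-0.1 Hz, so sample correlations converge to the
    model's implied correlation as T grows while carrying realistic
    autocorrelation.  Bitwise deterministic for a fixed ``run_seed``.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    rng = np.random.default_rng(run_seed)
    K, V = model.n_networks, model.n_voxels
    # burn-in on both sides so the retained interior is stationary: filtering
    # a short segment directly would let the boundary padding inflate the
    # realized autocorrelation
    burn = int(round(3.0 / (0.01 * tr)))

    def band_limited(dim: int) -> np.ndarray:
        x = _band_limit_rows(rng.standard_normal((dim, n_volumes + 2 * burn)), tr)
        return x[:, burn:burn + n_volumes]

    latents = band_limited(K)
    L = np.linalg.cholesky(model.network_cov)
    data = model.loadings @ (L @ latents)
    if model.local_sd > 0:
        data = data + model.local_sd * (model.smoother @ band_limited(
            model.smoother.shape[1]))
    if noise_sd is None:
        sd = np.sqrt(model.noise_var)[:, None]
    else:
        sd = float(noise_sd)
    data = data + sd * band_limited(V)
    return TimeSeries(data=data, tr_seconds=tr)


def simulate_session(model: LatentFCModel, config: SyntheticCohortConfig,
                     subject_id: int, session: int,
                     noise_sd: float | None = None) -> list[TimeSeries]:
    """One scan session as a list of runs.

    The session is simulated as a single continuous realization (seeded by
    ``(base_seed, subject, session)``) and cut into equal-length runs: cutting
    rather than simulating runs separately keeps the spliced series
    stationary, so re-concatenation introduces no boundary artifacts.
    """
    total = config.run_volumes * config.runs_per_session
    ts = simulate_bold(model, total, config.tr_seconds, noise_sd,
                       run_seed=[config.base_seed, subject_id, session])
    return [TimeSeries(data=ts.data[:, r * config.run_volumes:
                                    (r + 1) * config.run_volumes],
                       tr_seconds=ts.tr_seconds)
            for r in range(config.runs_per_session)]


def cohort_records(config: SyntheticCohortConfig,
                   noise_sd: float | None = None):
    """Yield in-memory :class:`SubjectRecord` objects, one subject at a time.

    Run seeds are ``(base_seed, subject, session, run)`` so every run is
    reproducible in isolation.  The head and mask are shared across subjects.
    """
    head, mask = make_spherical_head(
        config.scalp_radius_mm, config.cortex_radius_mm, config.subdiv,
        config.grid_mm, config.shell_mm)
    smoother = build_smoother(mask, config.local_smooth_mm) if config.local_sd > 0 else None
    for sid in range(config.n_subjects):
        model = sample_subject_model(config, sid, head, mask, smoother)
        sessions = []
        for sess in range(config.sessions_per_subject):
            sessions.append(simulate_session(model, config, sid, sess, noise_sd))
        yield SubjectRecord(subject_id=f"sub-{sid:02d}", head=head, mask=mask,
                            sessions=sessions, patho=patho_map(model))


def subject_models(config: SyntheticCohortConfig):
    """Ground-truth models for every subject (shared head and mask)."""
    head, mask = make_spherical_head(
        config.scalp_radius_mm, config.cortex_radius_mm, config.subdiv,
        config.grid_mm, config.shell_mm)
    smoother = build_smoother(mask, config.local_smooth_mm) if config.local_sd > 0 else None
    return head, mask, [sample_subject_model(config, sid, head, mask, smoother)
                        for sid in range(config.n_subjects)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def generate_cohort(config: SyntheticCohortConfig, out_dir: str | Path) -> Path:
    """Write a fully reproducible cohort fixture directory.

    Per subject: head surfaces (ASCII PLY + JSON sidecar), gray-matter mask
    and pathology map (NIfTI), one 4-D NIfTI per run, and the planted
    ground-truth model summary.  A manifest (YAML) records the configuration
    and file checksums.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    head, mask = make_spherical_head(
        config.scalp_radius_mm, config.cortex_radius_mm, config.subdiv,
        config.grid_mm, config.shell_mm)
    manifest = {"config": asdict(config), "subjects": {}}
    smoother = build_smoother(mask, config.local_smooth_mm) if config.local_sd > 0 else None
    for sid in range(config.n_subjects):
        sdir = out / f"sub-{sid:02d}"
        sdir.mkdir(exist_ok=True)
        model = sample_subject_model(config, sid, head, mask, smoother)
        save_head_model(head, sdir)
        mask.to_nifti().to_filename(str(sdir / "mask.nii"))
        patho = patho_map(model)
        patho.to_nifti(mask).to_filename(str(sdir / "pathology.nii"))
        entry = {"runs": {}, "sessions": config.sessions_per_subject}
        for sess in range(config.sessions_per_subject):
            runs = simulate_session(model, config, sid, sess)
            for run, ts in enumerate(runs):
                vol = np.zeros((int(np.prod(mask.shape)), ts.n_volumes),
                               dtype=np.float32)
                vol[mask.indices] = ts.data.astype(np.float32)
                img = nib.Nifti1Image(vol.reshape(*mask.shape, ts.n_volumes),
                                      mask.affine)
                fname = f"ses-{sess + 1}_run-{run + 1}_bold.nii"
                img.to_filename(str(sdir / fname))
                entry["runs"][f"ses-{sess + 1}/run-{run + 1}"] = {
                    "file": fname, "sha256": _sha256(sdir / fname)}
        gt = {"pathology_index": model.pathology_index,
              "centers": model.centers.tolist()}
        (sdir / "ground_truth.json").write_text(json.dumps(gt, indent=2))
        manifest["subjects"][f"sub-{sid:02d}"] = entry
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return out


def load_cohort(cohort_dir: str | Path):
    """Yield :class:`SubjectRecord` objects from a fixture directory."""
    cohort_dir = Path(cohort_dir)
    manifest = yaml.safe_load((cohort_dir / "manifest.yaml").read_text())
    cfg = manifest["config"]
    for sub in sorted(manifest["subjects"]):
        sdir = cohort_dir / sub
        head = load_head_model(sdir)
        mask = GrayMatterMask.from_nifti(sdir / "mask.nii")
        patho = BrainMap.from_nifti(sdir / "pathology.nii", mask, tag="pathological")
        sessions = []
        for sess in range(int(cfg["sessions_per_subject"])):
            runs = [load_run(sdir / f"ses-{sess + 1}_run-{run + 1}_bold.nii",
                             mask, tr_seconds=float(cfg["tr_seconds"]))
                    for run in range(int(cfg["runs_per_session"]))]
            sessions.append(runs)
        yield SubjectRecord(subject_id=sub, head=head, mask=mask,
                            sessions=sessions, patho=patho)
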