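"""Head geometry: CPC scalp coordinates, search spaces, cortical projection.

The continuous proportional coordinate (CPC) system extends the proportional
logic of the 10-20 EEG system to a continuous 2-D parameterization of the
scalp: ``p_nz`` is the proportion of arc length travelled along the scalp
geodesic from the nasion (NZ) over the vertex to the inion (IZ), and ``p_al``
the proportion along the left-to-right preauricular (AL -> AR) scalp geodesic
constrained to pass through that sagittal point.  Both geodesics are realized
here as plane/mesh intersection curves parameterized by arc length, which is
exact up to the mesh discretization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "GeometryError",
    "HeadModel",
    "CPCCoordinate",
    "ScalpSite",
    "SearchSpace",
    "cpc_to_scalp",
    "build_search_space",
    "mask_search_space",
    "scalp_to_cortex",
    "project_to_cortex",
    "to_mni",
    "mean_adjacent_spacing",
    "closest_point",
    "surface_normal",
    "save_head_model",
    "load_head_model",
]

FIDUCIAL_NAMES = ("NZ", "IZ", "AL", "AR")


class GeometryError(ValueError):
    """Raised for degenerate meshes, empty search spaces and the like."""


@dataclass
class CPCCoordinate:
    """Proportional scalp coordinate: ``p_nz`` nasion->inion, ``p_al`` left->right."""

    p_nz: float
    p_al: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_nz <= 1.0 and 0.0 <= self.p_al <= 1.0):
            raise ValueError(f"CPC coordinates must lie in [0,1]^2, got {self}")


@dataclass
class ScalpSite:
    """A point on the scalp surface with its outward unit normal."""

    position: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"normal must be unit length, |n| = {n}")


@dataclass
class HeadModel:
    """Triangulated scalp and cortex surfaces with fiducials and an MNI affine.

    Vertices are in subject millimetres.  ``fiducials`` maps NZ / IZ / AL / AR
    to 3-vectors on the scalp surface; ``mni_affine`` is the 4x4 subject-mm ->
    MNI-mm transform.
    """

    scalp: trimesh.Trimesh
    cortex: trimesh.Trimesh
    fiducials: dict[str, np.ndarray]
    mni_affine: np.ndarray
    # plane-slice geodesic cache; never serialized
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.fiducials = {k: np.asarray(v, dtype=float) for k, v in self.fiducials.items()}
        self.mni_affine = np.asarray(self.mni_affine, dtype=float)
        missing = [n for n in FIDUCIAL_NAMES if n not in self.fiducials]
        if missing:
            raise ValueError(f"missing fiducials: {missing}")
        if self.mni_affine.shape != (4, 4) or abs(np.linalg.det(self.mni_affine)) < 1e-12:
            raise ValueError("mni_affine must be an invertible 4x4 matrix")

    def validate(self, tol_mm: float = 0.1) -> None:
        """Check fiducials sit on the scalp surface (within ``tol_mm``)."""
        pts = np.array([self.fiducials[n] for n in FIDUCIAL_NAMES])
        _, dist, _ = closest_point(self.scalp, pts)
        if np.any(dist > tol_mm):
            bad = [n for n, d in zip(FIDUCIAL_NAMES, dist) if d > tol_mm]
            raise GeometryError(f"fiducials off the scalp surface (> {tol_mm} mm): {bad}")

    @property
    def up_axis(self) -> np.ndarray:
        """Unit vector pointing from the fiducial plane towards the vertex."""
        key = "up_axis"
        if key not in self._cache:
            f = self.fiducials
            u = np.cross(f["IZ"] - f["NZ"], f["AR"] - f["AL"])
            n = np.linalg.norm(u)
            if n < 1e-12:
                raise GeometryError("degenerate fiducial configuration (collinear axes)")
            u = u / n
            # orient towards the side of the fiducial plane holding the scalp bulk
            d = self.scalp.vertices @ u - float(np.mean([f[k] @ u for k in FIDUCIAL_NAMES]))
            if d.max() < -d.min():
                u = -u
            self._cache[key] = u
        return self._cache[key]


# ---------------------------------------------------------------------------
# plane-slice geodesics


def _closest_on_triangles(point: np.ndarray, triangles: np.ndarray):
    """Closest point to ``point`` on each triangle (Ericson's algorithm,
    vectorized over triangles).  Returns (points, squared distances)."""
    p = np.asarray(point, dtype=float)
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp, cp = p - b, p - c
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    def setwhere(mask, pts):
        m = mask & ~done
        out[m] = pts[m] if pts.ndim == 2 else pts
        done[m] = True

    setwhere((d1 <= 0) & (d2 <= 0), a)                                   # vertex A
    setwhere((d3 >= 0) & (d4 <= d3), b)                                  # vertex B
    setwhere((d6 >= 0) & (d5 <= d6), c)                                  # vertex C
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        setwhere((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        setwhere((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)
        w_bc = np.where((d4 - d3) + (d5 - d6) != 0,
                        (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
        setwhere((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
                 b + w_bc[:, None] * (c - b))
        denom = va + vb + vc
        denom = np.where(denom != 0, denom, 1.0)
        v = vb / denom
        w = vc / denom
        setwhere(np.ones(len(a), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    d2s = np.einsum("ij,ij->i", out - p, out - p)
    return out, d2s


def closest_point(mesh: trimesh.Trimesh, points: np.ndarray):
    """Closest surface points: returns (points, distances, triangle ids)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tris = mesh.triangles
    cp = np.empty_like(points)
    dist = np.empty(len(points))
    tid = np.empty(len(points), dtype=int)
    for k, p in enumerate(points):
        c, d2 = _closest_on_triangles(p, tris)
        i = int(np.argmin(d2))
        cp[k], dist[k], tid[k] = c[i], np.sqrt(d2[i]), i
    return cp, dist, tid


def _stitch_segments(segments: np.ndarray, tol: float = 1e-8) -> list[np.ndarray]:
    """Assemble (n, 2, 3) intersection segments into ordered polylines.

    Closed loops are returned with the first point repeated at the end.
    """
    if len(segments) == 0:
        return []
    scale = max(1.0, float(np.abs(segments).max()))
    key_of = lambda p: tuple(np.round(p / (tol * scale)).astype(np.int64))
    nodes: dict[tuple, int] = {}
    coords: list[np.ndarray] = []
    adj: dict[int, list[tuple[int, int]]] = {}

    def node_id(p: np.ndarray) -> int:
        k = key_of(p)
        if k not in nodes:
            nodes[k] = len(coords)
            coords.append(p)
            adj[nodes[k]] = []
        return nodes[k]

    for si, (a, b) in enumerate(segments):
        ia, ib = node_id(a), node_id(b)
        if ia == ib:  # degenerate sliver
            continue
        adj[ia].append((ib, si))
        adj[ib].append((ia, si))

    used = set()
    polylines = []
    for start in adj:
        if all(si in used for _, si in adj[start]):
            continue
        # prefer starting at an endpoint (odd degree) so open chains come out whole
        ends = [n for n in adj if sum(si not in used for _, si in adj[n]) == 1]
        cur = ends[0] if ends else start
        chain = [cur]
        while True:
            nxt = None
            for nb, si in adj[chain[-1]]:
                if si not in used:
                    used.add(si)
                    nxt = nb
                    break
            if nxt is None:
                break
            chain.append(nxt)
        if len(chain) >= 2:
            polylines.append(np.array([coords[i] for i in chain]))
    return polylines


def _slice_curve(mesh: trimesh.Trimesh, origin: np.ndarray, normal: np.ndarray,
                 anchors: np.ndarray) -> np.ndarray:
    """Intersect ``mesh`` with a plane; return the polyline nearest all anchors."""
    segments = trimesh.intersections.mesh_plane(
        mesh, plane_normal=normal, plane_origin=origin)
    polys = _stitch_segments(np.asarray(segments))
    if not polys:
        raise GeometryError("plane does not intersect the mesh (no geodesic path)")

    def anchor_cost(poly: np.ndarray) -> float:
        return max(_project_onto_polyline(poly, a)[2] for a in np.atleast_2d(anchors))

    return min(polys, key=anchor_cost)


def _cumlen(poly: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _project_onto_polyline(poly: np.ndarray, point: np.ndarray):
    """Closest point on a polyline: returns (arc-length position, point, distance)."""
    a, b = poly[:-1], poly[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", point - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d2 = np.einsum("ij,ij->i", proj - point, proj - point)
    i = int(np.argmin(d2))
    s = _cumlen(poly)
    return s[i] + t[i] * np.sqrt(denom[i]), proj[i], float(np.sqrt(d2[i]))


def _is_closed(poly: np.ndarray, tol: float = 1e-6) -> bool:
    return bool(np.linalg.norm(poly[0] - poly[-1]) < tol * max(1.0, np.abs(poly).max()))


def _arc_between(poly: np.ndarray, a: np.ndarray, b: np.ndarray,
                 via: np.ndarray | None = None,
                 side_dir: np.ndarray | None = None) -> np.ndarray:
    """Extract the sub-polyline from ``a`` to ``b``.

    On a closed loop two arcs exist; the one containing ``via`` (smallest
    distance) or lying towards ``side_dir`` (larger mean projection) is chosen.
    """
    s = _cumlen(poly)
    total = s[-1]
    sa, pa, _ = _project_onto_polyline(poly, a)
    sb, pb, _ = _project_onto_polyline(poly, b)

    def slice_arc(s0: float, s1: float, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
        """Points of the loop walking forward from s0 to s1 (wrapping)."""
        if s1 < s0:
            s1 += total
        pts = [p0]
        svals = s.copy()
        for lap in (0.0, total):
            inside = (svals + lap > s0 + 1e-9) & (svals + lap < s1 - 1e-9)
            pts.extend(poly[inside])
        pts.append(p1)
        return np.array(pts)

    if not _is_closed(poly):
        if sa <= sb:
            return slice_arc(sa, sb, pa, pb)
        return slice_arc(sb, sa, pb, pa)[::-1]

    fwd = slice_arc(sa, sb, pa, pb)
    bwd = slice_arc(sb, sa, pb, pa)[::-1]

    def score(arc: np.ndarray) -> float:
        if via is not None:
            return -_project_onto_polyline(arc, via)[2]
        center = (a + b) / 2.0
        return float(np.mean((arc - center) @ side_dir))

    return max((fwd, bwd), key=score)


def _point_at_fraction(arc: np.ndarray, frac: float) -> np.ndarray:
    s = _cumlen(arc)
    if s[-1] < 1e-12:
        raise GeometryError("degenerate (zero-length) geodesic arc")
    target = frac * s[-1]
    i = int(np.searchsorted(s, target, side="right")) - 1
    i = min(max(i, 0), len(arc) - 2)
    seg = s[i + 1] - s[i]
    t = 0.0 if seg < 1e-15 else (target - s[i]) / seg
    return arc[i] + t * (arc[i + 1] - arc[i])


def surface_normal(mesh: trimesh.Trimesh, point: np.ndarray) -> np.ndarray:
    """Outward unit normal at a surface point.

    Area-weighted vertex normals of the containing face, interpolated
    barycentrically, then oriented away from the mesh centroid.
    """
    point = np.asarray(point, dtype=float)
    closest, _, tri = closest_point(mesh, point[None, :])
    face = mesh.faces[int(tri[0])]
    bary = trimesh.triangles.points_to_barycentric(
        mesh.triangles[[int(tri[0])]], closest)[0]
    n = (mesh.vertex_normals[face] * bary[:, None]).sum(axis=0)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        n = mesh.face_normals[int(tri[0])]
        norm = np.linalg.norm(n)
    n = n / norm
    if np.dot(n, point - mesh.centroid) < 0:
        n = -n
    return n


def _sagittal_arc(head: HeadModel) -> np.ndarray:
    key = "sagittal_arc"
    if key not in head._cache:
        f = head.fiducials
        u = head.up_axis
        normal = np.cross(f["IZ"] - f["NZ"], u)
        normal /= np.linalg.norm(normal)
        loop = _slice_curve(head.scalp, f["NZ"], normal,
                            np.array([f["NZ"], f["IZ"]]))
        head._cache[key] = _arc_between(loop, f["NZ"], f["IZ"], side_dir=u)
    return head._cache[key]


def _coronal_arc(head: HeadModel, p_nz: float) -> np.ndarray:
    key = ("coronal_arc", round(float(p_nz), 9))
    if key not in head._cache:
        f = head.fiducials
        s = _point_at_fraction(_sagittal_arc(head), p_nz)
        normal = np.cross(f["AR"] - f["AL"], s - f["AL"])
        n = np.linalg.norm(normal)
        if n < 1e-9:
            raise GeometryError("sagittal point collinear with preauricular axis")
        loop = _slice_curve(head.scalp, f["AL"], normal / n,
                            np.array([f["AL"], f["AR"], s]))
        head._cache[key] = _arc_between(loop, f["AL"], f["AR"], via=s)
    return head._cache[key]


def cpc_to_scalp(head: HeadModel, cpc: CPCCoordinate) -> ScalpSite:
    """Map a CPC coordinate to the scalp surface.

    ``p_nz`` parameterizes the NZ->IZ sagittal geodesic by arc length;
    ``p_al`` the AL->AR geodesic constrained through that sagittal point.
    Deterministic for a fixed mesh.
    """
    if not isinstance(cpc, CPCCoordinate):
        cpc = CPCCoordinate(*cpc)
    arc = _coronal_arc(head, cpc.p_nz)
    pos = _point_at_fraction(arc, cpc.p_al)
    return ScalpSite(position=pos, normal=surface_normal(head.scalp, pos))


# ---------------------------------------------------------------------------
# search space


@dataclass
class SearchSpace:
    """Rectangular CPC grid with integer indices and inclusion flags.

    Node (i, j) sits at CPC ``(nz_values[i], al_values[j])``; ``included`` is
    the mask of nodes retained after any ROI-sphere masking.
    """

    nz_range: tuple[float, float]
    al_range: tuple[float, float]
    step: float
    nz_values: np.ndarray
    al_values: np.ndarray
    included: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.nz_values), len(self.al_values)

    @property
    def n_nodes(self) -> int:
        return self.included.size

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def cpc(self, i: int, j: int) -> CPCCoordinate:
        return CPCCoordinate(float(self.nz_values[i]), float(self.al_values[j]))

    def nodes(self, included_only: bool = False):
        """Yield (i, j, CPCCoordinate, include-flag) in row-major order."""
        for i in range(len(self.nz_values)):
            for j in range(len(self.al_values)):
                flag = bool(self.included[i, j])
                if included_only and not flag:
                    continue
                yield i, j, self.cpc(i, j), flag


def _axis_values(lo: float, hi: float, step: float) -> np.ndarray:
    if hi < lo:
        raise GeometryError(f"empty range [{lo}, {hi}]")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def build_search_space(nz_range: tuple[float, float], al_range: tuple[float, float],
                       step: float = 0.01) -> SearchSpace:
    """Full Cartesian CPC grid over both ranges, endpoints included."""
    if step <= 0:
        raise ValueError("step must be positive")
    for lo, hi in (nz_range, al_range):
        if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
            raise ValueError("CPC ranges must lie within [0, 1]")
    nz = _axis_values(*nz_range, step)
    al = _axis_values(*al_range, step)
    return SearchSpace(tuple(nz_range), tuple(al_range), step, nz, al,
                       np.ones((len(nz), len(al)), dtype=bool))


def mask_search_space(space: SearchSpace, head: HeadModel,
                      roi_centers_mni: np.ndarray, radius_mm: float) -> SearchSpace:
    """Retain nodes whose cortical projection (MNI) lies within ``radius_mm``
    of at least one ROI center.  Node ordering is unchanged."""
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    centers = np.atleast_2d(np.asarray(roi_centers_mni, dtype=float))
    included = space.included.copy()
    for i, j, cpc, flag in space.nodes():
        if not flag:
            continue
        site = cpc_to_scalp(head, cpc)
        mni = to_mni(head, scalp_to_cortex(head, site))
        included[i, j] = bool(np.min(np.linalg.norm(centers - mni, axis=1)) <= radius_mm)
    if not included.any():
        raise GeometryError("ROI masking excluded every search-space node")
    return SearchSpace(space.nz_range, space.al_range, space.step,
                       space.nz_values.copy(), space.al_values.copy(), included)


# ---------------------------------------------------------------------------
# cortical projection and MNI transform


def _ray_triangles(origin: np.ndarray, direction: np.ndarray,
                   triangles: np.ndarray) -> np.ndarray:
    """Möller–Trumbore: ray parameter t for each triangle (inf if missed)."""
    eps = 1e-9
    v0, v1, v2 = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(direction, e2)
    a = np.einsum("ij,ij->i", e1, h)
    t = np.full(len(triangles), np.inf)
    ok = np.abs(a) > eps
    f = np.zeros_like(a)
    f[ok] = 1.0 / a[ok]
    s = origin - v0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * (q @ direction)
    tt = f * np.einsum("ij,ij->i", q, e2)
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (tt > eps)
    t[hit] = tt[hit]
    return t


def project_to_cortex(head: HeadModel, site: ScalpSite,
                      max_depth_mm: float = 80.0) -> tuple[np.ndarray, bool]:
    """First inward-normal intersection with the cortex mesh.

    Returns ``(point, used_fallback)``: if the ray misses within
    ``max_depth_mm`` the nearest cortex vertex to the ray is returned and the
    fallback flag is set.
    """
    if len(head.cortex.faces) == 0:
        raise GeometryError("cortex mesh is empty")
    direction = -site.normal
    t = _ray_triangles(site.position, direction, head.cortex.triangles)
    tmin = float(t.min())
    if np.isfinite(tmin) and tmin <= max_depth_mm:
        return site.position + tmin * direction, False
    # fallback: nearest cortex vertex to the forward ray
    rel = head.cortex.vertices - site.position
    along = np.clip(rel @ direction, 0.0, None)
    d2 = np.einsum("ij,ij->i", rel, rel) - along**2
    return np.asarray(head.cortex.vertices[int(np.argmin(d2))], dtype=float), True


def scalp_to_cortex(head: HeadModel, site: ScalpSite, max_depth_mm: float = 80.0) -> np.ndarray:
    """Cortical point beneath a scalp site (see :func:`project_to_cortex`)."""
    return project_to_cortex(head, site, max_depth_mm)[0]


def to_mni(head: HeadModel, point: np.ndarray) -> np.ndarray:
    """Apply the head's subject-mm -> MNI-mm affine to a point."""
    p = np.asarray(point, dtype=float)
    return head.mni_affine[:3, :3] @ p + head.mni_affine[:3, 3]


def mean_adjacent_spacing(head: HeadModel, space: SearchSpace) -> float:
    """Mean scalp distance (mm) over grid-adjacent included node pairs."""
    pos: dict[tuple[int, int], np.ndarray] = {}
    for i, j, cpc, _ in space.nodes(included_only=True):
        pos[(i, j)] = cpc_to_scalp(head, cpc).position
    dists = []
    for (i, j), p in pos.items():
        for di, dj in ((1, 0), (0, 1)):
            q = pos.get((i + di, j + dj))
            if q is not None:
                dists.append(np.linalg.norm(p - q))
    if not dists:
        raise GeometryError("need at least two adjacent included nodes")
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# head-model I/O: ASCII PLY surfaces + JSON sidecar


def save_head_model(head: HeadModel, directory: str | Path, name: str = "head") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for tag, mesh in (("scalp", head.scalp), ("cortex", head.cortex)):
        (directory / f"{name}_{tag}.ply").write_bytes(
            trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))
    sidecar = {
        "fiducials": {k: np.asarray(v).tolist() for k, v in head.fiducials.items()},
        "mni_affine": np.asarray(head.mni_affine).tolist(),
    }
    path = directory / f"{name}.json"
    path.write_text(json.dumps(sidecar, indent=2))
    return path


def load_head_model(directory: str | Path, name: str = "head") -> HeadModel:
    directory = Path(directory)
    sidecar = json.loads((directory / f"{name}.json").read_text())
    scalp = trimesh.load(directory / f"{name}_scalp.ply", process=False)
    cortex = trimesh.load(directory / f"{name}_cortex.ply", process=False)
    return HeadModel(scalp=scalp, cortex=cortex,
                     fiducials=sidecar["fiducials"],
                     mni_affine=np.array(sidecar["mni_affine"]))
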