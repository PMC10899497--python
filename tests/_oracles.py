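"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: closed-form spherical
geometry, explicit full-matrix linear algebra, and brute-force flood fill.
"""

import numpy as np


def sphere_cpc(p_nz: float, p_al: float, radius: float = 92.0) -> np.ndarray:
    """Closed-form CPC construction on a fiducial-aligned sphere.

    The sagittal geodesic is the great circle x=0 from NZ=(0,R,0) over the
    vertex to IZ=(0,-R,0); the coronal geodesic through the sagittal point is
    the great circle spanned by the x-axis and that point, parameterized by
    arc length from AL=(-R,0,0).
    """
    theta = np.pi * p_nz
    phi = np.pi * p_al
    sagittal = np.array([0.0, np.cos(theta), np.sin(theta)])
    return radius * (np.cos(phi) * np.array([-1.0, 0.0, 0.0]) + np.sin(phi) * sagittal)


def flood_fill_labels(supra: np.ndarray, offsets) -> np.ndarray:
    """Brute-force connected components by repeated neighbourhood expansion."""
    labels = np.full(supra.shape, -1, dtype=int)
    current = 0
    for i in range(supra.shape[0]):
        for j in range(supra.shape[1]):
            if not supra[i, j] or labels[i, j] != -1:
                continue
            frontier = {(i, j)}
            labels[i, j] = current
            while frontier:
                nxt = set()
                for (ci, cj) in frontier:
                    for di, dj in offsets:
                        ni, nj = ci + di, cj + dj
                        if (0 <= ni < supra.shape[0] and 0 <= nj < supra.shape[1]
                                and supra[ni, nj] and labels[ni, nj] == -1):
                            labels[ni, nj] = current
                            nxt.add((ni, nj))
                frontier = nxt
            current += 1
    return labels


def full_matrix_seed_map(Z: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted average of explicit correlation-matrix rows (O(V^2) memory)."""
    T = Z.shape[1]
    R = (Z @ Z.T) / T
    wn = w / w.sum()
    return R.T @ wn


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))
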