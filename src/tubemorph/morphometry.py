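"""Per-vertex multivariate morphometry statistics (MMS).

For each subject registered to the template grid, the registration map's
2x2 face Jacobians J yield tensor-based morphometry features:

* TBM: sqrt(det J) — local area change;
* mTBM: the three unique entries of log sqrt(J J^T) — the Log-Euclidean
  deformation tensor, sensitive to rotation, dilation and shear along the
  surface tangent plane;

and the radial distance — the Euclidean distance from each surface point to
the corresponding point of the tube's medial core (centerline) — completes
the per-vertex 4-vector. Per subject the features form a W x 4 matrix with
a companion W-vector of det J used by the directionality ratio maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .correspondence import DeformationField, GridSurface
from .errors import DiffeomorphismError, NumericalError, SingularityError

MTBM_COLUMNS = ("m11", "m12", "m22")   # fixed serialization order


# ---------------------------------------------------------------------------
# Jacobians and tensor features
# ---------------------------------------------------------------------------

def face_jacobian(source_face: np.ndarray, target_face: np.ndarray) -> np.ndarray:
    """Linear map J sending source triangle edge vectors to target edges.

    J = [w3 - w1, w2 - w1] [v3 - v1, v2 - v1]^{-1}  (columns as listed),
    for parameter-plane triangles [v1, v2, v3] -> [w1, w2, w3].
    """
    v = np.asarray(source_face, dtype=float)
    w = np.asarray(target_face, dtype=float)
    A = np.column_stack([v[2] - v[0], v[1] - v[0]])
    B = np.column_stack([w[2] - w[0], w[1] - w[0]])
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if abs(det) < 1e-15 * max(1.0, np.abs(A).max() ** 2):
        raise SingularityError("source triangle is degenerate")
    return B @ np.linalg.inv(A)


def _face_jacobians_batch(src: np.ndarray, tgt: np.ndarray) -> np.ndarray:
    """Vectorized face Jacobians for (F, 3, 2) triangle arrays."""
    A = np.stack([src[:, 2] - src[:, 0], src[:, 1] - src[:, 0]], axis=-1)
    B = np.stack([tgt[:, 2] - tgt[:, 0], tgt[:, 1] - tgt[:, 0]], axis=-1)
    det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
    if np.any(np.abs(det) < 1e-30):
        raise SingularityError("degenerate source triangle in grid")
    Ainv = np.empty_like(A)
    Ainv[:, 0, 0] = A[:, 1, 1] / det
    Ainv[:, 0, 1] = -A[:, 0, 1] / det
    Ainv[:, 1, 0] = -A[:, 1, 0] / det
    Ainv[:, 1, 1] = A[:, 0, 0] / det
    return B @ Ainv


def tbm(J: np.ndarray) -> float:
    """Scalar TBM: sqrt(det J). Requires an orientation-preserving map."""
    d = float(np.linalg.det(np.asarray(J, dtype=float)))
    if d <= 0:
        raise DiffeomorphismError(f"non-positive Jacobian determinant {d:.3g}")
    return float(np.sqrt(d))


def _sym2_eig(S: np.ndarray):
    """Closed-form eigendecomposition of symmetric 2x2 batches (..., 2, 2)."""
    a, b, c = S[..., 0, 0], S[..., 0, 1], S[..., 1, 1]
    mean = 0.5 * (a + c)
    disc = np.sqrt(np.maximum(0.25 * (a - c) ** 2 + b ** 2, 0.0))
    lam1, lam2 = mean + disc, mean - disc
    # eigenvector for lam1: (b, lam1 - a) unless degenerate
    vx = np.where(disc > 1e-300, b, 1.0)
    vy = np.where(disc > 1e-300, lam1 - a, 0.0)
    norm = np.hypot(vx, vy)
    small = norm < 1e-150
    vx = np.where(small, 1.0, vx / np.where(small, 1.0, norm))
    vy = np.where(small, 0.0, vy / np.where(small, 1.0, norm))
    return lam1, lam2, vx, vy


def _sym2_func(S: np.ndarray, func) -> np.ndarray:
    """Apply a scalar function to a batch of symmetric 2x2 matrices."""
    lam1, lam2, vx, vy = _sym2_eig(S)
    f1, f2 = func(lam1), func(lam2)
    out = np.empty_like(S)
    out[..., 0, 0] = f1 * vx * vx + f2 * vy * vy
    out[..., 0, 1] = (f1 - f2) * vx * vy
    out[..., 1, 0] = out[..., 0, 1]
    out[..., 1, 1] = f1 * vy * vy + f2 * vx * vx
    return out


def mtbm(J: np.ndarray) -> np.ndarray:
    """mTBM 3-vector: unique entries [m11, m12, m22] of log sqrt(J J^T)."""
    J = np.asarray(J, dtype=float)
    if np.linalg.det(J) <= 0:
        raise DiffeomorphismError("mTBM requires det J > 0")
    S = J @ J.T
    logS = _sym2_func(S[None], lambda x: 0.5 * np.log(np.maximum(x, 1e-300)))[0]
    if not np.isfinite(logS).all():
        raise NumericalError("non-finite deformation tensor logarithm")
    return np.array([logS[0, 0], logS[0, 1], logS[1, 1]])


# ---------------------------------------------------------------------------
# medial core and radial distance
# ---------------------------------------------------------------------------

@dataclass
class MedialCore:
    """Tube centerline: one point per grid ring (the ring centroid)."""

    points: np.ndarray   # (n_u, 3)


def medial_core(grid_positions: np.ndarray) -> MedialCore:
    """Ring centroids of a (n_u, n_v, 3) position grid."""
    return MedialCore(points=np.asarray(grid_positions, dtype=float).mean(axis=1))


def radial_distances(grid_positions: np.ndarray) -> np.ndarray:
    """Per-node distance to its own ring's medial-core point; (n_u, n_v)."""
    pos = np.asarray(grid_positions, dtype=float)
    core = medial_core(pos).points
    return np.linalg.norm(pos - core[:, None, :], axis=-1)


# ---------------------------------------------------------------------------
# per-subject feature matrix
# ---------------------------------------------------------------------------

@dataclass
class MMSFeatureMatrix:
    """W x 4 multivariate morphometry statistics for one subject.

    Columns: the three mTBM components (m11, m12, m22 of log sqrt(J J^T))
    followed by the radial distance (mm); det J carried separately for the
    ratio maps. Rows follow the grid in row-major (u-ring, v) order.
    """

    mms: np.ndarray
    det_j: np.ndarray                    # surface area-change determinant
    grid_shape: tuple
    subject_id: str | None = None
    side: str | None = None
    det_j_param: np.ndarray | None = None   # parameter-plane determinant

    @property
    def n_vertices(self) -> int:
        return self.mms.shape[0]

    def save(self, path) -> None:
        path = Path(path)
        self.mms.astype(np.float64).tofile(path.with_suffix(".mms.bin"))
        self.det_j.astype(np.float64).tofile(path.with_suffix(".detj.bin"))
        header = {"n_vertices": int(self.mms.shape[0]),
                  "columns": list(MTBM_COLUMNS) + ["radial_distance"],
                  "grid_shape": [int(s) for s in self.grid_shape],
                  "subject_id": self.subject_id, "side": self.side,
                  "dtype": "float64"}
        path.with_suffix(".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, path) -> "MMSFeatureMatrix":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        w = header["n_vertices"]
        mms = np.fromfile(path.with_suffix(".mms.bin")).reshape(w, 4)
        det_j = np.fromfile(path.with_suffix(".detj.bin"))
        return cls(mms=mms, det_j=det_j,
                   grid_shape=tuple(header["grid_shape"]),
                   subject_id=header.get("subject_id"),
                   side=header.get("side"))


def _grid_param_faces(n_u: int, n_v: int):
    """Template parameter-domain triangulation of the grid: each quad split
    into two triangles; the angular coordinate unwrapped at the seam.
    Returns (node uv (n_u*n_v, 2) function via faces array referencing
    node ids, plus per-face wrap offsets)."""
    iu, iv = np.meshgrid(np.arange(n_u - 1), np.arange(n_v), indexing="ij")
    i0 = (iu * n_v + iv).ravel()
    i1 = (iu * n_v + (iv + 1) % n_v).ravel()
    j0 = ((iu + 1) * n_v + iv).ravel()
    j1 = ((iu + 1) * n_v + (iv + 1) % n_v).ravel()
    wrap = (iv.ravel() == n_v - 1)
    faces = np.concatenate([np.stack([i0, j0, j1], axis=1),
                            np.stack([i0, j1, i1], axis=1)])
    # wrap flag per face corner: corners using column 0 as "column n_v"
    wrap_corner = np.concatenate([
        np.stack([np.zeros_like(wrap), np.zeros_like(wrap), wrap], axis=1),
        np.stack([np.zeros_like(wrap), wrap, wrap], axis=1)]).astype(float)
    return faces, wrap_corner


def _sample_grid(values: np.ndarray, uv: np.ndarray) -> np.ndarray:
    """Bilinear sample of (n_u, n_v, ...) grid data at (u, v) coordinates
    (v periodic)."""
    n_u, n_v = values.shape[:2]
    su = np.clip(uv[..., 0], 0, 1) * (n_u - 1)
    sv = np.mod(uv[..., 1], 1.0) * n_v
    u0 = np.floor(su).astype(int)
    u1 = np.minimum(u0 + 1, n_u - 1)
    fu = (su - u0)[..., None]
    v0 = np.floor(sv).astype(int) % n_v
    v1 = (v0 + 1) % n_v
    fv = (sv - np.floor(sv))[..., None]
    flat = values.reshape(n_u * n_v, -1)
    res = ((1 - fu) * (1 - fv) * flat[u0 * n_v + v0]
           + (1 - fu) * fv * flat[u0 * n_v + v1]
           + fu * (1 - fv) * flat[u1 * n_v + v0]
           + fu * fv * flat[u1 * n_v + v1])
    return res.reshape(uv.shape[:-1] + values.shape[2:])


def compute_mms(subject: GridSurface, template: GridSurface,
                field: DeformationField,
                radial_frame: str = "subject") -> MMSFeatureMatrix:
    """MMS feature matrix for one registered subject.

    Per grid face, J maps the template parameter triangle to its image in
    the subject parameter domain (template node + backward displacement).
    Per-vertex deformation tensors J J^T and determinants are aggregated by
    area-weighted averaging over incident faces *before* the matrix
    logarithm, preserving positive-definiteness.

    The carried ``det_j`` is the determinant of the surface map differential
    — the parameter-plane determinant times the conformal-factor ratio
    lambda_subject(phi(x)) / lambda_template(x) — i.e. the local surface
    area change, so atrophy of the subject relative to the template gives
    det J < 1. (A conformal parameterization allocates *more* parameter
    area to a thinned region, so the raw parameter-plane determinant alone
    moves in the opposite direction; it is kept in ``det_j_param``.)

    The radial-distance column is computed on the registered subject
    geometry sampled at template grid nodes (``radial_frame='template'``
    instead measures distances to the template's own medial core).
    """
    n_u, n_v = template.shape
    gu, gv = np.meshgrid(np.linspace(0, 1, n_u), np.arange(n_v) / n_v,
                         indexing="ij")
    nodes_uv = np.stack([gu.ravel(), gv.ravel()], axis=-1)   # (W, 2)
    disp = field.backward.reshape(-1, 2)
    mapped_uv = nodes_uv + disp

    faces, wrap_corner = _grid_param_faces(n_u, n_v)
    src = nodes_uv[faces].copy()
    src[..., 1] += wrap_corner                    # unwrap the seam column
    tgt = mapped_uv[faces].copy()
    tgt[..., 1] += wrap_corner

    J = _face_jacobians_batch(src, tgt)           # (F, 2, 2)
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    if np.any(detJ <= 0):
        raise DiffeomorphismError(
            f"{int((detJ <= 0).sum())} grid faces have non-positive det J")
    JJt = J @ np.swapaxes(J, 1, 2)

    # source-triangle areas as aggregation weights (uniform on a regular
    # grid, kept general)
    e1 = src[:, 1] - src[:, 0]
    e2 = src[:, 2] - src[:, 0]
    w_face = 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])

    W = n_u * n_v
    T = np.zeros((W, 2, 2))
    dj = np.zeros(W)
    wsum = np.zeros(W)
    for k in range(3):
        np.add.at(T, faces[:, k], JJt * w_face[:, None, None])
        np.add.at(dj, faces[:, k], detJ * w_face)
        np.add.at(wsum, faces[:, k], w_face)
    T /= wsum[:, None, None]
    dj /= wsum

    logS = _sym2_func(T, lambda x: 0.5 * np.log(np.maximum(x, 1e-300)))
    if not np.isfinite(logS).all():
        raise NumericalError("non-finite deformation tensor logarithm")

    reg_pos = _sample_grid(subject.positions,
                           mapped_uv.reshape(n_u, n_v, 2))
    if radial_frame == "subject":
        rd = radial_distances(reg_pos)
    elif radial_frame == "template":
        core = medial_core(template.positions).points
        rd = np.linalg.norm(reg_pos - core[:, None, :], axis=-1)
    else:
        raise ValueError("radial_frame must be 'subject' or 'template'")

    lam_sub = _sample_grid(subject.conformal_factor[..., None],
                           mapped_uv.reshape(n_u, n_v, 2))[..., 0].ravel()
    lam_tmp = template.conformal_factor.ravel()
    det_surface = dj * lam_sub / np.maximum(lam_tmp, 1e-30)

    mms = np.column_stack([logS[:, 0, 0], logS[:, 0, 1], logS[:, 1, 1],
                           rd.ravel()])
    return MMSFeatureMatrix(mms=mms, det_j=det_surface,
                            grid_shape=(n_u, n_v),
                            subject_id=subject.subject_id,
                            det_j_param=dj)
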