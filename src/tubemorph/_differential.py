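"""Discrete differential-geometry helpers shared by the parameterization and
feature-extraction stages: cotangent Laplacians, per-face gradients, vertex
areas and mean curvature.

Conventions: faces are counter-clockwise when viewed from outside (outward
normals); the Laplacian is the positive semi-definite stiffness matrix
``L = D - W`` with cotangent edge weights, so ``(L x)_i = sum_j w_ij (x_i - x_j)``.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

# Cotangent weights are clamped at a small positive floor so the Dirichlet
# systems stay M-matrices (and hence uniquely solvable) on meshes with obtuse
# triangles; the floor is far below any weight on a well-shaped mesh.
COT_FLOOR = 1e-8


def face_areas_normals(vertices: np.ndarray, faces: np.ndarray):
    """Per-face area and unit normal (CCW orientation)."""
    p0, p1, p2 = (vertices[faces[:, k]] for k in range(3))
    cross = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(cross, axis=1)
    areas = 0.5 * norm
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = cross / np.where(norm > 0, norm, 1.0)[:, None]
    return areas, normals


def cotangent_laplacian(vertices: np.ndarray, faces: np.ndarray,
                        clamp: float = COT_FLOOR) -> sp.csr_matrix:
    """Cotangent-weight stiffness matrix (positive semi-definite, clamped)."""
    n = len(vertices)
    rows, cols, vals = [], [], []
    for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        # angle at vertex c, opposite edge (a, b)
        u = vertices[faces[:, a]] - vertices[faces[:, c]]
        v = vertices[faces[:, b]] - vertices[faces[:, c]]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        dot = np.einsum("ij,ij->i", u, v)
        cot = dot / np.maximum(cross, 1e-30)
        w = np.maximum(0.5 * cot, clamp)
        rows.append(faces[:, a])
        cols.append(faces[:, b])
        vals.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    W = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    W = W + W.T
    d = np.asarray(W.sum(axis=1)).ravel()
    return (sp.diags(d) - W).tocsr()


def vertex_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Barycentric lumped vertex areas (one third of incident face areas)."""
    areas, _ = face_areas_normals(vertices, faces)
    va = np.zeros(len(vertices))
    for k in range(3):
        np.add.at(va, faces[:, k], areas / 3.0)
    return va


def face_gradients(vertices: np.ndarray, faces: np.ndarray,
                   scalar: np.ndarray) -> np.ndarray:
    """Per-face 3D gradient of a piecewise-linear vertex scalar.

    grad u = (1 / 2A) * sum_i u_i (n x e_i) with e_i the edge opposite
    vertex i, oriented CCW.
    """
    areas, normals = face_areas_normals(vertices, faces)
    grad = np.zeros((len(faces), 3))
    for i, j, k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        e_opp = vertices[faces[:, k]] - vertices[faces[:, j]]
        grad += scalar[faces[:, i], None] * np.cross(normals, e_opp)
    grad /= np.maximum(2.0 * areas, 1e-30)[:, None]
    return grad


def rotated_gradients(vertices: np.ndarray, faces: np.ndarray,
                      scalar: np.ndarray) -> np.ndarray:
    """Gradient rotated by 90 degrees in each face plane (n x grad).

    This is the discrete Hodge star applied to ``d scalar``; integrating it
    yields the conjugate harmonic function.
    """
    _, normals = face_areas_normals(vertices, faces)
    return np.cross(normals, face_gradients(vertices, faces, scalar))


def weak_divergence(vertices: np.ndarray, faces: np.ndarray,
                    field: np.ndarray) -> np.ndarray:
    """Per-vertex weak divergence of a per-face vector field.

    b_i = sum_{f : i in f} A_f grad(phi_i) . X_f, the right-hand side of the
    least-squares Poisson problem  min sum_f A_f |grad v - X_f|^2.
    """
    _, normals = face_areas_normals(vertices, faces)
    b = np.zeros(len(vertices))
    for i, j, k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        e_opp = vertices[faces[:, k]] - vertices[faces[:, j]]
        contrib = 0.5 * np.einsum("ij,ij->i", np.cross(normals, e_opp), field)
        np.add.at(b, faces[:, i], contrib)
    return b


def mean_curvature(vertices: np.ndarray, faces: np.ndarray,
                   vertex_normals: np.ndarray | None = None) -> np.ndarray:
    """Signed pointwise mean curvature via the cotangent Laplace-Beltrami.

    H_i = (L x)_i . n_i / (2 A_i); positive on convex surfaces (sphere of
    radius r gives H = 1/r) when normals point outward. Boundary vertices have
    no meaningful curvature from this formula; they inherit the value of
    their nearest interior ring is NOT attempted here -- callers on open
    meshes should treat boundary rows with care (the registration features
    z-score over the full grid, where the two boundary rings are a small
    fraction).
    """
    L = cotangent_laplacian(vertices, faces)
    lx = L @ vertices
    va = vertex_areas(vertices, faces)
    if vertex_normals is None:
        areas, fnormals = face_areas_normals(vertices, faces)
        vertex_normals = np.zeros_like(vertices)
        for k in range(3):
            np.add.at(vertex_normals, faces[:, k], fnormals * areas[:, None])
        nn = np.linalg.norm(vertex_normals, axis=1)
        vertex_normals = vertex_normals / np.where(nn > 0, nn, 1.0)[:, None]
    return np.einsum("ij,ij->i", lx, vertex_normals) / np.maximum(2 * va, 1e-30)
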