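"""Vertex-wise multivariate group contrasts with two-level permutation
correction, directionality ratio maps, p-value CDF diagnostics and scalar
volume comparisons.

The per-vertex statistic is the two-sample Mahalanobis distance

    M = (N_S N_T / (N_S + N_T)) (Sbar - Tbar)^T  Sigma^{-1} (Sbar - Tbar)

with Sigma the pooled covariance of the two groups (Hotelling's T^2 up to
a constant). Inference is by label permutation: uncorrected vertex p-values
from the permutation distribution of M, and a map-level (corrected)
significance from the permutation distribution of the "p feature" — the
count of vertices below the nominal threshold. The p-value estimator uses
the (count + 1)/(n_perm + 1) correction so p is never exactly zero, and
ties count toward the numerator by default (conservative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import NumericalError, ParameterError

DEFAULT_N_PERM = 10_000
DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# batched symmetric inverses (hot path of the permutation loop)
# ---------------------------------------------------------------------------

def _sym_solve(S: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Quadratic form d^T S^{-1} d for batches of symmetric (k, k) with
    k <= 4 via closed-form adjugates; LAPACK fallback otherwise."""
    k = S.shape[-1]
    if k == 1:
        return d[..., 0] ** 2 / S[..., 0, 0]
    if k == 2:
        a, b, c = S[..., 0, 0], S[..., 0, 1], S[..., 1, 1]
        det = a * c - b * b
        x, y = d[..., 0], d[..., 1]
        return (c * x * x - 2 * b * x * y + a * y * y) / det
    if k == 3:
        return np.einsum("...i,...ij,...j->...", d, np.linalg.inv(S), d)
    if k == 4:
        return _quad_form_sym4(S, d)
    sol = np.linalg.solve(S, d[..., None])[..., 0]
    return np.einsum("...i,...i->...", d, sol)


def _sym4_adjugate_quad_det(a, b, c, e, f, g, h, i, j, k, x0, x1, x2, x3):
    """(x^T adj(S) x, det S) for symmetric S = [[a,b,c,e],[b,f,g,h],
    [c,g,i,j],[e,h,j,k]] — machine-generated common subexpressions."""
    x4 = j ** 2
    x5 = f * x4
    x6 = g ** 2
    x7 = k * x6
    x8 = h ** 2
    x9 = i * x8
    x10 = i * k
    x11 = g * j
    x12 = c * h
    x13 = j * x12
    x14 = e * x11
    x15 = g * k
    x16 = e * i
    x17 = b * x10 - b * x4 - c * x15 - h * x16 + x13 + x14
    x18 = g * x12
    x19 = b * h
    x20 = f * j
    x21 = b * x11 - c * x20 - e * x6 + f * x16 - i * x19 + x18
    x22 = c * k
    x23 = e * g
    x24 = b * x15 + c * x8 + e * x20 - f * x22 - h * x23 - j * x19
    x25 = c ** 2
    x26 = k * x25
    x27 = e ** 2
    x28 = i * x27
    x29 = c * e
    x30 = b * j
    x31 = a * h
    x32 = a * x15 - b * x22 + e * x12 + e * x30 - g * x27 - j * x31
    x33 = a * x11 + b * x16 - c * x23 - c * x30 + h * x25 - i * x31
    x34 = b ** 2
    x35 = k * x34
    x36 = a * f
    x37 = 2 * e
    x38 = a * x20 + b * x12 + b * x23 - f * x29 - g * x31 - j * x34
    x39 = 2 * b
    quad = (-x0 * (x0 * (-f * x10 - 2 * h * x11 + x5 + x7 + x9) + x1 * x17
                   - x2 * x24 + x21 * x3)
            - x1 * (x0 * x17 + x1 * (-a * x10 + a * x4 - 2 * j * x29 + x26 + x28)
                    + x2 * x32 - x3 * x33)
            - x2 * (-x0 * x24 + x1 * x32
                    + x2 * (a * x8 + f * x27 - k * x36 - x19 * x37 + x35)
                    + x3 * x38)
            - x3 * (x0 * x21 - x1 * x33 + x2 * x38
                    + x3 * (a * x6 - c * g * x39 + f * x25 + i * x34 - i * x36)))
    det = (a * f * i * k + 2 * a * g * h * j - a * x5 - a * x7 - a * x9
           + 2 * b * c * g * k + 2 * b * e * h * i + 2 * c * e * f * j
           - f * x26 - f * x28 - i * x35 - x13 * x39 - x14 * x39 - x18 * x37
           + x25 * x8 + x27 * x6 + x34 * x4)
    return quad, det


def _quad_form_sym4(S: np.ndarray, d: np.ndarray) -> np.ndarray:
    """d^T S^{-1} d for symmetric 4x4 batches via the adjugate."""
    quad, det = _sym4_adjugate_quad_det(
        S[..., 0, 0], S[..., 0, 1], S[..., 0, 2], S[..., 0, 3],
        S[..., 1, 1], S[..., 1, 2], S[..., 1, 3],
        S[..., 2, 2], S[..., 2, 3], S[..., 3, 3],
        d[..., 0], d[..., 1], d[..., 2], d[..., 3])
    return quad / det


# ---------------------------------------------------------------------------
# Mahalanobis statistic
# ---------------------------------------------------------------------------

def _pooled_sigma(A: np.ndarray, B: np.ndarray):
    """Per-vertex pooled covariance (..., W, k, k) and mean difference."""
    nA, nB = A.shape[0], B.shape[0]
    mA = A.mean(axis=0)
    mB = B.mean(axis=0)
    dA = A - mA
    dB = B - mB
    scatter = (np.einsum("nwi,nwj->wij", dA, dA)
               + np.einsum("nwi,nwj->wij", dB, dB))
    return scatter / (nA + nB - 2), mA - mB


def _shrink(S: np.ndarray, gamma: float) -> np.ndarray:
    diag = np.zeros_like(S)
    idx = np.arange(S.shape[-1])
    diag[..., idx, idx] = S[..., idx, idx]
    return (1 - gamma) * S + gamma * diag


def _condition_proxy(S: np.ndarray) -> np.ndarray:
    """det / prod(diag): a cheap ill-conditioning proxy for SPD matrices
    (1 for diagonal; -> 0 as columns become collinear)."""
    idx = np.arange(S.shape[-1])
    det = np.linalg.det(S)
    prod = np.prod(np.maximum(S[..., idx, idx], 1e-300), axis=-1)
    return det / prod


def mahalanobis_stat(group_a: np.ndarray, group_b: np.ndarray,
                     shrink_threshold: float = 1e-8,
                     shrink_gamma: float = 0.1) -> np.ndarray:
    """Per-vertex Mahalanobis statistic M for (N, W, k) feature stacks.

    The pooled covariance receives diagonal shrinkage where ill-conditioned
    (normalized determinant below ``shrink_threshold``, the determinant
    analogue of a ~1e8 condition bound for k = 4).
    """
    A = np.asarray(group_a, dtype=float)
    B = np.asarray(group_b, dtype=float)
    if A.ndim == 2:
        A = A[..., None]
    if B.ndim == 2:
        B = B[..., None]
    nA, nB = A.shape[0], B.shape[0]
    if nA < 2 or nB < 2:
        raise ParameterError("each group needs at least 2 subjects")
    S, diff = _pooled_sigma(A, B)
    bad = _condition_proxy(S) < shrink_threshold
    if bad.any():
        S = np.where(bad[..., None, None], _shrink(S, shrink_gamma), S)
        still = _condition_proxy(S) < shrink_threshold * 1e-4
        if still.any():
            raise NumericalError(
                "singular pooled covariance after shrinkage at vertices "
                f"{np.flatnonzero(still)[:5].tolist()}")
    c = nA * nB / (nA + nB)
    M = c * _sym_solve(S, diff)
    if not np.isfinite(M).all():
        raise NumericalError("non-finite Mahalanobis statistic")
    return M


# ---------------------------------------------------------------------------
# permutation contrast (Model/Results style)
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    """Results of a vertex-wise permutation contrast."""

    statistic: np.ndarray          # per-vertex M
    p_uncorrected: np.ndarray
    alpha: float
    p_feature: int                 # |{vertex : p < alpha}|
    corrected_p: float             # map-level overall significance
    n_perm: int
    seed: int | None
    group_sizes: tuple
    mask: np.ndarray = field(init=False)

    def __post_init__(self):
        self.mask = self.p_uncorrected < self.alpha

    @property
    def significant(self) -> bool:
        return self.corrected_p < self.alpha

    def summary(self) -> str:
        w = len(self.statistic)
        lines = [
            "Vertex-wise Hotelling/Mahalanobis permutation contrast",
            "=" * 54,
            f"vertices (W):            {w}",
            f"group sizes:             {self.group_sizes[0]} vs {self.group_sizes[1]}",
            f"permutations:            {self.n_perm}",
            f"nominal alpha:           {self.alpha}",
            f"max statistic M:         {self.statistic.max():.4f}",
            f"p feature (p < alpha):   {self.p_feature} "
            f"({100 * self.p_feature / w:.1f}% of vertices)",
            f"map-level corrected p:   {self.corrected_p:.4f}"
            + ("  (significant)" if self.significant else ""),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"p_feature": int(self.p_feature),
                "corrected_p": float(self.corrected_p),
                "n_perm": int(self.n_perm), "alpha": float(self.alpha),
                "seed": self.seed,
                "group_sizes": [int(g) for g in self.group_sizes],
                "max_statistic": float(self.statistic.max()),
                "significant": bool(self.significant)}


class HotellingPermutationTest:
    """Two-sample multivariate contrast with two-level permutation
    correction.

    Parameters
    ----------
    group_a, group_b : (N, W) or (N, W, k) arrays
        Per-subject feature stacks on common vertices.
    alpha : nominal vertex-level threshold for the p feature.
    ties : 'ge' counts permutation statistics equal to the observed one
        toward the numerator (conservative, default); 'gt' restores a
        strict comparison.
    """

    def __init__(self, group_a: np.ndarray, group_b: np.ndarray,
                 alpha: float = DEFAULT_ALPHA, ties: str = "ge",
                 shrink_threshold: float = 1e-8, shrink_gamma: float = 0.1):
        if not 0 < alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        if ties not in ("ge", "gt"):
            raise ParameterError("ties must be 'ge' or 'gt'")
        self.A = np.asarray(group_a, dtype=float)
        self.B = np.asarray(group_b, dtype=float)
        if self.A.ndim == 2:
            self.A = self.A[..., None]
        if self.B.ndim == 2:
            self.B = self.B[..., None]
        if self.A.shape[0] < 2 or self.B.shape[0] < 2:
            raise ParameterError("each group needs at least 2 subjects")
        if self.A.shape[1:] != self.B.shape[1:]:
            raise ParameterError("groups must share vertex/feature shape")
        self.alpha = alpha
        self.ties = ties
        self.shrink_threshold = shrink_threshold
        self.shrink_gamma = shrink_gamma

    def _perm_stats(self, X, T_tot, S_tot, P_A, chunk_slice):
        """M for every family member on a vertex chunk: (n_family, w).

        ``P_A`` stacks the observed labelling (row 0) with the random
        relabellings, so the whole family goes through one code path and
        the resulting p-maps are exchangeable under the null. Works on the
        unique entries of the pooled covariance in float32 -- the ranking
        is pure order information, so single precision is ample and halves
        the memory traffic.
        """
        nA = int(round(float(P_A[0].sum())))
        nB = X.shape[0] - nA
        k = X.shape[-1]
        Xc = X[:, chunk_slice].astype(np.float32)   # (N, w, k)
        flat = Xc.reshape(X.shape[0], -1)
        SA = (P_A @ flat).reshape(len(P_A), -1, k)
        # the second group's sum goes through the same matmul path (not
        # S_tot - SA): with equal group sizes a labelling and its
        # complement then produce bitwise-identical statistics, so they
        # register as exact ties in the family ranking
        SB = ((1.0 - P_A) @ flat).reshape(len(P_A), -1, k)
        mA = SA / nA
        mB = SB / nB
        diff = mA - mB
        c = nA * nB / (nA + nB)
        denom = nA + nB - 2
        Tc = T_tot[chunk_slice].astype(np.float32)
        if k != 4:
            # a + b before subtracting: addition is commutative bitwise, so
            # a labelling and its complement produce identical statistics
            # and register as exact ties in the family ranking
            S = (Tc[None]
                 - (nA * np.einsum("pwi,pwj->pwij", mA, mA)
                    + nB * np.einsum("pwi,pwj->pwij", mB, mB))) / denom
            bad = _condition_proxy(S) < self.shrink_threshold
            if bad.any():
                S = np.where(bad[..., None, None],
                             _shrink(S, self.shrink_gamma), S)
            return c * _sym_solve(S, diff)
        # pooled scatter components S_ij = (T_ij - nA mA_i mA_j - nB mB_i mB_j)/denom
        comp = {}
        for i in range(4):
            for j in range(i, 4):
                # commutative inner sum: complement labellings tie bitwise
                comp[(i, j)] = (Tc[:, i, j][None]
                                - (nA * mA[..., i] * mA[..., j]
                                   + nB * mB[..., i] * mB[..., j])) / denom
        quad, det = _sym4_adjugate_quad_det(
            comp[(0, 0)], comp[(0, 1)], comp[(0, 2)], comp[(0, 3)],
            comp[(1, 1)], comp[(1, 2)], comp[(1, 3)],
            comp[(2, 2)], comp[(2, 3)], comp[(3, 3)],
            diff[..., 0], diff[..., 1], diff[..., 2], diff[..., 3])
        diag_prod = (comp[(0, 0)] * comp[(1, 1)]
                     * comp[(2, 2)] * comp[(3, 3)])
        bad = det < self.shrink_threshold * diag_prod
        if bad.any():
            # re-evaluate with diagonal shrinkage only where ill-conditioned
            s = np.float32(1 - self.shrink_gamma)
            args = [comp[(0, 0)][bad], s * comp[(0, 1)][bad],
                    s * comp[(0, 2)][bad], s * comp[(0, 3)][bad],
                    comp[(1, 1)][bad], s * comp[(1, 2)][bad],
                    s * comp[(1, 3)][bad], comp[(2, 2)][bad],
                    s * comp[(2, 3)][bad], comp[(3, 3)][bad],
                    diff[..., 0][bad], diff[..., 1][bad],
                    diff[..., 2][bad], diff[..., 3][bad]]
            q_bad, d_bad = _sym4_adjugate_quad_det(*args)
            quad[bad] = q_bad
            det[bad] = d_bad
        return c * quad / det

    def fit(self, n_perm: int = DEFAULT_N_PERM, seed: int | None = 0,
            chunk_size: int = 2048) -> ContrastResult:
        if n_perm < 100:
            raise ParameterError("n_perm must be >= 100")
        A, B = self.A, self.B
        nA, nB = A.shape[0], B.shape[0]
        N = nA + nB
        W = A.shape[1]
        X = np.concatenate([A, B], axis=0)
        M_obs = mahalanobis_stat(A, B, self.shrink_threshold,
                                 self.shrink_gamma)

        rng = np.random.default_rng(seed)
        # one label permutation per repeat, shared across all vertices;
        # the observed labelling is member 0 of the family, so the observed
        # and permuted p-maps are computed identically and are exchangeable
        # under the null (the corrected p is then uniform up to ties)
        order = np.argsort(rng.random((n_perm, N)), axis=1)
        P_A = np.zeros((n_perm + 1, N))
        P_A[0, :nA] = 1.0
        np.put_along_axis(P_A[1:], order[:, :nA], 1.0, axis=1)

        T_tot = np.einsum("nwi,nwj->wij", X, X)     # (W, k, k)
        S_tot = X.sum(axis=0)                       # (W, k)

        # p = (leave-self-in family rank) / (n_perm + 1); 'ge' counts ties
        # toward the numerator (rank 'max'), 'gt' restores strict ranking
        rank_method = "max" if self.ties == "ge" else "min"
        p_unc = np.empty(W)
        pf_family = np.zeros(n_perm + 1, dtype=np.int64)
        for start in range(0, W, chunk_size):
            sl = slice(start, min(start + chunk_size, W))
            Mf = self._perm_stats(X, T_tot, S_tot, P_A, sl)  # (n_perm+1, w)
            p_fam = rankdata(-Mf, method=rank_method, axis=0) / (n_perm + 1)
            p_unc[sl] = p_fam[0]
            pf_family += (p_fam < self.alpha).sum(axis=1)

        p_feature_obs = int(pf_family[0])
        corrected = (int((pf_family[1:] >= p_feature_obs).sum()) + 1) \
            / (n_perm + 1)
        return ContrastResult(statistic=M_obs, p_uncorrected=p_unc,
                              alpha=self.alpha, p_feature=p_feature_obs,
                              corrected_p=float(corrected), n_perm=n_perm,
                              seed=seed, group_sizes=(nA, nB))


def permutation_pmap(group_a: np.ndarray, group_b: np.ndarray,
                     n_perm: int = DEFAULT_N_PERM,
                     alpha: float = DEFAULT_ALPHA,
                     seed: int | None = 0, **kwargs) -> ContrastResult:
    """Functional wrapper around :class:`HotellingPermutationTest`."""
    return HotellingPermutationTest(group_a, group_b, alpha=alpha,
                                    **kwargs).fit(n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# directionality ratio maps
# ---------------------------------------------------------------------------

@dataclass
class RatioMap:
    """Vertex-wise ratio of group-mean Jacobian determinants.

    R(k) = mean_i det J_1i(k) / mean_j det J_2j(k) on significant vertices;
    R > 1 marks atrophy of group 2 relative to group 1 at that vertex,
    R < 1 expansion.
    """

    ratio: np.ndarray              # NaN outside the mask
    mask: np.ndarray
    group_order: tuple

    @property
    def atrophy_mask(self) -> np.ndarray:
        return self.mask & (self.ratio > 1)

    @property
    def expansion_mask(self) -> np.ndarray:
        return self.mask & (self.ratio < 1)


def ratio_map(detj_group1: np.ndarray, detj_group2: np.ndarray,
              mask: np.ndarray,
              group_order: tuple = ("group1", "group2")) -> RatioMap:
    """Directionality map from per-subject det J stacks (N, W)."""
    d1 = np.asarray(detj_group1, dtype=float)
    d2 = np.asarray(detj_group2, dtype=float)
    if np.any(d1 <= 0) or np.any(d2 <= 0):
        raise ParameterError("det J must be positive everywhere")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("empty significance mask: ratio map has no defined "
                      "vertices", stacklevel=2)
    R = np.full(mask.shape, np.nan)
    R[mask] = d1.mean(axis=0)[mask] / d2.mean(axis=0)[mask]
    return RatioMap(ratio=R, mask=mask, group_order=tuple(group_order))


# ---------------------------------------------------------------------------
# p-value CDF diagnostics
# ---------------------------------------------------------------------------

def pvalue_cdf(p_values: np.ndarray):
    """Sorted p-values against uniform quantiles, plus the maximum vertical
    deviation of the empirical CDF above the null diagonal."""
    p = np.sort(np.asarray(p_values, dtype=float).ravel())
    n = len(p)
    ecdf = np.arange(1, n + 1) / n
    deviation = float(np.max(ecdf - p))
    return p, ecdf, deviation


def plot_pvalue_cdf(results: dict, path=None):
    """CDF curves for one or more contrasts (name -> p-map or
    ContrastResult); deviation above the diagonal indicates signal."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, res in results.items():
        p = res.p_uncorrected if isinstance(res, ContrastResult) else res
        x, y, dev = pvalue_cdf(p)
        ax.plot(x, y, label=f"{name} (dev {dev:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="null")
    ax.set_xlabel("p-value")
    ax.set_ylabel("cumulative fraction of vertices")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# scalar volume comparison
# ---------------------------------------------------------------------------

def compare_volumes(volumes_a, volumes_b, n_perm: int = DEFAULT_N_PERM,
                    seed: int | None = 0) -> float:
    """Two-sided permutation p-value for the group mean-volume difference."""
    a = np.asarray(volumes_a, dtype=float)
    b = np.asarray(volumes_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each volume list needs at least 2 entries")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("degenerate volume lists (zero variance); p = 1",
                      stacklevel=2)
        return 1.0
    obs = abs(a.mean() - b.mean())
    rng = np.random.default_rng(seed)
    nA = len(a)
    count = 0
    order = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
    pa = pooled[order[:, :nA]].mean(axis=1)
    pb = pooled[order[:, nA:]].mean(axis=1)
    count = int((np.abs(pa - pb) >= obs - 1e-12).sum())
    return (count + 1) / (n_perm + 1)
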