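"""Bliss-independence linear model for singlet viabilities.

Bliss independence states V_ij = V_i * V_j for non-interacting drugs.  On the
W = -log10(V) scale it is additive, W_ij = W_i + W_j, so the full set of
pairwise combination wells of one assay forms an over-determined linear
system: one equation per observed pair, one unknown per drug.  With 108 drugs
and all C(108,2) = 5778 pairs, 5778 equations constrain 108 unknowns, and
each drug appears in n-1 equations -- measured singlet wells are deliberately
left out, so the solved singlet log-viabilities borrow strength from the
whole combination dataset instead of relying on a single well.

The system is solved by ordinary least squares with no intercept (a shift is
not identifiable separately from the unknowns on a pure pair design).  The
residual r_ij = W_ij - (w_i + w_j) measures departure from independence with
the sign convention r_ij > 0  <=>  observed combination viability lower than
the Bliss expectation  <=>  synergy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .plate_io import AssayKey
from .preprocess import AssayTable

#: relative eigenvalue tolerance for declaring the normal equations singular
RANK_TOL = 1e-10

#: two-sided 95% normal quantile used for confidence intervals
Z_95 = 1.96


class DesignError(ValueError):
    """The pair design does not admit a unique least-squares solution."""


@dataclass
class DesignSystem:
    """The linear system of one assay: rows are pairs, columns are drugs."""

    assay: AssayKey
    drugs: list[str]  # lexicographic order
    pairs: list[tuple[int, int]]  # (i, j) with i < j, indices into drugs
    w_obs: np.ndarray  # W_ij = -log10(V_ij), one per pair

    @property
    def m(self) -> int:
        return len(self.pairs)

    @property
    def n(self) -> int:
        return len(self.drugs)

    @property
    def pair_names(self) -> list[tuple[str, str]]:
        return [(self.drugs[i], self.drugs[j]) for i, j in self.pairs]

    def incidence(self) -> np.ndarray:
        """Dense m x n 0/1 incidence matrix (two ones per row)."""
        x = np.zeros((self.m, self.n))
        for r, (i, j) in enumerate(self.pairs):
            x[r, i] = 1.0
            x[r, j] = 1.0
        return x


@dataclass
class BlissFit:
    """Least-squares solution for one assay."""

    assay: AssayKey
    drugs: list[str]
    w_hat: np.ndarray  # estimated W_i per drug
    se: np.ndarray  # standard error of W_i per drug
    pairs: list[tuple[str, str]]
    w_obs: np.ndarray  # observed W_ij per pair
    fitted: np.ndarray  # w_i + w_j per pair
    residuals: np.ndarray  # W_ij - fitted; > 0 means synergy
    sigma2_model: float  # RSS / (m - n)
    r_squared: float  # 1 - RSS/TSS, TSS about the mean of W_ij

    @property
    def m(self) -> int:
        return len(self.pairs)

    @property
    def n(self) -> int:
        return len(self.drugs)

    def se_of(self, drug: str) -> float:
        return float(self.se[self.drugs.index(drug)])

    def w_of(self, drug: str) -> float:
        return float(self.w_hat[self.drugs.index(drug)])

    def v_of(self, drug: str) -> float:
        return float(10.0 ** (-self.w_of(drug)))


def build_design(assay: AssayTable) -> DesignSystem:
    """Assemble the pair-design linear system of one assay.

    One row per observed combination well; missing pairs are simply absent.
    Singlet wells never enter the system.  Raises :class:`DesignError` when
    the design is too small, has more unknowns than equations, or when the
    drug graph is disconnected (the incidence matrix then loses full column
    rank and the solution is not unique).
    """
    drugs = assay.drugs
    n = len(drugs)
    if n < 3:
        raise DesignError(f"assay {assay.assay}: need >= 3 drugs, found {n}")
    index = {d: k for k, d in enumerate(drugs)}

    pairs: list[tuple[int, int]] = []
    w_obs: list[float] = []
    for (a, b), v in sorted(assay.pair_viabilities.items()):
        if v <= 0:
            raise DesignError(f"assay {assay.assay}: non-positive viability for pair ({a}, {b})")
        i, j = index[a], index[b]
        pairs.append((i, j) if i < j else (j, i))
        w_obs.append(-np.log10(v))

    m = len(pairs)
    rows = [i for i, _ in pairs]
    cols = [j for _, j in pairs]
    adj = coo_matrix((np.ones(m), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        comps = [sorted(d for d, lab in zip(drugs, labels) if lab == c) for c in range(n_comp)]
        raise DesignError(
            f"assay {assay.assay}: pair design is disconnected; components: {comps}"
        )
    if m < n:
        raise DesignError(
            f"assay {assay.assay}: under-determined system ({m} equations, {n} unknowns)"
        )
    return DesignSystem(assay=assay.assay, drugs=drugs, pairs=pairs, w_obs=np.asarray(w_obs))


def solve_singlets(system: DesignSystem) -> BlissFit:
    """Solve the assay's linear system by ordinary least squares.

    Minimizes sum over pairs of (W_ij - w_i - w_j)^2 via the normal
    equations (Cholesky); X'X for a pair design is the degree-plus-adjacency
    matrix and is well conditioned for connected designs.  Standard errors
    come from sigma2 * diag((X'X)^-1) with sigma2 = RSS/(m - n); R^2 is
    computed against the mean-model baseline (TSS about the mean of W_ij) so
    it is comparable with a standard linear-model report.
    """
    n, m = system.n, system.m
    w = system.w_obs

    # normal equations without materializing X: A = X'X, b = X'w
    a_mat = np.zeros((n, n))
    b = np.zeros(n)
    for (i, j), wij in zip(system.pairs, w):
        a_mat[i, i] += 1.0
        a_mat[j, j] += 1.0
        a_mat[i, j] += 1.0
        a_mat[j, i] += 1.0
        b[i] += wij
        b[j] += wij

    eigvals = np.linalg.eigvalsh(a_mat)
    if eigvals[0] <= RANK_TOL * max(eigvals[-1], 1.0):
        raise DesignError(
            f"assay {system.assay}: normal equations are rank deficient "
            f"(smallest eigenvalue {eigvals[0]:.3e})"
        )

    cho = scipy.linalg.cho_factor(a_mat)
    w_hat = scipy.linalg.cho_solve(cho, b)
    a_inv = scipy.linalg.cho_solve(cho, np.eye(n))

    idx_i = np.array([i for i, _ in system.pairs], dtype=int)
    idx_j = np.array([j for _, j in system.pairs], dtype=int)
    fitted = w_hat[idx_i] + w_hat[idx_j]
    residuals = w - fitted

    rss = float(residuals @ residuals)
    tss = float(np.sum((w - w.mean()) ** 2))
    if tss > 0:
        r_squared = 1.0 - rss / tss
    else:
        r_squared = 1.0 if rss <= np.finfo(float).eps else -np.inf

    sigma2 = rss / (m - n) if m > n else 0.0
    se = np.sqrt(np.maximum(sigma2 * np.diag(a_inv), 0.0))

    return BlissFit(
        assay=system.assay,
        drugs=system.drugs,
        w_hat=w_hat,
        se=se,
        pairs=system.pair_names,
        w_obs=w,
        fitted=fitted,
        residuals=residuals,
        sigma2_model=sigma2,
        r_squared=r_squared,
    )


def fit_assay(assay: AssayTable) -> BlissFit:
    """Convenience: build the design and solve it in one call."""
    return solve_singlets(build_design(assay))


def singlet_estimates(fit: BlissFit) -> pd.DataFrame:
    """Per-drug singlet estimates with 95% confidence intervals.

    Columns: drug, w_hat, se, ci_lo, ci_hi (all on the W scale) and
    v_hat = 10**(-w_hat) on the viability scale.
    """
    return pd.DataFrame(
        {
            "drug": fit.drugs,
            "w_hat": fit.w_hat,
            "se": fit.se,
            "ci_lo": fit.w_hat - Z_95 * fit.se,
            "ci_hi": fit.w_hat + Z_95 * fit.se,
            "v_hat": 10.0 ** (-fit.w_hat),
        }
    )


def fit_summary(fits: dict[AssayKey, BlissFit]) -> pd.DataFrame:
    """One row per assay: system size, R^2 and residual variance."""
    rows = [
        {
            "cell_line": key.cell_line,
            "dose_level": key.dose_level,
            "m": fit.m,
            "n": fit.n,
            "r_squared": fit.r_squared,
            "sigma2_model": fit.sigma2_model,
        }
        for key, fit in sorted(fits.items())
    ]
    return pd.DataFrame(rows)
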