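"""Statistical calling of synergy and antagonism from model residuals.

The null hypothesis is Bliss independence: the residual of a combination
well is pure measurement noise, Gaussian on the W = -log10(V) scale with
mean zero.  Its variance is taken from the data itself: the sample variance
of the assay's DMSO wells (experimental noise of a single well) plus the
squared standard errors of the two solved singlet log-viabilities.  The
resulting Z value yields one-sided p values in each direction,

    p_syn = 1 - Phi(z),    p_ant = Phi(z),

which are Benjamini-Hochberg adjusted per direction across all pairs of the
assay.  A pair is synergistic (antagonistic) when its q value is below
alpha, and a pair is synergistic for a cell line when either of the two
dose assays calls it.

Because the null variance grows with the DMSO variance, a noisy assay
automatically demands a larger deviation for significance -- in contrast to
thresholding the raw excess-over-Bliss score, whose call count explodes
with noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .bliss_model import BlissFit
from .plate_io import AssayKey
from .preprocess import AssayTable

DEFAULT_ALPHA = 0.05

#: viability below which the W-scale variance of a well may be underestimated;
#: such pairs are flagged, not corrected.
LOW_VIABILITY_FLAG = 0.1

# Numerical guards for exactly noise-free data: a null variance at machine
# zero together with a residual at machine zero is treated as "no evidence"
# (z = 0) rather than as an ill-defined 0/0 ratio.
_VAR_FLOOR = 1e-20
_RESIDUAL_ATOL = 1e-10


@dataclass
class NullModel:
    """Null variance rule of one assay: var_dmso + se_i^2 + se_j^2."""

    assay: AssayKey
    var_dmso: float  # unbiased sample variance of DMSO W values

    def __post_init__(self) -> None:
        if self.var_dmso < 0:
            raise ValueError("var_dmso must be non-negative")


def dmso_null(assay: AssayTable) -> NullModel:
    """Build the null model of an assay from its pooled DMSO wells."""
    return NullModel(assay=assay.assay, var_dmso=assay.var_dmso)


def null_variance(null: NullModel, fit: BlissFit, pair: tuple[str, str]) -> float:
    """Total null variance for one pair's residual."""
    a, b = pair
    return null.var_dmso + fit.se_of(a) ** 2 + fit.se_of(b) ** 2


def _z_from_residual(residual: np.ndarray, var_null: np.ndarray) -> np.ndarray:
    z = np.empty_like(residual)
    degenerate = var_null < _VAR_FLOOR
    with np.errstate(divide="ignore", invalid="ignore"):
        z[~degenerate] = residual[~degenerate] / np.sqrt(var_null[~degenerate])
    zero_resid = np.abs(residual) < _RESIDUAL_ATOL
    z[degenerate & zero_resid] = 0.0
    z[degenerate & ~zero_resid] = np.sign(residual[degenerate & ~zero_resid]) * np.inf
    return z


def synergy_pvalues(fit: BlissFit, null: NullModel, assay: AssayTable | None = None) -> pd.DataFrame:
    """Per-pair Z values and one-sided p values for synergy and antagonism.

    Also reports the excess-over-Bliss score S_ij = V_i*V_j - V_ij computed
    two ways: ``eob_raw`` from the measured singlet wells (NaN when a
    measured singlet is absent) and ``eob_model`` from the solved singlets.
    ``low_viability`` flags pairs with V_ij < 0.1, where the W-scale noise
    variance may be underestimated.
    """
    if assay is not None and assay.assay != fit.assay:
        raise ValueError("fit and assay table refer to different assays")

    idx = {d: k for k, d in enumerate(fit.drugs)}
    se2 = fit.se**2
    i_idx = np.array([idx[a] for a, _ in fit.pairs], dtype=int)
    j_idx = np.array([idx[b] for _, b in fit.pairs], dtype=int)
    var_null = null.var_dmso + se2[i_idx] + se2[j_idx]

    z = _z_from_residual(fit.residuals, var_null)
    p_syn = norm.sf(z)
    p_ant = norm.cdf(z)

    v_ij = 10.0 ** (-fit.w_obs)
    v_hat = 10.0 ** (-fit.w_hat)
    eob_model = v_hat[i_idx] * v_hat[j_idx] - v_ij

    if assay is not None:
        meas = assay.singlet_viabilities
        vi = np.array([meas.get(a, np.nan) for a, _ in fit.pairs])
        vj = np.array([meas.get(b, np.nan) for _, b in fit.pairs])
        eob_raw = vi * vj - v_ij
    else:
        eob_raw = np.full(fit.m, np.nan)

    return pd.DataFrame(
        {
            "cell_line": fit.assay.cell_line,
            "dose_level": fit.assay.dose_level,
            "drug1": [a for a, _ in fit.pairs],
            "drug2": [b for _, b in fit.pairs],
            "residual": fit.residuals,
            "var_null": var_null,
            "z": z,
            "p_syn": p_syn,
            "p_ant": p_ant,
            "eob_raw": eob_raw,
            "eob_model": eob_model,
            "low_viability": v_ij < LOW_VIABILITY_FLAG,
        }
    )


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_synergies(calls: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Attach BH q values and boolean calls to a per-assay p-value table.

    BH is applied separately to the synergy-direction and the antagonism-
    direction p-value families, each across all pairs of the assay.
    """
    out = calls.copy()
    out["q_syn"] = adjust_fdr(out["p_syn"].to_numpy())
    out["q_ant"] = adjust_fdr(out["p_ant"].to_numpy())
    out["synergistic"] = out["q_syn"] < alpha
    out["antagonistic"] = out["q_ant"] < alpha
    return out


def infer_assay(
    fit: BlissFit, assay: AssayTable, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Convenience: null model -> p values -> q values -> calls for one assay."""
    return call_synergies(synergy_pvalues(fit, dmso_null(assay), assay), alpha=alpha)


def combine_doses(high: pd.DataFrame | None, low: pd.DataFrame | None) -> pd.DataFrame:
    """Per (pair, cell line) synergy verdicts combined across the two doses.

    A combination is synergistic in a cell line if either dose assay calls
    it; a pair observed at only one dose inherits that dose's verdict.
    Returns columns (cell_line, drug1, drug2, synergistic, antagonistic).
    """
    frames = [f for f in (high, low) if f is not None and len(f)]
    if not frames:
        raise ValueError("no calls to combine")
    stacked = pd.concat(frames, ignore_index=True)
    combined = (
        stacked.groupby(["cell_line", "drug1", "drug2"], sort=True)[
            ["synergistic", "antagonistic"]
        ]
        .any()
        .reset_index()
    )
    return combined


def combine_all_doses(calls_by_assay: dict[AssayKey, pd.DataFrame]) -> pd.DataFrame:
    """Dose-combine per-assay call tables for every cell line of a screen."""
    cell_lines = sorted({k.cell_line for k in calls_by_assay})
    pieces = []
    for cl in cell_lines:
        high = calls_by_assay.get(AssayKey(cl, "high"))
        low = calls_by_assay.get(AssayKey(cl, "low"))
        pieces.append(combine_doses(high, low))
    return pd.concat(pieces, ignore_index=True)
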