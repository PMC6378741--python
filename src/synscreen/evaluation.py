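"""Internal-consistency analyses of a fitted screen.

The screen has no technical replicates, so consistency between the two dose
assays of the same cell line serves as a proxy for replication:

* per-drug Pearson correlation of singlet viabilities across cell lines
  between the high- and low-dose assays, computed once with the measured
  singlet wells and once with the model-estimated singlets -- the estimated
  singlets should correlate better because the linear model pools n-1
  combination wells per drug instead of relying on a single well;
* a paired t test comparing the two per-drug correlation vectors;
* per-drug Fisher exact tests for overlap of synergy calls between doses
  over the (partner drug, cell line) grid;
* per-assay agreement between estimated and measured singlet viabilities.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .bliss_model import BlissFit
from .plate_io import AssayKey
from .preprocess import AssayTable

logger = logging.getLogger(__name__)

CORRELATION_ALPHA = 0.05


def singlet_agreement(fit: BlissFit, assay: AssayTable) -> float:
    """Pearson r between estimated and measured singlet viabilities (V scale).

    Returns NaN when fewer than 3 drugs have measured singlets or when either
    side has zero variance.
    """
    drugs = [d for d in fit.drugs if d in assay.singlet_viabilities]
    if len(drugs) < 3:
        return float("nan")
    est = np.array([fit.v_of(d) for d in drugs])
    meas = np.array([assay.singlet_viabilities[d] for d in drugs])
    if np.std(est) == 0 or np.std(meas) == 0:
        return float("nan")
    return float(stats.pearsonr(est, meas).statistic)


def measured_singlet_matrix(
    assays: dict[AssayKey, AssayTable], dose_level: str
) -> pd.DataFrame:
    """Drugs x cell-lines matrix of measured singlet viabilities at one dose."""
    cols = {}
    for key, table in sorted(assays.items()):
        if key.dose_level == dose_level:
            cols[key.cell_line] = pd.Series(table.singlet_viabilities)
    return pd.DataFrame(cols)


def estimated_singlet_matrix(
    fits: dict[AssayKey, BlissFit], dose_level: str
) -> pd.DataFrame:
    """Drugs x cell-lines matrix of model-estimated singlet viabilities."""
    cols = {}
    for key, fit in sorted(fits.items()):
        if key.dose_level == dose_level:
            cols[key.cell_line] = pd.Series(10.0 ** (-fit.w_hat), index=fit.drugs)
    return pd.DataFrame(cols)


def cross_dose_correlations(
    high: pd.DataFrame, low: pd.DataFrame, variant: str = ""
) -> pd.DataFrame:
    """Per-drug correlation of singlet values across cell lines between doses.

    ``high`` and ``low`` are drugs x cell-lines matrices.  For each drug with
    >= 3 paired finite values, the Pearson r between its high- and low-dose
    vectors is computed with the exact t-transform correlation test
    (t = r * sqrt(n-2) / sqrt(1-r^2), two-sided).  Drugs with fewer paired
    values are skipped and logged.
    """
    cell_lines = [c for c in high.columns if c in low.columns]
    rows = []
    for drug in high.index:
        if drug not in low.index:
            continue
        x = high.loc[drug, cell_lines].to_numpy(dtype=float)
        y = low.loc[drug, cell_lines].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            logger.info("cross_dose_correlations: drug %s skipped (<3 paired values)", drug)
            continue
        res = stats.pearsonr(x[ok], y[ok])
        rows.append(
            {
                "drug": drug,
                "variant": variant,
                "r": float(res.statistic),
                "p": float(res.pvalue),
                "n_cell_lines": int(ok.sum()),
                "significant": bool(res.pvalue < CORRELATION_ALPHA),
            }
        )
    return pd.DataFrame(
        rows, columns=["drug", "variant", "r", "p", "n_cell_lines", "significant"]
    )


def compare_correlation_vectors(
    measured_rs: np.ndarray | pd.Series,
    estimated_rs: np.ndarray | pd.Series,
    paired: bool = True,
) -> dict:
    """Compare the two per-drug correlation vectors.

    Default is a paired two-sided t test on (estimated r - measured r) --
    the same drugs are evaluated under both variants.  Reports both medians.
    """
    meas = np.asarray(measured_rs, dtype=float)
    est = np.asarray(estimated_rs, dtype=float)
    if paired and len(meas) != len(est):
        raise ValueError("paired comparison needs vectors aligned by drug")
    if paired:
        diff = est - meas
        if np.allclose(diff, 0):
            p, t = 1.0, 0.0
        else:
            res = stats.ttest_rel(est, meas)
            t, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.ttest_ind(est, meas)
        t, p = float(res.statistic), float(res.pvalue)
    return {
        "median_measured": float(np.median(meas)),
        "median_estimated": float(np.median(est)),
        "statistic": t,
        "p_value": p,
    }


def fisher_overlap_per_drug(
    high_calls: pd.DataFrame, low_calls: pd.DataFrame
) -> pd.DataFrame:
    """Per-drug Fisher exact test for synergy overlap between the two doses.

    The unit is a (partner drug, cell line) combination present at both
    doses; the 2x2 table cross-tabulates synergy-at-high against
    synergy-at-low.  Columns: per-dose synergy counts, overlap count, the
    two-sided Fisher p and a significance flag at 0.05.
    """
    def melt(calls: pd.DataFrame, name: str) -> pd.DataFrame:
        a = calls[["cell_line", "drug1", "drug2", "synergistic"]].copy()
        b = a.rename(columns={"drug1": "drug2", "drug2": "drug1"})
        both = pd.concat([a, b], ignore_index=True)
        both = both.rename(columns={"drug1": "drug", "drug2": "partner", "synergistic": name})
        return both

    merged = melt(high_calls, "syn_high").merge(
        melt(low_calls, "syn_low"), on=["cell_line", "drug", "partner"], how="inner"
    )
    rows = []
    for drug, grp in merged.groupby("drug", sort=True):
        if len(grp) == 0:
            continue
        hi = grp["syn_high"].to_numpy(dtype=bool)
        lo = grp["syn_low"].to_numpy(dtype=bool)
        table = [
            [int((hi & lo).sum()), int((hi & ~lo).sum())],
            [int((~hi & lo).sum()), int((~hi & ~lo).sum())],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "drug": drug,
                "n_units": len(grp),
                "n_syn_high": int(hi.sum()),
                "n_syn_low": int(lo.sum()),
                "n_overlap": table[0][0],
                "fisher_p": float(p),
                "overlap_significant": bool(p < CORRELATION_ALPHA),
            }
        )
    return pd.DataFrame(rows)
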