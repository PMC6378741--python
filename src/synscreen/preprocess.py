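"""Normalization of raw nuclei counts to viabilities.

Per plate the pipeline is: (i) optional one-iteration Tukey median polish of
log10 counts over the physical rows and columns of the plate, re-exponentiated
(so that spatial plate artifacts are removed without ever producing negative
counts); (ii) a DMSO control value per plate, the 10%-per-side trimmed mean of
the (adjusted) control-well counts; (iii) viability = adjusted count / control
value for every well.

Viability V is a dimensionless fraction of control and can exceed 1 by noise.
All downstream modeling works on W = -log10(V), on which Bliss independence
is additive.  DMSO wells are themselves converted to W and pooled per assay:
their sample variance calibrates the null model for synergy testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .plate_io import AssayKey, PlateTable, WELL_CONTROL, WELL_PAIR, WELL_SINGLET

logger = logging.getLogger(__name__)

DEFAULT_TRIM_FRACTION = 0.10
DEFAULT_PSEUDOCOUNT = 0.5
LOG_BASE = 10.0  # fixed; W = -log10(V) throughout


def pair_key(drug_a: str, drug_b: str) -> tuple[str, str]:
    """Canonical unordered key for a drug pair (lexicographically sorted)."""
    if drug_a == drug_b:
        raise ValueError(f"self-pair {drug_a!r}")
    return (drug_a, drug_b) if drug_a < drug_b else (drug_b, drug_a)


@dataclass
class AssayTable:
    """Per (cell line, dose level): pair/singlet viabilities and DMSO stats."""

    assay: AssayKey
    pair_viabilities: dict[tuple[str, str], float]
    singlet_viabilities: dict[str, float]
    dmso_log_viabilities: np.ndarray  # W = -log10(V) per DMSO well, pooled over plates
    control_values: dict[str, float] = field(default_factory=dict)  # per plate
    pair_source_plate: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def drugs(self) -> list[str]:
        names: set[str] = set()
        for a, b in self.pair_viabilities:
            names.add(a)
            names.add(b)
        return sorted(names)

    @property
    def var_dmso(self) -> float:
        """Unbiased sample variance of the DMSO W values (>= 2 wells)."""
        if len(self.dmso_log_viabilities) < 2:
            raise ValueError(
                f"assay {self.assay}: need >= 2 DMSO wells for a sample variance"
            )
        return float(np.var(self.dmso_log_viabilities, ddof=1))


def _median_polish_log10_components(
    log_grid: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """One iteration of Tukey median polish on a log10 grid.

    One row sweep followed by one column sweep (medians ignore missing
    cells), with the customary re-centering of the effect vectors into the
    overall term.  Returns (overall, row_effects, col_effects, residuals).
    """
    z = log_grid.copy()
    n_rows, n_cols = z.shape
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    overall = 0.0

    with np.errstate(all="ignore"):
        r_med = np.nanmedian(z, axis=1)
    r_med = np.where(np.isnan(r_med), 0.0, r_med)
    z -= r_med[:, None]
    row_eff += r_med
    # median of (still all-zero) column effects is zero; kept for symmetry
    delta = np.median(col_eff)
    col_eff -= delta
    overall += delta

    with np.errstate(all="ignore"):
        c_med = np.nanmedian(z, axis=0)
    c_med = np.where(np.isnan(c_med), 0.0, c_med)
    z -= c_med[None, :]
    col_eff += c_med
    delta = np.median(row_eff)
    row_eff -= delta
    overall += delta

    return overall, row_eff, col_eff, z


def median_polish_log(
    grid: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> np.ndarray:
    """Remove row/column plate effects from a grid of counts.

    Exactly one row sweep followed by one column sweep of Tukey median polish
    is applied to log10 counts; the output cell is 10**(overall + residual),
    i.e. the count with fitted row and column effects divided out.  Missing
    cells (NaN) stay missing.  Zero counts are replaced by ``pseudocount``
    before taking logs (working on the log scale is what guarantees the
    adjusted counts stay positive).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2 or grid.shape[0] < 2 or grid.shape[1] < 2:
        raise ValueError("median polish needs a 2-D grid with >= 2 rows and >= 2 columns")
    finite = np.isfinite(grid)
    if not finite.any(axis=1).all() or not finite.any(axis=0).all():
        raise ValueError("median polish needs at least one finite value per row and column")

    work = grid.copy()
    zeros = finite & (work == 0)
    if zeros.any():
        logger.warning(
            "median_polish_log: %d zero count(s) replaced by pseudocount %g",
            int(zeros.sum()),
            pseudocount,
        )
        work[zeros] = pseudocount
    nonpos = finite & (work <= 0)
    if nonpos.any():
        r, c = np.argwhere(nonpos)[0]
        raise ValueError(f"non-positive count at grid cell ({r}, {c}) after pseudocount handling")

    log_grid = np.where(finite, np.log10(np.where(finite, work, 1.0)), np.nan)
    overall, _row, _col, resid = _median_polish_log10_components(log_grid)
    return np.power(10.0, overall + resid)


def trimmed_mean_control(
    counts: np.ndarray | list[float], trim_fraction: float = DEFAULT_TRIM_FRACTION
) -> float:
    """Symmetric trimmed mean of control-well counts.

    Removes floor(n * trim_fraction) smallest and largest values and returns
    the arithmetic mean of the rest (default 10% per side).
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    values = np.sort(np.asarray(counts, dtype=float))
    n = len(values)
    k = int(np.floor(n * trim_fraction))
    survivors = values[k : n - k] if k > 0 else values
    if len(survivors) == 0:
        raise ValueError("no control values survive trimming")
    return float(np.mean(survivors))


def _check_pair_connectivity(assay: AssayTable) -> None:
    drugs = assay.drugs
    if len(drugs) < 2 or not assay.pair_viabilities:
        return
    index = {d: i for i, d in enumerate(drugs)}
    rows = [index[a] for a, _ in assay.pair_viabilities]
    cols = [index[b] for _, b in assay.pair_viabilities]
    n = len(drugs)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        logger.warning(
            "assay %s: pair design does not connect all %d drugs "
            "(%d components); the linear model will fail for this assay",
            assay.assay,
            n,
            n_comp,
        )


def compute_viabilities(
    plates: PlateTable,
    polish: bool = True,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[AssayKey, AssayTable]:
    """Normalize a plate table into per-assay viability tables.

    Per plate: optional median polish of the count grid, then the DMSO
    control value (trimmed mean of adjusted control counts), then viability =
    adjusted count / control value for every well.  Records are then grouped
    by (cell line, dose level); DMSO wells contribute W = -log10(V) values
    pooled over all of the assay's plates.
    """
    records = plates.records
    n_rows, n_cols = plates.plate_shape

    adjusted = np.empty(len(records), dtype=float)
    control_values: dict[str, float] = {}
    viability = np.empty(len(records), dtype=float)

    pos = {rec_idx: i for i, rec_idx in enumerate(records.index)}
    for plate_id, plate_recs in records.groupby("plate_id", sort=False):
        rows = plate_recs["row"].to_numpy() - 1
        cols = plate_recs["col"].to_numpy() - 1
        counts = plate_recs["count"].to_numpy(dtype=float)
        if polish:
            grid = np.full((n_rows, n_cols), np.nan)
            grid[rows, cols] = counts
            # plates need not be full: polish only the occupied rows/columns
            used_rows = np.unique(rows)
            used_cols = np.unique(cols)
            sub = grid[np.ix_(used_rows, used_cols)]
            adj_sub = median_polish_log(sub, pseudocount=pseudocount)
            adj_grid = np.full((n_rows, n_cols), np.nan)
            adj_grid[np.ix_(used_rows, used_cols)] = adj_sub
            adj = adj_grid[rows, cols]
        else:
            adj = np.where(counts == 0, pseudocount, counts)

        is_ctrl = plate_recs["well_class"].to_numpy() == WELL_CONTROL
        if is_ctrl.sum() < 2:
            raise ValueError(f"plate {plate_id!r} has fewer than 2 DMSO wells")
        control = trimmed_mean_control(adj[is_ctrl], trim_fraction=trim_fraction)
        control_values[str(plate_id)] = control

        idx = [pos[i] for i in plate_recs.index]
        adjusted[idx] = adj
        viability[idx] = adj / control

    work = records.copy()
    work["viability"] = viability

    assays: dict[AssayKey, AssayTable] = {}
    for (cell_line, dose), grp in work.groupby(["cell_line", "dose_level"], sort=True):
        key = AssayKey(cell_line, dose)
        pairs: dict[tuple[str, str], float] = {}
        pair_src: dict[tuple[str, str], str] = {}
        pair_counts: dict[tuple[str, str], int] = {}
        singlets: dict[str, float] = {}
        singlet_counts: dict[str, int] = {}
        dmso_w: list[float] = []

        for rec in grp.itertuples(index=False):
            if rec.well_class == WELL_CONTROL:
                dmso_w.append(-np.log10(rec.viability))
            elif rec.well_class == WELL_SINGLET:
                singlets[rec.drug1] = singlets.get(rec.drug1, 0.0) + rec.viability
                singlet_counts[rec.drug1] = singlet_counts.get(rec.drug1, 0) + 1
            elif rec.well_class == WELL_PAIR:
                k = pair_key(rec.drug1, rec.drug2)
                pairs[k] = pairs.get(k, 0.0) + rec.viability
                pair_counts[k] = pair_counts.get(k, 0) + 1
                pair_src[k] = str(rec.plate_id)

        # replicate wells (rare in a sparse screen) are averaged
        for k, n in pair_counts.items():
            if n > 1:
                pairs[k] /= n
        for d, n in singlet_counts.items():
            if n > 1:
                singlets[d] /= n

        plate_ids = set(grp["plate_id"].astype(str))
        table = AssayTable(
            assay=key,
            pair_viabilities=pairs,
            singlet_viabilities=singlets,
            dmso_log_viabilities=np.asarray(dmso_w, dtype=float),
            control_values={p: control_values[p] for p in plate_ids},
            pair_source_plate=pair_src,
        )
        _check_pair_connectivity(table)
        assays[key] = table
    return assays
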