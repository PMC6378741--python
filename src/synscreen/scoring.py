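"""Drug-pair synergy scores aggregated across cell lines.

The dose-combined boolean calls form a synergy cube (drugs x drugs x cell
lines).  Two summary scores are computed per unordered pair:

* absolute synergy score ``T_ij`` -- the number of cell lines in which the
  pair is called synergistic (0..n_cell_lines);
* specificity score ``Sc_ij`` -- the smaller of the two partner-wise z
  standardizations of T_ij,

      Sc_ij = min( (T_ij - mean_k T_ik) / SD_k(T_ik),
                   (T_ij - mean_k T_kj) / SD_k(T_kj) ),

  with k ranging over all partners of the drug.  A promiscuous sensitizer
  synergizes with many partners, so all its T_ik are high and none stands
  out; the specificity score separates such broad potentiation from
  synergies that are specific to one partner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class SynergyCube:
    """Boolean synergy calls indexed by (drug i, drug j, cell line).

    ``synergy`` has shape (n_drugs, n_drugs, n_cell_lines), is symmetric in
    the first two axes and False on the diagonal (no self-pairs).
    """

    drugs: list[str]
    cell_lines: list[str]
    synergy: np.ndarray

    def __post_init__(self) -> None:
        n, ncl = len(self.drugs), len(self.cell_lines)
        if self.synergy.shape != (n, n, ncl):
            raise ValueError(f"synergy array must have shape {(n, n, ncl)}")
        if not np.array_equal(self.synergy, self.synergy.transpose(1, 0, 2)):
            raise ValueError("synergy cube must be symmetric in the drug axes")
        if self.synergy[np.arange(n), np.arange(n), :].any():
            raise ValueError("synergy cube must be False on the diagonal")

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_cell_lines(self) -> int:
        return len(self.cell_lines)


def cube_from_calls(
    combined: pd.DataFrame,
    drugs: list[str] | None = None,
    cell_lines: list[str] | None = None,
) -> SynergyCube:
    """Build a synergy cube from dose-combined calls.

    ``combined`` needs columns (cell_line, drug1, drug2, synergistic);
    (pair, cell line) units absent from the table count as not synergistic.
    """
    if drugs is None:
        drugs = sorted(set(combined["drug1"]) | set(combined["drug2"]))
    if cell_lines is None:
        cell_lines = sorted(set(combined["cell_line"]))
    d_idx = {d: i for i, d in enumerate(drugs)}
    c_idx = {c: i for i, c in enumerate(cell_lines)}

    cube = np.zeros((len(drugs), len(drugs), len(cell_lines)), dtype=bool)
    hits = combined[combined["synergistic"]]
    for rec in hits.itertuples(index=False):
        i, j, c = d_idx[rec.drug1], d_idx[rec.drug2], c_idx[rec.cell_line]
        cube[i, j, c] = cube[j, i, c] = True
    return SynergyCube(drugs=drugs, cell_lines=cell_lines, synergy=cube)


def absolute_synergy_scores(cube: SynergyCube) -> np.ndarray:
    """T_ij = number of cell lines in which pair (i, j) shows synergy."""
    return cube.synergy.sum(axis=2).astype(int)


def specificity_scores(t_matrix: np.ndarray, include_self: bool = True) -> np.ndarray:
    """Partner-standardized specificity score Sc per pair.

    ``include_self=True`` (default) takes the partner set of drug i as all
    k != i, so the pair's own T_ij enters its reference mean and SD.  A drug
    whose partner scores have zero SD contributes a neutral z of 0 instead of
    an infinity.  The diagonal is NaN (self-pairs are undefined).
    """
    t = np.asarray(t_matrix, dtype=float)
    n = t.shape[0]
    if t.shape != (n, n) or n < 3:
        raise ValueError("need a square T matrix over >= 3 drugs")
    if not np.allclose(t, t.T):
        raise ValueError("T matrix must be symmetric")

    z = np.zeros((n, n))
    off = ~np.eye(n, dtype=bool)
    for i in range(n):
        partners = t[i, off[i]]
        if include_self:
            mu = partners.mean()
            sd = partners.std(ddof=1)
            z[i] = np.divide(t[i] - mu, sd, out=np.zeros(n), where=sd > 0)
        else:
            for j in range(n):
                if j == i:
                    continue
                ref = t[i, (np.arange(n) != i) & (np.arange(n) != j)]
                if len(ref) < 2:
                    raise ValueError("need >= 2 reference partners per drug")
                sd = ref.std(ddof=1)
                z[i, j] = (t[i, j] - ref.mean()) / sd if sd > 0 else 0.0

    sc = np.minimum(z, z.T)
    np.fill_diagonal(sc, np.nan)
    return sc


def rank_combinations(
    t_matrix: np.ndarray, sc_matrix: np.ndarray, drugs: list[str]
) -> pd.DataFrame:
    """Ranked list of drug pairs.

    Ordered by absolute score descending, specificity score as tie-break;
    ``sc_percentile`` is the percentile of the pair's specificity score
    among all pairs (the maximum is at 100).
    """
    n = len(drugs)
    iu, ju = np.triu_indices(n, k=1)
    table = pd.DataFrame(
        {
            "drug1": [drugs[i] for i in iu],
            "drug2": [drugs[j] for j in ju],
            "absolute_score": t_matrix[iu, ju].astype(int),
            "specificity_score": sc_matrix[iu, ju],
        }
    )
    table["sc_percentile"] = (
        rankdata(table["specificity_score"], method="max") / len(table) * 100.0
    )
    table = table.sort_values(
        ["absolute_score", "specificity_score"],
        ascending=[False, False],
        kind="mergesort",
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


def score_screen(cube: SynergyCube, include_self: bool = True) -> pd.DataFrame:
    """Convenience: absolute + specificity scores as a ranked table."""
    t = absolute_synergy_scores(cube)
    sc = specificity_scores(t, include_self=include_self)
    return rank_combinations(t, sc, cube.drugs)
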