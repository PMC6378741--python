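"""Synthetic drug-combination screens with known ground truth.

The generator emulates the structure of a sparse 1536-well combination
screen: for each (cell line, dose) assay it lays out all C(n,2) combination
wells, one singlet well per drug and a block of DMSO wells in pseudo-random
positions on as many plates as needed.  The data-generating model matches
the assumptions of the analysis exactly:

    W_ij = W_i + W_j + delta_planted + eps,   eps ~ N(0, noise_sd_w^2)

on the W = -log10(viability) scale, with counts = base_count * 10**(-W)
times optional multiplicative per-plate row/column artifacts.  Singlet wells
receive ``singlet_well_noise_multiplier`` times the per-well noise SD,
modeling the fact that a viability measured in a single well is noisier than
what the pooled combination data implies.  True high-dose potencies are
drawn per (drug, cell line); low-dose potencies are a scaled-down version
with small jitter, giving the cross-dose correlation structure that the
consistency analyses quantify.

Planted synergies/antagonisms shift specific (pair, cell line, dose) cells
by ``delta_w`` on the W scale; a promiscuous drug gets Bernoulli-planted
synergies across its partners, emulating a broad sensitizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plate_io import AssayKey, PlateTable, CANONICAL_COLUMNS

MAX_PLATES_PER_ASSAY = 100

DOSES_BOTH = ("high", "low")


@dataclass(frozen=True)
class PlantedEffect:
    """A planted deviation from Bliss independence on the W scale.

    ``delta_w > 0`` is synergy (combination kills more than expected),
    ``delta_w < 0`` antagonism.  ``cell_lines``/``doses`` = None plants the
    effect everywhere.
    """

    drug1: str
    drug2: str
    delta_w: float
    cell_lines: tuple[str, ...] | None = None
    doses: tuple[str, ...] | None = None

    def applies(self, cell_line: str, dose: str) -> bool:
        if self.cell_lines is not None and cell_line not in self.cell_lines:
            return False
        return self.doses is None or dose in self.doses


@dataclass(frozen=True)
class PromiscuousDrug:
    """A broad sensitizer: synergy planted with each partner w.p. ``prob``."""

    drug: str
    prob: float
    delta_w: float


@dataclass
class ScreenSpec:
    """Parameters of one synthetic screen.

    ``singlet_w_mean/sd`` describe the distribution of true high-dose drug
    potencies W_i across (drug, cell line); low-dose potencies are
    ``low_dose_potency`` times the high-dose value plus N(0, cross_dose_jitter_sd).
    All noise SDs are on the W (log10 viability) scale.
    """

    n_drugs: int = 20
    n_cell_lines: int = 8
    doses: tuple[str, ...] = DOSES_BOTH
    plate_shape: tuple[int, int] = (16, 24)
    n_dmso_per_plate: int = 16
    singlet_w_mean: float = 0.15
    singlet_w_sd: float = 0.15
    low_dose_potency: float = 0.4
    cross_dose_jitter_sd: float = 0.03
    noise_sd_w: float = 0.05
    singlet_well_noise_multiplier: float = 3.0
    planted_synergies: tuple[PlantedEffect, ...] = ()
    planted_antagonisms: tuple[PlantedEffect, ...] = ()
    promiscuous_drugs: tuple[PromiscuousDrug, ...] = ()
    row_col_artifact_sd: float = 0.0
    base_count: float = 1000.0
    count_noise: str = "none"  # "none" (log-normal only) or "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 3:
            raise ValueError("need >= 3 drugs")
        if self.n_cell_lines < 1:
            raise ValueError("need >= 1 cell line")
        if self.n_dmso_per_plate < 2:
            raise ValueError("need >= 2 DMSO wells per plate")
        for sd in (self.singlet_w_sd, self.noise_sd_w, self.cross_dose_jitter_sd,
                   self.row_col_artifact_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.singlet_well_noise_multiplier < 1:
            raise ValueError("singlet_well_noise_multiplier must be >= 1")
        bad = [d for d in self.doses if d not in DOSES_BOTH]
        if bad:
            raise ValueError(f"unknown dose level(s) {bad}")

    @property
    def drug_names(self) -> list[str]:
        width = len(str(self.n_drugs))
        return [f"D{k:0{width}d}" for k in range(1, self.n_drugs + 1)]

    @property
    def cell_line_names(self) -> list[str]:
        width = len(str(self.n_cell_lines))
        return [f"CL{k:0{width}d}" for k in range(1, self.n_cell_lines + 1)]

    @property
    def n_pairs(self) -> int:
        return self.n_drugs * (self.n_drugs - 1) // 2


@dataclass
class GroundTruth:
    """True values behind a generated screen.

    ``w_true[assay][drug]`` -- true singlet W at that (cell line, dose);
    ``pair_effects[assay][(d1, d2)]`` -- planted delta_w (only planted pairs);
    ``true_pair_w[assay][(d1, d2)]`` -- noise-free W_ij including effects.
    """

    w_true: dict[AssayKey, dict[str, float]] = field(default_factory=dict)
    pair_effects: dict[AssayKey, dict[tuple[str, str], float]] = field(default_factory=dict)
    true_pair_w: dict[AssayKey, dict[tuple[str, str], float]] = field(default_factory=dict)

    def planted_pairs(self, assay: AssayKey) -> list[tuple[str, str]]:
        return sorted(self.pair_effects.get(assay, {}))


def _planted_effect_map(
    spec: ScreenSpec, rng: np.random.Generator
) -> dict[tuple[str, str, str, str], float]:
    """Resolve all planted effects into {(d1, d2, cell_line, dose): delta}."""
    effects: dict[tuple[str, str, str, str], float] = {}
    for eff in (*spec.planted_synergies, *spec.planted_antagonisms):
        a, b = sorted((eff.drug1, eff.drug2))
        for cl in eff.cell_lines or spec.cell_line_names:
            for dose in eff.doses or spec.doses:
                effects[(a, b, cl, dose)] = effects.get((a, b, cl, dose), 0.0) + eff.delta_w
    # promiscuous sensitizers: partners drawn once, effect applied at every
    # (cell line, dose) so the drug's T row is uniformly elevated
    for promo in spec.promiscuous_drugs:
        for partner in spec.drug_names:
            if partner == promo.drug:
                continue
            if rng.random() < promo.prob:
                a, b = sorted((promo.drug, partner))
                for cl in spec.cell_line_names:
                    for dose in spec.doses:
                        effects[(a, b, cl, dose)] = (
                            effects.get((a, b, cl, dose), 0.0) + promo.delta_w
                        )
    return effects


def generate_screen(spec: ScreenSpec) -> tuple[PlateTable, GroundTruth]:
    """Generate one complete synthetic screen plus its ground truth.

    Deterministic for a given spec (all randomness flows from ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    drugs = spec.drug_names
    cell_lines = spec.cell_line_names
    n_rows, n_cols = spec.plate_shape
    capacity = n_rows * n_cols

    treat_per_assay = spec.n_pairs + spec.n_drugs
    usable = capacity - spec.n_dmso_per_plate
    if usable <= 0:
        raise ValueError("plate has no room for treatment wells beside DMSO wells")
    n_plates = int(np.ceil(treat_per_assay / usable))
    if n_plates > MAX_PLATES_PER_ASSAY:
        raise ValueError(
            f"{treat_per_assay} treatment wells need {n_plates} plates per assay "
            f"(> {MAX_PLATES_PER_ASSAY}); reduce n_drugs or enlarge plate_shape"
        )

    effects = _planted_effect_map(spec, rng)
    truth = GroundTruth()

    pairs = [(drugs[i], drugs[j]) for i in range(spec.n_drugs) for j in range(i + 1, spec.n_drugs)]
    frames: list[pd.DataFrame] = []

    for cl in cell_lines:
        w_high = rng.normal(spec.singlet_w_mean, spec.singlet_w_sd, size=spec.n_drugs)
        for dose in spec.doses:
            key = AssayKey(cl, dose)
            if dose == "high":
                w_true = w_high.copy()
            else:
                w_true = spec.low_dose_potency * w_high + rng.normal(
                    0.0, spec.cross_dose_jitter_sd, size=spec.n_drugs
                )
            w_map = dict(zip(drugs, w_true))
            truth.w_true[key] = {d: float(w) for d, w in w_map.items()}
            truth.pair_effects[key] = {}
            truth.true_pair_w[key] = {}

            # ideal W per well, before noise
            well_drug1: list[object] = []
            well_drug2: list[object] = []
            well_w: list[float] = []
            well_noise_sd: list[float] = []
            well_is_ctrl: list[bool] = []

            for a, b in pairs:
                delta = effects.get((a, b, cl, dose), 0.0)
                wij = w_map[a] + w_map[b] + delta
                if delta != 0.0:
                    truth.pair_effects[key][(a, b)] = delta
                truth.true_pair_w[key][(a, b)] = float(wij)
                well_drug1.append(a)
                well_drug2.append(b)
                well_w.append(wij)
                well_noise_sd.append(spec.noise_sd_w)
                well_is_ctrl.append(False)
            for d in drugs:
                well_drug1.append(d)
                well_drug2.append(None)
                well_w.append(w_map[d])
                well_noise_sd.append(spec.noise_sd_w * spec.singlet_well_noise_multiplier)
                well_is_ctrl.append(False)

            n_treat = len(well_w)
            order = rng.permutation(n_treat)

            rows_out: dict[str, list] = {c: [] for c in CANONICAL_COLUMNS}
            cursor = 0
            for p in range(n_plates):
                plate_id = f"{cl}_{dose}_p{p + 1}"
                take = min(usable, n_treat - cursor)
                plate_idx = order[cursor : cursor + take]
                cursor += take

                n_wells = take + spec.n_dmso_per_plate
                positions = rng.permutation(capacity)[:n_wells]
                prow = positions // n_cols + 1
                pcol = positions % n_cols + 1

                row_eff = (
                    rng.normal(0.0, spec.row_col_artifact_sd, size=n_rows)
                    if spec.row_col_artifact_sd > 0
                    else np.zeros(n_rows)
                )
                col_eff = (
                    rng.normal(0.0, spec.row_col_artifact_sd, size=n_cols)
                    if spec.row_col_artifact_sd > 0
                    else np.zeros(n_cols)
                )

                w_ideal = np.concatenate(
                    [
                        np.array([well_w[k] for k in plate_idx]),
                        np.zeros(spec.n_dmso_per_plate),  # DMSO: W = 0
                    ]
                )
                noise_sd = np.concatenate(
                    [
                        np.array([well_noise_sd[k] for k in plate_idx]),
                        np.full(spec.n_dmso_per_plate, spec.noise_sd_w),
                    ]
                )
                w_noisy = w_ideal + rng.normal(0.0, 1.0, size=n_wells) * noise_sd
                counts = (
                    spec.base_count
                    * 10.0 ** (-w_noisy)
                    * 10.0 ** row_eff[prow - 1]
                    * 10.0 ** col_eff[pcol - 1]
                )
                if spec.count_noise == "poisson":
                    counts = rng.poisson(counts).astype(float)
                elif spec.count_noise != "none":
                    raise ValueError(f"unknown count_noise mode {spec.count_noise!r}")

                d1 = [well_drug1[k] for k in plate_idx] + [None] * spec.n_dmso_per_plate
                d2 = [well_drug2[k] for k in plate_idx] + [None] * spec.n_dmso_per_plate
                is_ctrl = [False] * take + [True] * spec.n_dmso_per_plate

                rows_out["plate_id"].extend([plate_id] * n_wells)
                rows_out["row"].extend(prow.tolist())
                rows_out["col"].extend(pcol.tolist())
                rows_out["cell_line"].extend([cl] * n_wells)
                rows_out["dose_level"].extend([dose] * n_wells)
                rows_out["drug1"].extend(d1)
                rows_out["drug2"].extend(d2)
                rows_out["is_control"].extend(is_ctrl)
                rows_out["count"].extend(counts.tolist())

            frames.append(pd.DataFrame(rows_out))

    records = pd.concat(frames, ignore_index=True)
    return PlateTable(records=records, plate_shape=spec.plate_shape), truth


def default_screen_spec(seed: int = 0) -> ScreenSpec:
    """A desk-scale screen echoing the reference design.

    20 drugs (190 pairs), 8 cell lines, two dose levels on 384-well plates
    with 16 DMSO wells each; per-well noise 0.05 on the W scale with a 3x
    noisier singlet well; three specific planted synergies, one planted
    antagonism and one promiscuous sensitizer; mild row/column artifacts.
    """
    return ScreenSpec(
        n_drugs=20,
        n_cell_lines=8,
        doses=DOSES_BOTH,
        plate_shape=(16, 24),
        n_dmso_per_plate=16,
        noise_sd_w=0.05,
        singlet_well_noise_multiplier=3.0,
        row_col_artifact_sd=0.02,
        planted_synergies=(
            PlantedEffect("D01", "D02", 0.25),
            PlantedEffect("D03", "D04", 0.25, cell_lines=("CL1", "CL2", "CL3", "CL4")),
            PlantedEffect("D05", "D06", 0.25, doses=("high",)),
        ),
        planted_antagonisms=(PlantedEffect("D08", "D09", -0.25),),
        promiscuous_drugs=(PromiscuousDrug("D07", prob=0.3, delta_w=0.25),),
        seed=seed,
    )
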