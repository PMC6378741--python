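"""End-to-end orchestration: plates -> viabilities -> fits -> calls -> scores.

`run_pipeline` drives the whole analysis from a :class:`PipelineConfig`
(built in code or loaded from YAML), writes every result table as CSV plus
the heatmap JSON, and returns the in-memory results.  Stages:

  preprocess -> per-assay Bliss fit -> synergy inference -> dose combining
  -> absolute / specificity scoring -> (optional) randomization -> export.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    bliss_model,
    evaluation,
    export,
    plate_io,
    preprocess,
    randomization,
    scoring,
    synergy_inference,
    synthetic_data,
)
from .plate_io import AssayKey, PlateTable

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending assay."""


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    input_csv: str | None = None  # mutually exclusive with simulate
    simulate: bool = False
    schema: dict[str, str] | None = None
    plate_shape: tuple[int, int] = plate_io.PLATE_SHAPE_1536
    polish: bool = True
    trim_fraction: float = preprocess.DEFAULT_TRIM_FRACTION
    pseudocount: float = preprocess.DEFAULT_PSEUDOCOUNT
    alpha: float = synergy_inference.DEFAULT_ALPHA
    include_self: bool = True
    run_randomization: bool = False
    randomization_threshold: int = randomization.DEFAULT_THRESHOLD
    n_rand: int = randomization.DEFAULT_N_RAND
    outdir: str = "synscreen_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.simulate and self.input_csv is None:
            raise ValueError("config needs either input_csv or simulate=true")
        if self.simulate and self.input_csv is not None:
            raise ValueError("input_csv and simulate are mutually exclusive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "plate_shape" in raw:
            raw["plate_shape"] = tuple(raw["plate_shape"])
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    plates: PlateTable
    assays: dict[AssayKey, preprocess.AssayTable]
    fits: dict[AssayKey, bliss_model.BlissFit]
    calls: dict[AssayKey, pd.DataFrame]
    combined: pd.DataFrame
    cube: scoring.SynergyCube
    t_matrix: np.ndarray
    sc_matrix: np.ndarray
    ranked: pd.DataFrame
    heatmap: dict
    randomization: randomization.RandomizationResult | None = None
    ground_truth: synthetic_data.GroundTruth | None = None


def _stage(name: str, assay=None):
    suffix = f" (assay {assay})" if assay is not None else ""
    return f"stage {name!r}{suffix}"


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ground_truth = None
    if config.simulate:
        spec = synthetic_data.default_screen_spec(seed=config.seed)
        plates, ground_truth = synthetic_data.generate_screen(spec)
        plate_io.write_plate_table(plates, outdir / "plates.csv")
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(_ground_truth_payload(ground_truth), fh, indent=1)
    else:
        try:
            plates = plate_io.read_plate_table(
                config.input_csv, schema=config.schema, plate_shape=config.plate_shape
            )
        except Exception as exc:  # noqa: BLE001 - stage wrapper
            raise PipelineError(f"{_stage('read')}: {exc}") from exc

    try:
        assays = preprocess.compute_viabilities(
            plates,
            polish=config.polish,
            trim_fraction=config.trim_fraction,
            pseudocount=config.pseudocount,
        )
    except Exception as exc:  # noqa: BLE001 - stage wrapper
        raise PipelineError(f"{_stage('preprocess')}: {exc}") from exc

    fits: dict[AssayKey, bliss_model.BlissFit] = {}
    calls: dict[AssayKey, pd.DataFrame] = {}
    singlet_frames = []
    for key in sorted(assays):
        table = assays[key]
        try:
            fit = bliss_model.fit_assay(table)
        except Exception as exc:
            raise PipelineError(f"{_stage('fit', key)}: {exc}") from exc
        fits[key] = fit
        logger.info(
            "assay %s: m=%d pairs, n=%d drugs, R^2=%.4f, DMSO var=%.3g",
            key, fit.m, fit.n, fit.r_squared, table.var_dmso,
        )
        est = bliss_model.singlet_estimates(fit)
        est.insert(0, "cell_line", key.cell_line)
        est.insert(1, "dose_level", key.dose_level)
        singlet_frames.append(est)
        try:
            calls[key] = synergy_inference.infer_assay(fit, table, alpha=config.alpha)
        except Exception as exc:
            raise PipelineError(f"{_stage('synergy', key)}: {exc}") from exc

    try:
        combined = synergy_inference.combine_all_doses(calls)
        drugs = sorted({d for t in assays.values() for d in t.drugs})
        cell_lines = sorted({k.cell_line for k in assays})
        cube = scoring.cube_from_calls(combined, drugs=drugs, cell_lines=cell_lines)
        t_matrix = scoring.absolute_synergy_scores(cube)
        sc_matrix = scoring.specificity_scores(t_matrix, include_self=config.include_self)
        ranked = scoring.rank_combinations(t_matrix, sc_matrix, drugs)
    except Exception as exc:
        raise PipelineError(f"{_stage('scoring')}: {exc}") from exc

    rand_result = None
    if config.run_randomization:
        try:
            rand_result = randomization.high_score_test(
                t_matrix,
                n_cell_lines=cube.n_cell_lines,
                threshold=config.randomization_threshold,
                n_rand=config.n_rand,
                seed=config.seed,
            )
        except Exception as exc:
            raise PipelineError(f"{_stage('randomization')}: {exc}") from exc

    try:
        heatmap = export.export_heatmap_json(
            drugs, t_matrix, sc_matrix, calls, fits, assays
        )
        export.validate_heatmap_payload(heatmap)
    except Exception as exc:
        raise PipelineError(f"{_stage('export')}: {exc}") from exc

    # ---- write outputs -------------------------------------------------
    plate_io.write_results_table(bliss_model.fit_summary(fits), outdir / "fit_summary.csv")
    plate_io.write_results_table(
        pd.concat(singlet_frames, ignore_index=True), outdir / "singlet_estimates.csv"
    )
    all_calls = pd.concat([calls[k] for k in sorted(calls)], ignore_index=True)
    plate_io.write_results_table(all_calls, outdir / "synergy_calls.csv")
    plate_io.write_results_table(combined, outdir / "combined_calls.csv")
    plate_io.write_results_table(ranked, outdir / "ranked_pairs.csv")
    with open(outdir / "heatmap.json", "w") as fh:
        json.dump(heatmap, fh, indent=1, sort_keys=True)
    if rand_result is not None:
        with open(outdir / "randomization.json", "w") as fh:
            json.dump(
                {
                    "observed_high_count": rand_result.observed_high_count,
                    "empirical_p": rand_result.empirical_p,
                    "threshold": rand_result.threshold,
                    "n_rand": rand_result.n_rand,
                    "null_mean": float(np.mean(rand_result.null_high_counts)),
                },
                fh,
                indent=1,
            )

    return PipelineResult(
        config=config,
        plates=plates,
        assays=assays,
        fits=fits,
        calls=calls,
        combined=combined,
        cube=cube,
        t_matrix=t_matrix,
        sc_matrix=sc_matrix,
        ranked=ranked,
        heatmap=heatmap,
        randomization=rand_result,
        ground_truth=ground_truth,
    )


def evaluate_screen(result: PipelineResult) -> dict:
    """Cross-dose consistency reports for a finished pipeline run."""
    meas_high = evaluation.measured_singlet_matrix(result.assays, "high")
    meas_low = evaluation.measured_singlet_matrix(result.assays, "low")
    est_high = evaluation.estimated_singlet_matrix(result.fits, "high")
    est_low = evaluation.estimated_singlet_matrix(result.fits, "low")

    meas_rep = evaluation.cross_dose_correlations(meas_high, meas_low, "measured")
    est_rep = evaluation.cross_dose_correlations(est_high, est_low, "estimated")
    merged = meas_rep.merge(est_rep, on="drug", suffixes=("_measured", "_estimated"))
    if len(merged):
        comparison = evaluation.compare_correlation_vectors(
            merged["r_measured"], merged["r_estimated"]
        )
    else:  # too few cell lines for any per-drug correlation
        comparison = {
            "median_measured": float("nan"),
            "median_estimated": float("nan"),
            "statistic": float("nan"),
            "p_value": float("nan"),
        }

    high_calls = pd.concat(
        [df for k, df in result.calls.items() if k.dose_level == "high"],
        ignore_index=True,
    )
    low_calls = pd.concat(
        [df for k, df in result.calls.items() if k.dose_level == "low"],
        ignore_index=True,
    )
    sensitization = evaluation.fisher_overlap_per_drug(high_calls, low_calls)

    agreement = {
        str(k): evaluation.singlet_agreement(result.fits[k], result.assays[k])
        for k in sorted(result.fits)
    }
    return {
        "cross_dose": pd.concat([meas_rep, est_rep], ignore_index=True),
        "comparison": comparison,
        "sensitization": sensitization,
        "singlet_agreement": agreement,
    }


def _ground_truth_payload(truth: synthetic_data.GroundTruth) -> dict:
    return {
        "w_true": {str(k): v for k, v in truth.w_true.items()},
        "pair_effects": {
            str(k): {f"{a}|{b}": d for (a, b), d in v.items()}
            for k, v in truth.pair_effects.items()
        },
    }
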