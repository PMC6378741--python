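"""JSON export of the drug x drug heatmap and per-pair detail payloads.

The payload mirrors the interactive viewer's data contract: a symmetric
score matrix (absolute synergy count and specificity score per pair) plus,
for every pair, per-(cell line, dose) details -- observed combination
viability with a DMSO-derived error bar, the expected viability under Bliss
independence with a propagated standard error, the two singlet estimates,
and the synergy/antagonism flags.  Standard errors live on the W scale and
are mapped to the viability scale by the delta method:

    se_V ~= V * ln(10) * se_W.

A machine-readable schema ships with the package (``heatmap_schema.json``)
and :func:`validate_heatmap_payload` checks a payload against that contract.
"""

from __future__ import annotations

import json
import math
from importlib import resources

import numpy as np
import pandas as pd

from .bliss_model import BlissFit
from .plate_io import AssayKey
from .preprocess import AssayTable

LN10 = math.log(10.0)


def se_viability(v: float, se_w: float) -> float:
    """Delta-method map of a W-scale standard error to the viability scale."""
    return abs(v) * LN10 * se_w


def export_heatmap_json(
    drugs: list[str],
    t_matrix: np.ndarray,
    sc_matrix: np.ndarray,
    calls_by_assay: dict[AssayKey, pd.DataFrame],
    fits: dict[AssayKey, BlissFit],
    assays: dict[AssayKey, AssayTable],
    drug_targets: dict[str, str] | None = None,
) -> dict:
    """Assemble the heatmap payload for all C(n,2) pairs."""
    n = len(drugs)
    cell_lines = sorted({k.cell_line for k in fits})

    call_index: dict[AssayKey, pd.DataFrame] = {
        key: df.set_index(["drug1", "drug2"]) for key, df in calls_by_assay.items()
    }

    matrix = []
    details: dict[str, list[dict]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d1, d2 = drugs[i], drugs[j]
            matrix.append(
                {
                    "i": i,
                    "j": j,
                    "drug1": d1,
                    "drug2": d2,
                    "absolute_score": int(t_matrix[i, j]),
                    "specificity_score": float(sc_matrix[i, j]),
                }
            )
            blocks = []
            for key in sorted(fits):
                fit = fits[key]
                table = assays[key]
                pair = (d1, d2)
                if pair not in table.pair_viabilities:
                    continue
                v_obs = table.pair_viabilities[pair]
                dmso_sd = float(np.std(table.dmso_log_viabilities, ddof=1))
                w1, w2 = fit.w_of(d1), fit.w_of(d2)
                se1, se2 = fit.se_of(d1), fit.se_of(d2)
                v_exp = 10.0 ** (-(w1 + w2))
                se_w_exp = math.sqrt(se1**2 + se2**2)
                flags = {"synergistic": False, "antagonistic": False}
                cdf = call_index.get(key)
                if cdf is not None and pair in cdf.index:
                    rec = cdf.loc[pair]
                    flags = {
                        "synergistic": bool(rec["synergistic"]),
                        "antagonistic": bool(rec["antagonistic"]),
                    }
                blocks.append(
                    {
                        "cell_line": key.cell_line,
                        "dose_level": key.dose_level,
                        "observed_v": float(v_obs),
                        "observed_se": se_viability(v_obs, dmso_sd),
                        "expected_v": float(v_exp),
                        "expected_se": se_viability(v_exp, se_w_exp),
                        "singlets": [
                            {"drug": d1, "v_hat": 10.0**-w1, "se_v": se_viability(10.0**-w1, se1)},
                            {"drug": d2, "v_hat": 10.0**-w2, "se_v": se_viability(10.0**-w2, se2)},
                        ],
                        **flags,
                    }
                )
            details[f"{d1}|{d2}"] = blocks

    return {
        "drugs": [
            {"name": d, "target": (drug_targets or {}).get(d)} for d in drugs
        ],
        "cell_lines": cell_lines,
        "matrix": matrix,
        "details": details,
    }


def load_heatmap_schema() -> dict:
    """The JSON schema document shipped with the package."""
    with resources.files("synscreen").joinpath("heatmap_schema.json").open() as fh:
        return json.load(fh)


def validate_heatmap_payload(payload: dict) -> None:
    """Structural validation of a heatmap payload.

    Checks the contract described by the shipped schema: required keys,
    entry types, C(n,2) matrix entries, score symmetry implied by single
    storage, and a detail block for every matrix entry.  Raises ValueError
    on the first violation.
    """
    for key in ("drugs", "cell_lines", "matrix", "details"):
        if key not in payload:
            raise ValueError(f"payload missing key {key!r}")
    n = len(payload["drugs"])
    expected_pairs = n * (n - 1) // 2
    if len(payload["matrix"]) != expected_pairs:
        raise ValueError(
            f"matrix has {len(payload['matrix'])} entries, expected C({n},2) = {expected_pairs}"
        )
    for entry in payload["matrix"]:
        for field in ("i", "j", "drug1", "drug2", "absolute_score", "specificity_score"):
            if field not in entry:
                raise ValueError(f"matrix entry missing field {field!r}")
        if not 0 <= entry["i"] < entry["j"] < n:
            raise ValueError(f"bad matrix indices ({entry['i']}, {entry['j']})")
        detail_key = f"{entry['drug1']}|{entry['drug2']}"
        if detail_key not in payload["details"]:
            raise ValueError(f"missing detail block for pair {detail_key}")
    for pair, blocks in payload["details"].items():
        for block in blocks:
            for field in (
                "cell_line",
                "dose_level",
                "observed_v",
                "observed_se",
                "expected_v",
                "expected_se",
                "singlets",
                "synergistic",
                "antagonistic",
            ):
                if field not in block:
                    raise ValueError(f"detail block for {pair} missing field {field!r}")
            if len(block["singlets"]) != 2:
                raise ValueError(f"detail block for {pair} must list exactly 2 singlets")
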