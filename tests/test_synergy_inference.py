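import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
import synscreen as ss
from synscreen.plate_io import AssayKey
from synscreen.synthetic_data import ScreenSpec
from test_bliss_model import assay_from_pair_w


def bh_stepup_oracle(p):
    """Independent BH implementation: sort, scale by m/k, cumulative min."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


class TestNullVariance:
    def test_additive_rule(self, small_noisy_screen):
        _, _, assays = small_noisy_screen
        table = assays[AssayKey("CL1", "high")]
        fit = ss.fit_assay(table)
        null = ss.dmso_null(table)
        pair = fit.pairs[0]
        expected = table.var_dmso + fit.se_of(pair[0]) ** 2 + fit.se_of(pair[1]) ** 2
        assert ss.null_variance(null, fit, pair) == pytest.approx(expected)

    def test_arithmetic_example(self):
        null = ss.NullModel(assay=AssayKey("CL1", "high"), var_dmso=0.01)
        fit = ss.fit_assay(
            assay_from_pair_w({("A", "B"): 0.1, ("A", "C"): 0.1, ("B", "C"): 0.1})
        )
        fit.se[:] = 0.05
        assert ss.null_variance(null, fit, ("A", "B")) == pytest.approx(0.015)

    def test_fewer_than_two_dmso_wells_rejected(self):
        table = assay_from_pair_w({("A", "B"): 0.1, ("A", "C"): 0.1, ("B", "C"): 0.1})
        table.dmso_log_viabilities = np.array([0.0])
        with pytest.raises(ValueError, match="2 DMSO"):
            ss.dmso_null(table)

    def test_scaling_dmso_spread_scales_variance_quadratically(self, small_noisy_screen):
        _, _, assays = small_noisy_screen
        table = assays[AssayKey("CL1", "high")]
        base = table.var_dmso
        w = table.dmso_log_viabilities
        scaled = type(table)(
            assay=table.assay,
            pair_viabilities=table.pair_viabilities,
            singlet_viabilities=table.singlet_viabilities,
            dmso_log_viabilities=w.mean() + 3.0 * (w - w.mean()),
        )
        assert scaled.var_dmso == pytest.approx(9.0 * base)


class TestPValues:
    def test_z_two_gives_upper_tail_probability(self):
        # residual 0.2 with null variance 0.01: z = 2
        null = ss.NullModel(assay=AssayKey("CL1", "high"), var_dmso=0.01)
        fit = ss.fit_assay(
            assay_from_pair_w(
                {("A", "B"): 0.6, ("A", "C"): 0.0, ("A", "D"): 0.0,
                 ("B", "C"): 0.0, ("B", "D"): 0.0, ("C", "D"): 0.0}
            )
        )
        fit.se[:] = 0.0
        calls = ss.synergy_pvalues(fit, null)
        row = calls.set_index(["drug1", "drug2"]).loc[("A", "B")]
        assert row["residual"] == pytest.approx(0.2)
        assert row["z"] == pytest.approx(2.0)
        assert row["p_syn"] == pytest.approx(0.0227501319, abs=1e-9)
        assert row["p_ant"] == pytest.approx(0.9772498681, abs=1e-9)

    def test_zero_residual_gives_half(self):
        null = ss.NullModel(assay=AssayKey("CL1", "high"), var_dmso=0.01)
        fit = ss.fit_assay(
            assay_from_pair_w({("A", "B"): 0.1, ("A", "C"): 0.1, ("B", "C"): 0.1})
        )
        calls = ss.synergy_pvalues(fit, null)
        np.testing.assert_allclose(calls["p_syn"], 0.5, atol=1e-12)
        np.testing.assert_allclose(calls["p_syn"] + calls["p_ant"], 1.0, atol=1e-12)

    def test_eob_from_model_singlets(self):
        # solved singlets at V = 0.5 each and an observed pair at V = 0.1
        # give an excess over Bliss of 0.5 * 0.5 - 0.1 = 0.15
        w_half = float(-np.log10(0.5))
        fit = ss.BlissFit(
            assay=AssayKey("CL1", "high"),
            drugs=["A", "B"],
            w_hat=np.array([w_half, w_half]),
            se=np.array([0.0, 0.0]),
            pairs=[("A", "B")],
            w_obs=np.array([-np.log10(0.1)]),
            fitted=np.array([2 * w_half]),
            residuals=np.array([-np.log10(0.1) - 2 * w_half]),
            sigma2_model=0.0,
            r_squared=1.0,
        )
        null = ss.NullModel(assay=AssayKey("CL1", "high"), var_dmso=0.01)
        calls = ss.synergy_pvalues(fit, null)
        assert calls["eob_model"].iloc[0] == pytest.approx(0.15, abs=1e-12)

    def test_p_syn_monotone_decreasing_in_residual(self):
        # at equal null variance the synergy p value must order inversely
        # to the residual
        null = ss.NullModel(assay=AssayKey("CL1", "high"), var_dmso=0.01)
        fit = ss.fit_assay(
            assay_from_pair_w(
                {("A", "B"): 0.6, ("A", "C"): 0.1, ("A", "D"): -0.2,
                 ("B", "C"): 0.05, ("B", "D"): 0.3, ("C", "D"): 0.0}
            )
        )
        fit.se[:] = 0.0
        calls = ss.synergy_pvalues(fit, null)
        by_residual = calls.sort_values("residual")
        assert by_residual["p_syn"].is_monotonic_decreasing

    def test_low_viability_pairs_flagged(self, small_noisy_screen):
        _, _, assays = small_noisy_screen
        table = assays[AssayKey("CL1", "high")]
        fit = ss.fit_assay(table)
        calls = ss.synergy_pvalues(fit, ss.dmso_null(table), table)
        v_ij = 10.0 ** (-fit.w_obs)
        np.testing.assert_array_equal(calls["low_viability"], v_ij < 0.1)


class TestFDR:
    def test_three_p_values_step_up(self):
        np.testing.assert_allclose(ss.adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_two_p_values(self):
        np.testing.assert_allclose(ss.adjust_fdr([0.001, 1.0]), [0.002, 1.0])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ss.adjust_fdr([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ss.adjust_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_matches_independent_step_up_oracle(self, pvalues):
        np.testing.assert_allclose(
            ss.adjust_fdr(pvalues), bh_stepup_oracle(pvalues), atol=1e-12
        )


class TestCalls:
    def test_flags_follow_q_threshold(self):
        df = pd.DataFrame(
            {
                "p_syn": [1e-6, 0.5, 0.999999],
                "p_ant": [1 - 1e-6, 0.5, 1e-6],
            }
        )
        out = ss.call_synergies(df, alpha=0.05)
        assert out["synergistic"].tolist() == [True, False, False]
        assert out["antagonistic"].tolist() == [False, False, True]
        assert (out["q_syn"] >= out["p_syn"] - 1e-15).all()

    def test_never_both_directions(self, small_noisy_screen):
        _, _, assays = small_noisy_screen
        for table in assays.values():
            calls = ss.infer_assay(ss.fit_assay(table), table)
            assert not (calls["synergistic"] & calls["antagonistic"]).any()

    def test_planted_synergy_detected(self, small_noisy_screen):
        _, truth, assays = small_noisy_screen
        flagged = []
        for key, table in assays.items():
            calls = ss.infer_assay(ss.fit_assay(table), table)
            hit = calls[(calls.drug1 == "D01") & (calls.drug2 == "D02")]
            flagged.append(bool(hit["synergistic"].iloc[0]))
        assert any(flagged)


class TestCombineDoses:
    def combined(self, hi, lo):
        def frame(flags):
            return pd.DataFrame(
                {
                    "cell_line": "CL1",
                    "drug1": ["A"],
                    "drug2": ["B"],
                    "synergistic": [flags[0]],
                    "antagonistic": [flags[1]],
                }
            )

        return ss.combine_doses(frame(hi), frame(lo))

    def test_either_dose_suffices(self):
        assert self.combined((True, False), (False, False))["synergistic"].iloc[0]
        assert self.combined((False, False), (True, False))["synergistic"].iloc[0]

    def test_neither_dose(self):
        assert not self.combined((False, False), (False, False))["synergistic"].iloc[0]

    def test_missing_dose_inherits_present_verdict(self):
        high = pd.DataFrame(
            {
                "cell_line": ["CL1"],
                "drug1": ["A"],
                "drug2": ["B"],
                "synergistic": [True],
                "antagonistic": [False],
            }
        )
        out = ss.combine_doses(high, None)
        assert out["synergistic"].iloc[0]
        out2 = ss.combine_doses(None, high)
        assert out2["synergistic"].iloc[0]


class TestErrorControl:
    def test_type_i_rate_without_planted_effects(self):
        # 60 independent null assays, 10 drugs each: synergy calls at BH 0.05
        # stay rare (the DMSO-calibrated null is conservative)
        calls_total, units = 0, 0
        for rep in range(60):
            spec = ScreenSpec(
                n_drugs=10,
                n_cell_lines=1,
                doses=("high",),
                noise_sd_w=0.05,
                row_col_artifact_sd=0.0,
                seed=500 + rep,
            )
            plates, _ = ss.generate_screen(spec)
            assays = ss.compute_viabilities(plates, polish=False)
            for table in assays.values():
                calls = ss.infer_assay(ss.fit_assay(table), table)
                calls_total += int(calls["synergistic"].sum())
                units += len(calls)
        assert calls_total / units <= 0.08
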