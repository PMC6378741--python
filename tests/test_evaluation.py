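import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import hypergeom

import synscreen as ss
from synscreen.plate_io import AssayKey
from synscreen.synthetic_data import ScreenSpec


def fisher_two_sided_oracle(table):
    """Brute-force two-sided Fisher p: sum of hypergeometric probabilities
    of all tables (same margins) no more likely than the observed one."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p_k = hypergeom.pmf(k, n, col1, row1)
        if p_k <= p_obs * (1 + 1e-9):
            total += p_k
    return total


class TestSingletAgreement:
    def test_noiseless_assay_reaches_r_one(self, noiseless_screen):
        _, plates, _ = noiseless_screen
        assays = ss.compute_viabilities(plates, polish=False)
        for key, table in assays.items():
            fit = ss.fit_assay(table)
            assert ss.singlet_agreement(fit, table) == pytest.approx(1.0, abs=1e-9)

    def test_constant_offset_does_not_break_correlation(self, small_noisy_screen):
        _, _, assays = small_noisy_screen
        table = assays[AssayKey("CL1", "high")]
        fit = ss.fit_assay(table)
        shifted = type(table)(
            assay=table.assay,
            pair_viabilities=table.pair_viabilities,
            singlet_viabilities={d: v + 0.2 for d, v in table.singlet_viabilities.items()},
            dmso_log_viabilities=table.dmso_log_viabilities,
        )
        r0 = ss.singlet_agreement(fit, table)
        r1 = ss.singlet_agreement(fit, shifted)
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_too_few_singlets_reported_missing(self, small_noisy_screen):
        _, _, assays = small_noisy_screen
        table = assays[AssayKey("CL1", "high")]
        fit = ss.fit_assay(table)
        trimmed = type(table)(
            assay=table.assay,
            pair_viabilities=table.pair_viabilities,
            singlet_viabilities=dict(itertools.islice(table.singlet_viabilities.items(), 2)),
            dmso_log_viabilities=table.dmso_log_viabilities,
        )
        assert np.isnan(ss.singlet_agreement(fit, trimmed))


class TestCrossDoseCorrelations:
    def test_identical_matrices_give_r_one(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(
            rng.normal(0.5, 0.2, size=(6, 10)),
            index=[f"d{k}" for k in range(6)],
            columns=[f"c{k}" for k in range(10)],
        )
        report = ss.cross_dose_correlations(mat, mat.copy())
        np.testing.assert_allclose(report["r"], 1.0, atol=1e-12)
        assert report["significant"].all()

    def test_p_matches_t_transform(self):
        rng = np.random.default_rng(1)
        high = pd.DataFrame(rng.normal(size=(5, 12)), index=list("abcde"))
        low = pd.DataFrame(
            0.5 * high.to_numpy() + rng.normal(size=(5, 12)), index=list("abcde")
        )
        report = ss.cross_dose_correlations(high, low)
        for _, row in report.iterrows():
            r, n = row["r"], row["n_cell_lines"]
            t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
            p_oracle = 2 * stats.t.sf(abs(t), df=n - 2)
            assert row["p"] == pytest.approx(p_oracle, rel=1e-9)

    def test_moderate_correlation_significant_at_forty_cell_lines(self):
        # r = 0.5 at n = 40 gives t ~ 3.56 and p < 0.05
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(size=40)
            y = 0.5 * x + rng.normal(size=40) * np.sqrt(3)
            r, p = stats.pearsonr(x, y)
            if abs(r - 0.5) < 0.02:
                assert p < 0.05

    def test_short_vectors_skipped(self):
        high = pd.DataFrame([[0.1, 0.2, np.nan]], index=["a"], columns=["c1", "c2", "c3"])
        low = pd.DataFrame([[0.2, 0.1, 0.3]], index=["a"], columns=["c1", "c2", "c3"])
        report = ss.cross_dose_correlations(high, low)
        assert len(report) == 0

    def test_type_i_calibration_independent_vectors(self):
        # independent vectors across 40 cell lines: ~5% of drugs significant
        rng = np.random.default_rng(4)
        n_drugs = 400
        high = pd.DataFrame(rng.normal(size=(n_drugs, 40)))
        low = pd.DataFrame(rng.normal(size=(n_drugs, 40)))
        report = ss.cross_dose_correlations(high, low)
        frac = report["significant"].mean()
        assert 0.02 <= frac <= 0.08


class TestCompareCorrelationVectors:
    def test_identical_vectors_give_p_one(self):
        rs = np.array([0.1, 0.5, 0.8])
        out = ss.compare_correlation_vectors(rs, rs.copy())
        assert out["p_value"] == pytest.approx(1.0)
        assert out["median_measured"] == out["median_estimated"]

    def test_constant_shift_forces_rejection(self):
        rng = np.random.default_rng(5)
        meas = rng.uniform(0, 0.4, size=50)
        est = meas + 0.3 + rng.normal(0, 1e-3, size=50)
        out = ss.compare_correlation_vectors(meas, est)
        assert out["p_value"] < 1e-20
        assert out["median_estimated"] > out["median_measured"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ss.compare_correlation_vectors([0.1, 0.2], [0.1])


class TestFisherOverlap:
    @staticmethod
    def calls_frame(flags, dose):
        rows = []
        for (partner, cl), flag in flags.items():
            rows.append(
                {
                    "cell_line": cl,
                    "drug1": "X",
                    "drug2": partner,
                    "synergistic": flag,
                    "antagonistic": False,
                }
            )
        return pd.DataFrame(rows)

    def test_perfect_association_is_significant(self):
        units = [(f"p{k}", f"c{j}") for k in range(5) for j in range(4)]
        flags = {u: (i % 2 == 0) for i, u in enumerate(units)}
        high = self.calls_frame(flags, "high")
        low = self.calls_frame(flags, "low")
        report = ss.fisher_overlap_per_drug(high, low)
        row = report[report["drug"] == "X"].iloc[0]
        assert row["fisher_p"] < 0.05
        assert row["overlap_significant"]

    def test_p_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 8, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            table = [[int(a), int(b)], [int(c), int(d)]]
            _, p_scipy = stats.fisher_exact(table, alternative="two-sided")
            assert p_scipy == pytest.approx(fisher_two_sided_oracle(table), rel=1e-6)

    def test_disjoint_calls_not_flagged_as_overlap(self):
        # strong *negative* association still yields small p (two-sided test),
        # so check the counts are reported faithfully
        units = [(f"p{k}", "c1") for k in range(10)]
        high = self.calls_frame({u: i < 5 for i, u in enumerate(units)}, "high")
        low = self.calls_frame({u: i >= 5 for i, u in enumerate(units)}, "low")
        report = ss.fisher_overlap_per_drug(high, low)
        row = report[report["drug"] == "X"].iloc[0]
        assert row["n_overlap"] == 0
        assert row["n_syn_high"] == 5 and row["n_syn_low"] == 5

    def test_calibration_under_independence(self):
        rng = np.random.default_rng(7)
        n_drugs, n_units = 100, 120
        rows_h, rows_l = [], []
        for k in range(n_drugs):
            for u in range(n_units):
                base = {"cell_line": f"c{u % 8}", "drug1": f"drug{k}", "drug2": f"p{u}"}
                rows_h.append({**base, "synergistic": bool(rng.random() < 0.1),
                               "antagonistic": False})
                rows_l.append({**base, "synergistic": bool(rng.random() < 0.1),
                               "antagonistic": False})
        report = ss.fisher_overlap_per_drug(pd.DataFrame(rows_h), pd.DataFrame(rows_l))
        assert report["overlap_significant"].mean() <= 0.08


class TestEndToEndConsistency:
    def test_estimated_singlets_track_doses_better_than_measured(self):
        # noisy singlet wells (3x) but informative combination data: the
        # model-estimated singlets correlate across doses where the measured
        # ones barely do
        spec = ScreenSpec(
            n_drugs=15,
            n_cell_lines=8,
            noise_sd_w=0.05,
            singlet_well_noise_multiplier=3.0,
            row_col_artifact_sd=0.0,
            seed=21,
        )
        plates, _ = ss.generate_screen(spec)
        assays = ss.compute_viabilities(plates, polish=False)
        fits = {k: ss.fit_assay(t) for k, t in assays.items()}
        meas = ss.cross_dose_correlations(
            ss.measured_singlet_matrix(assays, "high"),
            ss.measured_singlet_matrix(assays, "low"),
        )
        est = ss.cross_dose_correlations(
            ss.estimated_singlet_matrix(fits, "high"),
            ss.estimated_singlet_matrix(fits, "low"),
        )
        assert est["r"].median() > meas["r"].median()
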