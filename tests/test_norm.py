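"""Correction-factor computation, application, and suppression estimation."""

import numpy as np
import pytest

from hipquant import (HipMHCSpec, abundance_window_filter, apply_correction,
                      aggregate_to_peptides, compute_lf_correction,
                      compute_tmt_correction, correction_trigger,
                      default_standards, estimate_suppression,
                      normalize_experiment, per_condition_correction)
from conftest import CHANNELS, LOSS, heavy_mods, tmt_psm


class TestAbundanceWindow:
    """Window = [Q1/10, Q3*10] on mean per-PSM reporter intensity."""

    @pytest.fixture
    def endogenous(self):
        # means 10..100 -> Q1 = 32.5, Q3 = 77.5 (hand type-7 quantiles)
        return [tmt_psm(scan=i, reporter={"TMT126": float(v)})
                for i, v in enumerate(range(10, 101, 10))]

    @pytest.mark.parametrize("mean, retained", [
        (500.0, True),       # inside [3.25, 775]
        (2000.0, False),     # above Q3*10
        (775.0, True),       # exactly Q3*10: inclusive
        (3.25, True),        # exactly Q1/10: inclusive
        (3.0, False),
    ])
    def test_window_bounds(self, endogenous, mean, retained):
        std = tmt_psm(scan=99, reporter={"TMT126": mean})
        if retained:
            assert abundance_window_filter([std], endogenous) == [std]
        else:
            with pytest.raises(ValueError):
                abundance_window_filter([std], endogenous)

    def test_all_removed_is_hard_error(self, endogenous):
        with pytest.raises(ValueError, match="spike"):
            abundance_window_filter(
                [tmt_psm(scan=99, reporter={"TMT126": 1e6})], endogenous)

    def test_empty_endogenous_is_error(self):
        with pytest.raises(ValueError, match="endogenous"):
            abundance_window_filter([tmt_psm()], [])


class TestTMTCorrection:
    def test_single_psm_ratio(self):
        rec = tmt_psm(reporter={"TMT126": 100.0, "TMT127": 50.0})
        cf = compute_tmt_correction([rec], "TMT126")
        assert cf.factors == {"TMT126": 1.0, "TMT127": 2.0}

    def test_median_over_psms(self):
        # ratios 0.4, 0.5, 0.6 -> median 0.5 -> factor 2 (hand median)
        recs = [tmt_psm(scan=i, reporter={"TMT126": 100.0,
                                          "TMT127": 100.0 * r})
                for i, r in enumerate([0.4, 0.5, 0.6])]
        cf = compute_tmt_correction(recs, "TMT126")
        assert cf.factors["TMT127"] == pytest.approx(2.0)
        assert cf.n_standard_psms == 3

    def test_identical_channels_give_unit_factors(self):
        recs = [tmt_psm(scan=i) for i in range(3)]
        cf = compute_tmt_correction(recs, "TMT126")
        assert all(f == 1.0 for f in cf.factors.values())

    def test_zero_reference_psm_excluded(self):
        recs = [tmt_psm(reporter={"TMT126": 0.0, "TMT127": 10.0}),
                tmt_psm(scan=2, reporter={"TMT126": 100.0, "TMT127": 50.0})]
        cf = compute_tmt_correction(recs, "TMT126")
        assert cf.n_standard_psms == 1
        assert cf.factors["TMT127"] == pytest.approx(2.0)

    def test_reference_factor_always_one(self):
        rng = np.random.default_rng(3)
        recs = [tmt_psm(scan=i, reporter={c: float(v) for c, v in
                                          zip(CHANNELS,
                                              rng.uniform(10, 1000, 6))})
                for i in range(7)]
        cf = compute_tmt_correction(recs, "TMT128")
        assert cf.factors["TMT128"] == 1.0


class TestLFCorrection:
    def test_symmetric_ratios_cancel(self):
        aucs = {"h1": {"ref": 100.0, "s2": 80.0},
                "h2": {"ref": 100.0, "s2": 120.0}}
        cf = compute_lf_correction(aucs, "ref")
        assert cf.factors["s2"] == pytest.approx(1.0)

    def test_mean_of_ratios(self):
        aucs = {"h1": {"ref": 100.0, "s2": 50.0},
                "h2": {"ref": 200.0, "s2": 100.0}}
        cf = compute_lf_correction(aucs, "ref")
        assert cf.factors["s2"] == pytest.approx(2.0)

    def test_standard_missing_in_reference_is_error(self):
        with pytest.raises(ValueError, match="reference"):
            compute_lf_correction({"h1": {"s2": 50.0}}, "ref")

    def test_standard_missing_in_sample_excluded_from_mean(self):
        aucs = {"h1": {"ref": 100.0, "s2": 50.0},
                "h2": {"ref": 100.0}}
        cf = compute_lf_correction(aucs, "ref")
        assert cf.factors["s2"] == pytest.approx(2.0)


class TestApplyCorrection:
    def test_adjusted_is_raw_times_factor(self):
        table = aggregate_to_peptides(
            [tmt_psm(reporter={"TMT126": 100.0, "TMT127": 300.0})])
        cf = compute_tmt_correction(
            [tmt_psm(scan=2, reporter={"TMT126": 10.0, "TMT127": 5.0})],
            "TMT126")
        apply_correction(table, cf)
        assert table.adjusted.loc[("SIINFEKLM", ""), "TMT127"] == 600.0
        assert table.raw.loc[("SIINFEKLM", ""), "TMT127"] == 300.0

    def test_missing_factor_is_error(self):
        table = aggregate_to_peptides([tmt_psm()])
        cf = compute_tmt_correction(
            [tmt_psm(scan=2, reporter={"TMT126": 1.0, "TMT127": 1.0})],
            "TMT126")
        with pytest.raises(KeyError):
            apply_correction(table, cf)

    def test_correction_is_idempotent_on_standards(self):
        """Recomputing factors on corrected standards yields all ones."""
        rng = np.random.default_rng(5)
        recs = [tmt_psm(scan=i, reporter={
            c: float(30.0 * LOSS[c] * rng.lognormal(0, 0.1))
            for c in CHANNELS}) for i in range(12)]
        cf = compute_tmt_correction(recs, "TMT126")
        corrected = [tmt_psm(scan=100 + i, reporter={
            c: v * cf.factors[c] for c, v in r.reporter.items()})
            for i, r in enumerate(recs)]
        cf2 = compute_tmt_correction(corrected, "TMT126")
        for f in cf2.factors.values():
            assert f == pytest.approx(1.0, abs=1e-9)


class TestLossRecovery:
    """Standards feel the same per-sample losses as endogenous peptides,
    so the factors recover 1/k_s."""

    def test_noise_free_recovery_is_exact(self, noisefree_experiment):
        records, truth, layout = noisefree_experiment
        specs = default_standards(CHANNELS)
        norm = normalize_experiment(records, specs, layout)
        for c in CHANNELS:
            assert norm.factors.factors[c] == pytest.approx(
                1.0 / truth.loss_factors[c], rel=1e-12)

    def test_standard_intensities_equalized_after_correction(
            self, noisefree_experiment):
        records, _, layout = noisefree_experiment
        specs = default_standards(CHANNELS)
        norm = normalize_experiment(records, specs, layout)
        for spec in specs:
            if spec.role != "correction":
                continue
            row = norm.table.adjusted.loc[(spec.sequence,)].iloc[0]
            assert row.max() == pytest.approx(row.min(), rel=1e-9)

    def test_noisy_recovery_error_scales_with_standard_psms(self):
        """Median-of-ratios error: bounded at ~4 SE, shrinking with n.

        The log2 ratio of two channels carries sqrt(2)*sigma_log2 noise,
        and the median of n ratios has SE ~ 1.253 * sqrt(2) * sigma / sqrt(n).
        """
        from hipquant import SimulationConfig, generate_replicate_experiment

        def errors(n_std_psms, seed):
            cfg = SimulationConfig(seed=seed, n_peptides=150, sigma_log2=0.2,
                                   loss_factors=dict(LOSS),
                                   standard_psms=n_std_psms)
            records, truth, layout = generate_replicate_experiment(cfg)
            norm = normalize_experiment(records, default_standards(CHANNELS),
                                        layout)
            return np.array([abs(np.log2(norm.factors.factors[c]
                                         * truth.loss_factors[c]))
                             for c in CHANNELS])

        small = np.concatenate([errors(10, s) for s in range(5)])
        large = np.concatenate([errors(80, s) for s in range(5)])
        se_small = 1.253 * np.sqrt(2) * 0.2 / np.sqrt(20)
        assert small.max() < 4 * se_small
        assert large.mean() < small.mean()


class TestPerCondition:
    def _split_map(self):
        return {c: ("ifng" if i >= 3 else "dmso")
                for i, c in enumerate(CHANNELS)}

    def test_within_condition_equality_gives_unit_factors(self):
        rep = {c: 100.0 for c in CHANNELS}
        recs = [tmt_psm(scan=i, reporter=dict(rep)) for i in range(4)]
        refs = {"dmso": "TMT126", "ifng": "TMT129"}
        out = per_condition_correction(recs, self._split_map(), refs)
        for cf in out:
            assert all(f == 1.0 for f in cf.factors.values())
            assert cf.condition_scoped

    @pytest.mark.parametrize("shift, expect", [(2.4, True), (1.3, False)])
    def test_trigger_on_global_mean_fold_change(self, shift, expect):
        recs = []
        rng = np.random.default_rng(0)
        for i in range(60):
            base = float(rng.uniform(50, 500))
            rep = {c: base * (shift if j >= 3 else 1.0)
                   for j, c in enumerate(CHANNELS)}
            recs.append(tmt_psm(scan=i, sequence=f"PEPT{i:03d}IDE",
                                reporter=rep))
        table = aggregate_to_peptides(recs)
        trig, mean_fc = correction_trigger(
            table, self._split_map(), "ifng", "dmso")
        assert trig is expect
        assert 2 ** mean_fc == pytest.approx(shift, rel=1e-6)

    def test_condition_without_channels_is_error(self):
        with pytest.raises(ValueError):
            per_condition_correction([tmt_psm()], {"TMT126": "only"},
                                     {"only": "TMT126"})


class TestSuppression:
    def _spec(self, amounts):
        return HipMHCSpec("SVVESVKFL", [8], "titration", amounts)

    def test_extreme_point_arithmetic(self):
        spec = self._spec({"c1": 30.0, "c2": 300.0})
        est = estimate_suppression(spec, {"c1": 1000.0, "c2": 4000.0},
                                   {"c1": 1000.0, "c2": 4000.0})
        assert est.expected_fold == pytest.approx(10.0)
        assert est.observed_fold == pytest.approx(4.0)
        assert est.suppression == pytest.approx(2.5)

    def test_linear_response_means_no_suppression(self):
        spec = self._spec({"c1": 30.0, "c2": 100.0, "c3": 300.0})
        adj = {"c1": 300.0, "c2": 1000.0, "c3": 3000.0}
        est = estimate_suppression(spec, adj, adj)
        assert est.suppression == pytest.approx(1.0)
        assert est.fit_r2_adjusted == pytest.approx(1.0)

    def test_full_compression(self):
        spec = self._spec({"c1": 30.0, "c2": 300.0})
        adj = {"c1": 500.0, "c2": 500.0}
        est = estimate_suppression(spec, adj, adj)
        assert est.observed_fold == 1.0
        assert est.suppression == pytest.approx(est.expected_fold)

    def test_generator_gamma_round_trip(self):
        """Power-law compression gamma reappears as the suppression fold."""
        from hipquant import SimulationConfig, generate_replicate_experiment
        from hipquant.pipeline import suppression_from_experiment
        cfg = SimulationConfig(seed=3, n_peptides=120, sigma_log2=0.0,
                               gamma=2.0)
        records, _, layout = generate_replicate_experiment(cfg)
        specs = cfg.standards
        norm = normalize_experiment(records, specs, layout)
        (est,) = suppression_from_experiment(norm, specs)
        # expected fold 10, observed 10**(1/2) -> suppression 10**(1/2)
        assert est.suppression == pytest.approx(np.sqrt(10.0), rel=1e-6)
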