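from itertools import combinations

import numpy as np
import pytest

from isletpep import (
    ElispotPlate,
    FpSeries,
    SyntheticConfig,
    competition_model,
    dfr_both,
    dfr_test,
    fit_ic50,
    fraction_bound,
    generate_validation_assays,
)


class TestFractionBound:
    def test_formula_endpoints(self):
        series = FpSeries(
            fp_free=50.0,
            fp_no_comp=150.0,
            observations=((1e-6, 150.0), (1e-5, 50.0), (1e-4, 100.0)),
        )
        ys = dict((c, y) for c, y in fraction_bound(series))
        assert ys[1e-6] == pytest.approx(1.0)
        assert ys[1e-5] == pytest.approx(0.0)
        assert ys[1e-4] == pytest.approx(0.5)

    def test_no_dynamic_range_is_hard_error(self):
        series = FpSeries(fp_free=100.0, fp_no_comp=100.0, observations=((1e-6, 90.0),))
        with pytest.raises(ValueError):
            fraction_bound(series)

    def test_affine_invariance_under_constant_offset(self):
        obs = tuple((10.0 ** (-8 + i), 60.0 + 9.0 * i) for i in range(6))
        base = FpSeries(fp_free=50.0, fp_no_comp=150.0, observations=obs)
        shifted = FpSeries(
            fp_free=50.0 + 7.0,
            fp_no_comp=150.0 + 7.0,
            observations=tuple((c, fp + 7.0) for c, fp in obs),
        )
        for (c1, y1), (c2, y2) in zip(fraction_bound(base), fraction_bound(shifted)):
            assert y1 == pytest.approx(y2)


class TestIc50Fit:
    def test_half_maximal_binding_at_ic50(self):
        assert competition_model(np.array([300e-9]), 300e-9)[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("true_ic50", [3e-9, 30e-9, 300e-9, 3e-6])
    def test_noiseless_recovery_within_one_percent(self, true_ic50):
        conc = 40e-6 / 5.0 ** np.arange(10)
        points = [(c, float(competition_model(np.array([c]), true_ic50)[0])) for c in conc]
        fit = fit_ic50(points)
        assert fit.converged
        assert abs(fit.ic50 - true_ic50) / true_ic50 < 0.01

    def test_flat_response_does_not_converge(self):
        points = [(1e-7, 0.5), (1e-6, 0.5), (1e-5, 0.5)]
        fit = fit_ic50(points)
        assert not fit.converged and fit.ic50 is None

    def test_noisy_replicates_have_small_median_bias(self):
        """sigma = 0.03 noise, 100 replicates: |median bias| < 5%."""
        rng = np.random.default_rng(13)
        true_ic50 = 285e-9
        conc = 40e-6 / 5.0 ** np.arange(8)
        estimates = []
        for _ in range(100):
            y = competition_model(conc, true_ic50) + rng.normal(0, 0.03, size=len(conc))
            estimates.append(fit_ic50(list(zip(conc, y))).ic50)
        med = float(np.median(estimates))
        assert abs(med - true_ic50) / true_ic50 < 0.05
        assert 270e-9 <= med <= 300e-9  # within the assay's reported range


class TestDfr:
    def test_identical_wells_never_positive(self):
        plate = ElispotPlate({"pep": (2.0, 2.0)}, (2.0, 2.0, 2.0, 2.0, 2.0, 2.0))
        for m in (1, 2):
            (res,) = dfr_test(plate, m=m)
            assert not res.positive

    def test_strong_response_positive_by_exact_enumeration(self):
        plate = ElispotPlate({"pep": (100.0, 100.0)}, (1.0,) * 6)
        (res,) = dfr_test(plate, m=2, alpha=0.05)
        assert res.exact
        # oracle: all C(8,2)=28 arrangements, only the observed one reaches the statistic
        assert res.p_adjusted == pytest.approx(1 / 28)
        assert res.positive

    def test_exact_p_matches_explicit_enumeration_oracle(self):
        exp = (7.0, 3.0)
        ctrl = (1.0, 2.0, 0.3, 1.0, 3.0, 0.3)
        plate = ElispotPlate({"pep": exp}, ctrl)
        (res,) = dfr_test(plate, m=1)
        pooled = list(exp) + list(ctrl)
        obs = np.mean(exp) - np.mean(ctrl)
        count = 0
        for idx in combinations(range(8), 2):
            e = [pooled[i] for i in idx]
            c = [pooled[i] for i in range(8) if i not in idx]
            if np.mean(e) - np.mean(c) >= obs - 1e-12:
                count += 1
        assert res.p_adjusted == pytest.approx(count / 28)

    def test_imputation_raises_zero_wells_to_detection_floor(self):
        plate = ElispotPlate({"pep": (0.0, 5.0)}, (0.0, 0.0, 1.0, 0.0, 0.0, 1.0))
        imp = plate.imputed()
        assert min(imp.experimental_wells["pep"]) == 0.3
        assert min(imp.control_wells) == 0.3

    def test_dfr2x_positive_implies_dfr1x_positive(self):
        cfg = SyntheticConfig(seed=29, responder_fraction=0.4, responder_effect=6.0)
        assays = generate_validation_assays(cfg, n_plates=30)
        for plate in assays.plates:
            res = dfr_both(plate, seed=11)
            for pep, by_m in res.items():
                if by_m[2].positive:
                    assert by_m[1].positive
                assert by_m[2].p_adjusted >= by_m[1].p_adjusted - 1e-12

    def test_monte_carlo_agrees_with_exact_within_binomial_error(self):
        plate = ElispotPlate({"pep": (6.0, 4.0)}, (1.0, 2.0, 1.0, 3.0, 1.0, 2.0))
        (exact,) = dfr_test(plate, m=1)
        assert exact.exact
        (mc,) = dfr_test(plate, m=1, exact_limit=1, n_perm=4000, seed=2)
        assert not mc.exact
        se = np.sqrt(exact.p_adjusted * (1 - exact.p_adjusted) / 4000)
        assert abs(mc.p_adjusted - exact.p_adjusted) < 4 * se + 1 / 4000

    def test_type_one_error_controlled_on_null_plates(self):
        """DFR1x positive rate <= alpha + 2*SE over 1,000 null plates."""
        rng = np.random.default_rng(55)
        alpha = 0.05
        positives = 0
        n_plates = 1000
        for _ in range(n_plates):
            exp = tuple(float(x) for x in rng.poisson(1.0, size=2))
            ctrl = tuple(float(x) for x in rng.poisson(1.0, size=6))
            (res,) = dfr_test(ElispotPlate({"pep": exp}, ctrl), m=1, alpha=alpha)
            positives += res.positive
        rate = positives / n_plates
        se = np.sqrt(alpha * (1 - alpha) / n_plates)
        assert rate <= alpha + 2 * se

    def test_strong_responders_detected_with_high_power(self):
        cfg = SyntheticConfig(seed=77, responder_fraction=1.0, responder_effect=10.0,
                              n_elispot_peptides=1)
        assays = generate_validation_assays(cfg, n_plates=40)
        hits = 0
        for plate in assays.plates:
            (res,) = dfr_test(plate, m=2)
            hits += res.positive
        assert hits / 40 > 0.9

    def test_too_few_wells_skips_hypothesis(self):
        plate = ElispotPlate({"pep": (5.0,)}, (1.0, 1.0, 1.0))
        assert dfr_test(plate, m=1) == []
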