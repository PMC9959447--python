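"""Super-efficiency SBM scoring: closed-form cases, invariances, panel API."""

import numpy as np
import pytest

from _oracles import sbm_crs_bruteforce
from ecoeff.dea import DMU, EfficiencyResult, sbm_standard, sbm_super_efficiency, score_panel
from ecoeff.exceptions import ValidationError
from ecoeff.pipeline import accounts_from_activity, dmus_from_accounts
from ecoeff.synthetic import SyntheticConfig, generate_activity_panel


def _random_dmus(rng, n, m=2, r1=1, r2=1):
    return [DMU(i, rng.uniform(1, 5, m), rng.uniform(1, 5, r1), rng.uniform(1, 5, r2))
            for i in range(n)]


class TestClosedFormCases:
    def test_two_point_ratio_example(self):
        # A=(x=1,y=2), B=(x=1,y=1): B scores y_B/x_B / best ratio = 1/2
        A, B, C = DMU("A", [1.0], [2.0]), DMU("B", [1.0], [1.0]), DMU("C", [1.0], [1.2])
        res = sbm_super_efficiency(B, [A, B, C], rts="crs")
        assert res.score == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("rts", ["crs", "vrs"])
    def test_duplicate_twin_scores_exactly_one(self, rts):
        twin = dict(inputs_x=[2.0, 3.0], good_outputs_yd=[1.5], bad_outputs_yu=[0.7])
        d1, d2 = DMU("d1", **twin), DMU("d2", **twin)
        other = DMU("o", [4.0, 5.0], [0.5], [1.4])
        res = sbm_super_efficiency(d1, [d1, d2, other], rts=rts)
        assert res.score == pytest.approx(1.0, abs=1e-9)

    def test_strictly_dominated_unit_scores_below_one(self):
        good = DMU("g", [1.0, 1.0], [3.0], [0.5])
        bad = DMU("b", [2.0, 2.0], [1.5], [1.0])  # dominated in every coordinate
        other = DMU("o", [1.5, 1.4], [2.0], [0.8])
        res = sbm_super_efficiency(bad, [good, bad, other], rts="crs")
        assert res.score < 1.0


class TestInvariances:
    def test_units_invariance_of_scores(self):
        rng = np.random.default_rng(1)
        dmus = _random_dmus(rng, 6)
        base = [r.score for r in score_panel(dmus, rts="crs")]
        scaled = [DMU(d.id, d.inputs_x * np.array([10.0, 0.01]),
                      d.good_outputs_yd * 7.0, d.bad_outputs_yu * 0.2) for d in dmus]
        new = [r.score for r in score_panel(scaled, rts="crs")]
        np.testing.assert_allclose(new, base, atol=1e-8)

    def test_worsening_an_input_never_raises_the_score(self):
        rng = np.random.default_rng(2)
        dmus = _random_dmus(rng, 6)
        k = dmus[3]
        before = sbm_super_efficiency(k, dmus, rts="crs").score
        worse = DMU(k.id, k.inputs_x * np.array([1.5, 1.0]),
                    k.good_outputs_yd, k.bad_outputs_yu)
        after = sbm_super_efficiency(worse, [d for d in dmus if d.id != k.id] + [worse],
                                     rts="crs").score
        assert after <= before + 1e-9

    def test_vrs_not_below_crs_for_every_interior_unit(self):
        rng = np.random.default_rng(3)
        dmus = _random_dmus(rng, 8)
        import warnings
        crs = {r.id: r for r in score_panel(dmus, rts="crs")}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vrs = {r.id: r for r in score_panel(dmus, rts="vrs")}
        for i in crs:
            if crs[i].score < 1 and vrs[i].status == "optimal" and vrs[i].score < 1:
                assert vrs[i].score >= crs[i].score - 1e-8

    def test_exclusion_leaves_interior_scores_unchanged(self):
        rng = np.random.default_rng(4)
        dmus = _random_dmus(rng, 7)
        for k in dmus:
            inclusive = sbm_standard(k, dmus, rts="crs", include_self=True)
            if inclusive.score is not None and inclusive.score < 1 - 1e-7:
                excluded = sbm_standard(k, dmus, rts="crs", include_self=False)
                assert excluded.score == pytest.approx(inclusive.score, abs=1e-6)

    def test_vrs_lambda_weights_sum_to_one(self):
        rng = np.random.default_rng(5)
        dmus = _random_dmus(rng, 6)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for r in score_panel(dmus, rts="vrs"):
                if r.status == "optimal" and r.lambdas:
                    assert sum(r.lambdas.values()) == pytest.approx(1.0, abs=1e-6)


class TestBruteForceAgreement:
    def test_small_instances_with_bad_outputs_match_fractional_solve(self):
        rng = np.random.default_rng(11)
        for _ in range(4):
            dmus = _random_dmus(rng, int(rng.integers(3, 6)))
            for k in dmus:
                lp = sbm_super_efficiency(k, dmus, rts="crs").score
                bf = sbm_crs_bruteforce(k, dmus)
                assert lp == pytest.approx(bf, abs=1e-6)


class TestScorePanel:
    def test_synthetic_panel_scores_are_finite_with_a_frontier(self):
        activity = generate_activity_panel(SyntheticConfig(seed=0, n_units=10, n_years=3))
        dmus = dmus_from_accounts(accounts_from_activity(activity))
        res = score_panel(dmus, rts="crs", frontier="pooled")
        scores = np.array([r.score for r in res])
        assert len(scores) == 30
        assert np.all(np.isfinite(scores)) and np.all(scores > 0)
        assert scores.max() > 0.99  # a frontier unit always exists

    def test_by_year_equals_pooled_when_cross_sections_identical(self):
        """Replicating one cross-section across years: interior units keep the
        same score either way, and pooled frontier units pin at exactly 1
        (their other-year twin reproduces them)."""
        rng = np.random.default_rng(6)
        base = [(rng.uniform(1, 5, 2), rng.uniform(1, 5, 1), rng.uniform(1, 5, 1))
                for _ in range(5)]
        dmus = [DMU((f"u{i}", year), x, yd, yu)
                for year in (2011, 2012) for i, (x, yd, yu) in enumerate(base)]
        pooled = {r.id: r.score for r in score_panel(dmus, rts="crs", frontier="pooled")}
        by_year = {r.id: r.score for r in score_panel(dmus, rts="crs", frontier="by_year")}
        for uid, sc in pooled.items():
            if sc < 1 - 1e-7:
                assert by_year[uid] == pytest.approx(sc, abs=1e-7)
            else:
                assert sc == pytest.approx(1.0, abs=1e-9)

    def test_small_group_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValidationError):
            score_panel(_random_dmus(rng, 2), rts="crs")

    def test_nonpositive_data_rejected(self):
        with pytest.raises(ValidationError):
            DMU("z", [1.0, 0.0], [1.0], [1.0])

    def test_dimension_mismatch_rejected(self):
        a = DMU("a", [1.0], [1.0])
        b = DMU("b", [1.0, 2.0], [1.0])
        c = DMU("c", [1.0], [2.0])
        with pytest.raises(ValidationError):
            sbm_super_efficiency(a, [a, b, c])

    def test_infeasible_vrs_super_substitutes_standard_score(self):
        rng = np.random.default_rng(0)
        dmus = _random_dmus(rng, 8)
        with pytest.warns(RuntimeWarning):
            res = score_panel(dmus, rts="vrs")
        infeas = [r for r in res if r.status == "infeasible_super"]
        assert infeas, "expected at least one infeasible VRS super instance"
        for r in infeas:
            assert r.score == pytest.approx(1.0, abs=1e-7)
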