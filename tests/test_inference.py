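import numpy as np
import pandas as pd
import pytest

from listlength.glmm import DesignMatrix, LogisticGLMM
from listlength.inference import (
    MANDATORY_TERMS,
    OPTIONAL_TERMS,
    CandidateSet,
    ModelSpec,
    SpeciesTrendModel,
    akaike_weights,
    best_model_set,
    classify_trend,
    collinearity_report,
    enumerate_models,
    model_average,
)


class TestEnumerateModels:
    def test_four_optional_terms_give_sixteen_models(self):
        specs = enumerate_models(OPTIONAL_TERMS)
        assert len(specs) == 16
        assert len({s.optional_terms for s in specs}) == 16

    def test_no_optional_terms_gives_effort_null(self):
        specs = enumerate_models(())
        assert len(specs) == 1
        assert specs[0].terms == MANDATORY_TERMS

    def test_every_spec_contains_effort_controls(self):
        for spec in enumerate_models(OPTIONAL_TERMS):
            assert "logL" in spec.terms and "records" in spec.terms


class TestAkaikeWeights:
    def test_delta_two(self):
        w = akaike_weights([100.0, 102.0])
        assert w == pytest.approx([0.7311, 0.2689], abs=5e-5)

    def test_equal_aicc_uniform(self):
        assert akaike_weights([50.0] * 5) == pytest.approx([0.2] * 5)

    def test_huge_delta_no_overflow(self):
        w = akaike_weights([0.0, 200.0])
        assert w[0] == pytest.approx(1.0, abs=1e-12)
        assert np.isfinite(w).all()

    def test_sum_to_one(self, rng):
        w = akaike_weights(rng.uniform(100, 150, size=16))
        assert abs(w.sum() - 1.0) < 1e-12


def _fake_candidates(weights, betas=None, ses=None, term="year"):
    """CandidateSet stand-in from target weights (synthetic FitResults)."""

    class FakeResult:
        def __init__(self, aicc_val, beta, se, terms):
            self.aicc = aicc_val
            self._terms = terms
            self.params = pd.Series(
                {t: beta for t in ("intercept", *terms)}, dtype=float
            )
            self.bse_series = pd.Series(
                {t: se for t in ("intercept", *terms)}, dtype=float
            )

    weights = np.asarray(weights, dtype=float)
    aiccs = -2.0 * np.log(weights)  # inverts the weight formula up to a constant
    specs, results = [], []
    for i, a in enumerate(aiccs):
        terms = (term,) if betas is None or betas[i] is not None else ()
        spec = ModelSpec(optional_terms=terms, mandatory_terms=())
        beta = 0.0 if betas is None else (betas[i] if betas[i] is not None else 0.0)
        se = 1.0 if ses is None else ses[i]
        specs.append(spec)
        results.append(FakeResult(a, beta, se, terms))
    return CandidateSet("toy", specs, results)


class TestBestModelSet:
    def test_evidence_ratio_rule(self):
        cand = _fake_candidates([0.6, 0.3, 0.02])
        retained = best_model_set(cand, ratio=0.05)
        # weights renormalize over the full candidate set (0.6/0.92, 0.3/0.92)
        assert [round(w, 4) for _, _, w in retained] == [0.6522, 0.3261]

    def test_dominant_model_retained_alone(self):
        cand = _fake_candidates([0.95, 0.04, 0.01])
        retained = best_model_set(cand)
        assert len(retained) == 1
        assert retained[0][2] == pytest.approx(0.95, abs=1e-6)

    def test_equal_weights_all_retained(self):
        cand = _fake_candidates([0.25, 0.25, 0.25, 0.25])
        assert len(best_model_set(cand)) == 4

    def test_retained_weights_renormalize_to_one(self):
        cand = _fake_candidates([0.5, 0.3, 0.15, 0.05])
        retained = best_model_set(cand, ratio=0.2)
        avg = model_average(retained)
        assert avg.summed_weight["year"] == pytest.approx(0.95, abs=1e-9)


class TestModelAverage:
    def test_hand_computed_toy_example(self):
        """(0.6*0.5 + 0.2*0.3)/0.8 = 0.45 with the absent-model weight dropped."""
        cand = _fake_candidates([0.6, 0.2, 0.2], betas=[0.5, 0.3, None])
        retained = [
            (s, r, w) for (s, r), w in zip(zip(cand.specs, cand.results), [0.6, 0.2, 0.2])
        ]
        avg = model_average(retained)
        assert avg.estimates["year"] == pytest.approx(0.45, abs=1e-12)
        assert avg.n_models["year"] == 2
        assert avg.summed_weight["year"] == pytest.approx(0.8)

    def test_single_model_term_passes_through(self):
        cand = _fake_candidates([0.7, 0.3], betas=[0.42, None], ses=[0.11, 1.0])
        retained = [
            (s, r, w) for (s, r), w in zip(zip(cand.specs, cand.results), [0.7, 0.3])
        ]
        avg = model_average(retained)
        assert avg.estimates["year"] == pytest.approx(0.42)
        assert avg.ses["year"] == pytest.approx(0.11)

    def test_identical_betas_invariant_to_weights(self):
        cand = _fake_candidates([0.5, 0.4, 0.1], betas=[0.33, 0.33, 0.33], ses=[0.2, 0.2, 0.2])
        retained = [
            (s, r, w) for (s, r), w in zip(zip(cand.specs, cand.results), [0.5, 0.4, 0.1])
        ]
        avg = model_average(retained)
        assert avg.estimates["year"] == pytest.approx(0.33, abs=1e-12)
        assert avg.ses["year"] == pytest.approx(0.2, abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            model_average([])


class TestClassifyTrend:
    @pytest.mark.parametrize(
        "estimate,se,call",
        [(-0.5, 0.1, "decline"), (0.1, 0.2, "no_trend"), (0.4, 0.1, "increase")],
    )
    def test_ci_rule(self, estimate, se, call):
        tc = classify_trend(estimate, se, species="sp")
        assert tc.call == call
        assert tc.ci_low == pytest.approx(estimate - 1.96 * se, abs=1e-3)
        assert tc.ci_high == pytest.approx(estimate + 1.96 * se, abs=1e-3)

    def test_decline_boundary_is_strict(self):
        # CI upper exactly 0 is not "completely below zero"
        tc = classify_trend(-1.959963984540054, 1.0)
        assert tc.call == "no_trend"

    def test_nonfinite_se_is_insufficient(self):
        assert classify_trend(0.2, np.nan).call == "insufficient"


class TestCollinearity:
    def test_orthogonal_columns_unit_vif(self):
        # zero-mean mutually orthogonal contrast columns
        a = np.array([1, 1, 1, 1, -1, -1, -1, -1], dtype=float)
        b = np.array([1, 1, -1, -1, 1, 1, -1, -1], dtype=float)
        c = np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
        X = pd.DataFrame({"a": a, "b": b, "c": c})
        report = collinearity_report(X)
        assert report["vif"]["vif"].tolist() == pytest.approx([1.0] * 3, abs=1e-9)
        assert not report["vif"]["flagged"].any()

    def test_duplicated_column_flagged_infinite(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
        report = collinearity_report(X)
        assert np.isinf(report["vif"].set_index("term").loc["a", "vif"])
        assert report["vif"].set_index("term").loc["a", "flagged"]

    def test_monotone_pair_spearman_one(self, rng):
        x = rng.normal(size=40)
        X = pd.DataFrame({"a": x, "b": np.exp(x)})
        rho = collinearity_report(X)["spearman"]
        assert rho.loc["a", "b"] == pytest.approx(1.0)


class TestSpeciesTrendModel:
    @pytest.fixture(scope="class")
    def design(self, small_simulation):
        _, _, truth = small_simulation
        return truth.design_matrix("speciesA")

    def test_full_run_produces_trend_call(self, design):
        result = SpeciesTrendModel("speciesA", design).fit(n_nodes=7)
        assert len(result.candidates.results) == 16
        assert abs(result.candidates.weights.sum() - 1.0) < 1e-12
        assert result.trend.call in {"decline", "increase", "no_trend"}
        assert "model-averaged coefficients" in result.summary()

    def test_candidate_table_schema(self, design):
        result = SpeciesTrendModel("speciesA", design, optional_terms=("year",)).fit(n_nodes=7)
        frame = result.candidates.to_frame()
        assert set(frame.columns) >= {"model", "aicc", "delta_aicc", "weight", "retained"}
        assert frame["delta_aicc"].iloc[0] == 0.0
        assert frame["retained"].any()

    def test_noise_covariate_does_not_flip_strong_trend(self, small_simulation, rng):
        """A pure-noise optional covariate leaves the averaged year sign alone."""
        _, _, truth = small_simulation
        base = truth.design_matrix("speciesA")
        noise = rng.normal(size=base.exog.shape[0])
        noise = (noise - noise.mean()) / noise.std(ddof=1)
        augmented = DesignMatrix(
            endog=base.endog,
            exog=np.column_stack([base.exog, noise]),
            groups=base.groups,
            exog_names=[*base.exog_names, "noise"],
        )
        plain = SpeciesTrendModel("speciesA", base, optional_terms=("year", "bio6")).fit(n_nodes=7)
        noisy = SpeciesTrendModel(
            "speciesA", augmented, optional_terms=("year", "bio6", "noise")
        ).fit(n_nodes=7)
        assert np.sign(plain.averaged.estimates["year"]) == np.sign(
            noisy.averaged.estimates["year"]
        )

    def test_missing_design_column_rejected(self, design):
        incomplete = DesignMatrix(
            endog=design.endog,
            exog=design.exog[:, :2],
            groups=design.groups,
            exog_names=design.exog_names[:2],
        )
        with pytest.raises(ValueError):
            SpeciesTrendModel("speciesA", incomplete)
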