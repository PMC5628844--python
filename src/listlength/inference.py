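"""All-subsets AICc model selection, model averaging and trend classification.

For each species, every subset of the optional fixed effects
``{year, bio6, bio10, bio18}`` is fitted on top of the mandatory
effort-control terms (log list length, record count) and the county random
intercept — 16 candidate GLMMs.  Candidates are ranked by AICc; Akaike
weights give each model's probability of being the best in the set.  If no
single model dominates (weight >= 0.9), the best-model set keeps every model
whose weight is at least 5% of the top weight (evidence ratio 0.05).
Coefficients are conditionally model-averaged (over the models that contain
the term), and the 95% CI of the averaged year term classifies the species as
declining, increasing or trendless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import DesignMatrix, GLMMResults, LogisticGLMM, standardize

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "enumerate_models",
    "akaike_weights",
    "best_model_set",
    "model_average",
    "classify_trend",
    "collinearity_report",
    "CandidateSet",
    "AveragedCoefficients",
    "TrendCall",
    "SpeciesTrendModel",
    "SpeciesTrendResults",
]

MANDATORY_TERMS = ("logL", "records")
OPTIONAL_TERMS = ("year", "bio6", "bio10", "bio18")
Z_95 = 1.959963984540054  # standard-normal 97.5% quantile


@dataclass(frozen=True)
class ModelSpec:
    """One candidate: mandatory effort terms + a subset of optional terms.

    The intercept and the county random intercept are always present.
    """

    optional_terms: tuple[str, ...]
    mandatory_terms: tuple[str, ...] = MANDATORY_TERMS

    @property
    def terms(self) -> tuple[str, ...]:
        # stable order: effort controls first, then optional terms in canonical order
        return self.mandatory_terms + self.optional_terms

    @property
    def label(self) -> str:
        return "+".join(self.terms)


def enumerate_models(optional_terms: tuple[str, ...] = OPTIONAL_TERMS) -> list[ModelSpec]:
    """All 2^m subsets of the optional terms, each with the mandatory effort terms.

    Ordered lexicographically by inclusion pattern (null model first), which
    also serves as the deterministic tie-break order for equal AICc.
    """
    optional_terms = tuple(optional_terms)
    specs = []
    for mask in range(2 ** len(optional_terms)):
        included = tuple(t for j, t in enumerate(optional_terms) if mask >> j & 1)
        specs.append(ModelSpec(optional_terms=included))
    return specs


def akaike_weights(aicc_values) -> np.ndarray:
    """w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2), deltas from the minimum AICc."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("empty AICc vector")
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


@dataclass
class CandidateSet:
    """Ranked candidate models for one species."""

    species: str
    specs: list[ModelSpec]
    results: list[GLMMResults]
    aicc_values: np.ndarray = field(init=False)
    delta_aicc: np.ndarray = field(init=False)
    weights: np.ndarray = field(init=False)

    def __post_init__(self):
        self.aicc_values = np.array([r.aicc for r in self.results])
        self.delta_aicc = self.aicc_values - self.aicc_values.min()
        self.weights = akaike_weights(self.aicc_values)

    def to_frame(self) -> pd.DataFrame:
        retained = best_model_set(self)
        retained_idx = {id(s) for s, _, _ in retained}
        rows = []
        for spec, res, d, w in zip(self.specs, self.results, self.delta_aicc, self.weights):
            rows.append(
                {
                    "species": self.species,
                    "model": spec.label,
                    "k": res.k_params,
                    "logLik": res.llf,
                    "aicc": res.aicc,
                    "delta_aicc": d,
                    "weight": w,
                    "retained": id(spec) in retained_idx,
                }
            )
        df = pd.DataFrame(rows)
        return df.sort_values(["delta_aicc", "model"], ignore_index=True)


def best_model_set(
    candidates: CandidateSet, ratio: float = 0.05, dominance: float = 0.9
) -> list[tuple[ModelSpec, GLMMResults, float]]:
    """Evidence-ratio model retention.

    If one model carries weight >= ``dominance`` it is retained alone;
    otherwise all models with weight >= ``ratio`` * max(weight) are retained.
    Returns (spec, result, weight) triples in candidate order.
    """
    w = candidates.weights
    if w.max() >= dominance:
        keep = w == w.max()
        if keep.sum() > 1:  # exact tie at the top: keep first in spec order
            first = int(np.argmax(w))
            keep = np.zeros_like(keep)
            keep[first] = True
    else:
        keep = w >= ratio * w.max()
    return [
        (s, r, float(wi))
        for s, r, wi, k in zip(candidates.specs, candidates.results, w, keep)
        if k
    ]


@dataclass
class AveragedCoefficients:
    """Conditionally model-averaged estimates: per term, the weighted mean over
    the models containing the term (weights renormalized over those models)."""

    estimates: dict[str, float]
    ses: dict[str, float]
    n_models: dict[str, int]
    summed_weight: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": t,
                "estimate": self.estimates[t],
                "se": self.ses[t],
                "ci_low": self.estimates[t] - Z_95 * self.ses[t],
                "ci_high": self.estimates[t] + Z_95 * self.ses[t],
                "n_models": self.n_models[t],
                "summed_weight": self.summed_weight[t],
            }
            for t in self.estimates
        ]
        return pd.DataFrame(rows)


def model_average(retained: list[tuple[ModelSpec, GLMMResults, float]]) -> AveragedCoefficients:
    """Conditional (natural) model averaging over a retained model set.

    estimate_t = sum_i w~_i beta_it over models containing t, w~ renormalized
    over those models; the averaged SE is the revised unconditional estimator
    SE_t = sum_i w~_i sqrt(SE_it^2 + (beta_it - avg)^2), which folds
    between-model spread into the within-model variance.
    """
    if not retained:
        raise ValueError("empty retained model set")
    terms: list[str] = []
    for spec, _, _ in retained:
        for t in spec.terms:
            if t not in terms:
                terms.append(t)
    terms = ["intercept", *terms]

    estimates, ses, n_models, summed = {}, {}, {}, {}
    for t in terms:
        entries = [
            (res.params[t], res.bse_series[t], w)
            for spec, res, w in retained
            if t == "intercept" or t in spec.terms
        ]
        if not entries:
            continue
        betas = np.array([e[0] for e in entries])
        sigmas = np.array([e[1] for e in entries])
        ws = np.array([e[2] for e in entries])
        total = ws.sum()
        wt = ws / total
        bbar = float(wt @ betas)
        estimates[t] = bbar
        ses[t] = float(wt @ np.sqrt(sigmas**2 + (betas - bbar) ** 2))
        n_models[t] = len(entries)
        summed[t] = float(total)
    return AveragedCoefficients(estimates, ses, n_models, summed)


@dataclass
class TrendCall:
    """Species trend from the 95% CI of the (averaged) year coefficient:
    decline iff the CI lies entirely below 0, increase iff entirely above,
    no_trend iff it straddles 0."""

    species: str
    year_coefficient: float
    ci_low: float
    ci_high: float
    call: str

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "estimate": self.year_coefficient,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "call": self.call,
        }


def classify_trend(
    estimate: float, se: float, species: str = "", z: float = Z_95
) -> TrendCall:
    if not (np.isfinite(estimate) and np.isfinite(se)):
        return TrendCall(species, float(estimate), np.nan, np.nan, "insufficient")
    lo, hi = estimate - z * se, estimate + z * se
    if hi < 0:
        call = "decline"
    elif lo > 0:
        call = "increase"
    else:
        call = "no_trend"
    return TrendCall(species, float(estimate), float(lo), float(hi), call)


def collinearity_report(
    predictors: pd.DataFrame, vif_threshold: float = 5.0
) -> dict[str, pd.DataFrame]:
    """Variance inflation factors and pairwise Spearman rank correlations.

    VIF_j = 1/(1 - R^2_j) from the OLS regression of column j on the others
    (with intercept); a perfectly collinear column yields inf and is flagged.
    """
    cols = list(predictors.columns)
    X = predictors.to_numpy(dtype=float)
    n, p = X.shape
    vifs = []
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        y = X[:, j]
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            r2 = 1.0
        else:
            r2 = 1.0 - ss_res / ss_tot
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        vifs.append(vif)
    vif_df = pd.DataFrame(
        {"term": cols, "vif": vifs, "flagged": [v >= vif_threshold for v in vifs]}
    )
    if p == 1:
        rho = np.ones((1, 1))
    elif p == 2:
        r = stats.spearmanr(X[:, 0], X[:, 1]).statistic
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = stats.spearmanr(X).statistic
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    return {"vif": vif_df, "spearman": rho_df}


# --------------------------------------------------------------------- orchestration


class SpeciesTrendModel:
    """Multi-model trend inference for one species' reporting rate.

    Statsmodels-style wrapper: construct from the per-event design (shared,
    standardized covariates) and the species' 0/1 response, then ``fit()``.
    """

    def __init__(
        self,
        species: str,
        design: DesignMatrix,
        optional_terms: tuple[str, ...] = OPTIONAL_TERMS,
    ):
        missing = [
            t for t in MANDATORY_TERMS + tuple(optional_terms) if t not in design.exog_names
        ]
        if missing:
            raise ValueError(f"design is missing required columns: {missing}")
        self.species = species
        self.design = design
        self.optional_terms = tuple(optional_terms)

    def _submodel(self, spec: ModelSpec) -> LogisticGLMM:
        idx = [self.design.exog_names.index(t) for t in spec.terms]
        return LogisticGLMM(
            self.design.endog,
            self.design.exog[:, idx],
            self.design.groups,
            exog_names=list(spec.terms),
        )

    def fit(
        self,
        n_nodes: int = 15,
        evidence_ratio: float = 0.05,
        dominance: float = 0.9,
        z: float = Z_95,
    ) -> "SpeciesTrendResults":
        specs = enumerate_models(self.optional_terms)
        fitted_specs, fitted_results = [], []
        for spec in specs:
            res = self._submodel(spec).fit(n_nodes=n_nodes)
            if not res.converged:
                logger.warning(
                    "species %s: model %s did not converge; dropped from candidate set",
                    self.species, spec.label,
                )
                continue
            fitted_specs.append(spec)
            fitted_results.append(res)
        if not fitted_results:
            raise RuntimeError(f"species {self.species}: no candidate model converged")
        candidates = CandidateSet(self.species, fitted_specs, fitted_results)
        retained = best_model_set(candidates, ratio=evidence_ratio, dominance=dominance)
        averaged = model_average(retained)

        if "year" in averaged.estimates:
            est, se = averaged.estimates["year"], averaged.ses["year"]
        else:
            # year dropped out of the best set entirely: average over the
            # year-containing candidates so a trend estimate is still defined
            with_year = [
                (s, r, float(w))
                for s, r, w in zip(candidates.specs, candidates.results, candidates.weights)
                if "year" in s.terms
            ]
            if with_year:
                fallback = model_average(with_year)
                est, se = fallback.estimates["year"], fallback.ses["year"]
            else:
                est, se = np.nan, np.nan
        trend = classify_trend(est, se, species=self.species, z=z)
        return SpeciesTrendResults(self.species, candidates, retained, averaged, trend)


@dataclass
class SpeciesTrendResults:
    species: str
    candidates: CandidateSet
    retained: list[tuple[ModelSpec, GLMMResults, float]]
    averaged: AveragedCoefficients
    trend: TrendCall

    def summary(self) -> str:
        lines = [
            f"Species: {self.species}",
            f"candidate models: {len(self.candidates.results)}; "
            f"retained (evidence ratio): {len(self.retained)}",
            f"trend: {self.trend.call}  year = {self.trend.year_coefficient:.4f} "
            f"({self.trend.ci_low:.4f}, {self.trend.ci_high:.4f})",
            "model-averaged coefficients:",
        ]
        for t, b in self.averaged.estimates.items():
            lines.append(f"  {t:<10} {b:>9.4f}  (SE {self.averaged.ses[t]:.4f})")
        return "\n".join(lines)


def build_design(
    events: pd.DataFrame,
    response: np.ndarray,
    covariate_columns: list[str] | None = None,
    group_column: str = "county",
    standardized: bool = False,
) -> DesignMatrix:
    """Assemble a species design from an event table with covariates attached.

    The continuous covariates (year, logL, records, bio6, bio10, bio18 by
    default, with logL computed as log(L) if absent) are standardized once
    here unless ``standardized`` is already true.
    """
    events = events.copy()
    if "logL" not in events.columns and "L" in events.columns:
        events["logL"] = np.log(events["L"].to_numpy(dtype=float))
    if covariate_columns is None:
        covariate_columns = ["year", "logL", "records", "bio6", "bio10", "bio18"]
        covariate_columns = [c for c in covariate_columns if c in events.columns]
    constants: dict[str, tuple[float, float]] = {}
    frame = events[covariate_columns].astype(float)
    if not standardized:
        frame, constants = standardize(frame)
    return DesignMatrix(
        endog=np.asarray(response, dtype=float),
        exog=frame.to_numpy(),
        groups=events[group_column].to_numpy(),
        exog_names=list(covariate_columns),
        constants=constants,
    )
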