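"""End-to-end orchestration: records -> lists -> per-species trend inference
-> trait tests, with every stage writing a CSV artifact and logging its
exclusion counts.

All randomness lives in the synthetic generator; given fixed inputs the
analysis stages are deterministic, and pipeline outputs are invariant to the
row order of the input tables (lists are rebuilt in a canonical order).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, bioclim, fisher, lists
from .inference import OPTIONAL_TERMS, SpeciesTrendModel, build_design, collinearity_report
from .simulate import SimulationConfig, simulate_climate, simulate_records, simulate_traits

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineOutputs", "run_pipeline", "subset_records"]


@dataclass
class PipelineConfig:
    """Configuration for a full run.

    Either the three input CSV paths or a :class:`SimulationConfig` must be
    provided.  Thresholds mirror the analysis defaults: lists need at least
    two species, rostered species at least ten lists, candidate models are
    compared with the 0.05 evidence ratio and trends called from 95% CIs.
    """

    records_csv: str | None = None
    traits_csv: str | None = None
    climate_csv: str | None = None
    simulation: SimulationConfig | None = None
    activity_classes: tuple[str, ...] = ("diurnal", "nocturnal")
    min_list_length: int = 2
    min_lists_per_species: int = 10
    optional_terms: tuple[str, ...] = OPTIONAL_TERMS
    n_nodes: int = 15
    evidence_ratio: float = 0.05
    ci_z: float = 1.959963984540054
    merge_map: dict[str, str] = field(default_factory=dict)
    region_labels: tuple[str, ...] | None = None  # subset records to these regions
    output_dir: str = "listlength_output"

    def __post_init__(self):
        if self.simulation is None and self.records_csv is None:
            raise ValueError("provide input CSVs or a simulation config")
        if not (0 < self.evidence_ratio <= 1):
            raise ValueError("evidence_ratio must be in (0, 1]")
        if self.min_list_length < 1 or self.min_lists_per_species < 1:
            raise ValueError("thresholds must be positive")


@dataclass
class PipelineOutputs:
    events: pd.DataFrame
    membership: pd.DataFrame
    covariates: pd.DataFrame
    candidates: pd.DataFrame
    coefficients: pd.DataFrame
    trends: pd.DataFrame
    fisher_tests: pd.DataFrame | None
    collinearity: dict[str, pd.DataFrame]
    output_dir: Path


def subset_records(records: pd.DataFrame, region_labels, column: str = "region") -> pd.DataFrame:
    """Keep records from the given regions (e.g. drop parasitoid-refuge areas
    to compare exposed-only against all-records trends)."""
    if column not in records.columns:
        raise ValueError(f"record table has no {column!r} column to subset on")
    keep = records[column].isin(list(region_labels))
    logger.info("region subset %s: retained %d of %d records",
                list(region_labels), int(keep.sum()), len(records))
    return records[keep].reset_index(drop=True)


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        records, truth = simulate_records(config.simulation)
        climate = simulate_climate(config.simulation)
        traits = simulate_traits(config.simulation)
        return records, traits, climate, truth
    records = pd.read_csv(config.records_csv)
    if config.traits_csv is None or config.climate_csv is None:
        raise ValueError("traits_csv and climate_csv are required with records_csv")
    traits = pd.read_csv(config.traits_csv)
    climate = pd.read_csv(config.climate_csv)
    return records, traits, climate, None


def run_pipeline(config: PipelineConfig) -> PipelineOutputs:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, traits, climate, truth = _load_inputs(config)
    logger.info("input: %d record rows, %d species in trait table", len(records), len(traits))

    if config.region_labels is not None:
        records = subset_records(records, config.region_labels)
    if config.merge_map:
        records = lists.taxon_merge(records, config.merge_map)

    covariates = bioclim.county_year_covariates(climate)
    events, membership = lists.build_lists(records)
    logger.info("built %d lists from %d record rows", len(events), len(records))
    events, membership = lists.filter_events(events, membership, min_L=config.min_list_length)
    datasets = lists.split_by_activity(
        events, membership, traits, min_lists=config.min_lists_per_species
    )

    candidate_frames, coef_frames, trend_rows = [], [], []
    collin: dict[str, pd.DataFrame] = {}
    for activity in config.activity_classes:
        ds = datasets[activity]
        if not ds.species_roster:
            logger.info("%s: no species meet the %d-list rule; skipped",
                        activity, config.min_lists_per_species)
            continue
        ev = bioclim.attach_covariates(ds.events, covariates)
        design_cols = ["year", "logL", "records", "bio6", "bio10", "bio18"]
        for species in ds.species_roster:
            design = build_design(
                ev, ds.response[species].to_numpy(), covariate_columns=design_cols
            )
            if species == ds.species_roster[0]:
                report = collinearity_report(pd.DataFrame(design.exog, columns=design.exog_names))
                collin[activity] = report["vif"]
                logger.info("%s collinearity: max VIF = %.3f", activity,
                            report["vif"]["vif"].max())
            model = SpeciesTrendModel(species, design, optional_terms=config.optional_terms)
            result = model.fit(
                n_nodes=config.n_nodes, evidence_ratio=config.evidence_ratio, z=config.ci_z
            )
            cand = result.candidates.to_frame()
            cand.insert(0, "activity", activity)
            candidate_frames.append(cand)
            coefs = result.averaged.to_frame()
            coefs.insert(0, "species", species)
            coefs.insert(0, "activity", activity)
            coef_frames.append(coefs)
            trend_rows.append({"activity": activity, **result.trend.to_dict()})

    candidates = pd.concat(candidate_frames, ignore_index=True) if candidate_frames else pd.DataFrame()
    coefficients = pd.concat(coef_frames, ignore_index=True) if coef_frames else pd.DataFrame()
    trends = pd.DataFrame(trend_rows)

    fisher_df = None
    if len(trends) and {"host_habit", "flight_end_month", "pest"} <= set(traits.columns):
        fisher_df = _trait_tests(trends, traits)

    _write_outputs(out_dir, config, events, membership, covariates,
                   candidates, coefficients, trends, fisher_df, truth)
    return PipelineOutputs(
        events=events, membership=membership, covariates=covariates,
        candidates=candidates, coefficients=coefficients, trends=trends,
        fisher_tests=fisher_df, collinearity=collin, output_dir=out_dir,
    )


def _trait_tests(trends: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame | None:
    calls = trends[["species", "call"]].copy()
    rows = []
    for label, summer in (("all_species", False), ("summer_only", True)):
        try:
            table = fisher.build_table(calls, traits, summer_only=summer)
            rows.append(
                {
                    "test": label,
                    "n11": table.counts[0, 0], "n12": table.counts[0, 1],
                    "n21": table.counts[1, 0], "n22": table.counts[1, 1],
                    "odds_ratio": fisher.odds_ratio(table),
                    "p_value": fisher.fisher_exact_two_tailed(table),
                }
            )
        except (ValueError, KeyError) as exc:
            logger.info("trait test %s not computable: %s", label, exc)
    return pd.DataFrame(rows) if rows else None


def _write_outputs(out_dir, config, events, membership, covariates,
                   candidates, coefficients, trends, fisher_df, truth) -> None:
    events.to_csv(out_dir / "events.csv", index=False)
    membership.to_csv(out_dir / "membership.csv", index=False)
    covariates.to_csv(out_dir / "covariates.csv", index=False)
    candidates.to_csv(out_dir / "candidate_models.csv", index=False)
    coefficients.to_csv(out_dir / "averaged_coefficients.csv", index=False)
    trends.to_csv(out_dir / "trends.csv", index=False)
    if fisher_df is not None:
        fisher_df.to_csv(out_dir / "fisher_tests.csv", index=False)
    if truth is not None:
        truth.coefficients.to_csv(out_dir / "true_coefficients.csv")

    manifest = {
        "package": "listlength",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": {
            k: (v if isinstance(v, (int, float, str, bool, type(None), list)) else str(v))
            for k, v in vars(config).items()
        },
        "n_events": int(len(events)),
        "n_trend_calls": int(len(trends)),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
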