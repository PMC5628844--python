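"""Synthetic opportunistic-record generator with known ground truth.

Emulates a century of museum/private collecting of a moth assemblage:
sampling events ("lists") scattered over counties and years 1900–2012 with a
sharp effort increase in the mid-1960s (the arrival of mercury-vapor light
collecting), each event carrying a list length and a record count, and each
species detected on each list with a probability from the logistic
observation model

    logit(p) = alpha + b_year*year + b_logL*log(L) + b_rec*records
               + b_bio6*bio6 + b_bio10*bio10 + b_bio18*bio18 + county_effect

with all continuous covariates standardized and county effects drawn
N(0, county_sd^2).  Everything needed for parameter-recovery checks (county
effects, coefficient vectors, per-(species,event) probabilities, the exact
standardized design) is returned as :class:`GroundTruth`.

The event-level covariates L and records are drawn from configurable
distributions and species detections are simulated *conditionally* on them —
exactly the conditional observation model that the GLMM estimates.  The
materialized record table contains rows only for detected species, so the
list length a downstream pipeline recomputes from the table is a noisy,
emergent version of the drawn L (as in real collecting, where the recorded
list is itself the outcome of detection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from . import bioclim

__all__ = [
    "EffortRegime",
    "SimulationConfig",
    "GroundTruth",
    "default_coefficients",
    "simulate_climate",
    "simulate_records",
    "simulate_traits",
    "COEF_TERMS",
    "COVARIATE_TERMS",
]

COEF_TERMS = ("intercept", "year", "logL", "records", "bio6", "bio10", "bio18")
COVARIATE_TERMS = COEF_TERMS[1:]

# Monthly climatology loosely matching the northeastern U.S. (°C, mm)
_TMEAN_CYCLE = np.array([-5.0, -4.0, 1.0, 8.0, 14.0, 19.0, 22.0, 21.0, 17.0, 10.0, 4.0, -2.0])
_TMIN_OFFSET = -6.0
_PRCP_CYCLE = np.array([80.0, 75.0, 90.0, 95.0, 100.0, 105.0, 110.0, 100.0, 105.0, 100.0, 95.0, 90.0])


@dataclass
class EffortRegime:
    """Expected total sampling events per year: low before the breakpoint,
    high after (piecewise constant)."""

    breakpoint_year: int = 1965
    events_per_year_early: float = 8.0
    events_per_year_late: float = 30.0

    def rate(self, year) -> np.ndarray:
        year = np.asarray(year)
        return np.where(
            year < self.breakpoint_year, self.events_per_year_early, self.events_per_year_late
        ).astype(float)


def default_coefficients(n_species: int, beta_year: float = -0.5) -> np.ndarray:
    """One coefficient vector per species on the standardized scale.

    Defaults give a baseline reporting rate around 0.25, a strong positive
    list-length effect (the premise of the effort correction), a modest
    record-count effect and weak climate effects.
    """
    base = np.array([-1.2, beta_year, 1.0, 0.3, 0.3, -0.2, 0.1])
    return np.tile(base, (n_species, 1))


@dataclass
class SimulationConfig:
    #: the northeastern-US study region spans on the order of 60-80 counties
    n_counties: int = 30
    year_range: tuple[int, int] = (1900, 2012)
    n_species: int = 5
    true_coefficients: np.ndarray | None = None  # (n_species, 7) in COEF_TERMS order
    county_sd: float = 0.5
    effort_regime: EffortRegime = field(default_factory=EffortRegime)
    #: L = 1 + Poisson(list_size_mean_extra)
    list_size_mean_extra: float = 1.0
    #: records = L + Poisson(records_mean_extra)
    records_mean_extra: float = 1.5
    #: extra individuals per detected species: 1 + Poisson(individuals_mean_extra)
    individuals_mean_extra: float = 0.5
    seed: int = 0
    #: if set, exactly this many events are placed (multinomially over
    #: county-year cells in proportion to the effort rates)
    n_events: int | None = None
    # climate-generator knobs (°C / mm)
    temp_noise_sd: float = 1.2
    prcp_noise_sd: float = 25.0
    county_temp_sd: float = 1.5
    county_prcp_sd: float = 30.0
    n_sites_per_county: int = 5
    n_collectors: int = 25
    species_names: list[str] | None = None

    def __post_init__(self):
        lo, hi = self.year_range
        if hi - lo < 1:
            raise ValueError("year_range must span at least 2 years")
        if self.n_counties < 1 or self.n_species < 1:
            raise ValueError("n_counties and n_species must be positive")
        if self.county_sd < 0:
            raise ValueError("county_sd must be nonnegative")
        if (
            self.effort_regime.events_per_year_early <= 0
            or self.effort_regime.events_per_year_late <= 0
        ):
            raise ValueError("expected event rates must be positive")
        if self.true_coefficients is None:
            self.true_coefficients = default_coefficients(self.n_species)
        self.true_coefficients = np.atleast_2d(np.asarray(self.true_coefficients, dtype=float))
        if self.true_coefficients.shape == (1, len(COEF_TERMS)) and self.n_species > 1:
            self.true_coefficients = np.tile(self.true_coefficients, (self.n_species, 1))
        if self.true_coefficients.shape != (self.n_species, len(COEF_TERMS)):
            raise ValueError(
                f"true_coefficients must have shape ({self.n_species}, {len(COEF_TERMS)})"
            )
        if np.isnan(self.true_coefficients).any():
            raise ValueError("true_coefficients contain NaN")
        if self.species_names is None:
            self.species_names = [f"species{chr(65 + s // 26) if s >= 26 else ''}{chr(65 + s % 26)}"
                                  for s in range(self.n_species)]

    @property
    def counties(self) -> list[str]:
        return [f"county{i:02d}" for i in range(self.n_counties)]

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_range[0], self.year_range[1] + 1)


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would not."""

    county_effects: pd.Series  # realized N(0, sd^2) intercepts, sample mean kept
    coefficients: pd.DataFrame  # species x COEF_TERMS, standardized scale
    probabilities: pd.DataFrame  # events x species latent detection probabilities
    detections: pd.DataFrame  # events x species 0/1 outcomes
    design: pd.DataFrame  # per event: event_id, county, year + standardized covariates
    constants: dict[str, tuple[float, float]]  # standardization (mean, sd) per covariate

    def design_matrix(self, species: str):
        """Exact standardized design used in simulation, as a GLMM design for
        the given species (for parameter-recovery fits)."""
        from .glmm import DesignMatrix

        return DesignMatrix(
            endog=self.detections[species].to_numpy(dtype=float),
            exog=self.design[list(COVARIATE_TERMS)].to_numpy(),
            groups=self.design["county"].to_numpy(),
            exog_names=list(COVARIATE_TERMS),
            constants=self.constants,
        )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent substreams so climate is identical whether simulated alone
    # or as part of simulate_records
    return np.random.default_rng([config.seed, stream])


def simulate_climate(config: SimulationConfig) -> pd.DataFrame:
    """Monthly county climate series: seasonal cycle + county offset + noise.

    Returns a long table ``county, year, month, tmin_C, tmean_C, prcp_mm``
    with 12 months per county-year, reproducible under a fixed seed.
    """
    rng = _rng(config, 1)
    counties, years = config.counties, config.years
    n_c, n_y = len(counties), len(years)

    temp_offsets = rng.normal(0.0, config.county_temp_sd, size=n_c) if config.county_temp_sd else np.zeros(n_c)
    prcp_offsets = rng.normal(0.0, config.county_prcp_sd, size=n_c) if config.county_prcp_sd else np.zeros(n_c)

    shape = (n_c, n_y, 12)
    tmean = np.broadcast_to(
        _TMEAN_CYCLE[None, None, :] + temp_offsets[:, None, None], shape
    ).copy()
    if config.temp_noise_sd:
        tmean += rng.normal(0.0, config.temp_noise_sd, size=shape)
        tmin = tmean + _TMIN_OFFSET + rng.normal(0.0, config.temp_noise_sd, size=shape)
    else:
        tmin = tmean + _TMIN_OFFSET
    prcp = np.broadcast_to(
        _PRCP_CYCLE[None, None, :] + prcp_offsets[:, None, None], shape
    ).copy()
    if config.prcp_noise_sd:
        prcp += rng.normal(0.0, config.prcp_noise_sd, size=shape)
    prcp = np.clip(prcp, 0.0, None)

    county_idx, year_idx, month_idx = np.meshgrid(
        np.arange(n_c), np.arange(n_y), np.arange(12), indexing="ij"
    )
    return pd.DataFrame(
        {
            "county": np.asarray(counties)[county_idx.ravel()],
            "year": years[year_idx.ravel()],
            "month": month_idx.ravel() + 1,
            "tmin_C": tmin.ravel(),
            "tmean_C": tmean.ravel(),
            "prcp_mm": prcp.ravel(),
        }
    )


def simulate_traits(config: SimulationConfig, diurnal_fraction: float = 0.2) -> pd.DataFrame:
    """Species trait table matching the simulated assemblage.

    Activity is drawn with the given diurnal fraction (hawk-moth assemblages
    are predominantly nocturnal), host-plant habit is split evenly between
    tree/vine and shrub/herb feeders, flight windows fall within May-September
    and no synthetic species is a crop pest.
    """
    rng = _rng(config, 3)
    n = config.n_species
    activity = np.where(rng.random(n) < diurnal_fraction, "diurnal", "nocturnal")
    habit = np.where(rng.random(n) < 0.5, "tree/vine", "shrub/herb")
    start = rng.integers(5, 8, size=n)
    end = start + rng.integers(1, 3, size=n)
    return pd.DataFrame(
        {
            "species": config.species_names,
            "activity": activity,
            "host_habit": habit,
            "flight_start_month": start,
            "flight_end_month": np.minimum(end, 9),
            "pest": False,
        }
    )


def _place_events(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Counts of events per (county, year): Poisson with county-specific
    multipliers (opportunistic collecting clusters in favorite counties), or a
    multinomial allocation when an exact total is requested."""
    counties, years = config.counties, config.years
    shares = rng.dirichlet(np.full(config.n_counties, 5.0))
    rates = shares[:, None] * config.effort_regime.rate(years)[None, :]
    if config.n_events is not None:
        flat = rates.ravel() / rates.sum()
        counts = rng.multinomial(config.n_events, flat).reshape(rates.shape)
    else:
        counts = rng.poisson(rates)
    c_idx, y_idx = np.nonzero(counts)
    rows = {
        "county": np.repeat(np.asarray(counties)[c_idx], counts[c_idx, y_idx]),
        "year": np.repeat(years[y_idx], counts[c_idx, y_idx]),
    }
    return pd.DataFrame(rows)


def simulate_records(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a record table and its ground truth.

    Returns ``(records, truth)`` where records has one row per collected
    individual with columns ``species, year, month, day, locality, county,
    collector``.
    """
    rng = _rng(config, 2)
    climate = simulate_climate(config)
    covars = bioclim.county_year_covariates(climate)

    events = _place_events(config, rng)
    n_ev = len(events)
    if n_ev == 0:
        raise RuntimeError("effort regime produced no events; increase the rates")
    events = events.reset_index(drop=True)
    events["event_id"] = np.arange(n_ev)
    events["L"] = 1 + rng.poisson(config.list_size_mean_extra, size=n_ev)
    events["records"] = events["L"] + rng.poisson(config.records_mean_extra, size=n_ev)
    events = events.merge(covars, on=["county", "year"], how="left", validate="m:1")
    if events[["bio6", "bio10", "bio18"]].isna().any().any():
        raise RuntimeError("internal: event without climate covariates")

    # standardize the continuous covariates over the realized events (n-1 SD)
    from .glmm import standardize

    raw = pd.DataFrame(
        {
            "year": events["year"].astype(float),
            "logL": np.log(events["L"].astype(float)),
            "records": events["records"].astype(float),
            "bio6": events["bio6"],
            "bio10": events["bio10"],
            "bio18": events["bio18"],
        }
    )
    std, constants = standardize(raw)

    county_effects = pd.Series(
        rng.normal(0.0, config.county_sd, size=config.n_counties) if config.county_sd > 0
        else np.zeros(config.n_counties),
        index=config.counties,
        name="county_effect",
    )
    b_event = county_effects.loc[events["county"]].to_numpy()

    X = np.column_stack([np.ones(n_ev), std.to_numpy()])  # COEF_TERMS order
    # infinite intercepts (always/never-detected species) are legal limit cases
    with np.errstate(invalid="ignore"):
        eta = X @ config.true_coefficients.T + b_event[:, None]  # (n_ev, n_species)
        probs = special.expit(eta)
    if np.isnan(probs).any():
        raise ValueError("non-finite detection probability (check true_coefficients)")
    y = (rng.random(probs.shape) < probs).astype(int)

    design = pd.concat(
        [events[["event_id", "county", "year"]].rename(columns={"year": "calendar_year"}), std],
        axis=1,
    )
    truth = GroundTruth(
        county_effects=county_effects,
        coefficients=pd.DataFrame(
            config.true_coefficients, index=config.species_names, columns=list(COEF_TERMS)
        ),
        probabilities=pd.DataFrame(probs, columns=config.species_names),
        detections=pd.DataFrame(y, columns=config.species_names),
        design=design,
        constants=constants,
    )

    records = _materialize_records(config, rng, events, y)
    return records, truth


def _materialize_records(
    config: SimulationConfig, rng: np.random.Generator, events: pd.DataFrame, y: np.ndarray
) -> pd.DataFrame:
    """One row per collected individual for every detected (event, species);
    each event gets a unique (locality, date, collector) label."""
    n_ev = len(events)
    sites = rng.integers(1, config.n_sites_per_county + 1, size=n_ev)
    collectors = rng.integers(1, config.n_collectors + 1, size=n_ev)
    months = rng.integers(5, 10, size=n_ev)  # flight season May-September
    days = rng.integers(1, 29, size=n_ev)

    seen: set[tuple] = set()
    for i in range(n_ev):
        key = (events.at[i, "county"], sites[i], events.at[i, "year"], months[i], days[i], collectors[i])
        tries = 0
        while key in seen:
            days[i] = int(rng.integers(1, 29))
            collectors[i] = int(rng.integers(1, config.n_collectors + 1))
            key = (events.at[i, "county"], sites[i], events.at[i, "year"], months[i], days[i], collectors[i])
            tries += 1
            if tries > 200:
                raise RuntimeError("could not generate unique event keys; add collectors/sites")
        seen.add(key)

    rows = []
    ev_idx, sp_idx = np.nonzero(y)
    n_ind = 1 + rng.poisson(config.individuals_mean_extra, size=len(ev_idx))
    for (i, s, k) in zip(ev_idx, sp_idx, n_ind):
        rows.append(
            {
                "species": config.species_names[s],
                "year": int(events.at[i, "year"]),
                "month": int(months[i]),
                "day": int(days[i]),
                "locality": f"{events.at[i, 'county']}-site{sites[i]}",
                "county": events.at[i, "county"],
                "collector": f"collector{collectors[i]:03d}",
                "_n": int(k),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) == 0:
        return pd.DataFrame(
            columns=["species", "year", "month", "day", "locality", "county", "collector"]
        )
    table = table.loc[table.index.repeat(table["_n"])].drop(columns="_n").reset_index(drop=True)
    return table
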