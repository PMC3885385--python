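"""Synthetic elevational-gradient community and station-temperature generators.

The generators emulate the design of a national biodiversity monitoring
scheme: ~214 regularly spaced 1-km² sample squares spanning roughly
263–2840 m a.s.l., each surveyed twice five years apart on a rotating
five-year panel, with species richness declining with altitude and the
community temperature index (CTI) declining approximately linearly with
altitude.  Species occupancy follows a Gaussian response curve along the
altitude gradient; a between-survey community shift is imposed by raising
every species' effective niche optimum, so that the survey-2 community at
altitude *a* resembles the survey-1 community at altitude *a − s(a)*.

Station temperature series emulate a small network of homogenized
meteorological stations (14 stations, 273–2501 m, 1995–2010) with a linear
lapse rate, a linear warming trend, and crossed station/year random effects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesPool",
    "ShiftScenario",
    "SurveyDataset",
    "StationSeries",
    "generate_species_pool",
    "generate_surveys",
    "generate_station_series",
]

# Study-design constants used as generator defaults: the squares span the
# monitored altitude band, surveys sit on a rotating 5-year panel starting
# in 2003, and butterfly-like communities hold ~29 species at mid altitude.
DEFAULT_N_SQUARES = 214
DEFAULT_ALTITUDE_RANGE = (263.0, 2840.0)
DEFAULT_FIRST_SURVEY_YEAR = 2003
SURVEY_INTERVAL_YEARS = 5
REFERENCE_ALTITUDE = 500.0


@dataclass(frozen=True)
class SpeciesPool:
    """A pool of virtual species with temperature niches along altitude.

    ``sti`` is the species temperature index (the position of the species'
    temperature niche, in °C for fauna or on an Ellenberg-like 1–5 scale for
    plants).  ``niche_optimum_alt`` is the altitude of peak occupancy and is
    by construction strictly decreasing in STI, which makes the community
    temperature index decline with altitude.
    """

    species_id: np.ndarray          # dtype=object labels
    sti: np.ndarray                 # float, niche position
    niche_optimum_alt: np.ndarray   # m
    niche_width: np.ndarray         # m, Gaussian SD of the response curve
    max_occupancy: np.ndarray       # probability at the optimum

    def __post_init__(self) -> None:
        n = len(self.species_id)
        for name in ("sti", "niche_optimum_alt", "niche_width", "max_occupancy"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length mismatch")
        if n and (np.any(self.niche_width <= 0)):
            raise ValueError("niche_width must be > 0")
        if n and (np.any(self.max_occupancy < 0) or np.any(self.max_occupancy > 1)):
            raise ValueError("max_occupancy must lie in [0, 1]")
        if n > 1:
            order = np.argsort(self.niche_optimum_alt)
            if not np.all(np.diff(self.sti[order]) < 0):
                raise ValueError("sti must be strictly decreasing in niche optimum altitude")

    def __len__(self) -> int:
        return len(self.species_id)

    def sti_table(self, group: str = "synthetic") -> pd.DataFrame:
        """Return the pool's STI lookup as a (species_id, group, sti) table."""
        return pd.DataFrame(
            {"species_id": self.species_id, "group": group, "sti": self.sti}
        )


@dataclass(frozen=True)
class ShiftScenario:
    """Parameters of a simulated two-survey campaign with an imposed shift.

    The imposed uphill displacement of species optima between the two surveys
    is ``shift_at_reference + shift_gradient * (altitude − 500)`` metres, so
    a negative gradient makes the community shift fade (or reverse) towards
    high altitude.  ``detection_noise`` is a per-occurrence false-negative
    probability applied to both surveys.  ``richness_at_reference`` sets the
    expected species richness at 500 m; richness then decays as
    ``exp(−richness_decay · (altitude − 500))``.
    """

    shift_at_reference: float = 0.0     # m uphill at 500 m
    shift_gradient: float = 0.0         # m per m of altitude
    detection_noise: float = 0.05
    n_squares: int = DEFAULT_N_SQUARES
    altitude_range: tuple[float, float] = DEFAULT_ALTITUDE_RANGE
    richness_decay: float = 3.0e-4      # per m
    richness_at_reference: float | None = 33.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_squares < 2:
            raise ValueError("n_squares must be >= 2")
        lo, hi = self.altitude_range
        if not lo < hi:
            raise ValueError("altitude_range must satisfy min < max")
        if not 0.0 <= self.detection_noise < 1.0:
            raise ValueError("detection_noise must lie in [0, 1)")

    def shift_at(self, altitude_m: np.ndarray | float) -> np.ndarray | float:
        """Imposed uphill displacement (m) of optima at a given altitude."""
        return self.shift_at_reference + self.shift_gradient * (
            np.asarray(altitude_m, dtype=float) - REFERENCE_ALTITUDE
        )

    def replace(self, **kw) -> "ShiftScenario":
        return dataclasses.replace(self, **kw)


@dataclass
class SurveyDataset:
    """Presence/absence occurrences for two surveys plus square metadata.

    ``occurrences`` columns: square_id, survey_index (1 or 2), year,
    species_id.  ``squares`` columns: square_id, altitude_m,
    altitudinal_range_m.
    """

    occurrences: pd.DataFrame
    squares: pd.DataFrame

    OCC_COLUMNS = ("square_id", "survey_index", "year", "species_id")
    SQ_COLUMNS = ("square_id", "altitude_m", "altitudinal_range_m")

    def __post_init__(self) -> None:
        for col in self.OCC_COLUMNS:
            if col not in self.occurrences.columns:
                raise ValueError(f"occurrences missing column {col!r}")
        for col in self.SQ_COLUMNS:
            if col not in self.squares.columns:
                raise ValueError(f"squares missing column {col!r}")

    @property
    def n_squares(self) -> int:
        return len(self.squares)

    def copy(self) -> "SurveyDataset":
        return SurveyDataset(self.occurrences.copy(), self.squares.copy())


@dataclass
class StationSeries:
    """Monthly mean temperatures per meteorological station.

    ``records`` columns: station_id, altitude_m, year, month, mean_temp_c;
    at most one record per (station, year, month).
    """

    records: pd.DataFrame

    COLUMNS = ("station_id", "altitude_m", "year", "month", "mean_temp_c")

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.records.columns:
                raise ValueError(f"station records missing column {col!r}")
        months = self.records["month"]
        if len(months) and (months.min() < 1 or months.max() > 12):
            raise ValueError("month must lie in 1..12")
        if self.records.duplicated(["station_id", "year", "month"]).any():
            raise ValueError("duplicate station-year-month records")


def generate_species_pool(
    n_species: int,
    sti_bounds: tuple[float, float] = (8.0, 13.0),
    seed: int = 0,
    *,
    optimum_span: tuple[float, float] = (-1200.0, 4300.0),
    width_range: tuple[float, float] = (450.0, 300.0),
    max_occupancy_range: tuple[float, float] = (0.2, 0.9),
    sti_step: float | None = None,
) -> SpeciesPool:
    """Draw a species pool with STIs inversely ordered along altitude.

    STIs are uniform on ``sti_bounds`` and mapped linearly (and strictly
    decreasingly) onto niche optima spanning ``optimum_span``, so the
    community temperature index declines with altitude at a slope of about
    ``−(sti_max − sti_min) / (opt_max − opt_min)`` per metre — with the
    defaults ≈ −9×10⁻⁴, matching the magnitude seen in occurrence-based
    monitoring data.  Niche widths taper linearly from ``width_range[0]`` at
    the lowest optimum to ``width_range[1]`` at the highest, which gives
    high-altitude communities a narrower spread of member STIs (a declining
    community temperature variation).

    ``sti_step`` rounds STIs to a discrete grid (e.g. 0.5 for Ellenberg-like
    plant values); ties in the rounded values are broken by an infinitesimal
    jitter so optima remain strictly ordered.
    """
    lo, hi = sti_bounds
    if not lo < hi:
        raise ValueError("sti_bounds must satisfy min < max")
    if n_species < 0:
        raise ValueError("n_species must be >= 0")
    rng = np.random.default_rng(seed)
    sti = np.sort(rng.uniform(lo, hi, size=n_species))[::-1]
    if sti_step is not None:
        sti = np.round(sti / sti_step) * sti_step
        # keep a strictly decreasing sequence for the optimum mapping
        sti = sti - np.arange(n_species) * 1e-9
    opt_lo, opt_hi = optimum_span
    frac = (sti - lo) / (hi - lo)          # 1 at sti=hi → low altitude
    optimum = opt_hi - frac * (opt_hi - opt_lo)
    w_lo, w_hi = width_range
    wfrac = (optimum - opt_lo) / (opt_hi - opt_lo)
    width = w_lo + wfrac * (w_hi - w_lo)
    max_occ = rng.uniform(*max_occupancy_range, size=n_species)
    ids = np.array([f"sp{i:04d}" for i in range(n_species)], dtype=object)
    return SpeciesPool(ids, sti, optimum, width, max_occ)


def _occupancy(pool: SpeciesPool, altitudes: np.ndarray, optima: np.ndarray) -> np.ndarray:
    """Occupancy probability matrix (squares × species) for given optima."""
    z = (altitudes[:, None] - optima[None, :]) / pool.niche_width[None, :]
    return pool.max_occupancy[None, :] * np.exp(-0.5 * z * z)


def generate_surveys(pool: SpeciesPool, scenario: ShiftScenario) -> SurveyDataset:
    """Simulate the two-survey occurrence dataset under a shift scenario.

    Survey-1 occupancy of species *s* at square altitude *a* is the Gaussian
    response ``max_occupancy·exp(−(a − optimum)²/(2·width²))``.  In survey 2
    every species' effective optimum is raised by the scenario's imposed
    shift evaluated at the square's altitude.  Rows of both occupancy
    matrices are rescaled by a common square-specific factor so that expected
    survey-1 richness matches the scenario's richness profile (the rescaling
    preserves relative composition, hence the community temperature index).
    Presence is drawn independently per (square, survey); detection noise
    thins occurrences at rate ``detection_noise``.
    """
    if len(pool) == 0:
        raise ValueError("species pool is empty")
    rng = np.random.default_rng(scenario.seed)
    lo, hi = scenario.altitude_range
    altitudes = np.linspace(lo, hi, scenario.n_squares)
    alt_range = rng.uniform(50.0, 600.0, size=scenario.n_squares)
    year1 = DEFAULT_FIRST_SURVEY_YEAR + (np.arange(scenario.n_squares) % SURVEY_INTERVAL_YEARS)
    year2 = year1 + SURVEY_INTERVAL_YEARS

    p1 = _occupancy(pool, altitudes, pool.niche_optimum_alt)
    shift = np.asarray(scenario.shift_at(altitudes), dtype=float)
    # effective optima raised per square: broadcast shift over species
    z2 = (altitudes[:, None] - (pool.niche_optimum_alt[None, :] + shift[:, None]))
    z2 = z2 / pool.niche_width[None, :]
    p2 = pool.max_occupancy[None, :] * np.exp(-0.5 * z2 * z2)

    if scenario.richness_at_reference is not None:
        target = scenario.richness_at_reference * np.exp(
            -scenario.richness_decay * (altitudes - REFERENCE_ALTITUDE)
        )
        base = p1.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(base > 0, target / base, 0.0)
        p1 = np.clip(p1 * scale[:, None], 0.0, 0.98)
        p2 = np.clip(p2 * scale[:, None], 0.0, 0.98)

    keep = 1.0 - scenario.detection_noise
    present1 = rng.random(p1.shape) < p1 * keep
    present2 = rng.random(p2.shape) < p2 * keep

    frames = []
    for survey_index, present, years in ((1, present1, year1), (2, present2, year2)):
        sq_idx, sp_idx = np.nonzero(present)
        frames.append(
            pd.DataFrame(
                {
                    "square_id": sq_idx,
                    "survey_index": survey_index,
                    "year": years[sq_idx],
                    "species_id": pool.species_id[sp_idx],
                }
            )
        )
    occurrences = pd.concat(frames, ignore_index=True)
    occurrences["square_id"] = "q" + occurrences["square_id"].astype(str).str.zfill(3)
    square_ids = np.array([f"q{i:03d}" for i in range(scenario.n_squares)], dtype=object)
    squares = pd.DataFrame(
        {"square_id": square_ids, "altitude_m": altitudes, "altitudinal_range_m": alt_range}
    )
    return SurveyDataset(occurrences, squares)


def generate_station_series(
    n_stations: int = 14,
    years: range = range(1995, 2011),
    trend_per_year: float = 0.07,
    lapse_rate: float = -0.0055,
    noise_sd: float = 0.8,
    seed: int = 0,
    *,
    altitude_range: tuple[float, float] = (273.0, 2501.0),
    station_sd: float = 0.5,
    year_sd: float = 0.3,
    baseline_mean: float = 9.0,
    seasonal_amplitude: float = 9.0,
) -> StationSeries:
    """Simulate monthly station temperature series with a warming trend.

    Monthly mean = sinusoidal seasonal baseline (peak in July) +
    ``lapse_rate·altitude`` + ``trend_per_year·(year − first year)`` +
    station random intercept + year random intercept + observation noise.
    Defaults emulate a 14-station homogenized network spanning 273–2501 m
    over 1995–2010 warming at 0.07 °C per year.
    """
    if n_stations < 1:
        raise ValueError("n_stations must be >= 1")
    years = list(years)
    if not years:
        raise ValueError("years must be nonempty")
    rng = np.random.default_rng(seed)
    if n_stations == 1:
        altitudes = np.array([np.mean(altitude_range)])
    else:
        altitudes = np.linspace(*altitude_range, n_stations)
    station_eff = rng.normal(0.0, station_sd, size=n_stations)
    year_eff = rng.normal(0.0, year_sd, size=len(years))

    months = np.arange(1, 13)
    seasonal = baseline_mean + seasonal_amplitude * np.cos(2 * np.pi * (months - 7) / 12)

    st = np.repeat(np.arange(n_stations), len(years) * 12)
    yr = np.tile(np.repeat(np.arange(len(years)), 12), n_stations)
    mo = np.tile(months, n_stations * len(years))
    temp = (
        seasonal[mo - 1]
        + lapse_rate * altitudes[st]
        + trend_per_year * yr
        + station_eff[st]
        + year_eff[yr]
        + rng.normal(0.0, noise_sd, size=st.shape)
    )
    records = pd.DataFrame(
        {
            "station_id": np.array([f"st{i:02d}" for i in range(n_stations)], dtype=object)[st],
            "altitude_m": altitudes[st],
            "year": np.array(years)[yr],
            "month": mo,
            "mean_temp_c": temp,
        }
    )
    return StationSeries(records)
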