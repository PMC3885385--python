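"""Standardization of temporal index changes into metres of altitudinal shift.

A temporal change ΔCTI at a square is divided by the group-specific slope
*b* of the first-survey CTI–altitude regression.  The quotient ΔCTI/b is the
displacement in metres one would have to travel along the altitude gradient
to find the same index difference (negative = downhill).  Because *b* is
negative wherever communities get colder with altitude, a warming community
(ΔCTI > 0) gives a negative (downhill) quotient; the shift is reported with
the opposite sign so that positive values mean an uphill community shift.
Example: ΔCTI = 0.05 with b = −0.001 gives a quotient of −50 m — the survey-2
community resembles the survey-1 community 50 m downhill — i.e. an uphill
shift of +50 m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SlopeB",
    "StandardizedShift",
    "NonNegativeSlopeError",
    "fit_altitude_slope",
    "standardize_change",
    "standardized_changes",
    "rate_ratio",
]


class NonNegativeSlopeError(ValueError):
    """Raised when the fitted index–altitude slope b is >= 0.

    Standardization interprets a positive raw change as a downhill quotient
    only because b < 0; with b ≥ 0 the metres interpretation silently flips,
    so the caller must opt out explicitly.
    """


@dataclass(frozen=True)
class SlopeB:
    """Slope of the first-survey index–altitude regression for one group."""

    group: str
    kind: str           # "cti" or "ctv"
    b: float            # index units per metre
    intercept: float    # index units at 0 m
    n: int              # squares used

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("slope must be fitted on at least 3 squares")
        if not np.isfinite(self.b):
            raise ValueError("slope b must be finite")


class StandardizedShift(NamedTuple):
    """Both sign conventions of a standardized change, in metres."""

    quotient_m: float   # raw_delta / b, negative = downhill
    shift_m: float      # −quotient, positive = uphill community shift


def fit_altitude_slope(first_survey_values, altitudes, group: str = "", kind: str = "cti") -> SlopeB:
    """Ordinary least-squares fit of first-survey index values on altitude.

    Pairs with a missing index value are dropped; needs ≥ 3 squares with
    non-degenerate altitudes.
    """
    values = np.asarray(first_survey_values, dtype=float)
    alts = np.asarray(altitudes, dtype=float)
    if values.shape != alts.shape or values.ndim != 1:
        raise ValueError("values and altitudes must be 1-d and aligned")
    ok = np.isfinite(values) & np.isfinite(alts)
    values, alts = values[ok], alts[ok]
    if values.size < 3:
        raise ValueError("need at least 3 squares with defined index values")
    if np.ptp(alts) == 0:
        raise ValueError("altitudes are all equal; slope undefined")
    slope, intercept = np.polyfit(alts, values, 1)
    return SlopeB(group=group, kind=kind, b=float(slope), intercept=float(intercept),
                  n=int(values.size))


def standardize_change(raw_delta: float, b: SlopeB | float) -> StandardizedShift:
    """Convert a raw index change into metres of equivalent altitudinal shift.

    ``quotient_m = raw_delta / b`` is the signed displacement along the
    fitted gradient (negative = downhill); ``shift_m = −quotient_m`` so that
    positive output means an uphill community shift (CTI) or increased
    thermal variability (CTV).
    """
    slope = b.b if isinstance(b, SlopeB) else float(b)
    if slope == 0:
        raise ZeroDivisionError("slope b is zero; standardized shift undefined")
    q = raw_delta / slope
    return StandardizedShift(quotient_m=q, shift_m=-q)


def standardized_changes(
    index_records: pd.DataFrame,
    kind: str = "cti",
    *,
    slope: SlopeB | None = None,
    allow_nonnegative_slope: bool = False,
    richness_basis: str = "mean",
) -> tuple[pd.DataFrame, SlopeB]:
    """Build the per-square standardized change set for one group.

    ``index_records`` is the output of :func:`thermocomm.indices.index_table`.
    The slope *b* is fitted to the first-survey values (unless supplied), the
    raw change is survey 2 − survey 1, and squares lacking the index in
    either survey are dropped.  Richness is carried for the downstream
    variance model as the mean of the two surveys (symmetric in the two
    surveys whose difference is modelled) or, with
    ``richness_basis="survey1"``, the first survey's count.

    Raises :class:`NonNegativeSlopeError` if the fitted b is ≥ 0, unless
    ``allow_nonnegative_slope`` is set — on such data the metres
    interpretation would be inverted.
    """
    if kind not in ("cti", "ctv"):
        raise ValueError("kind must be 'cti' or 'ctv'")
    if richness_basis not in ("mean", "survey1"):
        raise ValueError("richness_basis must be 'mean' or 'survey1'")
    wide = index_records.pivot_table(
        index="square_id", columns="survey_index", values=kind, aggfunc="first"
    )
    rich = index_records.pivot_table(
        index="square_id", columns="survey_index", values="richness", aggfunc="first"
    )
    meta = index_records.drop_duplicates("square_id").set_index("square_id")
    group = str(index_records["group"].iloc[0]) if len(index_records) else ""

    if slope is None:
        first = wide[1].reindex(meta.index)
        slope = fit_altitude_slope(first.to_numpy(), meta["altitude_m"].to_numpy(),
                                   group=group, kind=kind)
    if slope.b >= 0 and not allow_nonnegative_slope:
        raise NonNegativeSlopeError(
            f"fitted {kind.upper()}–altitude slope b = {slope.b:.3g} is not negative; "
            "standardized shifts would invert their interpretation"
        )

    ok = wide[1].notna() & wide[2].notna()
    raw = (wide[2] - wide[1])[ok]
    q = raw / slope.b
    out = pd.DataFrame(
        {
            "square_id": raw.index,
            "raw_delta": raw.to_numpy(),
            "quotient_m": q.to_numpy(),
            "shift_m": -q.to_numpy(),
            "altitude_m": meta.loc[raw.index, "altitude_m"].to_numpy(),
            "altitudinal_range_m": meta.loc[raw.index, "altitudinal_range_m"].to_numpy(),
            "richness": (rich.loc[raw.index, 1].to_numpy()
                         if richness_basis == "survey1"
                         else rich.loc[raw.index, [1, 2]].mean(axis=1).to_numpy()),
        }
    ).reset_index(drop=True)
    return out, slope


def rate_ratio(shift_a: float, shift_b: float) -> float:
    """Ratio of two groups' standardized shift rates (e.g. birds / butterflies).

    Standardization puts all groups on a common metres scale, so the ratio of
    two predicted shifts compares how fast their communities change.
    """
    if shift_b == 0:
        raise ZeroDivisionError("reference shift is zero")
    return shift_a / shift_b
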