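"""Community temperature index (CTI) and community temperature variation (CTV).

The CTI of a local assemblage is the unweighted arithmetic mean of the
species temperature indices (STI) of the species recorded there — occurrence
based, so common and rare species contribute equally.  The CTV is the
standard deviation of the member STIs and measures how thermally
heterogeneous the community is.  Both are computed per (sample square,
survey, taxon group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SurveyDataset

__all__ = [
    "StiTable",
    "MissingStiError",
    "UndefinedIndexError",
    "apply_exclusions",
    "compute_cti",
    "compute_ctv",
    "index_table",
    "cross_taxon_correlation",
]

logger = logging.getLogger(__name__)

#: Wandering butterfly species excluded a priori from Swiss analyses.
DEFAULT_BUTTERFLY_EXCLUSIONS = ("Colias crocea", "Vanessa atalanta", "Vanessa cardui")


class MissingStiError(KeyError):
    """Raised when occurring species lack an STI value (silent dropping would bias CTI)."""

    def __init__(self, species: list[str]):
        self.species = list(species)
        super().__init__(f"no STI value for species: {', '.join(map(str, self.species))}")


class UndefinedIndexError(ValueError):
    """Raised when an index is requested for a community too small to define it."""


@dataclass(frozen=True)
class StiTable:
    """Species → (group, STI) lookup.

    One STI per species per group; values must be finite.
    """

    entries: pd.DataFrame  # columns: species_id, group, sti

    def __post_init__(self) -> None:
        for col in ("species_id", "group", "sti"):
            if col not in self.entries.columns:
                raise ValueError(f"STI table missing column {col!r}")
        if self.entries.duplicated(["species_id", "group"]).any():
            raise ValueError("duplicate (species, group) entries in STI table")
        if not np.all(np.isfinite(self.entries["sti"].to_numpy(dtype=float))):
            raise ValueError("non-finite STI values")

    def groups(self) -> list[str]:
        return sorted(self.entries["group"].unique())

    def for_group(self, group: str) -> pd.Series:
        sub = self.entries[self.entries["group"] == group]
        return pd.Series(sub["sti"].to_numpy(dtype=float), index=sub["species_id"].to_numpy())


def apply_exclusions(dataset: SurveyDataset, exclusion_list: list[str]) -> SurveyDataset:
    """Remove all occurrences of the listed species (e.g. wandering butterflies).

    Species ids in the list that never occur are ignored with a logged
    warning; square metadata is untouched.
    """
    excl = set(exclusion_list)
    if not excl:
        return dataset.copy()
    present = set(dataset.occurrences["species_id"].unique())
    unknown = sorted(excl - present)
    if unknown:
        logger.warning("exclusion list contains %d species not in the data: %s",
                       len(unknown), ", ".join(map(str, unknown)))
    occ = dataset.occurrences[~dataset.occurrences["species_id"].isin(excl)]
    return SurveyDataset(occ.reset_index(drop=True), dataset.squares.copy())


def compute_cti(member_stis) -> float:
    """Unweighted mean STI of the community members."""
    values = np.asarray(member_stis, dtype=float)
    if values.size == 0:
        raise UndefinedIndexError("CTI undefined for an empty community")
    return float(np.mean(values))


def compute_ctv(member_stis) -> float:
    """Sample standard deviation (n−1 divisor) of the member STIs."""
    values = np.asarray(member_stis, dtype=float)
    if values.size < 2:
        raise UndefinedIndexError("CTV undefined for fewer than 2 species")
    return float(np.std(values, ddof=1))


def index_table(dataset: SurveyDataset, sti: StiTable, group: str) -> pd.DataFrame:
    """Per-(square, survey) CTI, CTV and richness for one taxon group.

    Occurrences are deduplicated to presence/absence before computing the
    indices.  Every square appears in both surveys; squares where nothing was
    recorded get richness 0 and missing indices (CTV additionally missing at
    richness 1), so callers can drop them per analysis.  A species occurring
    in the data but absent from the STI table is a hard error listing the
    offenders.
    """
    lookup = sti.for_group(group)
    occ = dataset.occurrences.drop_duplicates(["square_id", "survey_index", "species_id"])
    occurring = pd.unique(occ["species_id"])
    missing = sorted(set(occurring) - set(lookup.index))
    if missing:
        raise MissingStiError(missing)

    occ = occ.assign(sti=occ["species_id"].map(lookup))
    grouped = occ.groupby(["square_id", "survey_index"])["sti"]
    table = grouped.agg(cti="mean", ctv=lambda v: v.std(ddof=1), richness="size")
    full_index = pd.MultiIndex.from_product(
        [dataset.squares["square_id"], (1, 2)], names=["square_id", "survey_index"]
    )
    table = table.reindex(full_index)
    table["richness"] = table["richness"].fillna(0).astype(int)
    table.loc[table["richness"] < 2, "ctv"] = np.nan
    table = table.reset_index()
    table["group"] = group
    meta = dataset.squares[["square_id", "altitude_m", "altitudinal_range_m"]]
    return table.merge(meta, on="square_id", how="left")[
        ["square_id", "survey_index", "group", "cti", "ctv", "richness",
         "altitude_m", "altitudinal_range_m"]
    ]


def cross_taxon_correlation(x, y) -> tuple[float, float, int, float]:
    """Pearson correlation between two groups' per-square index values.

    Returns ``(r, t, df, p)`` with ``t = r·√df/√(1−r²)``, ``df = n − 2`` and
    a two-sided p from the t distribution — the form used to check that
    groups surveyed on the same squares carry a coherent altitude signal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length, paired by square")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired squares")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedIndexError("correlation undefined for zero-variance input")
    r, _ = stats.pearsonr(x, y)
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
        p = 2.0 * stats.t.sf(abs(t), df)
    return float(r), float(t), int(df), float(p)
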