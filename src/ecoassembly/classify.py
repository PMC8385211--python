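"""Seven-category rare/abundant taxon classification.

Each OTU is classified from its minimum and maximum relative abundance
across samples, against two cutoffs: ``rare_cut`` (default 0.01% = 1e-4)
and ``abundant_cut`` (default 1% = 1e-2):

========  =====================================================
AAT       always abundant: >= 1% in every sample
CAT       conditionally abundant: >= 0.01% everywhere, >= 1% somewhere
CRAT      conditionally rare and abundant: spans < 0.01% and >= 1%
MT        moderate: within [0.01%, 1%) everywhere
CRT       conditionally rare: < 1% everywhere, < 0.01% somewhere
ART       always rare: < 0.01% everywhere
========  =====================================================

The coarse roll-up is AT (abundant taxa) = {AAT, CAT, CRAT, MT} and
RT (rare taxa) = {ART, CRT}.  Cut semantics: the abundant and lower-rare
bounds are inclusive (>=), the rare conditions strict (<); an OTU at
exactly 1e-4 everywhere is MT, at exactly 1e-2 everywhere AAT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CommunityTable, RelAbundance, ValidationError

__all__ = [
    "CATEGORIES",
    "ABUNDANT_CATEGORIES",
    "RARE_CATEGORIES",
    "AbundanceClassification",
    "classify_otu",
    "classify_all",
    "subset_by_class",
]

CATEGORIES = ("AAT", "CAT", "CRAT", "MT", "CRT", "ART")
ABUNDANT_CATEGORIES = frozenset({"AAT", "CAT", "CRAT", "MT"})
RARE_CATEGORIES = frozenset({"CRT", "ART"})

DEFAULT_RARE_CUT = 1e-4
DEFAULT_ABUNDANT_CUT = 1e-2


def classify_otu(
    min_ra: float,
    max_ra: float,
    rare_cut: float = DEFAULT_RARE_CUT,
    abundant_cut: float = DEFAULT_ABUNDANT_CUT,
) -> str:
    """Classify one OTU from its min/max relative abundance across samples.

    The decision tree tests the abundant side first, so an OTU spanning
    both cutoffs is CRAT (not CRT), and ART's stricter all-samples
    condition takes precedence over CRT.
    """
    if not (0 <= min_ra <= max_ra <= 1):
        raise ValidationError(f"need 0 <= min_ra <= max_ra <= 1, got ({min_ra}, {max_ra})")
    if max_ra >= abundant_cut:
        if min_ra >= abundant_cut:
            return "AAT"
        if min_ra >= rare_cut:
            return "CAT"
        return "CRAT"
    if min_ra >= rare_cut:
        return "MT"
    if max_ra < rare_cut:
        return "ART"
    return "CRT"


@dataclass
class AbundanceClassification:
    """Per-OTU category and AT/RT roll-up, with the thresholds used."""

    category: pd.Series  # OTU id -> category
    rare_cut: float
    abundant_cut: float

    @property
    def coarse(self) -> pd.Series:
        """AT/RT roll-up of the fine categories."""
        return self.category.map(
            lambda c: "AT" if c in ABUNDANT_CATEGORIES else "RT"
        ).rename("coarse")

    def otus_in(self, classes) -> list[str]:
        classes = set(classes)
        fine = classes & set(CATEGORIES)
        if "AT" in classes:
            fine |= ABUNDANT_CATEGORIES
        if "RT" in classes:
            fine |= RARE_CATEGORIES
        mask = self.category.isin(fine)
        return list(self.category.index[mask])

    def summary(self) -> pd.DataFrame:
        counts = self.category.value_counts().reindex(CATEGORIES, fill_value=0)
        out = counts.rename("n_otus").to_frame()
        out["fraction"] = out["n_otus"] / max(len(self.category), 1)
        out["coarse"] = ["AT" if c in ABUNDANT_CATEGORIES else "RT" for c in out.index]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"category": self.category, "coarse": self.coarse})


def classify_all(
    relabund: RelAbundance,
    rare_cut: float = DEFAULT_RARE_CUT,
    abundant_cut: float = DEFAULT_ABUNDANT_CUT,
) -> AbundanceClassification:
    """Classify every OTU of a relative-abundance table.

    All-zero OTUs come out as ART (min = max = 0 < rare_cut).
    """
    mins = relabund.values.min(axis=1)
    maxs = relabund.values.max(axis=1)
    cats = [
        classify_otu(lo, hi, rare_cut=rare_cut, abundant_cut=abundant_cut)
        for lo, hi in zip(mins, maxs)
    ]
    series = pd.Series(cats, index=pd.Index(relabund.otu_ids, name="otu_id"),
                       name="category")
    return AbundanceClassification(series, rare_cut=rare_cut, abundant_cut=abundant_cut)


def subset_by_class(
    table: CommunityTable,
    classification: AbundanceClassification,
    classes,
) -> CommunityTable:
    """Restrict a count table to OTUs in the given categories.

    ``classes`` may mix fine categories (CRT, AAT, ...) and the coarse
    labels AT/RT.  Counts are left untouched; any renormalisation happens
    downstream.
    """
    keep = [o for o in table.otu_ids if o in set(classification.otus_in(classes))]
    if not keep:
        raise ValidationError(
            f"no OTUs in classes {sorted(classes)}; present categories: "
            f"{sorted(classification.category.unique())}"
        )
    return table.subset_otus(keep)
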