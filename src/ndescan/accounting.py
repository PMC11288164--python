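"""Sample and genome accounting over heterogeneous data collections.

A study of the human microbiome typically pools isolate-genome projects,
MAG catalogs, assembled metagenomes and read-level metagenome samples.
This module checks the arithmetic of such a pooled collection: given a
per-study counts table it returns exact integer subtotals per category,
genome/metagenome grand totals, and body-site totals for the read-level
samples.

Categories:

* ``pure_culture`` -- genomes of cultured isolates
* ``mag``          -- metagenome-assembled genomes (MAG catalogs)
* ``assembled_metagenome`` -- metagenomes distributed pre-assembled
* ``read_sample``  -- metagenome samples distributed as short reads

``pure_culture`` and ``mag`` roll up into the genome total;
``assembled_metagenome`` and ``read_sample`` roll up into the metagenome
total.  Whether a borderline catalog counts as MAGs or metagenomes is a
property of the input table, not of this module.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

CATEGORIES = ("pure_culture", "mag", "assembled_metagenome", "read_sample")
GENOME_CATEGORIES = ("pure_culture", "mag")
METAGENOME_CATEGORIES = ("assembled_metagenome", "read_sample")


@dataclass(frozen=True)
class CollectionTotals:
    """Exact subtotal sums of a collection counts table."""

    by_category: dict[str, int] = field(default_factory=dict)
    by_study: dict[str, int] = field(default_factory=dict)
    by_body_site: dict[str, int] = field(default_factory=dict)

    @property
    def genomes_total(self) -> int:
        return sum(self.by_category.get(c, 0) for c in GENOME_CATEGORIES)

    @property
    def metagenomes_total(self) -> int:
        return sum(self.by_category.get(c, 0) for c in METAGENOME_CATEGORIES)

    @property
    def grand_total(self) -> int:
        return self.genomes_total + self.metagenomes_total

    def as_dict(self) -> dict:
        return {
            "by_category": dict(self.by_category),
            "by_study": dict(self.by_study),
            "by_body_site": dict(self.by_body_site),
            "genomes_total": self.genomes_total,
            "metagenomes_total": self.metagenomes_total,
            "grand_total": self.grand_total,
        }


def verify_collection_totals(counts: pd.DataFrame | str | os.PathLike) -> CollectionTotals:
    """Sum a per-study counts table into category/study/body-site totals.

    ``counts`` is a DataFrame (or path to a TSV) with columns ``study``,
    ``category``, ``count`` and an optional ``body_site`` column that is
    only meaningful for read-level sample rows.  Splitting one study over
    several rows is legal and preserves all totals (sums are additive and
    order-invariant).  Negative counts are a validation error.
    """
    if not isinstance(counts, pd.DataFrame):
        counts = pd.read_csv(counts, sep="\t", dtype={"count": "Int64"})
    required = {"study", "category", "count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table lacks column(s) {sorted(missing)}")
    if counts.empty:
        return CollectionTotals({}, {}, {})
    if counts["count"].isna().any():
        raise ValueError("counts table has missing counts")
    if (counts["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    unknown = set(counts["category"]) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown category label(s) {sorted(unknown)}")

    by_category = counts.groupby("category")["count"].sum().astype(int).to_dict()
    by_study = counts.groupby("study")["count"].sum().astype(int).to_dict()
    by_body_site: dict[str, int] = {}
    if "body_site" in counts.columns:
        sited = counts[counts["body_site"].notna() & (counts["body_site"] != "")]
        by_body_site = sited.groupby("body_site")["count"].sum().astype(int).to_dict()
    return CollectionTotals(by_category, by_study, by_body_site)
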