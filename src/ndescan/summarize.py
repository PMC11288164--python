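"""Distribution and prevalence summaries of an annotation table.

Answers the descriptive questions asked of an NDE annotation run: how many
homologs of each type were found in genomes vs metagenomes, which taxa the
positive genomes belong to, how strongly the taxon sets of two enzyme
types overlap, and what fraction of samples in a group (body site, oral
subsite, smoking stratum, study) encode at least one homolog of a type.

A sample/genome is *positive* for a type when it contains at least one
annotated homolog of that type; abundance is not weighted.  Prevalence is
displayed rounded to one decimal (ratios to two), matching the usual
reporting precision, while full precision is retained internally.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .model import NDE_TYPES, SampleMetadata, TaxonomyAssignment, TAXONOMIC_RANKS

UNCLASSIFIED = "Unclassified"


def _annotated(annotations: pd.DataFrame) -> pd.DataFrame:
    return annotations[annotations["final_status"] == "annotated"]


def count_by_source(annotations: pd.DataFrame) -> pd.DataFrame:
    """Sequence and positive-source counts per NDE type, split genome vs
    metagenome.

    Returns one row per NDE type with columns ``n_seq_genome``,
    ``n_seq_metagenome`` (annotated sequences) and ``n_src_genome``,
    ``n_src_metagenome`` (sources containing >= 1 annotated sequence of the
    type).
    """
    ann = _annotated(annotations)
    rows = []
    for nde_type in NDE_TYPES:
        sub = ann[ann["nde_type"] == nde_type]
        row = {"nde_type": nde_type}
        for kind in ("genome", "metagenome"):
            k = sub[sub["source_kind"] == kind]
            row[f"n_seq_{kind}"] = len(k)
            row[f"n_src_{kind}"] = k["source_id"].nunique()
        rows.append(row)
    return pd.DataFrame(rows).set_index("nde_type")


def _taxon_lookup(taxonomy: Iterable[TaxonomyAssignment], rank: str) -> dict[str, str]:
    if rank not in TAXONOMIC_RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {TAXONOMIC_RANKS}")
    return {t.genome_id: t.ranks.get(rank, UNCLASSIFIED) or UNCLASSIFIED for t in taxonomy}


def taxon_distribution(
    annotations: pd.DataFrame,
    taxonomy: Iterable[TaxonomyAssignment],
    rank: str,
    nde_type: str,
) -> pd.DataFrame:
    """Taxon composition of the NDE-positive genomes of one type at one rank.

    Returns rows {taxon, n_genomes, percent}; percents are fractions of the
    positive genomes and sum to 100.  Genomes without a taxonomy row (or
    without a label at the rank) count under "Unclassified".  Only
    genome-kind sources are classified.
    """
    lookup = _taxon_lookup(taxonomy, rank)
    ann = _annotated(annotations)
    positive = ann[(ann["nde_type"] == nde_type) & (ann["source_kind"] == "genome")]
    genomes = sorted(positive["source_id"].unique())
    counts: dict[str, int] = {}
    for g in genomes:
        taxon = lookup.get(g, UNCLASSIFIED)
        counts[taxon] = counts.get(taxon, 0) + 1
    total = sum(counts.values())
    rows = [
        {"taxon": taxon, "n_genomes": n, "percent": 100.0 * n / total}
        for taxon, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    df = pd.DataFrame(rows, columns=["taxon", "n_genomes", "percent"])
    df.insert(0, "rank", rank)
    df.insert(0, "nde_type", nde_type)
    return df


class TaxonOverlap(NamedTuple):
    n_taxa_a: int
    n_taxa_b: int
    n_shared: int
    n_union: int
    n_taxa_all_types: int


def taxon_overlap(
    annotations: pd.DataFrame,
    taxonomy: Iterable[TaxonomyAssignment],
    rank: str,
    type_a: str,
    type_b: str,
) -> TaxonOverlap:
    """Cardinalities of the taxon sets containing positive genomes of two
    NDE types at one rank, plus the union over all types."""
    lookup = _taxon_lookup(taxonomy, rank)
    ann = _annotated(annotations)
    genome_rows = ann[ann["source_kind"] == "genome"]

    def taxa_of(nde_type: str) -> set[str]:
        genomes = genome_rows[genome_rows["nde_type"] == nde_type]["source_id"].unique()
        return {lookup.get(g, UNCLASSIFIED) for g in genomes}

    set_a, set_b = taxa_of(type_a), taxa_of(type_b)
    all_taxa = set()
    for t in NDE_TYPES:
        all_taxa |= taxa_of(t)
    return TaxonOverlap(
        len(set_a), len(set_b), len(set_a & set_b), len(set_a | set_b), len(all_taxa)
    )


def prevalence(
    annotations: pd.DataFrame,
    metadata: Iterable[SampleMetadata],
    group_by: str | Sequence[str],
    nde_type: str,
) -> pd.DataFrame:
    """Positive proportions per metadata group for one NDE type.

    ``group_by`` is one or more :class:`SampleMetadata` fields (e.g.
    ``"body_site"`` or ``("study", "smoking")``).  Every annotation source
    must have a metadata row; a sample is positive when it contains at
    least one annotated homolog of ``nde_type``.  Returns rows
    {group fields..., n_samples, n_positive, prevalence_pct} with
    ``prevalence_pct`` at full precision (round for display).
    """
    fields = [group_by] if isinstance(group_by, str) else list(group_by)
    meta = list(metadata)
    known = {m.sample_id for m in meta}
    ann = _annotated(annotations)
    unknown = set(ann["source_id"].unique()) - known
    if unknown:
        raise KeyError(
            f"annotation source(s) missing from metadata: {sorted(unknown)[:5]}"
        )
    positive_sources = set(ann[ann["nde_type"] == nde_type]["source_id"].unique())

    meta_df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            **{f: [getattr(m, f) for m in meta] for f in fields},
        }
    )
    meta_df["positive"] = meta_df["sample_id"].isin(positive_sources)
    grouped = (
        meta_df.groupby(fields, sort=True)
        .agg(n_samples=("sample_id", "size"), n_positive=("positive", "sum"))
        .reset_index()
    )
    grouped["n_positive"] = grouped["n_positive"].astype(int)
    grouped["prevalence_pct"] = 100.0 * grouped["n_positive"] / grouped["n_samples"]
    return grouped


def prevalence_ratio(table: pd.DataFrame, group_a, group_b) -> float:
    """Ratio of two groups' prevalences, reported to 2 decimals.

    Groups are matched on the grouping column(s) of a :func:`prevalence`
    table; both prevalences are taken at display precision (1 decimal), the
    precision at which such proportions are reported.
    """
    fields = [c for c in table.columns if c not in ("n_samples", "n_positive", "prevalence_pct")]

    def pick(group) -> float:
        key = (group,) if not isinstance(group, (tuple, list)) else tuple(group)
        mask = pd.Series(True, index=table.index)
        for f, v in zip(fields, key):
            mask &= table[f] == v
        sub = table[mask]
        if len(sub) != 1:
            raise KeyError(f"group {group!r} not found (or ambiguous) in prevalence table")
        return round(float(sub["prevalence_pct"].iloc[0]), 1)

    pa, pb = pick(group_a), pick(group_b)
    if pb == 0:
        raise ZeroDivisionError(f"group {group_b!r} has zero prevalence; ratio undefined")
    return round(pa / pb, 2)
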