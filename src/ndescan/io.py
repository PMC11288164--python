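"""Readers and writers for the plain-text formats the pipeline consumes.

Sequences travel as protein FASTA, one file per genome or assembled
metagenome; everything tabular (metadata, taxonomy, collection counts, hit
tables, reports) is tab-separated with a header row.  The reference-panel
configuration is a small YAML mapping from NDE type to reference/outgroup
FASTA paths.

The FASTA reader is deliberately strict: records must carry a non-empty
header, residues are validated against the 20-letter amino-acid alphabet
plus X, and errors name the offending line so malformed catalogs fail fast
instead of polluting downstream joins.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .model import (
    NDE_TYPES,
    ProteinRecord,
    ReferencePanel,
    SampleMetadata,
    TaxonomyAssignment,
    TAXONOMIC_RANKS,
    BODY_SITES,
    ORAL_SUBSITES,
    SMOKING_LEVELS,
)


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the file and line number."""


def read_fasta(
    path: str | os.PathLike,
    source_id: Optional[str] = None,
    source_kind: str = "genome",
) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    The record id is the first whitespace-delimited token of the header;
    sequences are uppercased; input order is preserved.  Duplicate ids
    within one file are an error, as are illegal residues (reported with
    their line number).
    """
    path = Path(path)
    if source_id is None:
        source_id = path.stem
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"{path}:{header_line}: record {header!r} has no sequence")
        try:
            rec = ProteinRecord(header, seq, source_id=source_id, source_kind=source_kind)
        except ValueError as exc:
            raise FastaParseError(f"{path}:{header_line}: {exc}") from exc
        if rec.id in seen:
            raise FastaParseError(f"{path}:{header_line}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        records.append(rec)
        header, chunks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                token = line[1:].split(None, 1)
                if not token:
                    raise FastaParseError(f"{path}:{line_no}: empty FASTA header")
                header = token[0]
                header_line = line_no
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{line_no}: sequence data before first header"
                    )
                if any(c.isspace() for c in line):
                    raise FastaParseError(f"{path}:{line_no}: whitespace inside sequence")
                chunks.append(line)
        flush(line_no=-1)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | os.PathLike, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequences at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


class PanelConfigError(ValueError):
    """Invalid reference-panel configuration."""


def load_reference_panel(config_path: str | os.PathLike) -> list[ReferencePanel]:
    """Load reference panels from a YAML configuration.

    The configuration maps each NDE type to reference and (optionally)
    outgroup FASTA paths, resolved relative to the config file::

        NicX:
          references: nicx_refs.fasta
          outgroups: nicx_out.fasta   # optional; absent or empty is legal
        NicA2:
          references: nica2_refs.fasta

    Panels are returned in canonical NDE-type order.  A panel with zero
    reference sequences is a configuration error; empty outgroups are legal
    (NicA2 has no characterized outgroup family).
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise PanelConfigError(f"{config_path}: expected a mapping of NDE types")
    unknown = set(raw) - set(NDE_TYPES)
    if unknown:
        raise PanelConfigError(f"{config_path}: unknown NDE type(s) {sorted(unknown)}")

    def load_paths(value) -> list[ProteinRecord]:
        paths = value if isinstance(value, list) else [value]
        recs: list[ProteinRecord] = []
        for p in paths:
            recs.extend(read_fasta(config_path.parent / p, source_id="panel"))
        return recs

    panels = []
    for nde_type in NDE_TYPES:
        if nde_type not in raw:
            continue
        entry = raw[nde_type] or {}
        if "references" not in entry:
            raise PanelConfigError(f"{config_path}: panel {nde_type} lacks references")
        references = load_paths(entry["references"])
        if not references:
            raise PanelConfigError(f"{config_path}: panel {nde_type} has zero references")
        outgroups = load_paths(entry["outgroups"]) if entry.get("outgroups") else []
        try:
            panels.append(ReferencePanel(nde_type, tuple(references), tuple(outgroups)))
        except ValueError as exc:
            raise PanelConfigError(f"{config_path}: panel {nde_type}: {exc}") from exc
    return panels


def read_metadata(path: str | os.PathLike) -> list[SampleMetadata]:
    """Read the sample-metadata TSV.

    Required columns: sample_id, source_kind; optional: body_site,
    oral_subsite, smoking, study.  Unknown or missing categorical values map
    to the explicit ``unknown`` level (``none`` for oral_subsite) rather
    than being dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "source_kind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata lacks column(s) {sorted(missing)}")

    def level(value: str, levels: Sequence[str], default: str) -> str:
        return value if value in levels else default

    out = []
    for row in df.itertuples(index=False):
        out.append(
            SampleMetadata(
                sample_id=row.sample_id,
                source_kind=row.source_kind,
                body_site=level(getattr(row, "body_site", ""), BODY_SITES, "unknown"),
                oral_subsite=level(getattr(row, "oral_subsite", ""), ORAL_SUBSITES, "none"),
                smoking=level(getattr(row, "smoking", ""), SMOKING_LEVELS, "unknown"),
                study=getattr(row, "study", ""),
            )
        )
    return out


def write_metadata(metadata: Iterable[SampleMetadata], path: str | os.PathLike) -> None:
    rows = [
        (m.sample_id, m.source_kind, m.body_site, m.oral_subsite, m.smoking, m.study)
        for m in metadata
    ]
    pd.DataFrame(
        rows,
        columns=["sample_id", "source_kind", "body_site", "oral_subsite", "smoking", "study"],
    ).to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | os.PathLike) -> list[TaxonomyAssignment]:
    """Read the taxonomy TSV: genome_id plus one column per rank (labels may
    be blank and are then treated as absent)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "genome_id" not in df.columns:
        raise ValueError(f"{path}: taxonomy lacks a genome_id column")
    out = []
    # label-based access: "class" is a keyword and itertuples would rename it
    for _, row in df.iterrows():
        ranks = {
            rank: row[rank] for rank in TAXONOMIC_RANKS if rank in df.columns and row[rank]
        }
        out.append(TaxonomyAssignment(row["genome_id"], ranks))
    return out


def write_taxonomy(taxonomy: Iterable[TaxonomyAssignment], path: str | os.PathLike) -> None:
    rows = [
        [t.genome_id] + [t.ranks.get(rank, "") for rank in TAXONOMIC_RANKS] for t in taxonomy
    ]
    pd.DataFrame(rows, columns=["genome_id", *TAXONOMIC_RANKS]).to_csv(
        path, sep="\t", index=False
    )


#: Column order of the tabular hit output (the familiar 15-column format of
#: protein search tools; the e-value column is a placeholder since this
#: aligner reports every positive-scoring optimal alignment).
HIT_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "qcovhsp",
    "qlen",
    "slen",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


def hits_to_frame(hits) -> pd.DataFrame:
    """Convert :class:`AlignmentHit` objects to the 15-column hit table."""
    rows = [
        (
            h.query_id,
            h.subject_id,
            round(h.identity_pct, 1),
            round(h.ref_coverage_pct, 1),
            h.qlen,
            h.slen,
            h.aln_len,
            h.mismatches,
            h.gap_opens,
            h.qstart,
            h.qend,
            h.sstart,
            h.send,
            "NA",
            round(h.bit_score, 1),
        )
        for h in hits
    ]
    return pd.DataFrame(rows, columns=list(HIT_COLUMNS))


def write_hits(hits, path: str | os.PathLike) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)
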