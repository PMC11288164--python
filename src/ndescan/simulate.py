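"""Synthetic sequence families, proteomes and sample metadata with ground truth.

The generator emulates the statistical structure of a multi-collection
microbiome survey at desk scale: for each NDE type it evolves a reference
clade and an outgroup clade from a founder pair at controlled sequence
identity, plants true homologs (reference-clade descendants), outgroup-side
decoys (outgroup-clade descendants that are detectably similar to the
references but closer to the negative controls), length-aberrant decoys and
random-sequence decoys into per-sample protein catalogs, and emits the
metadata/taxonomy tables the rest of the package consumes, plus a truth
table stating which pipeline stage should dispose of every planted
sequence.

Divergence is steered by expected substitution count: evolving a sequence
to target identity t substitutes round((1-t)*L) distinct sites, with the
replacement residue sampled proportional to the exponentiated substitution
matrix row (excluding the original residue), then applies geometric-length
indels at a small per-site rate.  Realized identity therefore tracks the
target to within a few percent for realistic protein lengths.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .align import _substitution_matrix
from .io import write_fasta, write_metadata, write_taxonomy
from .model import (
    AMINO_ACIDS,
    NDE_TYPES,
    ProteinRecord,
    ReferencePanel,
    SampleMetadata,
    ScoringParams,
    TaxonomyAssignment,
)

TRUTH_CLASSES = ("true_homolog", "decoy_outgroup", "decoy_random", "decoy_length")

TRUTH_COLUMNS = (
    "protein_id",
    "source_id",
    "nde_type",
    "truth_class",
    "expected_stage",
    "target_identity",
)


@dataclass(frozen=True)
class SampleStratum:
    """One homogeneous block of samples in the study layout."""

    body_site: str
    n_samples: int
    source_kind: str = "metagenome"
    oral_subsite: str = "none"
    smoking: str = "unknown"
    study: str = "simstudy"
    #: optional per-type planting probability: each sample in the stratum
    #: independently receives one homolog of the type with this probability.
    prevalence: dict[str, float] = field(default_factory=dict)


def default_layout() -> tuple[SampleStratum, ...]:
    """60 samples mixing isolate genomes and metagenomes over gut, oral
    (three subsites) and lung, with smoker/non-smoker strata in the gut."""
    return (
        SampleStratum("gut", 12, "genome", smoking="non_smoker", study="sim_gut_genomes"),
        SampleStratum("gut", 8, "genome", smoking="smoker", study="sim_gut_genomes"),
        SampleStratum("gut", 5, "metagenome", smoking="smoker", study="sim_gut_reads"),
        SampleStratum("gut", 5, "metagenome", smoking="non_smoker", study="sim_gut_reads"),
        SampleStratum("oral", 5, "metagenome", oral_subsite="tooth", study="sim_oral"),
        SampleStratum("oral", 5, "metagenome", oral_subsite="plaque", study="sim_oral"),
        SampleStratum("oral", 5, "metagenome", oral_subsite="saliva", study="sim_oral"),
        SampleStratum("lung", 10, "metagenome", study="sim_lung"),
        SampleStratum("oral", 5, "genome", study="sim_oral_genomes"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic benchmark.

    Identity parameters are fractions in (0, 1].  ``ref_out_identity`` is
    the identity between the reference-clade and outgroup-clade founders;
    it is set high enough (0.55) that outgroup-clade sequences are
    *detectably similar* to the references -- they pass the candidate gates
    and must be removed by the outgroup filters, which is precisely the
    confusion the negative-control design exists for.
    """

    seed: int
    ancestor_length: int = 450
    ref_clade_divergence: float = 0.9
    out_clade_divergence: float = 0.9
    ref_out_identity: float = 0.55
    n_references: int = 2
    n_outgroups: int = 2
    nde_types: tuple[str, ...] = NDE_TYPES
    n_true_homologs: int = 20
    homolog_identity_range: tuple[float, float] = (0.35, 0.9)
    n_decoys_outgroup_side: int = 20
    decoy_outgroup_identity_range: tuple[float, float] = (0.85, 0.95)
    n_decoys_random: int = 50
    n_decoys_length: int = 10
    indel_rate: float = 0.005
    background_per_sample: int = 10
    background_length_range: tuple[int, int] = (250, 550)
    per_sample_layout: tuple[SampleStratum, ...] = field(default_factory=default_layout)
    phylum_proportions: dict[str, float] = field(
        default_factory=lambda: {"Proteobacteria": 0.5, "Firmicutes": 0.3, "Bacteroidota": 0.2}
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "ref_clade_divergence",
            "out_clade_divergence",
            "ref_out_identity",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        for name in (
            "n_references",
            "n_outgroups",
            "n_true_homologs",
            "n_decoys_outgroup_side",
            "n_decoys_random",
            "n_decoys_length",
            "background_per_sample",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_references < 1:
            raise ValueError("need at least one reference per panel")
        unknown = set(self.nde_types) - set(NDE_TYPES)
        if unknown:
            raise ValueError(f"unknown NDE type(s) {sorted(unknown)}")
        if not self.per_sample_layout:
            raise ValueError("per_sample_layout must name at least one stratum")
        for s in self.per_sample_layout:
            if s.n_samples <= 0:
                raise ValueError("every stratum needs n_samples >= 1")


@lru_cache(maxsize=None)
def _substitution_weights(matrix: str, lam: float) -> dict[str, np.ndarray]:
    """Per-residue replacement distributions: exp(lambda * score) over the 20
    standard residues excluding the original."""
    m = _substitution_matrix(matrix)
    weights = {}
    for orig in AMINO_ACIDS:
        w = np.array(
            [np.exp(lam * m[orig, a]) if a != orig else 0.0 for a in AMINO_ACIDS]
        )
        weights[orig] = w / w.sum()
    return weights


def random_protein(
    rng: np.random.Generator, length: int, *, id: str, source_id: str = "", source_kind: str = "genome"
) -> ProteinRecord:
    """An i.i.d. uniform-composition random protein."""
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ProteinRecord(id, seq, source_id=source_id, source_kind=source_kind)


def evolve_protein(
    ancestor: ProteinRecord,
    target_identity: float,
    indel_rate: float = 0.0,
    *,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    new_id: Optional[str] = None,
    scoring: ScoringParams = ScoringParams(),
) -> ProteinRecord:
    """Evolve a descendant at a controlled identity to ``ancestor``.

    round((1 - target) * L) distinct sites are substituted (replacement
    sampled from the exponentiated substitution-matrix row, never the
    original residue), then geometric-length insertions/deletions are
    applied at ``indel_rate`` per site.  With the same seed the output is
    identical.  Targets below 0.1 cannot be realized against the ~5%
    identity background of unrelated proteins and raise an error.
    """
    if not (0.1 <= target_identity <= 1.0):
        raise ValueError("target_identity must be in [0.1, 1.0]")
    if rng is None:
        rng = np.random.default_rng(seed)
    seq = list(ancestor.sequence)
    n_sub = int(round((1.0 - target_identity) * len(seq)))
    weights = _substitution_weights(scoring.matrix, scoring.karlin_lambda)
    aa = list(AMINO_ACIDS)
    sites = rng.choice(len(seq), size=n_sub, replace=False) if n_sub else []
    for site in sites:
        orig = seq[site]
        w = weights.get(orig)
        if w is None:  # X has no substitution row; replace uniformly
            seq[site] = aa[rng.integers(20)]
        else:
            seq[site] = aa[rng.choice(20, p=w)]
    if indel_rate > 0:
        n_indels = rng.binomial(len(seq), indel_rate)
        for _ in range(n_indels):
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5 and len(seq) > length + 1:  # deletion
                pos = int(rng.integers(0, len(seq) - length))
                del seq[pos : pos + length]
            else:  # insertion
                pos = int(rng.integers(0, len(seq) + 1))
                seq[pos:pos] = list(rng.choice(aa, size=length))
    return ProteinRecord(
        new_id or f"{ancestor.id}_desc",
        "".join(seq),
        source_id=ancestor.source_id,
        source_kind=ancestor.source_kind,
    )


@dataclass
class Benchmark:
    """A generated benchmark: everything the pipeline consumes plus truth."""

    config: SimulationConfig
    panels: list[ReferencePanel]
    proteomes: dict[str, list[ProteinRecord]]
    metadata: list[SampleMetadata]
    taxonomy: list[TaxonomyAssignment]
    truth: pd.DataFrame


def _allocate_phyla(genome_ids: list[str], proportions: dict[str, float]) -> dict[str, str]:
    """Largest-remainder allocation so realized phylum proportions are exact."""
    n = len(genome_ids)
    if n == 0 or not proportions:
        return {}
    items = sorted(proportions.items())
    quotas = [(name, p * n) for name, p in items]
    counts = {name: int(q) for name, q in quotas}
    short = n - sum(counts.values())
    by_remainder = sorted(quotas, key=lambda kv: -(kv[1] - int(kv[1])))
    for name, _ in by_remainder[:short]:
        counts[name] += 1
    assignment = {}
    i = 0
    for name, _ in items:
        for _ in range(counts[name]):
            assignment[genome_ids[i]] = name
            i += 1
    return assignment


def build_benchmark(config: SimulationConfig) -> Benchmark:
    """Generate panels, per-sample proteomes, metadata, taxonomy and truth.

    Fully deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)

    # --- samples ---------------------------------------------------------
    metadata: list[SampleMetadata] = []
    counters = {"genome": 0, "metagenome": 0}
    for stratum in config.per_sample_layout:
        for _ in range(stratum.n_samples):
            counters[stratum.source_kind] += 1
            prefix = "G" if stratum.source_kind == "genome" else "M"
            metadata.append(
                SampleMetadata(
                    sample_id=f"{prefix}{counters[stratum.source_kind]:04d}",
                    source_kind=stratum.source_kind,
                    body_site=stratum.body_site,
                    oral_subsite=stratum.oral_subsite,
                    smoking=stratum.smoking,
                    study=stratum.study,
                )
            )
    sample_ids = [m.sample_id for m in metadata]
    kind_of = {m.sample_id: m.source_kind for m in metadata}
    proteomes: dict[str, list[ProteinRecord]] = {s: [] for s in sample_ids}

    # --- reference and outgroup clades ----------------------------------
    panels: list[ReferencePanel] = []
    refs_by_type: dict[str, list[ProteinRecord]] = {}
    outs_by_type: dict[str, list[ProteinRecord]] = {}
    for nde_type in config.nde_types:
        founder = random_protein(rng, config.ancestor_length, id=f"{nde_type}_founder")
        refs = [
            evolve_protein(
                founder, config.ref_clade_divergence, rng=rng, new_id=f"{nde_type}_ref{i + 1}"
            )
            for i in range(config.n_references)
        ]
        n_out = 0 if nde_type == "NicA2" else config.n_outgroups
        outs = []
        if n_out:
            out_founder = evolve_protein(
                founder, config.ref_out_identity, rng=rng, new_id=f"{nde_type}_outfounder"
            )
            outs = [
                evolve_protein(
                    out_founder, config.out_clade_divergence, rng=rng, new_id=f"{nde_type}_out{i + 1}"
                )
                for i in range(n_out)
            ]
        refs_by_type[nde_type] = refs
        outs_by_type[nde_type] = outs
        panels.append(ReferencePanel(nde_type, tuple(refs), tuple(outs)))

    truth_rows: list[tuple] = []

    def place(record: ProteinRecord, sample_id: str) -> ProteinRecord:
        placed = ProteinRecord(
            record.id, record.sequence, source_id=sample_id, source_kind=kind_of[sample_id]
        )
        proteomes[sample_id].append(placed)
        return placed

    def plant_homolog(idx: int, nde_type: str, sample_id: str) -> None:
        parent = refs_by_type[nde_type][rng.integers(len(refs_by_type[nde_type]))]
        t = float(rng.uniform(*config.homolog_identity_range))
        rec = evolve_protein(parent, t, config.indel_rate, rng=rng, new_id=f"hom{idx:04d}")
        place(rec, sample_id)
        truth_rows.append((rec.id, sample_id, nde_type, "true_homolog", "annotated", round(t, 4)))

    # --- fixed-count planting -------------------------------------------
    for i in range(config.n_true_homologs):
        nde_type = config.nde_types[i % len(config.nde_types)]
        plant_homolog(i, nde_type, sample_ids[rng.integers(len(sample_ids))])

    out_types = [t for t in config.nde_types if outs_by_type[t]]
    if config.n_decoys_outgroup_side and not out_types:
        raise ValueError("outgroup-side decoys requested but no type has outgroups")
    for i in range(config.n_decoys_outgroup_side):
        nde_type = out_types[i % len(out_types)]
        parent = outs_by_type[nde_type][rng.integers(len(outs_by_type[nde_type]))]
        t = float(rng.uniform(*config.decoy_outgroup_identity_range))
        rec = evolve_protein(parent, t, config.indel_rate, rng=rng, new_id=f"odec{i:04d}")
        sample = sample_ids[rng.integers(len(sample_ids))]
        place(rec, sample)
        truth_rows.append((rec.id, sample, nde_type, "decoy_outgroup", "outgroup", round(t, 4)))

    for i in range(config.n_decoys_length):
        nde_type = config.nde_types[i % len(config.nde_types)]
        parent = refs_by_type[nde_type][rng.integers(len(refs_by_type[nde_type]))]
        base = evolve_protein(parent, 0.7, config.indel_rate, rng=rng, new_id=f"ldec{i:04d}")
        if i % 2 == 0:  # truncation well under the 50%-length / 40%-coverage gates
            frac = float(rng.uniform(0.30, 0.36))
            keep = max(1, int(frac * len(base)))
            start = int(rng.integers(0, len(base) - keep + 1))
            seq = base.sequence[start : start + keep]
        else:  # extension beyond the 150%-length gate
            frac = float(rng.uniform(1.65, 1.80))
            extra = int((frac - 1.0) * len(base))
            left = "".join(rng.choice(list(AMINO_ACIDS), size=extra // 2))
            right = "".join(rng.choice(list(AMINO_ACIDS), size=extra - extra // 2))
            seq = left + base.sequence + right
        rec = ProteinRecord(base.id, seq)
        sample = sample_ids[rng.integers(len(sample_ids))]
        place(rec, sample)
        truth_rows.append((rec.id, sample, nde_type, "decoy_length", "thresholds", 0.7))

    for i in range(config.n_decoys_random):
        length = int(rng.integers(*config.background_length_range))
        rec = random_protein(rng, length, id=f"rdec{i:04d}")
        sample = sample_ids[rng.integers(len(sample_ids))]
        place(rec, sample)
        truth_rows.append((rec.id, sample, "", "decoy_random", "thresholds", np.nan))

    # --- prevalence-driven planting -------------------------------------
    hom_counter = config.n_true_homologs
    sample_iter = iter(metadata)
    for stratum in config.per_sample_layout:
        stratum_samples = [next(sample_iter).sample_id for _ in range(stratum.n_samples)]
        for nde_type, p in sorted(stratum.prevalence.items()):
            if nde_type not in refs_by_type:
                raise ValueError(f"stratum plants {nde_type!r} but it is not simulated")
            for sid in stratum_samples:
                if rng.random() < p:
                    plant_homolog(hom_counter, nde_type, sid)
                    hom_counter += 1

    # --- background ------------------------------------------------------
    bg = 0
    for sid in sample_ids:
        for _ in range(config.background_per_sample):
            length = int(rng.integers(*config.background_length_range))
            place(random_protein(rng, length, id=f"bg{bg:05d}"), sid)
            bg += 1

    # --- taxonomy for genome samples -------------------------------------
    genome_ids = [m.sample_id for m in metadata if m.source_kind == "genome"]
    phylum_of = _allocate_phyla(genome_ids, config.phylum_proportions)
    taxonomy = []
    for idx, gid in enumerate(genome_ids):
        phylum = phylum_of.get(gid, "Unclassified")
        genus = f"{phylum}_gen{idx % 3 + 1}"
        taxonomy.append(
            TaxonomyAssignment(
                gid,
                {
                    "phylum": phylum,
                    "class": f"{phylum}_c",
                    "order": f"{phylum}_o",
                    "family": f"{phylum}_f{idx % 2 + 1}",
                    "genus": genus,
                    "species": f"{genus}_sp{idx + 1}",
                },
            )
        )

    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return Benchmark(config, panels, proteomes, metadata, taxonomy, truth)


def write_benchmark(benchmark: Benchmark, outdir: str | os.PathLike) -> None:
    """Emit the benchmark as the exact on-disk formats the pipeline reads:
    one FASTA per source, panel FASTAs plus a YAML panel config, metadata
    and taxonomy TSVs, and the truth TSV."""
    outdir = Path(outdir)
    (outdir / "sources").mkdir(parents=True, exist_ok=True)
    (outdir / "panels").mkdir(exist_ok=True)
    for source_id in sorted(benchmark.proteomes):
        write_fasta(benchmark.proteomes[source_id], outdir / "sources" / f"{source_id}.fasta")
    panel_cfg = {}
    for panel in benchmark.panels:
        write_fasta(panel.references, outdir / "panels" / f"{panel.nde_type}_refs.fasta")
        entry = {"references": f"{panel.nde_type}_refs.fasta"}
        if panel.outgroups:
            write_fasta(panel.outgroups, outdir / "panels" / f"{panel.nde_type}_outgroups.fasta")
            entry["outgroups"] = f"{panel.nde_type}_outgroups.fasta"
        panel_cfg[panel.nde_type] = entry
    with open(outdir / "panels" / "panels.yaml", "w") as fh:
        yaml.safe_dump(panel_cfg, fh, sort_keys=True)
    write_metadata(benchmark.metadata, outdir / "metadata.tsv")
    write_taxonomy(benchmark.taxonomy, outdir / "taxonomy.tsv")
    benchmark.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def simulation_config_from_yaml(path: str | os.PathLike, seed: Optional[int] = None) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from YAML; ``seed`` overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "per_sample_layout" in raw:
        raw["per_sample_layout"] = tuple(
            SampleStratum(**entry) for entry in raw["per_sample_layout"]
        )
    for key in ("nde_types", "homolog_identity_range", "decoy_outgroup_identity_range",
                "background_length_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if seed is not None:
        raw["seed"] = seed
    if "seed" not in raw:
        raise ValueError(f"{path}: simulation config must specify a seed")
    return SimulationConfig(**raw)


@dataclass(frozen=True)
class BenchmarkScore:
    """Precision/recall of an annotation run against the planted truth."""

    tp: int
    fp: int
    fn: int
    precision: Optional[float]
    recall: Optional[float]
    fp_by_class: dict[str, int]
    stage_agreement: Optional[float]
    stage_mismatches: tuple[tuple[str, str, str], ...]  # (protein_id, expected, observed)


def score_benchmark(truth: pd.DataFrame, annotations: pd.DataFrame) -> BenchmarkScore:
    """Score an annotation table against the truth table.

    True positives are planted homologs annotated under their planted type;
    any other annotated sequence (decoy or background) is a false positive.
    ``stage_agreement`` is the fraction of decoys disposed of at the stage
    their truth label predicts: length/random decoys must fail the
    threshold gates (never become candidates), outgroup-side decoys must be
    removed by the score-ratio or tree filter.
    """
    ann = annotations[annotations["final_status"] == "annotated"]
    annotated_keys = set(zip(ann["source_id"], ann["protein_id"], ann["nde_type"]))

    homologs = truth[truth["truth_class"] == "true_homolog"]
    hom_keys = set(zip(homologs["source_id"], homologs["protein_id"], homologs["nde_type"]))
    tp = len(hom_keys & annotated_keys)
    fn = len(hom_keys - annotated_keys)
    fp_keys = annotated_keys - hom_keys

    class_of = {
        (sid, pid): cls
        for sid, pid, cls in zip(truth["source_id"], truth["protein_id"], truth["truth_class"])
    }
    fp_by_class: dict[str, int] = {}
    for sid, pid, _ in fp_keys:
        cls = class_of.get((sid, pid), "background")
        fp_by_class[cls] = fp_by_class.get(cls, 0) + 1
    fp = len(fp_keys)

    # stage agreement for decoys
    observed_stage: dict[tuple[str, str], str] = {}
    for row in annotations.itertuples(index=False):
        key = (row.source_id, row.protein_id)
        if row.final_status == "annotated":
            observed_stage[key] = "annotated"
        elif observed_stage.get(key) != "annotated":
            observed_stage[key] = row.stage_failed
    expected_ok = {
        "thresholds": {"thresholds"},
        "outgroup": {"score_ratio", "tree_filter"},
    }
    mismatches = []
    n_decoys = 0
    for row in truth.itertuples(index=False):
        if row.truth_class == "true_homolog":
            continue
        n_decoys += 1
        observed = observed_stage.get((row.source_id, row.protein_id), "thresholds")
        if observed not in expected_ok[row.expected_stage]:
            mismatches.append((row.protein_id, row.expected_stage, observed))
    stage_agreement = (n_decoys - len(mismatches)) / n_decoys if n_decoys else None

    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    return BenchmarkScore(
        tp, fp, fn, precision, recall, fp_by_class, stage_agreement, tuple(mismatches)
    )
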