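"""Domain types for the NDE annotation pipeline.

The pipeline annotates homologs of five nicotine-degrading enzymes (NDEs)
in protein catalogs of microbial genomes and assembled metagenomes:

* NdhB  -- nicotine dehydrogenase large subunit B (variant pyridine/pyrrolidine
  pathway; negative-control outgroup: xanthine dehydrogenase large subunit XdhB)
* NdhL  -- nicotine dehydrogenase large subunit L (pyridine pathway; outgroup
  XdhB)
* NicX  -- nicotine-degrading enzyme of gut *Bacteroides xylanisolvens*
  (outgroup: group II intron reverse transcriptase)
* NicA1 -- nicotine oxidoreductase of *Pseudomonas putida* S16 (outgroup:
  group II intron reverse transcriptase)
* NicA2 -- nicotine oxidoreductase of *P. putida* S16; no characterized
  outgroup family is known, so NicA2 candidates are annotated on the
  threshold gates alone.

Each type is searched with a panel of trusted reference proteins plus the
outgroup proteins that act as negative controls against spurious homology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

NDE_TYPES = ("NdhB", "NdhL", "NicX", "NicA1", "NicA2")

SOURCE_KINDS = ("genome", "metagenome")
BODY_SITES = ("gut", "lung", "oral", "unknown")
ORAL_SUBSITES = ("tooth", "plaque", "saliva", "none")
SMOKING_LEVELS = ("smoker", "non_smoker", "unknown")
TAXONOMIC_RANKS = ("phylum", "class", "order", "family", "genus", "species")

#: 20 standard amino acids; X is the ambiguous residue and scores 0 against
#: every letter during alignment.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")

#: Pipeline stages, in execution order.
STAGES = ("thresholds", "score_ratio", "indel_inspection", "tree_filter")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with the identity of the (meta)genome it came from."""

    id: str
    sequence: str
    source_id: str = ""
    source_kind: str = "genome"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"protein id {self.id!r} is empty or contains whitespace")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains illegal residue(s) {sorted(bad)}"
            )
        if self.source_kind not in SOURCE_KINDS:
            raise ValueError(f"unknown source kind {self.source_kind!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferencePanel:
    """Reference and outgroup proteins for one NDE type.

    Outgroups are experimentally characterized non-NDE proteins detectably
    similar to the NDE; they may be absent (NicA2), in which case the
    outgroup-based filters are bypassed for that type.
    """

    nde_type: str
    references: tuple[ProteinRecord, ...]
    outgroups: tuple[ProteinRecord, ...] = ()

    def __post_init__(self) -> None:
        if self.nde_type not in NDE_TYPES:
            raise ValueError(f"unknown NDE type {self.nde_type!r}")
        object.__setattr__(self, "references", tuple(self.references))
        object.__setattr__(self, "outgroups", tuple(self.outgroups))
        if not self.references:
            raise ValueError(f"panel {self.nde_type}: references must be non-empty")
        ref_ids = {r.id for r in self.references}
        out_ids = {o.id for o in self.outgroups}
        if len(ref_ids) != len(self.references):
            raise ValueError(f"panel {self.nde_type}: duplicate reference ids")
        if len(out_ids) != len(self.outgroups):
            raise ValueError(f"panel {self.nde_type}: duplicate outgroup ids")
        shared = ref_ids & out_ids
        if shared:
            raise ValueError(
                f"panel {self.nde_type}: ids {sorted(shared)} appear as both "
                "reference and outgroup"
            )

    @property
    def has_outgroups(self) -> bool:
        return len(self.outgroups) > 0


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations used for prevalence grouping.

    Genome ids double as sample ids for genome-type sources, so one table
    covers isolate genomes, MAGs and assembled metagenomes alike.
    """

    sample_id: str
    source_kind: str
    body_site: str = "unknown"
    oral_subsite: str = "none"
    smoking: str = "unknown"
    study: str = ""

    def __post_init__(self) -> None:
        if self.source_kind not in SOURCE_KINDS:
            raise ValueError(f"sample {self.sample_id}: bad source kind {self.source_kind!r}")
        if self.body_site not in BODY_SITES:
            raise ValueError(f"sample {self.sample_id}: bad body site {self.body_site!r}")
        if self.oral_subsite not in ORAL_SUBSITES:
            raise ValueError(f"sample {self.sample_id}: bad oral subsite {self.oral_subsite!r}")
        if self.smoking not in SMOKING_LEVELS:
            raise ValueError(f"sample {self.sample_id}: bad smoking status {self.smoking!r}")
        if self.oral_subsite != "none" and self.body_site != "oral":
            raise ValueError(
                f"sample {self.sample_id}: oral subsite {self.oral_subsite!r} "
                f"set for body site {self.body_site!r}"
            )


@dataclass(frozen=True)
class TaxonomyAssignment:
    """GTDB-style rank labels for one genome (labels may be absent)."""

    genome_id: str
    ranks: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.ranks) - set(TAXONOMIC_RANKS)
        if bad:
            raise ValueError(f"genome {self.genome_id}: unknown rank(s) {sorted(bad)}")


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring: substitution matrix, affine gap penalties and the
    Karlin-Altschul parameters used to convert raw scores to bit scores.

    A gap of length ``g`` costs ``gap_open + g * gap_extend``, i.e. opening a
    length-1 gap is charged open + extend (BLAST convention).  Defaults are
    the standard BLOSUM62 11/1 scheme with its gapped Karlin-Altschul
    parameters (lambda = 0.267, K = 0.041).
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")


@dataclass(frozen=True)
class FilterParams:
    """Candidate filter thresholds.

    Gate thresholds mirror the published exclusion rules, which are phrased
    as strict inequalities; boundary values (identity exactly 30%, coverage
    exactly 40%, subject length exactly 50% or 150% of the reference) are
    therefore kept.  ``score_ratio`` is the outgroup negative-control rule:
    a candidate is excluded when its best reference bit score is strictly
    below ``score_ratio`` times its best outgroup bit score.  ``tree_margin``
    operationalizes "distance to references close to or bigger than distance
    to outgroups": keep iff d_ref < tree_margin * d_out.
    """

    min_ref_coverage_pct: float = 40.0
    min_identity_pct: float = 30.0
    min_len_frac: float = 0.5
    max_len_frac: float = 1.5
    score_ratio: float = 1.2
    tree_margin: float = 0.9
    max_indel_run: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.min_len_frac < self.max_len_frac):
            raise ValueError("require 0 < min_len_frac < max_len_frac")
        if self.score_ratio < 1:
            raise ValueError("score_ratio must be >= 1")
        if not (0 < self.tree_margin <= 1):
            raise ValueError("tree_margin must be in (0, 1]")
        if min(self.min_ref_coverage_pct, self.min_identity_pct, self.max_indel_run) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    """Statistics of one local alignment of a reference (query) against a
    candidate protein (subject).

    ``identity_pct`` counts identical residue pairs over all alignment
    columns including gap columns; ``ref_coverage_pct`` is the fraction of
    the reference spanned by the aligned region.  Coordinates are 1-based
    inclusive.
    """

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    identity_pct: float
    ref_coverage_pct: float
    qlen: int
    slen: int
    aln_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int

    def __post_init__(self) -> None:
        if not (1 <= self.qstart <= self.qend <= self.qlen):
            raise ValueError("query coordinates out of range")
        if not (1 <= self.sstart <= self.send <= self.slen):
            raise ValueError("subject coordinates out of range")
        if not (0 <= self.identity_pct <= 100):
            raise ValueError("identity_pct out of range")


@dataclass
class DecisionTrace:
    """Outcome of one pipeline stage for one candidate."""

    stage: str
    passed: bool
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class CandidateNDE:
    """A protein that passed the threshold gates for one NDE type, together
    with its filter trail.

    ``score_ref`` / ``score_out`` hold the highest bit score against the
    reference / outgroup panel (``score_out`` is None for types without
    outgroups, which bypass the outgroup filters).
    """

    protein: ProteinRecord
    nde_type: str
    best_ref_hit: AlignmentHit
    score_ref: float
    score_out: Optional[float] = None
    decisions: list[DecisionTrace] = field(default_factory=list)
    final_status: str = "excluded"

    def __post_init__(self) -> None:
        if self.score_ref <= 0:
            raise ValueError("candidate must have a positive reference score")

    def add_decision(self, stage: str, passed: bool, **metrics) -> None:
        order = [d.stage for d in self.decisions] + [stage]
        if order != list(STAGES[: len(order)]):
            raise ValueError(f"stage {stage!r} out of pipeline order (have {order})")
        self.decisions.append(DecisionTrace(stage, passed, metrics))

    @property
    def stage_failed(self) -> Optional[str]:
        for d in self.decisions:
            if not d.passed:
                return d.stage
        return None


@dataclass(frozen=True)
class DiscriminationResult:
    """Patristic-distance verdict for one candidate on the per-type tree."""

    candidate_id: str
    d_ref: Optional[float]
    d_out: Optional[float]
    kept: bool

    def __post_init__(self) -> None:
        for d in (self.d_ref, self.d_out):
            if d is not None and d < 0:
                raise ValueError("patristic distances must be non-negative")
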