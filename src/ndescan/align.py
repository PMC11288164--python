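"""Exact local protein alignment and the candidate threshold gates.

Full Smith-Waterman with affine gaps stands in for a seed-and-extend search
engine: at the scale of curated reference panels against per-sample protein
catalogs, exactness is affordable and removes heuristic variance from the
filter stages downstream.  Hit statistics mirror the conventional tabular
search output: ``identity_pct`` counts identical residue pairs over all
alignment columns (gap columns included), ``ref_coverage_pct`` is the
fraction of the reference (query) spanned by the aligned region.

The dynamic programming itself is delegated to Biopython's C
:class:`PairwiseAligner`, configured so a gap of length ``g`` costs
``gap_open + g * gap_extend``.  The ambiguous residue X scores 0 against
every letter.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .model import (
    AlignmentHit,
    CandidateNDE,
    FilterParams,
    ProteinRecord,
    ReferencePanel,
    ScoringParams,
)

DEFAULT_SCORING = ScoringParams()
DEFAULT_FILTERS = FilterParams()


@lru_cache(maxsize=None)
def _substitution_matrix(name: str):
    m = substitution_matrices.load(name)
    if "X" in m.alphabet:
        for letter in m.alphabet:
            m[letter, "X"] = 0.0
            m["X", letter] = 0.0
    return m


@lru_cache(maxsize=None)
def _aligner(params: ScoringParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _substitution_matrix(params.matrix)
    # Biopython's open_gap_score applies to the first gapped residue, so the
    # open+extend convention puts open_gap_score at -(gap_open + gap_extend).
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = mode
    if mode == "global":
        aligner.end_gap_score = 0  # free end gaps: overhangs are not penalized
    return aligner


def local_aligner(params: ScoringParams = DEFAULT_SCORING) -> Align.PairwiseAligner:
    """The shared Smith-Waterman aligner for ``params`` (cached)."""
    return _aligner(params, "local")


def global_aligner(params: ScoringParams = DEFAULT_SCORING) -> Align.PairwiseAligner:
    """End-gap-free global (overlap) aligner for ``params`` (cached)."""
    return _aligner(params, "global")


def bit_score(raw_score: float, params: ScoringParams = DEFAULT_SCORING) -> float:
    """Karlin-Altschul normalized score in bits.

    bits = (lambda * S - ln K) / ln 2; strictly increasing in the raw score,
    so score-ratio comparisons see the same ordering search tools report in
    their bitscore column.
    """
    if raw_score < 0:
        raise ValueError("raw score must be non-negative")
    return (params.karlin_lambda * raw_score - math.log(params.karlin_k)) / math.log(2)


def align_local(
    query: ProteinRecord,
    subject: ProteinRecord,
    params: ScoringParams = DEFAULT_SCORING,
) -> Optional[AlignmentHit]:
    """Optimal Smith-Waterman local alignment of ``query`` (the reference)
    against ``subject``; returns None when no positive-scoring local
    alignment exists.  One optimal alignment is reported (deterministic
    first traceback)."""
    aligner = local_aligner(params)
    alignments = aligner.align(query.sequence, subject.sequence)
    if alignments.score <= 0:
        return None
    aln = alignments[0]
    counts = aln.counts()
    q_blocks, s_blocks = aln.aligned
    qstart, qend = int(q_blocks[0][0]) + 1, int(q_blocks[-1][1])
    sstart, send = int(s_blocks[0][0]) + 1, int(s_blocks[-1][1])
    identities = counts.identities
    aln_len = int(aln.length)
    gap_opens = counts.open_internal_insertions + counts.open_internal_deletions
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        raw_score=int(round(alignments.score)),
        bit_score=bit_score(alignments.score, params),
        identity_pct=100.0 * identities / aln_len,
        ref_coverage_pct=100.0 * (qend - qstart + 1) / len(query),
        qlen=len(query),
        slen=len(subject),
        aln_len=aln_len,
        mismatches=counts.mismatches,
        gap_opens=gap_opens,
        qstart=qstart,
        qend=qend,
        sstart=sstart,
        send=send,
    )


def hit_passes_thresholds(
    hit: AlignmentHit, params: FilterParams = DEFAULT_FILTERS
) -> tuple[bool, list[str]]:
    """Apply the candidate gates; returns (passed, failed-rule names).

    A hit passes iff reference coverage >= ``min_ref_coverage_pct``,
    identity >= ``min_identity_pct`` and the full subject length lies in
    ``[min_len_frac, max_len_frac]`` times the full reference length.
    Boundary values pass: the published exclusions are strict inequalities.
    """
    failed = []
    if hit.ref_coverage_pct < params.min_ref_coverage_pct:
        failed.append("coverage")
    if hit.identity_pct < params.min_identity_pct:
        failed.append("identity")
    if not (params.min_len_frac * hit.qlen <= hit.slen <= params.max_len_frac * hit.qlen):
        failed.append("length")
    return (not failed, failed)


def find_candidates(
    panel: ReferencePanel,
    proteome: list[ProteinRecord],
    scoring: ScoringParams = DEFAULT_SCORING,
    filters: FilterParams = DEFAULT_FILTERS,
) -> list[CandidateNDE]:
    """Search the panel references against a proteome and gate the hits.

    Every protein with at least one reference hit passing
    :func:`hit_passes_thresholds` becomes one candidate (deduplicated per
    protein per NDE type).  ``best_ref_hit`` is the passing hit with the
    highest bit score, ties broken by higher identity then lexicographic
    reference id; ``score_ref`` is the highest bit score over *all*
    positive reference alignments.  Output order is independent of proteome
    input order (sorted by source then protein id).
    """
    candidates = []
    for protein in sorted(proteome, key=lambda p: (p.source_id, p.id)):
        hits = []
        for ref in panel.references:
            hit = align_local(ref, protein, scoring)
            if hit is not None:
                hits.append(hit)
        passing = [h for h in hits if hit_passes_thresholds(h, filters)[0]]
        if not passing:
            continue
        best = min(passing, key=lambda h: (-h.bit_score, -h.identity_pct, h.query_id))
        cand = CandidateNDE(
            protein=protein,
            nde_type=panel.nde_type,
            best_ref_hit=best,
            score_ref=max(h.bit_score for h in hits),
        )
        cand.add_decision(
            "thresholds",
            True,
            identity_pct=best.identity_pct,
            ref_coverage_pct=best.ref_coverage_pct,
            len_frac=best.slen / best.qlen,
            n_passing_refs=len(passing),
        )
        candidates.append(cand)
    return candidates
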