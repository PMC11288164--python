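"""Outgroup-based false-positive filters and the full annotation cascade.

A candidate homolog that passed the threshold gates may still be a member
of a related-but-distinct protein family (e.g. xanthine dehydrogenase
large subunit vs the nicotine dehydrogenase subunits, or group II intron
reverse transcriptase vs NicX).  Two filters use the outgroup panel as a
negative control:

1. **Score-ratio rule** -- a candidate is excluded when its best reference
   bit score is strictly below ``score_ratio`` (default 1.2) times its best
   outgroup bit score.  Equality keeps the candidate; the rule is phrased
   as a strict exclusion.
2. **Tree filter** -- a per-type tree over surviving candidates plus all
   references and outgroups (neighbor joining on Kimura-corrected global
   alignment distances); a candidate is kept only when its patristic
   distance to the closest reference is clearly smaller than to the closest
   outgroup: keep iff ``d_ref < tree_margin * d_out`` (default margin 0.9,
   so equality or "close to" is excluded).

Between the two sits an automated **indel inspection**: candidates whose
end-gap-free alignment to their best reference contains a contiguous
insertion or deletion longer than ``max_indel_run`` residues (default 50)
are removed, replacing manual curation of alignment columns.

Types without outgroups (NicA2) bypass both outgroup stages and are
annotated on the gates alone.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import skbio
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj as _skbio_nj

from .align import (
    DEFAULT_FILTERS,
    DEFAULT_SCORING,
    align_local,
    find_candidates,
    global_aligner,
)
from .model import (
    CandidateNDE,
    DiscriminationResult,
    FilterParams,
    ProteinRecord,
    ReferencePanel,
    ScoringParams,
)

logger = logging.getLogger(__name__)

#: Saturation ceiling for the Kimura distance; applied when the fraction of
#: differing aligned residues reaches 0.85, where the correction diverges.
KIMURA_CEILING = 5.0
KIMURA_MAX_P = 0.85


def compute_ref_out_scores(
    candidate: ProteinRecord,
    panel: ReferencePanel,
    scoring: ScoringParams = DEFAULT_SCORING,
) -> tuple[float, Optional[float]]:
    """Best bit score of a candidate against the reference panel and the
    outgroup panel (None when the panel has no outgroups or no outgroup
    alignment has a positive score)."""
    ref_bits = [
        hit.bit_score
        for ref in panel.references
        if (hit := align_local(ref, candidate, scoring)) is not None
    ]
    if not ref_bits:
        raise ValueError(
            f"protein {candidate.id!r} has no positive-scoring reference alignment; "
            "it cannot be a candidate"
        )
    out_bits = [
        hit.bit_score
        for out in panel.outgroups
        if (hit := align_local(out, candidate, scoring)) is not None
    ]
    return max(ref_bits), (max(out_bits) if out_bits else None)


def score_ratio_decision(
    score_ref: float, score_out: Optional[float], ratio: float = 1.2
) -> bool:
    """Keep/exclude under the outgroup score-ratio rule; True means keep.

    Exclude iff an outgroup score exists and ``score_ref < ratio * score_out``
    (strict, so exact equality with the ratio boundary keeps the candidate;
    an isclose guard absorbs floating-point noise at the boundary).
    """
    if score_ref <= 0:
        raise ValueError("score_ref must be positive")
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if score_out is None:
        return True
    threshold = ratio * score_out
    if math.isclose(score_ref, threshold, rel_tol=1e-9, abs_tol=1e-9):
        return True
    return score_ref >= threshold


@dataclass(frozen=True)
class IndelResult:
    keep: bool
    longest_insertion: int
    longest_deletion: int


def indel_inspection(
    candidate: ProteinRecord,
    reference: ProteinRecord,
    scoring: ScoringParams = DEFAULT_SCORING,
    max_indel_run: int = 50,
) -> IndelResult:
    """Measure the longest contiguous indel in an end-gap-free global
    alignment of candidate to reference.

    Only gaps inside the aligned core count; terminal overhangs are length
    differences, not indels.  The candidate is excluded when either the
    longest insertion (gap run in the reference row) or the longest deletion
    (gap run in the candidate row) exceeds ``max_indel_run`` residues.
    """
    aln = global_aligner(scoring).align(reference.sequence, candidate.sequence)[0]
    ref_blocks, cand_blocks = aln.aligned
    longest_ins = 0
    longest_del = 0
    for i in range(len(ref_blocks) - 1):
        ref_jump = int(ref_blocks[i + 1][0] - ref_blocks[i][1])
        cand_jump = int(cand_blocks[i + 1][0] - cand_blocks[i][1])
        longest_del = max(longest_del, ref_jump)   # unmatched reference residues
        longest_ins = max(longest_ins, cand_jump)  # unmatched candidate residues
    keep = longest_ins <= max_indel_run and longest_del <= max_indel_run
    return IndelResult(keep, longest_ins, longest_del)


def kimura_distance(
    a: ProteinRecord,
    b: ProteinRecord,
    scoring: ScoringParams = DEFAULT_SCORING,
) -> float:
    """Kimura-corrected protein distance from an end-gap-free global alignment.

    p is the fraction of differing residues over aligned residue pairs (gap
    columns excluded); d = -ln(1 - p - 0.2 p^2).  Saturated comparisons
    (p >= 0.85, where the correction diverges) map to a fixed ceiling of 5.0.
    """
    counts = global_aligner(scoring).align(a.sequence, b.sequence)[0].counts()
    aligned_pairs = counts.identities + counts.mismatches
    if aligned_pairs == 0:
        return KIMURA_CEILING
    p = 1.0 - counts.identities / aligned_pairs
    if p >= KIMURA_MAX_P:
        return KIMURA_CEILING
    return max(0.0, -math.log(1.0 - p - 0.2 * p * p))


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (Saitou-Nei) from a distance matrix.

    Negative estimated branch lengths are clamped to zero so patristic
    distances stay non-negative.  On additive matrices the generating
    topology and branch lengths are recovered exactly.
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(np.asarray(dm[1], dtype=float), list(dm[0]))
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    return _skbio_nj(dm, neg_as_zero=True)


def patristic_distance(tree: TreeNode, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths along the unique path between two leaves."""
    try:
        node_a = tree.find(leaf_a)
        node_b = tree.find(leaf_b)
    except skbio.tree.MissingNodeError as exc:
        raise KeyError(str(exc)) from exc
    if leaf_a == leaf_b:
        return 0.0
    return float(node_a.distance(node_b))


def distance_decision(d_ref: float, d_out: float, margin: float = 0.9) -> bool:
    """Keep/exclude under the tree filter; True means keep.

    Keep iff ``d_ref < margin * d_out``: a candidate whose distance to the
    nearest reference is close to (within the margin) or bigger than its
    distance to the nearest outgroup is excluded.  Equal distances are
    excluded under any margin <= 1.
    """
    return d_ref < margin * d_out


def _candidate_label(c: CandidateNDE) -> str:
    return f"cand|{c.protein.source_id}|{c.protein.id}"


def tree_filter(
    candidates: list[CandidateNDE],
    panel: ReferencePanel,
    filters: FilterParams = DEFAULT_FILTERS,
    scoring: ScoringParams = DEFAULT_SCORING,
) -> tuple[list[DiscriminationResult], Optional[TreeNode]]:
    """Patristic-distance discrimination on a per-type NJ tree.

    Builds one tree containing all candidates plus the panel references and
    outgroups (Kimura distances on pairwise global alignments) and keeps a
    candidate iff its minimum patristic distance to a reference leaf is
    below ``tree_margin`` times its minimum distance to an outgroup leaf.
    Types without outgroups bypass the filter (all kept, no tree); with
    fewer than 3 leaves the filter is skipped with a warning.
    """
    if not candidates:
        return [], None
    if not panel.has_outgroups:
        return [
            DiscriminationResult(_candidate_label(c), None, None, True) for c in candidates
        ], None

    labels = [f"ref|{r.id}" for r in panel.references]
    labels += [f"out|{o.id}" for o in panel.outgroups]
    labels += [_candidate_label(c) for c in candidates]
    seqs = (
        list(panel.references) + list(panel.outgroups) + [c.protein for c in candidates]
    )
    if len(labels) < 3:
        warnings.warn(
            f"panel {panel.nde_type}: fewer than 3 tree leaves; tree filter skipped",
            stacklevel=2,
        )
        return [
            DiscriminationResult(_candidate_label(c), None, None, True) for c in candidates
        ], None

    n = len(seqs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kimura_distance(seqs[i], seqs[j], scoring)
    tree = nj_tree(DistanceMatrix(mat, labels))

    ref_labels = labels[: len(panel.references)]
    out_labels = labels[len(panel.references) : len(panel.references) + len(panel.outgroups)]
    results = []
    for c in candidates:
        label = _candidate_label(c)
        d_ref = min(patristic_distance(tree, label, r) for r in ref_labels)
        d_out = min(patristic_distance(tree, label, o) for o in out_labels)
        results.append(
            DiscriminationResult(label, d_ref, d_out, distance_decision(d_ref, d_out, filters.tree_margin))
        )
    return results, tree


ANNOTATION_COLUMNS = (
    "source_id",
    "source_kind",
    "protein_id",
    "nde_type",
    "best_reference",
    "identity_pct",
    "ref_coverage_pct",
    "bit_score",
    "score_ref",
    "score_out",
    "longest_insertion",
    "longest_deletion",
    "d_ref",
    "d_out",
    "stage_failed",
    "final_status",
)


@dataclass
class AnnotationResult:
    """Full output of the annotation cascade."""

    table: pd.DataFrame
    candidates: list[CandidateNDE]
    trees: dict[str, Optional[TreeNode]]
    stage_counts: pd.DataFrame

    def annotated(self) -> pd.DataFrame:
        return self.table[self.table["final_status"] == "annotated"]


def annotate(
    panels: list[ReferencePanel],
    proteomes: dict[str, list[ProteinRecord]],
    scoring: ScoringParams = DEFAULT_SCORING,
    filters: FilterParams = DEFAULT_FILTERS,
) -> AnnotationResult:
    """Run the full cascade for every panel over every proteome.

    Stages per NDE type: threshold gates (candidate search), outgroup
    score-ratio rule, indel inspection against the best reference, and the
    patristic tree filter.  Every candidate carries a stage-by-stage
    decision trace; stages after an exclusion are not applied (the failing
    stage is recorded as ``stage_failed``).  Output is deterministic for
    identical inputs.
    """
    all_proteins = [p for source in sorted(proteomes) for p in proteomes[source]]
    all_candidates: list[CandidateNDE] = []
    trees: dict[str, Optional[TreeNode]] = {}
    counts_rows = []

    for panel in panels:
        candidates = find_candidates(panel, all_proteins, scoring, filters)
        logger.info("%s: %d candidate(s) passed the threshold gates", panel.nde_type, len(candidates))
        counts_rows.append((panel.nde_type, "thresholds", len(all_proteins), len(candidates)))

        survivors = []
        for cand in candidates:
            score_ref, score_out = compute_ref_out_scores(cand.protein, panel, scoring)
            cand.score_ref = score_ref
            cand.score_out = score_out
            keep = score_ratio_decision(score_ref, score_out, filters.score_ratio)
            cand.add_decision("score_ratio", keep, score_ref=score_ref, score_out=score_out)
            if keep:
                survivors.append(cand)
        counts_rows.append((panel.nde_type, "score_ratio", len(candidates), len(survivors)))

        ref_by_id = {r.id: r for r in panel.references}
        entered = survivors
        survivors = []
        for cand in entered:
            res = indel_inspection(
                cand.protein,
                ref_by_id[cand.best_ref_hit.query_id],
                scoring,
                filters.max_indel_run,
            )
            cand.add_decision(
                "indel_inspection",
                res.keep,
                longest_insertion=res.longest_insertion,
                longest_deletion=res.longest_deletion,
            )
            if res.keep:
                survivors.append(cand)
        counts_rows.append((panel.nde_type, "indel_inspection", len(entered), len(survivors)))

        results, tree = tree_filter(survivors, panel, filters, scoring)
        trees[panel.nde_type] = tree
        n_kept = 0
        for cand, res in zip(survivors, results):
            cand.add_decision("tree_filter", res.kept, d_ref=res.d_ref, d_out=res.d_out)
            cand.final_status = "annotated" if res.kept else "excluded"
            n_kept += res.kept
        counts_rows.append((panel.nde_type, "tree_filter", len(survivors), n_kept))

        all_candidates.extend(candidates)

    rows = []
    for cand in all_candidates:
        metrics = {d.stage: d.metrics for d in cand.decisions}
        indel = metrics.get("indel_inspection", {})
        tree_m = metrics.get("tree_filter", {})
        rows.append(
            (
                cand.protein.source_id,
                cand.protein.source_kind,
                cand.protein.id,
                cand.nde_type,
                cand.best_ref_hit.query_id,
                round(cand.best_ref_hit.identity_pct, 3),
                round(cand.best_ref_hit.ref_coverage_pct, 3),
                round(cand.best_ref_hit.bit_score, 3),
                round(cand.score_ref, 3),
                round(cand.score_out, 3) if cand.score_out is not None else np.nan,
                indel.get("longest_insertion", np.nan),
                indel.get("longest_deletion", np.nan),
                round(tree_m["d_ref"], 6) if tree_m.get("d_ref") is not None else np.nan,
                round(tree_m["d_out"], 6) if tree_m.get("d_out") is not None else np.nan,
                cand.stage_failed or "",
                cand.final_status,
            )
        )
    table = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    table = table.sort_values(["nde_type", "source_id", "protein_id"], kind="mergesort").reset_index(drop=True)
    stage_counts = pd.DataFrame(
        counts_rows, columns=["nde_type", "stage", "entered", "kept"]
    )
    stage_counts["excluded"] = stage_counts["entered"] - stage_counts["kept"]
    return AnnotationResult(table, all_candidates, trees, stage_counts)
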