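# Methods

`ndescan` annotates homologs of five nicotine-degrading enzymes (NDEs) —
NdhB, NdhL, NicX, NicA1 and NicA2 — in protein catalogs of microbial
genomes and assembled metagenomes, and summarizes their distribution across
taxa, body sites and smoking strata. This note documents the model, its
parameters, the numerical choices, and what the synthetic benchmark does
and does not demonstrate.

## The annotation model

Homology annotation by similarity search alone confuses an enzyme family
with its detectably similar relatives: the xanthine dehydrogenase large
subunit (XdhB) resembles the nicotine dehydrogenase large subunits
NdhB/NdhL, and group II intron reverse transcriptases resemble NicX and
NicA1 closely enough to be mislabeled in public databases. The pipeline
therefore treats each NDE type as a pair of panels — trusted *reference*
proteins and *outgroup* proteins that act as negative controls — and runs
a four-stage cascade:

1. **Threshold gates.** Each reference is aligned (exact Smith–Waterman,
   BLOSUM62, affine gaps 11/1) against every protein. A hit survives iff
   reference coverage ≥ 40%, identity ≥ 30% and the candidate's full length
   lies within 50–150% of the reference length. All three exclusions are
   strict inequalities, so boundary values survive. Identity counts
   identical residue pairs over all alignment columns (gaps included);
   coverage is the reference-side aligned span.
2. **Score-ratio rule.** For each candidate, ScoreRef is the best bit score
   against the references and ScoreOut the best against the outgroups
   (Karlin–Altschul bits, λ = 0.267, K = 0.041, the gapped BLOSUM62 11/1
   values). A candidate with ScoreRef < 1.2·ScoreOut is excluded; exact
   equality keeps it. Working in bits rather than raw scores matters: the
   raw→bit transform is affine, so the two scales order ratios differently.
3. **Indel inspection.** The candidate is globally aligned (free end gaps)
   to its best reference; a contiguous insertion or deletion longer than 50
   residues inside the aligned core excludes it. Terminal overhangs are
   length differences, not indels, and are ignored. This automates what is
   traditionally a manual alignment-curation step, making it reproducible.
4. **Tree filter.** Per type, one unrooted tree over surviving candidates
   plus all references and outgroups: pairwise Kimura-corrected distances
   from global alignments, then Saitou–Nei neighbor joining. A candidate
   is kept iff its minimum patristic distance to a reference leaf is less
   than 0.9 times its minimum distance to an outgroup leaf — "close to or
   bigger than the outgroup distance" is inherently fuzzy, so the margin is
   an explicit, configurable parameter (`tree_margin`); equality is always
   excluded for any margin ≤ 1.

Types without a characterized outgroup family (NicA2) pass stages 2 and 4
vacuously and are annotated on the gates alone; their decision traces still
record all four stages so every annotated sequence carries a complete
audit trail.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `matrix`, `gap_open`, `gap_extend` | BLOSUM62, 11, 1 | substitution matrix and affine gap penalties; a length-g gap costs open + g·extend |
| `karlin_lambda`, `karlin_k` | 0.267, 0.041 | raw→bit conversion, matched to the scoring scheme |
| `min_identity_pct`, `min_ref_coverage_pct` | 30, 40 | gate thresholds (percent) |
| `min_len_frac`, `max_len_frac` | 0.5, 1.5 | candidate length relative to reference |
| `score_ratio` | 1.2 | outgroup bit-score ratio rule |
| `max_indel_run` | 50 | longest tolerated internal indel (residues) |
| `tree_margin` | 0.9 | patristic-distance margin; keep iff d_ref < margin·d_out |

## Design choices

* **Exact alignment instead of a seed-and-extend engine.** At the scale
  this package targets (panels of a few references against per-sample
  catalogs), full Smith–Waterman is affordable and removes heuristic
  variance from everything downstream. The per-hit statistics reproduce
  the conventional 15-column tabular search output so existing tooling can
  consume the hit tables. An e-value cutoff is deliberately not applied:
  with a positive-score requirement plus 30% identity and 40% coverage
  gates, an e-value threshold of the usual magnitude is never the binding
  constraint at this scale. The e-value column in hit tables is a
  placeholder.
* **One optimal alignment per pair.** Sub-optimal HSPs are out of scope;
  the first optimal traceback is reported deterministically.
* **Neighbor joining instead of approximate maximum likelihood.** The tree
  filter asks a separation question — is the candidate closer to the
  reference clade than to the outgroup clade — for which distance methods
  are consistent, deterministic and dependency-light. NJ is consistent on
  additive matrices (verified to 1e-9 in the tests); negative estimated
  branch lengths are clamped to zero so patristic distances stay
  non-negative. Kimura's correction, −ln(1 − p − 0.2p²), diverges as
  p → 0.856, so p ≥ 0.85 maps to a fixed ceiling of 5.0.
* **Stage order.** Indel inspection runs before tree building, so the tree
  contains only structurally plausible candidates; duplicates are retained
  as distinct leaves.
* **Floating-point boundaries.** The ratio rule compares score_ref against
  ratio·score_out with an `isclose` guard (rel 1e-9) so that exact
  printed-boundary equality (e.g. 60 vs 1.2·50) is kept despite binary
  rounding of the product.
* **Positivity.** A sample or genome is positive for a type when it
  contains at least one annotated homolog; abundance is not weighted.
  Prevalences are displayed at 1 decimal, ratios at 2, and ratios are taken
  between display-precision prevalences (the precision at which such
  numbers are reported); full precision is kept internally. No
  significance testing is layered on the descriptive proportions, and
  smoking-stratum prevalences are reported per study, never pooled: studies
  differ in recruitment and sequencing depth, and the package has no
  harmonization model.
* **Accounting.** Collection accounting is pure integer arithmetic over a
  per-study counts table; whether a borderline catalog counts as MAGs or
  as assembled metagenomes is a property of the input table, not a
  hard-coded rule. The table shipped in `ndescan/data/collection_counts.tsv`
  assigns the Human Oral v1.0 catalog to the MAG category, the assignment
  under which the published genome/metagenome grand totals reconcile.

## The synthetic benchmark

Real NDE surveys need tens of thousands of genomes; the simulator stands
in with families whose ground truth is known by construction.

Per NDE type it draws a random 450-residue founder, evolves an outgroup
founder at 55% identity, and evolves reference and outgroup clade members
at 90% identity to their founders. Evolution to target identity t
substitutes round((1−t)·L) distinct sites — the replacement drawn from the
exponentiated BLOSUM62 row of the original residue, never the residue
itself — then applies geometric-length indels (mean 2) at a 0.005 per-site
rate. Realized identity therefore tracks the target to within a few
percent at realistic lengths (validated in the tests with the package's
own aligner).

The 55% founder identity is the load-bearing choice: outgroup-clade
sequences then sit at roughly 40–45% identity to the references —
*detectably similar*, passing the gates — so that removing them genuinely
exercises the score-ratio and tree filters. With founders much more
distant, outgroup decoys would already fail the 30% identity gate and the
negative-control machinery would never be tested.

The default benchmark plants, across 60 samples (a mix of gut/oral/lung,
genome/metagenome, smoker/non-smoker strata):

* 20 true homologs at 35–90% identity to a reference clade member,
* 20 outgroup-side decoys at 85–95% identity to an outgroup member
  (must be removed by the score-ratio or tree filter),
* 10 length-aberrant decoys (truncated to 30–36% or extended to 165–180%
  of the reference length; must fail the gates),
* 50 random decoys and 10 background proteins per sample (i.i.d. uniform
  residues, 250–550 long; must never become candidates).

The truth table records which stage must dispose of each planted class,
and the benchmark score checks the pipeline's decision traces against it,
alongside precision and recall over the planted homologs.

Prevalence structure is planted per layout stratum: each sample receives a
homolog of a type independently with the stratum's planting probability,
so recovered prevalences are compared against binomial sampling bounds,
not against the rate itself. Taxonomy for genome samples is assigned by
largest-remainder allocation of configured phylum proportions (exact by
construction), with small per-phylum genus pools beneath.

Problem sizes (60–200 samples, ~700–1,600 proteins, 450-residue families)
were chosen so a full benchmark cascade completes in well under a minute
per run while still exercising every stage with non-trivial candidate
counts.

**What passing does not show.** Background and decoy sequences are i.i.d.
uniform-composition strings; real proteomes have biased composition,
low-complexity regions and genuine distant homologs, all of which make the
gate thresholds less cleanly separating than they are here. The simulator
evolves sequences star-wise from founders rather than along realistic tree
shapes, does not model assembly or gene-calling error, and plants at most
one homolog per (sample, planting event). Benchmark precision/recall of
1.0 therefore validates the pipeline's mechanics and threshold semantics,
not its error rate on real data.

## Known limitations

* Single-HSP semantics: a protein matching a reference in two widely
  separated segments is scored by its best single local alignment.
* The Kimura ceiling compresses all saturated distances to 5.0; for leaves
  past saturation the tree filter degenerates toward the score-ratio rule.
* Sub-optimal co-optimal alignments are resolved by the aligner's
  deterministic first traceback; identity/coverage at the gate boundary
  can in principle depend on that tie-break.
* The outgroup logic presumes the outgroup family is the *nearest*
  confusable family; a confusable family absent from the panel is
  invisible to the filters (NicA2 annotations carry exactly this caveat).
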