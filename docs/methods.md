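# Methods

`transdiff` re-implements, as a tested library, the computational chain that
takes an assembled holothurian gut-regeneration transcriptome to a short list
of candidate transdifferentiation-regulating transcription factors (TFs).
Because the original raw reads and live protein databases are not desk-scale
inputs, every stage is exercised against synthetic data with planted ground
truth; this note records the models, the defaults, and the design choices
that were genuinely open.

## CDS extraction (`transdiff.cds`)

Candidate coding regions are the maximal stop-free stretches in all six
reading frames: a stretch starts immediately after the previous stop codon
(or at the frame start) and ends at the next stop codon (or the sequence
end). The deliberate departure from conventional ORF calling is that an ATG
never defines a start — assembled contigs are often 5'-truncated, and
requiring Met would discard genuine partial CDSs. Consequences the tests
pin down: an internal ATG never opens a separate record, and the reported
interval always back-translates to the reported protein.

Choices: the default minimum length is 30 aa (strict `>=` on the codon
count); both strands are scanned because assembled contigs are unoriented;
stop codons are TAA/TAG/TGA under the standard code; codons containing N
translate to X and do not terminate a stretch, but a stretch whose
translation is entirely X is suppressed (it carries no coding evidence —
this is what makes an all-N input return nothing). Records are ordered by
protein length descending; a `single_best` post-filter (longest, then '+'
strand, then lowest frame, then smallest start) reduces to one CDS per
transcript. Homology rescue of sub-threshold stretches is a hook taking a
precomputed ID list, since no live BLAST search is in scope.

## Best hits, contaminants, TF homologs (`transdiff.homology`)

Best-hit annotation keeps, per query, the maximal-bitscore hit among hits
with e-value ≤ 1e-5 (the conventional BLASTP significance ceiling). Ties
break by lower e-value, then lexicographic subject ID — bitscores and
e-values are platform-reproducible, so this makes every downstream set
deterministic.

The contaminant filter removes a query iff its best non-panel (NRP) hit is
(a) non-deuterostome with bitscore strictly above 200 and (b) no hit against
the echinoderm reference panel (A. japonicus, P. parvimensis, C. schmeltzii,
P. miniata, L. variegatus, S. purpuratus) reaches strictly more than 80% of
that bitscore. A missing panel hit counts as bitscore 0, so a confident
foreign match with no echinoderm support is removed. Queries with no NRP
hit are kept: the filter targets confident foreign matches, not unannotated
sequences. The deuterostome test applies to the single best NRP hit.
Raising the panel fraction can only grow the removal set; raising the
bitscore floor can only shrink it (tested).

TF homologs are queries whose best hit is in a reference TF list and whose
predicted protein is strictly longer than 200 aa — short fragments cannot
be confidently typed as TFs.

## Ortholog pairing (`transdiff.orthologs`)

Two one-to-one matchers over a cross-species hit table:

* **Greedy best-pair**: repeatedly commit the globally best remaining hit
  and delete every hit touching either member. Implemented as one sweep
  over the globally sorted hit list (bitscore desc, e-value asc,
  (query, subject) lex), skipping used members — provably equivalent to the
  iterative deletion phrasing, and checked against a literal brute-force
  simulation of that phrasing on random tables.
* **Reciprocal best hit (RBH)**: a pair is emitted only when each member is
  the other's top match; a tie at the top invalidates the member unless
  `break_ties=True` applies the same deterministic policy.

When all best hits are unique, a mutual-best pair outscores every hit
touching either member, so the greedy sweep commits it first: RBH pairs are
a subset of greedy pairs and greedy never returns fewer. The practical gain
appears with protein families: when one strong query is the best match of
several family members, RBH loses all but one pairing while greedy assigns
the remaining members to their next-best partners.

Bitscore is the pairing score. It is the standard single-number proxy for
alignment quality, and the contaminant rule already operates on it; the
score column is a plain DataFrame column, so an alternative metric can be
substituted upstream.

## Expression math (`transdiff.expression`)

**TPM** is computed per sample as `1e6 * (c_g/L_g) / sum_j (c_j/L_j)` with
per-gene effective lengths; condition values are replicate means. An
all-zero sample is rejected rather than silently propagated.

**Pre-filter** (all strict): total mapped reads > 50; coverage
`total_reads * read_length / eff_length` > 10 with the default 100-nt read
length; and no condition whose replicate-summed count is zero. The
zero-read rule defaults to per-condition evaluation with a per-sample
variant and an off switch behind flags, and coverage uses single-read
length because paired-end coverage is not otherwise defined here.

**Normalization** is DESeq-style median-of-ratios over zero-free genes
(cross-checked in the tests against an independent implementation), with a
library-size fallback plus warning when no zero-free gene exists.

**LogFC** is `log2((m_A + 0.5)/(m_B + 0.5))` on normalized condition means;
the 0.5 pseudocount keeps condition-zero genes finite and is recorded in
the output header.

**Significance** is a transparent negative-binomial stand-in for a full
shrinkage DE framework, kept deliberately simple so its behaviour is
auditable: per-gene method-of-moments dispersion pooled across the two
conditions (`alpha = (v̄ − m̄)/m̄²`, floored at 1e-8 so the variance never
drops below Poisson), Wald statistic on the difference of normalized
condition means with `SE² = (μ_A + αμ_A²)/n_A + (μ_B + αμ_B²)/n_B`,
referred to a t distribution with `n_A + n_B − 1` degrees of freedom. The
extra degree of freedom relative to the residual count reflects that the
Poisson part of the variance is supplied by the model, not estimated;
Monte-Carlo calibration under the NB null at this design's replicate
numbers (2+2) shows type-I error ≈ 0.045–0.05 across dispersions 0.02–0.3,
where the residual-df choice is markedly conservative (~0.02) and a normal
reference is badly anticonservative (~0.15). The calibrated reference costs
some power: planted 4-fold changes at mean 200 and dispersion 0.05 are
detected with probability ≈ 0.78 rather than the ≈ 0.9 a normal reference
would claim while over-rejecting nulls. At very low dispersion or very low
counts the test is conservative, never inflated. P-values are raw; a
Benjamini–Hochberg column is emitted for transparency but DEG calls gate on
raw p < 0.05 and |LogFC| ≥ 1, matching the screening intent (the candidate
screen itself does not gate on p at all).

**ΔΔCt**: within each qPCR sample, target Ct is normalized against the
arithmetic mean of the two reference genes' Ct values (Tubulin, EF1a) —
the geometric mean on the linear expression scale, since Ct is already
log2. ΔCt is replicate-averaged per condition, the first regeneration
stage is the control, and relative expression is `2^(−ΔΔCt)`. Agreement
with RNA-seq is summarized as the squared Pearson correlation of the two
log2-fold-change vectors with the least-squares line.

## The candidate screen (`transdiff.select`)

A gene is a candidate iff it is a TF homolog, stage-2 TPM > 1, the mean of
its two stage-2 LogFCs (vs stages 1 and 3) > 0.5, and at least one of those
LogFCs > 1 — all strict, with each failed gate named in a `reasons` column
so near-misses are auditable. Stage-2 TPM is the replicate mean.
Significance is reported but is not a gate: a sharp biological peak with a
noisy p-value still makes the list. Manual curation (e.g. removing
zinc-finger calls that fail by-hand verification, or merging assembly
duplicates) enters as explicit include/exclude lists flagged in a
`curation` column, never as silent edits.

## Enrichment and the overlap network (`transdiff.enrichnet`)

Gene sets are first restricted to those containing at least one candidate
TF. The enrichment score is the classical weighted Kolmogorov–Smirnov
running sum over a ranking by signed LogFC (one ranking per contrast:
stage 2 vs 1 and stage 2 vs 3): hits add `|metric|^p` normalized over
in-set genes (p = 1), misses subtract `1/(N − n_set)`, and the score is the
extremum of largest magnitude, clamped to [−1, 1] against float drift, with
positive preferred on exact magnitude ties. Significance is a gene-label
permutation null (set size preserved) with the add-one estimator
`p = (1 + #{|ES*| ≥ |ES|})/(n_perm + 1)`; gene-label rather than phenotype
permutation because two replicates per condition admit no meaningful
phenotype shuffling. Each (contrast, set) pair draws an independent child
seed so results are iteration-order free. Nodes carry both contrasts'
scores; an edge joins sets whose overlap coefficient `|A∩B|/min(|A|,|B|)`
reaches 0.375, the conventional enrichment-map default.

## Synthetic data (`transdiff.synthetic`)

One global seed feeds named substreams (`truth`, `hits`, `nrp`, `counts`,
`ct`, `transcripts`, `genesets`), so every artefact is byte-reproducible
and independently regenerable. Defaults mirror the emulated design: four
conditions (intact gut, three regeneration stages) × two pooled biological
replicates; 100-nt reads; effective lengths log-uniform on [300, 10000] nt;
background means log-uniform on [20, 500]; NB dispersion 0.05 (pooled-
animal replicates are less dispersed than individual-level ones, but the
pools' variance is not otherwise characterized, so this is a free
parameter, not a measured one); planted stage-2 peak of 1.5 log2 units —
0.5 above the screen's strictest gate, so recovery is non-trivial but
attainable; 40 planted TFs of which 20 peak (the flat 20 are screen
decoys); 20 foreign contaminants.

Hit tables give every true pair a base bitscore uniform on [400, 800],
paralog decoy hits 25 bits below within simulated families of four, and
Gaussian noise (SD 10 by default) on all scores: at zero noise every true
pair is the unique mutual best, and growing noise creates exactly the
family collisions where greedy pairing out-recovers RBH. Counts are NB with
variance μ + αμ² (Poisson when α ≤ 1e-8); an `exact_means` mode writes
rounded expected counts for zero-noise recovery checks. Ct tables encode
the planted fold changes as `baseline − log2(rel)` plus Gaussian noise
(SD 0.1 cycles, under the half-cycle technical-replicate tolerance), with
condition-invariant reference genes.

What the generator does **not** emulate: read-level artefacts (mapping
bias, multi-mapping, 3' coverage bias), correlated gene-gene structure,
condition-dependent library composition, assembly chimerism or
fragmentation, and primer-efficiency deviations from 2.0 in qPCR. Passing
tests therefore demonstrate algorithmic correctness and calibration under
the stated generative model, not robustness to those real-data pathologies.

## Problem sizes and numerical choices

The shipped tests and the results script use: 500 random tables (≤ 6×6)
for the greedy-matcher oracle, 500 random sequences (≤ 300 nt) for the CDS
oracle, exhaustive subsets of rankings up to 8 genes for the enrichment
oracle, 10,000 null genes for type-I calibration, 1,000 random sets ×
199 permutations for permutation-p uniformity (the larger sample keeps the
KS distance's own sampling noise well under the 0.05 bound being asserted),
and a 2,000-gene universe with 20 planted peaks for screen recovery. Tie
handling, strictness of every threshold, and the dispersion floor are all
fixed as described above and asserted in the tests; degenerate inputs
(empty tables, all-zero samples, missing references, disjoint sets) raise
informative errors rather than propagating NaNs.
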