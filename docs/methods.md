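# Methods

## Model and rationale

A miRNA represses mRNAs whose 3′UTRs contain the reverse complement of its
seed (mature positions 2–8).  Without control samples, each gene's expected
expression is approximated by its median logged expression across all
samples/cells in the run; the analysis object is the relative expression
Δe<sub>gs</sub> = e<sub>gs</sub> − median<sub>s′</sub>(e<sub>gs′</sub>).
The median is a surrogate, not a true unrepressed baseline — its virtue is
that genes switched off in most samples do not rank extreme.  A direct
consequence, visible in every planted-signal experiment: when a large
fraction of samples share the miRNA's activity, inactive samples score
*negative* (their targets sit above the pooled median), so scores separate
states rather than measuring absolute activity.

Per sample, genes are ranked by Δe ascending (most repressed first) and each
miRNA's target-motif enrichment toward the repressed end is tested.  Scores
are −log10(p)·sign(statistic), clamped via a p-value floor of 1e−300
(|score| ≤ 300).  Scores are comparative across samples/cells, not
calibrated p-values: the hypergeometric landscape minimum, in particular, is
reported without multiple-testing correction across cutoffs (a Bonferroni
flag exists).

Assumptions worth stating explicitly: repression acts through mRNA
destabilisation (translational repression without decay is invisible — by
design the δ=0 generator setting emulates exactly this blind spot); the
7-mer presence/absence binding model (no G:U wobble, 6mer/8mer classes or
context scores); one UTR per gene, the longest isoform, although the true
isoform may be tissue-specific; the i.i.d.-composition null for motif
occurrence (no higher-order background model in v1).

## Null probabilities p_g

For each motif × UTR pair, p_g = P(≥1 occurrence) in a random i.i.d.
sequence of the same length and base composition.  The motif is embedded in
an 8-state KMP prefix automaton (state = longest motif prefix matching the
current suffix; state 7 absorbing); scanning i.i.d. bases is then a Markov
chain, and p_g is the absorbing mass after `length` steps.  The scalar
routine iterates the distribution vector step by step; the table builder
applies binary exponentiation to the per-gene 8×8 chain matrix — the same
recurrence reassociated — and the two agree to ≤1e−12 (tested).  Both are
exact up to float arithmetic; Monte-Carlo agreement at 100,000 draws is part
of the acceptance checks.

Composition binning (`cache_policy="binned"`, the default) rounds base
frequencies to 3 decimals (renormalised) and shares computation among genes
with identical (length, rounded composition).  Three decimals keeps the
induced error in p_g below 1e−3 (tested against exact mode); two-decimal
binning was measured at ~2.5e−3 and rejected for exceeding that bound.
`cache_policy="exact"` disables sharing.

## The four statistics

* **mrs** (default): T = Σ c_g(I_g − p_g) with c_g = (N+1)/2 − r_g
  (midranks), Var = Σ c_g² p_g(1−p_g), Z = T/√Var, two-sided normal p.
  Centring each indicator by its own p_g is what corrects for UTR length and
  composition: an unweighted rank sum rejects >50% of nulls at α=0.05 when
  motif propensity correlates with rank, while mrs stays nominal (tested).
  The null model is I_g ~ Bernoulli(p_g) independent given the ranking.
* **bb**: walk S_k = Σ_{j≤k}(I_j − p_j) over the stable full ordering,
  bridge B_k = (S_k − (k/N)S_N)/√V, V = Σ p_g(1−p_g); D = max|B_k| tested
  against the Kolmogorov sup-of-bridge series 2Σ(−1)^{j−1}exp(−2j²d²)
  (terms truncated below 1e−16).  The discrete max underestimates the
  continuous supremum, leaving p-values conservative at finite N (mean
  ≈0.52 at N=1000); the Broadie–Glasserman–Kou continuity correction
  D += 0.5826/√N restores calibration (type-I error 0.04–0.06, KS-uniform;
  tested).  Direction is the bridge's sign at its first argmax — the drift
  sign at the maximal deviation; with the two-sided statistic either
  convention is defensible and this one is deterministic.
* **hypergeom**: presence of the motif among the leading n genes, scanned
  over 20 evenly spaced cutoffs in {1..N−1}; both tails recorded per cutoff
  (the landscape), overall p = min over cutoffs and tails.  Presence-based
  per gene; no occurrence counting and no composition correction — the
  p_g-aware statistics cover that, and this method exists as the
  hypergeometric baseline.
* **tarbase**: two-sided Mann–Whitney (asymptotic, tie-corrected) of curated
  target genes vs the rest; the gene universe is the expression genes found
  in the target lists, since no UTR sequence is involved.

All four are two-sided with the direction reported separately (+1 = enriched
among repressed = active).  Ties in Δe — pervasive in sparse single-cell
data — use midranks for rank statistics and stable lexicographic gene-id
ordering for the walk-based ones, so results are deterministic across
platforms and input orderings.

## Preprocessing

Counts: cells with total reads < 1000 removed (boundary kept: a cell with
exactly 1000 reads survives); v → log2(v/total_cell × max_total + 1); Δe by
per-gene median subtraction (even sample counts use the midpoint median;
≥3 samples required unless overridden).  Already-normalised logged matrices
(bulk cohorts) enter as `layer=logexpr` and skip normalisation.  Medians are
computed on the full matrix; only then is the universe restricted to
UTR-bearing genes for ranking — genes lacking a UTR are excluded rather than
scored as motif-absent, because absence of sequence is not evidence of
absence of a site.  All-zero genes have Δe ≡ 0 and are retained by default
(they dilute but do not bias the rank statistics); `--drop-zero-genes`
removes them.

UTRs: one record per gene (longest isoform, ties broken by smallest
transcript id), lengths kept in [20, 10000] inclusive, U→T normalised,
N bases never match any motif and are excluded from composition.

## Synthetic data generator

The generator emulates the one feature the method detects — coordinated
down-shift of motif-bearing genes in the cells where a miRNA is active —
on top of negative-binomial single-cell noise:

| parameter | default | why |
| --- | --- | --- |
| genes / cells / active / targets | 2000 / 200 / 100 / 200 | reference conditions for all planted-signal checks |
| effect size δ | 1.0 log2 units | a twofold target knock-down, typical of effective miRNA repression |
| library size | 100,000 reads/cell | the depth regime where scRNA-seq cell-type signal saturates |
| NB dispersion | 0.3 | scRNA-seq overdispersion; Var = m + 0.3 m² |
| baseline log2-mean | Normal(1.0, 1.5) | spans silent to highly expressed genes over ~3 orders of magnitude |
| UTR lengths | Uniform(100, 2000) nt | the bulk of real 3′UTR lengths |
| GC content | 0.45 | typical of UTR sequence |
| miRNA panel | 50 matures | one planted 5p, its reverse-complement 3p decoy, 48 unrelated |

The planted motif is inserted at a random position of each target UTR
(length-preserving) and scrubbed from non-targets by redrawing, so the
indicator contrast is exact; counts are gamma–Poisson then multinomially
rescaled to the exact library size.  The ground truth (targets, active
cells, δ, seed, every parameter) is serialised next to the data.

What the generator does *not* emulate: batch effects, doublets, ambient
RNA, gene-length bias, isoform switching, correlated gene programs, or
several simultaneously active miRNAs.  Passing the planted-signal checks
therefore shows the statistics recover a clean repression signal under
realistic sparsity and overdispersion — not that real tissues behave this
cleanly.  One structural caveat discovered while validating: planting makes
the planted motif's indicators deterministic rather than
Bernoulli(p_g)-distributed, so at δ=0 its p-values are over-dispersed even
though its direction is an exact fair coin; the chance-occurring decoy motif
is the correct probe of pipeline-level null uniformity, and is tested as
such.

## Downsampling

Sparsity is emulated by a multinomial draw per sample at fixed total depth
with probabilities proportional to expression (raw counts or normalised
values both accepted — the probabilities only need the proportions).  The
default sweep grid is {1e3, 5e3, 1e4, 5e4, 1e5, 5e5, 1e6, 5e6, 1e7} total
reads.  Each (depth, replicate) cell gets an independent child seed stream,
so sweeps are reproducible and order-independent.

## Numerical choices

* p-value floor 1e−300 before the log transform; Kolmogorov series clamped
  into (0,1], terms truncated below 1e−16.
* Motifs present in all or in no genes of a sample's universe score 0 in the
  orchestrated run ("no evidence either way"); the low-level tests raise
  `NoContrastError` instead, so the distinction between "no contrast" and
  "tested, null" is never silent at the API level.
* Null probabilities are clipped to [0, 1) before variance computation.
* Per-sample work is embarrassingly parallel (`n_jobs`); rows are assembled
  in sample order, so results are bitwise identical for any worker count.
* Activity is computed once per unique target motif and broadcast to all
  miRNAs sharing it (seed families), which is exactly equivalent to
  computing per miRNA.

## Problem sizes used in the checks

The validation suite runs at desk scale, chosen to finish in minutes while
keeping every statistic in its asymptotic regime: null calibration at
N=1000 genes × 2000 replicates; Monte-Carlo probability agreement at
100,000 draws over 10 motifs × 3 lengths × 3 compositions; planted-signal
recovery at the reference conditions above for δ ∈ {0.25, 0.5, 1.0}; the
depth sweep at {1e3, 1e4, 1e5} reads × 5 replicates; δ=0 null behaviour
over 200 independent reduced replicates (300 genes, 6 cells).

## Known limitations

* The activity score conflates effect size and statistical power: deeper
  libraries and more targets give larger |scores| for the same biology.
* Median-centring ties every cell's score to the run's composition; scores
  are not comparable across runs (the max-total normalisation constant also
  differs per run).
* The single longest UTR per gene misrepresents genes with tissue-specific
  3′UTR isoforms.
* Translational repression without mRNA decay is invisible.
* The hypergeometric landscape's minimum-p is anti-conservative as a
  p-value; it is used as a comparative score only.
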