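# Methods

`cisgrammar` implements a gene-centric workflow for finding DNA sequence
motifs associated with cell-type-specific expression and for testing their
regulatory grammar in a combinatorial reporter (STARR-seq) library.  This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic-data tests do and do not establish.

## Gene specificity ranking

Inputs are an already-normalized expression matrix (genes × samples) and a
binary sample map (target cell type vs background).  Per gene we compute
aggregate (summed) expression in each group, drop genes whose target
aggregate falls below the pre-filter median (genes exactly at the median are
kept), and rank the survivors: descending in the target aggregate,
ascending in the background aggregate, with average ranks for ties (average
ranks keep the rank sum symmetric between tied genes; the alternative "min"
convention would not).  The *rank sum* of the two is the quantity whose
distribution carries the signal: for abundance-driven genes its two
components are anti-correlated, so it concentrates near n+1 with a long
left tail of target-specific genes.  The *specificity score* is the
ascending rank of the rank sum and is used for ordering.

Gene sets are cut with mean-minus-k·SD thresholds (population SD, ddof=0):
top below μ − k_top·σ (default k_top = 4), comparator above μ − k_comp·σ
(default 3), the gap being a deliberate zone of exclusion, and a bottom set
size-matched to the top at the other extreme.  **The thresholds are applied
to the rank sum, not to the final specificity score**: the final score is
itself a rank and therefore uniformly distributed, so μ − 4σ on it lies
below the attainable minimum and could never select a gene, whereas the
rank-sum distribution has exactly the shape these cuts are designed for.
`partition_gene_sets(..., score_col=...)` exposes the choice.

## Region curation and gene linking

Coordinates are BED-style 0-based half-open throughout; "overlap" always
means an intersection of at least one base, so bookended intervals do not
overlap and are not merged.  A region is retained only when each required
sample group (e.g. the CD4 and CD8 compartments) contains at least one
sample annotating it — by exact (chrom, start, end) identity by default,
since consensus open-chromatin annotations repeat identical regions across
samples; overlap-based support is available (`match="overlap"`).  Regions
on the Y and mitochondrial chromosomes are excluded.

Merged regions are classed *proximal* when the nearest TSS point lies
within 500 bp of the interval (edge-to-point distance, 0 if the TSS is
inside, inclusive at exactly 500), else *distal*.  Distal regions attach to
a gene through chromatin interactions: any loop with an anchor bin
overlapping one of the gene's proximal regions links every distal region
overlapping either of its bins.  Interaction score filtering (`min_score`)
is optional input preprocessing; loop calling and loop merging are upstream
of this package.

## Motif discovery

Unique region sequences (each region id counted once) are decomposed into
overlapping k-mers (k = 12; windows containing non-ACGT are skipped;
k-mers are strand-specific by default since downstream scanning covers both
strands, with `collapse_rc` available).  K-mers are clustered into the
connected components of the Hamming-distance ≤ 1 graph — single linkage, so
chains of 1-mismatch neighbours merge; the components are found in
O(n·k·4) by hashing every 1-substitution variant, and the test suite checks
them against a quadratic connected-components oracle.  Each cluster becomes
a position probability matrix with columns weighted by k-mer occurrence
counts and no pseudocount.

Motif comparison uses a deliberately simple statistic: the mean per-column
Pearson correlation over the best gapless alignment with at least
`min_overlap` (default 8) aligned columns, taking the better of the second
motif's two orientations; constant columns compare as r = 1 when equal,
else 0.  This replaces a full TOMTOM-style null-model p-value — a
documented simplification; the thresholds (`r_match` = 0.75 against the
known database, `r_cluster` = 0.9 for redundancy collapsing) are
configurable and should be tuned against a known-motif benchmark before any
claim about novel-motif counts.  Redundancy clustering is greedy single
linkage; the representative is the heaviest member (ties: lexicographically
smallest id) and output order is deterministic.

## PWM scanning and exact p-values

PPMs become log2-odds PWMs against a 0-order background (uniform by
default, configurable): entry = log2(((p + c)/(1 + 4c))/bg) with
pseudocount c = 1e-4; with c = 0, zero-probability letters score −∞ and
their sequences carry probability mass at score −∞.  The p-value of a score
is the probability that a random background L-mer scores at least as high,
computed exactly by dynamic programming over column scores discretized at
1e-3 log2 units — the discretization is the only source of p-value error,
and the test suite brackets the DP tail between brute-force enumerations at
±L·granularity slack.  Scanning reports all windows on both strands with
p ≤ 1e-4 (and optionally score strictly above a cutoff); the reverse-strand
score is computed with the position- and letter-reversed matrix, and
N-containing windows are skipped.  Overlapping hits are all reported —
downstream presence tests only ask for ≥ 1 hit.  The score cutoff used in
the enrichment stage is not a constant but `derive_score_cutoff`: the mean
score of all hits in the regions linked to the top gene set.

## Monte Carlo enrichment

For each motif (or pair), the observed statistic is the number of
target-set genes with at least one linked region of the requested class
containing a filtered hit (for pairs: both motifs anywhere among the gene's
regions, not necessarily the same region).  The null draws 10,000
size-matched gene sets from the comparator set without replacement;
p = proportion of draws with count ≥ observed (no +1 smoothing), fold
change = observed / mean null count (+∞ when the null mean is 0 and
something was observed; an observed count of 0 is never enriched), and the
enrichment call is p < 0.05 ∧ fold > 2.

Because presence is boolean per gene, the null count of a uniformly drawn
subset is exactly hypergeometric; `mc_test` therefore draws the
per-iteration counts from `rng.hypergeometric` rather than materialising
gene subsets — statistically identical and O(1) per iteration
(`method="subset"` retains the explicit sampler, and a test checks the two
agree).  The MC p-value is discrete: under a null in which targets are
drawn from the comparator pool, P(p < 0.05) equals the largest achievable
tail below 0.05, about half a lattice step short of 0.05.  The calibration
test therefore uses a pool (8,000 genes, 800 targets, presence fractions
0.2–0.5) large enough that the lattice is fine and the expected rejection
rate, computed exactly beforehand, lies inside 0.05 ± 0.01; with small
target sets (e.g. 22 genes) the same test is visibly conservative, which is
a property of the discrete statistic, not an error.

Candidate selection for the reporter library follows the ranked pair lists
(rank sum of descending observed count and ascending null mean, ties
lexicographic): walk the known-motif pairs collecting members whose
DNA-binding archetype is not yet represented until nine are found, then
walk the known:novel pairs restricted to pairs containing a selected known
motif until nine novel motifs are found.  Each selected motif is
represented by its most frequent matched genomic subsequence (ties: highest
scan score, then lexicographic).

## Reporter library design

Oligos are fixed-length inserts (88 bp) with up to three oriented motif
sites.  Enumeration treats each of the three slots independently as empty
or one of m motifs in forward/reverse orientation: (2m + 1)³ designs,
50,653 at m = 18, including the all-empty background design.  Rendering
packs occupied slots left to right from `left_margin`, each followed by a
10-bp spacer taken from the background at the corresponding coordinates;
empty slots contribute nothing and the remainder is background, so the
all-empty design renders the background prefix exactly.  A consequence of
this packing is that assignments differing only in *which* slots are empty
render identical sequences; the manifest keeps them as distinct design rows
(position analyses group by occupied order, which is what is physically
rendered) and `build_library` emits a collision warning so a synthesis
export can deduplicate.  Slot 1 — the first occupied position — is the end
closest to the core promoter.

The background is designed in silico: draw a random 125-bp sequence, scan
it with every screened motif, replace each base inside a hit window with a
uniformly chosen *different* base, and repeat (cap 100 rounds) until no
motif hits remain; the result is a pure function of the seed.  Inserts are
flanked by AgeI (ACCGGT) and SalI (GTCGAC) sites plus pass-through
adapters, with a warning if a recognition site occurs inside the insert.
Control sequences (e.g. a 200-bp positive control) are tiled into every
88-bp window — 113 tiles for 200 bp — with first-occurrence deduplication.

## STARR-seq analysis

QC keeps oligos with DNA count ≥ 10 in all (eight) DNA replicates and
RNA > 0 in at least two of three RNA replicates.  Counts are CPM-normalized
per replicate, DNA replicates are collapsed by averaging their CPMs, and
activity is log2(RNA CPM / mean DNA CPM) per RNA replicate, defined only
where both are positive, minus the same quantity for the motif-free
background oligo — so the background sits at exactly zero and any
multiplicative distortion of a whole replicate cancels.  The unit of
analysis for all grammar tests is the per-oligo mean adjusted activity over
available RNA replicates.

The grammar statistics, each on groups defined purely from the design
manifest:

* **Oriented motif effect** — oligos carrying only the motif of interest
  (1–3 copies, all in the tested orientation) vs oligos without it in any
  orientation; Welch's two-sided t-test (the unequal-variance form, since
  group sizes and spreads differ) with Bonferroni-corrected α and an
  effect-size gate |Cohen's d| > 0.5.  Cohen's d uses the pooled
  Bessel-corrected SD.
* **Copy number** — OLS of mean activity on copy count (1–3) for
  single-motif oligos; two-sided slope p and its 95% CI.
* **Position** — among two-motif oligos, the motif promoter-proximal vs
  promoter-distal (occupied order); Wilcoxon rank-sum, two-sided.
* **Pair effect** — oligos whose occupied slots are exactly the two motifs
  (each 1–2 copies, fixed orientations) vs oligos missing at least one of
  them; Welch t + d gate.
* **Order** — one copy of each of two motifs; one order vs the other;
  rank-sum plus the ratio gate |mean₁/mean₂| > 2.
* **Synergy** — requires (1) the pair's |d| to exceed the stronger single
  motif's |d| by a one-sided Z-test at 0.05 using the large-sample SE of d,
  and (2) the pair's mean activity to exceed the sum of the single motifs'
  means.  The appropriate type-I null for this test is the
  *dominant-single-motif* configuration (one motif active, its partner and
  the interaction inert): with two equally active motifs and no
  interaction, the pair genuinely does outperform either motif alone and
  condition (1) fires by construction — the mean-exceeds-sum criterion is
  what separates additivity from synergy there, and it is a coin flip at
  exact additivity.

Bonferroni families are per analysis (n_tests is the number of subjects
tested in that family) with family α = 0.05 by default; printed thresholds
from any particular dataset are outputs, never constants.

## Synthetic data

All generators are pure functions of their seed; counts are negative
binomial with variance μ + α·μ² (dispersion α = 0.2 by default, so the
per-count CV approaches √α ≈ 0.45 at depth — the loose replicate
correlation of a T-lymphoblast host; a per-(oligo, replicate) log-normal
random effect can be switched on to loosen correlations further toward the
noisy-host regime, and smaller dispersions emulate clean hosts).

* `synth_expression`: log-normal gene baselines, NB counts, planted genes
  multiplied by `fold` in target samples and divided by `fold` in
  background samples (defaults: 2,000 genes, 8 target / 6 background
  samples, 20 planted, fold 8).
* `synth_regulatory_genome`: one chromosome, per gene a TSS, a proximal
  region centred on it, distal regions linked by loops whose bins cover the
  respective regions; motif consensus sites written into regions at
  class-dependent odds with random strand.  Placements are recorded and are
  recoverable by the scanner.
* `synth_starr`: DNA ~ NB(depth); expected RNA rate ∝ DNA CPM × 2^η with
  η = Σ β(present oriented motif) + Σ slope·(copies − 1) + γ(motif pair)
  + Σ δ(motif, occupied position), η(background) = 0.  β is a presence
  effect counted once per oriented motif — reading it per-slot would double
  count against the explicit copy-number slope — and δ keys on occupied
  order, matching what rendering physically places nearest the promoter.

Simulated studies are 10–100× smaller than a real library (two motifs,
125 oligos, depth 500).  At NB dispersion 0.2 a single such library gives
an in-vs-out contrast SE of ≈ 0.19 log2 units, so recovery studies pool 25
independently simulated libraries (SE ≈ 0.04) rather than altering depth,
replicate count or dispersion; `replicate_starr_study` implements the
pooling.  What passing these tests shows: the estimators are unbiased and
correctly sized against their own generative model.  What they do not
show: robustness to features of real reporter data the generator omits —
position-specific synthesis/PCR bias, sequence-dependent capture
efficiency, UMI saturation, cross-contamination between oligos, or
cell-state heterogeneity beyond a log-normal replicate effect.

## Known limitations

* Motif similarity is a correlation heuristic, not a calibrated p-value;
  known-motif filtering with it will not match TOMTOM match-for-match.
* The enrichment p-values are nominal and uncorrected across motifs, by
  design; genome-wide-expectation analyses are out of scope.
* The interval routines are quadratic in the worst case per chromosome and
  are sized for curated region sets (10²–10⁴ intervals), not whole-genome
  feature sets.
* Exact-identity region support matching assumes the upstream annotation
  repeats identical intervals across samples; use overlap matching
  otherwise.
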