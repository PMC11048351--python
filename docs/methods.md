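# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing the
outputs. Nothing here states a result the tests or `scripts/acceptance.py`
do not themselves compute.

## Localization from percentage composition

Because the total RNA yield of an sEV preparation is far below the
intracellular yield, absolute signals are not comparable across
compartments. Each compartment is therefore reduced to percentage
composition per replicate: the miRNA's signal divided by the summed
signals of all reliably detected miRNAs in that replicate (analogous to
reads-per-million scaling). "Reliably detected" means DABG p < `dabg_alpha`
(default 0.05) in **every** replicate of the compartment; the all-replicates
rule is the conservative reading of "reliably detected" and is
configurable (`rule="any"`). The composition denominator is computed per
replicate within the compartment's own detected set. A miRNA detected in
one compartment only is assigned composition 0 in the other, symmetrically
in both directions.

Per miRNA, the three sEV replicate compositions are compared with the
three cell replicate compositions by an unpaired two-sided Student t-test
with pooled variance (df = n_x + n_y − 2). Degenerate inputs are defined
explicitly: zero pooled variance with equal means gives (t = 0, p = 1);
with unequal means, (t = ±∞, p = 0). Since compositions are scale-free,
multiplying all signals of one replicate by any constant changes nothing
downstream; this is asserted in the tests.

Multiplicity is handled by the adaptive two-stage linear step-up FDR
procedure (Benjamini–Krieger–Yekutieli): stage 1 runs Benjamini–Hochberg
at q′ = q/(1+q); with r₁ rejections the null count is estimated as
m₀ = m − r₁; r₁ = 0 rejects nothing, r₁ = m rejects everything, otherwise
stage 2 runs BH at q′·m/m₀. Ties in the step-up share the verdict of the
highest qualifying rank. Adjusted q-values are computed exactly by an
interval scan on the c = q/(1+q) scale, on which the stage-1 rejection
count is piecewise constant, so that (q_i ≤ q) holds iff miRNA i is
rejected at level q — for any level, not only 0.05. A caution for users of
adaptive FDR: the two-stage rejection set provably contains the BH set run
at the shrunk level q/(1+q), but is **not** always a superset of BH at q
itself; the naive superset claim fails precisely when stage 1 rejects
fewer than m·q/(1+q) points.

Calls: q < `q` (default 0.05) with mean sEV composition above / below the
mean cell composition gives SEV_ENRICHED / CELL_ENRICHED; otherwise
NEUTRAL; miRNAs detected in neither compartment are UNDETECTED and carry
no test. The AU% (fraction of A+U bases) and length of each class are
summarized and compared between the two enriched classes with the same
t-test; classes with fewer than two sequenced members report the statistic
and skip the test with a notice.

## Motif scanning and enrichment

Motifs are position frequency matrices over (A, C, G, U), rows
renormalized to sum to 1 on input (both the U and T CISBP text dialects
are accepted). The log-odds score of base b at position i is
log2((pfm[i][b] + c·bg[b]) / ((1+c)·bg[b])) with pseudocount weight
c = 0.1 and a 0-order background estimated from the background sequence
set (uniform if not supplied; a base absent from the background gets one
pseudo-observation to keep scores finite). Scanning is single-strand, best
window per sequence, leftmost on ties; the scaled score divides by the
motif's maximum achievable score and clips to [0, 1]. A motif whose PWM is
uniform scores 0 everywhere and is retained; a sequence shorter than the
motif is flagged absent.

Enrichment of one localization class (positives) against the other
(background) follows the simple-enrichment-analysis idea with transparent
mechanics. The neutral class is excluded from the background so weakly
localized miRNAs cannot dilute it, and shuffled sequences are deliberately
not offered as a background model, since miRNA sequences are not random
draws over ACGU. Per motif: candidate thresholds are the distinct scaled
scores observed on a stratified 90% training split (the split is seeded
and order-independent); the threshold minimizing the one-sided Fisher
exact p on the training counts is kept (ties resolve to the most stringent
threshold); the reported `fisher_p` is the raw one-sided Fisher p
recomputed on the full set at that threshold; and the stratified 10%
holdout must show fold enrichment ≥ 1 at that threshold for the motif to
count as significant (an empty holdout defaults to consistent, with a
warning for sets under 10 sequences).

The E-value is `fisher_p × n_motifs × (n_sequences + 1)`. The second
factor is a Bonferroni bound over the maximum number of distinct score
thresholds a sweep can visit. It is needed because the raw p at an
optimized threshold is anti-conservative: without it, a motif-count-only
E-value flags spurious motifs in a large fraction of null datasets, which
defeats the point of reporting E. With it, the E-value is a valid
(conservative) family-wise bound over the whole search — motifs and
thresholds — and the null-calibration tests confirm the false-positive
rate stays at or below nominal. The factor is constant across motifs, so
ranking by E-value equals ranking by p within a run; truly enriched
motifs in these data have p-values tens of orders of magnitude below any
threshold, so the conservatism costs no power at realistic effect sizes.
Significance means E < `e_threshold` (default 0.05) **and** holdout
consistency.

## Prediction from motif strength

Feature matrix: rows are miRNAs called SEV_ENRICHED or CELL_ENRICHED
(binary problem; neutral excluded), columns are motifs significant in
either enrichment direction ordered by (E-value, motif id), values are the
miRNA's best scaled match score, set to 0 when below that motif's optimal
threshold. "Motif strength" is interpreted per miRNA — the scaled best
match — because only a per-miRNA quantity can populate a per-row feature.
The positive class is SEV_ENRICHED throughout.

Classifiers are pinned surrogates of common "default settings": Random
Forest with 100 bootstrap CART trees, Gini impurity, unlimited depth,
per-split feature subset of size floor(log2 m) + 1, probability = fraction
of trees voting positive; and Gaussian Naive Bayes with
maximum-likelihood per-class means and variances, a variance floor of
1e-9, and training-frequency priors. Evaluation is seeded stratified
k-fold (default 10) with **pooled** out-of-fold probabilities; ROC is
swept over the pooled scores and AUC is the trapezoidal area, which
equals the tie-aware Mann–Whitney statistic exactly. If the minority
class has fewer members than k, the fold count is reduced to keep both
classes in every fold; below two members, stratification is impossible
and the run errors.

Feature selection (which motifs are significant, and their thresholds) is
computed once on the full labeled set, exactly as the original
whole-dataset analysis style does; this leaks label information into the
features, so the pooled CV AUC is an optimistic estimate of out-of-sample
performance. `cross_validate_nested` recomputes enrichment and thresholds
inside each training fold and is the leakage-free estimate; it scores no
higher on average, and the tests assert that ordering qualitatively.

## Synthetic data generator

The generator emulates the *shape* of a replicated two-compartment
microarray comparison; its defaults are the study conditions used in all
tests. Defaults: 527 miRNAs (all detected intracellularly), 129 detected
in sEVs, 3 replicates, 15% sEV-enriched and 45% cell-enriched planted
classes, composition fold change 4, multiplicative log-normal replicate
noise with CV 0.2, log-normal baseline abundances (σ = 1.5), sequence
lengths uniform on 18–25 nt, detection p-values U(0, 0.04) for detected
and U(0.1, 1) for undetected entries, AGGGA planted in 80% of secreted /
5% of retained sequences and UCUUC conversely, plus 20 random Dirichlet
decoy PWMs drawn from a fixed stream so the decoy set is identical across
simulation seeds. GC bias (default on) gives secreted sequences 40% AU
and retained 60%, matching the observed direction that secreted miRNAs
are GC-richer; neutral sequences are unbiased and receive no planted
motifs.

Compositions are closed (each replicate sums to 1), so a planted fold
change cannot hold for every miRNA at once. The generator pins neutral
miRNAs to exactly equal compositions in both compartments and absorbs the
closure factor into the two enriched classes alone; the realized contrast
between the secreted and retained classes is then exactly fold_change²
for every seed, and "neutral" is exactly neutral — without this, the
closure drifts with the heavy-tailed abundance draws and the planted
truth is not self-consistent. sEV detection slots are filled by all
planted sEV-enriched miRNAs plus the highest-abundance others.

What the generator does **not** emulate: probe-level microarray
artifacts, cross-hybridization, abundance-dependent noise (real CV rises
sharply at low signal), sEV isolation efficiency, or miRNA families with
shared seeds. Two visible consequences, worth understanding before
reading test output as statements about real data: (i) with constant CV
and one-sided detection, almost every miRNA undetected in sEVs is a
significant cell-enriched call, so the default scenario calls ~78%
cell-enriched against 45% planted — on real arrays the low-abundance tail
is noisier and many such tests stay neutral; (ii) passing the planted
recovery tests shows the machinery is correct, not that real effect sizes
are detectable at n = 3.

The fully null configuration (`null_config`) sets fold change 1, disables
GC bias, plants nothing, and makes detection complete in both
compartments — one-sided detection is itself a composition signal, so a
genuine null must remove it.

## Numerical conventions and edge cases

- Consensus strings map to PFMs with probability 1 on the consensus base;
  lowercase positions (e.g. the leading "u" of uAGGGA) get probability
  0.55 with the remainder spread evenly. Consensus extraction from a PFM
  breaks ties alphabetically (A < C < G < U).
- The one-sided Fisher p is the hypergeometric upper tail; the empty
  table is defined as p = 1. Fold enrichment with a zero background rate
  is +∞ if the positive rate is positive, else 1; 0/0 rates are treated
  as direction-consistent in the holdout.
- Scaled scores from a motif with non-positive maximum score are defined
  as 0.
- All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; holdout splits sort ids before permuting so results do
  not depend on input record order. Pipeline artifacts contain no
  wall-clock content, and a rerun under the same config is byte-identical
  (asserted by hashing every output).
- Test problem sizes are the defaults above; Monte-Carlo assertions use
  20–50 seeded replicates per scenario, chosen to keep the whole suite in
  the low minutes on one CPU while leaving the asserted margins
  comfortably away from their thresholds.

## Known limitations

- The SEA variant here is transparent but not guaranteed identical to the
  MEME-suite tool (whose exact threshold search and significance
  estimator are not fully specified in its description); the E-value here
  is deliberately more conservative than a motif-count-only correction.
- Only two compartments and unpaired designs are supported; no paired
  tests, no more-than-two-way comparisons.
- DABG p-values are consumed, never computed; upstream normalization
  (e.g. RMA) is out of scope.
- The prediction stage deliberately mirrors the original
  select-then-cross-validate design; use the nested mode for honest
  generalization estimates.
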