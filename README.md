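# mirsort

Cells do not release microRNAs into small extracellular vesicles (sEVs,
including exosomes) at random: some miRNAs are preferentially secreted
while others are retained, and short RNA-binding-protein (RBP) motifs in
the ~22-nt miRNA sequence are a strong candidate sorting signal. `mirsort`
implements that analysis as a tested, reusable pipeline for anyone with
replicated two-compartment miRNA abundance profiles (e.g. microarray
signal plus detected-above-background p-values for cells and their sEVs):

1. **Localization calls.** Each profile is reduced to *percentage
   composition*: x_ij = s_ij / Σ_k s_kj over the miRNAs reliably detected
   (DABG p < 0.05 in every replicate) in that compartment, so unequal
   total yields cannot masquerade as enrichment. A miRNA detected in only
   one compartment carries composition 0 in the other. Replicate
   compositions are compared with an unpaired equal-variance two-sided
   t-test and corrected with the adaptive two-stage
   Benjamini–Krieger–Yekutieli FDR procedure; q < 0.05 plus the sign of
   the composition difference yields sEV-enriched / cell-enriched /
   neutral calls.
2. **Motif enrichment.** CISBP-RNA-style position frequency matrices are
   converted to log2-odds PWMs (pseudocount weight 0.1) and each sequence
   gets a best-window match score scaled to [0, 1]. A simple-enrichment
   analysis tests each motif in one class against the opposite class as
   background (neutral excluded, never shuffled sequences): the match
   threshold is optimized on a 90% split, the Fisher exact p is recomputed
   on the full set, a 10% holdout must agree in direction, and the
   E-value corrects p for the number of motifs and score thresholds
   searched.
3. **Prediction.** Every significant motif (either direction) becomes a
   feature — the scaled match score, zeroed below that motif's threshold —
   and Random Forest (100 Gini trees, mtry = ⌊log₂ m⌋ + 1) and Gaussian
   Naive Bayes are
   scored by pooled out-of-fold AUC-ROC under seeded stratified 10-fold
   cross-validation.

Because real profiling data of this kind is typically not deposited, the
package ships a first-class synthetic data generator
(`mirsort.synthetic_data`) that emulates the study design — log-normal
abundances, planted composition fold changes, detection structure, GC-bias
between classes, and motif consensus strings planted at class-specific
rates — with exact ground truth, so every stage is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic design (527 miRNAs detected intracellularly, 129 in sEVs, three
replicates, 15%/45% planted secreted/retained classes at fold change 4,
AGGGA planted in the secreted class and UCUUC in the retained class among
20 decoy motifs):

```sh
python analysis/01_simulate.py
python analysis/02_classify_localization.py
python analysis/03_motif_enrichment.py
python analysis/04_predict_localization.py
python analysis/05_null_calibration.py
```

which prints, among other lines:

```
tested 527 miRNAs detected in at least one compartment:
  SEV_ENRICHED: 108 (20.49%)
  CELL_ENRICHED: 412 (78.18%)
  NEUTRAL: 7 (1.33%)
mean AU%: sEV 43.9 vs cell 55.8 (t-test p = 2.58e-19)
sev_vs_cell: ... planted_AGGGA (RBP_AGGGA): fold = 26.28, E = 1.43e-36
random_forest: pooled 10-fold AUC-ROC = 0.8968
naive_bayes: pooled 10-fold AUC-ROC = 0.8909
random_forest: AUC against planted labels = 0.9730
```

Reading the output: far more miRNAs are *called* cell-enriched (78%) than
were planted (45%) because 398 of the 527 miRNAs are undetected in sEVs —
their sEV composition is 0 by definition, which the composition test
rightly reads as retention; the planted classes are recovered almost
perfectly when detection is complete (see `tests/`). The planted AGGGA
motif ranks first in the secreted direction by a wide margin, the secreted
class is measurably GC-richer while lengths do not differ, and motif
strength alone predicts the localization call with AUC ≈ 0.89 (and the
planted truth with AUC ≈ 0.97). The negative controls in
`05_null_calibration.py` call essentially nothing enriched and flag no
motif when no signal was planted.

The same stages are available as a CLI (`mirsort simulate | classify |
enrich | predict | run`) for use on real tables; see `mirsort run
--config` with a YAML listing either input paths (abundance TSVs, FASTA,
CISBP-RNA PWM directory + metadata) or a `simulation:` block.

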