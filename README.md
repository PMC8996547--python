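# xspecies

Predicting tissue-specific open-chromatin conservation across species from
DNA sequence.

Alignment-based conservation scores (PhastCons, PhyloP) ask whether
individual nucleotides are constrained.  Enhancers frequently conserve their
*regulatory* function — a combinatorial code of transcription-factor binding
sites driving tissue-specific open chromatin — while their nucleotides turn
over, and a well-aligned region can lose one critical site and with it its
activity in a tissue.  `xspecies` takes the regulatory-code route: train a
convolutional network to predict whether a 500 bp summit-centered window is
an open chromatin region (OCR) in a tissue, apply it to the orthologs of
OCRs across a phylogeny, and read conservation or lineage-specific loss of
activity off the predictions.

The package is aimed at comparative regulatory genomicists and provides the
whole workflow as a library:

- **`intervals` / `io`** — 0-based half-open genomic intervals, peaks with
  summits, one-hot encodings, chromosome-level train/validation/test splits;
  narrowPeak/BED/FASTA/bedGraph/ortholog-TSV readers and writers.
- **`datasets`** — positive-set filters (non-exonic, ≥20 kb from a TSS,
  ≤1 kb) and six negative-set strategies, including the distinctive
  *non-OCR orthologs of OCRs*: regions closed in one species whose ortholog
  in another species is open in the same tissue.  Class weights equal the
  fraction of examples in the other class.
- **`cnn`** — the sequence CNN (valid width-7 convolutions, dropout 0.2,
  L2 1e-5, max-pool 26, FC, sigmoid) with the full training protocol in
  numpy: He-normal init, a balanced pre-training warm start, class-weighted
  Nesterov SGD, early stopping on recall@80% precision (or specificity@80%
  NPV when positives outnumber negatives), strand-averaged prediction.
- **`evaluation`** — lineage-, clade-, species- and tissue-specific
  evaluation sets; AUROC/AUPRC/NPV-specificity metrics; conservation-track
  comparisons with rank-sum and sign-rank tests.
- **`phylo`** — phylogeny-matching correlations: per-species prediction
  means/SDs vs divergence time, with the exponential decay fit
  `y = a·e^{bx}`.
- **`clustering`** — masked-cosine k-means + affinity propagation
  (preference −0.6) over OCR × species prediction matrices, and LOLA-style
  hypergeometric enrichment of clusters against external enhancer sets.
- **`simulate`** — a fully synthetic six-species, two-clade cohort:
  sequences evolved along a tree with planted tissue-specific motif
  grammars, motif gain/loss, purifying selection on active sites, ortholog
  dropout and a stand-in conservation track, so every stage runs without
  downloading anything.

## Worked example

Train on a simulated cohort and measure conservation-prediction quality:

```python
from sklearn.metrics import roc_auc_score
from xspecies import SimConfig, simulate_cohort, predict_strand_averaged
from xspecies.pipeline import train_cohort_model

cohort = simulate_cohort(SimConfig(seed=1))           # 2,000 regions, 6 species
model, history, arrays = train_cohort_model(cohort, "brain")
x_test, y_test = arrays["test"]
scores = predict_strand_averaged(model, x_test)
print(f"monitor: {history.monitor}")
print(f"stopped at epoch {history.stopped_epoch}, best epoch {history.best_epoch}")
print(f"held-out AUROC: {roc_auc_score(y_test, scores):.3f}")
```

```
monitor: specificity_at_80pct_npv
stopped at epoch 6, best epoch 3
held-out AUROC: 0.923
```

Positives here are mouse brain OCRs; negatives are mouse orthologs of other
species' OCRs that are closed in mouse — so the AUROC measures exactly the
hard task, separating conserved from lineage-specifically lost open
chromatin, not open-vs-random.  The phylogeny-matching pattern falls out of
the same model:

```python
from xspecies.phylo import filter_sparse_rows, per_species_summary, phylogeny_correlation
from xspecies.pipeline import prediction_matrix

lab = cohort.labels["brain"]
mat = prediction_matrix(model, cohort, list(lab.index[lab["mouse"]]))
fit = phylogeny_correlation(per_species_summary(filter_sparse_rows(mat)),
                            cohort.divergence)
print(f"Spearman r (mean prediction vs MY since divergence): {fit.spearman_r_mean:.2f}")
```

```
Spearman r (mean prediction vs MY since divergence): -0.94
```

Mean predicted open chromatin at mouse-OCR orthologs falls with divergence
time from mouse, as it must if the model has learned a conserved regulatory
code.  A shell interface wraps the common workflows:

```sh
xspecies simulate --seed 7 --n-regions 500 --out cohort/
xspecies regions --peaks cohort/mouse_brain.narrowPeak --flank 250 --out windows.bed
xspecies phylo-corr --matrix predictions.tsv --divergence cohort/divergence.tsv
```

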