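# Methods

## Problem and model

`cpgnet` predicts the binary methylation status of CpG sites from local
sequence context alone. Input data are a reference sequence (FASTA) and a
site-level methylation table (`chrom  pos  beta_percent`, the typical
product of RRBS/bisulfite processing). A site with methylation percentage
β ≥ 50 is labeled *methylated*, below 50 *unmethylated*; the threshold is
inclusive at 50. For each site a fixed window of W ∈ {100, 200, 300} bases
centered on the C of the CG is extracted and one-hot encoded, and a 1-D
convolutional classifier maps the encoded window to two softmax
probabilities (class order: unmethylated, methylated; exact probability
ties resolve to unmethylated).

### Coordinates and windows

Internal positions are 0-based indices of the C of a CG dinucleotide.
Tables may be read as 0-based (`bed0`, the ENCODE BED convention) or
1-based (`tsv1`). The window is the half-open interval
[pos − W/2, pos + W/2), so the C sits at offset W/2 and the CG is always
fully inside the window. Sites whose window would overrun a chromosome
end are skipped (not padded: padding would inject synthetic residues the
encoder cannot distinguish from sequence). All sites are treated as
forward-strand Cs. Windows with more than 10% ambiguous bases are skipped.

### Encodings

*Monomer*: each base maps to a length-4 indicator in the fixed order
(A, C, G, T), giving an L × 4 matrix. *Dimer* (the canonical scheme): each
overlapping dinucleotide is the concatenation of its two monomer vectors,
giving (L − 1) × 8 with every row summing to 2. A 16-channel indicator
variant (`dimer16`, one bit per dinucleotide identity) is available but
not the default — the 8-channel concatenation is the scheme that matches
the published worked example and tensor shapes this package mirrors.
Ambiguous bases produce all-zero rows so tensor shapes depend only on W.

### Architectures

All three classifiers consume (batch, length, channels) tensors and end
in global average pooling → dense(2) → softmax.

* **unet1d** — encoder: conv(16) → maxpool ÷4 → conv(32) → maxpool ÷4 →
  conv(64) bottleneck; decoder: transposed conv ×4 (64 filters) with a
  skip from the mid-resolution encoder map, transposed conv ×4
  (32 filters) with a skip from the full-resolution map, then conv(16).
  For a 299 × 8 input the length ladder is 299 → 74 → 18 (floor division
  by 4, twice) and 18 → 72 → 288 (multiplication by 4, twice). Because
  floor division loses remainders, encoder maps are center-cropped to the
  decoder length before concatenation (74 → 72, 299 → 288); cropping was
  chosen over padding to avoid edge artifacts.
* **cnn1d** — three conv blocks (16/32/64 filters, each followed by a ÷4
  max-pool where length permits).
* **mobilenet1d** — conv stem (16 filters) then three inverted-residual
  blocks (pointwise expansion ×4, depthwise kernel 3, squeeze-and-
  excitation with reduction 4, linear pointwise projection; stride 2 on
  the first two blocks). The residual shortcut is present exactly where
  stride is 1 and input/output channels match.

Every convolution uses kernel size 3 with length-preserving zero padding
(only pooling changes length), followed by batch normalization and ReLU;
transposed convolutions use kernel = stride = 4, making the upsampling an
exact ×4. The 1-D convolution primitive is the sliding dot product
F_i = Σ_m I_{i+m} K_m (cross-correlation orientation, no kernel flip) —
the operation convolutional layers actually compute.

### Training

Adam (step size 1e-3, β₁ = 0.9, β₂ = 0.999), batch size 32, softmax
cross-entropy, 50 epochs by default, no early stopping, no dropout or
weight decay. Weights are initialized Glorot-uniform, matching the defaults of the
mainstream deep-learning toolchains this architecture family comes from;
batch-norm running statistics use momentum 0.1 so inference-mode
statistics converge within the first few hundred optimizer steps even in
short trainings. One seed
fixes initialization and batch order, so two runs with identical inputs
produce identical histories on one platform. The per-epoch history
records train/validation accuracy and loss; learning curves are drawn
from the validation split, and the test split is touched only for final
metrics.

The network engine itself (convolutions, batch norm, pooling, transposed
and depthwise convolutions, SE gates, Adam) is implemented directly on
numpy with explicit backpropagation; gradients were verified against
central finite differences layer by layer.

### Dataset handling

An n-site dataset is shuffled (seed-deterministic) and partitioned
70:20:10 into train/test/validation with floor sizes and the remainder to
validation — exactly 3500/1000/500 at n = 5000. Subsampling to a target n
is stratified by label, preserving the class ratio within ±1 site.

## Evaluation

Positive class is *methylated*. SN = TP/(TP+FN), SP = TN/(TN+FP),
ACC = (TP+TN)/n, precision = TP/(TP+FP), MCC with the standard product
denominator, F1 = harmonic mean of precision and SN. Metrics whose
denominator is zero are reported as an explicit undefined marker (None),
never coerced to 0, so degenerate classifiers remain visible. ROC and PR
curves sweep distinct score values (ties grouped into one point); both
areas use the trapezoidal rule, AUPRC over recall with the recall-0
endpoint carrying the first precision value — under which a
constant-score classifier scores exactly the positive prevalence. Areas
are reported on the 0–1 scale with a 0–100 convenience column in the
serialized report.

`solve_confusion_matrix` inverts a printed (ACC, SN, SP) tuple at 2-dp
half-up rounding back to all integer confusion matrices consistent with
it, by exhaustive search over the positive count. It is the verification
route for published results tables, and settles definitional ambiguities:
the standard precision definition is the one that reproduces the
companion precision/F-1 values of the published tuples.

## Synthetic methylome generator

The generator emulates the two real inputs so the full pipeline is
testable offline. A genome is drawn i.i.d. with a target GC fraction
(default 0.5, split evenly between G and C). `plant_methylome` selects
well-separated CG positions (minimum spacing twice the motif radius, so
neighborhoods do not overlap) and plants a rule: sites with the motif
(default `TATAAT`, a TATA-like 6-mer) within a 50 bp radius draw β from a
high-mean distribution, others from a low-mean one.

* β noise is a scaled Beta distribution on [0, 100] parameterized by its
  mean (defaults 80 high / 20 low) and a concentration c (default 6);
  c = ∞ is the noiseless limit. With the defaults,
  P(β ≥ 50 | high) ≈ 0.951, giving a Bayes accuracy of ≈ 0.95 — the
  honest ceiling any classifier can reach on the fixture, computed in
  closed form from the Beta tail mass and recorded in the manifest.
* The motif is injected near half of the selected sites (class balance is
  engineered, since real class ratios vary by cell line); injection
  places a cluster of 3 copies, mirroring how methylation-associated
  sequence features occur as local enrichments (CpG density, binding-site
  clusters) rather than single faint hits. A single-copy feature is at
  the edge of what the fixed architecture/budget can separate from
  memorization noise at n = 2000; a cluster makes the planted feature
  unambiguously learnable, which is the generator's purpose. The label
  rule is unchanged — it asks only whether the motif occurs, re-read from
  the final sequence after injection, so rule and emitted genome are
  exactly consistent.

What the generator does *not* emulate: bisulfite read noise, sequencing
error, strand asymmetries, CpG-island–scale methylation autocorrelation,
and the long-range dependency structure of real chromatin. Passing the
end-to-end tests therefore shows that the pipeline is correct and the
models can extract a planted local sequence determinant — not that real
methylomes are predictable at any particular accuracy.

## Problem sizes used by the test suite

The end-to-end learnability check trains the UNet on the default fixture
(n = 2000 sites, 100 bp windows, dimer encoding, 20 epochs), where it
reaches test accuracy ≥ 0.85 and AUROC ≥ 0.90 against the 0.95 Bayes
ceiling, and sits at chance (0.40–0.60) when labels are permuted. The
encoding-comparison probe uses the lighter CNN at n = 1200 and 10 epochs.
These sizes keep a full run at desk scale while leaving the contracts
(split sizes, shapes, ladders) at the published values.

## Known limitations

* Minus-strand CpGs are not merged with their forward-strand partners;
  the table is taken at face value.
* Batch normalization statistics make training-history reproducibility a
  single-platform guarantee (BLAS reduction order may differ across
  builds).
* The promoter-region evaluation mode scores any user-supplied site list
  but provides no promoter annotation itself.
* `dimer16` is provided for completeness; all defaults and published
  shape contracts use the 8-channel dimer concatenation.
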