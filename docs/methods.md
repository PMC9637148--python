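# Methods

## Model

The model predicts gene expression from binned histone-modification (HM)
signals using three stacked transformer submodules, instantiated
independently for each input resolution r ∈ {100, 500, 2000} bp over a
40 kbp window centred on the TSS (400 / 80 / 20 bins):

1. **Embedding transformer.** The (n_r × C) promoter matrix (C = 7 HM
   channels by default) is linearly projected to width d = 128, a sinusoidal
   positional encoding P (P[i,2k] = sin(i/10000^{2k/d}),
   P[i,2k+1] = cos(i/10000^{2k/d})) is added, and one encoder layer —
   2-head scaled dot-product self-attention with per-head width 64, residual
   + layer norm, position-wise FFN (128 → 128 → ReLU → 128), residual +
   layer norm — produces X_emb. Row inner products of P depend only on
   |a − b|, so attention can reason about relative genomic distance.
2. **Pairwise Interaction transformer.** For each of up to i_max = 8
   interacting pCREs, two encoder-decoder layers decode the promoter
   embedding against the pCRE's position-encoded feature matrix: queries
   from X_emb (then from the intermediate X_pair), keys/values from the pCRE
   matrix, all four projections bias-free; FFN hidden width 256.
3. **Regulation transformer.** The TSS-bin rows of X_emb and of each X_pair
   form the composite matrix X_comp ((i_max + 1) × 128, row 0 = promoter;
   dummy rows are exactly zero). Six layers of gated self-attention follow:
   Q, K, V and a gate G are bias-free projections (4 heads × 32 dims); the
   attention logits receive an additive bias γ·B where B's first row holds
   the normalized interaction frequencies f and γ is a learnable scalar per
   layer; the value-path output is multiplied elementwise by σ(G). No
   positional encoding — the pCRE set is unordered.

Row 0 of X_reg per resolution is the regulatory embedding; the three are
concatenated (384 dims) and passed to a head with one 128-unit ReLU hidden
layer emitting 2 logits (classification), one scalar (regression), or — in
the Siamese differential variant — a log2 fold-change from the concatenated
768-dim pair plus a shared auxiliary head predicting each cell type's
absolute log2 expression (equal loss weights).

Design points that were genuinely open and how they were fixed:

* **Head counts.** Only the Embedding transformer's head count is fixed by
  its per-head width statement; for the Pairwise (64-dim heads) and
  Regulation (32-dim heads) modules the head counts (2 and 4) follow from
  requiring heads × head-width = 128.
* **No output projection after head concatenation.** Heads are concatenated
  back to width 128 and fed directly to residual + layer norm; no extra W_O
  (none is described for this architecture).
* **Regulation FFN.** Each gated-attention layer is followed by the same
  residual + layer-norm + FFN pattern as the other modules, hidden width 128
  (configurable).
* **Padding mask.** Dummy pCRE rows are masked on the key side (zero
  attention weight) so padding cannot absorb attention; `use_pad_mask=False`
  restores unmasked softmax over the zero rows. A query row whose keys are
  all masked degenerates to self-only attention instead of NaN.
* **γ initialisation** 1.0, one scalar per layer; **B is injected at every
  layer** (it encodes a static contact prior; `bias_every_layer=False`
  restricts it to layer 1).
* **No dropout by default**; a rate can be configured. Layer-norm ε = 1e-5;
  softmax uses max-subtraction; masked logits get −1e9, which underflows to
  exactly zero weight.
* **Initialisation** is the uniform fan-in scheme, fully seeded; all
  computation is float64, so fixed seed + fixed input reproduces outputs
  bit-exactly.

The model and its training are implemented on a small reverse-mode autodiff
core over numpy written for this package (`chromoformer.autodiff`); its
gradients are verified against central finite differences in the test suite.

## Feature pipeline

Coverage is consumed as bedGraph (piecewise-constant per-base depth; any
position outside covered intervals, including beyond chromosome ends, reads
zero). Bin value = log2(mean depth + 1); the pseudocount is configurable.
Coordinates are 0-based half-open; GTF is converted on read (TSS = start for
+, end for −). For minus-strand genes the bin order is reversed so that
increasing bin index always means downstream of transcription — an explicit
choice (`strand_aware=False` disables it) made so that downstream-specific
attention has a consistent direction. The TSS bin is the bin whose left edge
is the TSS (0-based index n_r/2).

pCREs are binned with their own non-overlapping windows (the last bin may
extend past the interval so the bins cover it fully), center-aligned and
zero-padded to the promoter matrix shape; intervals wider than the window
are center-truncated. Interactions with normalized frequency strictly
> 1.5 are kept, ranked by descending frequency (ties broken by ascending
genomic start for determinism) and truncated to i_max = 8.

Labels: classification = expression strictly above the within-cell-type
median (ties → 0; with distinct values the split is balanced within one
gene); regression = log2(RPKM + 1); differential = log2 ratio of
pseudocounted RPKMs. Cross-validation folds are chromosome-disjoint:
chromosomes are shuffled with the seed and greedily assigned to the
currently smallest fold.

## Training protocol

AdamW (decoupled weight decay, default coefficient 0.01 — unconstrained
otherwise), 10 epochs, initial learning rate 3e-5 multiplied by 0.87 after
each epoch (so lr_5/lr_0 = 0.87^5 ≈ 0.498), batch size 64, cross-entropy
for classification and MSE otherwise, last-epoch weights kept (no early
stopping). Shuffling is per-epoch and seeded; no gradient clipping by
default. Validation loss is logged per epoch but never used for selection.

## Interpretation

PCRI for a gene is the Euclidean distance between the standardized
multi-resolution promoter embedding (concatenated TSS-bin rows of X_emb —
the same "midpoint" vectors that seed X_comp, the only choice that compares
like with like) and the standardized multi-resolution regulatory embedding
(concatenated rows 0 of X_reg). Standardization is per vector across its
components with sample (n−1) sd; zero-variance vectors are flagged
degenerate and excluded downstream. PCRI is computed for validation genes
only, each with its own fold's model. Cross-cell-type normalization is a
z-score within cell type with population sd (making the operation idempotent
with exact unit moments); gene ranking uses the variance of normalized PCRI
across cell types; clustering is average linkage on 1 − Pearson correlation
along both axes (zero-variance rows/columns excluded with a warning).

## Synthetic epigenome

The simulator emits exactly the formats the pipeline consumes. Each gene
owns a 70 kbp territory; its promoter state is binary
(active, base = 2.8 log2 units, 60% of genes; repressed, base = 1.0) and is
observed only through Gaussian signal bumps with per-mark lognormal
amplitude noise (sd 0.35): activating marks at the TSS, repressive domains
on repressed genes, and an elongation-mark bump centred 5 kbp downstream of
transcription (sd 1.5 kbp). The elongation mark tracks base + η_body, where
η_body ~ N(0, 0.8²) is a transcription component visible in no other
channel — this is what makes the channel genuinely non-redundant, so
removing it must cost accuracy.

30% of genes are interaction-free. The rest carry up to 4 enhancer pCREs
(H3K4me1/H3K27ac bumps) and — on active genes with probability 0.5 — up to
4 silencer pCREs (H3K27me3), placed in eight distal slots 21.5–27.5 kbp from
the TSS: outside the 40 kbp promoter window, so their effects reach the
model only through the interaction branch. Interaction frequencies follow
2.2 · (d/20 kbp)^(−1) with lognormal noise (sd 0.15), so most but not all
pCREs pass the 1.5 filter; only contacted (filter-passing) pCREs act on
expression. log2 expression = base + 0.75 · (#contacted enhancers) −
3.0 · 1[#contacted silencers ≥ 2] + η_body + N(0, 0.3²);
RPKM = max(2^x − 1, 0).

What the simulator does *not* emulate: read-level sampling noise, mappability
artefacts, replication-timing and domain-scale covariance between marks,
shared enhancers, TAD structure, or realistic interaction-frequency
distributions. Passing behavioural tests therefore shows that the
architecture and pipeline recover the planted additive / switch-like /
channel-specific structure through the full featurization-training path —
not that the model attains its published accuracy on real epigenomes.

## Scaled study conditions

The behavioural study (acceptance tests and `scripts/acceptance.py`) runs on
the medium fixture (2,000 genes, 8 chromosomes) with a reduced model —
width 32 (16×2 / 16×2 / 8×4 heads), 2 regulation layers, FFN widths 64,
head hidden 32 — and coarser featurization (1000/2000/4000 bp bins over the
same 40 kbp window; the synthetic signal geometry lives at multi-kbp scale,
so nothing material is lost). Training uses 5 epochs of AdamW at lr 1e-3
with the same 0.87 per-epoch decay, batch 16, chromosome-disjoint 4-fold CV.
Bin-count and protocol fidelity at the full published configuration are
verified separately (they do not require training).

In the PCRI dose-response, each generative rule is read out in the stratum
that isolates it: the enhancer Spearman uses silencer-free
interaction-bearing genes, and the silencer medians use enhancer-free active
genes — otherwise the two rules confound each other's dose axis.

## Known limitations

* The numpy autodiff core is single-threaded beyond BLAS and intended for
  the scaled study sizes, not Roadmap-scale training.
* The Regulation transformer encodes pCRE dose through softmax attention
  mass, which saturates with count; near a planted switch threshold the
  learned embedding shift is graded rather than perfectly step-like at
  small training budgets.
* PCRI carries a mechanical baseline: even with zero interactions the
  regulation transform moves the lone promoter token (nothing pushes it
  toward the identity), so absolute PCRI of interaction-free genes is not
  small — only contrasts along a regulatory dose axis are interpretable at
  this scale.
* Interaction frequencies are consumed as given; no pcHi-C normalization is
  performed.
* The differential (Siamese) variant is implemented and unit-tested but not
  part of the scaled behavioural study.
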