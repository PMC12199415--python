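# Methods

## Problem and data model

The unit of prediction is a fixed odd-length sequence window (*segment*)
centered on one of the four residue types that dominate protein
carbonylation: K, P, R, T.  Every target residue carries exactly one of
three labels — carbonylation site, ligand interaction site, or
nonfunctional — and non-target residues are outside the problem.
Annotations are 1-based positions against the full protein sequence, the
convention of PTM databases; all internal indexing is 0-based.  Segments
are stored at 27 residues (the widest window any model uses) and cropped
to the working window at feature time, so one extraction pass serves every
window size.  Sequence termini are padded with `X`, which encodes as the
all-zero physicochemical vector and the uniform-background PSSM row —
padding carries no signal by construction.  Working window defaults are
13/15/17/17 for K/P/R/T; the window-search harness retrains over
{5, 7, …, 21} and selects by validation AUROC under the overfitting guard.

## Feature channels

Three channels describe a segment:

1. **Physicochemical** — a (2w+1)×10 binary matrix over ten residue
   classes (hydrophilicity, hydrophobicity, tiny, acidity, positive and
   negative charge, polarity, aromaticity, sulfur content, aliphatic).
   The residue-to-class table ships as an editable TSV
   (`scans/data_tables/physchem.tsv`) using standard biochemical
   assignments (aromatic = F/W/Y/H, sulfur = C/M, tiny = A/C/G/S/T, …);
   keeping the table in data rather than code makes the assignment
   inspectable and replaceable.
2. **Evolutionary profile** — a (2w+1)×20 slice of the protein's PSSM
   log-odds matrix centered on the target residue, terminal overhang
   filled with the background row.  PSSM values are consumed as provided
   (no sigmoid rescaling; a config switch exists but defaults off).  The
   TSV reader accepts the 20-column matrix portion of common PSSM dialects
   and reorders columns to alphabetical.
3. **Language-model embedding** — one vector for the center residue from
   a pluggable provider.  Providers included: a zero provider (the
   predictor must work without a language model, since the embedding
   channel contributes least among the design elements) and a synthetic
   provider (below).  A real protein-language-model adapter can implement
   the same one-vector-per-residue contract.  Only the center residue's
   vector enters the model; the window channels already carry the flanks.

## Network

Both prediction modules — the ligand interaction-sites module (LISPM) and
the carbonylation-sites module (CSPM) — share one architecture:

- **TRF block**: the 20-dim PSSM rows are linearly projected to
  `model_dim` (default 64), learned positional vectors are added, and
  three pre-norm transformer layers follow (multi-head scaled dot-product
  attention, h = 4 heads, d_k = model_dim/h; feed-forward expansion
  model_dim → 4·model_dim → model_dim; layer normalization; residual
  connections).  The token mean is the block's feature vector.  Learned
  positional vectors and the 4× feed-forward ratio are standard
  transformer choices made where the design was open.
- **CNN block**: parallel 1-D (positions as sequence axis, properties as
  channels) and 2-D (positions × properties, one input channel) stacks of
  two convolution layers each, kernel 2, stride 1, batch normalization
  (learnable γ, β, ε = 1e-5, running statistics for inference), ReLU,
  max pooling with kernel 2 and dropout 0.5 at training time.  Both
  branches run on every input and their flattened outputs concatenate;
  pooling skips an axis already reduced below the pool kernel so the same
  stack serves windows down to 5.  Output sizes follow from convolution
  arithmetic and are asserted against a dry forward at build time.
- **Embedding reducer** (CSPM only): two affine+ReLU layers mapping the
  provider embedding to exactly 10 dimensions.
- **Fusion**: the CSPM feature space (TRF ⊕ CNN ⊕ reduced embedding) and
  the LISPM feature space concatenate into a four-layer fully connected
  head (default widths 256/64/16/1, config-exposed); the final sigmoid
  yields a carbonylation propensity in (0,1).

The network, reverse-mode autodiff and Adam optimizer are implemented on
numpy in `scans.nn` (float64 throughout, fan-in uniform initialization
from a single run seed, dropout only in training mode) — training and
inference are deterministic given the seed, and inference is additionally
batch-size independent.

## Loss and training protocol

The customized focal loss on propensity p with one-hot labels
(l_c carbonylation, l_n nonfunctional, l_i ligand):

    loss = −(1−p)^r·l_c·log p − α·p^r·l_n·log(1−p) − β·p^r·l_i·log(1−p)

r (default 2, the standard focusing exponent) damps well-classified
examples; α weights overprediction errors and β cross-prediction errors.
With r = 0, α = β = 1 the loss is exactly binary cross-entropy with
carbonylation as the positive class.  Propensities are clamped to
[1e-7, 1−1e-7] before logarithms.

Training is two-phase: (1) pretrain the LISPM with BCE on ligand-vs-rest
(carbonylation counts as negative), select the epoch maximizing validation
AUROC subject to |AUROC_train − AUROC_val| ≤ 0.03; (2) freeze every LISPM
parameter (the optimizer refuses frozen parameters; bit-identity is
verified after training) and train the CSPM, reducer and fusion head under
the customized loss with the same selection rule.  Adam, learning rate
0.001, batch size 256, early stopping with patience 10 (defaults;
config-exposed).  Epoch-wise training AUROC is monitored on a capped
stratified subsample when the training set is large; this affects logging
and the gap guard input only, never gradients.

The loss-parameter grid search selects, among (α, β) cells, the
maximum-AUROC cell whose AUCPC is within 0.02 (absolute) of the grid
minimum; ties break toward lower AUCPC then lower (α, β), making the pick
independent of enumeration order.  The band is absolute because AUCPC is
already on a proportion scale; it is config-exposed.

Ablation variants are first-class: `transfer=False` (joint training, no
pretrain/freeze), `loss_variant="bce"|"l2"`, `attention="fcnn"` (dense
modules in place of the CNN/TRF blocks), and a zero embedding provider.

## Evaluation framework

False positives are decomposed by truth: CPR is the fraction of
ligand-labeled residues predicted positive (cross-predictions), OPR the
same for nonfunctional residues (overpredictions).  The rate reading —
rather than a precision-style denominator — is forced by the calibration
requirement that a scorer with no information satisfies SN = CPR = OPR,
making CPRratio = SN/CPR and OPRratio = SN/OPR equal 1 at random and > 1
for genuinely selective predictors.  A zero rate is floored at half a
count (1/(2·class size)) before the ratio and flagged; an absent class
reports absent, not zero.

The CP curve plots CPR (y) against SN (x) over the shared descending
threshold sweep (tied scores move together; thresholds sit strictly
between distinct scores), anchored at (0,0) and (1,1); AUCPC is its
trapezoidal area, 0.5 for a random scorer and 0 for a predictor that
recovers every carbonylation site before flagging one ligand site.  The
OP curve/AUOPC are analogous with OPR.  ROC and PR use the standard
estimators (trapezoidal AUROC — equal to the Mann–Whitney statistic — and
step-wise AUPRC).  AULC is the partial ROC area on FPR ∈ [0, c]
(c ∈ {0.05, 0.10} both reported); its random reference is c²/2, so
AULCratio = 1 at random.  Threshold optima (MCCmax, F1max, SN at
SP ≥ 0.95/0.90) come from an exhaustive sweep; MCC with a zero denominator
is 0; an unreachable SP target is reported absent with a flag.

Significance between two predictors: ten stratified 50% subsamples (each
class drawn independently, without replacement), the metric computed per
replicate for both, an Anderson–Darling check at the 5% level on each
sample — both normal ⇒ Student's t-test, otherwise Wilcoxon rank-sum —
and significance declared at p < 0.001.

## Motif discovery

Candidates are wildcard patterns of length 4–10 over the amino-acid
alphabet plus `x` (matches any residue, never the `X` padding; terminal
wildcards are disallowed as equivalent to shorter patterns).  Half of the
candidates (configurable) are mined from k-mers observed in positive
segments before wildcarding, so the frequency filter is not vacuously
empty at small corpus sizes; fully random generation remains available.
A pattern survives when its frequency in the carbonylation segment set
exceeds T = 5% while its mean frequency over ten size-matched random
noncarbonylation draws stays below T (strict inequalities; presence /
absence semantics per segment).

Information gain is the class-label (decision-tree) gain of splitting on
pattern presence, in bits.  The gain of a single-class set is identically
zero, so the ranking ratio needs a reference: for each replicate τ the
true-label gain is computed on D_cs ∪ replicate-τ, and the null gain on
the same union with labels randomly permuted (seeded per replicate); both
average over the ten replicates and IGR is their ratio with a 1e-6-bit
floor.  This permuted-label null is this package's documented
construction for the denominator.  Motifs sort by IGR (ties: gain, then
pattern string) and classify as highly (IGR > 10), moderately
(2 < IGR ≤ 10) or marginally (1 ≤ IGR < 2) favored.  The motif-based
predictor scores a segment by the summed gain of the model motifs it
contains.

## Synthetic-data generator

The generator emulates the statistical structure the method assumes, not
the chemistry of oxidative modification.  Per protein: a uniform random
sequence (background residue frequencies configurable), target residues
labeled by a multinomial draw at the configured class proportions
(default 2%/6%/92%, the imbalance of curated carbonylation benchmarks);
carbonylation neighborhoods receive a planted motif (default probability
0.5, start within ±6 of the site) from a short vocabulary; ligand
neighborhoods receive an aromatic compositional bias plus, at lower
probability, a motif from the same vocabulary — the shared vocabulary is
what makes the two positive classes confusable, so cross-prediction is
observable in synthetic tests.  Edits never overwrite assigned sites or
previously planted motifs (a blocked mandatory planting yields to the
current site only); labels are finalized on the edited sequence, so the
invariants hold exactly and edits perturb only the nonfunctional pool.
PSSM rows are sharpness-weighted one-hots mixed with the uniform
background, floored, renormalized, log2-odds transformed and optionally
noised.  Embeddings are a fixed random projection of the local 3-mer
one-hot plus smoothed positional noise, giving the language-model-like
property that identical residues in identical 3-mers embed near
identically.  All randomness derives from one seed through named
sub-streams keyed per protein, so any subset of outputs is independently
reproducible.

What passing synthetic tests does **not** show: that the predictor works
on real proteomes.  The generator has no residue-frequency realism, no
homology structure, no position-specific chemistry, and its planted
motifs are far cleaner than biological motifs; synthetic results
demonstrate that the machinery behaves as designed (signal is found when
present, calibration holds at random, the loss and transfer mechanisms
act in the right direction), not that its absolute numbers transfer.

## Desk-scale experiment harness

`scans.experiments` runs the design-direction experiments at a size that
trains in minutes on one CPU core: 60 proteins per replicate (~1700
pooled K/P/R/T segments), enriched positives (5%/10%/85%), dense planting
(0.9) with heavy vocabulary sharing (0.5), a 16-dim three-layer attention
stack, 10 epochs at batch 64 with learning rate 0.003.  These conditions
were fixed so the scaled-down model reliably learns above-chance signal —
a comparison of cross-prediction areas is only meaningful for models that
learn at all.  The shortened schedule uses a larger step and smaller
batch than the production defaults to reach a trained model in few
passes.  The overfitting guard is widened to 0.30 here: with ~10 positive
validation examples the AUROC standard error is several times the 0.03
production guard, which would reject nearly every epoch.  The experiment
compares held-out AUCPC for (β = 12, transfer) vs (β = 0, transfer) vs
(β = 12, no transfer) over five seeds.

## Numerical and degenerate-input choices

- Entropies in bits throughout; the log base cancels in IGR.
- MCC = 0 at a zero denominator; F1 = 0 when no prediction and no
  positive exists.
- Tied scores move between classes together; curves are evaluated only at
  thresholds strictly between distinct score values.
- Constant score vectors: curves degenerate to the anchors without error;
  SP-anchored sensitivities report absent with a flag.
- The Anderson–Darling gate treats a zero-variance sample as trivially
  normal (the statistic is undefined there); identical metric vectors
  short-circuit to p = 1.
- Propensity clamp 1e-7; batch-norm ε 1e-5; IGR floor 1e-6 bits.
- Checkpoints are single `.npz` files containing every parameter, the
  batch-norm running statistics, and the embedded network configuration
  with a format version.

## Known limitations

- The IGR denominator is a documented interpretive construction (permuted
  null); other reasonable references (e.g., gain on the negative set
  against a random pattern) would rescale IGR values, though not the
  ranking by enrichment.
- Transfer learning's benefit is regime-dependent: at very small data and
  epoch budgets, joint training can match or beat the frozen-module
  recipe; the desk harness measures direction, not effect size.
- The PSSM and embedding channels are synthetic stand-ins by default;
  real profiles (from a profile search) and embeddings plug in through
  the reader and provider interfaces but are not fetched by this package.
- Per-residue-type models are independent; no parameter sharing across
  K/P/R/T is attempted.
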