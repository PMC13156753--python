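# Methods

## The problem

A multiallelic (MA) immunopeptidomics sample expresses up to six class-I
HLA alleles; mass spectrometry identifies which peptides were MHC-bound but
not which allele presented each one. `mhcassign` treats this as a multiple
instance learning (MIL) problem: the observed peptide defines a *bag*, each
candidate (peptide, allele) pair an *instance*, and supervision may be
available only at bag level ("presented by some allele"). Around the
classifier sit the pieces a realistic evaluation needs: hard-negative decoy
construction, operating-point assignment, benchmarking at the class
imbalance that governs real discovery, and a hydrophobicity analysis of
elution-condition bias.

## Decoy construction

Positives alone do not define a learning problem. Negatives are built from
the positives themselves: each observed ligand is mapped to the proteins it
occurs in, and only ligands matching **exactly one** protein are used
(multi-mapping and unmapped ligands are reported, not silently dropped).
All 8–11mer fragments of those source proteins are enumerated
(count per protein = Σ_k max(0, L−k+1), k = 8..11), candidates overlapping
known positives are removed, and the survivors are restricted to *hard*
negatives: fragments a binding-affinity predictor scores at or below
2000 nM for the paired allele. The boundary is inclusive by default and
configurable, since both conventions appear in practice. Final decoys are
drawn uniformly without replacement at `ratio`:1 to the positives;
candidates are canonically sorted by (protein, start, length) before the
seeded draw, so the result depends only on the candidate *set* and the
seed, never on file order. The test-time ratio default is 1000:1 —
roughly the number of combinatorially possible fragments per observed
ligand — while desk-scale training uses 50:1.

## Model

One transformer encoder (pre-LN, default 2 layers, width 64, 4 heads,
feed-forward width 2×, learned positional embeddings) is shared between
peptides and HLA binding-groove pseudosequences. Sequences are tokenized
over the 20 canonical residues plus [CLS]/[PAD], right-padded only to the
batch maximum; the attention mask removes padded keys from every softmax,
which makes the pooled representation *exactly* invariant to batch
composition (asserted in tests at 1e-5). The sequence vector is a tanh
projection of the final [CLS] state.

An instance is h_i = [peptide vector ; HLA vector]. A classifier MLP
(hidden 128) maps any embedding to a logit; tanh attention
(a_i ∝ exp(w·tanh(V h_i)), hidden 128; a gated variant is available)
aggregates instances into bag = Σ a_i h_i. The *same* MLP head scores
instances and bags, which (a) makes the single-instance identity exact —
a monoallelic record's bag probability is its instance probability — and
(b) lets bag-level supervision train the instance scores. Monoallelic-style
records are therefore just single-instance bags; no separate loss stream or
mixing weight is needed.

Training: BCE-with-logits on smoothed targets y′ = y(1−ε)+ε/2 with ε = 0.1,
AdamW (lr 1e-4, decoupled weight decay 1e-4), batch 512, gradient
accumulation 2, early stopping on validation loss with patience 10 and
best-validation weight restore. Peptide-level split leakage raises.
The defaults mirror the published recipe for fine-tuning a pretrained
protein language model; the from-scratch desk-scale experiments use lr 1e-3
because the small randomly initialized encoder needs a larger step size to
converge in a few epochs.

At prediction time all peptide × allele pairs of a sample are scored;
optionally an affinity pre-filter removes instances above 2000 nM before
attention is applied (filtered instances are reported with a flag and NaN
probability; a fully filtered bag is reported not-presented rather than
raising). Attention renormalizes over the surviving instances.

The whole stack runs on a ~300-line NumPy reverse-mode autodiff core
(float32 by default; float64 in gradient tests). Every primitive's gradient
is checked against central finite differences, including the fused
layer-norm and the embedding scatter.

## Assignment and confirmation

Instance probability ≥ 0.5 (inclusive) defines ordinary assignment;
monoallelic assignment requires **exactly one** allele at ≥ 0.95 —
ambiguous peptides are excluded, not arbitrated. External predictor tables
are ingested as generic (peptide, allele, %Rank) rows with the conventional
≤ 2 cutoff (inclusive; a strict exclusive mode, e.g. < 0.05, is available),
and a quantile-matching helper picks a threshold reproducing a target
assignment count. Overlap analysis partitions two predictors' pair sets
into shared/unique and confirms each partition against a single-allelic
reference on exact (peptide, normalized allele) — no peptide-only fallback,
since allele-matched confirmation is the point. A `min_year` option drops
older reference records first (the stricter benchmark restricts references,
never predictions); per-source confirmation counts are retained.

## Benchmarking

Average precision is the non-interpolated mean of precision at each
positive's rank (an interpolated variant exists behind a flag); PPV@k is
the positive fraction among the k top-ranked items. Ties are always broken
by (score descending, stable input index) — breaking ties by label would
inflate every metric. Both metrics are tested for exact agreement with
brute-force rank-walk oracles on 1000 random instances, and AP against
scikit-learn on tie-free inputs.

The resampling protocol draws, per iteration, n_pos positives and
n_pos × neg_ratio negatives without replacement (defaults 500 and 1000:1 →
500,000 negatives per iteration, 100 iterations) and reports
across-iteration mean ± sd of AP and PPV@{10,20,50,100} plus a pointwise
precision band on a 200-point recall grid. The sd is across iterations, not
a binomial approximation. Analytic limits pin the implementation down: a
perfect scorer gives AP 1.0 with sd 0, and a uniform-random scorer at r:1
imbalance concentrates at prevalence 1/(r+1) ≈ 0.000999 for r = 1000.

## Hydrophobicity

GRAVY is the mean Kyte–Doolittle hydropathy (the scale is pluggable). The
anchor-weighted variant counts anchor-position residues twice and divides
by (9 + number of anchors) — a true mean over the duplicated multiset, so
an empty anchor set reduces exactly to GRAVY and homopolymers are
invariant. It is defined for 9mers only; per-allele means drop non-9mers
with a logged count. Default anchors are {2, 9} (P2 and PΩ, the canonical
class-I anchors), overridable per allele. Fold changes between elution
conditions compare per-allele *shares* of the immunopeptidome by default
(FC = (n_b/N_b)/(n_a/N_a)); raw count ratios are available, and zero
denominators exclude the allele with a warning instead of raising. The OLS
regression (slope t-test, n−2 df) delegates to scipy and is verified
against the closed form at 1e-10.

## Synthetic data

A motif is a per-length PWM: anchor positions place mass
`anchor_concentration` uniformly on that position's anchor residues and the
remainder uniformly on the rest; non-anchor positions are uniform (so
concentration 1/20 with one anchor residue is exactly the uniform PWM).
Lengths default to 70% 9mers and 10% each of 8/10/11mers, echoing the
class-I length bias. Ligands are planted into i.i.d.-uniform background
proteins on non-overlapping stretches; a placement that leaves the ligand
occurring twice anywhere in the proteome is reverted and retried, so the
decoy pipeline's unique-mapping rule holds at 100% by construction.

The affinity surrogate scores PWM log-likelihood, min-max scaled to
s ∈ [0,1] against a seeded reference sample of uniform random peptides, and
maps s to pseudo-nM via nM = 50000^(1−s) (s=1 → 1 nM, s=0 → 50,000 nM). It
exists so the ≤ 2000 nM rule is exercisable end to end; any external
predictor satisfying `predict(peptide, allele) → nM` plugs into the same
interface.

What the generator does **not** model: residue correlations, non-anchor
preferences, MS detectability, elution chemistry, PTMs. Passing tests
demonstrate that the machinery is correct and that allele deconvolution
works when motifs are informative — not that the model reaches
literature-level performance on real immunopeptidomes.

## The two-allele experiment

The end-to-end check: two alleles with disjoint four-position anchor motifs
(anchor concentration 0.9), 500 ligands per allele planted in a 150 × 320
proteome, hard negatives at 50:1, a 70/15/15 peptide-level split, the
default encoder (2 layers, dim 64), 8 epochs at lr 1e-3, batch 512. Four
anchor positions were chosen by design arithmetic: with two anchors, a
fully motif-matching decoy arises at rate (1/20)² among fragments, and at
50:1 imbalance the posterior P(presented | fully matching) is only ~0.4;
with four anchors it is ≈ 0.997, so a correct model can actually be
confident. The proteome size guarantees the hard-negative pool exceeds the
requested 50,000 decoys. Half the training ligands are represented as
monoallelic-style single-instance bags: with *only* symmetric two-allele
bags the presenting allele is unidentifiable (the bag likelihood is
invariant to which instance carries the signal), and the model was observed
to break the symmetry arbitrarily per peptide; the monoallelic stream
anchors instance scores to alleles, as monoallelic datasets do in real
training corpora.

Evaluation runs the full predict pipeline (surrogate affinity pre-filter,
re-aggregation) on held-out peptides and reports instance-level AUROC
against the generative ground truth (≈ 0.99), top-instance allele recovery
(≈ 0.99), and strict monoallelic assignment accuracy.

**A calibration interaction worth knowing about.** With label smoothing
ε = 0.1 the loss-optimal output for a perfectly pure positive group is
exactly 1 − ε/2 = 0.95, and strictly below 0.95 for any group containing
hard negatives — and the hard-negative construction guarantees every
feature group contains some. A converged, well-calibrated model therefore
produces *no* scores at or above the strict 0.95 operating point; whether
any held-out ligand crosses it depends on transient optimizer overshoot and
varies by seed (some training runs assign a few dozen ligands, all
correctly; others assign none). Whenever the assigned set is nonempty its
accuracy has been 100% in our runs, but the *existence* of strict
assignments at a threshold equal to the smoothing ceiling is not a robust
property of a calibrated model. Operating points strictly below 1 − ε/2
(e.g. 0.9) do not have this problem.

## Problem sizes and numerics

Default experiment sizes (500 ligands/allele, 50:1 decoys, 8 epochs) keep a
full run under two minutes on one CPU core; the resampling protocol at the
full 500 / 500,000 scale runs 100 iterations in about a minute. Attention
masking uses an additive −1e9 before softmax; probabilities are produced by
a numerically stable sigmoid; BCE uses the softplus form
softplus(z) − y′z. Degenerate inputs (empty bags, empty partitions,
zero-count alleles, exhausted decoy pools) are defined behaviors — report,
warn, or exclude — never crashes.
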