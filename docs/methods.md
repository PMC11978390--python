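# Methods

## The prediction problem

A chemical perturbation instance is a triplet: a small molecule *m*, a
cancer cell line *c*, and the signed differential-expression (DEG) profile
Y_G ∈ R^|G| of the landmark genes measured after treating *c* with *m*
(positive = up-regulated).  The model predicts Ŷ_G = f(m, c) and is judged
on how well it *ranks* genes by differential expression, separately for the
up- and the down-regulated tail — the quantity that matters for
connectivity-map-style signature matching and drug repurposing.

In the reference configuration there are 978 landmark genes, 140 pathways
overlapping those genes, and 114 anchor cell lines; all three are plain
configuration numbers here and every component works at any scale.

## Input representations

**Molecules.**  The SMILES string is decomposed with the BRICS
retrosynthetic rules into *k* fragments (a molecule with no cleavable bond
is its own single fragment).  Fragments are ordered lexicographically by
canonical SMILES so attention matrices are comparable across runs.  Each
fragment is hashed to a folded 1024-bit Morgan fingerprint of radius 2,
giving F ∈ {0,1}^{k×1024}.  BRICS attachment points (`[14*]` etc.) are kept
in the fragment SMILES for display but replaced by hydrogens before
hashing, so a fragment's bits reflect its chemistry, not its cleavage
labels.

**Cell lines.**  A cell line is represented by the vector of Spearman rank
correlations between its basal (untreated) expression profile and the
profiles of the anchor panel — the training-fold cell lines.  An unseen
cell line therefore needs only a basal profile, never an identity slot;
anchors for each cross-validation fold are restricted to that fold's
training cells so no test-cell information leaks into the embedding.

## Architecture

Encoders (one MLP each) map F to fragment embeddings X_M ∈ R^{k×d} and the
similarity vector to a cell embedding x_C ∈ R^d.  The cell embedding is
row-repeated, concatenated with X_M and fused by an MLP into fragment-wise
perturbation embeddings X_{M+C} ∈ R^{k×d}.  Three attention blocks follow:

1. **Perturbation→pathway (PPAB).**  A learnable pseudo-fragment token p_F
   is appended to X_{M+C} (always the last row).  140 trainable pathway
   embeddings query the k+1 keys through multi-head cross-attention.  The
   head-averaged post-softmax matrix A ∈ R^{140×(k+1)} is row-stochastic;
   the per-pathway association score Ŷ_P[p] = Σ_{j≤k} A[p,j] = 1 − A[p,k+1]
   is the probability mass the pathway places on *real* fragments.  The
   pseudo-token exists so that a pathway untouched by the drug has
   somewhere to park its attention; regularization (below) makes Ŷ_P a
   calibrated drug–pathway association readout.
2. **Pathway→gene (PGAB).**  Trainable gene embeddings query the
   perturbation-contextualized pathway embeddings; no pseudo token and no
   regularization.
3. **Gene→gene (GGAB).**  Self-attention over gene embeddings (no
   positional encoding, hence exactly permutation-equivariant over gene
   rows).

Between PGAB and GGAB the mean-pooled X_{M+C} (pseudo row excluded) is
row-repeated and fused with the gene embeddings, preserving molecule/cell
information in the gene states.  Finally one small two-layer feed-forward
head per gene (implemented as a batched weight slice; semantically 978
independent heads) emits that gene's signed DEG value.

Each attention block is a single pre-norm residual layer (layer
normalization → attention → residual, then layer normalization →
position-wise MLP → residual).  Activations are GELU.  Defaults: d = 128,
4 heads, MLP width 256, head width 32, dropout 0.1 — all configurable; the
synthetic benchmark uses a proportionally smaller model (below).

The `use_ppab=False` ablation removes block 1: the static pathway table
feeds PGAB directly, and no attention readout Ŷ_P exists.

## Objective

Per instance, with α = 0.05:

    L = RankCosine(Ŷ_G, Y_G) + MSE(Ŷ_G, Y_G) + α · CrossEntropy(Y_P, Ŷ_P)

RankCosine is ½(1 − cos(Ŷ_G, Y_G)) ∈ [0,1] (scale-invariant; a zero-norm
prediction is treated as orthogonal, 0.5, and logged).  The attention
regularizer is the mean binary cross-entropy of Ŷ_P (clamped to
[1e-7, 1−1e-7]) against the binary drug–pathway labels Y_P, built by
marking every pathway linked to a target of the drug.  Instances without
target annotations contribute no regularization term.  Training uses Adam
(default lr 1e-4, batch 64, up to 100 epochs, gradient-norm clip 5);
minibatches are processed one instance at a time with gradient
accumulation, so variable fragment counts need no padding or masking and
an instance's outputs are independent of its batch companions by
construction.

The implementation runs on a small reverse-mode autodiff engine over numpy
(`badger._autodiff`, `badger.nn`) whose gradients are verified against
central finite differences in the test suite.

## Evaluation

NDCG (0–100): relevance of gene *i* is max(s·y_i, 0) with s = +1 for the
up direction, −1 for down; genes are ranked by s·ŷ descending with
ascending-index tie-break, discounted by log2(rank+1) over the full list,
and normalized by the ideal ordering.  The gain/discount convention is a
package choice (conventions vary across the literature), so absolute NDCG
values are comparable within this package, not across tools.  P@K (0–100): the fraction of the top-K predicted genes (signed,
direction-aware) found in the truth's top-`ref_size` set (200 at full
scale; scaled down with small synthetic gene panels).  Down-regulation
reuses the up-direction machinery on negated vectors.

Cross-validation regimes: `new_cell` partitions cell lines, `new_drug`
partitions molecules, `new_pair` partitions both and keeps only test
instances pairing a held-out cell with a held-out drug, discarding
train/test-mixed instances (counts logged).  Leakage is checked by hard
assertion on every fold.

## Synthetic world

The generator plants exactly the causal structure the model assumes:
fragments → pathways → member genes.  A drug is a bag of 2–4 fragments from
a vocabulary of V fragments; fragment–pathway links are Bernoulli(sparsity
= 0.12); a drug's binary label vector is the union of its fragments'
links.  The DEG profile of (drug d, cell c) is

    y_g = Σ_{p active for d} β_p · m_{c,p} · member_{p,g} + ε_g,
    ε_g ~ N(0, noise_sd²)

with pathway effect sizes β_p uniform in ±[0.5, 1.5] (signs balanced so
both directions occur), multiplicative lognormal(0, 0.4) cell modifiers
m_{c,p}, and disjoint equal-size member blocks when the gene count allows.
Basal expression is pathway-structured (m @ members plus gene-level noise)
so Spearman cell similarity is informative about shared pathway modifiers.

Default world: 40 drugs, 6 cells, 12 pathways, 60 genes, noise_sd 0.1,
V = 16 fragments, 240 sampled instances.  V was set so that the planted
labels are statistically identifiable from the ~32 training drugs of a
held-out-drug split: an independent per-pathway logistic regression from
fragment membership to labels reaches AUROC ≈ 0.98 across seeds, so a
shortfall of the attention readout indicts the model, not the benchmark.
With a larger vocabulary (V = 30) the same oracle ceiling drops to ≈ 0.89
because fragments co-occur too rarely to disambiguate credit — a benchmark
defect, not a model property.

Two molecule modes: `abstract` (fragments are random binary codes; no
chemistry involved, n_bits = 64) and `smiles` (drugs assembled from a
built-in pool of parseable fragment SMILES, exercising the BRICS/Morgan
path).

What the world does *not* emulate: plate/replicate noise structure,
signature-strength (TAS) biology (contaminated TAS/QC/dose values are
injected independently at configurable rates purely to exercise the
filters), correlated pathway membership, or realistic fingerprint
collision statistics.  Passing the recovery benchmark therefore shows the
architecture and losses can extract planted fragment→pathway→gene signal
end to end; it says nothing about absolute performance on real
perturbation corpora.

## Recovery benchmark

`synthetic_world.run_recovery_benchmark(seed)` trains on fold 0 of a
5-fold held-out-drug split of the default world and reports, on the
held-out instances: (a) AUROC of Ŷ_P against the planted labels, (b) mean
NDCG (both directions) of Ŷ_G against the realized profiles, and (c) the
same NDCG under a permuted pairing of predictions to truths (the null).
The benchmark model is scaled to the world: d = 32, 2 heads, MLP width 64,
head width 8, dropout 0.1, trained 300 Adam steps at lr 3e-3, batch 64,
α = 0.05.  The step size is larger than the full-scale default because the
benchmark model and dataset are orders of magnitude smaller; it was fixed
together with the benchmark, and the acceptance checks average three
seeds.  The ablated variant (`use_ppab=False`) trains under identical
settings; having no pathway readout, its label alignment is chance by
construction, and its held-out NDCG is consistently below the full
model's — the pathway bottleneck helps ranking even on synthetic data
whose generative process matches both variants' fusion path.

## Repurposing screen

Candidates are compared with a reference drug in a fixed cell context on
four [0,1] criteria: Jaccard overlap of attended pathway sets (pathways
with Ŷ_P above a threshold, default 1/(k+1) — the uniform-attention
baseline), symmetrized mean-best-match Tanimoto similarity of attended
fragments (column-max attention above the same threshold; the pseudo
column is never attended), and Jaccard overlaps of the top-200 up- and
down-regulated predicted gene sets.  The final score is the arithmetic
mean of the four; candidates are ranked by it (name tie-break) and drugs
classified anti-cancer (explicit annotation, else the "-ib"
kinase-inhibitor suffix convention) are excluded from the shortlist.  The
choice of Jaccard for the set overlaps and of mean-best-match Tanimoto for
fragments is a package decision: the published screening procedure reports
set "similarity" without naming a coefficient.

## Numerical conventions and degenerate inputs

* Attention rows are softmax outputs and sum to 1 within 1e-6 after head
  averaging.
* Spearman correlation with a constant vector is an error (undefined), as
  is an all-zero truth profile in RankCosine.
* All-zero relevance in NDCG (no gene moved in that direction) scores a
  vacuous 100 and is logged.
* Ties anywhere in ranking are broken by ascending gene index, making every
  metric permutation-stable and reproducible.
* Dose/time filtering is exact equality after parsing (the upstream
  metadata is categorical at those levels); the TAS filter is strict
  (`tas > 0.2` retained).
* Seeds flow explicitly: world and dataset generation, fold partitioning,
  parameter initialization, dropout and batch shuffling each consume a
  deterministic generator, so fixed-seed runs are bit-reproducible on one
  machine.

## Known limitations

* Pathway and gene embedding tables initialize from a seeded normal
  (sd 0.02); initializing them from externally derived vectors (ontology-
  or corpus-based) is supported through `load_state_dict` but no such
  vectors ship with the package.
* Single attention layer per block; no dose/time conditioning (the
  filtered corpus is single-dose by construction).
* The numpy engine is single-threaded and meant for the synthetic scale;
  full-corpus training (tens of thousands of instances, d = 128, 978
  genes) would require a GPU tensor backend behind the same interfaces.
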