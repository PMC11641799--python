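# Methods

## Experimental design the pipeline models

A clonal plant line is split into a control lineage (P1CK) and a stressed
lineage (P1S) during a first cultivation stage (P1), the stressed lineage is
propagated under control conditions for two further stages (P2, P3), and
both lineages are re-exposed in a fourth stage (P4). Five RNA-seq groups
exist — CK, S, P1S–P2CK, P1S–P3CK, P1S–P4S, three replicates each — so every
differential-expression contrast uses the single P1 control group as
reference; no stage-matched control is available, and that limitation is
inherited by everything downstream. Trait phenotyping covers all stages and,
at P4, the full lineage × condition quadruple needed for reaction norms.

## Differential expression

Counts are modelled as negative binomial with mean m and dispersion φ,
variance m + φm². The steps:

* **Normalization** — median-of-ratios size factors over genes positive in
  every sample, rescaled to geometric mean 1. An input where no gene is
  expressed everywhere is refused with a pointer to filtering.
* **Dispersion** — per-gene method of moments, φ̂ = max(0, (var − mean)/mean²)
  on normalized counts, pooled across replicate groups with (n_g − 1)
  weights, then shrunk 50% toward a hyperbolic trend φ_tr(μ) = a + b/μ
  fitted by least squares over all genes. The shrinkage stabilises the very
  noisy 3-replicate estimates; the 50/50 weight is a fixed design choice,
  not data-tuned per run.
* **Wald test** — group means of normalized counts (all-zero group means
  floored at 0.5 so the fold change is defined), delta-method SE of
  log2(m_B/m_A) from Var(m̂) = (m + φm²)/n, two-sided normal p, BH across
  genes, and a ternary direction call at p_adj < 0.05 and |log2FC| > 0.5.
  The fold-change gate is applied to both signs because both up- and
  down-regulated sets are biologically meaningful here. Fold changes are
  not shrunk.

A type-I-error check is part of the acceptance suite: on fully null
simulations the raw rejection rate at 0.05 stays within [0.03, 0.07] and
the BH-significant fraction below 0.01.

## Transcriptional memory identification

Memory is defined on the ternary direction calls, not on magnitudes: a
"same pattern" means the identical direction (sign and significance). The
three steps are pure set operations — robust responsive (d_P1 = d_P4 ≠ ns),
TMG2 (∩ d_P2 = d_P1), TMG3 (∩ d_P3 = d_P1) — and are therefore tested
against brute-force enumeration. The residual taxonomy is fixed as:
transient = differentially expressed in exactly one contrast; fluctuating =
DE in ≥ 2 contrasts with conflicting signs and not robust. A gene DE in two
or more contrasts with a consistent sign but not robust (e.g. up in P1 and
P2 only) matches none of these definitions and is reported non-responsive;
the category is intentionally narrow rather than overloaded. The gene
universe is the intersection of genes tested in all four contrasts.

One ambiguity in the source material deserves a note: the figure legend of
the original study defines TMG3 as the intersection of TMG2 with the P4
contrast, while the methods text says the P3 contrast. The P3 reading is
implemented — it is the only one that adds information beyond TMG2 (TMG2
already conditions on P4), and it matches the stated meaning of "memory
persisting into the third generation".

## Trait statistics

Fisher's LSD pools the within-group variance of all k groups (one-way
ANOVA MSE, df = N − k) and performs unprotected pairwise t tests; the
omnibus F is reported alongside but not used as a gate, since the source
protocol does not state a protected procedure. With MSE = 0 the test is
degenerate: p = 1 for zero differences and p = 0 (flagged) otherwise.
Compact letter displays are built greedily from the pairwise p-matrix in
descending-mean order.

The weaken/strengthen classifier operationalizes the comparative phrasing
of the trait definitions with explicit deltas: Δ_CK = mean(P1CK–P4S) −
mean(P1CK–P4CK), Δ_S = mean(P1S–P4S) − mean(P1S–P4CK), and L = LSD p of the
lineage contrast under stress. Weaken requires both deltas negative with
Δ_S > Δ_CK and L < 0.05; strengthen both positive with Δ_S > Δ_CK and
L < 0.05; everything else is unclassified. The two classes are *not* mirror
images — weaken is "less of a decrease", strengthen "a greater increase" —
so negating a trait's unit does not swap the labels; only positive affine
rescaling is invariant. P1 dose–response behaviour is descriptive and does
not enter the classifier.

2^−ΔΔCt is implemented as the standard closed form over a Ct quadruple and
as a tidy-table version keyed by a calibrator sample.

## Co-expression network

Expression input is the DEG union (any non-ns call in any contrast) in
FPKM-like units; inside the pipeline, counts divided by size factors stand
in for FPKM (gene length is a constant per gene and cancels in per-gene
z-scores). Standardization is log2(x+1) followed by per-gene z-scoring,
with genes missing in > 50% of samples or with zero variance removed
(quantile normalization is available behind a flag). The network is
unsigned, a_ij = |PCC|^β with β = 20 by default; the soft-threshold scan
reports the signed scale-free fit R² (log10 p(k) vs log10 k over ten
equal-occupancy bins, sign from the slope) and mean connectivity per power.

Topological overlap uses ω_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 −
a_ij) with unit diagonal; modules come from average-linkage clustering of
1 − ω with a *static* height cut — a grid of heights is scanned from just
below the tree top and the height maximizing the number of clusters of at
least 30 genes is kept — rather than the dynamic hybrid cut; the
simplification is validated by planted-module recovery (adjusted Rand
index ≥ 0.9 on 5 planted blocks at both β = 6 and β = 20). Modules whose
eigengenes correlate ≥ 0.75 are merged iteratively, largest module name
surviving. Eigengenes are the first right singular vector of the
gene-centered module submatrix, sign-aligned to the module's mean profile.

Module–trait association maps each RNA sample to its group's trait mean
(5 groups × 3 replicates = 15 paired observations) — an approximation, as
trait replicates are not paired with RNA replicates — and flags modules
with PCC > 0.5 and p < 0.05 (t approximation, df = n − 2). The positive-PCC
convention works for both response signs because eigengene sign is aligned
to module expression: a down-regulated module's eigengene falls under
stress exactly as a weaken trait does. Module classes
(weaken-/strengthen-related/other) resolve conflicts by larger |PCC|.

Edges are ranked by TOM weight (adjacency ranking available) and the top
30% kept; degree on that filtered graph defines hubs, the top
ceil(0.10 × module size) genes per module, ties broken by incident weight
then gene id. TMG enrichment per module class uses the inclusive TMG2 set
(TMG3 ∪ TMG2-only) and a 2×2 Fisher exact test of trait-related vs other
module genes.

## Synthetic-data generator

The generator is the ground-truth instrument for the whole pipeline, not a
fixture. Counts: NB with per-gene baseline log-uniform on [20, 2000]
(keeping the Poisson term 1/m small relative to φ), dispersion log-uniform
on [0.01, 0.5] (typical bulk RNA-seq range), library-size factors uniform
on [0.7, 1.4] to exercise normalization. Planted classes: memory genes
respond at log2FC = base (default 2.0) in S, attenuated by 0.7 at P2 and
0.5 at P3, and amplified by 1.2 at P4 (re-exposure priming); tmg2_only
genes lose the P3 effect; transient genes respond only in S; fluctuating
genes alternate sign (+, −, +, −) at full amplitude. Defaults plant 150 +
150 TMG3, 100 + 100 TMG2-only, 200 transient, 200 fluctuating among 5000
genes — a DEG share comparable to the motivating study's.

Traits: Gaussian replicates (default 6 per cell, matching the phenotyping
protocol's average replication) around deterministic cell means: weaken
traits drop by the full effect under stress but only half of it in the
stressed lineage at P4; strengthen traits rise symmetrically with a 1.5×
overshoot; recovery stages carry a decaying residual (30%, 10% of the
effect) in the stressed lineage, which couples trait profiles to planted
memory-gene expression across the five sequenced groups. Default noise SD
is 5% of the effect size; the study reports no within-group variances, so
this is a free parameter chosen once.

What the generator does **not** emulate: gene–gene correlation beyond the
planted classes (null genes are independent), GC/length biases, outlier
samples, batch effects, or count–trait coupling through shared noise.
Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability of planted signal, not performance on real
libraries.

## Problem sizes and known limitations

Test and acceptance runs use the default 5000-gene scenario for memory
recovery (10 seeds), 2000-gene null simulations (10 seeds), 500-gene
planted-module networks, and 200-seed trait-classifier Monte Carlo; these
sizes give stable estimates while keeping a full run in seconds.

With three replicates and dispersions up to 0.5, the attenuated recovery
contrasts (log2FC of 1.4 at P2 and 1.0 at P3) are power-limited: an oracle
z-test with known dispersion has two-sided power below 0.75 for the ~23% of
genes with φ ≥ 0.2 at P2, and TMG2 membership requires a joint pass in P1,
P2 and P4. Measured TMG2-union sensitivity at the default scenario is
therefore ≈ 0.77 (FDR ≈ 0.014); the dominant error mode of the three-step
intersection is missed memory genes, not false ones. Real designs wanting
higher memory-gene sensitivity need more replicates, not a different test.

In the unsigned network, up- and down-regulated memory genes co-cluster
(|cor| ignores sign), so synthetic runs typically yield one large
memory-gene module associated with both trait classes through the shared
reaction-norm shape; a signed network would separate them but is not what
the reference workflow uses.
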