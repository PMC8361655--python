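# Methods

## Model and assumptions

The pipeline treats a condition-versus-control transcriptomics study as a
three-layer object: (i) two expression matrices (miRNA and mRNA), assumed
already normalised and log2-transformed; (ii) a global miRNA→target
catalog, treated as an opaque input (its provenance — validated versus
predicted interactions — is recorded but not re-derived); (iii) a scored
PPI catalog in the STRING convention (combined score in [0, 1], optional
evidence-channel flags). The condition-specific network is the
intersection of the catalogs with the differentially expressed feature
lists; all set operations run on canonicalised identifiers (mature miRNA
names without the species prefix, e.g. `miR-145-5p`; upper-case gene
symbols) so that case or prefix variation cannot silently drop edges.

The central modelling idea is that a miRNA's regulatory importance is the
topological importance of its targets: genes that are simultaneously
high-degree, high-closeness and high-betweenness in the condition PPI
layer (the CORE set) carry more weight than peripheral targets, and a
biomarker candidate is a miRNA whose overall reach (NTG_A) *and* CORE
reach (NTG_C) are extreme relative to every other miRNA in the network.

## The exceedance test

Significance of "extreme" is decided by a one-sided exact Wilcoxon
signed-rank test applied to the paired differences between the
candidate's value and each other miRNA's value. Zero differences are
dropped before ranking (Wilcoxon's convention, not Pratt's); tied
absolute differences receive midranks. Because midranks may be
half-integers, the implementation doubles all ranks and convolves an
exact integer generating function over the 2^n sign assignments, so the
null distribution is exact for any tie pattern (Python integers; no
floating-point accumulation). The reported p is P(W ≥ w_obs). A Gaussian
approximation with tie-corrected variance and continuity correction is
available by explicit opt-in for very large backgrounds, where the exact
convolution is unnecessary; it is deliberately not the default because
the interesting p-values sit in the far tail, where the Gaussian is off
by orders of magnitude.

Two structural consequences are worth knowing. First, the minimal
achievable p is 2^-n_eff: a candidate strictly above all 30 others gets
p = 2⁻³⁰ ≈ 9.31e-10 regardless of margins. Second, ties are the test's
specificity mechanism: values shared by many miRNAs drop out of n_eff,
so a moderately high count that ties with much of the background cannot
reach significance, while the same count in a spread-out background can.
On smooth, tie-free backgrounds the two-step screen therefore behaves
like an upper-tail selector and can nominate an occasional non-planted
hub alongside the planted biomarkers; the recovery guarantee the test
suite enforces is sensitivity (planted candidates found), not perfect
specificity on every random background.

Step 2's background is all other miRNAs by default. The alternative —
restricting the NTG_C background to Step-1 survivors — is available via
`step2_background="survivors"`; with a single survivor it degenerates
(empty background, p = 1), which is why it is not the default.

## Differential expression

The moderated t follows the standard empirical-Bayes hierarchy: sample
variances s²_g on d residual degrees of freedom are modelled as scaled-F
around a prior s₀² with d₀ degrees of freedom. The prior is fitted in
closed form by moment matching on e_g = log s²_g − ψ(d/2) + log(d/2):
the sample variance of e in excess of ψ′(d/2) equals ψ′(d₀/2) (solved by
Newton's method on the trigamma), and s₀² follows from the mean of e.
Zero-variance features contribute nothing to the moment fit but are still
shrunk toward s₀² (they get t = 0 rather than NaN); if every feature has
zero variance the fit aborts with an error. Setting the prior weight to
zero reproduces the ordinary pooled t exactly; an infinite prior pins all
variances at s₀². The implementation is cross-checked in the test suite
against the canonical R implementation (limma) to 1e-6 and against an
independent step-by-step re-derivation to 1e-10.

BH adjustment is delegated to statsmodels and verified against the
step-up definition exhaustively for small inputs. The DE cutoff is a
strict inequality (adj. p < 0.05); probe collapse keeps the probe with
the smallest adjusted p, breaking ties by larger |logFC| and then by
probe identifier so results are independent of input order.

## Topology conventions

Closeness uses the component-local node count N (the Cytoscape-style
convention): CC(i) = N_c / Σ d(i, j) over i's component, singletons
defined as 0. Using the global N instead only rescales closeness within
each component and cannot reorder genes inside a component; a flag
exposes the global convention for comparison. Betweenness sums over
unordered pairs with endpoints excluded and is reported unnormalised, as
the defining formula has no normalisation. CORE membership uses strict
inequalities against arithmetic means over PPI-layer genes only; genes
outside the PPI layer have no centralities and are never CORE (they still
count toward NTG_A). Degree-distribution slopes are ordinary least
squares on (log2 degree, log2 fraction) over observed positive degrees —
matching how such plots are conventionally drawn — rather than a
maximum-likelihood power-law fit; with fewer than two distinct degrees
the slope is reported as missing.

## MCODE

The three-stage algorithm is re-implemented from its published
description: (1) every node is weighted by k·density of the highest
k-core of its closed neighbourhood (nodes below the degree cutoff, 2 by
default, weight 0); (2) complexes grow from the highest-weighted
unassigned seed, including neighbours whose weight is within
`node_score_cutoff` (0.2) of the seed's, never revisiting assigned
nodes, to a depth limit of 100; (3) complexes lacking a 2-core are
dropped, and the haircut removes members of within-complex degree < 2 in
a single simultaneous pass (the published behaviour; an iterative
variant is available by flag). Fluff is off, so complexes are disjoint.
Tie-breaks are fully deterministic — seeds ordered by (weight
descending, identifier ascending), neighbours visited in sorted order —
making output invariant to input row order and node relabeling. Scores
are density × size; ranking ties break by size, then smallest member.

## Evaluation

AUC uses the rank/Mann–Whitney convention with half-credit for ties and
is reported for the stated orientation — a biomarker that is *low* in
cases scores below 0.5, and the CLI's `--auto-flip` reports 1−AUC with a
note rather than silently flipping. The combined signature is an
in-sample logistic fit (IRLS, convergence when the largest coefficient
step < 1e-8, ≤ 100 iterations), matching the single-split workflow of
small biomarker studies; no cross-validation by default. Perfect
separation — routine when a planted effect of two log2 units separates
the groups — is detected by divergence and handled by refitting with a
small ridge penalty (λ = 1e-4, intercept unpenalised), which leaves the
score ranking, hence the AUC, unchanged. Constant predictor columns are
dropped with a warning.

## Synthetic data: what it emulates and what it does not

`gen_expression` draws i.i.d. Gaussian log2 intensities around
per-feature baselines (baseline mean 8, SD 1.5 across features; noise
σ = 0.5 per sample) and shifts planted features by ±Δ (default 2 log2
units) in the case group, with 6 case and 6 control samples — the scale
of a small rejection-biopsy cohort. At this design point planted
features are recovered essentially always and the null type-I rate is
binomially calibrated; both are asserted in the tests.

`gen_catalogs` draws background miRNA out-degrees from a discrete power
law (exponent −1.3, support 10–100, capped at 60 by default) so miRNAs
with many targets are few, and plants `n_biomarkers` miRNAs at a fixed
high out-degree (250) whose targets include the entire planted module.
The PPI catalog places a dense 12-gene module (internal density 0.8,
high-confidence scores ≥ 0.7) at the centre and attaches all other genes
by super-linear preferential attachment (weight ∝ (degree+1)³, 3 edges
per gene), condition genes first: the condition-specific subnetwork is
then hub-centred and degree-skewed — few central genes, most targets at
the border — which is precisely the regime in which the CORE construct
is meaningful. Background edge scores are Uniform(0.4, 1), so the
0.7 confidence filter removes about half of them; the dense module's
high-confidence scores reflect the fact that curated complexes carry
strong evidence, and keep the module's density intact through the
filter. The super-linear attachment exponent is what keeps non-module
genes out of CORE: with linear attachment, early-attached periphery
genes accumulate enough degree to enter CORE and their incidental
regulation produces spurious screen candidates.

Not emulated: array-level artifacts (background correction, batch
effects), correlated expression between a miRNA and its targets, probe
layers by default (a probe map can be supplied to exercise collapse),
and the gene-side popularity skew of real target catalogs. Passing the
recovery tests therefore demonstrates that the pipeline's inference
chain is correct under its own assumptions, not that the method's
specificity or the reported effect sizes transfer to real cohorts.

## Problem sizes and numerical choices

The test suite runs the full pipeline over 50 seeds at the default
design point (300 miRNA features, 2000 gene features, ~30-miRNA /
~300-gene condition networks) — chosen to mirror the scale of the
networks this method is meant for while keeping a full 50-seed sweep
under a minute. Exact signed-rank convolution is integer arithmetic
throughout; BH and hypergeometric tails come from statsmodels/scipy;
centralities come from networkx (Brandes betweenness), rescaled to the
closeness convention above and verified against BFS and path-enumeration
oracles on small graphs. Ties in probe collapse, MCODE seeding and
cluster ranking all have explicit deterministic tie-breaks; every source
of randomness in the generator flows through one seeded NumPy generator,
so identical seed and configuration give byte-identical outputs.

## Known limitations

- The exceedance screen's specificity depends on the tie structure of
  the NTG backgrounds (see above); on tie-free backgrounds it flags the
  upper tail generally.
- In-sample AUCs of the combined signature are optimistic by
  construction; the `--cv` style evaluation is deliberately out of scope.
- Component-local closeness inflates values in tiny disconnected
  components; in highly fragmented networks the CORE means shift
  accordingly (the global-N flag does not remove this, it only rescales).
- Multi-group designs (e.g. two rejection subtypes against control in
  one model) are not supported; comparisons are two-group.
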