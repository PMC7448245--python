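# Methods

## The screening model

`multiscreen` ranks a compound library against a panel of protein targets by
fusing two independent lines of evidence per compound–target pair:

* a **ligand-based probability** `P_Activity` — the fraction of trees in a
  Random Forest classifier voting "active", trained on molecular descriptors
  of assayed compounds binarised at a per-target pIC50 threshold; and
* a **structure-based probability** `Prob_Dc = E_Lig / E_MLig` — the
  compound's docking score normalised by the best (most negative) score in
  the same table.

Where both exist they are fused as

```
Prob_Comb = (Prob_Dc + (1 + ESP) * P_Activity) / (2 + ESP)
```

with `ESP` the classifier's mean specificity over external-test and
cross-validation. The fusion is a convex combination: the weight on the
ligand-based side, `(1+ESP)/(2+ESP)`, rises from 1/2 (a useless classifier,
ESP = 0) to 2/3 (a perfectly specific one, ESP = 1). The rationale is
false-positive control: the more the classifier can be trusted to reject
inactives, the more say it gets. Among the candidate groupings of this expression, the adopted one is the
only form bounded in [0, 1] for all valid inputs.

A compound is called active on a target when

* combined targets: `Prob_Comb >= 0.5` **and** `Prob_Dc` strictly above the
  reference ligand's own normalised probability **and** in-domain;
* classifier-only targets: `P_Activity >= 0.5` **and** in-domain;
* docking-only targets: `Prob_Dc` strictly above the reference ligand's.

The 0.5 threshold is inclusive (a decision probability of exactly 0.50
counts as active); the docking comparison is strict. Compounds active on
`min_targets >= 2` targets are the multitarget hits; those then pass through
the ADMET funnel.

## Model and procedure choices

**Random Forest.** 250 trees, random seed 1, scikit-learn implementation
with otherwise default hyperparameters; the ensemble-size parameter is the
tree count, its standard meaning in WEKA-style RF. Probabilities are tree-vote fractions; a probability of
exactly 0.5 classifies as active, consistent with the screening rule.

**Validation.** Stratified 80/20 external split (per-class train counts
within one compound of the fraction) plus stratified 10-fold
cross-validation; the fold count is the field-convention default. Cross-validation pools out-of-fold
predictions and scores them once rather than averaging per-fold metrics —
pooling is better-behaved at these class sizes; this is an open choice,
flagged here. Metrics with zero denominators are reported as undefined
(None), never as 0. Reports round to 2 decimals; all decisions use full
precision.

**Applicability domain.** `APD = d_bar + Z * sigma`, `Z = 0.5`. Several
variants of the distance statistics circulate in the literature; the
adopted recipe is the standard Euclidean-APD scheme: z-score descriptors on training
mean/SD (they have wildly different natural scales), compute all pairwise
training distances, retain those no greater than their grand mean, and take
`d_bar`/`sigma` as the mean and *population* SD of the retained set. A
query is in-domain when its nearest-training-neighbour distance is <= APD
(boundary inclusive). The all-pairwise variant is available via
`retain="all"`; `scale=False` skips z-scoring for descriptors already on a
common scale. The domain is defined on the QSAR descriptor space, so
docking-only targets carry no domain gate.

**Docking normalisation.** The ratio `E_Lig / E_MLig` is computed for every
compound (the fused score needs it); the "active" condition
`E_Lig < E_Inib` gates the activity call, not the ratio. Scores >= 0
(non-binding poses) are clamped to probability 0 with a warning, since the
sign flip would otherwise invert the ranking.

**ADMET funnel.** Conjunctive rules over externally predicted property
tables (the predictors themselves are out of scope; their CSV exports are
the input): solubility in {soluble, moderately soluble}; absorption =
at most 2 Lipinski violations (MW <= 500 Da, logP <= 5, HBD <= 5,
HBA <= 10; boundaries on the compliant side) **and** consensus
logP <= 4.15 **and** not a P-gp substrate; BBB permeation; all four
toxicity endpoints (mutagenic, tumorigenic, reproductive, irritant) at
level "none" — any non-"none" level, including "low", fails. Rotatable
bonds <= 10 is Veber's rule, not a Lipinski violation; it is available as
an optional extra stage. CYP substrate/inhibition flags are carried through
and reported but never filtered on, as no accepted cutoff applies to them.
Because the rules are conjunctive, the final survivor set is independent of
stage order; the per-stage counts are not.

## Synthetic data: what it emulates and what it does not

The generator (`multiscreen.synthdata`) emulates the statistical structure
the pipeline assumes, not chemistry:

* **Descriptor data** — actives and inactives are multivariate Gaussians
  whose means differ by `separation` pooled SDs along one random direction
  (default separation 6, 150+150 training compounds, 20 descriptors). A
  single discriminative direction is the simplest model under which forest
  performance is a monotone function of separation, enabling
  parameter-recovery tests; real descriptor blocks are correlated,
  heavy-tailed and multimodal.
* **Docking tables** — actives drawn uniformly from a score range strictly
  below the reference ligand (default ligand −100, actives −180..−120,
  decoys −95..−40), so planted actives are docking hits by construction.
* **ADMET tables** — each rule's fields sampled so its marginal pass rate
  equals a configured probability (defaults 0.66 solubility / 0.8
  absorption / 0.3 BBB / 0.5 toxicity, chosen to mirror the attrition
  pattern of a natural-product library), independently across rules;
  correlated property modes are out of scope.
* **Full study** — a 159-compound library (the scale of the motivating
  lignan screen) with 40 planted true multitarget actives drawn from every
  target's active-class Gaussian; each target has its own descriptor space.
  All generators are pure functions of `(spec, seed)` via a NumPy
  `SeedSequence`.

Passing tests on these data establish that the pipeline's arithmetic,
gating and bookkeeping are correct and that it recovers a known planted
signal; they say nothing about the accuracy of any particular descriptor
set or docking program on real compounds, and absolute performance numbers
from the motivating study (which depend on proprietary descriptors and
unpublished per-compound tables) are explicitly not reproduction targets.

## Numerical and degenerate-input conventions

* Labelling ties (pIC50 exactly at threshold) go to active.
* Stratified split and CV are deterministic given their seeds.
* An all-identical training set yields `d_bar = sigma = APD = 0`; a
  zero-variance descriptor is dropped with a warning before scaling.
* `E_Lig = E_MLig` gives probability exactly 1; equal fusion inputs are a
  fixed point of the fusion formula.
* Sorting of multitarget hits breaks ties by compound id for deterministic
  reports; duplicate compound or target ids raise errors naming them.
* Problem sizes in the test suite (e.g. n = 400 compounds, 20 descriptors,
  seeds 1–5 for recovery checks; n = 2000 profiles for funnel calibration)
  are the package's chosen study conditions for establishing statistical
  behaviour at desk scale.

## Known limitations

* The descriptor backend ships with RDKit 2D descriptors only; the backend
  registry is pluggable but no 3D or fingerprint backend is provided.
* Probabilities are raw vote fractions; no calibration is applied.
* The applicability domain is a single global Euclidean threshold —
  leverage/Williams-plot and density-based domains are out of scope.
* ADMET fields are consumed, never predicted; the funnel is only as good as
  the upstream property predictions.
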