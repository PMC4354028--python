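# Methods

## The model

`epipluri` treats pluripotency classification as a thresholding problem on
DNA-methylation beta-values. A beta-value β ∈ [0, 1] is the fraction of
methylated alleles at one CpG site in a cell preparation; pluripotent cells
(ESCs/iPSCs) occupy a characteristic epigenetic ground state, so at a few
CpGs the beta-value ranges of pluripotent and somatic samples do not overlap
at all.

### Criterion 1: range margin

For one CpG with training groups 1 and 2 the two directional margins are

```
m_hypo  = min(group 2) − max(group 1)     (CpG low in group 1)
m_hyper = min(group 1) − max(group 2)     (CpG high in group 1)
```

and the CpG's margin is the larger of the two. A positive margin is the
width of the empty gap between the group ranges — any threshold inside the
gap classifies the training data without error, and the gap midpoint
(mean of the two boundary values) is the canonical cutoff. A negative
margin quantifies range overlap. Margins are invariant to permuting samples
within a group and depend only on the group extremes, which makes the
criterion deliberately conservative: a single outlying training sample can
destroy a margin, which is the intended behaviour for a marker that must
hold across laboratories and platforms.

### Criterion 2: differentiated-sample refinement

Several hyper-direction CpGs typically separate the training groups about
equally well. They are disambiguated on the in-vitro differentiated
samples — pluripotent-derived cells partway through differentiation, whose
methylome still mostly resembles the pluripotent state. For each candidate
within `margin_tolerance` of the best hyper margin, the fraction of
differentiated samples falling strictly on the non-pluripotent side of the
candidate's cutoff is computed, and the candidate maximising that fraction
wins (ties: larger margin, then lexicographic CpG id). Two open choices are
resolved as follows, since the source assay specifies neither:

* the per-CpG "classification" of a differentiated sample uses the gap
  midpoint with a strict inequality toward the non-pluripotent side —
  symmetric and parameter-free, consistent with margin maximisation;
* `margin_tolerance` defaults to 0.05 (beta units); it bounds how much
  criterion-1 margin may be sacrificed for criterion-2 responsiveness and
  is exposed as a model parameter.

### Scores

* Epi-Pluri-Score = β(hyper marker) − β(hypo marker), published probes
  cg23737055 (*ANKRD46*) and cg22247240 (*C14orf115*). Range [−1, 1];
  strictly increasing in the first argument, strictly decreasing in the
  second; call = pluripotent iff score > 0. A score of exactly 0 is called
  non-pluripotent with a logged boundary warning — the conservative
  resolution of a case the sign rule leaves open.
* POU5F1 complement: flag = β(cg13083810) > cutoff. No numeric cutoff is
  published; the default is the training-derived gap midpoint of that CpG,
  reported alongside the flag.
* Parthenogenic-Score = β(cg18506672, SNURF) − β(cg17769238, H19) − 0.2;
  the constant shifts the decision cutoff to zero. Which sign means
  "parthenogenic" is not stated by the assay; this package calls positive
  scores parthenogenic-like, on the biological ground that two maternal
  genomes hypermethylate the maternally imprinted SNURF site and
  hypomethylate H19. This is documented as an assumption, not a validated
  convention.

### Multi-CpG comparator

The comparator classifier is the maximum-margin separating hyperplane over
all perfect-separator CpGs, fitted with a linear-kernel SVM
(scikit-learn `SVC`, `C = 1e6` by default). With linearly separable
training data the large `C` makes the fit effectively hard-margin (zero
training error); `C` is exposed because the appropriate soft-margin
strength for non-separable data is data-bound. Beta-values are already on
[0, 1], so no feature scaling is applied. Calls use the same sign/tie rule
as the score.

### Validation metrics

Sensitivity = 100·tp/(tp+fn), specificity = 100·tn/(tn+fp), positive class
pluripotent. Report strings round half-up to one decimal; machine output
keeps raw fractions. Samples whose truth label is neither pluripotent nor
somatic are excluded from the confusion matrix with a logged count;
mismatched sample ids are an error, never a silent drop.

## Missing data and I/O conventions

Beta matrices are tab-separated, CpG rows × sample columns, `NA` for
missing, decimal point `.`, scientific notation accepted; writing uses
shortest round-trip float formatting so write→read is bit-identical.
Missing values are never imputed: any selection or scoring operation that
touches a missing beta-value fails loudly naming the CpG and sample, unless
`allow_missing` is set, in which case missing samples are dropped per CpG
(an explicit choice, because silent exclusion changes margins). Sample
annotation files need a header row (`sample_id`, `label`, optional `day`);
the label vocabulary {pluripotent, somatic, differentiated, parthenogenic,
unknown} is closed and enforced at parse time, and `day` is only accepted
for differentiated (or unknown) samples. Platform manifests are
one-CpG-per-line text files; the exact shared-probe list between array
generations depends on manifest versions, so it is user input and not
shipped.

## The synthetic cohort generator

`simulate()` emulates the statistical structure of a curated methylation
array compendium; it does **not** emulate array chemistry (probe types,
detection p-values), batch or chip effects, genomic coordinates, or the
epigenetic-memory heterogeneity of real iPSC panels. Passing tests
therefore demonstrate correctness of the selection/scoring machinery under
the stated statistical assumptions, not performance on real arrays.

All draws are beta-distributed, parameterised by (mean m, precision s) with
shapes a = m·s, b = (1−m)·s, so variance = m(1−m)/(1+s) — natural for
bounded methylation fractions. Components:

* **Planted markers** — per-class means per CpG. Defaults
  (C14orf115-like 0.05/0.85, ANKRD46-like 0.90/0.10, both precision 50;
  POU5F1-like 0.10/0.80 with precision 25 so its margin is smaller than the
  score pair's, mirroring its published role as complement rather than
  score component; SNURF-like 0.45→0.90 and H19-like 0.45→0.05 in
  parthenogenic samples, precision 60 around the half-methylated imprinted
  baseline). No quantitative noise level is published for the real
  cohorts; these precisions are this package's choice of a realistic
  array-level spread (SD ≈ 0.03–0.08) and are documented as such.
* **Noise CpGs** — one class-independent distribution per CpG, mean drawn
  uniformly from [0.05, 0.95], precision 8 (broad, overlapping classes).
* **Differentiated samples** at day t have marker mean
  `m_pluri + (m_somatic − m_pluri)·logistic((t − t50)/tau)`; defaults place
  the transitions at t50 = 7 d (POU5F1-like, tau 1.5) and 15/20 d (score
  CpGs, tau 2.5), reproducing the qualitative kinetics in which the POU5F1
  site hypermethylates around day 8 while reliable score flips occur only
  after ~20 days. Sampling days default to (3, 8, 11, 15, 20, 25).
* **Partially reprogrammed stand-ins** — convex mixtures of the class
  means (`mixture_fraction`); a statistical stand-in, not a biological
  model of reprogramming intermediates.
* **Class sizes** default to the published training scale: 63 pluripotent,
  177 somatic, 18 differentiated, 6 parthenogenic, 1,000 noise CpGs.

Determinism: all randomness flows through `numpy.random.default_rng(seed)`;
identical config (including seed) gives bit-identical cohorts.

## Numerical choices and degenerate inputs

* Ties in every ranking break by (larger margin, then lexicographic CpG id).
* A margin of exactly 0 is not a separator (strict inequality) and has no
  cutoff.
* Empty groups, absent labels, empty feature sets and empty platform
  intersections raise typed errors (`SelectionError`, `EpiPluriError`)
  rather than returning degenerate results.
* Beta-distribution means are clipped to [1e−6, 1−1e−6] before converting
  to shape parameters.
* The constant-feature weight in the SVM is zero only up to solver
  tolerance (~1e−8).

## Problem sizes used in the test and acceptance runs

The oracle-equivalence check runs on a 10,005-CpG × 36-sample matrix
against a pure-Python brute-force scan; marker-pair recovery uses 100
seeded simulations of 302 CpGs × 51 samples (planted margins ≥ 0.2 by
construction); end-to-end validation trains on 126 and scores 250 fresh
samples. These sizes exercise every code path at full statistical fidelity
while keeping the whole suite in the tens of seconds.

## Known limitations

* The method is a classifier for extreme states: it does not discriminate
  ESC from iPSC, does not detect lineage-specific differentiation bias,
  and classifies embryonal carcinomas and parthenogenic ESCs as
  pluripotent (the Parthenogenic-Score exists precisely because of the
  latter, and is itself unvalidated on independent data).
* Margins are extreme-value statistics; one mislabelled training sample
  can eliminate a true marker. The package surfaces this honestly rather
  than robustifying, because the derivation being reproduced is defined on
  extremes.
* The embryonal-carcinoma bimodality of the POU5F1 CpG (hypo- or
  hypermethylated) is noted in the source literature but not modelled by
  the simulator.
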