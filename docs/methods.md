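# Methods

mesosieve analyses filtration-chromatography proteomics of cytoplasm to ask
two questions: which proteins live in deformable, dilution-sensitive
mesoscale assemblies (biomolecular condensates, BMCs), and what fraction of
the detected proteome they account for. Because the real measurements are a
single pass through frozen eggs' worth of extract, every statistical step
here is validated against a synthetic cytoplasm whose ground truth is known.
This note records the models, the defaults and why they were chosen, and
what the synthetic validation does and does not establish.

## The forward model (synthetic cytoplasm)

Each simulated species belongs to one of four classes: *free* (monomeric,
well below any pore cutoff), *complex* (rigid assembly, 32–90 nm — the
ribosome-to-vault scale), *condensate* (deformable assembly, 60–120 nm,
log-uniform — the ~100 nm mesoscale the assays probe), and
*membrane-bound organelle* (rigid, 200–1000 nm). Class fractions default to
free 0.12, condensate 0.25, organelle 0.40, complex 0.23, the composition
regime the analysis is meant to resolve.

**Filtration.** A species of effective diameter `d_eff` meeting a membrane
of cutoff `d_pore` elutes with instantaneous filtrate concentration
(relative to input; 1 = free passage):

- `d_eff <= d_pore`: FC(t) = 1.
- rigid, above cutoff: FC = leak + (1 − leak)·exp(−(r − 1)/w), with
  `r = d_eff/d_pore` and pore-polydispersity width `w = 0.2`. The cutoff is
  where retention becomes *confident*; real membranes have a pore-size
  distribution, so rigid retention is graded near the cutoff and saturates
  at the leak floor far above it. This grading is what populates the
  scatter's upper edge continuously, as rigid complexes of varying size do
  in real data.
- deformable, above cutoff: FC(t) = 0 for t < t_on, then
  1 − exp(−(t − t_on)/τ), with onset `t_on = min(1, β(r − 1)/λ)` and
  squeezing time `τ = τ0·r/λ`; λ ∈ (0, 1] is the deformability. A sampling
  window's value is the exact mean of FC(t) over the window (closed form,
  cross-checked against quadrature in the tests), floored at `leak`.

`leak = 0.02` keeps heavily retained species detectable but far from free
passage, matching the finite fold changes of retained proteins in real
multiplexed data; it doubles as the detection floor for deformable species
before onset, so no simulated measurement is exactly zero (a zero has no
log fold change and no physical counterpart in MS quantification).
`β = 0.2` and `τ0 = 0.15` were set so that a ~100 nm condensate of typical
deformability shows measurable squeezing at the 30 nm pore — the regime in
which the assay is most informative — while stiff or very large condensates
remain heavily retained. Windows default to T1 = [0.1, 0.3] and
T2 = [0.6, 0.9] of the spin (early/late), and the dilution experiments use a
single mid-elution window [0.3, 0.7], which is most sensitive to onset
shifts.

**Dilution.** A condensate carries a saturation ratio `c_ratio = c0/c_sat`
and a non-dissolving core fraction `phi_core`. At dilution factor f the
condensed fraction is `φ(f) = max(phi_core, 1 − f/c_ratio)` and the
representative assembly shrinks with cube-root mass scaling,
`d_eff = max(d_mono, d0·(φ(f)/φ(1))^{1/3})`. A single representative
assembly per species is assumed; polydispersity appears only in the bead
module. Species with `phi_core = 1` are dilution-invariant by construction.

**Noise.** Measurements are multiplied by `2^ε` per cell
(ε ~ N(0, 0.1) in log2, a typical multiplexed-quantification CV) and by a
shared `2^L` per condition column (L ~ N(0, 0.1)), emulating channel-loading
imbalance. Random streams are split per operation from one master seed, so
adding a simulation to a script perturbs nothing else.

**Sequence features and annotations.** Condensate-class species draw
disorder content from Beta(5, 2.7) (mean 0.65) versus Beta(2, 6) for the
rest, with correspondingly shifted IDR counts, nucleic-acid-binding flags
(RNA binding 0.6 vs 0.15) and composition fractions (glycine-rich,
aliphatic-poor). Five simulated LLPS databases each list a condensate with
probability increasing in its disorder and RNA binding, so high consensus
levels select the most canonical LLPS proteins — the property that makes a
consensus-4 reference a learnable, slightly elite subset of all condensates,
as curated databases are. Complex and organelle flags mirror ground truth
(they stand for reliable curation); LLPS membership is deliberately noisy
and incomplete.

## The analysis

**Normalization.** Fold changes are normalized per experiment to the pooled
0.95 quantile of all that experiment's condition columns (linear
interpolation between order statistics), putting the freely passing
population at unit fold change. Pooling the columns of an experiment — not
normalizing each channel separately — preserves the early/late-window
contrast the squeezing score needs; the per-channel part of the loading
imbalance is instead absorbed downstream by line intercepts (anchor lines,
replicate fits). Normalizing twice is an error; the transform is exactly
scale-equivariant.

**Squeezing score.** In the log2 scatter of early-window against
late-window fold change (late on the abscissa), freely passing and rigidly
retained species form a sharp upper edge near the identity line and
squeezing species fall below it. The edge is fitted in two stages: an OLS
line through all points; then, within 20 equal-width bins along that line,
the top 4% of points by perpendicular offset (at least one per nonempty
bin, ties kept) are refitted by OLS. The squeezing score is the signed
orthogonal distance below the edge (higher = more squeezing). 20 bins is
stable from ~2000 proteins; the edge is assumed straight. The score is
signed rather than absolute because only the below-edge direction is
interpretable as deformation-limited passage.

**Recall metrics.** ROC curves rank by descending score with ties grouped;
the trapezoid AUC equals the Mann–Whitney pair statistic (asserted to 1e-12
against an O(n²) oracle). Negatives are the universe minus the positives —
proteins of other reference groups are not excluded, matching
recall-versus-proteome-accepted plots. Group comparisons use the two-sample
KS test with the asymptotic p-value (group sizes here are tens to
thousands). At equal sample sizes the D statistic is discrete; the
calibration test accounts for the attainable size nearest the nominal level.

**Liquid-like behavior and FDR.** For each selected experiment (filtration:
early vs late window; dilution: undiluted vs diluted), an OLS line in log2
space is fitted through anchor proteins only — annotated large complexes
and transmembrane proteins, assemblies retained by size alone — and every
protein's signed *vertical* residual from that line is recorded; behavior is
the mean residual over the experiments in which the protein is measured.
Vertical (not orthogonal) residuals are used throughout because the null
model is built from vertical residuals of replicate line fits; mixing
metrics would invalidate the calibration. The null is empirical: replicate
condition pairs (same pore, dilution and window; Pearson r > 0.8 of log2
values) are line-fitted and the pooled residuals form the noise
distribution. Classification at level q (default 0.02) uses the plug-in
estimate FDR(t) = N·S_null(t)/#{behavior ≥ t}, with S_null median-aligned
to the anchor residuals and carrying a +1 tail pseudo-count; the threshold
is the smallest observed value with estimate ≤ q, so positive sets nest in
q. The pseudo-count bounds the estimate below by N/(n_null + 1): a lone
extreme protein is only detectable when the pooled null is much larger than
the cohort, which replicate pooling provides. A per-comparison alternative
(threshold at the null's upper-q quantile) is available as
`method="tail"`; both readings of "beyond a 2% false discovery rate of the
null model" occur in practice and neither is claimed canonical here.
"Small" proteins are those whose *mean* log2 filtration fold change lies
within the two-sided null bound at the same level — the mean over channels,
rather than each channel separately, so that per-channel loading offsets
cannot disqualify a genuinely unaffected protein. Composition fractions
partition detected proteins as organelle (annotation) > BMC (flag) > small
(flag) > unassigned, summing to one.

**LLPS classifier.** Features are the eight experimental fold changes (30
and 100 nm at T1/T2; 100 nm at dilutions 1×/1.2×/1.44×/2×) and the sequence
features; only proteins complete across all sources are used, so the matrix
has no missing values. Each ensemble bags bootstrap-resampled learners,
alternating depth-limited decision trees (min 32 per leaf, at most
⌊0.75·n_features⌋ splits) and two-class Gaussian linear discriminants with
shared ridge-regularized covariance (the symmetric tree/discriminant mix is
a default, configurable). Cross-validation is partition-based: many
ensembles are trained on 80% of class 1 and 10% of class 2, and each
protein's score is the *median over the ensembles that did not train on
it*, with the evaluation count recorded (it equals the ensemble count minus
the training appearances, exactly — the auditable no-leakage property).
Experiment-only and sequence-only scores are combined by negated Euclidean
distance to the joint best corner, so higher always means more LLPS-like;
the ranking is invariant to joint shifts of the two components.

A property worth knowing: with a small positive class, the permutation-null
AUC of this scheme sits slightly *below* 0.5 (~0.44 with 30–40 positives on
clustered features), because a held-out positive's scoring ensembles lack
its own contribution to the local positive density — a finite-population
self-exclusion effect, conservative rather than leaky. With uncorrelated
features the null is 0.5 as expected; the test suite checks the null
against its seed-to-seed spread, not against an exact 0.5.

**Beads.** The fill fraction at cutoff s is f = I_in/(I_out·ρ0), with the
accessible volume ρ0 measured from dextran calibration rows; f is not
clamped at 1 (super-unity values are legitimate noise the CV metric needs).
The step set of a profile is the increments from 0, through the fill values
at the sorted cutoffs, to 1 at the extrapolation scale (default 1 μm, where
microscopy shows no residual organization; the anchor can be disabled).
Including the initial rise is what gives one-scale organizers (one dominant
jump) a high step CV and mesoscale-spread profiles a low one — the contrast
the metric exists to quantify; with the initial rise included, an
equal-step profile still gives CV = 0 exactly. Stokes–Einstein sizing
(r = k_B·T/(6πηD)) and reference-calibrated sizing (r = r_ref·D_ref/D) are
provided for diffusion measurements; bead nm cutoffs are user-supplied
config, since no instrument-independent molecular-weight-to-nm formula
exists.

## Numerical and scale choices

- Log base 2 everywhere a log is taken; '.' decimal, tab-separated UTF-8
  I/O; floats round-trip bit-exactly (shortest-repr write, round-trip
  parse).
- Quantiles: linear interpolation between order statistics, stated so
  results are dialect-stable.
- Edge fit requires ≥ 10·bin_count finite points; vertically collinear
  input is a degenerate-fit error. Ties at the top-fraction cutoff are all
  kept (deterministic).
- OLS throughout is `numpy.polyfit` degree 1; anchor fits require ≥ 2
  anchors with non-constant abscissa.
- The default test/validation sizes — 4000-species studies for recall and
  composition, 1600 species with 600 ensembles of 8 learners for classifier
  integrity, 2500 species with 250 ensembles of 24 learners in the
  acceptance script — keep each check to seconds-to-minutes on one core;
  all sizes are ordinary config and scale linearly.

## What the synthetic validation shows — and does not

Passing tests establish that the estimators recover what the forward model
plants: the edge fit recovers a planted edge where the edge has support in
every projection bin; squeezing scores rank planted condensates above
complexes and free species (AUC > 0.9 at default noise); the FDR machinery
is calibrated on its own null and recovers planted composition fractions
within ±0.05; the classifier's out-of-training bookkeeping is exact and its
planted-feature recall exceeds 0.85. They do *not* establish performance on
real cytoplasm: the simulator is monodisperse per species, its noise is
log-normal and independent across cells, its annotations are cleaner than
curated databases, and real elution kinetics need not be
exponential-after-onset (the qualitative curve family — flat-zero, delayed
onset, saturating rise — is the modelling target, not a claimed law).
Headline numbers from real data (proteome fractions, AUCs) depend on the
deposited datasets and are out of scope here.

## Known limitations

- The single-assembly cube-root dilution coupling ignores polydispersity
  and Ostwald-type size redistribution; only the bead module models a size
  distribution.
- The plug-in FDR threshold is conservative when the null is recentred on
  anchors that themselves carry slight liquid-like shifts.
- The partition-CV permutation null is mildly below 0.5 for small positive
  classes (self-exclusion; see above).
- Two-sample KS at equal n has a discrete statistic; nominal and attainable
  size differ (3.9% attainable at nominal 5% for n = m = 50).
- The edge fit assumes a straight edge; curved or quantile-regression edges
  are out of scope.
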