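# Methods

This note records the models, the synthetic-data design, the numerical
choices and the limitations of `serumnmr`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Spectrum model and the synthetic cohort

A spectrum is a sum of Lorentzian multiplets on a ppm axis. Each library
entry carries a chemical shift δ, a splitting pattern, scalar couplings J
(Hz) and a proton count; first-order patterns expand into the usual line
trees (d: ±J/2 at equal weight; t: 1:2:1 spaced J; q: 1:3:3:1; dd: four
equal lines from two couplings), J is converted to ppm by J/ν with ν the
spectrometer frequency (500.26 MHz), and the integrated area equals
amplitude × proton count. Unresolved multiplets ("m" in the library, used
where the source assignments give no coupling tree) are rendered as one
line with 3× the linewidth — same area, realistic width, no invented
couplings. The shipped library covers 26 serum metabolites; entries whose
stated multiplicity has no J (e.g. a CH₃ doublet reported only as
"overlapped") are transcribed at their stated shift as "m" rather than
given a fabricated coupling. Overlap between metabolites (threonine CH₃ on
lactate CH₃, glucose/glycerol/serine in 3.5–3.9 ppm) is deliberate: it is a
property of real serum spectra that the variable-selection stage must cope
with.

The cohort generator emulates a two-class replicate study: 51 case and 39
control subjects by default, three replicate spectra per subject, on a
0–10 ppm grid of 16 384 points (a 32K/12 kHz acquisition at desk scale;
analyses in the tests use 2 048–8 192-point grids, chosen to keep the suite
fast — the algorithms are resolution-agnostic). Nuisance terms, with
defaults chosen once for serum realism:

| term | default | why |
|---|---|---|
| linewidth | 2.0 Hz | serum lines are macromolecule-broadened |
| concentration CV (between subjects) | 0.15 | typical biological variability |
| marker fold change (case class) | 1.5 on 8 low/mid-abundance metabolites | a plausible disease signature that leaves the majority of total signal unchanged — the regime quotient normalization assumes |
| dilution (per sample) | log-normal, σ = 0.15 | sample-prep variation |
| global shift (per sample) | N(0, 0.002 ppm) | referencing/field drift; what stage-1 alignment removes |
| per-metabolite shift jitter | N(0, 0.0015 ppm) | pH/ionic sensitivity; kept below the linewidth |
| baseline | linear, slope ±2/ppm, offset ±5 | 1st-order drift for the baseline stage to remove |
| noise | N(0, 0.5) per point | thermal noise |
| residual water | fixed Lorentzian, 60 Hz at 4.70 ppm | exists so the 4.35–5.0 ppm exclusion has something to remove |
| lipid resonances | 25 Hz lines at 0.88/1.28/5.27 ppm, per-subject log-normal amplitude (σ = 0.3) | lipoprotein content varies strongly between subjects and is a subject property, constant across replicates |

An optional broad protein/lipoprotein envelope
(`include_protein_background`, off by default) adds seven very broad
class-independent resonances with subject-level amplitude variation; it is
useful for stress-testing quotient normalization against composition
changes but is not part of the standard condition set.

Determinism: all draws flow from one `numpy` Generator seeded by
`SimulationConfig.seed`; identical (library, config) pairs give
bit-identical datasets. Ground truth (per-subject concentrations, dilution
factors, planted shifts, marker shift lists, background scales) is stored
on the dataset for oracle-based tests.

What the generator does **not** emulate: second-order (strong-coupling)
effects and roofing, relaxation-weighted lineshapes, solvent-suppression
phase distortions, 13C satellites, and realistic correlation structure
between metabolite concentrations. Passing tests demonstrate that the
algorithms behave correctly under the modelled nuisance structure, not that
the specific accuracy figures transfer to any real cohort.

## Preprocessing

**Region exclusion** drops columns inside closed ppm intervals (defaults:
4.35–5.0 water window, <0.17 and >8 ppm edges); membership is decided on
the stored axis values, so the operation remains well-defined on an already
gapped axis.

**Baseline** is a per-sample least-squares line over anchor regions
(defaults 0.2–0.4, 6.6–6.8, 9.5–10.0 ppm — peak-free in the synthetic
library), subtracted from the whole spectrum.

**Alignment** maximizes cross-correlation under rigid integer shifts
(brute-force over ±max_shift, ties to the smaller |lag|; default budget 50
points, clamped by the pipeline to the realized reference width on coarse
grids). Stage 1 shifts whole spectra against the reference zone 5.12–5.35
ppm (the anomeric α-glucose doublet beside the 5.27 ppm lipid line) for 4
iterations, the target being the median spectrum of the current data —
this removes the global referencing component. Stage 2 aligns intervals
independently; the `interval_align` default covers the two classic trouble
zones (1.16–1.22, 3.62–3.69 ppm), while the pipeline default segments the
whole retained axis into ~50-point intervals and estimates lags on
first-derivative-pretreated segments (the derivative suppresses broad
background so the lag follows the sharp peaks); the raw intensities are
what get shifted. Vacated edge points repeat the edge value rather than
zero-filling, to avoid creating artificial baseline steps. Shifting never
changes a spectrum's multiset of intensities except at edge-fill positions.

**PQN** first normalizes each spectrum to the median total area, takes the
column-median spectrum as reference, forms per-variable quotients
sample/reference over the top-intensity half of the reference (noise-level
columns would otherwise dominate), and divides each sample by its median
quotient. The stored dilution estimate is the product of the area factor
and the median quotient, so a spectrum duplicated at 3× dilution reports a
quotient of 3 exactly. PQN is a fixed point once residual dilution is the
only between-sample scale difference; on generic data a second pass moves
intensities at the ~10⁻³ level because the median reference itself moves.
A caveat the tests document explicitly: subject-level lipid-amplitude
variation is a composition change, and a quotient-based dilution estimator
partially absorbs it; dilution-recovery checks therefore run with the lipid
envelope disabled.

## QC screening

Column moments use the biased sample skewness g₁ and non-excess kurtosis
(normal ≈ 3); zero-variance columns are reported as NaN, not raised.
Outlier rules: (a) moment zones — the zone is the set of columns with
kurtosis above an absolute floor (10) *and* in the top 0.5 % of all column
kurtoses; a sample is flagged when it exceeds zone mean + 4 sd in at least
two zone columns (a genuine artifact spans neighbouring points;
single-point excursions are noise); (b) PCA — Hotelling T² with the
F-approximation limit and Q residuals with the Box weighted-χ² limit on a
mean-centered PCA (2 components by default, limit quantile 0.95 at the
function, 0.99 in the pipeline default because automatic whole-subject
removal at 0.95 deletes a substantial share of subjects by chance alone);
(c) SNR — median intensity over the data-driven peak columns (top 2 % of
the median spectrum) divided by the noise-region sd, floor 5. Flags always
propagate to whole subjects.

## Scaling, PCA, OPLS-DA

Scaling methods: center (offset = column mean), Pareto (scale = √sd), auto
(scale = sd, ddof = 1), and class-centroid (offset = (x̄_A + x̄_B)/2, scale =
pooled sd) — the latter keeps the class boundary from drifting toward the
larger class when group sizes are unequal. Zero-variance columns under a
variance-based method are dropped with a warning and recorded. All methods
are exactly invertible on the kept columns.

PCA is the SVD of the scaled matrix; component k's variance fraction is
σ_k²/Σσ². OPLS extracts orthogonal components iteratively: w ∝ X′y
(normalized); per round p = X′t/(t′t), w_o ∝ p − (w′p)w, t_o = X w_o,
p_o = X′t_o/(t_o′t_o), deflate X ← X − t_o p_o′; the predictive component
(t, p, q) is computed on the filtered matrix, and the direct-prediction
vector is b = q·M₁⋯M_k w with M_j = I − w_oj p_oj′. Orthogonal extraction
stops early when a score norm falls below 10⁻¹² × ‖X‖; the count actually
extracted is reported. Key algebraic properties, asserted in tests: t_o′(y−ȳ)
= 0, w′w_o = 0, p_o′M_j = 0 (so perturbations along an orthogonal loading
leave predictions unchanged), and the fitted values coincide with a plain
NIPALS PLS1 using one more component. Explained variance is reported
against total scaled-X sum of squares, per block (predictive, each
orthogonal, total). Class coding is {0,1} with the case class = 1.

Back-scaled loadings multiply the predictive loading by the column scales
so the vector resembles a spectrum again; the per-variable weight is
|corr(X_s,i, t)| ∈ [0,1], used as color coding for relative importance.

## Validation

Block CV: subjects are shuffled by seed and assigned to contiguous blocks
of ⌈N/(r·n_folds)⌉ subjects (r = replicate count), so a 265-sample
triplicate set in 7 folds gives 13-subject, 39-sample blocks; every
replicate of a subject shares a fold, and a leakage guard asserts this on
every CV run. Fold counts can come out below the requested number when the
ceiling rounds up (documented behaviour). RMSEC/RMSECV are computed for
orthogonal-component counts 0..max; the chosen count is the smallest within
1 % of the minimum RMSECV (parsimony tie-break).

Bayesian thresholds: a Gaussian is fitted to each class's calibration
predictions (the pipeline uses the cross-validated predictions as
calibration); the class threshold is the ŷ where the two posteriors are
equal — the root of the corresponding quadratic chosen between the class
means, with a flagged midpoint fallback for degenerate overlap. Priors
default to class proportions. Under {0,1} coding the control model sees
mirrored predictions, so the two thresholds are complementary (sum = 1) up
to root tolerance — the asymmetric pair the unequal classes produce.
Classification is two-sided: the case rule fires at ŷ ≥ θ_case, the control
rule at 1−ŷ ≥ θ_control; firing neither or both yields "Unassigned", and
accuracy counts correctly assigned samples over all samples.

The permutation test permutes class labels at the subject level (replicates
move together — sample-level permutation would leak replicate identity into
the null), re-runs the full CV pipeline per iteration, and reports
p = (1 + #{null ≥ observed})/(n_iter + 1); the statistic is CV accuracy at
the 0.5 cut (larger = better), with RMSECV available by flag (smaller =
better). Default 200 iterations.

## Variable selection

VIP over the predictive components: vip_i = √(P·Σ_a w_ia² SSY_a / Σ_a
SSY_a) with per-component normalized weights, so Σ vip² = P; with one
component this collapses to √P·|w|. Selectivity ratio via target
projection: t_TP = X_s b/‖b‖, p_TP = X_s′t_TP/(t_TP′t_TP), and per variable
the ratio of explained to residual sum of squares — equal to r²/(1−r²)
against t_TP for centered columns, hence scale-equivariant under
autoscaling. Region reports merge variables strictly above the chosen
quantile into runs (gaps ≤ 3 grid points allowed), annotate each region
with every library multiplet within ±0.02 ppm, and take the direction of
class association from the sign of the summed back-scaled loading. A
quantile of 1.0 selects nothing and raises the documented empty-selection
error.

On the synthetic cohort the selectivity-ratio profile concentrates on the
densest discriminatory regions first; sharp low-abundance markers sit
lower in the ranking because sub-grid shift jitter adds class-independent
variance at their peak columns. This mirrors the behaviour on real data,
where broad sugar regions dominate such rankings.

## Cross-cohort overlap

The shipped presence table transcribes the published ±-grid of 63 serum
biomarkers over the Serbian, Brazilian and Chinese cohorts, preserving the
source spellings verbatim (a synonym map provides canonical names) and
carrying per-row citation keys; one row marks a citation/percentage-grid
mismatch in a note column rather than silently "fixing" it. Overlap counts
are intersections of boolean columns; the consensus set preserves row
order.

## Problem sizes

The default test suite runs cohorts of 10–28 subjects on 1 024–8 192-point
grids, permutation tests with 99 iterations, and a full end-to-end run at
25 vs 20 subjects on 8 192 points; `scripts/acceptance.py` uses the same
desk-scale sizes. These sizes were chosen so the whole suite completes in
well under a minute per module while keeping every statistical check
adequately powered.

## Known limitations

- The two-stage alignment corrects integer-grid shifts only; sub-grid
  misalignment survives and is the main power limiter for sharp
  low-abundance markers in variable selection.
- PQN's dilution estimate absorbs part of any genuine composition change
  (class fold changes, lipid amplitude); this is intrinsic to
  quotient-based normalization, not an implementation artifact.
- The OPLS implementation is two-class (single predictive component);
  multi-class discrimination and kernel variants are out of scope.
- QC control limits assume approximately multivariate-normal scores;
  heavy-tailed biological data will flag more samples than the nominal
  quantile suggests.
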