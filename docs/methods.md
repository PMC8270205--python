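# Methods

## Optical indices

All absorbance indices start from the Naperian absorption coefficient
a(λ) = ln(10)·A(λ)/L with A the decadal (base-10) absorbance and L the
cuvette path length in metres.  Index wavelengths (255, 350, 365, 420, 465,
665 nm) are read off the spectrum exactly when they fall on the instrument
grid and by linear interpolation otherwise; on the standard 5 nm grid every
index wavelength is on-grid, so interpolation is a compatibility path, not
the normal one.  A spectrum must cover at least 250–420 nm for the default
index set; E4:E6 additionally needs coverage to 665 nm.

**SUVA convention.** SUVA is computed at 255 nm as ln(10)·A₂₅₅/(L·[DOC]),
i.e. the DOC-specific *Naperian* coefficient, in L mg⁻¹ m⁻¹.  This differs
from the widespread decadal SUVA₂₅₄ by the ln(10) ≈ 2.303 factor (and 1 nm);
it is the convention under which the field ranges quoted below
(1.1–21 L mg⁻¹ m⁻¹) are expressed.  SAC₃₅₀ and SAC₄₂₀ are the same quantity
at 350 and 420 nm; all three share one unit.

**Spectral slopes.** S is estimated by nonlinear least squares of
a(λ) = a_ref·e^(−S(λ−λ_ref)) over the window (endpoints inclusive), with
λ_ref at the lower window edge and the ordinary least-squares fit of ln a
vs λ supplying the starting point.  The nonlinear route weights absolute
residuals, which matches fitting the physical coefficient itself; the
log-linear route weights relative residuals and is retained as an
independent cross-check (`method="log_linear"`) and as the fallback if the
optimizer fails.  On noise-free exponential data the two agree to better
than 1e-8.  Points with a ≤ 0 are excluded before fitting (logarithm
undefined; such values are instrument noise floor), and fewer than three
usable points yields a missing slope rather than a fit.  No baseline
correction is applied by default (blank correction is assumed done at the
instrument).

With 1% multiplicative noise and five 5 nm grid points per window, a single
sample's S₂₇₅₋₂₉₅ carries a standard error of roughly 6×10⁻⁴ nm⁻¹ (a few
percent of typical values); the estimator is unbiased, so cohort means
converge on the truth.  Round-trip tests therefore bound the *mean*
relative deviation of S (≤1%), and the per-sample mean absolute error of
SUVA (≤2%), rather than per-sample slope errors.

## Chemistry

DON is TDN minus the inorganic species (NO₃-N + NO₂-N + NH₄-N), all in
mg N/L.  A negative difference — possible within analytical error when
inorganic N dominates — is reported missing, not clipped to zero: a clipped
zero would fabricate unbounded DOC:DON ratios.  DOC:DON is molar, using
atomic masses 12.011 (C) and 14.007 (N).

## Missing data

Missing values propagate explicitly (NaN in tables, empty CSV cells) and
are never imputed or zero-filled.  Site averaging takes the arithmetic mean
of the *derived metrics* over non-missing events — not a recomputation from
averaged spectra — and a metric missing in every event of a group stays
missing.  The PCA restricts to the complete-case subset and logs its size.

## PCA screening and axis selection

Columns are centered and scaled to unit variance (so the decomposition is
of the correlation structure) and decomposed by SVD
(`sklearn.decomposition.PCA`, full solver).  Component signs are fixed by
making each component's largest-magnitude loading positive; results are
then deterministic and invariant to row order and to affine rescaling of
any input column.  A variable's contribution to component k is
100·loading²(j,k)/Σⱼloading²(j,k); the PC1+PC2 combination weights the two
components by their eigenvalues,

    combined₁₂(j) = (contrib(j,1)·λ₁ + contrib(j,2)·λ₂) / (λ₁ + λ₂),

the convention of standard ordination-contribution plots (the exact
statistic behind published contribution figures is rarely stated; this one
is documented and cross-checked against a brute-force recomputation from
the loadings).

Axis selection is constrained by *method family* before contribution:
every variable belongs to one of absorbance-magnitude (SUVA, SAC₃₅₀,
SAC₄₂₀), absorbance-shape (S₂₇₅₋₂₉₅, S₃₅₀₋₄₀₀, S_R, E2:E3, E4:E6),
size-exclusion (BP, HSF, BB, LMWN, LMWA, HS-MW), or stoichiometry
(DOC:DON).  Within each family, variables below the screening threshold
(default 2% combined contribution) are dropped and the top contributor
wins (ties broken alphabetically and logged).  A family whose members all
fall below the threshold still contributes its best variable, with a
warning: independence of measurement principle outranks raw contribution,
which is what lets a weakly contributing but analytically unique measure
(typically DOC:DON) onto the wheel.  Only if *no* variable anywhere
survives the threshold is selection an error.

## Wheel construction

Per-axis min-max normalization against the reference dataset maps each
metric to [0, 1]; bounds can also be loaded from a published
`metric,min,max` file so new samples are drawn against fixed bounds, in
which case out-of-range values clip to [0, 1] with a logged warning
(wheels from new studies stay drawable).  Axis order and orientation are
arbitrary in principle; the default places SUVA up-left, S₂₇₅₋₂₉₅
up-right, HSF down-right, DOC:DON down-left (angles 135°, 45°, −45°,
−135°), so the photolyzed end member elongates to the top-right.  Wheels
generalize to k ≥ 3 axes (angles evenly spaced, clockwise from 135°) for
surrogate-axis substitution — e.g. fluorescence components replacing HSF —
with all defaults at k = 4.

Polygon vertices sit at (v·cos θ, v·sin θ); area uses the shoelace formula,
which for orthogonal axes reduces to ½Σvᵢvᵢ₊₁ (all-ones wheel: area 2).
Wheel-to-wheel distance is Euclidean in normalized 4-space, requiring
identical axis specs.

**End-member templates.** Qualitative template levels low/mid/high map to
numeric anchors 0.15/0.5/0.85 — conventions chosen to sit well inside the
normalized range, not measured values.  Groundwater: high SUVA, HSF and
DOC:DON, low S₂₇₅₋₂₉₅.  (Survey descriptions of the groundwater end member
disagree on DOC:DON: observed dataset extremes place it highest in
groundwater, while some figure annotations describe it as low.  The default
follows the observed extremes; `groundwater_caption_variant=True` selects
the other reading.)  Photolyzed: high S₂₇₅₋₂₉₅, low elsewhere.  Three
further templates (microbially degraded, terrestrial leachate, aquatic
production) are provided as conventions for hypothesis-framing, not
validated end members.  Classification is nearest-template with a
configurable cutoff (default 0.6 in normalized distance) beyond which a
sample is "intermediate"; ties break by template order and are logged.

Degradation-shift annotations encode expected axis responses — photolysis:
(SUVA −, S₂₇₅₋₂₉₅ +, HSF −, DOC:DON −); microbial: (SUVA +, S₂₇₅₋₂₉₅ 0,
HSF 0, DOC:DON −) — and are returned as sign vectors only, never applied
to data, because quantitative rates differ across environments.

## Synthetic data generator

`fixtures.synth_dataset` emulates a two-end-member survey.  Target metrics
are drawn per cluster from truncated normals and the raw inputs are
*back-solved*: the spectrum is a single exponential whose amplitude makes
a(255)/DOC equal the target SUVA exactly, and TDN is set so the molar
DOC:DON hits its target exactly — ground truth is exact before noise.
Absorbance noise is multiplicative lognormal (relative instrument error;
keeps A > 0), default σ = 1%.  Defaults, chosen once as realistic values
inside the observed field ranges (SUVA 1.1–21 L mg⁻¹ m⁻¹, S 0.005–0.032
nm⁻¹, DOC:DON 9–124, HSF 14–85%):

| | groundwater-like | photolyzed-like |
|---|---|---|
| SUVA (L mg⁻¹ m⁻¹) | 9.0 ± 1.5 | 2.8 ± 0.6 |
| S₂₇₅₋₂₉₅ (nm⁻¹) | 0.011 ± 0.0015 | 0.026 ± 0.003 |
| HSF (%) | 72 ± 6 | 28 ± 6 |
| DOC:DON (molar) | 90 ± 15 | 18 ± 4 |
| DOC (mg C/L) | lognormal, median 30 | lognormal, median 5 |

End members are, by definition, the compositional extremes of a survey, so
the two clusters are well separated; classification accuracy ≥95% on this
generator demonstrates the geometry and normalization machinery, not
classifier power on real, continuous mixtures.  The generator omits several
features of field data — iron interference with absorbance, non-exponential
spectral shape (scattering shoulders, residual baseline), correlated
measurement errors across metrics, intermediate mixtures along the
groundwater–photolyzed continuum, and seasonal revisits of one site — so
passing tests say nothing about classification on such data.  A seed is
mandatory everywhere; identical seeds give byte-identical CSV bundles.

## Problem sizes and numerics

Tests and the acceptance script run desk-scale: 100–130-sample synthetic
studies, 1000-replicate noise simulations, 1000 random wheels for the
geometry identity.  Slope-fit convergence tolerance is scipy's default;
exactness assertions use 1e-6 (slope recovery), 1e-8 (method agreement),
1e-9 (closed-form ratios), 1e-12 (geometry identities).  Metric CSVs are
written with 17 significant digits so write/read round-trips are exact to
float precision.

## Known limitations

* No iron-interference correction for absorbance; high-iron samples should
  be excluded upstream.
* LC-OCD fractions are consumed as-is (% of DOM); chromatogram integration
  is out of scope.
* Fluorescence indices are supported only as pre-computed surrogate
  columns, never computed here.
* The contribution statistic and complete-case policy match common
  ordination practice but published contribution plots rarely state their
  formula; comparisons to such plots are approximate.
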