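# Methods

## The grey GM(0,N) relational model

The package analyses a panel of heart-rate-variability (HRV) indices —
physiological stress index (PSI), total power (TP) and the band powers VLF,
LF, HF (ms²) — measured for each subject before and after a weekly
intervention over four weeks.  The question it answers is relational: how
strongly does each spectral factor co-move with the stress index, and how
does that structure change after the intervention?

GM(0,N) is the zero-order (static) member of the grey-model family.  With
PSI as the major sequence x₀ and (TP, VLF, LF, HF) as influence sequences
x₁…x₄, all of length L (subjects in a fixed order), the model is built on
first-order accumulated sequences X_j(k) = Σ_{g≤k} x_j(g) (1-AGO) and the
background values of the accumulated major sequence,

    z(k) = (X₀(k) + X₀(k−1)) / 2,      k = 2…L,

giving the linear system z = Xλ with X the (L−1)×4 matrix of accumulated
influence values at k = 2…L.  The relationship weightings λ are the ordinary
least-squares solution; |λ_j| ranks the influence of factor j.  Accumulation
smooths short, noisy, distribution-free sequences into monotone ones — the
grey-system device for stabilising a relation estimated from few samples.

Numerical choices:

- The system has L−1 equations (the background is defined only from k = 2);
  no intercept column is included.
- The solve uses an orthogonal decomposition (LAPACK least squares), not the
  textbook normal-equation inverse; on well-conditioned problems the two
  agree to machine precision (property-tested), and the orthogonal route is
  stable on the near-collinear designs this model produces.
- The developing coefficient that formally scales the left-hand side of the
  grey differential equation is not identifiable in the zero-order model
  (only ratios enter the system); it is fixed to 1 and never exposed.
- Rank-deficient designs (duplicated factors, zero columns) raise a
  singular-system error naming the offending columns, found by QR with
  column pivoting; no pseudo-inverse fallback is attempted.
- Ranking ties in |λ| are broken by the canonical factor order TP, VLF, LF,
  HF, then by column order, for determinism.

### Reporting convention: magnitudes

Because TP ≈ VLF + LF + HF row-wise, the accumulated TP column is nearly the
sum of the other three: the design is strongly collinear.  The least-squares
solution on such data routinely carries large coefficients of mixed sign
(positive on TP, negative on the bands) whose individual signs are not
interpretable; the magnitudes are.  The package keeps the signed
coefficients internally (`WeightingResult.weights`) and reports and ranks
magnitudes (`magnitudes`, `ranking`), which is also how the published
weighting tables in this literature are printed (no signs).  Weightings are
rounded to 4 decimals, averaged tables to 2, weekly means to 1 — at report
time only; full precision is kept internally.

A practical consequence of the collinearity, verified on the bundled data:
the fit is sensitive to last-digit rounding of its inputs.  Fitting the
4-week averages recomputed at full precision from the weekly panel shifts
the pre-phase weightings by about 4% relative to fitting the printed
(2-decimal) averaged table.  Tests that compare against published weightings
therefore use the printed averaged tables as input, and pipeline-level
checks from the weekly panel use correspondingly looser tolerances.

## Pipeline

`fit_phase` composes: per-subject arithmetic mean over available weeks of
one phase (LF/HF dropped as functionally dependent on LF and HF) → sequence
assembly (PSI major; TP, VLF, LF, HF influences; subjects in panel order) →
design construction → least-squares solve.  `compare_phases` runs both
phases and reports per-factor magnitude ratios and both rankings.

`subsample_cv` refits both phases on random subject subsets of requested
sizes (default 45, 30, 20, 15).  The subsampling unit is the subject; one
uniform subset per size is drawn without replacement from a seeded
generator, and the same subset serves both phases so they remain
comparable.  A size equal to the panel reproduces the full fit bit-for-bit.
The seed is mandatory — there is no silent wall-clock seeding.

`weekly_summary` averages each index over subjects per (week, phase);
standard deviations are computed and stored in the JSON report but carry no
acceptance weight.  Several candidate definitions of the percent reduction
in weekly mean PSI are reported side by side (per-week mean drop, drop of
the 4-week mean, first-pre to last-post); none is privileged, since the
arithmetic behind a single published summary percentage of this kind is
generally not recoverable.

`render_report` emits machine JSON (deterministic, sorted keys) and a
Markdown rendering; a JSON Schema for the report ships in
`docs/report.schema.json`.

### Known limitation: rank stability under subsampling

On the bundled study data the post-phase weighting magnitudes of TP, LF and
HF are close (0.85, 0.92, 0.95).  Under random subject subsampling the
fitted magnitudes move by more than these gaps, so the full-sample ranking
HF > LF > TP > VLF is preserved only in a minority of random subsets
(roughly 15–30% of seeds at sizes 30/20/15, measured over 50 seeds).  The
package reports the rankings it computes; users should treat ranking
differences smaller than the subsampling variability as ties.

## Synthetic data

### Panel generator

`generate_panel` emulates the study's structure — 45 subjects × 4 weeks ×
2 phases — with the intervention effects applied in the post phase: stress
index × 0.7, total power × 1.4, HF power × 2.0, LF unchanged (all
configurable).  Per subject, latent pre-phase band powers are log-normal
around configurable means (defaults VLF 450, LF 400, HF 300 ms², near the
middle of the observed pre-intervention range); log-normal noise is used
throughout because HRV indices are positive and right-skewed.  Post-phase
latents scale LF and HF by their factors and rebalance VLF so total power
scales by its factor.  Weekly values multiply the phase latents by
independent log-normal noise; TP is the band sum times a small jitter
(CV 0.025), keeping the soft band-additivity invariant
|TP − (VLF+LF+HF)| ≤ 0.05·TP for the vast majority of records.

The device's stress index has no published formula.  The synthetic stand-in
is a fixed zero-intercept linear functional of the measured spectrum,

    PSI = p·(VLF + LF) − p_h·HF + q·(TP − VLF − LF − HF) + ε_dev,

with positive loadings on the sympathetically-dominated bands and on the
excess (non-band) power, a negative loading on vagal HF, and small additive
device noise (SD 1.5).  The coefficients (p, p_h) are solved from the
configured means and effects so the functional's expectation equals the
configured PSI mean in both phases; the psi_factor effect then multiplies
the post phase explicitly.  Two properties of this form are deliberate and
load-bearing:

- **Zero intercept.**  The grey fit has no constant column; any
  intercept-like component of the index is absorbed along the near-null
  (collinear) direction of the design with a seed-dependent coefficient
  that scrambles the fitted ranking.  An index that is a direct functional
  of the spectrum — as a device-computed index is — gives the generator a
  ground truth the fit can recover.
- **Excess-power loading q (default 0.9).**  Loading the index on
  TP − (VLF+LF+HF) pins the sign of the TP coefficient, which makes the
  HF-vs-TP magnitude gap first-order insensitive to the random collinear
  split.  With the defaults, the post-phase fit ranks HF first in ≈95 of
  100 seeds.

Default dispersions (between-subject CV 0.25, week-to-week CV 0.12) are
moderate — real cohorts are substantially more dispersed.  This is a
deliberate regime choice: the generator's role is to verify that the
pipeline recovers a known planted structure, and at realistic dispersion
the GM(0,N) ranking is provably unstable (see the subsampling limitation
above), so no generator can make recovery reliable there.  Passing the
recovery tests therefore shows correctness of the machinery, not that the
method is robust on data as noisy as a real cohort.  A residual limitation
remains even in this regime: the background value carries a half-row term
−x₀(k)/2, an effective negative intercept whose seed-random absorption
perturbs the fitted coefficient scale by an amount comparable to the 30%
deterministic drop in mean weighting, so the "mean weighting falls after
the intervention" readout holds in roughly 85 of 100 seeds rather than
always; the HF-first ranking readout is insensitive to this term.

The generator does not emulate: week-to-week autocorrelation,
subject-by-week interaction of the intervention effect, missing visits
(supported by the averaging stage but not generated), or any dependence
structure between PSI noise and the bands beyond the surrogate formula.

### RR-interval simulator and spectral analysis

`generate_rr` builds a 5-minute interbeat series as a base interval
(800 ms) plus one sinusoid centred in each band — VLF 0.0033–0.04, LF
0.04–0.15, HF 0.15–0.40 Hz, the conventional short-term bands; half-open,
lower edge inclusive — with variance equal to the requested band power
(amplitude √(2P)) and random phase, plus white jitter (SD 2 ms).  Intervals
are clipped to 300–2000 ms with the clipping rate logged; targets whose
summed amplitudes approach the base interval are rejected.

`band_powers` places intervals at their beat times, resamples by cubic
spline onto a uniform 4 Hz grid (cubic rather than linear because linear
interpolation low-passes the HF band by ~25% at typical beat rates),
removes the mean, estimates the PSD by Welch averaged periodograms (150 s
Hann segments, 50% overlap), and integrates each band by the trapezoid
rule; TP is the sum of the three band integrals.  Verified properties:
Parseval agreement between integrated PSD and series variance within 5%;
band additivity; generator→analyzer round trip within 25% per band over 20
seeds (the residual error is spectral-estimation variance plus interpolation
bias).

## Problem sizes used in checks

All published-value checks run on the bundled 45-subject tables (fits take
milliseconds).  Seed-ensemble checks use 50 seeds (subsampling stability)
and 100 seeds (synthetic recovery); the RR round trip uses 20 seeds at
300 s duration.
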