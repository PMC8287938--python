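# Methods

This note documents the models, conventions and numerical choices
behind `oligosaxs`, and what the synthetic-data tests do and do not
demonstrate about real measurements.

## Scattering model and containers

A 1D profile is I(s) versus momentum transfer s = 4π·sin θ/λ (2θ the
scattering angle), stored in Å⁻¹ with pointwise uncertainties σ.
Curves are immutable after validation (s strictly increasing and
non-negative, σ > 0 where I is finite, ≥ 8 points); every transform
returns a new curve, so the provenance of a reduced profile is never
destroyed in place.  A SEC-SAXS measurement is an ordered stack of
such frames on one shared grid (tolerance 10⁻⁸ Å⁻¹), one exposure per
frame.  Files are 3-column text; whitespace and comma dialects are
both accepted, non-parsing lines are treated as header text, and
nm⁻¹ input is converted only through an explicit unit flag — unit
guessing is the classic SAXS I/O failure mode and is deliberately
absent.

## SEC-SAXS reduction

The chromatogram is the per-frame summed intensity.  The sample window
is the n (default 20) contiguous frames centred on the chromatogram
maximum; buffer frames are found automatically as the longest
near-baseline run (median ± 3·MAD of the first decile of frames)
ending a margin (default 5 frames) before the first frame that exceeds
baseline by 10·MAD.  Frames are scaled onto a reference frame by the
ratio of inverse-variance-weighted summed intensities over the upper
half of the s-grid restricted to points with reference SNR ≥ 5.  The
ratio-of-sums estimator is used instead of the pointwise least-squares
scalar because it is unbiased under noise (E[Σw·I] = Σw·signal,
whereas E[I²] = signal² + σ² biases the LS denominator down) and exact
for scalar multiples.  Averaging is the inverse-variance weighted mean
with its standard error as σ.  Because sample and buffer averages are
each pinned to their own reference frame's noisy level, the averaged
buffer is rescaled onto the sample over the top quarter of the grid
(solvent-dominated) before pointwise subtraction with σ added in
quadrature; without this step the subtraction carries a small constant
offset of order σ_ref.  On simulated series the reduced curve matches
the generator's protein curve as a shape (one free scalar, itself
within ~1% of unity) with reduced χ² ≈ 1.

## Guinier analysis

The Guinier law I(s) = I(0)·exp(−s²Rg²/3) is fitted as a weighted
linear regression of ln I on s² (weights (I/σ)², the δ-method variance
of ln I).  Automatic window selection starts at the smallest usable s
(up to 5 leading points may be skipped for beamstop artifacts) and
finds the self-consistent window end with s_max·Rg ≤ 1.3; the window
is then shrunk until the fit is statistically consistent with the
data (weighted r² ≥ 0.99 and reduced χ² ≤ 1.5).  The result is
invariant under intensity rescaling and independent of data beyond
the selected window.

Two systematic effects of the sRg ≤ 1.3 convention are inherent to
the method, not the implementation, and the test suite asserts them
rather than hiding them: a uniform sphere is overestimated by
~1.8% (ln I = −x²/5 − x⁴/350 + …, x = sR_sphere), and a Gaussian
chain is underestimated by 5–7% (positive ln-curvature).  The
real-space Rg from P(r) is the package's estimator of record for
parameter recovery; the Guinier Rg is the quality-control and
convention-matching quantity.

## Dimensionless Kratky diagnostics

The transform (sRg)²·I(s)/I(0) versus sRg is scale-free.  An ideal
globular (Gaussian-form) curve peaks at exactly (√3, 3/e ≈ 1.104);
the peak is located by 3-point quadratic interpolation so its
coordinates do not depend on the s-grid.  A Debye chain instead rises
to a plateau of 2 — note the plateau value is 2 only in the true-Rg
coordinates; with the (biased) Guinier Rg of a chain it lands at
(Rg_fit/Rg_true)²·2.  Flexibility is flagged when the mean ordinate
over sRg ≥ 2.5 exceeds 0.5 (configurable): compact bodies decay well
below this, chains and globular/chain mixtures sit above it.

## P(r) inversion

The pair-distance distribution solves

  I(s) = 4π ∫₀^Dmax P(r)·sin(sr)/(sr) dr

with P(0) = P(Dmax) = 0.  P is represented directly on a uniform
r-grid (default 100 points); the endpoint bins are pinned to zero and
the interior values minimize χ² + α·‖P″‖² (second differences).  With
non-negativity enabled (default) the problem is solved exactly by
NNLS on the stacked system; a bin basis was chosen over a sine series
precisely so the constraint is exact rather than a projection
heuristic.  α is a relative weight (normalized against the data
term); when unset it is chosen by an L-curve corner search over a
13-point log grid 10⁻⁴…10².  Diagnostics: reduced χ² of the
back-computed curve, i0_est = 4π∫P dr, rg_est = √(∫r²P dr / 2∫P dr).
On a noiseless sphere the recovered P(r) matches the closed form
r²·γ₀(r/2R) to <2% normalized RMS and rg_est to 0.1%.

### Dmax estimation

Candidates over a search range are each fitted with non-negativity;
a Dmax below the particle's true extent truncates real distances and
χ² rises steeply, while beyond it χ² flattens (the constraint
suppresses most of the slow overfitting drift an unconstrained fit
shows).  The estimate is the smallest candidate within a tolerance of
the plateau minimum; the tolerance floor adapts to the observed
plateau spread.  A trace that is still falling (or flat) at the
search bounds raises an error instead of returning a boundary value.

Identifiability limits, measured on the generators: a sphere's Dmax
is recovered within one grid step and a two-sphere dumbbell within
5%, but the Dmax of a smooth 2:1 prolate ellipsoid is **not**
identifiable to 5% at 1% noise — less than 4×10⁻⁴ of its pair mass
lies beyond 0.9·Dmax, so a 10% truncation perturbs I(s) by ≲0.1σ.
Observed spread across noise seeds is roughly −13…+18%.  This is a
property of the data, not of the algorithm, and no tolerance was
loosened to mask it.  For flexible chains the support is unbounded;
the reported convention is Dmax = 4.5×Guinier-Rg, beyond which the
Debye distribution carries <0.1% of its pair mass (any choice in
~3.7–5×Rg behaves equivalently).

## Porod invariant and volume

Q = ∫s²I ds is assembled from three pieces: a Guinier-model fill over
the unmeasured [0, s_min], trapezoidal integration of the data up to
s_cut (default 0.25 Å⁻¹), and the Porod-tail closure Q_tail = K/s_cut
with K the mean of the s⁴I plateau over [s_cut/2, s_cut] (the mean,
not the median, averages out form-factor oscillations).  Without the
tail closure ~13% of the invariant of a 30 Å sphere is lost and the
volume misses by the same factor.  A residual constant background is
estimated from the top decile of the measured range by fitting
I ≈ B + K′s⁻⁴ (B clamped ≥ 0; the estimate can be disabled).  Then
Vp = 2π²·I(0)/Q; on uniform bodies (sphere, 2:1 prolate) Vp is within
5% of the true volume and invariant under intensity rescaling.  The
truncation sensitivity across s_cut ∈ {0.20, 0.25, 0.30} is below 5%.

## Molecular weight and oligomeric state

Two routes: (i) the forward-scattering ratio against a standard,
MWᵘ = MWˢ·[I(0)ᵘ/cᵘ]/[I(0)ˢ/cˢ], valid for ideal dilute particles
where I(0) ∝ c·MW; and (ii) the Porod rule MW(Da) = Vp(Å³)/1.66.  On
uniform-density synthetics the routes agree within 20%; for flexible
particles the Porod route carries the well-known volume bias and the
I(0) route is preferred.  The oligomeric state is
n = round(MW/unit), with the range [⌊(MW−δ)/unit⌋, ⌈(MW+δ)/unit⌉]
clipped to ≥ 1; δ defaults to 10% of the estimate.  Frame-by-frame MW
across a chromatogram subtracts buffer per frame, runs the automatic
Guinier fit, and applies route (i) with the per-frame concentration;
frames without a usable Guinier region are reported as missing, never
interpolated.

## Structure geometry

SASA is Shrake–Rupley with a deterministic Fibonacci sphere (default
960 points, <1% from the 3840-point value) and a fixed element-typed
van der Waals table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å, plus
common hetero elements); unknown elements are an error, not a guess.
Hydrogens are excluded by default since X-ray depositions carry them
inconsistently.  The buried surface area of an interface is
SASA(A) + SASA(B) − SASA(A∪B); both this total and its half (the
per-interface convention of PISA-style tools) are always reported
because published figures quote either.  Rotation invariance holds to
the angular sampling (~0.5% at default settings).  Contacts are
classified geometrically: salt bridge for basic-N–acidic-O ≤ 4.0 Å,
hydrogen bond for N/O–N/O ≤ 3.5 Å, hydrophobic for C–C ≤ 4.5 Å, with
salt bridge taking precedence.

Crystallographic expansion applies (rotation, translation) operators
in fractional coordinates (the C222₁ operator set ships as a bundled
constant; arbitrary operators are accepted) plus integer lattice
translations; intra-copy distances are preserved exactly and copies
get operator-suffixed chain ids.  The anti-parallel stack builder
applies a screw (default 180° with a caller-supplied translation —
half the a-repeat, 13.6 Å, for the crystal packing in question)
repeatedly to a dimeric unit; adjacent units then have anti-parallel
helix axes (principal-axis test), and inter-unit atom pairs closer
than 1.5 Å trigger a clash warning with a count.

## Motif scanning

The YG-box is Y..G repeated three times (12 residues); the
serine-motif is S...SW..S...T (13 residues) with anchor positions
1/5/9/13.  Species variants relax single anchors: K at position 1
with A at 9 (S. pombe), A at 5 (D. melanogaster); `variant_set="all"`
is their union, and each hit records whether it matches the strict
pattern.  All overlapping matches are reported.  Gaps in aligned
input are stripped before scanning, with hit positions mapped back to
alignment columns.  'x' means any standard residue; 'X' (unknown) is
tolerated in sequences but only matches wildcard positions.

## Synthetic data: what it emulates, and what it does not

Generators provide uniform spheres, prolate ellipsoids (numerical
orientation average), Gaussian chains, exact Debye double sums over
bead coordinates (≤ 5000 points), convex mixtures, Gaussian-elution
SEC series with flat buffer background, and ideal helix fixtures.
The noise model is Gaussian with σ ∝ √(I·I₀) plus a small floor —
photon counting after radial averaging.  Curves generated "noiseless"
carry exact intensities with a nominal 1% σ scale so χ²-weighted
fits remain meaningful.  All generators are bitwise reproducible
under a fixed seed.

Deliberate idealizations: no interparticle structure factor, no
hydration-shell contrast, no radiation damage or capillary-fouling
drift, flat (s-independent) buffer scattering, Gaussian elution with
a single species or a two-state concentration-dependent mixture, and
uncorrelated noise across s.  Passing tests therefore demonstrate the
correctness of the estimators under these conditions, not robustness
to beamline systematics; on real data the buffer-subtraction and
background-handling steps are the ones most exposed to the
unmodelled effects.

## Pipeline defaults

All tunables live in one table (`oligosaxs.defaults.DEFAULTS`):
sRg limit 1.3, 20 peak frames, buffer margin 5 frames, flexibility
threshold 0.5, 100 P(r) bins, s_cut 0.25 Å⁻¹, Porod divisor 1.66
Da/Å³, oligomer δ 10%, probe 1.4 Å, 960 SASA points.  A run report
records the fully resolved configuration, input checksums, per-stage
results, and per-stage failure reasons; stages downstream of a failure
are skipped, never filled in.  Problem sizes used throughout the test
suite (200-frame series, 400-point grids, 2000-bead Debye sums) were
chosen as the smallest at which the statistical behaviour of the
estimators is representative.
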