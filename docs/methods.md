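# Methods

This note documents the models, the numerical choices and the synthetic
data behind `cellmech`, in enough detail to judge what passing tests do and
do not establish about real data.

## Force-curve model and fitting

### Geometry and conventions

All mechanics are SI internally (m, N, Pa). The piezo height `z` decreases
toward the sample during approach; indentation `δ ≥ 0` means the tip is
pressing in. Deflection is stored as the raw photodiode signal in volts and
converted with `F = k·S·V` (`k`: spring constant, N/m; `S`: sensitivity,
m/V). Calibration defaults (15.2 nm/V, 18 pN/nm) sit mid-range of a typical
soft-cantilever thermal calibration; both are always explicit inputs.

### Contact model

For a rigid four-sided pyramid on an incompressible elastic half-space the
load–indentation relation is `F = (tan α/√2)·E/(1−ν²)·δ²`. The geometric
prefactor is isolated in one function; the Bilodeau variant
(`0.7453·tan α`) is selectable per fit (`prefactor_variant="bilodeau"`),
which matters when comparing absolute moduli across labs — the two
prefactors differ by ~5%, a systematic scale factor on every fitted E. The
tip half-angle defaults to 18° (nominal pyramidal probe value) and is
surfaced in provenance; an error in α propagates as a constant factor
`tan α_true / tan α_assumed` on E.

### Per-curve pipeline

1. **Baseline**: least-absolute-deviations line (IRLS) over the far 30% of
   the approach; removes photodiode offset and thermal drift tilt. LAD
   rather than OLS so occasional glitches in the baseline window do not
   tilt the fit.
2. **Contact point**: first index where baseline-corrected force exceeds
   `3 × (1.4826·MAD)` for 5 consecutive samples (robust noise scale; the
   persistence window suppresses isolated noise spikes). A curve with no
   persistent crossing is flagged non-contacting — this flag, not an
   exception, is what map cleaning consumes. The crossing is then refined
   by a profile fit of the kink model `F = A·(z₀ − z)₊²` over a window
   spanning the crossing (up to 100 baseline samples before, up to 400
   after): for each candidate `z₀` the amplitude is profiled out in closed
   form, and the SSE is minimized by grid search plus bounded polish.
   Threshold crossing alone is systematically late for soft samples (the
   quadratic response stays under the noise floor until
   `δ_c = √(thr/(C·E))`), and the kink fit removes most of that bias:
   across 200 simulated curves at 1% deflection noise the median contact
   error is ~1.5–2 sample spacings.
3. **Separation**: `δ = (z₀ − z) − F/k`, negative values excluded.
4. **Fit**: `F` is linear in `E` given `z₀`, so `Ê` is closed-form; by
   default `z₀` is re-fitted jointly (1-D search over a window scaled to
   the expected detection offset `3·δ_c`). The standard error comes from
   the linearized fit. Moduli are bounded to [1 Pa, 10 MPa]; estimates at a
   bound are flagged and treated as invalid downstream, which is also how
   glass-like substrate pixels (near-vertical contact, too few in-contact
   samples) are rejected. A minimum of 20 in-contact samples is required.

Noiseless round trips recover E to better than 0.1% over [100 Pa, 50 kPa];
with 1% deflection noise the per-curve median across seeds is within ~0.3%.
Whether the original batch-processing software re-fitted the contact point
per curve is unknown; both behaviors are available (`refine_contact`).

## Map statistics

Cleaning keeps valid pixels with E in [10 Pa, 100 kPa] (configurable),
optionally restricted to a cell mask, and reports the kept fraction so
silent data loss is visible. Median and IQR use linear-interpolation
quantiles (no convention was stated for the original analysis; this is the
numpy default and is documented here as the package's choice). The
inverse-Gaussian fit uses the closed-form MLE; it is appropriate for the
positive, right-skewed modulus distributions cell maps produce and is
cross-checked in tests against numeric likelihood maximization.

The Lilliefors test computes the KS statistic against a normal with
estimated mean/sd; the p-value is simulation-based (seeded Monte-Carlo
null table, 10,000 reps by default, cached per sample size) rather than an
asymptotic approximation table. `select_representative_sample` returns the
n values nearest the median (ties: smaller value, then input order) — the
sub-sampling rule used to pair elasticity samples with adhesion-energy
inputs.

### Adhesion energy

The zero-external-load JKR relation `γ = 2a³E/(9πR²(1−ν²))` follows from
the zero-load contact radius `a³ = 6πγR²/K` with `K = (4/3)E/(1−ν²)`. It is
dimensionally checked and isolated in one function so an alternative JKR
form is a one-line change. γ is reported in J/m². The printed units of the
published surface-energy values are mutually inconsistent (J µm⁻² vs µm⁻²),
so only the functional form and internal consistency are asserted, never an
absolute printed value.

### Group comparisons

`kw_dunn` uses the tie-corrected Kruskal–Wallis omnibus and hand-computed
Dunn z-statistics on pooled mean ranks with Holm family-wise adjustment
(the exact multiple-comparison variant used by the original GraphPad
analysis is unspecified; Holm is the documented substitute).
`welch_anova_gh` delegates the Welch F (Welch–Satterthwaite df) and
Games–Howell pairwise tests (studentized range) to pingouin. Mann–Whitney
is exact by enumeration when `n·m ≤ 400` with no ties, otherwise the
normal approximation with tie correction. Welch-type designs reject any
group with zero variance, naming it. Type-I error of both omnibus tests is
verified at α ± 2 Monte-Carlo s.e. over 2,000 null simulations at 30
observations per group — the regime where the chi-square and
Welch–Satterthwaite approximations are expected to be calibrated; at very
small n the Kruskal–Wallis chi-square approximation is conservative
(rejection ~0.04 at n=15/group), which is a property of the approximation,
not of this implementation.

## Imaging chain

`quantify_fas` composes, with the recipe's defaults:

1. **Sliding-paraboloid background** (radius 25 px): grey opening with a
   1-D parabolic structuring function applied separably along rows and
   columns (a paraboloid is additively separable; sliding 1-D parabolae is
   also how the classic implementation works). The ball convention is used
   — the structuring function is a negative parabola with apex 0 — and its
   depth is scaled to the image intensity range. Output is clipped at 0 and
   never exceeds the input.
2. **CLAHE** (block 19, 256 bins, max slope 3) via
   `skimage.exposure.equalize_adapthist`, with the clip limit derived from
   the slope as `slope/bins` (a slope equal to the bin count would leave
   the transfer function unclipped). Constant images pass through.
3. **Enhance contrast**: linear rescale saturating 0.35% of pixels, split
   between tails, to [0, 1]; monotone by construction.
4. **Auto-threshold ("Default")**: the image is mapped to 8 bits and the
   iterative isodata variant is applied — threshold = mean of the
   below-class and above-class means, iterated to a fixpoint; foreground is
   strictly above. Verified bin-for-bin against a brute-force fixpoint
   search over all 256 candidate thresholds.
5. **Particle analysis**: 8-connected labelling, per-particle area,
   perimeter and circularity `4πA/P²`, filtered to size 0.30–15 µm²
   (interpreted in calibrated units — sub-pixel px² areas would be
   meaningless at confocal pixel sizes; px² is available as an option) and
   circularity 0.00–0.99. The perimeter uses the Crofton (4-direction)
   estimator: the weighted boundary-count estimator underestimates small
   particles' perimeters badly enough to push genuinely elongated
   few-pixel particles above the 0.99 cap (an analytic circularity of 0.87
   can digitize to 1.00), while Crofton tracks the analytic value and
   keeps large digital disks in [0.85, 1.1]. The 0.99 cap itself can still
   exclude near-perfect disks; a warning is logged when more than 5% of
   candidates are cap-excluded.

Stage hashes and settings are recorded in the result's provenance, making
the chain's determinism auditable.

A known property of this recipe (also true of its ImageJ original): on a
featureless noisy image the global auto-threshold slices the noise
distribution and segments spurious specks. The zero-puncta contract is
therefore exact only for noiseless featureless images; on real "empty"
fields the particle filter output is noise-dependent.

`nc_ratio` is `(ΣI_nuc/A_nuc)/(ΣI_cyto/A_cyto)` — mean nuclear over mean
cytoplasmic intensity; areas cancel in any consistent unit. Region masks
are inputs (hand-drawn or generator ground truth); Otsu-plus-fill nucleus
segmentation from a DNA channel is provided only as a convenience.

## Synthetic data: what it emulates, what it does not

### Force maps

Curves are generated approach-only (only E is extracted; retract, adhesion
hysteresis, hydrodynamic drag and cantilever dynamics are out of scope) by
inverting the forward model: past the ground-truth contact point the
indentation solves `C·E·δ² = k·(z₀ − z − δ)` (one positive root), the
curve truncates at the 1 nN setpoint, and Gaussian noise is added on the
deflection signal. Defaults mirror the standard protocol: 15 µm ramp at
30 µm/s sampled at 2 kHz (1,000 samples), 64×64 grid over 100×100 µm. The
contact point sits at 40% of the ramp, leaving 9 µm of indentation travel —
enough for the softest cells of interest (~100 Pa needs ~5.8 µm to reach
setpoint). Substrate pixels emit a 1 GPa near-vertical response by default
(so outlier cleaning has realistic targets; the original maps' substrate
behavior is undocumented) or a flat no-contact trace. Per-pixel seeds are
spawned deterministically from the master seed. The "1% noise" convention
is an s.d. of 0.01 × setpoint force on the deflection channel.

Not emulated: viscoelastic creep, lateral tip-sample friction, cell-height
variation across the map, piezo nonlinearity. Parameter-recovery results
therefore validate the inference chain, not the physics of a living cell.

### Images

Two channels of a micropatterned cell: "vinculin" (cell-body signal plus
bright elliptical puncta) and "yap" (nucleus and cytoplasm at configured
means), on a noisy background with optional gradient. Defaults, chosen for
a well-exposed confocal maximum-intensity projection at 63×/Nyquist:
0.1 µm/px, background 200, cytoplasm 400, punctum peak 4,000 (≈10× over
the cell body), Gaussian read noise s.d. 20, Poisson shot noise optional
and off by default. Puncta are anti-aliased ellipses (4×4 supersampling)
with aspect ratio U(1.8, 3.0) — focal adhesions are elongated — placed by
dart throwing with ≥2 px clearance between supports so neighbouring puncta
cannot bridge after thresholding; placement failure after the retry budget
raises with advice. The "area" ground truth is the analytic ellipse area.

Not emulated: the microscope PSF (edges are sharp at sub-pixel accuracy,
not diffraction-limited), out-of-focus haze, punctum intensity variation,
FA clustering at the cell rim, cytoskeletal texture. Exact-count recovery
on these images demonstrates the chain's correctness and determinism; on
real images the same chain inherits the usual sensitivity of global
thresholding to staining quality.

## Acceptance experiments

The study conditions recomputed by `scripts/acceptance.py` are: uniform
64×64 maps seeded at the four reported group medians (11,518 / 371 /
1,320.62 / 405.28 Pa) with 1% deflection noise, recovered as the cleaned
map median; the reported 4,900 µm² nucleus/cytoplasm ratio (5.19) on a
constructed noiseless two-region image; and the reported wild-type count of
284 puncta on a 4,900 µm² synthetic cell (spot areas 0.5–5 µm²), recovered
exactly by the default chain. Problem sizes (4,096 curves per map, ~1 M px
images) were chosen to match the original acquisition geometry while
keeping a full run around a minute on one CPU.

## Known limitations

- The Sneddon prefactor and tip half-angle are assumptions shared with all
  pyramidal-tip AFM analyses; absolute moduli carry that systematic.
- Contact-point detection is an in-house design (threshold crossing + kink
  profile fit); vendor batch software is undocumented, so agreement with a
  specific vendor's E values is not guaranteed even though round trips
  through this package's own forward model are exact.
- The Games–Howell and Welch ANOVA stages inherit pingouin's
  implementations; Dunn's adjustment is Holm, which may differ from other
  software's in-house variants near the significance boundary.
- `simulate_cell_image` places puncta outside the nuclear ellipse only;
  projections of real cells can show perinuclear adhesions.
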