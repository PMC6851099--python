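# Methods

`peritrack` re-implements, as a tested pipeline on synthetic data, the
bespoke computations used to study transcription-driven relocation of a
gene locus toward the nucleoid periphery in live *E. coli*: counting
actively transcribing polymerases from fluorescence images, fitting the
transcription on/off kinetics, sub-pixel locus localization in
cell-normalized coordinates, and a cylindrical Monte Carlo that converts a
projected positional shift into a 3D radial displacement.

## Kinetic model of transcription

A single chromosomal gene carries a phage-polymerase-specific promoter;
labeled polymerases bind, elongate, and leave at termination.  We model the
number of gene-bound polymerases per cell as an immigration–death process:

- arrivals at constant pseudo-first-order rate `k_on` (promoter search,
  promoter-complex formation and initiation, lumped into one rate);
- independent departures at rate `k_off`, set by the elongation duration
  (termination is much faster than elongation and is neglected).

The population mean after induction at t = 0 is

    <N>(t) = a (1 − e^(−b t)),   a = k_on / k_off,   b = k_off .

`kinetics.fit_induction` fits (a, b) by weighted nonlinear least squares
(weights 1/SEM² when per-point dispersion is available, unweighted
otherwise — the choice matters little for balanced designs).  Derived
quantities: elongation rate `L·k_off` (bp/s) for gene length `L`,
elongation time `1/k_off`, promoter search time `1/k_on`.  The reported
`k_on` is the pseudo-first-order aggregate `a·b`; the per-polymerase rate
`k'_on = k_on/[RNAP_total]` is available with a configurable total
polymerase count (default 35 per cell).  The identity
`elongation_rate × elongation_time = L` holds exactly before rounding;
integer rounding is applied only at the reporting layer.

Polymerase dwell is exponential by default, keeping the process Markovian;
a fixed-duration dwell (`dwell_mode="fixed"`) is provided for sensitivity
checks — it shares the same mean curve at the plateau but differs
transiently.

A fit whose time span covers less than one e-folding of `b`
(`b·t_max < 1`) sets `plateau_reached=False` rather than failing: the
plateau and rate are then strongly correlated and the estimate should be
treated with caution.

## Intensity observables and polymerase counting

The focus-intensity estimator is the ROMIF: the 5×5-pixel window with the
maximum integrated fluorescence among windows lying **fully inside** the
cell mask (boundary handling is our choice; requiring all 25 pixels inside
avoids membrane-edge artifacts; ties break at the smallest row-major
origin).  From it:

    I_max             = mean(ROMIF) − mean(cell minus ROMIF)
    I_transcribing(t) = <I_max(t)> − <I_max(0)>
    count(t)          = I_transcribing(t) / <Ī_single>

Cells without a visible focus are included in the averages, and the
pre-induction group defines time 0.  The single-fluorophore unit
`<Ī_single>` is the mean integrated 5×5 intensity of isolated
single-fluorophore dots divided by 25, measured at the same optics; because
the same aperture is used for foci and calibration dots, the fraction of
PSF flux captured by the window cancels in the count.

Known estimator bias: because the ROMIF is a maximum over windows, cells
without a focus report a small positive `I_max` (the window-max of noise).
The time-0 baseline carries the same bias, so focus-free cells contribute
≈ 0 after subtraction, but focus-bearing cells are under-counted by
roughly (window-max noise)/unit.  The effect shrinks as the per-fluorophore
signal grows relative to the background noise; the end-to-end recovery test
runs at a bright budget where it is a few percent.

Cells whose total fluorescence exceeds a configurable percentile (default
95th) are excluded, mirroring the exclusion of cells with too many labeled
polymerases; auto-fluorescence is a configurable constant per-pixel level
(default 0 for synthetic data).

## Localization and normalized coordinates

Foci are localized by least squares of a symmetric 2D Gaussian plus
constant offset; candidate peaks must exceed the cell background by k×
robust noise sd (k = 5 by default).  When a cell mask is supplied the fit
uses only in-mask pixels: the intensity step at the cell edge (diffuse
cellular background inside, dark outside) otherwise drags the fitted
center toward the cell axis by up to a pixel.

Cell outlines are summarized by a moment-based ellipse (centroid and
orientation from second-order moments); the half-axes are the maximal
pixel extents along the principal directions plus half a pixel, so the
membrane of an ideal mask sits exactly at the half-axis.  A spot's offset
is projected onto the axes and divided by the **full** axis length
(2 × half-axis), placing the membrane at 0.5, then folded into the first
quadrant by absolute value — justified by the cylindrical symmetry of the
rod-shaped cell.  With this convention a confinement radius of l = 0.35
puts the nucleoid boundary at 70% of the cell radius, consistent with a
300-nm nucleoid half-width in a ≈0.43-µm-radius cell.  The folded
coordinates are rigid-motion invariant (property-tested).

`bootstrap_mean_ci` quantifies the uncertainty of the averaged subcellular
position by nonparametric bootstrap of the mean |x|.

## Cylindrical Monte Carlo and the inverse problem

`periphery` simulates the cell cross-section in normalized units: spots
uniform on the disk of radius `l` (rejection sampling; the square bound is
implied by the disk bound), an isotropic Gaussian localization error of
`loc_error_nm` per axis (default 70 nm), and an outward radial step of
configurable mean (default fixed magnitude, so "61 nm on average" holds
exactly; an exponential-magnitude mode exists for sensitivity analysis).
The observable is the projected shift Δmean|x| between the blurred initial
and blurred displaced ensembles.  Useful identities used as oracles:
uniform-disk moments E|x| = 4l/(3π) and Var(x) = l²/4, and the small-step
projected gain E Δ|x| = (2/π)·step before blur.

`invert_shift` maps a measured projected shift back to a 3D radial step by
bisection under common random numbers (every candidate step reuses the
same spot positions, blur noise and direction draws, and the fixed-mode
magnitude scales deterministically), making the step→shift map smooth and
monotone.

The physical scale of the normalized coordinates (nm per full cell width)
is not derivable from the cross-section model alone; `calibrate_scale`
pins it to a measured correspondence — a 61-nm mean radial step producing
a 0.07 shift of the mean folded coordinate — yielding ≈ 437 nm per
normalized unit under the full blurred pipeline (the blur and folding
attenuate the naive 2/π projection, which alone would suggest ≈ 555 nm).
This calibrated value is the `CylinderModel.scale_nm` default and is
recomputed, not hard-coded, by the calibration routine.  The axial (y)
direction is ignored in the cross-section simulation.

`nucleoid_fwhm` measures nucleoid dimensions from stained-image intensity
profiles as the linearly interpolated full width at half of (max −
baseline), the baseline being the smaller end value of the profile;
displacement magnitudes can be expressed as percent of the nucleoid
half-width (`percent_of_nucleoid`, 300 nm default half-width).

## Bulk assays

- mRNA decay: abundance series after transcription arrest are fitted by
  ordinary least squares of log abundance vs time; half-life = ln2/|slope|
  with a delta-method standard error.  A non-negative slope is an error
  (no decay).
- Degradation-corrected expression: at steady state abundance = production
  × mean lifetime, so a strain pair's production ratio is the abundance
  ratio × (τ_den/τ_num).  Verified against a forward ODE steady state to
  1e-9.
- Two-probe elongation rate: amplicon onset times (x-intercepts of the
  rising ramps) separated by a known template distance give rate =
  separation/Δonset.
- β-galactosidase activity in Miller units: 1000·OD420/(t·V·OD660).

## Synthetic data: what it emulates, and what it does not

`synthcell` generates every input with known ground truth: rod-shaped
(spherocylinder) cells of Gaussian-varying size placed without overlap by
rejection sampling (axis-aligned by default); per-cell bound-polymerase
trajectories from the immigration–death event log; the gene locus confined
uniformly in the nucleoid cross-section disk with an optional outward
relocation of configurable mean at a configurable onset; foci rendered as
flux-conserving pixel-integrated Gaussians over a uniform cellular
background with Poisson shot noise, Gaussian read noise, and optional
per-frame Bernoulli photobleaching of bound fluorophores; first-order mRNA
decay with mean-one lognormal noise; and delayed linear two-amplicon onset
ramps.

Default optics: 100-nm pixels (16-µm camera pixel / 160× magnification),
130-nm PSF sigma, frames every 10 s.  The photon budget — 450 counts per
fluorophore per frame over a background of 100 counts/pixel with 20-count
read noise — is a free parameter of the emulation, chosen once so that the
robust per-axis dispersion of repeated single-fluorophore fits is ≈ 70 nm,
the localization resolution of the experiment.  A consequence of plain
Poisson statistics is that at this budget a single fluorophore sits below
a 5σ detection threshold; pipeline demonstrations that exercise detection
therefore use a brighter budget (2,000 counts), while the 70-nm budget is
exercised by the repeated-fit dispersion test.

Not emulated: phase-contrast physics (masks are inputs), diffusion of
unbound polymerases beyond a uniform background term, cell growth and
division during the movie, camera gain/EM excess noise, and structured
autofluorescence.  Passing tests therefore validate the estimators and
their calibration chain on data matching these assumptions; they do not
certify segmentation quality or detector-specific noise behavior on real
images.

## Problem sizes and numerical choices

Simulation-backed tests use 3,000–10,000 cells for population-mean checks
(standard-error-scaled assertions at 3σ), 150 rendered cells for the
end-to-end counting check, and 40,000–100,000 Monte Carlo spots for the
geometry checks; the acceptance script uses 4,000 cells sampled every 10 s
for 6 min and the six-point decay design at 5% noise.  All stochastic
outputs are bit-reproducible under a fixed integer seed
(`numpy.random.default_rng`); the workflow derives every stage seed from
one registry.  Bisection tolerances: 1e-4 normalized units for shift
inversion (≈ 0.1 nm at the default scale).  Degenerate inputs are
explicit errors: cells too small for a 5×5 window, masks with multiple
components, ramps that never rise, profiles that never cross half-maximum,
non-decaying series.
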