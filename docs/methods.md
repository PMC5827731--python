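# Methods

This note documents the models behind each phasekit module, the defaults
and why they were chosen, the numerical choices that affect results, and
what the synthetic-data tests do and do not demonstrate.

## Sequence charge metrics (`seqcharge`)

Net charge per residue (NCPR) over a window is
(count{K,R} − count{D,E}) / length.  Histidine is counted neutral, the
convention of IDR charge-patterning tools; it *is* titrated in the
pH-dependent charge, where every ionizable group contributes a
Henderson–Hasselbalch fraction: acidic groups −1/(1+10^(pKa−pH)), basic
groups +1/(1+10^(pH−pKa)), termini included by a flag.

Two pKa presets ship: `protcalc` (D 4.0, E 4.4, C 8.5, Y 10.0, H 6.5,
K 10.0, R 12.0, N-term 8.0, C-term 3.1) and `emboss`.  The protcalc set is
the default because the NPM1 reference charge of −37.0 for residues 1–188
at pH 7.5 was computed with that calculator; the bundled sequence
reproduces it exactly, along with the B2-tract NCPR pair
(+0.212 wild type, +0.135 after T199/T219/T234/T237 → D).

Tract boundaries are data, not code: `data/npm1_tracts.yaml` places B2 at
189–240 (fixed by the published NCPR values), the construct boundaries at
188/240/241, and A2/B1/A3 at the charge blocks readable from the sequence
itself.  A1 lies inside the folded pentamerization domain and is not
annotated to residue precision.

One property has a caveat: the "net charge approaches the ionic-group
count at extreme pH" check is run at pH 0.5/13.5 on arginine-free
sequences, because Arg (pKa 12.0) still retains ~0.03 charges at pH 13.5 —
the asymptote is simply not reachable below pH 14 for that group.

## Turbidity phase diagrams (`phasediagram`)

A grid point is *demixed* iff its replicate-mean blank-subtracted A340 is
at or above a threshold, default **0.05 AU** — far above plate-reader noise
(~0.01 AU) and far below the turbidity of a demixed sample (~0.3 AU in the
generator).  The rule is inclusive at the threshold.  The boundary is the
lowest demixed partner concentration per row (and symmetrically per
column), reported on the tested grid only; no interpolation, because the
underlying assay reports points, not a fitted binodal.  Missing grid cells
are untested and excluded.  No thermodynamic (Flory–Huggins) fitting is
attempted.

## Droplet imaging (`dropletquant`)

**Segmentation** is a global Otsu threshold on the designated mask channel
(default: the partner/dense-marker channel, which has the higher SNR),
8-connected labelling, and a size filter keeping objects with equivalent
diameter 2·sqrt(area/π)·pixel_size strictly above 2 µm.  The mask is then
applied unchanged to every channel.

**Partition coefficients** follow
PC = [(I_DP − I_bkrd)/c_corr]/(I_LP − I_bkrd), all statistics means (never
medians).  I_LP is the mean of a 5-µm-diameter circle placed automatically
at the pixel farthest (Euclidean distance transform) from any droplet, with
manual override; I_bkrd is the mean of a central 5-µm ROI on a buffer-only
image.  The dye quantum-yield corrections c_corr — 0.73 (AlexaFluor 488)
and 1.43 (AlexaFluor 647) — ship as constants, and the procedure that
produces them is implemented for synthetic spectra: integrate emission over
the microscope bandpass, normalize to the water value, and average over
spectra measured at viscosity > 0.3 Pa·s, where the change plateaus.

**FRAP** is fit with the simplest standard model, a single exponential with
an immobile fraction: after normalizing to the pre-bleach mean,
I(t) = I₀ + A(1 − e^(−t/τ)); mobile fraction A/(1 − I₀) with I₀ the fitted
bleach depth, half-time τ·ln 2.  No reference-bleach correction is applied.
Recovery tests use traces sampled at 5 Hz for 40 s (200 post-bleach
frames), which holds both parameters within ~6% at 2% additive noise.

## Single-molecule FRET (`smfret`)

Photon traces are binned at 500 µs.  Burst search is a dual-threshold
scheme: the per-bin background rate is the mean of total counts at or
below their 90th percentile; bins exceeding background + 3σ (Poisson σ)
seed bursts, contiguous seed bins merge, and bursts with N ≥ N_T photons
are kept with E = N_A/N.  No γ-factor, crosstalk, or direct-excitation
corrections are applied (γ = 1), matching uncorrected ratiometric
efficiencies.

The shot-noise-limited histogram for mean efficiency ε is a Gaussian of
variance σ²(ε,N) = ε(1−ε)/N per burst size — the binomial partitioning
limit, valid when conformational dynamics are fast compared with the bin
time — averaged over the empirical burst-size distribution (N ≥ N_T).
Histograms use bin width 0.025 on [−0.1, 1.1].

Two estimator choices matter for the **excess-width ratio** (fitted σ /
shot-noise σ), and both are made for like-for-like comparison:

1. The FRET-peak width of the data is a least-squares Gaussian fit whose
   width is anchored to the second moment of the FRET-region histogram
   (E > 0.1), adjustable by ±50%.  For a unimodal peak the constraint is
   inactive; for a multi-state histogram it keeps the fit on the broad
   envelope instead of letting least squares latch onto the single tallest
   sub-state, which would hide exactly the broadening the diagnostic is
   for.
2. The predicted width is the Gaussian-fit width of the model density on
   the same binning, not its analytic standard deviation: the burst-size
   mixture is leptokurtic, so its analytic SD exceeds its Gaussian-fit
   width by ~5–10% and would bias the ratio low.

With both choices, data simulated at a single ε give ratios within 5% of
1 across seeds, and a 0.4/0.8 two-state mixture gives ratios of 2.5–5.5,
flagged as broadened (threshold: ratio > 1.1).  The zero peak (donor-only
molecules) is a narrow Gaussian (|center| ≤ 0.05, σ ≤ 0.08); fits whose
FRET peak collapses into that window or vanishes in amplitude are flagged
rather than reported.

## SAXS (`saxs`)

The default analysis window is q = 0.018–0.31 Å⁻¹.

**Guinier**: iterative fit of ln I vs q² on the largest low-q window whose
upper edge satisfies q_max·R_g ≤ 1.3 for the R_g fitted on that window;
R_g = sqrt(−3·slope).  A statistically significant positive slope is
flagged (repulsion/aggregation); a flat curve returns R_g = 0 unflagged.
Note the classic truncation bias: for a hard sphere the qR_g ≤ 1.3 window
overestimates R_g by ~2%, right at the tolerance used in the recovery
tests, so sphere tests extend low-q coverage to 0.008 Å⁻¹ (bias 1.8%).

**P(r) inversion** expands P(r) on sine functions sin(nπr/D_max) — zero at
both endpoints by construction, the classic indirect-Fourier-transform
basis — and minimizes the σ-weighted residual plus α·∫P″² dr, which is
diagonal in this basis.  The basis size is the Shannon channel count
ceil(q_max·D_max/π) plus a 15-term margin (capped at 50); smoothness is
controlled by α, not truncation.  α defaults to an L-curve corner search
over a 25-point log grid, and doubling it changes the real-space R_g of
noiseless sphere data by < 1%.  Negative P(r) excursions are reported as a
negativity fraction, not clamped.  R_g² = ∫r²P dr / (2∫P dr).  A strong
systematic trend in the weighted residuals (lag-1 autocorrelation > 0.5
with large misfit) flags D_max as too small.

**Bead models**: one bead per residue, unit scattering weight, no
hydration shell or atomic form factors — a deliberately coarse model whose
purpose is R_g/χ² behaviour of ensembles, not absolute-scale curve
prediction.  Debye sums are exact by default; ensemble scoring bins pair
distances at 0.02 Å (phase error < 0.003 rad over the q window, relative
intensity error ~2×10⁻⁴, ~15× faster).

**Ensembles**: the rigid core (a synthetic five-cluster pentamer ring
unless caller-supplied coordinates are given) is held fixed across
conformers; each tail regrows per conformer as an excluded-volume random
walk (bond 3.8 Å, bead diameter 4 Å, clash checks against everything but
the bond predecessor, whole-tail restart on dead ends, 10⁴ step-rejection
budget per tail).  Generation is deterministic per seed.  Tail end-to-end
distances scale as N^2ν with ν ≈ 0.57, inside the 0.5–0.65 band expected
between ideal and self-avoiding walks.

**χ²**: reduced, χ² = (1/(n−1))·Σ[(c·I_model − I_target)/σ]², with the
scale c minimized analytically.  A conformer scored against a 2%-noise
curve generated from itself lands in [0.5, 1.5], and the χ²-vs-R_g basin
minimum falls at the generating R_g.

## Hydrodynamics (`hydro`)

Stejskal–Tanner decays are fit as one group (all replicates, e.g. 6
gradients × 3 replicates = 18 points) by least squares through the origin
in ln(I/I₀) vs b = ϒ²g²δ²(Δ−δ/3); the model has no intercept, and a
free-intercept mode exists purely as a normalization diagnostic.
ϒ(¹H) = 2.675222×10⁸ rad s⁻¹ T⁻¹.  Defaults for Stokes–Einstein
conversion are 298.15 K and η = 8.9×10⁻⁴ Pa·s (25 °C water), explicit in
`HydroConditions` since R_H scales linearly with both.

Gradient calibration solves for the 100% gradient amplitude from a decay
of a reference sample of known R_H (the anchor used in the reference
protocol: R_H = 2.3 nm, six gradient fractions of 0.423 T/m): the slope
against b evaluated at unit g_max equals −D·g_max², so
g_max = sqrt(−slope/D_ref).  Note the direction of the scaling law this
implies: assuming a *larger* reference R_H (smaller D_ref) yields a
*larger* g_max, by sqrt(R_ratio).

For sedimentation velocity, only the algebraic size-and-shape relations
are implemented: f = M(1−v̄ρ)/(N_A·s), f₀ = 6πηR₀ with
R₀ = (3Mv̄/4πN_A)^⅓ (anhydrous sphere, cgs units internally).  Lamm
equation inversion and 2-D regularization are out of scope; s, M, v̄, ρ
are inputs.

## Synthetic data (`synthetic_data`)

Each generator is an exact forward model of the corresponding analysis
plus controlled noise: step-profile turbidity grids with Gaussian read
noise (σ 0.01 AU); two-phase disk images where the in-droplet signal is
light-level × PC × c_corr above background (so the partition analysis is
an exact inverse in the noiseless case), optional Poisson noise;
Poisson-process photon traces with geometric burst sizes (mean 60
photons — a modelling choice, since real burst-size distributions depend
on setup), binomial acceptor partitioning, and a donor-only fraction for
the zero peak; analytic sphere or Debye ensemble curves with relative
Gaussian noise; Stejskal–Tanner decays with multiplicative noise; and
single-exponential FRAP recoveries with additive noise.

All randomness derives from one integer seed per invocation, namespaced
by stage name (`(seed, crc32(stage))`), so outputs are bitwise
reproducible and adding a stage never perturbs another stage's data.
Every generator returns a ground-truth dictionary sufficient to score the
downstream analysis.

**What passing recovery tests shows — and what it does not.**  The
generators share their forward models with the fitting code (deliberately,
so inverse consistency is testable to machine precision), and they omit
instrument artifacts: detector afterpulsing, beam smearing, photobleaching
during FRAP acquisition, uneven illumination, droplet drift and fusion,
aggregation upturns in scattering.  Recovery therefore demonstrates
correctness of the estimators under their stated assumptions, not
robustness to systematic errors of real instruments.  Conversely, the
charge metrics are not simulation-based at all: they are checked against
published reference values for the bundled NPM1 sequence.

## Problem sizes

Default test and reproduction sizes: 10⁴ bursts per smFRET condition
(10⁵ draws for the Monte-Carlo density check), 40–50 conformers of a
125-bead core with five 40-bead tails for χ² basins, 12×12 turbidity grids
in triplicate, 256² px images at 0.2 µm/px, 18-point diffusion decays, and
500 repeats for the diffusion error-coverage check.  These sizes give
stable statistics for every tolerance quoted above while keeping the whole
suite fast.
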