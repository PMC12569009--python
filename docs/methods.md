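# Methods

`lensulm` models a large-aperture, low-channel-count 3D ultrasound imaging
chain end to end: a 1 MHz matrix of 252 large (4.5 × 4.5 mm², ≈3λ)
piezocomposite elements on a 5.48 mm pitch, each widened by a compound
diverging acoustic lens, firing single-element diverging waves and feeding a
3D ultrasound localization microscopy (ULM) pipeline. This note documents
the models, the parameters that matter, the numerical choices, and what the
synthetic data generator does and does not emulate.

## Coordinates and units

Right-handed coordinates with the probe face at z = 0 and +z into the
medium. Lengths are millimetres, times seconds, speeds of sound m/s in
specifications (converted internally), frequencies MHz for transducer
specs and Hz for rates. Volumes follow node-centred voxel grids: world =
origin + index × spacing.

Two wavelength constants are used deliberately: λ = 1.5 mm for design
arithmetic (element counts, pitch ratios) and λ = 1.54 mm (= c/f₀ at
1540 m/s) for field simulation.

## Compound lens model

The lens stack is an epoxy plano-convex spherical cap (c₁ = 2570 m/s,
apex thickness and radius of curvature both 3.2 mm) under a silicone layer
(c₂ = 1015 m/s) filling up to a flat top 0.375 mm above the apex, radiating
into tissue at c₃ = 1540 m/s. It is treated as a thin phase screen: each
point of the element face carries the one-way transit-time offset through
the local layer thicknesses, plus a constant amplitude transmission from
the interface impedance steps (3 / 1.1 / 1.54 MRayl). Because the epoxy is
fast, the centre of the wavefront is advanced and the beam diverges — the
screen is well approximated by a spherical wave from a **virtual point
source** f ≈ 2.4 mm behind the element face (least-squares fit of the
screen over the face; residuals ≲ 0.6 rad rms at f₀).

Two consequences:

* **Field simulation** uses the exact screen: the transmit field is a
  broadband time-domain Rayleigh summation over λ/8-sampled sub-sources
  with soft-baffle obliquity, and "pressure" is the peak analytic-signal
  magnitude of a 2-cycle Hann tone burst.
* **Beamforming** uses the virtual source: two-way delays are computed to
  the virtual element positions plus a constant per-element offset (apex
  delay − f/c + the screen's on-axis group delay). This keeps the full
  aperture coherent; the cruder constant-apex-only correction is available
  as `lens_model="apex"` and degrades lateral resolution roughly three-fold.

Directivity is quantified as the −6 dB angle at 35 mm depth along a
circular arc: the contiguous span around the peak where the amplitude stays
above half its maximum. The package reports the **half-angle** from the
beam axis; simulated values are ≈ 49.6° (λ/2 element), ≈ 35.0° (lensed 3λ)
and ≈ 11.8° (bare 3λ), reproducing the design ordering.

## Receive sensitivity and coverage

Sensitivity follows the receive-energy definition
I(x, y, z) = Σᵢ ∫|RFᵢ|² dt for a small transmitter at every voxel. The
implementation evaluates each element's Rayleigh surface integral exactly
(near field included) at three frequencies across the pulse band — a
discrete Parseval quadrature of the echo energy. Maps are normalized
per array to their own maximum; the covered volume at −18 dB then compares
each design's usable field of view around its own peak sensitivity. The
comparison volume spans 105 × 100 × 90 mm³ starting 10 mm from the probe
face: inside the contact near field the map maximum reflects the grid
discretization (distance to the nearest element face) rather than array
design, so it is excluded. Under this model the dense λ/2 matrix covers
≈ 42% of the multi-lens volume; the sparse array's incoherent 1/r² sum is
nearly uniform over the volume and saturates coverage, which is a known
divergence from the reference behaviour of a physical sparse probe (whose
absolute sensitivity, not geometry, is limiting).

## Synthetic acquisitions

Microbubbles are ideal linear point scatterers. Each echo is a delayed,
weighted replica of the 2-cycle transmit pulse: delay = (source→bubble +
bubble→element)/c plus the lens apex delay per path, with the envelope
additionally shifted by the lens's angular group delay; amplitude =
product of the two far-field element gains (complex, tabulated at f₀ from
the lens screen), obliquity and 1/r per path, times a per-bubble
echogenicity drawn uniformly in [0.5, 1]. The record is sampled as
**complex analytic (IQ) data at 2 samples per wavelength** — the faithful
software equivalent of 100%-bandwidth bandpass digitization, where storing
real samples would put the carrier exactly at Nyquist. The time reference
is the pulse envelope peak, so an echo culminates exactly at its two-way
transit time. Optional white complex noise is set relative to the peak
echo amplitude. Records can be depth-gated (`record_start`).

The tube phantom carries Poiseuille flow: v(d) = v_max(1 − (d/R)²) with
v_max = 2Q/(πR²); 75 mL/h through the 870 µm tube gives v_max ≈ 70.1 mm/s.
Bubbles arrive as a Poisson process with **flux-weighted radial positions**
(no arrivals exactly at the no-slip wall) and the tube is seeded in steady
state (uniform along its length, expected count = arrival rate × mean
transit time), so the population is stationary from the first frame. When
driven through the pipeline, the arrival rate is concentration × flow
(constant dilution), and the imaging box excludes an 8 mm inlet zone where
discrete-time point-inlet arrivals are still bunched. What this generator
does **not** emulate: nonlinear bubble dynamics, shell resonance,
polydispersity, tissue speckle and attenuation, out-of-plane vessel motion;
passing the synthetic tests therefore demonstrates the pipeline's geometry,
timing and statistics, not contrast-specific physics.

Vessel trees obey r_parentˣ = r₁ˣ + r₂ˣ exactly at every bifurcation
(asymmetry fraction uniform in [0.35, 0.65]), with flows split in the same
proportions — ground truth for Murray's-law fits. Synthetic ECG
(Gaussian R-peaks with 2% RR jitter) and sinusoidal respiration provide
gating windows (|respiration| below a quantile) and triggers (R-peaks
inside windows).

## Beamforming and Doppler

Delay-and-sum with coherent compounding over the transmits of one volume,
then envelope: RF is band-limited-upsampled ×4 along time (one-sided FFT
zero-padding), linearly interpolated per channel, and summed as complex
numbers in a numba kernel; the envelope is the magnitude of the compounded
sum. No receive apodization. Delays past the record end contribute zero
and are counted. The clutter filter is the standard spatiotemporal SVD on
the space × time Casorati matrix with index band cuts; power Doppler is the
per-voxel sum of squared envelope over frames.

## Localization and tracking

The two-threshold scheme:

1. **Amplitude**: 3D local maxima (26-connectivity) above
   max(4 × robust noise (MAD), volume max − 12…14 dB). The max-relative
   floor is what suppresses side- and grating-lobe ghosts of bright
   bubbles; intensity-sorted non-maximum suppression (ellipsoidal
   exclusion, 2 PSF FWHM) removes residual satellites.
2. **PSF correlation**: Pearson correlation between the candidate
   neighbourhood (2 FWHM window per axis) and a Gaussian PSF model,
   threshold 0.6 by default. Elongated grating-lobe ringing correlates
   poorly with the isotropic model and is rejected.

Survivors are refined per axis by log-parabolic interpolation through the
three samples across the peak after subtracting the window-boundary median
as background (exact for Gaussian peaks; an intensity-weighted-centroid
variant is available). Median 3D localization error on isolated simulated
bubbles at 20 dB SNR is ≈ 0.12 mm (< λ/10).

Tracking is optimal frame-to-frame assignment (Hungarian) under a hard
distance gate of 1.2 × expected displacement + 0.3λ jitter allowance, with
1-frame gap closing and a 3-localization minimum. Track positions are
smoothed (5-point moving average) and per-step velocities are local linear
regressions over ±2 frames of the raw positions — frame-difference
velocities at λ/10 jitter would carry ~50 mm/s of noise and a strong
speed-magnitude inflation. Maps deposit resampled track points (half-voxel
steps) into density / mean-speed / axial-direction volumes, usually on a
much finer grid (75 µm default in the pipeline) than the beamforming grid.

## Motion correction

Inter-block rigid registration maximizes normalized cross-correlation of
power Doppler volumes over the valid overlap, with a 3-level pyramid,
phase-correlation translation initialization, multi-start Powell search
and the reference-volume intensity centroid as rotation centre. The
reference block is the one with the most tracked bubbles (ties → lowest
index). Recovered transforms (inverted) move each block's track points;
track counts and frame indices are never touched. The intra-block variant
splits a block into three contiguous segments (remainder to the last:
85/85/86 for 256 frames) and registers segment power Doppler to the first.
On blob phantoms, translations recover to < 0.1 voxel and rotations to
< 0.2° for motions up to ±5 mm / ±5°.

## Quantification

* **Skeletons**: binarize density (≥ 1 count), 3D skeletonize, assign each
  centreline voxel the anisotropy-aware Euclidean distance transform as
  radius; branch labels from connected components after junction removal.
* **Poiseuille profiles**: per-track aggregation (mean transverse offsets,
  median speed, in-slab step count as weight; tracks with < 12 in-slab
  steps excluded as transient ghosts), then a linear fit of
  v = a + b·ρ² + c·d_n — the paraboloid with its centre free along the
  axial offset direction, absorbing the small systematic depth offset of
  the imaging chain — with 2.5-MAD robust re-fitting. v_max = centre value,
  R = √(v_max/|b|). A fixed-radius variant fits only the amplitude. The
  binned 1D profile for display and adjacent-bin t-tests uses the signed
  offset along the chosen normal within a one-bin-wide band in the third
  direction.
* **Flow**: Q = v_max πR²/2 (Poiseuille mean = v_max/2), reported in mL/h.
* **t-tests**: classic pooled-variance unpaired two-sided Student's t per
  adjacent bin pair; under-filled bins are skipped and flagged.
* **Murray fits**: OLS of log Q on log r; exponent = slope.
* **FSC**: per-shell (one frequency voxel wide) normalized cross-spectral
  correlation; the ½-bit threshold uses the standard information-content
  formula with n_eff = shell voxel count / 2; resolution = 1 / first
  crossing frequency, or "not reached". Splitting is the caller's choice
  (random 50/50 of tracks with a fixed seed in the examples).
* **Gated dynamics**: cardiac phase = (t − previous R)/(RR interval) per
  track step, averaged per phase bin within an optional vessel mask;
  resistivity index RI = (v_max − v_min)/v_max over the cycle (the standard
  clinical definition; the source material does not print a formula).

## Study sizes

All simulations are desk-scale, chosen once for a single-CPU workstation:
directivity on 713-point arcs; coverage on a 4–6 mm grid over
105 × 100 × 90 mm³; synthetic-aperture PSFs with all 252 transmits on a
0.1 mm lateral line; the tube-flow study as 3 repeated measurements per
rate (2 blocks × 96 volumes, ~4 concurrent bubbles) summarized by the
median — the robust desk-scale analogue of a repeated-measurement protocol
with means and error bars; Murray recovery over 100 six-generation trees;
registration on 32³ blob phantoms. The physical acquisition parameters
(PRF 5000 Hz, 16 sources, 312.5 Hz volume rate, 2 samples/λ, 256-volume
blocks with a 300 ms inter-block gap) are never scaled — only durations and
grids are.

## Known limitations

* The sparse-array coverage saturates under any linear receive model we
  examined (see above); the dense-array ratio and the multi-lens/dense
  ordering are reproduced.
* The synthetic-aperture lateral width at 30 mm comes out ≈ 0.96 mm —
  slightly sharper than the reference 1.15 mm — because the virtual-source
  beamformer compensates the modelled lens almost perfectly; deeper targets
  (45/60 mm) agree within 10%.
* Echo synthesis is narrowband in directivity (gain at f₀ with a
  group-delay envelope shift); strongly broadband angular effects are only
  captured by the transmit-field engine.
* Tube diameters inferred from sparse track sets are quantized by map
  voxels until the lumen fills; the flow estimator therefore leans on the
  velocity-profile radius, not the skeleton, at desk scale.
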