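# Methods

`epinav` is a desk-scale model of a motion-robust whole-brain 3D-EPI BOLD
fMRI acquisition with embedded volumetric navigators, together with the
reconstruction, pulse-design and resting-state analysis machinery needed to
evaluate it. Everything below runs on synthetic data generated by the
package itself; no download or scanner data is involved.

## The acquisition being modelled

One resting-state run consists of:

* a **3D gradient-echo EPI** volume acquisition, segmented over kz (two
  shots per kz plane, TR 39 ms, TE 21 ms), undersampled 3 x 4 with a CAIPI
  lattice (12-fold), volume TR 2.34 s;
* an **embedded volumetric navigator** between each excitation and the BOLD
  readout: a low-resolution single-echo 3D-EPI volume sharing the imaging
  FOV, undersampled 4 x 2 with blipped CAIPI, eight ky-kz lines per TR, so
  a whole navigator volume fills 12 TRs of the full protocol (468 ms
  temporal resolution; 3.76 ms of readout per TR at 0.47-ms echo spacing);
* a fully sampled multi-echo GRE **reference scan** that supplies receive
  sensitivities, the GRAPPA autocalibration block and a high-resolution
  anatomical reference;
* subject-specific **kT-point spatial-spectral pTx pulses** for uniform
  water-selective excitation (24 points, 3.8 ms, 10 degrees nominal flip,
  fat stopband at the -1565 Hz water-fat shift of 10.5 T).

The desk-scale default grid is 48 x 44 x 36 voxels at 4 mm (navigator
24 x 16 x 16); the k-space undersampling factors, navigator schedule and
timing are the protocol's own.

## Forward model and reconstruction

Per shot *s* the signal model is

    y_s = P_s F Phi_s C T_s x + n,

with `T_s` the rigid head pose of the shot, `C` the receive sensitivities,
`Phi_s` the off-resonance phase of the shot's field state (global g0 in Hz
plus spatially linear gx, gy, gz in Hz/mm, accrued on the time since *that
shot's excitation*), `F` the DFT and `P_s` the sampled CAIPI lines. Key
numerical choices:

* **Exact rigid motion operator.** `T_s` is implemented spectrally: each
  axis rotation as three FFT shears and the translation as an FFT phase
  ramp. The operator is unitary, its adjoint is the inverse motion, and it
  introduces no interpolation blur. This matters: with a trilinear or even
  cubic sparse resampler, the pose-dependent interpolation error (0.2-2% of
  signal) dominates the corrected-mode temporal noise floor and can make
  the corrected reconstruction *look* worse than the uncorrected one on
  temporal-stability metrics. Pull-resampling with trilinear interpolation
  remains the default for ordinary image resampling (`apply_rigid`), where
  a blur-free periodic operator is not wanted.
* The DFT over the phase-encode plane is evaluated with explicit phase
  matrices (exact adjoint by conjugation); the operator passes a
  dot-product test at machine precision for arbitrary encoding states.
* Off-resonance phase is evaluated per ky line at the line's echo time
  within its own TR. Using the volume clock instead is a factor-16 error
  that makes a few-Hz drift catastrophic; the within-TR clock reproduces
  the mild degradation the protocol actually suffers.
* Volumes are reconstructed by conjugate gradients on the Tikhonov
  normal equations (eps 1e-6, relative-residual tolerance 1e-6, up to 60
  iterations; the quadratic cost is recorded and non-increasing). The
  **uncorrected** control is the identical solve with identity states.
  At 12-fold undersampling with 16 synthetic channels the normal operator
  needs about 60 Krylov steps; the classic 30 are not enough.

## Navigator processing

* **GRAPPA**: 2D kernels on the ky-kz plane (default 5 x 2 x 2 acquired
  sources per missing sample, Tikhonov 1e-3 relative), calibrated on the
  navigator-matrix centre crop of the reference scan. Missing-sample
  classes are residues of the *sheared* CAIPI lattice
  (`dy = (ky - shift*(kz div Rz)) mod Ry`); acquired samples are preserved
  bit-exactly.
* **Motion estimation** registers each navigator magnitude to the run's
  first frame. Two paths exist:
  * the plain path warps the reference frame with trilinear interpolation
    and minimises masked SSD by Gauss-Newton over a 2-level pyramid —
    adequate when frames and reference share a generation chain;
  * the pipeline path (used by the session driver) compares the frame
    against an *acquisition-consistent prediction*: cubic-spline warp of
    the reference-scan volume, coil weighting, k-space crop to the
    navigator band, undersampling and GRAPPA fill with the session kernel,
    root-sum-of-squares magnitude. At navigator resolution a rotation
    changes the band-limited image less than a trilinear warp's own
    interpolation error, and GRAPPA residual aliasing is pose-dependent;
    building both effects into the prediction removes an otherwise
    irreducible 0.1-0.3 degree rotation bias. Gauss-Newton with a
    finite-difference Jacobian, frozen ("chord") after the first steps.
* **Field estimation** fits the motion-compensated navigator phase
  difference against [1, x, y, z] by weighted least squares
  (magnitude-squared weights); it is exact on noiseless linear-phase
  inputs and warns when more than 5% of masked voxels approach the wrap.
  No unwrapping is attempted — scanner drifts at this scale stay wrap-free
  at the 10-ms navigator echo time.

On the default session (20 frames, smooth drift <= 2 mm / 2 degrees, B0
drift <= 4 Hz global and 0.02 Hz/mm linear, 2% complex k-space noise) the
recovered motion has RMS error of a few thousandths of a millimetre /
hundredths of a degree — far inside the 0.2 mm / 0.15 degree residual
scale reported for the in-vivo protocol, as a noise-free-model simulation
should be.

## Pulse design

The small-tip system matrix maps per-channel drives at each kT point to
flip angle at (voxel, frequency) samples: water passband {-100, 0, 100} Hz
at the nominal flip, fat stopband at the same offsets around -1565 Hz.
Magnitude least squares is solved by variable exchange (phase update /
regularised linear solve); the cost is monotone non-increasing and the
best iterate is returned. The default lambda comes from a 10-point
logarithmic sweep constrained to four times the CP-mode RF power. The
hard-pulse Bloch simulator shares the matrix's transverse-phase convention
(an earlier sign mismatch suppressed the mirror of the fat band — caught
by the stopband check, worth a warning to anyone reimplementing). On the
default 16-channel fixture the design reaches a flip-angle CoV of ~0.01
against ~0.31 for the CP mode, mean fat-band flip under 0.2 degrees, and
agrees with the linear model to ~1.5% median at 10 degrees.

kT-point locations are a fixed symmetric set within +/-2 cycles/FOV (the
selection method is a design freedom; the locations are inputs and are
never mutated by the designer).

## Synthetic data: what it does and does not emulate

* The **phantom** is procedural: nested, strongly eccentric soft-edged
  ellipsoids defined in world coordinates, so any grid over the same FOV
  sees the same object and a posed evaluation is analytic (motion never
  passes through gridded interpolation). The edge transition defaults to
  1.5 voxels of the simulation grid — an object sharper than its grid can
  resolve injects aliasing that no real acquisition shows and biases every
  comparison. The eccentric interior is what makes rotations observable at
  navigator resolution; a rotationally symmetric object would leave rz
  nearly unconstrained.
* **Receive coils** are Gaussian lobes tiled over a helmet with
  channel-specific linear and quadratic phases. The phase diversity is
  load-bearing: without it, 12-fold undersampling is not invertible with
  16 channels. They are not Biot-Savart solutions.
* **Transmit maps** place elements on a ring with a propagation-like phase
  that makes the CP mode centre-bright with CoV ~0.3 over the head, the
  nonuniformity scale reported for CP drive at this field strength.
* **Motion** is an integrated low-pass random walk (frame 0 = identity),
  optionally with a breathing-linked 0.3-Hz oscillation on tz/rx, or a
  single mid-series step. **Field drift** is an analogous walk in
  (g0, gx, gy, gz).
* **BOLD dynamics** are seeded sinusoids (0.01-0.08 Hz) in spherical
  parcels riding on the moving head, at 2% of parcel baseline.
* Not modelled: physiological noise beyond the rigid respiratory proxy,
  relaxation/spin history, slice profiles, susceptibility distortion,
  EPI ghosts, through-motion coil changes. Passing tests therefore
  demonstrate algorithmic correctness and the qualitative corrected vs
  uncorrected ordering, not in-vivo effect sizes.

## The moving-session comparison

The resting-state comparison session is deliberately small (24 x 20 x 16 at
8 mm, 8 channels, 2 x 2 CAIPI, 40 volumes at the protocol's 2.34-s volume
TR — 36P regression needs more volumes than regressors). The evaluation
chain mirrors the study's: volume realignment, 9 base confounds (6 motion +
global/WM/CSF means) expanded to 36P, zero-phase second-order Butterworth
band-pass (0.01-0.08 Hz) of data *and* confounds, voxelwise regression,
then tSNR / ALFF / ReHo (27-voxel Kendall W) / parcel FC. Two choices are
worth stating:

* For the tSNR and ReHo comparisons the uncorrected series is realigned
  with the *known* per-volume poses using the exact spectral operator —
  realignment then neither smooths the noise (trilinear resampling would
  inflate the uncorrected tSNR by 10-25% at these voxel sizes) nor injects
  registration noise. The residual-FD comparison keeps *estimated*
  realignment: estimation is the quantity there.
* The acceptance comparison uses the step-motion style (4 mm / 3 degrees at
  mid-run), the abrupt-movement scenario where intra-run inconsistency
  hurts the uncorrected reconstruction most; with slow drift alone the
  uncorrected artifacts are temporally smooth and largely invisible to
  temporal-stability metrics, which compresses the margins.

With these conditions the corrected series shows higher in-mask tSNR,
lower residual-realignment FD, higher ReHo inside the ground-truth
coherent parcels and lower ReHo elsewhere than the uncorrected series —
the qualitative pattern of the in-vivo evaluation. The margins are a few
percent (tSNR) and are not calibrated to the in-vivo effect sizes, which
depend on the human data and full external preprocessing.

## Conventions and degenerate cases

* World frame: right-handed, mm, axes aligned with array axes; 0-based
  indices; rotations extrinsic x -> y -> z about the volume centre,
  degrees in all interfaces. Decomposition at |ry| = 90 degrees raises an
  explicit gimbal-lock error.
* k-space indices put DC at floor(N/2) on every axis; even matrix sizes
  are assumed by the centred-FFT helpers.
* Zero-SD voxels yield 0 and a flag in tSNR/ALFF; KCC neighbourhoods are
  truncated at the mask edge to the voxels actually present; standardized
  DVARS divides by the series' median raw DVARS; FD uses the 50-mm
  rotation radius convention.
* All generators are pure functions of (spec, seed); identical configs
  give bit-identical sessions.
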