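# Methods

This note documents the models behind the synthetic-data generators, the
measurement pipeline's estimator designs, the numerical choices, and the
limits of what the passing test suite demonstrates.

## Synthetic confocal fields

The imaging generator (`cochleaquant.synth.imaging`) emulates the quantified
content of an organ-of-Corti whole-mount z-stack, not its full optics or
histology.

**Geometry.** Inner hair cells sit in a single row, elliptical footprints of
5.0 × 3.8 µm semi-axes on a 12 µm pitch, 10–20 cells per field.  Each cell
carries a configurable number of synaptic pairs (default 16) on a basal ring
at 0.92 of the footprint.  Ring slots are spaced uniformly in *arc length*
with a small angular (±8% of a slot) and radial (±0.1 µm) jitter, which
keeps nearest-neighbour puncta ~1.5 µm apart all around the ellipse.  This
mirrors the anatomy — ribbons ring the IHC basal pole and are resolvable at
confocal resolution, which is the premise of projection-based counting —
and it is a deliberate design constraint: slots uniform in *angle* crowd
near the minor axis and produce systematic merge undercounts that no
counting algorithm could undo.  Paired receptor puncta are offset 0.3 µm
radially outward (the synaptic cleft); orphans (unpaired puncta) are added
per channel at a configurable rate.

**Volumes.** Punctum volumes are log-normal, median 0.35 µm³ with
σ(log) = 0.4, clipped to [0.1, 2] µm³ — inside the 0.04–5 µm³ admissible
range and consistent with reported ribbon / receptor-patch sizes.  The
lower clip also keeps objects above the *sizing* resolution floor of the
default PSF (see below); smaller volumes can be simulated but cannot be
sized from shape, only from flux.

**Rendering.** Each punctum is rasterised as a solid ellipsoid (axial
elongation equal to the PSF's axial/lateral width ratio, 2.5 by default) of
*exactly* `round(volume / voxel volume)` voxels — voxels ranked by
normalised ellipsoid distance — so planted volumes are exact in voxel
units.  Channels are blurred with a separable Gaussian PSF
(σ_xy = 0.2 µm, σ_z = 0.5 µm by default; a standard confocal
approximation), then degraded with Poisson shot noise and additive
Gaussian read noise (background 10 counts, read σ = 2, peak signal
160–200 counts; peak SNR ≈ 8–10, and no voxel approaches saturation).
Two voxel presets mirror the two acquisition modes: 0.11 × 0.11 × 0.3 µm
(counting) and 0.11 × 0.11 × 0.2 µm (volumetry); both are supported
everywhere and neither is asserted as "the" setting.

**What is not modelled:** hair-cell nuclei (CtBP2 weakly stains them in
real tissue), tissue autofluorescence and depth-dependent attenuation,
chromatic or stage drift between channels, non-Gaussian PSF side lobes,
and cell-to-cell brightness variation.  Passing recovery tests therefore
show the algorithms are correct for well-calibrated, geometrically
resolvable data; they do not show robustness to those real-world artefacts.

## Counting branch

Per-channel maximum projections are binarised (threshold strictly above the
cut; foreground recorded in a provenance log), the ribbon and receptor
projections are multiplied into a float64 merged image whose binarised
particles define colocalized puncta (multiply-then-binarise by default;
binarise-then-multiply is available), and 8-connected particles of at least
4 px (≈0.05 µm² at 0.11 µm pixels, below any admissible synapse footprint)
are counted per ROI by centroid membership — a deterministic, tie-free
assignment.

Two scale-covariant thresholds are provided: robust background
(median + k·MAD, default k = 4; the default) and Otsu.  Scale covariance
makes counts invariant to acquisition gain, which is asserted as a
metamorphic test.

Automatic ROIs come from the hair-cell channel: threshold, fill, drop
sub-cell fragments, split touching cells by marker-based watershed on the
distance transform (markers at least 60 px apart, under one cell pitch),
drop border-touching cells, then extend each ROI 6 px beyond the cell body
— the synaptic rim sits just outside the myosin footprint — while keeping
ROIs disjoint by clipping to the watershed tiling of the full frame.

## Volumetric branch

**Richardson–Lucy.** Multiplicative RL with the observed image as the
starting point, reflective (symmetric) boundary handling to avoid edge
ringing on small fields, and a floor of 1e−12 in the ratio to avoid
division by zero.  Ten iterations is the pipeline default.  With a
normalised PSF, total intensity is conserved to well under 0.1% on
interior-supported images (asserted).  Separable kernels run as three 1D
convolutions; general kernels use an FFT with a cached transfer function.

**Segmentation and the voxel gate.** Detection uses the robust-background
threshold on the deconvolved stack; 26-connectivity labels components
(6/18 configurable); the 20–2000 voxel gate discards everything outside
0.048–4.84 µm³ at the volumetric voxel size.  Labels are deterministic
(sorted by first-voxel position).  Border-touching objects are kept but
flagged; objects under 2 voxels across any axis are flagged as below the
instrument resolution limit.

**Why sizing needs calibration.** At this PSF, puncta are comparable in
size to the blur: a single global background cut inflates voxel counts
3–5× through the residual blur skirt, while any fixed fraction-of-peak cut
under-counts large objects (RL concentrates their flux into sharp interior
peaks) and over-counts small ones.  Both failure modes were measured during
development; neither meets a 25% volume-recovery tolerance.

**Flux-calibrated sizing (`refine="model"`, the default).** Deconvolution
conserves flux, so an object's excess flux F equals (brightness A) ×
(volume in voxels), and F is the one statistic that is unbiased at every
size.  The unknown brightness is self-calibrated per channel in two
stages: (1) a forward model of the full measurement chain — solid
ellipsoid, PSF blur, the same number of RL iterations — is computed at run
time on a log-spaced volume grid, and its fraction-of-peak voxel count
(fraction 0.3, measured on a 3-voxel-median-filtered image to suppress RL
speckle) is inverted for each detected object; (2) the median F/V ratio
over the objects whose shape statistic is safely above the model's
resolution floor calibrates A, and every object is then sized as F/A and
trimmed to its brightest voxels, so that `volume_um3 = n_vox·dx·dy·dz`
holds exactly and the voxel gate applies to the refined count.  On default
synthetic stacks the self-calibrated brightness lands within ~5% of the
rendered truth and median pair-volume error is ~10%.  The assumption doing
the work is *shared per-channel staining brightness*; fields whose puncta
brightness varies strongly would need an external calibration.  Objects at
the shape-sizing floor keep the below-resolution flag.

**Pairing.** Greedy one-to-one matching: candidate pairs by descending
voxel overlap first, then unmatched objects by ascending centroid distance
up to 1.0 µm; ties break on (distance, labels).  Unmatched objects are
reported as orphans, never forced into pairs.

## ABR

The simulator plants a wave complex (Gaussian peaks at 1.5/2.0/2.7/3.3/4.1
ms — waves 1–3 with their troughs) whose wave-1 peak-to-peak amplitude is
0.5 µV at the planted threshold and grows 0.1 µV/dB above it; below
threshold the record is pure noise.  Averages are generated directly at
the statistically exact residual level (σ/√n for n = 1024 sweeps) rather
than materialising individual sweeps; the two polarity sub-averages are
generated explicitly, so an optional stimulus artifact appears with
opposite signs and cancels exactly in the full average (the alternating-
polarity design).  Records run from −2 to +8 ms around stimulus onset at
40 kHz; the pre-stimulus segment serves as the noise baseline.

Wave-1 amplitude is P1-maximum minus the first following minimum within a
1.0–2.5 ms window (the window is configurable; a global max-minus-min mode
exists).  "Repeatable wave 1" is formalised as: amplitude > 3 × baseline
RMS *and* split-half correlation ≥ 0.5 in the window; threshold is the
lowest level such that every higher tested level also responds, censored
when even 80 dB SPL fails.  A zero-phase 0.3–3 kHz Butterworth bandpass
mirrors the acquisition passband when raw epochs are supplied.

## DPOAE

Primaries follow f1 = f2/1.2, L2 = L1 − 10; the distortion product sits at
2f1 − f2.  Levels map to amplitudes via 20·log10(a/ref) with a single
configurable reference, so all level arithmetic is relative.  Recordings
(250 kHz sampling, i.e. 4 µs intervals) are cut into Hann-windowed
segments (3 by default) and amplitudes are estimated by windowed DFTs
evaluated exactly at the target frequencies.

The DP bin is **vector-averaged** across segments (tones are phase
coherent), while the noise floor — 5 bins per side of the DP frequency
with a 1-bin guard, excluding anything near a primary — is
**magnitude-averaged**.  This asymmetry is what makes the "SNR > 1"
threshold rule automatable: with a same-scale estimator, a noise-only DP
bin exceeds its own expected floor about half the time and a threshold
scan becomes a coin flip, whereas vector averaging suppresses incoherent
noise in the DP bin by ~√n_segments, so noise-only SNR sits below 1 almost
always (median ≈ 0.58 at 3 segments).  The threshold is the lowest f2
level with SNR > 1 sustained at all higher levels, censored when the top
level fails.  The ladder simulator plants an emission threshold: no DP
below it, DP at floor + 6 dB at it, growing 1 dB/dB above.

## Statistical tree

`compare` routes exactly per the gate: Shapiro–Wilk on within-group
residuals at α = 0.05 (groups with n < 3 or zero-variance residuals force
the nonparametric branch with a logged note).  Parametric: Student's
t (two groups) or one-way ANOVA with Holm–Šidák pairwise post hoc tests.
Nonparametric: Mann–Whitney U or Kruskal–Wallis with Dunn's rank
contrasts (tie-corrected z statistics, Šidák family adjustment, mirroring
the parametric branch's correction; Bonferroni available).  Dunn's test is
implemented in-package (rank statistics via scipy, adjustment closed
form).  Adjusted p-values are never below raw ones and never above 1
(asserted).  Conventional degrees of freedom are reported alongside group
sizes.  Censored observations (e.g. no ABR response at the 80 dB ceiling)
are excluded from comparisons with counts logged, not imputed.  The full
gated tree holds its empirical type-I error inside [0.035, 0.065] at
nominal 0.05 on both Gaussian and skewed null data (2000 replicates,
n = 10/group).

## Problem sizes and determinism

Every generator is a pure function of its configuration and seed
(bit-identical outputs on repeat; asserted).  The validation suite uses 20
rendered stacks of 10 cells × 16 pairs for count/volume recovery, 100
seeded series/ladders for ABR and DPOAE threshold recovery, and 2000
replicates per null family for the type-I study; the standalone
reproduction script uses 10 stacks and the same Monte-Carlo sizes, which
keeps a full run in a few CPU-minutes while leaving the recovery margins
far from their tolerances.

## Known limitations

- The synthetic fields are geometrically benign by design (resolvable
  rings, constant per-channel brightness, flat background).  Recovery
  rates measured here are upper bounds for messy real tissue.
- Flux-calibrated sizing assumes shared staining brightness per channel
  within a field.
- The place–frequency map is not computed; `apex`/`middle`/`base` region
  labels are carried as metadata only.
- Waves 2–5 of the ABR are rendered but not quantified; no
  latency–intensity modelling.
- The DPOAE simulator plants the distortion product phenomenologically;
  there is no cochlear-nonlinearity model, and no middle-ear or acoustic
  exposure model anywhere.
- Repeated measures across ages are simulated but analysed per
  age/frequency cell, not with mixed-effects models.
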