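# cochleaquant

Quantification pipeline for cochlear ribbon-synapse anatomy and auditory
physiology, with synthetic-data generators that plant known ground truth for
every stage.

Noise exposure and altered efferent (medial olivocochlear) feedback change
both the *number* and the *morphology* of the synapses between inner hair
cells (IHCs) and auditory-nerve fibers, and the functional readouts that go
with them.  Studies of this kind quantify four things:

1. **Synaptic puncta counts per IHC** on confocal z-stacks immunolabelled
   for CtBP2 (presynaptic ribbons), GluA2 (postsynaptic AMPA-receptor
   patches) and MyosinVIIa (hair cells).  A putative synapse is a
   *colocalized* CtBP2/GluA2 punctum pair at the IHC basal pole.
2. **Synaptic volumes**: after Richardson–Lucy deconvolution, 3D objects are
   segmented, gated to 20–2000 voxels (0.11 × 0.11 × 0.2 µm voxels, i.e.
   0.048–4.84 µm³, inside the 0.04–5 µm³ range a synapse can occupy),
   and matched into pre/postsynaptic pairs whose CtBP2 and GluA2 volumes
   are the readout.
3. **ABR wave 1**: auditory brainstem responses to tone pips, levels
   20–80 dB SPL in 5-dB steps, 1024 sweeps averaged with alternating
   stimulus polarity.  Threshold is the lowest level with a repeatable
   wave 1; amplitude is the P1-to-trough peak-to-peak value in µV.
4. **DPOAE**: the cochlea's 2f1−f2 distortion product for primaries with
   f2/f1 = 1.2 and L2 = L1 − 10 dB; threshold is the lowest f2 level whose
   signal-to-noise-floor ratio exceeds 1.

Group comparisons run through a normality-gated decision tree
(Shapiro–Wilk on residuals; then t-test / Mann–Whitney U for two groups,
one-way ANOVA + Holm–Šidák or Kruskal–Wallis + Dunn for three), with
significance at p < 0.05.

This package reimplements that entire measurement chain as a tested,
reusable library.  Because raw animal data of such studies is typically not
deposited, a first-class synthetic-data module generates every input with
planted ground truth — rendered confocal fields, ABR waveform series,
ear-canal recordings, cohort tables — so every stage is validated by
recovery against a known answer.

## Worked example

```python
import numpy as np
from cochleaquant import abr, puncta, volumetric as vol
from cochleaquant.psf import make_psf
from cochleaquant.synth import (NoiseModel, VOLUMETRIC_VOXELS,
                                plant_ground_truth, render_stack,
                                simulate_abr_series)

psf = make_psf(sigma_xy=0.2, sigma_z=0.5, voxel_dims=VOLUMETRIC_VOXELS)
gt = plant_ground_truth(n_cells=10, pairs_per_cell=16, seed=1)
stack = render_stack(gt, psf, NoiseModel(), VOLUMETRIC_VOXELS, seed=1)

# counting branch: projections -> thresholds -> per-IHC particle counts
rois = puncta.derive_rois(puncta.max_projection(stack.channels["cell"]))
records, _ = puncta.count_synapses(stack, rois)
print(f"{len(rois)} IHCs, mean colocalized synapses/IHC: "
      f"{np.mean([r.n_colocalized for r in records]):.1f} (planted: 16)")

# volumetric branch: deconvolve -> segment -> gate -> pair
objs = {}
for ch in ("ribbon", "receptor"):
    dec = vol.richardson_lucy(stack.channels[ch], psf, n_iter=10)
    objs[ch] = vol.segment_objects(
        dec, vol.SegmentationConfig(voxel_dims=VOLUMETRIC_VOXELS), ch, psf=psf)
pairs = vol.pair_synapses(objs["ribbon"], objs["receptor"]).pairs
print(f"{len(pairs)} synaptic pairs; median CtBP2 volume "
      f"{np.median([p.ctbp2_volume_um3 for p in pairs]):.3f} um^3")

# physiology: level series with a planted 45 dB SPL threshold
series = simulate_abr_series(threshold_db=45.0, noise_sigma_uv=0.5, seed=1)
res = abr.detect_threshold(series)
w80 = abr.wave1_metrics(series.waveforms[-1])
print(f"ABR threshold: {res.threshold_db:.0f} dB SPL (planted 45); "
      f"wave 1 at 80 dB: {w80.amplitude_uv:.2f} uV")
```

prints

```
10 IHCs, mean colocalized synapses/IHC: 15.8 (planted: 16)
160 synaptic pairs; median CtBP2 volume 0.368 um^3
ABR threshold: 45 dB SPL (planted 45); wave 1 at 80 dB: 4.00 uV
```

The counting stage recovers the planted 16 pairs per cell to within a few
percent, the volumetric stage finds all 160 planted pairs with volumes close
to the planted medians, and the threshold detector lands exactly on the
planted 45 dB SPL.

A thin CLI exposes the same stages
(`cochleaquant simulate {stack|abr|dpoae|cohort}`, `cochleaquant count`,
`cochleaquant volumes`, `cochleaquant abr`, `cochleaquant dpoae`,
`cochleaquant stats`); run `cochleaquant --help` for details.

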