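# chromodyn

Quantification toolkit for two complementary readouts of heterochromatin
state in living cells:

1. **Focus dynamics from 4D fluorescence time-lapses.** Bright
   pericentromeric heterochromatin foci (chromocenters, marked by a
   fluorescent methyl-CpG-binding probe) are detected in each 3D frame,
   linked into tracks, and their motion is summarized by a
   rigid-motion-invariant statistic: for every pair of foci the 3D distance
   d(t) is measured at each time point and the inter-frame change
   Δd(t_n) = d(t_{n+1}) − d(t_n) is formed. Because inter-point distances
   are unchanged by translation or rotation of the whole nucleus, Δd
   isolates the *relative* motion of the chromatin itself. **Mobility**
   (µm/min) is |Δd| divided by the frame interval; a 0–95 min series at
   5-min spacing gives 20 samples and 19 mobility values per pair. Groups
   (e.g. embryonic cells vs ESCs vs fibroblasts) are compared with the
   Steel–Dwass all-pairs and Steel many-to-one rank tests.

2. **Nuclear texture and two-channel MeDIP-seq comparison.** On
   z-projections, the **heterochromatin index** = SD/mean of nuclear
   intensity × 100 (a coefficient of variation: punctate heterochromatin
   scores high, uniform staining near zero), together with mean intensity
   and nuclear area. On the genomics side, two methylated-DNA enrichment
   channels are binned into fixed windows, normalized to RPKM
   (reads/kb/million mapped), input-subtracted, correlated genome-wide at
   several window sizes (2/5/10 kbp by default), compared over CpG islands
   split at 80% methylation into heavy/light groups (Student's t test per
   channel), and rendered onto Hilbert curves for locality-preserving 2D
   visualization.

A synthetic-data module generates both kinds of input with known ground
truth (Brownian foci inside a rigid-moving nucleus; a shared latent
methylation landscape behind negative-binomial channel counts), so every
stage has a parameter-recovery test and the whole pipeline runs without
external downloads.

## Worked example

```python
import numpy as np
from chromodyn import synthdata, dynamics, ranktests

mob = {}
for i, (label, D) in enumerate({"embryo": 0.05, "ESC": 0.01, "MEF": 0.002}.items()):
    params = synthdata.TimelapseParams(
        n_frames=20, frame_interval=5.0, n_foci=8,
        diffusion_coeff=D, seed=1 + i,
    )
    tracks = synthdata.simulate_tracks(params)
    mob[label] = dynamics.mobility_by_group({label: tracks}, dt=5.0)[label]
    print(label, "median mobility %.3f µm/min" % np.median(mob[label]))

for r in ranktests.steel_control(
    ranktests.GroupData(list(mob), list(mob.values())), control="embryo"
):
    print(r.comparison, "p = %.2e" % r.p, r.stars)
```

prints

```
embryo median mobility 0.116 µm/min
ESC median mobility 0.058 µm/min
MEF median mobility 0.029 µm/min
('ESC', 'embryo') p = 0.00e+00 ***
('MEF', 'embryo') p = 0.00e+00 ***
```

i.e. focus mobility tracks the planted diffusion coefficient (embryonic
chromatin is the most mobile), and both slower groups differ from the
embryonic control with three-star significance in the many-to-one Steel
test (p below double precision here because each group pools >500
pair-interval values).

The same workflows are scriptable from a shell:

```sh
chromodyn simulate --seed 1 --out out/fixtures   # TIFF/CSV/bedGraph + truth
chromodyn dynamics --seed 1 --out out/dyn        # mobility CSVs, box plot, Steel tests
chromodyn medip    --seed 1 --out out/med        # correlation table, islands, Hilbert PNGs
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs both arms from scratch with the given seed: it renders the
three-group time-lapse, detects and links foci from the images, computes
pairwise mobilities and Steel tests, then simulates the two enrichment
channels and recomputes the window correlations and island statistics,
printing the group medians and correlation table to stderr and writing the
(empty) target-metric JSON to `--out`.
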