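# dorsalhorn

Quantification of synaptic-bouton density in the superficial spinal
dorsal horn after peripheral nerve injury, with the matching behavioural
endpoints — built around a seeded synthetic-micrograph generator so the
whole measurement chain can be validated against known ground truth.

After a chronic constriction injury (CCI) of the sciatic nerve in rat,
non-peptidergic C-fibre terminals (labelled by isolectin B4, IB4) are
depleted from a circumscribed "lesion zone" in lamina II (LII) of the
dorsal horn, and inhibitory terminals (GAD65-immunoreactive puncta) are
transiently lost in LII and the adjacent lamina I (LI), with a nadir
around three weeks and partial recovery by eight. This package
re-implements the quantitative methodology of that kind of study for
anyone who wants to reproduce, stress-test or extend it without access
to the original tissue:

- **Synthetic data** (`dorsalhorn.synth`, `geometry`, `cohort`,
  `timecourse`): two-channel 12-bit transverse-section micrographs with
  a white-matter boundary, LI/LII bands, a medio-lateral lesion zone and
  puncta drawn from a homogeneous spatial Poisson process (log-normal
  areas, mean 0.3 μm² for IB4 and 0.2 μm² for GAD65), plus full ground
  truth; von Frey up-down response sequences from a logistic
  psychometric model over the 0.6–26 g filament set; Hargreaves
  latencies with a 20.48 s cutoff.
- **Puncta counting** (`dorsalhorn.quantify`): bouton-scale contrast
  accentuation (white top-hat), thresholding into 4-connected blobs, a
  0.05 μm² minimum-size filter, and a mean-area overlap correction that
  converts merged blobs into an estimated varicosity count.
- **Rectangle placement** (`dorsalhorn.roi`): the protocol's 15 × 40 μm
  LI rectangle flush with the white matter and 30 × 50 μm LII rectangle
  50 μm below it, centred on the detected IB4 lesion, mirrored
  contralaterally, homotopic in sham sections; densities per 100 μm².
- **Behavioural scoring** (`dorsalhorn.behavior`): the up-down 50%
  withdrawal threshold `(10^(Xf + kδ))/10⁴` with δ = 0.224 and k from
  the Dixon likelihood, and mean Hargreaves latency over three trials.
- **Cohort statistics** (`dorsalhorn.stats`): percent-of-sham
  normalization (statistics always on absolute values), sham-vs-cuff
  and ipsi-vs-contra t-tests, two-way ANOVA with Bonferroni contrasts
  for behaviour, and the two-phase IB4–GAD65 Spearman correlation.

## Worked example

Render one sham-like section (both dorsal horns, 0.1 μm/pixel), quantify
all eight rectangle × marker combinations, and score one von Frey
session:

```python
import numpy as np
from dorsalhorn import (GeometryConfig, generate_geometry, sample_puncta,
                        render_micrograph, NoiseModel, quantify_section,
                        simulate_updown_trials, estimate_threshold)

geom = generate_geometry(GeometryConfig(), seed=42)
fields = {"IB4": [], "GAD65": []}
for g in (geom, geom.mirrored()):
    for marker, dens, area in (("IB4", 25.0, 0.3), ("GAD65", 25.0, 0.2)):
        for lamina in ("LI", "LII"):
            d = 4.0 if (marker == "IB4" and lamina == "LI") else dens
            fields[marker].append(sample_puncta(
                g.band_rect(lamina), d, area, 0.5,
                np.random.default_rng((42, hash((marker, lamina, g.side)) & 0xFFFF)),
                marker))
micro = render_micrograph(geom, fields, NoiseModel(), seed=42)
records, audit = quantify_section(micro, geom, sham=True)
print(records[["side", "lamina", "marker", "raw_count", "corrected_count", "density"]]
      .to_string(index=False))

seq = simulate_updown_trials(true_threshold_g=2.0, psychometric_slope=5.0, seed=7)
print("pattern:", seq.pattern(), "filaments:", seq.filaments_g)
res = estimate_threshold(seq)
print(f"50% withdrawal threshold: {res.threshold_g:.2f} g  (Xf={res.x_f:.3f}, k={res.k:.3f})")
```

prints

```
         side lamina marker  raw_count  corrected_count   density
  ipsilateral     LI    IB4         16             16.0  2.666667
  ipsilateral     LI  GAD65        125            138.0 23.000000
  ipsilateral    LII    IB4        290            382.0 25.466667
  ipsilateral    LII  GAD65        303            342.0 22.800000
contralateral     LI    IB4         29             32.0  5.333333
contralateral     LI  GAD65        125            165.0 27.500000
contralateral    LII    IB4        330            397.0 26.466667
contralateral    LII  GAD65        322            377.0 25.133333

pattern: 0X0X0 filaments: (2.0, 4.0, 2.0, 4.0, 2.0)
50% withdrawal threshold: 3.11 g  (Xf=4.301, k=0.856)
```

The IB4 LII density (~24 per 100 μm² in the 1500 μm² rectangle) and
GAD65 densities (~21–26 per 100 μm²) recover the configured generative
densities (25, 25 and 4 per 100 μm²) to within counting noise; the
corrected count exceeds the raw blob count where merged varicosities
were split by the mean-area correction. The staircase alternating
between 2 and 4 g yields a threshold between the two filaments.

## Command-line pipeline

```
dorsalhorn simulate --config run.yaml --seed 1 --out dataset/
dorsalhorn quantify --in dataset/ --out densities.csv
dorsalhorn analyze  --densities densities.csv --behavior dataset/behavior.csv --out results/
```

`simulate` writes multi-page TIFFs with YAML sidecars (channel names,
pixel size, section geometry), a ground-truth manifest and the
behavioural table; `quantify` emits one density record per section ×
side × lamina × marker plus a placement audit per image; `analyze`
writes normalized series, hypothesis tests, phase correlations, a
summary JSON and optional time-course figures.

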