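# Methods

## What is being modelled

The package reproduces a densitometric workflow for synaptic boutons in
the superficial dorsal horn of the rat spinal cord after a cuff-induced
chronic constriction injury, together with the behavioural assays run
in parallel. Because no micrographs or animal records are deposited for
this kind of study, the package pairs the measurement chain with a
generative model of the raw data; every stage can therefore be checked
against exact ground truth, and the study-level quantities are
reproduced as parameter-recovery experiments.

## Synthetic sections

A section image spans both dorsal horns (620 × 300 μm at 0.1 μm/pixel,
configurable) with the midline as mirror axis. Each horn has a
white-matter boundary polyline (flat by default, with a configurable
ventral sag and ±3 μm seeded depth jitter), a lamina I band (20 μm) and
a lamina II band (80 μm) beneath it, and a lesion zone: a rectangle
spanning LII's depth, 80 μm wide, centred (±8 μm jitter) in the
intermediate third of the horn's medio-lateral extent. Coordinates are
μm with origin at the top-left pixel corner, x medio-lateral, y
dorso-ventral, half-open pixel bins.

The pixel size default of 0.1 μm/px resolves the 0.05 μm² size-filter
cutoff as 5 pixels, typical of a 63× oil-immersion confocal acquisition
with digital zoom. Images are 12-bit in a 16-bit container.

Puncta are a homogeneous spatial Poisson process in each laminar band:
the expected count is density × area / 100 (densities are reported per
100 μm² throughout). Single-punctum areas are log-normal with the
marker's mean (IB4 0.3 μm², GAD65 0.2 μm²) and CV 0.5 — positive
support and right skew, as measured bouton areas show. Peak amplitudes
are uniform in 800–1000 DN above a Gaussian background (level 200 DN,
SD 15 DN), keeping every pixel below the 4095 DN ceiling, as in an
acquisition tuned to avoid saturation. Each punctum is painted as the
`round(area/px²)` pixels nearest its (sub-pixel) centre — a compact
blob of exactly the nominal area — then convolved with a Gaussian PSF
(σ 0.08 μm) and quantized. Optional Poisson shot noise is off by
default; the Gaussian background already dominates at these levels.

In cuff animals the configured percent-of-sham multiplies the density
inside the lesion zone's medio-lateral interval (in LII, and in LI for
the GAD65 loss there); outside it densities stay at baseline, matching
the circumscribed character of the depletion. Sham animals and the
contralateral side are at baseline (contralateral percentages are
configurable). Baseline densities are 25 per 100 μm² for IB4 in LII
and GAD65 in both laminae, and 4 per 100 μm² for the sparse IB4
labelling of LI — chosen once as realistic operating points: at the
IB4 values the boutons cover ~7.5% of the band, dense but resolvable.

Variance components: the study protocol fixes cohort sizes (here 5 sham
and 6 cuff animals, 6 sections each, from the protocol's stated ranges)
but not biological dispersion. The generator uses mean-preserving
log-normal multiplicative factors per animal (CV 5%) and per section
(CV 5%), with a configurable fraction (default 0.7) of the per-animal
factor shared between the IB4 and GAD65 channels so the cross-marker
correlation can be tuned (coupling 0 gives the null). These CVs are
deliberately modest — printed SEMs in real cohorts imply per-animal CVs
several times larger — so recovery tests validate the *measurement
chain*, not robustness to real biological scatter; passing them does
not certify performance on real tissue, where staining variability,
anisotropy and laminar ambiguity add error sources the generator does
not emulate. The generator also renders only the LI/LII bands (the
quantified region); deeper laminae and cell bodies are not simulated,
and sections are single optical planes, not stacks.

Every stochastic operation takes an explicit seed; cohorts derive
per-animal and per-section sub-seeds from (seed, day, animal index,
section index), so identical configuration and seed give byte-identical
datasets.

## Puncta counting

1. **Accentuation.** A white top-hat with a disc structuring element
   whose radius is 1.5× the expected bouton diameter (diameter ≈ 3×
   bouton diameter; ~0.9 μm for IB4, ~0.75 μm for GAD65). Bouton-scale
   spots pass nearly unchanged while wider structures and background
   are levelled, which is the behaviour attributed to bouton-targeted
   contrast tools in commercial densitometry packages. The disc is
   applied via a sequence decomposition for speed.
2. **Segmentation.** Supra-threshold pixels form 4-connected
   components (conservative splitting of touching puncta); components
   below 0.05 μm² are discarded so cut axon fragments are not counted.
3. **Overlap correction.** Three rules are implemented, all driven by
   the marker's mean single-varicosity area. Per blob:
   `max(1, round(area/mean_area))` (round-half-to-even), which
   preserves raw counts for isolated boutons and never falls below the
   raw blob count. Total-area: pooled blob area divided by the mean
   area. Boolean: the area-fraction inversion of the total-area rule — for
   Poisson-placed varicosities the covered fraction of a region of
   area A is `p = 1 − exp(−λ·mean_area)`, so
   `count = −A·ln(1 − total_area/A)/mean_area` — which also restores
   the union area lost where varicosities clump and reduces to the
   total-area rule at low coverage. The function default is the
   per-blob rule; **the packaged pipeline default is the Boolean
   rule**, because ground-truth calibration showed (i) the per-blob
   rule inflates counts of isolated boutons by ~+14% under CV-0.5
   areas (the right tail of the area distribution rounds to 2), and
   (ii) the plain total-area rule under-counts by ~4% at baseline
   coverage (~7%), giving both a density-dependent bias; the Boolean
   inversion stays within about ±1–2% of truth across 0.4–40 puncta
   per 100 μm² for both markers. The area-based rules do not floor at
   the raw blob count: with dispersed areas that floor is one-sided
   and inflates sparse-region counts by several percent, so
   "corrected ≥ raw" is guaranteed only under the per-blob rule.

The detection threshold applies to the accentuated image. The packaged
default (450 DN, roughly half of the dimmest punctum peak) was set by
the same calibration: it makes the measured area of an isolated
varicosity track its true area, which the mean-area correction assumes.
A generic fallback for unknown images is background + 3 SD. An image
saturated everywhere yields a warning and an empty result, since the
acquisition protocol excludes saturation.

## Rectangle placement and densities

The LI rectangle (15 × 40 μm, long side flush with the white-matter
boundary) and the LII rectangle (30 × 50 μm, horizontal, near edge
50 μm from the boundary measured along the local boundary normal) are
centred on the medio-lateral middle of the lesion. The lesion is
located from the IB4 channel: blob centroids in the LII band are
counted in 30 μm sliding windows (stride 5 μm); windows in the middle
third falling below 50% of the flanking-region density are lesion
candidates, and the contiguous candidate run containing the global
minimum becomes the lesion rectangle (spanning LII's depth). Without
sufficient contrast — sham sections, uniform labelling, an empty
channel, or depletions milder than the 50% criterion — the geometry's
default middle-third rectangle is used, which is also the sham
homotopic placement; a manual rectangle can be supplied instead. The
50% contrast criterion and window size are this package's
operationalization (the source protocol drew the zone by eye); at the
late-recovery time points (~52% of sham) detection intentionally falls
back to the default placement, which coincides with where the lesion
"normally occurs".

Contralateral rectangles mirror the ipsilateral ones across the
midline. Blobs are assigned to a rectangle if their centroid falls
inside it (unbiased under translation); density = 100 × corrected
count / rectangle area. Six sections per animal are averaged to one
value per animal × condition before any statistic, since the study's n
is animals. For speed, segmentation is restricted to the laminar bands
and the middle third plus 40 μm flanks; every legal placement lies
inside this window and results are identical to full-frame processing.

## Behavioural endpoints

**Von Frey.** Sessions run the up-down staircase over the printed set
(0.6–26 g), starting at 2 g, stopping four presentations after the
first reversal or on stepping past either end of the set. Responses
come from a logistic psychometric function in log10 grams
(P(withdraw)=0.5 at threshold; default slope 5). Scoring uses
`(10^(Xf + kδ))/10⁴` with Xf = log10(grams)+4 for the final filament
and δ = 0.224 (the protocol's stated constant; the set's actual mean
log-spacing is 0.182, and the printed constant is used deliberately).
`k` is obtained by maximizing the Dixon likelihood — a normal
psychometric with spread δ — over the whole response sequence; this is
the construction from which the published pattern→k tables were
derived, so tabulated patterns reproduce their table behaviour and
unlisted patterns get a principled value. The pre-reversal monotone
walk is included in the likelihood because discarding it biases
estimates toward the starting filament (up to −21% median bias at
8–15 g with the shallow default slope; within ±20% everywhere in
1–15 g when included). Sessions with no reversal that end at a bound
are censored to 0.6 or 26 g.

The printed behavioural percentages are *assay outputs*, not latent
truths: at slope 5 the bounded staircase is materially biased (the
group-mean ratio lands near 21% whenever the latent ratio is 16.3%,
for any sham baseline in 7–12 g). The packaged time-course therefore
encodes the printed percentages on the measured scale and derives
latent thresholds by inverting the assay's operating characteristic
m(t), estimated by simulation on a fixed internal calibration seed and
cached. The sham latent baseline is 10 g; Hargreaves measurement (mean
of 3 trials, SD 1.5 s, 20.48 s cutoff; sham baseline 10 s) is unbiased
at these values, so its latent values equal the printed percentages
directly.

## Statistics

Endpoints are expressed as percent of the matched sham-side mean per
day; all hypothesis tests run on absolute values. "One-way ANOVA
t-tests" of the source protocol are implemented as two-sided t-tests
(unpaired sham-vs-cuff ipsilateral; paired ipsi-vs-contra within cuff
animals), which for two groups are equivalent to one-way ANOVA.
Behaviour uses a two-way (group × day) ANOVA plus per-day contrasts
with Bonferroni correction over days. The IB4–GAD65 relationship is a
Spearman rank correlation over per-animal mean densities pooled within
a phase (decreasing: days 5–14; recovery: 21–56); the p-value is an
exact permutation probability up to n = 8 (full enumeration; beyond
that 9!–12! permutations are impractical) and the t-approximation
otherwise. Degenerate strata (fewer than two animals per cell, missing
sham strata) are skipped with warnings or raise named errors.

## Problem sizes and numerical choices

Recovery experiments use the protocol-sized cohorts (11 animals × 6
sections per histology day; 20 animals per behavioural day). The
acceptance script averages two replicate cohorts for each histology
day and forty for the behavioural ratios, replication being
proportional to how cheap each simulation is and how noisy each
estimator is. The Dixon likelihood is maximized on
a 1201-point grid over the filament range ±3δ (resolution ≪ the
estimate's sampling noise); k is clipped to ±3. Rounding of blob-count
ratios is numpy's round-half-to-even. ROI containment uses half-open
intervals, so a centroid exactly on the shared edge of two rectangles
belongs to one and only one.

## Known limitations

- The generator's noise model (Gaussian background, uniform punctum
  amplitudes, isotropic PSF, no out-of-focus light, no staining
  gradients) is much cleaner than real immunofluorescence.
- The accentuation step is a principled stand-in for a proprietary,
  algorithmically undocumented contrast function; only its stated
  behaviour (size-selective contrast preservation) is reproduced.
- Lesion detection assumes one contiguous depletion inside the middle
  third; multifocal or laterally displaced lesions fall back to the
  default placement.
- The behavioural calibration inverts the measurement model under the
  same psychometric family used for simulation; with a different real
  psychometric shape the latent values would differ even though the
  measured contrast is matched.
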