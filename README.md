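# axoncontact

Quantification pipeline for fluorescence-microscopy experiments on
endoplasmic-reticulum–ribosome contacts in axons, paired with a synthetic
imaging simulator so that every estimator can be validated by parameter
recovery on data with known ground truth.

Developing axons translate mRNAs locally, far from the soma, and a sizeable
fraction of axonal ribosomes sit within nanometers of the tubular axonal ER.
Establishing that claim from images requires a family of small, careful
quantifications: overlap fractions between a punctate ribosome channel and a
thresholded ER mask (with a mirrored-channel chance control), background-
corrected line-profile intensities along axon segments, axon/dendrite
polarity indices, per-batch normalization of proximity-labeling signal,
photobleaching-recovery (FRAP) curves, Sholl profiles and kymographs. This
package implements all of them as a tested library with a thin CLI, for
image analysts who want the measurements to be reproducible and checkable
rather than embedded in ad-hoc scripts.

## The core estimator

For one straightened axon segment with an ER channel $E$ and a ribosome
channel $R$ (same grid, pixel size $p$ nm):

1. threshold $E$ (Otsu by default) into a binary mask $M$;
2. dilate $M$ by a disk of radius $\lceil d/p \rceil$ pixels for an
   enlargement distance $d$ (5 nm by default; a positive sub-pixel distance
   still dilates by one pixel) giving $M_+$;
3. report the intensity proportions

$$f_{\text{mask}} = \frac{\sum_{M} R}{\sum R},\qquad
  f_{\text{enl}} = \frac{\sum_{M_+} R}{\sum R},\qquad
  f_{\text{flip}} = \frac{\sum_{M} \tilde R}{\sum \tilde R},$$

where $\tilde R$ is $R$ mirrored about the vertical midline. $f_{\text{flip}}$
is the chance-overlap null: the mirror preserves the axon's intensity
envelope but destroys true co-alignment with the ER, so
$f_{\text{mask}} \gg f_{\text{flip}}$ indicates genuine association.

Supporting effect sizes follow the field's conventions: percent change
$100\,(\bar{x}_{\text{ctrl}} - \bar{x}_{\text{test}})/\bar{x}_{\text{ctrl}}$
on background-corrected means, polarity index
$\mathrm{PI} = (I_d - I_a)/(I_d + I_a)$ with $I_d$ the mean of three
dendrites, branch enrichment $\bar{x}_{\text{branch}}/\bar{x}_{\text{shaft}}$,
and FRAP curves anchored to 100% (mean of the three prebleach frames) and 0%
(first post-bleach frame) after background and acquisition-bleach correction.

The simulator (`axoncontact.synth`) generates the ground truth these
estimators are tested against: a 3D axon cylinder containing a meandering
ER tubule, ribosome-like puncta with a programmable bound fraction and
binding distance, Gaussian-PSF rendering with Poisson and read noise, SMLM
localization tables, condition pairs with programmed intensity or density
reductions, branch-point density enrichment, FRAP traces and simple neuron
morphologies. Named presets in `presets.yaml` encode the programmed effect
sizes (e.g. a 29% knockdown reduction, a 45% bound fraction, a 1.75-fold
branch enrichment).

## Worked example

```python
from axoncontact import synth, intensity
from axoncontact.contact import ContactConfig
from axoncontact.pipeline import quantify_contact, quantify_pair
from axoncontact.presets import get_preset

# 20 STED-like two-channel segments, 45% of puncta bound to the tubule
preset = get_preset("fig2-sted-contact")
segments = synth.simulate_contact_segments(preset, 20, seed=5)
df = quantify_contact(segments, ContactConfig(dilate_nm=preset.dilate_nm))
print(df[["fraction_in_mask", "fraction_in_enlarged",
          "fraction_flipped"]].mean().round(3))

# a simulated knockdown with a programmed 29% intensity reduction
pair = synth.simulate_condition_pair(get_preset("fig1-kd-puro"), 30, seed=42)
values = quantify_pair(pair)
print("percent_change:",
      round(intensity.percent_change(values["control"], values["test"]), 1))
```

prints

```
fraction_in_mask        0.407
fraction_in_enlarged    0.534
fraction_flipped        0.373
dtype: float64
percent_change: 29.5
```

Read: with 45% of ribosome puncta tethered within 30 nm of the tubule
surface, ~41% of ribosome-channel intensity falls inside the Otsu ER mask
(53% inside the 5 nm-enlarged mask), while mirroring the ribosome channel
drops the overlap to ~37% — the gap the paired flip-null test detects. The
intensity pipeline recovers the programmed 29% knockdown reduction to within
half a percentage point at n = 30 segments per group.

The same workflows are scriptable from the shell, e.g.

```sh
axoncontact simulate --preset fig2-sted-contact --n 20 --seed 5 --out scratch/sted
axoncontact contacts --er scratch/sted/er_000.tif --ribo scratch/sted/ribo_000.tif --out result.csv
axoncontact report --preset fig1-kd-puro --quantifier intensity --seed 42 --out report.json
```

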