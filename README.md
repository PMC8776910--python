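# myofield

Quantification toolkit for "in vitro exercise" experiments: cultured human
myotubes differentiated on a fibroblast feeder layer, driven to contract by
electrical pulse stimulation (EPS, typically 1 Hz), then scored for
contractility, for nucleocytoplasmic redistribution of marker proteins such
as TDP-43, for p62 puncta load, and for contraction-induced gene expression.
It is aimed at muscle-biology labs that quantify these readouts from
bright-field videos, multi-channel immunofluorescence and qPCR tables, and
it ships a ground-truthed synthetic-data generator so every stage can be
validated end to end without microscope data.

## What it computes

**Movement index.** Contractility is scored by differential image
subtraction: for frame pairs $(I_t, I_{t+\ell})$ of a bright-field
time-lapse, the absolute difference image $|I_t - I_{t+\ell}|$ is averaged
over all pixels and normalized by the full bit scale; the movement index is
the mean over pairs,

$$\mathrm{MI} = \frac{1}{P}\sum_{p=1}^{P} \frac{\overline{|I_{t_p} - I_{t_p+\ell}|}}{2^{B}-1}.$$

Intensity changes between a contraction and a relaxation frame come from
moving scattering objects, so a static field scores exactly 0 and the index
rises with deformation amplitude. The lag $\ell$ defaults to one frame, or
to half a stimulation period when the pacing frequency is known.

**Localization scoring.** The myotube boundary is segmented from the
sarcomeric α-actinin channel (which also excludes feeder-fibroblast nuclei:
DAPI-positive but α-actinin-negative), nuclei from the DAPI channel with a
watershed split. Per myotube, the marker-positive area $A_{\mathrm{tot}}$
is partitioned as $A_{\mathrm{cyt}} = A_{\mathrm{tot}} - A_{\mathrm{nuc}}$,
the positive-nuclei ratio is (marker-positive nuclei)/(all nuclei in the
myotube), and a myotube is accumulation-positive when its largest
cytoplasmic marker blob and cytoplasmic area fraction both pass thresholds.
Condition summaries pool flagged/total myotubes and report means ± SE.

**Puncta.** p62-style granules are isolated from diffuse signal by a white
top-hat plus Otsu threshold and size gate; the readout is puncta area /
myotube area.

**Expression.** Relative expression by the 2^−ΔCT method against a
reference gene (e.g. RPLP0), with fold changes versus a basal condition
(equivalently 2^−ΔΔCT); the basal group's mean fold is 1 by construction.

**Statistics.** Student's t-test for two groups; one-way ANOVA with Tukey
(all pairs) or Dunnett (versus control) for more, reported as means ± SE
with significance stars at α = 0.05.

## Worked example

```python
from myofield import (MotionSpec, SceneSpec, generate_contraction_sequence,
                      generate_fluorescence_field, movement_index,
                      score_field, summarize_condition)

# contractility: paced vs unpaced synthetic video
seq, _ = generate_contraction_sequence(MotionSpec(amplitude=3.0, seed=7))
print(movement_index(seq).movement_index)        # 0.00334...
seq0, _ = generate_contraction_sequence(MotionSpec(amplitude=0.0, seed=7))
print(movement_index(seq0).movement_index)       # 0.0

# localization: five fields, 30% of myotubes carry cytoplasmic deposits
fields = [score_field(generate_fluorescence_field(
              SceneSpec(seed=200 + k, n_myotubes=10, accumulation_fraction=0.3,
                        marker_nuclear_fraction=0.7))[0])
          for k in range(5)]
s = summarize_condition(fields)
print(s.n_myotubes, s.fraction_accumulation_positive, round(s.mean_nuclear_positive_ratio, 3))
# 50 0.3 0.728
```

The first two numbers say a paced synthetic culture moves (index 0.0033 in
bit-scale units) while an unpaced one scores exactly zero; the summary says
that over 50 myotubes the pipeline recovered the generated 30% accumulation
fraction exactly and measured a mean nuclear-positive ratio of 0.728 against
the generated 0.7.

A full simulated experiment (control vs paced conditions, Dunnett versus
control) runs from a YAML config:

```sh
myofield run config.yaml     # writes per_myotube.csv, condition_summary.csv,
                             # comparisons.csv and a reproducibility manifest
```

Other subcommands (`simulate`, `movement-index`, `segment`, `localize`,
`puncta`, `expression`, `stats`) wrap the corresponding library functions.

## Limitations

The synthetic generator guarantees geometry, counts and area fractions, not
photorealism; absolute movement-index values are in arbitrary units and
only relative comparisons are meaningful. See `docs/methods.md` for the
model, parameter defaults and numerical choices.
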