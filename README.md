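# nucleoscape

Quantitative 3D nuclear-architecture analysis and permutation gene-set
statistics for cell-scattering experiments — with synthetic, ground-truthed
inputs so every read-out is testable end to end.

## The problem

When hepatic progenitor cells scatter — after function-blocking of the
α5β1 fibronectin receptor, or on HGF/SF1 stimulation — their nuclei keep a
constant volume (~250 µm³) while pericentromeric heterochromatin
disaggregates: chromocenters become more numerous and individually smaller
(mean volumes around 8 µm³ per chromocenter untreated, ~6 µm³ under
antibody blockade, ~4 µm³ under HGF/SF1), and gene loci such as
*Itgb1*/*Itgb3* hold a peripheral radial position (80–100% of the nuclear
radius).  Demonstrating this requires measuring objects in confocal
z-stacks, normalizing locus positions by nuclear radius, and summarizing
three-condition expression data per gene set.  `nucleoscape` implements
that computational pipeline for anyone analysing such data, and pairs it
with generators that render image stacks and expression matrices with
known truth.

## What it computes

**Imaging arm.**  Nuclei are segmented from the DAPI channel (Otsu, hole
filling, 26-connected 3D labelling); objects in any channel are detected
within each nuclear ROI and measured (voxel count, volume, intensity,
intensity-weighted centre of mass).  A locus signal's radial position is
its distance from the nuclear centre of mass divided by the
centre-to-periphery distance along the same ray (0 = centre, 1 =
periphery), binned into five concentric shells of 20% relative radius.
Conditions are compared with the two-sample Kolmogorov–Smirnov test
(distributions), a pooled-rate z test (objects per nucleus), and Welch's t
(mean volumes/intensities).

**Expression arm.**  For gene set G and class c, the observed score is
mean over g ∈ G of (mean expression in c − mean expression in the other
classes).  Class-versus-rest membership is permuted (N = 10000, or
exhaustively over all C(S, k) splits when that is smaller); with n_up and
n_down the permuted scores at least as extreme in each tail, the heat value
is 1 − n_up/N for up-regulated sets and n_down/N for down-regulated ones,
so both directions share one [0, 1] color scale (values in (0.05, 0.95)
are flagged not significant).  Around it: a calibrated per-gene t-test
stand-in for array DE, per-chromosome DE-density ratios, and hypergeometric
GO over-representation with Holm correction.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

```python
from nucleoscape.synthetic_microscopy import condition_config, generate_nuclei_dataset
from nucleoscape.pipeline import quantify_stacks
from nucleoscape.nuclear_architecture_stats import (
    summarize_condition, compare_counts, compare_means,
)

frames = {}
for cond in ("control", "antibody"):
    cfg = condition_config(cond, n_nuclei=30, seed=7)
    stacks, truth = generate_nuclei_dataset(cfg)
    objects, nuclei = quantify_stacks(stacks, channels=("centromere",))
    objects["condition"] = cond; nuclei["condition"] = cond
    frames[cond] = (objects, nuclei)

for cond in frames:
    s = summarize_condition(*frames[cond], cond)
    print(f"{cond}: {s.n_nuclei} nuclei, {s.n_objects} chromocenters, "
          f"{s.mean_count:.2f} per nucleus, "
          f"mean volume {s.mean_volume_um3:.2f} +/- {s.se_volume_um3:.2f} um^3, "
          f"nuclear volume {s.mean_nuclear_volume_um3:.1f} um^3")

sc = summarize_condition(*frames["control"], "control")
sa = summarize_condition(*frames["antibody"], "antibody")
z, p_count = compare_counts(sa.counts_per_nucleus, sc.counts_per_nucleus)
t, p_vol = compare_means(frames["antibody"][0].volume_um3,
                         frames["control"][0].volume_um3)
print(f"count rate z = {z:.2f}, p = {p_count:.2g}")
print(f"volume Welch t = {t:.2f}, p = {p_vol:.2g}")
```

Output:

```
control: 30 nuclei, 159 chromocenters, 5.30 per nucleus, mean volume 8.29 +/- 0.22 um^3, nuclear volume 259.9 um^3
antibody: 30 nuclei, 202 chromocenters, 6.73 per nucleus, mean volume 6.21 +/- 0.14 um^3, nuclear volume 252.0 um^3
count rate z = 2.26, p = 0.024
volume Welch t = -8.07, p = 2.1e-14
```

Reading it: the antibody condition shows significantly more chromocenters
per nucleus (rate z test) of significantly smaller mean volume (Welch t),
at unchanged nuclear volume — the disaggregation signature — and the
recovered means (8.29 and 6.21 µm³) sit on the generating set points
(8 and 6 µm³).

## Command line

```bash
nucleoscape simulate-images  --config cfg.yaml --out DIR --seed 1
nucleoscape quantify         --images DIR --channel centromere --out objects.csv
nucleoscape radial           --images DIR --channel locus --out radial.csv
nucleoscape compare          --objects objects.csv --nuclei nuclei.csv \
                             --a control --b antibody --metric volume
nucleoscape simulate-expression --config expr.yaml --out DIR --seed 1
nucleoscape enrich           --expr DIR --class antibody --n-perm 10000 --seed 1
nucleoscape run              --config pipeline.yaml
```

`run` executes a YAML-declared stage list with one root seed and writes a
manifest (`manifest.json`) from which every output is re-derivable.

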