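# avfstudy

Quantitative pipeline for a rat carotid–jugular arteriovenous-fistula (AVF)
study of how rising vascular wall shear stress engages Notch receptor–ligand
signaling. The package re-implements, as tested and reusable code, the four
measurement chains such a study runs:

1. **Hemodynamics** — wall shear stress from Doppler flow recordings via the
   Poiseuille relation τ = 4ηQ/(πR³) (τ in dyn/cm², η blood viscosity in
   dyn·s/cm², Q mean flow in cm³/s, R internal radius in cm), with strict
   unit handling and per-day group summaries.
2. **Immunofluorescence quantification** — marker expression as fluorescence
   intensity units (FIU, the mean gray value of an ROI on the max-projected
   image), corrected by subtracting the primary-antibody control, expressed
   as percent change versus the pre-fistula baseline (day −1).
3. **PLA event counting** — proximity-ligation-assay spots called on z-stack
   maximum projections with a fixed gray threshold (100 on 8-bit images),
   a 2–50 px size gate, the merged-blob rule (a blob > 50 px counts
   `round(area / 10)` events, 10 px being the median single-event size), and
   negative-control background subtraction of event densities (events/mm²).
4. **Statistics** — mean ± SE summaries, unpaired two-tailed t-tests against
   baseline, a Levene-gated ANOVA/Mann–Whitney choice for multi-group
   comparisons, and Pearson correlation / linear regression of per-day group
   means against time or against wall shear stress.

Because no raw images or flow recordings are publicly available for such
studies, the package ships a first-class **synthetic phantom generator**:
seeded, calibrated flow traces, vessel geometries and 8-bit phantom
z-stacks (annular lumen/intima/media cross-sections with marker rings and
PLA spot fields) whose ground truth is known exactly. Every analysis stage
is validated by recovering what the generator seeded.

Intended users: image-analysis and vascular-biology researchers who want a
transparent, testable reference implementation of these measurement rules,
or a ground-truth-known surface to benchmark their own quantification code.

## Worked example

```python
import avfstudy as a

# wall shear stress from a recorded mean flow
geometry = a.VesselGeometry(internal_radius_cm=0.1, viscosity=0.04)
est = a.poiseuille_wss(0.0867, geometry)          # 5.2 mL/min in cm^3/s
print(round(est.tau_dyn_cm2, 3))                  # 4.416

# a calibrated phantom study arm, quantified end to end in memory
profile = a.default_calibration(seed=1)
tc = a.recover_marker_timecourse(profile, "caspase3")
endo = tc[tc["compartment"] == "endothelium"]
print(endo[["day", "n", "mean", "se", "pct_change"]].round(2).to_string(index=False))
```

which prints (seed 1):

```
 day  n   mean   se  pct_change
  -1  4  86.27 1.25        0.00
   1  4  96.28 3.22       11.59
   3  4 108.28 1.98       25.51
   7  4 106.38 1.33       23.31
  14  4 108.40 3.46       25.64
  21  4 114.42 2.55       32.63
  42  4 122.90 3.90       42.45
  84  4 114.58 4.21       32.81
```

Each row is one study day: n rats, group mean ± SE of the control-corrected
FIU, and the percent change versus the day −1 baseline group mean. The
generator seeded a caspase3 time-course peaking at +35% on day 42; the
pipeline recovers +42.5% here, within the sampling error of a 4-rat design
with 5% replicate variation (the delta-method SE of this estimator is about
5 percentage points).

The same flow works from the shell on an on-disk study:

```sh
avfstudy init-config --out study.yaml
avfstudy run --config study.yaml
```

which writes a dataset (TIFF stacks + CSV tables + manifest) and a report
bundle (`wss.csv`, `fiu.csv`, `pla.csv`, time-courses, per-day tests,
correlations, `summary.csv`, `run_manifest.json`). Per-stage subcommands
(`generate`, `wss`, `ifquant`, `pla`, `stats`) operate on saved outputs —
`pla` in particular can run on any manifest of multi-page TIFF z-stacks.

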