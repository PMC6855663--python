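# radgem

Analysis pipeline for preclinical combination-therapy studies of ionising
radiation (radionuclide therapy or external-beam radiotherapy) with a
radiosensitising drug (gemcitabine) in tumour-bearing mice.

It is written for researchers running subcutaneous-xenograft therapy
experiments who need the full chain from raw calliper tables and tracer
kinetics to synergy calls and quantified histology:

* **Growth curves** — ellipsoid tumour volumes V = (π/6)·l·w·h, relative
  tumour volumes RTV(t) = V(t)/V(0), per-arm mean ± SEM curves and per-day
  ratios to the untreated control arm.
* **Progression-free survival** — per-animal progression detection (first
  RTV > 1 at or after the RTV nadir; kills count as events) and a
  hand-implemented Kaplan–Meier product-limit estimator with median time
  to progression.
* **Internal dosimetry (MIRD)** — mono-exponential fit to time-activity
  concentration data, analytic time-integrated activity Ã = C₀/λ, and mean
  absorbed dose D = Ã·ΣEᵢYᵢ·φ (beta-only ¹⁷⁷Lu defaults: 147.9 keV, φ = 1),
  plus body-surface-area conversion of mg/kg animal doses to mg/m².
* **Bliss-independence interaction** — fractional responses
  F = 1 − RTV_arm/RTV_control, predicted additive response
  F_add = F_rad + F_gem − F_rad·F_gem, and per-day classification of the
  combination arm as synergistic / additive / antagonistic.
* **Group statistics** — per-day one-way ANOVA and pairwise Student's
  t-tests (Welch optional) with Bonferroni–Holm correction, implemented
  from first principles.
* **Quantitative IHC** — colour-threshold segmentation of Masson's
  trichrome and Ki67 (DAB) sections, artefact removal, automatic
  necrotic/viable partition, control-point registration of the MT mask
  onto the Ki67 section, and area-fraction quantification (Ki67 in viable
  tumour only; collagen over the whole tumour).
* **Synthetic data** — seeded generators for growth cohorts, tracer
  washout and stained-section pairs with exactly known ground truth, so
  every stage is testable end to end without animal data.

See `docs/methods.md` for models, conventions and numerical choices.

## Worked example

Run the shipped seven-arm study emulation end to end:

```sh
radgem run-all --preset study-like --seed 3 --out out/
```

or equivalently from Python:

```python
from radgem.pipeline import load_preset, run
manifest = run(load_preset("study-like", seed=3), "out")
```

`out/summary.md` then reads (excerpt):

```
## Growth
- Gem high: final mean RTV 1.04 (day 16, n=5, ratio to control 0.54)
- control: final mean RTV 3.58 (day 30, n=8, ratio to control 1.00)
- EBRT: final mean RTV 1.50 (day 44, n=5, ratio to control nan)

## Progression-free survival
- control: median TTP 3 d
- EBRT: median TTP 37 d
- EBRT + Gem low: median TTP 51 d

## Bliss interaction
- EBRT + Gem low: {'additive': 7, 'antagonistic': 2}

## Dosimetry
- C0 = 0.01808 MBq/g, effective half-life 57.2 h, A-tilde 1.49 MBq*h/g,
  mean absorbed dose 0.127 Gy

## Histology
- pair-01 (control): Ki67 in viable 64.0%, MT whole-tumour 3.0%
```

Reading this: untreated control tumours triple in volume by day 30 and
progress at the first visit (median TTP 3 days); radiotherapy dips below
baseline and delays progression to ~5 weeks; the drug arm sits near half
the control RTV after its dosing window; and the combination arm — built
with independent effects in this preset — is classified additive on most
days. The histology pair round-trips its planted 64% Ki67 / 3% collagen
fractions. Alongside the summary the run writes tidy CSVs for every stage
(`per_animal.csv`, `per_group.csv`, `survival_curves.csv`,
`interaction_*.csv`, `stats.csv`, `histology.csv`) and a `manifest.json`
whose config and file hashes are byte-identical across repeat runs with
the same seed.

Individual stages work on plain files too, e.g.

```sh
radgem simulate --preset study-like --seed 3 --out measurements.csv
radgem growth   --measurements measurements.csv --control control --out growth/
radgem stats    --measurements measurements.csv --control control --out stats.csv
radgem dose     --csv time_activity.csv
```

and small building blocks are importable directly:

```python
>>> from radgem import bliss_additive, mean_absorbed_dose, human_equivalent_dose
>>> bliss_additive(0.71, 0.52)     # monotherapy fractions at 29% / 48% of control
0.8608
>>> mean_absorbed_dose(100.0)      # Gy per 100 MBq·h/g, beta-only 177Lu
8.529688799999999
>>> human_equivalent_dose(60.0)    # mouse mg/kg -> human mg/m², Km = 3
180.0
```

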