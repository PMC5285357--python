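# pomarch

Allometric models of apple (*Malus × domestica*) shoot architecture: predict
the individual and total leaf area of the three shoot types found on a
first-order apple branch — bourse shoots (BS), rosettes (RO) and vegetative
shoots (VS) — and the position of every leaf along a bearing spur, from two
inputs that are quick to score in the orchard: the number of leaves on the
shoot (*nl*) and the length of its longest leaf (*L*max).  The reconstructed
leafy architecture is the input a functional–structural plant model (FSPM)
needs to compute light interception or spray deposition at the organ scale.

The package is written for plant-architecture modellers and horticultural
scientists.  It ships the published parameter sets for the cultivars Ariane
(AR), Fuji (FU) and Rome Beauty (RB), the full
parameterization/calibration/testing workflow to refit the models on new
data, and a synthetic-data generator with recorded ground truth so that
every fitting stage is testable without orchard measurements.

## The models

Leaf blades are treated as ellipses with a genotype-constant width/length
ratio *k* = W/L = √(1 − e²), so a blade's area is A = (π/4)·k·L².  Within a
bourse shoot or rosette, leaf area normalized by the biggest leaf area
follows a Lorentz curve over normalized rank *x*:

    N(A_R) = 1 / (1 + (x − x₀)² / s²)

with the peak at x₀ (bourse shoots: rank 2, so ranks are shifted by −2;
rosettes: x₀ ≈ 0.63).  Summing over ranks ties the curve to the total-leaf-
area allometry TLA = β·nl·Amax, and integrating it gives the closed form

    s·[ atan((x − x₀)/s) ]_a^b = β ,

a monotone equation in *s* that the package inverts by bracketed root
finding — this is how the profile width *s* is obtained from the robustly
estimable slope β without ever fitting the noisy normalized scatter.  The
final calibrated per-leaf model is

    A_R = α · (π/4)·k·Lmax² / (1 + (R − R_peak)² / (nl²·s²)) ,

where α is the calibration slope of measured on calculated total leaf area.
Vegetative shoots use the descriptive linear profile A_R = p·(R/nl)·(π/4)·k·Lmax².
Leaf insertion heights along the bourse → bourse-shoot continuum follow a
logistic in normalized rank, N(D_I) = 1/(1 + exp((qi − R_I/nl)/si)).
Shoot development is tracked in growing degree hours above a 7 °C base,
accumulated into degree days from full bloom.

## Worked example

Predict the seven leaves of a Fuji bourse shoot whose longest leaf measures
9.5 cm, using the shipped parameters:

```sh
$ pomarch predict --shoot-type BS --genotype FU --nl 7 --lmax-cm 9.5
rank,area_cm2
1,39.830527511208224
2,44.91095193865825
3,39.830527511208224
4,29.738333040462898
5,20.90866171015919
6,14.769373456337279
7,10.721737612639485
# TLA_cm2 = 200.71
```

The profile peaks at rank 2 (44.9 cm² = α·(π/4)·k·Lmax² with α = 0.99,
k = 0.64), falls off symmetrically around it with the width s(nl=7) = 0.40,
and the seven leaves together carry about 200 cm².  The same library call is
`ShootLeafAreaResults.predict` / `predict_leaf_area`.

Refitting on data (here: a synthetic dataset, then the workflow):

```python
from pomarch import PipelineConfig, run_parameterization
from pomarch.synthetic import SyntheticConfig, generate_leaf_dataset

leaves, truth = generate_leaf_dataset(SyntheticConfig(), seed=11)
report = run_parameterization(leaves, PipelineConfig(seed=4))
print(report.summary())
```

prints, per shoot-type and genotype group, the fitted slope β with its R²,
the scale table, and per genotype the blade ratio k, the calibration slope
α and the held-out testing regression, e.g. for the pooled Ariane/Fuji
bourse shoots:

```
Leaf-area model: shoot type BS, genotype group AR|FU
  shoots      : 120 (80 train / 40 test, seed 4)
  beta        : 0.6563  (R^2 = 0.991)
  s           : per-nl table (e.g. s(5) = 0.343); x0 = 0
  AR: k = 0.599 (R^2 = 0.94), alpha = 1.244
      test TLA  : slope = 0.977, R^2 = 0.963, RMSE = 16.9 cm^2 (n = 20)
  FU: k = 0.635 (R^2 = 0.96), alpha = 1.030
      test TLA  : slope = 1.005, R^2 = 0.979, RMSE = 10.6 cm^2 (n = 20)
```

A testing slope near 1 with high R² means the calibrated model transfers to
held-out shoots.  `pomarch reconstruct` assembles a whole spur (rosette +
bourse shoot) as one table of leaf areas and insertion distances; `pomarch
fit`, `simulate`, `phenology` and `evaluate` cover the rest of the workflow
from the shell.

## Layout

- `pomarch.geometry` — elliptical blade area, eccentricity, the ratio k
- `pomarch.profile` — Lorentz profile, the arctan closed form and its inversion
- `pomarch.prediction` — calibrated forward models, shipped parameters, spur reconstruction
- `pomarch.internode` — logistic internode model (`InternodeModel.fit()`)
- `pomarch.phenology` — growing degree hours/days, full-development filter
- `pomarch.pipeline` — `ShootLeafAreaModel` / `VegetativeShootModel`, grouping
  tests, train/test split, `run_parameterization`
- `pomarch.synthetic` — orchard-like data generator with recorded truth
- `pomarch.io`, `pomarch.cli` — CSV/JSON dialects and the `pomarch` command

See `docs/methods.md` for the modelling assumptions, parameter meanings,
numerical choices and known limitations.
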