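# meicoc

Crossover-interference statistics for meiotic focus-mapping data.

During meiosis, crossover (CO) sites marked cytologically (e.g. by Zip3
foci on budding-yeast synaptonemal complexes) are spaced more evenly along
the chromosome axis than chance predicts — *crossover interference*. This
package implements the standard cytological analysis toolkit around that
phenomenon for focus-position datasets (one chromosome axis per record,
with its length in µm and the ordered focus positions measured from a
marked end):

* **Coefficient of coincidence (CoC) curves.** Each axis is normalized to 1
  and cut into *n* equal intervals (default 30). For an interval pair
  (*i*, *j*), `CoC = ObsDCO / PredDCO`, where ObsDCO is the frequency of
  chromosomes with foci in *both* intervals and PredDCO = *f<sub>i</sub> f<sub>j</sub>*
  is the product of the single-interval focus frequencies. Averaging CoC
  over pairs with equal midpoint distance gives the CoC curve: ~0 at short
  distances under strong interference, fluctuating around 1 once
  interference has decayed.
* **Gamma-shape interference estimation.** Inter-adjacent focus distances
  are fitted by a two-parameter gamma distribution via maximum likelihood;
  the shape ν is the interference-strength scalar (ν = 1 ⇒ Poisson, no
  interference). Confidence intervals come from a parametric bootstrap —
  either iid resampling from the fitted gamma, or a renewal-aware bootstrap
  that resimulates the fitted point process on the observed axes and
  thereby corrects the edge-censoring bias of the plain MLE.
* **Focus/axis metrics.** Per-nucleus focus counts, axis lengths,
  foci-per-µm densities, zero-focus (obligatory-CO failure) frequencies,
  multiplicative independence expectations for double mutants, overlap and
  conditional percentages, Welch/Student *t* and pooled two-proportion *z*
  tests with the usual significance-star convention.
* **Tetrad missegregation scoring.** Tetrads carrying spore-autonomous
  YFP/RFP markers on homologous centromeres segregate 2-yellow : 2-red when
  faithful; any other fluorescent pattern scores as missegregation, and
  all-dark tetrads are excluded from the denominator.
* **Immunofluorescence quantification.** Per-nucleus background is the
  flattening level of three line profiles drawn perpendicular to chromosome
  fragments; the corrected integrated intensity is
  `Σ(pixels > background) − background × n_above` over the nucleus mask.
* **Synthetic data.** A seeded generator places foci by a *stationary
  gamma-renewal process* (first event from the equilibrium
  forward-recurrence distribution, gaps iid Gamma(ν, µ/ν)), draws lognormal
  axis lengths, and also emits tetrad color patterns and spot-on-background
  nucleus images with recorded ground truth — so every analysis stage can
  be validated without microscopy data.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on simulated
cohorts (2000 chromosome-XV-like axes each, ~6 foci per 3 µm axis) and
write their tables under `results/`:

```sh
python analysis/01_simulate_focus_data.py
python analysis/02_coc_curves.py
```

prints

```
poisson  CoC(shortest)= 1.022  CoC(d>0.5)=1.033 -> coc_poisson.tsv
wt_like  CoC(shortest)= 0.569  CoC(d>0.5)=1.030 -> coc_wt_like.tsv
strong   CoC(shortest)= 0.017  CoC(d>0.5)=1.022 -> coc_strong.tsv
```

i.e. without interference (gamma shape 1) the curve is flat at 1; with
shape 10 the short-distance CoC collapses to ~0 while long distances stay
at 1. The gamma fit recovers the generating interference strength
(`analysis/03_gamma_interference.py`, micron units):

```
poisson  micron     shape= 1.033  95% CI=(0.974, 1.033)  n_gaps=9871
wt_like  micron     shape= 2.028  95% CI=(1.942, 2.041)  n_gaps=10043
strong   micron     shape= 9.939  95% CI=(9.627, 10.135)  n_gaps=10054
```

The same operations are available as a CLI (`meicoc simulate | coc | gamma
| metrics | missegregation | compare | quantify | validate | run`), with
`meicoc run config.yaml` executing a staged simulate→analyze pipeline that
records a reproducibility manifest.

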