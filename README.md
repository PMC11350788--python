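# rangerisk

Climate-change conservation assessment for species with point occurrence
records: fit presence–background **maximum-entropy** distribution models,
binarize habitat suitability with **Jenks natural breaks**, project ranges
onto future climate scenarios, and reclassify species into **IUCN threat
categories** from projected range loss — including geometry-based rules for
species too data-poor to model. The whole pipeline is validated end-to-end
on **virtual species** with known climatic niches, so every estimate can be
checked against an exact ground truth.

It is written for conservation biogeographers and ecological modellers who
want a transparent, scriptable, fully reproducible version of the standard
MaxEnt → binarize → range-change → red-list workflow.

## The model

For a species with presence cells *P* on a landscape of background cells,
the fitted distribution is the Gibbs / maximum-entropy model

```
q(x) = exp(λ·z(x)) / Z,     Z = Σ_x exp(λ·z(x)),
```

where `z(x)` are min–max-normalized linear and quadratic climate features.
`λ` maximizes the L1-penalized presence log-likelihood

```
f(λ) = mean_{x∈P} λ·z(x) − log Z − Σ_j β_j |λ_j|,
```

with `β_j = b·sd_j/√m` (background feature sd, `m` presences, global knob
`b = 0.05`), so the allowed slack on the fitted feature means shrinks at the
same rate as the sampling error of the presence means. Suitability is
reported on the logistic scale `p(x) = e^H q(x) / (1 + e^H q(x))` with `H`
the entropy of the fitted distribution.

Seven replicate models (75/25 presence splits, background capped at
100,000 cells) are averaged; quality is the Mann–Whitney AUC of presence vs
background scores. The averaged map is cut into non/low/medium/high
habitability by Fisher–Jenks optimal 1-D classification; the range is the
union of the low/medium/high zones with geodesic cell areas. Range loss

```
L = (A_current − A_future) / A_current
```

maps onto the threat ladder: `EX` at L = 1, `CR` ≥ 0.8, `EN` ≥ 0.5,
`VU` ≥ 0.3, `NT` ≥ 0.1, else `LC`. Species with 1–3 records skip the model:
their baseline category is elevated by 1–3 levels from the area of the
3-record triangle (< 100 / 500 / 10,000 km²), the 2-record distance
(< 10 / 50 / 500 km), or unconditionally by 3 levels for singletons, and
held constant across future horizons.

Before any fitting, predictors are screened on the current climate:
pairwise Pearson |r| > 0.8 exclusion, then iterative elimination of
variance inflation factors above 10.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from rangerisk import (RunConfig, run, summarize_declining_fraction,
                       synthesize_study)

study = synthesize_study(n_species=4, n_data_poor=2, seed=1)
report = run(RunConfig(seed=1), study.occurrences, study.current, study.futures)

print(report.auc_summary.round(3).to_string(index=False))
cols = ["species", "scenario", "horizon", "path", "loss_fraction", "category"]
sub = report.assessments.query("horizon == '2070s' and scenario == 'SSP5-8.5'")
print(sub[cols].round(3).to_string(index=False))
print(summarize_declining_fraction(report))
```

prints

```
species  auc_train  auc_test  n_records
  vs000      0.908     0.899        195
  vs001      0.956     0.954        186
  vs002      0.928     0.921        188
  vs003      0.946     0.934        187
species scenario horizon               path  loss_fraction category
  vs000 SSP5-8.5   2070s        model_based          0.256       NT
  vs001 SSP5-8.5   2070s        model_based          0.117       NT
  vs002 SSP5-8.5   2070s        model_based          0.085       LC
  vs003 SSP5-8.5   2070s        model_based         -0.116       LC
  dp000 SSP5-8.5   2070s   data_poor_single            NaN       EN
  dp001 SSP5-8.5   2070s data_poor_distance            NaN       VU
{'SSP2-4.5/2050s': 0.75, 'SSP2-4.5/2070s': 0.75, 'SSP5-8.5/2050s': 0.75, 'SSP5-8.5/2070s': 0.75}
```

Four virtual species are modelled (replicate-averaged AUC ≈ 0.9–0.95); under
the high-emission late-century scenario the cold-adapted `vs000` loses a
quarter of its range (`NT`), the warm-margin `vs003` expands (`LC`,
negative loss), and the two data-poor species are elevated by the
single-record (+3 → `EN`) and two-record-distance (+2 → `VU`) rules. 75% of
modelled species decline under every scenario. For comparison,
`study.true_loss` holds each species' exact loss fraction computed from its
known niche.

A `rangerisk` console script exposes the same stages
(`synthesize`, `screen`, `fit`, `classify`, `assess`, `run-all`, `report`):

```sh
rangerisk synthesize --out study/ --n-species 5 --seed 42
rangerisk run-all --study study/ --out run/ --seed 42
```

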