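# troph

Trophic niche metrics and mixed-model analysis of dietary overlap between
coexisting river fishes, plus a synthetic field-survey generator with known
ground truth.

## The problem

When two fish species share a river reach, how strongly they compete for
food can be read from their **dietary overlap**: the percentage similarity
of their stomach contents. A central ecological question is what drives
overlap down — and a leading candidate is the **diversity of the prey
community**: where many prey taxa are available, sympatric consumers can
specialize on different prey and partition the resource; where prey
diversity is low, they are forced onto the same food.

`troph` implements the full analysis chain used to test this in a
multi-site river survey of juvenile Atlantic salmon (*Salmo salar*) and
alpine bullhead (*Cottus poecilopus*):

* **Diet composition** from fullness-scored stomach contents:
  percent prey abundance `A_i = 100 Σ S_i / Σ S_t`.
* **Schoener percentage overlap** `P_jk = Σ_i min(A_ij, A_ik)` between two
  populations (0 = disjoint diets, 100 = identical), computed over all prey
  or over aquatic prey only (surface prey removed and diets renormalized).
* **Levins niche breadth** `B = 1 / Σ P_i²` (1 = monophagy, k = uniform
  use of k prey).
* **Individual specialization**: Bolnick's proportional similarity
  `PS_i = 1 − ½ Σ_j |p_ij − Q_j|` per fish, and its population prevalence
  `1 − mean(PS_i)`.
* **Shannon prey diversity** `H′ = −Σ p_i log₁₀ p_i` of benthos kick
  samples (base-10 logarithm), with abundance in individuals per m².
* **Zippin removal estimation** of fish density from multi-pass
  electrofishing catches (profile-likelihood over integer N with
  `p̂(N) = T / (T + R + k(N−T))`).
* **Drivers of overlap**: Pearson screening of candidate explanatory
  variables, forward stepwise selection by ML-based AIC, REML linear
  mixed-effect models with a site random intercept ranked by AICc, and a
  parametric bootstrap of the best model.

A synthetic-data module generates complete surveys (benthos, stomachs,
removal catches) whose prey pools hit target diversities and whose
species-level diet divergence grows with diversity, so every stage is
testable against known truth without field data. The package also ships
the published 11-site per-site summary matrix as a fixture.

## Worked example

```python
from troph import ModelSpec, fit_lmm, load_site_summary_fixture, pearson

sites = load_site_summary_fixture()          # 11 sites x 20 columns

r = pearson(sites["prey_diversity"], sites["overlap_total"])
print(f"r = {r.r:.3f}, p = {r.p:.3f}")       # r = -0.726, p = 0.011

fit = fit_lmm(ModelSpec("overlap_total", ["prey_diversity"]), sites)
c = fit.coefficients["prey_diversity"]
print(f"slope = {c['estimate']:.2f} (SE {c['se']:.2f}), t = {c['t']:.3f}")
# slope = -75.21 (SE 23.75), t = -3.166
```

Dietary overlap drops by about 75 percentage points per unit of Shannon
prey diversity across the surveyed range (H′ 0.50–0.98): prey-rich sites
show strong resource partitioning, prey-poor sites almost complete diet
sharing. With one overlap value per site the site random-intercept variance
is estimated at its zero boundary, so the fixed effects coincide with
ordinary least squares while the AICc accounting still counts both variance
components.

From a shell, the same pipeline runs end to end:

```bash
troph simulate --seed 11 --out survey/          # synthetic raw tables
troph pipeline --stomachs survey/stomachs.csv --benthos survey/benthos.csv \
    --removals survey/removals.csv --taxonomy survey/taxonomy.csv \
    --bootstrap 1000 --seed 1 --out results/
```

which writes the site summary, correlation table, AICc model ranking, best
model coefficients and bootstrap summary.

## Layout

```
src/troph/
  io_tables.py             CSV schemas, record types, packaged survey fixture
  community_metrics.py     Shannon diversity, benthos abundance
  diet_metrics.py          composition, overlap, breadth, specialization
  abundance_estimation.py  Zippin removal estimator
  model_selection.py       Pearson, REML/ML mixed models, AICc, stepwise, bootstrap
  synthetic_data.py        ground-truth survey generator
  pipeline.py, cli.py      orchestration and `troph` command
docs/methods.md            model and design notes
```
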