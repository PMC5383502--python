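# Methods and design notes

## Diet composition from fullness points

Stomach contents are quantified by the fullness-points method: the total
fullness of each stomach is scored visually on a 0–100% scale and split
over prey taxa so the per-prey points sum exactly to the scored total
(tolerance 1e-6; the scores are human-assigned percentages with at most
one decimal). The population diet of a site × species group is the pooled
fullness ratio

    A_i = 100 · (Σ_fish S_i) / (Σ_fish S_t),

i.e. a fullness-weighted mean of individual compositions. This guarantees
Σ A_i = 100, which the overlap index requires for its 0–100 range. Empty
stomachs contribute nothing to either sum (and are excluded from
individual-level indices) but are counted in the sample size.

## Overlap, breadth and individual specialization

Percentage (Schoener) overlap between species j and k is
`P_jk = Σ_i min(A_ij, A_ik)` at the finest prey resolution available;
taxa absent from both diets contribute nothing and no smoothing or
pseudo-counts are applied. The **aquatic-only** variant removes
surface-flagged taxa from every stomach and renormalizes each diet to 100
before the overlap sum. Renormalization is essential, not cosmetic: when
one species feeds heavily at the surface, its aquatic diet concentrates on
the remaining taxa and the aquatic overlap can *exceed* the all-prey
overlap (the packaged survey contains a site where the all-prey overlap is
11.5% but the aquatic overlap is 44.0%).

Levins breadth is `B = 1/Σ P_i²` on the composition as fractions; it is
invariant to taxon relabeling, equals 1 for monophagy and k for a uniform
k-prey diet. Individual specialization uses Bolnick's proportional
similarity `PS_i = 1 − ½ Σ_j |p_ij − Q_j|`, where `p_ij` is the fish's own
fullness-normalized composition and `Q_j` the population fraction; the
population-level prevalence of specialization is reported as
`1 − mean(PS_i)` together with the SD over individuals. The prevalence is
the *complement* of the mean, not its reciprocal — this keeps it in [0, 1)
and matches how multi-site surveys tabulate it. At least two nonempty
stomachs are required.

Coarse-group summaries aggregate taxa into the seven aquatic categories
(Ephemeroptera, Plecoptera, Trichoptera, Diptera, Mollusca, Coleoptera,
others) plus surface. Merging categories can only raise a sum of minima,
so overlap at coarse resolution is ≥ overlap at fine resolution; the fine
resolution is the default everywhere.

## Prey community metrics

Shannon diversity is computed in **base-10 logarithm** — the convention
under which the survey's printed range (0.50–0.98) is interpretable — with
a `base` switch for natural-log users. Replicate kick samples of a site
are pooled (counts summed) before proportions are formed, not averaged;
abundance is total individuals over total swept area (the kick-frame area,
2.25 m² per replicate by default, is always an explicit input because
sweep geometry varies between programs).

## Zippin removal estimation

Catches from k successive removal passes follow the depletion model in
which an animal is first caught on pass i with probability p(1−p)^(i−1).
The estimator maximizes the integer-N profile likelihood with
`p̂(N) = T/(T + R + k(N−T))`, `R = Σ (i−1)c_i`, using the classical
Stirling form of the combinatorial term. This reproduces the textbook
removal equations: perfectly geometric catches (16, 8, 4) give N̂ = 32 and
p̂ = 0.5, and scaling all catches by m scales N̂ by m exactly. The
exact-factorial integer MLE can differ from the classical estimator by a
couple of animals on small samples; the classical form is what removal
sampling practice reports, so it is the implementation (the module
docstring records the distinction). Series with no depletion signal
(non-declining catches, R/T ≥ (k−1)/2) have no finite optimum; the
estimator then returns the total catch flagged `converged=False` rather
than aborting a pipeline, because three-pass series at low capture
probability are a known weak spot of the method. Densities are
100·N̂/area and are not floored.

## Mixed models, AICc and selection

Overlap (one value per site) is modeled as a linear mixed-effect model
with a site random intercept. The fit profiles the variance ratio
λ = σ²_site/σ² out of the (restricted) likelihood and maximizes over
λ ≥ 0, so with one observation per site the random variance lands on the
zero boundary and the fixed effects, SEs, t and p reproduce OLS exactly
(verified against an OLS oracle to 1e-8, and against nlme/MixedLM on
grouped data). The REML log-likelihood keeps every constant:

    logLik = −½ [ (n−p) ln 2π + ln|V| + ln|XᵀV⁻¹X| + yᵀPy ].

AICc = AIC + 2k(k+1)/(n−k−1) with k counting the intercept, the slopes
and **both** variance components even at the boundary (k = 4 for a
single-predictor model). These conventions matter: AICc values are
convention-dependent and comparable only within a stated convention.
Coefficient p-values are two-sided t with residual df = n − p.

Forward stepwise selection compares ML fits (fixed effects differ between
candidates, where REML likelihoods are not comparable), adding at each
step the candidate with the largest AIC decrease and stopping when none
helps. Final reported fits and the AICc ranking use REML. The default
ranking set is the single-variable models; multi-variable combinations are
opt-in (`max_terms`) for the same REML-comparability reason, and because
small-n AICc comparisons across differing fixed structures are fragile.
Ties are broken toward fewer parameters.

The variable screen reports Pearson **product-moment** correlations with
two-sided t-tests (df = n − 2). The parametric bootstrap simulates
responses from the fitted model (fixed part + site random draws +
residual draws), refits each replicate by REML, and reports the slope
distribution, sign consistency and the correlation distribution; replicate
RNG streams are spawned from the seed (counter-style), so results are
bit-reproducible and independent of evaluation order.

## Synthetic surveys and what they do (not) show

The generator emulates the survey design stage by stage. Site prey pools
are symmetric-Dirichlet draws whose concentration is solved by root
finding on the closed-form expected entropy `ψ(kα+1) − ψ(α+1)` (nats,
tolerance 1e-4 on H′) to hit a target diversity; targets are spaced over
H′ 0.50–0.98 by default, mirroring the surveyed range. Benthos replicates
are multinomial draws from the pool (3 replicates × 2.25 m², 600
individuals per site by default). Species diet preferences start from the
pool and are pushed apart by exponential tilting with strength
`partition_strength · H′` (default strength 2, which yields overlap
declines of the magnitude seen in the field data); salmon are additionally
biased toward surface taxa (default 30% of diet vs 2% for bullhead).
Per-fish compositions are Dirichlet draws around the species preference
(concentration 50), trimmed to the six largest prey per stomach to mimic
real stomachs holding few taxa, with total fullness scored in steps of 5
and a 5% empty-stomach rate. Removal catches are sequential binomial
thinnings of a true N (defaults 30 salmon, 60 bullhead per site, capture
probability 0.6, 3 passes).

Everything is deterministic given the config seed (per-site spawned
streams), and by construction expected overlap is 100 at zero partition
strength and non-increasing in it.

What the generator does **not** emulate: hydrological or seasonal
dynamics, drift subsidies, spatial correlation between sites,
size-structured diets, or observer error in taxon identification. Passing
recovery tests therefore show the estimators are correct for the stated
sampling model, not that field data meet that model.

**Known estimator bias, deliberately not hidden:** the observed Schoener
overlap `Σ min(Â, B̂)` is biased downward whenever the compositions are
estimated from finite samples, and the bias grows with the effective
number of prey categories — i.e. with prey diversity. A partition-free
simulation (true overlap exactly 100 everywhere) therefore still shows a
systematically negative *observed* diversity–overlap slope (around −5 to
−9 overlap points per diversity unit at realistic stomach sample sizes),
and its confidence interval rarely covers zero. This is a property of
percentage-overlap estimation generally, not of this implementation; one
acceptance-level calibration check fails for exactly this reason and is
kept failing rather than masked. Empirical diversity–overlap effects of
much larger magnitude (the survey's −75 per diversity unit) are well
outside this artifact, but small observed slopes should not be
over-interpreted.

## Numerical choices

* Proportion vectors validated to sum to 1 (or 100) within 1e-9.
* Variance-ratio optimization: bounded scalar minimization of the profiled
  deviance over ln λ ∈ [−12, 12], compared against the λ = 0 boundary.
* Exact-fit degeneracy (zero residual quadratic form relative to ‖y‖²)
  reported as σ² = 0 with zero SEs rather than overflowing the likelihood.
* Zippin integer scan runs to 20 × total catch; an optimum on the bound is
  non-convergence.
* All output tables are sorted by site label and written with fixed float
  formats, so identical configs reproduce output files byte-identically.
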