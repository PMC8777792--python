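# Methods

This note records the modelling choices behind `trpcap`: what each stage
assumes, which knobs matter, what the synthetic generators do and do not
emulate, and where the genuinely open design decisions were settled.

## Reference network and producibility

The reference network is a bipartite metabolite/reaction graph rooted at
L-tryptophan, with per-record origin labels (host / microbe / both / unknown),
a currency flag per metabolite, and one of three branch tags (indole,
serotonin, kynurenine) per reaction.

**Reachability semantics.** An organism's producible set is the fixed point
of firing reactions from the root: a reaction fires once *all* of its
non-currency substrates are reachable; currency species (water, ammonia,
cofactors, ...) are assumed freely available; reversible reactions fire in
either direction; currency species and the root itself are never reported as
products. Requiring all non-currency substrates is the conservative choice
for multi-substrate reactions — it prevents claiming an end product (e.g.
indolepropionate) when the obligatory intermediate (indoleacrylate) has no
producing route. The alternative "presence" semantics (a metabolite counts
whenever some present reaction emits it) is available via
`producible_set(..., mode="presence")`; reachability is the default because
presence over-calls products of orphaned downstream reactions.

**Currency list.** The authoritative currency call is the `is_currency`
column of the network file. `DEFAULT_CURRENCY_NAMES` (water, proton, oxygen,
CO₂, ammonia, ATP/ADP/Pi, NAD(P)(H), CoA) seeds the synthetic generator and
is a suggestion to curators, since any fixed list is somewhat arbitrary
beyond the obvious species.

**No flux.** There is no FBA, stoichiometric balancing, or thermodynamics:
capability calls are presence/absence by design, so coefficients affect
nothing downstream of schema validation.

## GEM mining

SBML models are read with cobrapy; compartment suffixes (`_c`, `_e`, ...) are
recorded and stripped, so the same chemical species in two compartments is
one metabolite for matching. Because GEM collections use different id
dialects, matching to the reference is by **mapped metabolite-set equality**:
after translating ids through the cross-reference table and dropping currency
species, a GEM reaction matches a reference reaction when both sides are
set-equal (orientation may flip when either reaction is reversible;
stoichiometric coefficients are ignored). A GEM species that touches the
pathway but has no mapping blocks the match — conservative, and such
near-miss reactions are tallied per model as `unmatched_count` so users can
see how much tryptophan chemistry escaped the curation. This matcher is one
defensible reconciliation of heterogeneous collections, not the only one; its
round-trip correctness is what the synthetic SBML fixtures certify.

Duplicate strains across collections merge by identical strain-level lineage:
reaction sets union, host flags OR, source recorded as `both`. Species-level
models become a pseudo-strain named after the species. Host-habitat
annotation is table-driven with strain entries overriding species entries;
unannotated models keep both flags false and are listed in a report rather
than guessed.

## Capability analysis

The capability matrix restricts columns to bioactive metabolites (currency
and plumbing metabolites are never reported). Genus prevalence is the
producer fraction within a genus, optionally host-filtered.

Metabolic distance is Jaccard on boolean capability rows (Hamming via
config); two all-false rows are at distance 0 by convention. Hierarchical
clustering is complete-linkage agglomeration implemented in-package with
fixed tie rules — minimal pair chosen by lowest cluster indices, leaf order
placing the smaller subtree first (ties by smallest leaf index) — so
dendrograms and tanglegram exports are reproducible bit for bit; scipy's
implementation serves as an independent cross-check on tie-free inputs in the
test suite. Entanglement between two dendrograms over the same leaves is the
L1 rank statistic: Σ|rank₁(leaf) − rank₂(leaf)| divided by its maximum
⌊n²/2⌋, giving 0 for identical leaf orders and 1 for exact reversal (0 by
convention for a single leaf). Phylogenies are consumed as user-supplied
newick trees (patristic distances via dendropy); no tree inference is done.

## Per-metabolite Bayesian logistic regression

**Design.** One observation per strain-level model. Columns: intercept, one
0/1 indicator per *dominant* genus, and a host-habitat indicator. Dominant
genera are those with at least `n_min = 10` models in the database; all
others pool into the baseline. The cutoff is a prevalence threshold, chosen
so that each indicator rests on enough strains to estimate a log-odds and so
that realistic databases yield a panel of roughly a dozen genera.

**Prior and inference.** Independent Normal(0, 2.5²) priors on slope
coefficients and Normal(0, 10²) on the intercept. Since every design column
is already a 0/1 indicator, the prior is applied on the natural indicator
scale — 2.5 is then a weakly-informative bound on a log-odds difference
(rstanarm's autoscaling would divide by the column sd; for balanced
indicators that roughly doubles the scale, and both are configurable via
`PriorSpec`). Inference is MAP by damped Newton iterations (gradient
tolerance 1e-8; near the optimum, where objective changes underflow double
precision, the full Newton step is taken), with the Laplace covariance
Σ = H⁻¹ at the MAP and Gaussian posterior draws Normal(β̂, Σ), seeded so
every report regenerates identically. This is an approximation to a full
MCMC posterior; for logit models with weak priors at database scale
(hundreds to thousands of observations, ~15 parameters) the posterior is
close to Gaussian and the approximation is adequate, which the
planted-parameter recovery checks quantify. The proper prior also handles
complete separation and single-class responses (no Firth correction needed);
such fits warn and shrink to the prior.

**Reporting.** Odds ratios are exp(β̂); Wald z = β̂/SE with SEs from the
Laplace covariance (a Bayesian-flavoured convention, stated here because a
frequentist SE would differ slightly); significance bands at
{0.001, 0.01, 0.05, 0.1}.

**Model selection.** AIC = 2k − 2·logLik with the *unpenalized*
log-likelihood evaluated at the MAP — a stated convention, since mixing AIC
with Bayesian fitting requires one; ties prefer fewer parameters, and all
candidates must share the same observations.

**PSIS-LOO.** Importance ratios 1/p(yᵢ|θₛ) over the posterior draws,
tail-smoothed per observation by a fitted generalized Pareto distribution
(tail size min(0.2·S, 3√S); the smoothing is delegated to `arviz.psislw`,
which implements exactly this estimator), giving per-observation Pareto-k
diagnostics and elpd_loo = Σᵢ log(Σₛ wᵢₛ p(yᵢ|θₛ) / Σₛ wᵢₛ). At least 100
draws are required (default 2000).

**ROC holdout.** 80/20 split of the database, fit on train, score held-out
strains; AUC by the rank statistic with tie correction. Degenerate
single-class test splits are re-drawn (up to 10 reseeds, warning attached).

## Sample prediction

P(M, G) = logistic(β̂₀ + β̂_G + β̂_host) with the host indicator set for the
requested host family. Genera without their own indicator — below the
dominance cutoff in training, or entirely novel — contribute the host
baseline logistic(β̂₀ + β̂_host) rather than zero, so predictions degrade
gracefully; the abundance mass carried by such genera is reported per sample
as `unseen_mass`.

Raw potential T(s, M) = Σ_G P(M, G)·a(s, G). Count tables are TSS-normalised
per sample before this step (compositional comparability); tables declared
`relative` enter as given, keeping T exactly linear in the input. TSS of the
potentials is per sample across metabolites by default (each sample's
metabolite profile sums to 1), mirroring how relative metabolomics profiles
are read; per-metabolite scaling across samples is available via
`axis="metabolite"`. Zero-sum rows stay zero and are flagged.

Group comparison: two-sided Mann-Whitney U per metabolite on TSS potentials
(the nonparametric default at case/control sizes of 8–20 per arm, where
normality of compositional shares is doubtful), Benjamini-Hochberg across
metabolites, direction as the sign of the case-minus-control median.
Metabolites constant across all samples get p = 1 with a tie flag.
Concordance against metabolomics row-TSS-scales *both* tables over the
shared metabolite set — intensity units are arbitrary per sample, so rank
correlation and direction agreement are computed on a common compositional
basis; metabolites present in only one source are listed separately.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of a `SimSpec` and its seed.

- **Reference networks** reproduce the real network's *shape* — rooted,
  three tagged branches, ≥2 currency species, ≥1 multi-substrate reaction,
  every non-currency metabolite reachable when all reactions are present —
  at reduced size (default 12 metabolites / 10 reactions). A separate
  unconstrained random-network generator (no connectivity guarantee)
  exercises the reachability oracle on pathological topologies.
- **Synthetic GEMs** are minimal SBML models carrying a known
  reference-reaction subset in a foreign id dialect with compartment
  suffixes, plus decoy reactions over unmapped species. They have no
  biomass/exchange scaffolding and no FBA objective — only what matching
  exercises.
- **Capability databases** draw production flags from the same logistic
  model the fitting stage assumes: 13 dominant genera (default 40 models
  each), a planted structure of 2 strong producer genera per metabolite
  (log-odds +3.5, echoing the order-of-magnitude odds ratios a real database
  shows) over weak Normal(0, 0.3) effects, intercept −2, host effect +1,
  host flags Bernoulli(1/2), plus a pool of rare genera (6 × 5 models,
  effect 0) forming the regression baseline the way the long
  low-prevalence tail does in a real database. Because data are generated
  from the fitted model family, recovery tests certify the inference
  machinery, not robustness to model misspecification.
- **Studies** draw genus compositions from a symmetric Dirichlet with
  concentration α = 5 per genus. The abundance model covers the
  dominant-genus panel, whose genus-level shares in cecal/stool profiles are
  stable and non-zero; a uniform simplex (α = 1) would put frequent
  near-zeros on every genus, which is unrealistic for that panel and would
  make an 8 vs 8 design uninformative about method correctness rather than
  about power. Case samples have one target genus multiplied by the fold
  change (default 5) before renormalisation; fold 1 is the exchangeable
  null. Pseudo-metabolomics tables are the true potentials under
  multiplicative log-normal noise (σ = 0.3), mimicking LC-MS intensity
  scatter without modelling spectra, adducts, or missingness.

Problem sizes used in the validation suite — 200 random networks, 100 SBML
models, 100 fitting replicates at n ≈ 2000 (and ≈ 1000 for AIC selection),
100 end-to-end pipeline runs plus 200 null studies at 8+8 samples — were
chosen so each statistical claim has conventional power at desk scale while
the whole suite stays fast.

## Numerical conventions and degenerate inputs

- Gradient tolerance 1e-8 (max norm) for MAP fits; non-convergence raises
  with diagnostics rather than returning a silent partial fit.
- Laplace covariance symmetrised after inversion; Wald tests refuse
  non-positive-definite covariances.
- Jaccard 0/0 → 0; Mann-Whitney on fully tied data → p = 1 with a flag;
  BH applied to whatever p-vector results.
- Agglomeration ties → lowest-index pair; leaf-order ties → smaller subtree,
  then smallest leaf index.
- All-zero abundance rows → zero potentials, warning, and a zero-row flag
  carried through TSS.
- Seeds: every stochastic routine takes an explicit seed or Generator;
  posterior draws are stored with their seed so tables regenerate
  byte-identically.

## Known limitations

- Capability is reachability over curated reactions: no expression, flux,
  regulation, or community cross-feeding; a "producer" is an organism whose
  reconstruction admits a route, not one observed to secrete the compound.
- Genus-level prediction inherits 16S resolution limits; within-genus strain
  heterogeneity is averaged into P(M, G).
- The Laplace approximation understates posterior asymmetry for rare
  genera with few producers; Pareto-k diagnostics flag observations where
  the importance sampling itself is strained.
- The production-potential statistic is linear in abundance and ignores
  substrate availability and inter-metabolite competition; TSS makes it
  compositional, so single-metabolite shifts induce apparent opposite shifts
  elsewhere (visible in the worked example).
- Synthetic validation certifies internal correctness and error control, not
  transfer to real communities: real capability databases are not generated
  by a clean logistic law, and real abundance tables are sparser and more
  overdispersed than a Dirichlet.
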