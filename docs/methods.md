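# Methods

This note documents the model, the likelihood derivation, the numerical
choices and the synthetic-data conventions used throughout `islert`, in
the package's own terms.

## The CES model

Island community assembly is modelled per mainland lineage as a
continuous-time Markov process. For a guild with mainland pool size
`M_guild`, each lineage independently:

* colonizes the island at rate `gamma · max(0, 1 − n/K)`, where `n` is the
  clade's current island diversity. A colonization while a conspecific
  non-endemic population is extant has no effect; a colonization of a
  clade whose survivors are all endemic re-establishes a non-endemic
  population (the `endemic_and_non_endemic` status);
* each island species goes extinct at `mu` and splits cladogenetically at
  `lambda_c · max(0, 1 − n/K)`; when the splitting species is the
  non-endemic immigrant population, both daughters are endemic;
* a non-endemic population anagenetically becomes an endemic species at
  `lambda_a` (local species counts unchanged).

`K` is a per-clade carrying capacity; `K = ∞` removes diversity
dependence, in which case species evolve as independent linear
birth–death lineages and colonizations accrue as a gated Poisson stream.
Times are Myr before present; the island originates at `T` (default 88,
66 as a sensitivity choice) and the two guilds are bats (22% of a
1000-species mainland pool by default) and non-volant mammals.

## Likelihood

The observation per colonist lineage is: colonization time (precise stem
age, or a maximum age when only an upper bound is known), the branching
times of the reconstructed (extant-lineage) island tree, the endemicity
status, and a count of missing species (known clade members without
branching-time information). Mainland lineages are independent, so

```
log L(data) = Σ_colonists log L_clade + Σ_guilds (M_guild − C_guild) · log P_0
```

where `P_0` is the probability that a lineage leaves no observed colonist
and `C_guild` the number of observed colonists. Two routes compute
`L_clade`; they are cross-validated against each other and against
simulation.

**Analytic route (K = ∞, no missing species).** Doomed side lineages are
marginalized with linear birth–death theory. With `E(t)` the probability
that a species alive at `t` leaves no extant descendant, the
reconstructed-branch factor is `q(t) = (1 − p0)(1 − η)`, which satisfies
`dq/dt = −(λc + μ − 2 λc E) q` — the factor 2 arises because an unordered
daughter pair realizes the pattern (doomed, surviving) in two ways. The
density of a sorted branching-time vector carries a factor `k λc q(x)`
per node with `k` reconstructed lineages, i.e. a factorial over
branchings relative to the labeled-tree convention. Four auxiliary value
functions close the computation, each a 2-dimensional linear ODE in time
with coefficient `c(t) = μ + λa E + λc E²` (the immigrant doom kernel):

* `P0(t)` / `P1(t)`: probability, starting with no island population at
  `t`, that at the present the lineage has nothing extant / exactly an
  extant non-endemic population (terminal conditions [1,0] and [0,1]);
* `w(t)`: the adjoint weight propagated from the island origin, giving
  `P_pre(t_c)` — no colonization older than `t_c` leaves extant issue and
  the lineage is unoccupied at `t_c`;
* max-age non-endemic records evaluate in closed form from these:
  `w(t_max) · [P1(t_max), P1b(t_max) − exp(−R_i t_max)]`, the
  homogeneous subtraction removing the immigrant-survives-past-the-bound
  path.

The founder's conversion from non-endemic to endemic (anagenesis, or
cladogenesis with a doomed daughter, kernel `λa + 2 λc E`) is integrated
by Gauss–Legendre quadrature over the stem interval;
`endemic_and_non_endemic` records replace the recolonization-doom factor
`P0` by the recolonization-survivor factor `P1`. Max-age endemic clades
integrate the colonization time over (crown, t_max].

**Master-equation route (finite K, max-age windows, missing species).**
The per-lineage Kolmogorov equations are integrated over the joint state
(pre-colonization occupancy; observed lineage count; `j` = founder still
non-endemic; `h` = hidden re-colonist population; `n` = hidden endemic
count, truncated at `n_max`). Branchings and precise colonizations are
point operators; propagation uses chunked uniformization of the sparse
generator (non-negative, numerically stable for density vectors). With
`K = ∞` the pre-colonization phase is replaced exactly by the analytic
weight `γ P_pre(t_c)`, so hidden survivors at the present are clade
members only — the missing-species semantics. The truncation bound is
accepted when boundary mass is negligible relative to the terminal value
and otherwise verified by doubling until the log-likelihood is stable to
1e-5 (bounded by a cap, 512 by default, 160 inside optimizations where
saturating corners are treated as impossible).

**Missing species** are extant clade members whose attachment is
marginalized over both time and lineage ("anywhere within the clade"),
which weights later intervals by the number of reconstructed lineages;
brute-force integration over placements reproduces the route exactly on
2- and 3-species clades. Missing-species likelihoods carry a fixed
combinatorial multiplicity from the sampled/unsampled designation; being
rate-independent, it does not affect inference. Extant endemics founded
by re-colonizations are folded into the missing count by the pruning
convention, and the likelihood's terminal states match that convention
by construction.

**Conditioning** defaults to none; conditioning on at least one observed
colonization is available and divides by `1 − Π P_0^{M_guild}`.

The likelihood equations are validated against the generative process:
state distributions agree with exact Gillespie frequencies (total
variation < 0.02 at 1e5 simulations across a grid including finite `K`),
and the 2-species clade density matches a binned Monte-Carlo estimate.

## Inference

Free parameters are optimized on the log scale (the shift time on a
logistic scale) by Nelder–Mead with one fresh-simplex restart from the
incumbent — the restart guards against premature collapse along nearly
flat directions such as the anagenesis rate. Starts combine one
method-of-moments warm start (colonist counts over lineage-time;
branching counts over reconstructed tree length) with log-uniform draws
on [1e-4, 10] (K on [largest clade, 1e3]), resampled when they land in
impossible regions; a box (rates ≤ 30/Myr, `K` ≥ largest observed clade)
keeps the search out of absurd corners. `AIC = 2k − 2 logL`;
`BIC = k ln(n_eff) − 2 logL` with `n_eff` defaulting to the number of
observed colonizations plus branching events (the literature does not fix
this choice; it is configurable). Model selection defaults to BIC, ties
broken toward fewer parameters.

The model family `M1`–`M30` is generated programmatically: `M1`–`M4` are
one-guild models (`K` free or infinite × anagenesis free or zero);
`M5`–`M30` let a subset of {γ, λc, λa, μ} differ for bats, each with `K`
free or infinite. Which sharing pattern carries which numeric id is a
documented convention anchored at `M1`, `M3`, `M5`, `M6` and `M26`
(separate γ and μ, shared λc and λa, `K = ∞` — the preferred model for
the Madagascar system); code should select models by pattern rather than
number. `M31`/`M32` add a colonization-rate shift at an estimated time.

## Return times

The evolutionary return time (ERT) is the time for a guild's diversity to
return from a start to a target level under natural rates. With `K = ∞`
the expected local diversity obeys `dN/dt = Γ + rN` (`Γ = γ·M_guild`,
`r = λc − μ`), giving the crossing time in closed form; for `r < 0` the
guild sits in a sink equilibrium at `Γ/(μ − λc)` — targets above it are
reported unreachable rather than extrapolated. The default estimator is
the expected-trajectory crossing; a stochastic first-passage estimator
(vectorized Gillespie over aggregate counts, censored at a horizon
defaulting to 10× the deterministic estimate) provides distributions, in
local diversity or global-endemic diversity (only new endemic species
count; colonization adds locally but not globally). Colonization inflow
during forward simulation is `Γ` uncorrected for species already present
(the correction is < 5% for the Madagascar pools). With `K = ∞`, clade
identity is dynamically irrelevant, so start communities are instantiated
as aggregate counts; finite-K forward simulation requires an explicit
clade assignment and is therefore exposed only through the full
simulator.

Recovery-vs-loss curves draw start diversities uniformly between 0 and
the target with a uniform endemic proportion (non-endemics capped by the
mainland pool). Discovery perturbations append each newly discovered
species as a missing species to a uniformly chosen island clade of its
guild (lone non-endemic populations cannot host unplaced members; the
uniform choice is a documented convention, as is entering discoveries
into the refit data under every fate, mirroring the
anthropogenic-extinction treatment of recent extinctions), refit the
model per replicate and recompute the ERT with the target raised by the
number of discoveries.

## Tree extraction

Node ages come from branch lengths with present-day tips at age zero
(ultrametricity tolerance 1e-6 × tree height). An island clade's
colonization time is the age of its MRCA's parent (stem age); branching
times are the nodes of the subtree induced by the clade's sampled island
tips; a lone non-endemic tip yields a max-age record at its tip
divergence age; a clade with both endemic and non-endemic tips keeps all
its branching times (within-island cladogenesis followed by off-island
expansion). Species absent from the tree are added as missing species to
their annotated clade, or — when a whole lineage is unsampled — as a
max-age colonist at an annotated reference age. The alternative
colonization scenarios CS1 (fewer colonizations) and CS2 (more) are
expressed entirely through the annotation's clade-assignment columns;
crown-versus-stem reference choices likewise enter through the
annotation, never through topology heuristics.

## Synthetic data and fixtures

The packaged fixtures store only printed aggregate quantities of the
Madagascar system: 249 pre-human species (46 bats, 9 of them non-endemic;
203 non-volant), 30 recent extinctions (2 bats), threatened totals
56/110/128 for 2010/2015/2021 (2021 split 5 bats / 123 non-volant), 18
unassessed species (10 bats / 8 non-volant), the preferred model's rates
(λc = 0.33, λa = 1.47, μ = 0.29 non-volant / 0.46 bats, γ = 0.00036
non-volant / 0.034 bats, `K = ∞`) and the pool (M = 1000, 22% bats,
T = 88). The guild split of the 2010/2015 threatened totals is not a
published quantity; the fixture's split (2/54 and 4/106) is a synthetic
stand-in and is labelled as such, as are the extinction cause/timing
assignments beyond the published margins (16 anthropogenic / 4 natural /
10 uncertain causes; 9 undated relative to human arrival, 2 of them bats;
two undated extinctions kept anthropogenic under both impact scenarios).

The checklist generator reproduces a configuration's aggregates exactly
with monotone non-improving IUCN statuses; the pseudo-posterior generator
jitters event times log-normally (unit mean) with resampling of ordering
violations; the tree-set generator hangs known island clades off a
mainland spine so each is monophyletic by construction. What these
emulate — and what they do not — bounds what passing tests show about
real data: synthetic checklists have no taxonomic ambiguity, synthetic
trees no topological uncertainty beyond age jitter, and simulated
communities no rate heterogeneity within guilds. Agreement on synthetic
data therefore validates the estimators and their implementation, not the
biological adequacy of constant-rate CES models.

## Problem sizes in the test suite

The test suite runs the study's analyses at sizes chosen to keep the full
suite practical on a single CPU: the simulator/likelihood equivalence
grid uses 1e5 simulations per rate combination at T = 5; parameter
recovery fits 12 replicate islands at the full Madagascar scale (T = 88,
M = 1000) with one warm start per fit; model selection contrasts the one-
and two-guild models on 50 smaller islands (T = 12, M = 150-200);
goodness-of-fit examples use 100–150 simulations. The corresponding
operations accept larger sizes (e.g. 5000 simulated islands for
goodness of fit) unchanged.

## Known limitations

* Finite-K likelihoods with missing species treat pre-colonization hidden
  survivors approximately (exactly handled for `K = ∞`, where the
  preferred models live); finite-K forward ERT simulation needs explicit
  clade assignments.
* The anagenesis rate is weakly identified from single datasets (its
  profile is nearly flat over a several-fold range), and because
  non-endemic populations enter the data only as max-age records —
  bound-type observations whose true colonization time the likelihood
  deliberately integrates away — its maximum-likelihood estimate does not
  concentrate on the generative value even as colonist numbers grow.
  Recovery experiments therefore assess colonization, cladogenesis and
  extinction; anagenesis uncertainty is reported via batch intervals.
* No Bayesian machinery, no standard errors from the Hessian (uncertainty
  is propagated by fitting across tree posteriors), no trait-dependent or
  multi-shift temporal rate variation, and no spatial structure such as
  temporary land bridges.
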