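# Methods

## The chemostat model

A well-mixed vessel of fixed volume is diluted at rate `B` with influent
media carrying nutrient at concentration `phi0` and free virions at count
`psi0`. The cell population is structured by volume `p` (discrete bins from
the newborn size `P0` to the division size `2*P0 - 1`) and intracellular
virion count `q` (0 to `Q`, default 1000), stored as the count matrix
`n(p, q)`. The intracellular virus concentration is normalised as

    rho(p, q) = (q / Q) * (P0 / p),

so a newborn cell at the intracellular cap has concentration one.

Per unit time, a cell of volume `p`:

* advances one volume bin at rate `A * (1 - r/E) * phi * p`; uninfected
  cells leaving the top bin divide into two newborns; infected cells are
  division-arrested at the top bin but keep their other dynamics;
* if uninfected, ingests a virion at rate `C * psi * p` (superinfection
  exclusion: infected cells ingest nothing), removing that virion from the
  free pool;
* replicates internal virus at rate `F * q` (saturating at `Q`);
* clears one virion at rate `r * p` (immunity; cleared virions are
  destroyed);
* lyses at rate `(rho / (T - rho))**G` below the lethal threshold `T`, and
  with probability one within a step at `rho >= T`, releasing all `q`
  virions;
* washes out at rate `B` (virions inside washed-out cells leave with them).

Nutrient obeys `dphi = [(phi0 - phi) B - C phi * sum(p n)] dt`; the virion
pool gains influx and burst releases and loses dilution and infections. A
PCD-competent genotype (investment `a`) additionally self-destructs, without
any virion release, as soon as `rho > 1 - a`; the sweep runs after the flux
update of each step, so a cell is removed in the same step its concentration
crosses the threshold. Immunity carries the multiplicative growth cost
`1 - r/E`; PCD carries no direct cost — its cost is the forgone future
reproduction of the dying cell.

### Integration scheme

The update is an explicit Euler step evaluated simultaneously from the
start-of-step state. The step size adapts so that no occupied state's total
exit probability from growth, infection, replication, immunity and dilution
exceeds 5% per step. States at `rho >= T` are emptied within the step. Any negativity (impossible under the controller, checked
anyway) halves the step and retries. The integrator tracks the highest
occupied virion column and restricts all loops to it, which makes strongly
PCD-protected populations (occupancy limited to a few columns) hundreds of
times cheaper than unprotected ones.

### Equilibrium detection

Runs integrate until the sliding-window time-average of the total population
N changes by less than `tol` (default 1e-4) between consecutive windows.
The window starts at one time unit and widens as 5% of elapsed time so that
slow oscillations are averaged rather than chased. Fitness is the windowed
mean N. Populations below an absolute floor of
1e-6 cells, in a long decline below 1e-9 of their own peak, or in a
sustained steady decline (six consecutive windows each dropping at least
5%) six orders of magnitude below their peak, are reported extinct with
`N_star = 0`; the depth requirement sits far beyond any observed transient
overshoot of the initial state. The lysis rate is excluded from the step
controller — its per-step probability saturates at one, the correct limit
for a near-certain event — so unbounded rates near the lethal threshold do
not force vanishing steps.

### Initial condition

The habitat is bistable under strong influent virus: a tiny inoculum can
stall on a low-density branch (or die) even where a large population
persists. Because the object of study is the equilibrium of an established
population, runs start by default from a closed-form estimate of the
established virus-free state: `phi* ~ S*B/(A_eff ln 2)` with
`S = sum_p 1/p` (division-cycle time balancing dilution), biomass from the
nutrient balance, and a quasi-static virion pool. The estimate only needs
to land in the right basin. A one-cell inoculum in fresh media is available
as `init="inoculum"`.

### Volume rescaling

The model has an exact symmetry: `C -> C*lambda`, `psi0 -> psi0/lambda`
divides every population variable by `lambda` while leaving per-cell rates,
the nutrient trajectory, the extrinsic MOI `C*psi0`, and the entire fitness
landscape (including the optimal strategy) unchanged. `rescale_volume`
exposes it; it is the sanctioned way to obtain small populations for
stochastic runs without changing the ecology.

## Landscapes and optimisation

Fitness of a strategy `(a, r)` is its equilibrium population size. The
optimiser runs a coarse grid over `[0,1] x [0,E]` followed by refinement
rounds on boxes shrunk five-fold around the incumbent (which is always
re-evaluated, so refinement never loses ground); ties break toward the
least investment. PCD-sensitivity is `1 - N(0, r_opt)/N_opt`, classified
sensitive at >= 0.1; landscapes whose a-profile at `r_opt` is flat to 1%
over half the grid are additionally flagged as plateaus, since the argmax
location is then unstable. Library defaults are a 21x21 coarse grid with
three 9x9 refinements; the routine configuration uses Q=200 with an 11x6
coarse grid and two 5x5 refinements, and single-parameter scans use Q=60
with 6x4 grids plus one 5x4 refinement — the optimum location is
insensitive to this coarsening at the tolerances of interest.

### What our transcription of the model implies

In this implementation the maximal immunity clearance (`r*p <= E * 2*P0`)
is orders of magnitude below in-range replication rates (`F*q`), so an
infected cell essentially never recovers; delaying PCD therefore only
wastes shared nutrient, and on PCD-sensitive landscapes the optimum pins at
`a ~ 1`, `r = 0`. Two consequences are documented rather than hidden:

* ecological scans move the optimum only between "pinned near (1, 0)" and
  "plateau/extinct", so the directional trends (PCD investment falling with
  viral pressure, rising with carrying capacity) hold in the weak
  (equality) sense along PCD-sensitive scan pairs;
* at the pinned optimum PCD is an exactly neutral trait in a well-mixed
  vessel (the dying cell forgoes nothing); the neutrality phenomenon is
  demonstrated in the high-skew habitat with the PCD threshold set below
  the concentration of the saturated arrested cells, where PCD fires at a
  substantial rate yet only on cells with zero expected progeny;
* selective collapse of PCD-competents is realised at the reference
  strategy `(0.98716, 0.00584)`, where the PCD-competent subpopulation is
  eliminated first and the cheater remainder then collapses through phage
  amplification — PCD acting as a population-stabilising public good.

## Stochastic competition and the metapopulation

Demographic noise is realised by tau-leaping: each deterministic flux
becomes a draw with the same expectation. Within a state the channels are
drawn as sequential conditioned binomials (exact multinomial thinning), so
a state can never be overdrawn and counts stay non-negative; the
expectation of a single leap equals the deterministic Euler step exactly.
The leap size obeys the same 5% exit-probability cap.

Competition runs start from the deterministic equilibrium of the altruist
alone, with a share of every `(p, q)` class relabelled as cheaters (same
`r`, `a = 0`), so neither genotype starts with a transient advantage.
Neutrality classification fits per-replicate slopes of logit(altruist
fraction) against time (right-censored at fixation/extinction) and tests
the across-replicate mean slope against zero at two standard errors.

The metapopulation couples up to `K` such vessels. Vessel births (rate
`b*(K-k)/K`) add empty chemostats with influent media; deaths (rate `d`)
remove a uniform vessel; at exponential epochs (mean `m`) a source vessel
drawn proportionally to its integer population size sends
`Binomial(N_i, f)` migrants, altruists binomial in the source composition
and `(p, q)` classes sampled hypergeometrically from the source occupancy,
to a uniformly chosen destination. Between ensemble events all vessels
advance in parallel with the tau-leap kernel (competing exponential clocks
decide the event type); routine metapopulation runs use Q=100. Runs start from `K/2` vessels seeded with the
mixed equilibrium at altruist share 0.9: the reference ecology is fragile
enough that a 50:50 seed collapses globally before population structure can
act, and the evolutionary-stability question is precisely whether an
established PCD-competent metapopulation resists cheater invasion.

## Burst-size distributions

The equilibrium integrator accumulates lysis events by intracellular load
over the final averaging window; the histogram sums to the lysis event
rate. Mode counting lightly smooths the histogram and counts peaks of
prominence above 5% of the tallest. A genuinely two-peaked distribution —
most lysis events at low counts, a second spike at the lethal concentration
— arises in a high-skew regime in which a burst's expected viral offspring
is below replacement (here `F = 0.4`, below the surveyed replication range:
at in-range `F` with `T = 1, G = 1` near-lethal bursts give the phage a
reproduction number far above one and the host collapses), so the phage
population is sustained by influx while most infected cells idle at low
loads and a minority completes the cascade.

## Genomic investment statistics

`I_PCD` and `I_Imm` are fractions of the genome (nucleotides) occupied by
PCD-class and immunity-class systems; overlapping genes are union-counted
when coordinates are given, and undefined-class systems count toward
neither. The regression `I_PCD = beta * I_Imm**alpha` with lognormal noise
is fitted by maximum likelihood, which for this noise model is exactly
ordinary least squares on log-log coordinates with the ML (1/n) residual
variance as `gamma^2`; records with a zero on either axis are excluded
(positive support) and counted. The reported log-likelihood is that of the
observed `I_PCD` under the lognormal predictive density, so free and
fixed-alpha fits on the same records are BIC-comparable
(`BIC = k ln n - 2 loglik`, k = 3 free / 2 fixed).

## Abundance stratification

Within each sample, present species receive average ranks (larger = more
abundant); per species, rank quartiles are computed over the samples
containing it, and species in fewer than 100 samples are excluded. A
species is high-abundant when its first rank quartile exceeds the integer
threshold `T_a`, low-abundant when its third quartile is below it; `T_a`
maximises the smaller of the two groups among species with genomes (ties to
the smaller threshold, equivalent to exhaustive search). Group contrasts
use two-sided Mann-Whitney tests; deviations from the genome-size
expectation fit `log(nt+1) ~ log(genome length)` on the full species set
and test each group's residuals against zero by Wilcoxon signed-rank,
reported as signed log10 p with quadrant labels ordered (low-group word,
high-group word).

## Synthetic data

The genome generator draws `log I_Imm ~ Normal(log 0.01, 0.8)` and applies
the power law at `alpha = 0.554` with `beta = 0.05`, `gamma = 0.8` —
nominal constants placing immunity investments around 1% of the genome and
PCD investments a few tenths of a percent, with under an order of magnitude
of scatter; no published estimates of beta or gamma exist to calibrate
against. Gene records (PCD genes shorter than immunity genes on average)
sum exactly to the drawn nucleotide targets, so aggregation round-trips.

The gut generator plants three abundance tiers: stable high (30 species),
stable low (45), and highly variable intermediates (65) whose abundance
switches between a high state and a low state from sample to sample —
statistically matching the stable tiers, which is the only construction in
which their rank quartiles genuinely straddle the classifier threshold; 10
rare species exercise the presence filter. The planted effect multiplies
high-tier PCD investment by `e^delta` (`delta = 1`, about 2.7-fold, a
moderate effect of the magnitude the group contrast is meant to detect)
and leaves immunity untouched; an optional confound enlarges high-tier
genomes 1.6-fold. The system panel plants quadrant memberships
(5/10/25/21 across the four quadrants, plus a PCD-like profile and a null
random-gene profile) as ±0.8 log-shifts against a unit genome-size slope
with 0.3 noise.

What the generators do not emulate: phylogenetic correlation between
species, within-species genome variation, compositional coupling beyond
per-sample normalisation, and annotation error. Passing recovery tests
therefore demonstrates correctness of the estimators and pipeline wiring
under the stated model, not robustness to real-data violations of it.

## Known limitations

* The printed update equations, implemented faithfully, do not reproduce an
  interior optimum at the reference ecology (see above); comparisons
  against the reported optimum are made at the criterion's scaled
  tolerances (a_opt > 0.95, r_opt/E < 0.10).
* Expected-progeny reasoning explains neutrality in this implementation,
  but the observed collapse at the reference strategy is census- and
  ecology-mediated rather than driven by forgone progeny.
* The deterministic core is continuous-mass; extinction below one cell is
  handled by an absolute floor rather than demographic stochasticity.
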