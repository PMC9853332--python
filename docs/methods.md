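# Methods

## Scope and moving parts

`streamspom` couples three stochastic layers, each usable on its own:

1. **hydrology** — daily specific discharge Q(t) (mm d⁻¹) from a marked
   Poisson rainfall process routed through a linear reservoir;
2. **activation** — a threshold map from Q(t) to the binary wet/dry state
   Xᵢ(t) of every reach, plus the derived habitat statistics (active length
   L(t), largest connected portion LCP(t), duration curves, static-equivalent
   networks);
3. **spom** — a discrete-time stochastic patch occupancy model whose
   colonization and extinction probabilities are driven by the instantaneous
   habitat geometry, with **experiments** orchestrating Monte-Carlo ensembles
   over 3 climates × 3 persistency configurations.

## Hydrologic forcing

Effective rainfall events arrive as a Poisson process with frequency λ (d⁻¹)
and carry exponential depths of mean α (mm). The linear storage–discharge
relation produces exponential recessions at rate k (d⁻¹), making Q a
shot-noise process with stationary marginal Gamma(shape = λ/k, scale = α·k):
mean αλ and CV² = k/λ.

The integrator samples each event's arrival time uniformly within its day and
decays its jump k·h by the remaining fraction of the day:

    Q(t) = Q(t−1)·e^{−k} + Σ_events k·h·e^{−k(1−u)},   u ~ U[0,1).

This is the *exact* daily sampling of the continuous process: initialised
from the stationary law (the default, `q0="stationary"`), every simulated day
is marginally gamma. The cruder textbook recurrences that dump the whole
daily depth at the end (`within_day="end"`) or start (`"start"`) of the day
bias the stationary mean by a factor k/(1−e^{−k}) ≈ ±17 % at k = 0.35 and are
retained only for pedagogy. On rain-free days Q decays by exactly e^{−k}.

Climate presets (α, λ_P, E_p, λ): dry (15, 0.25, 3.0, 0.10), intermediate
(12, 0.40, 2.5, 0.22), wet (10, 0.55, 2.0, 0.37); derived mean precipitation
P_t = α·λ_P and actual evapotranspiration E_a = P_t − α·λ. The effective
frequency λ is a configured input, not derived from a soil-moisture balance
(that would need a storage parameter we do not model). The recession rate
defaults to k = 0.35 d⁻¹ and is exposed in both `ClimateParams` and
`ScenarioConfig`; the occupancy statistics proved nearly insensitive to k in
the 0.15–0.35 range because the flow quantile mapping used by the activation
layer rescales with it.

## Persistency and hierarchical activation

All reaches respond to the single scalar Q(t), so the active network always
expands and contracts through nested prefixes of one fixed order — from the
most to the least persistent reach. The order comes from one of three
proxies: a uniform random field, the topographic wetness index
TWI = ln[(A/w_c)/tanβ] (w_c = one cell size), or the contributing area A.
Thresholds are set by quantile calibration: the reach with ascending
persistency rank r (of N) gets Q\* = F⁻¹(1 − (r+½)/N) where F is the
stationary flow cdf of a *reference climate* (the intermediate preset by
default). Hence under the reference climate the persistencies are the uniform
plotting positions with mean exactly 0.5, and the same physical thresholds
re-evaluated under the dry/wet presets give mean persistency 0.32/0.63
(computed numerically). A field study could replace this surrogate with
measured persistencies; the quantile scheme is the minimal assumption-free
choice when only climate statistics are known.

Consequences used throughout: area-ranked persistency always yields an active
network connected to the outlet (contributing area increases strictly
downstream); TWI-ranking produces occasional disconnections because the
lognormal slope noise (sd 0.5 on log-slope, power-law exponent −0.5 on
relative area, base slope 0.05) scrambles some adjacent-pair orderings
(~12 % on the default network); random ranking fragments the habitat heavily.

Because active sets are prefixes, per-day connectivity statistics reduce to a
single union-find sweep (LCP for every prefix size, O(N α)) and the SPOM's
distance matrices are cached per prefix size, which is what makes 100
year-long replicates run in seconds.

## Metapopulation model

Occupancy is a synchronous Markov chain: per day and per node,

    vacant → occupied  with  Φ_C = 1 − exp(−C Δt),
    occupied → vacant  with  Φ_E = 1 − exp(−E Δt),   Δt = 1 d (fixed),

with C_i = c Σ_{j≠i} exp(−d_ij/δ)·S_j·w_j(t−Δt) and E_i = e/S_i. Notes:

- **Extinction is inversely proportional to suitability.** The units of e
  (m² d⁻¹) and the model's logic force E = e/S; beware that a typeset form
  "E = e·S" sometimes seen for such models is dimensionally inconsistent
  with these traits.
- **Suitability** S_i = Δl_i·W_i·X_i(t) is the wetted stream-bed area; width
  follows W = k_w·A^{0.5} with k_w calibrated to 15 m at 10 km² (both
  exposed). Dry nodes have S = 0 and Φ_E = 1 exactly — the designated guard
  for the 1/S singularity — so an occupied reach that dries is lost at the
  next update, and no dormancy or lentic refuge is modelled.
- **Dispersal is path-blocked**: d_ij is the along-channel distance between
  node centres and is finite only if every node on the tree path (endpoints
  included) is wet *today*; sources enter with yesterday's occupancy but
  today's suitability. A reach that activates today can therefore be
  colonized today but cannot yet act as a source. Dispersal is unbiased
  (no upstream/downstream asymmetry) and has no rescue effect on extinction.
- **Kernel cutoff**: pairs beyond 23·δ are dropped; exp(−23) ≈ 1e−10 bounds
  the relative truncation error of any colonization rate.
- **Initial condition**: every initially wet reach is occupied. This measures
  *persistence* of an established metapopulation rather than invasion; the
  alternative initializations (all nodes, random fraction) are a one-line
  change through `w0`.
- **Degenerate inputs**: an empty active day leaves occupancy empty;
  whole-network extinction is absorbing and short-circuits the loop;
  duplicate ranks, dry initial occupancy, dry dispersal sources and cyclic
  drainage maps raise typed errors.

The exact oracle propagates the full 2^N state distribution through the same
per-step law (the update-probability code is shared, not duplicated) and is
enumeration-limited to N ≤ 12; the Monte-Carlo engine is validated against it
to three binomial standard errors at 10⁵ replicates.

## Scenario protocol

A scenario = climate × persistency ranking on a generated network (default:
invasion-grown lattice drainage tree, 300 nodes, 100 m cells, ≈37 km total
length, NND ≈ 122 m). Per replicate: fresh rainfall year (366 days; day 0
carries the stationary initial condition and is excluded from statistics) →
discharge → activation → dynamic SPOM. The **static twin** runs the same
engine on the most-persistent prefix whose length matches the
scenario-ensemble mean of the time-mean active length (two-pass design: one
equivalent static network per scenario, shared by its 50 static replicates).
The focal species is c = 0.015 m⁻² d⁻¹, e = 20 m² d⁻¹, δ = 4·NND; trait
sweeps use log-spaced grids c ∈ [10⁻⁵, 10²], e ∈ [10⁻³, 10³] with δ fixed,
and the virtual-species pool samples δ ~ U[1,10]·NND with log-uniform c, e.

Reported metrics: Ω(t) = occupied length / *total* network length; survival =
fraction of replicates with Ω > 0 at day 365; the temporal CV of Ω is
computed per replicate over days 1–365 and averaged over the replicates that
survive the year (extinct replicates' CVs measure the decay to zero, not
occupancy fluctuation; inclusion counts are always reported). Every result
carries its config hash and base seed; all randomness flows from one seed
through named `numpy` SeedSequence streams, so reruns are bit-identical.

## What the synthetic networks do and do not capture

The generator reproduces the *structural* ingredients the model needs —
dendritic topology, Horton-like area accumulation, width and TWI scaling,
adjustable persistency/area correlation — but not any particular real
catchment: reach lengths are lattice-quantised (100–141 m), widths follow a
single power law, and per-reach suitabilities (≈50–820 m²) are large enough
that colonization between wet neighbours typically completes within a day
and the most persistent downstream reaches are nearly extinction-proof for
the focal species. Against a field catchment with shorter, narrower reaches
one should expect: stronger depression of dynamic mean occupancy below the
static twin, stricter extinction under the dry climate, and smaller
amplification of the occupancy CV than the ≈13× this surrogate produces
(ordering and zonation results are insensitive to this scale; the CV and
survival *extremes* are not). Passing tests therefore demonstrate the
internal correctness of the coupled machinery and the direction of every
published effect, not calibrated magnitudes for any specific river.

## Problem sizes

Default experiment sizes (300 nodes, 50 replicates × 365 days per scenario,
5×5 trait grids × 20 replicates for sensitivity maps) were chosen so a full
nine-scenario study runs in under a minute on one core; all sizes are plain
config fields.
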