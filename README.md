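# streamspom

Coupled stochastic simulation of **expanding/contracting stream networks**
and the **metapopulation dynamics** of an aquatic species living on them.

Many river networks are temporary: individual reaches dry out whenever local
runoff drops below a threshold, so the flowing ("active") network pulses with
the hydrologic forcing. For species that disperse along the wetted channel —
a stream fish, say — this pulsing continually reshapes both the amount of
habitat and its connectivity. `streamspom` is a research tool for asking how
much that matters: it simulates daily discharge from climate parameters,
converts it into a wet/dry state for every reach of a dendritic network, runs
a stochastic patch occupancy model (SPOM) on the pulsing habitat, and compares
the outcome with a *static* twin network of equal mean flowing length.

## Model

**Hydrology.** Daily effective rainfall is a marked Poisson process (event
frequency λ d⁻¹, exponential depths with mean α mm); a linear reservoir turns
it into specific discharge Q(t) (mm d⁻¹) with exponential recessions at rate
k d⁻¹. The stationary law of Q is Gamma(λ/k, αk) — mean αλ, CV² = k/λ. Three
climate presets (dry / intermediate / wet) are built in.

**Network activation.** Each reach i carries an activation threshold Q\*ᵢ:
it is wet on day t iff Q(t) ≥ Q\*ᵢ. Thresholds come from ranking the reaches
by a persistency proxy — a random field, the topographic wetness index
TWI = ln[(A/w)/tanβ], or the contributing area A — and mapping the ranks
through the quantiles of a reference climate's flow distribution, so the
local persistency Pᵢ (the fraction of time reach i flows) follows the proxy
and averages 0.5 under the reference climate. Activation is *hierarchical*:
reaches always wet up from the most to the least persistent and dry in the
reverse order, so disconnections appear exactly where persistency varies
non-monotonically in space.

**Metapopulation.** Occupancy wᵢ(t) ∈ {0,1} evolves as a synchronous
discrete-time Markov chain with

    Φ_C,i = 1 − exp(−C_i Δt),  C_i = c Σ_{j≠i} e^{−d_ij/δ} S_j w_j(t−Δt)
    Φ_E,i = 1 − exp(−E_i Δt),  E_i = e / S_i          (Φ_E,i = 1 when dry)

where Sᵢ = Δlᵢ·Wᵢ·Xᵢ(t) is the wetted stream-bed area (m²), δ the dispersal
distance, and d_ij the along-channel distance, finite only if *every* reach
on the path is currently wet — dispersal cannot cross dry channels. An exact
2^N state-distribution propagator is included as an oracle for the stochastic
engine on small networks.

## Worked example

```python
import json
from streamspom.experiments import ScenarioConfig, run_scenario

cfg = ScenarioConfig(climate="wet", scenario="twi", n_mc=20, base_seed=7)
res = run_scenario(cfg)
print(json.dumps(res.summary(), indent=2))
```

prints (abridged):

```json
{
  "climate": "wet",
  "scenario": "twi",
  "survival_dynamic": 1.0,
  "survival_static": 1.0,
  "mean_omega_dynamic": 0.5565070738505988,
  "mean_omega_static": 0.5527195549734166,
  "cv_dynamic": 0.3748384882476193,
  "cv_static": 0.027015427958242272,
  "mean_active_length_m": 23125.98540907035,
  "mean_lcp_m": 22987.308194014648,
  "mean_persistency": 0.6268110257878828,
  "static_target_length_m": 23190.663761154774
}
```

Read this as: under the wet climate with TWI-ranked persistency, the focal
species (c = 0.015 m⁻² d⁻¹, e = 20 m² d⁻¹, δ = 4 NND) survives the year in
every replicate in both model variants, and occupies ~56 % of the 37 km
network on average; but the *temporal variability* of occupancy is an order
of magnitude larger on the pulsing network (CV 0.37 vs 0.03), and the largest
connected flowing portion (23.0 km) stays close to the active length
(23.1 km) — the few TWI-induced disconnections barely fragment the habitat.

The same machinery is exposed on the command line:

```bash
streamspom generate-network --n-nodes 300 --out net.csv
streamspom simulate-hydrology --climate wet --days 365 --out q.csv
streamspom run-scenario --climate int --scenario random --seed 1 --out run/
streamspom sensitivity --climate wet --n-c 5 --n-e 5 --out sens/
```

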