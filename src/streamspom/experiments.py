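"""Scenario orchestration: climates × persistency configurations, Monte-Carlo
ensembles, occupancy metrics, survival probabilities and sensitivity maps.

A *scenario* couples one hydroclimatic regime (dry / intermediate / wet) with
one spatial configuration of reach persistency (random / twi / area) on a
synthetic dendritic network. For every Monte-Carlo replicate a fresh year of
daily discharge is drawn, mapped to the pulsing active network, and the
dynamic stochastic patch occupancy model is run on it; a *static* counterpart
runs the same engine on a time-invariant network whose flowing length equals
the scenario-ensemble mean active length (one equivalent static network per
scenario, shared by all its static replicates). All randomness derives from a
single base seed through named ``numpy`` seed sequences, so reruns are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .activation import (
    ActivationSeries,
    PersistencyField,
    activate,
    calibrate_thresholds,
    duration_curve,
    lcp_series,
    persistency_under,
    static_equivalent,
)
from .errors import ParameterError
from .hydrology import ClimateParams, effective_rainfall, simulate_discharge
from .network_gen import (
    StreamNetwork,
    assign_slopes,
    compute_twi,
    compute_width,
    generate_network,
    proxy_ranking,
)
from .spom import DispersalCache, OccupancyTrajectory, SpeciesTraits, simulate_spom

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "build_network",
    "occupancy_fraction",
    "survival_probability",
    "temporal_cv",
    "local_occupancy",
    "run_scenario",
    "sensitivity_analysis",
    "species_pool",
]

# seed-sequence stream tags
_NET, _SLOPE, _RANK, _RAIN, _Q0, _SPOM_DYN, _SPOM_STA, _CELL = range(8)


@dataclasses.dataclass
class ScenarioConfig:
    """Everything needed to reproduce one climate × persistency scenario."""

    climate: Union[str, ClimateParams] = "intermediate"
    scenario: str = "area"
    n_nodes: int = 300
    cell_size: float = 100.0
    style: str = "lattice_random_tree"
    k: float = 0.35
    reference_climate: str = "intermediate"
    rank_offset: float = 0.5
    T: int = 365
    dt: float = 1.0
    n_mc: int = 50
    base_seed: int = 0
    c: float = 0.015
    e: float = 20.0
    delta_nnd: float = 4.0
    static: bool = True
    slope_exponent: float = -0.5
    slope_noise_sd: float = 0.5
    slope_s0: float = 0.05
    b_w: float = 0.5
    k_w: Optional[float] = None
    network_file: Optional[str] = None

    def __post_init__(self):
        if self.T < 1:
            raise ParameterError("T must be >= 1")
        if self.n_mc < 1:
            raise ParameterError("n_mc must be >= 1")
        if self.dt != 1.0:
            raise ParameterError("the daily-resolution model requires dt = 1 d")

    def resolve_climate(self) -> ClimateParams:
        if isinstance(self.climate, ClimateParams):
            return self.climate
        return ClimateParams.preset(self.climate, k=self.k)

    def resolve_reference(self) -> ClimateParams:
        return ClimateParams.preset(self.reference_climate, k=self.k)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.climate, ClimateParams):
            d["climate"] = dataclasses.asdict(self.climate)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _seed(cfg: ScenarioConfig, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(cfg.base_seed), spawn_key=tuple(key))


def build_network(cfg: ScenarioConfig):
    """Generate (or load) the network, attach attributes, rank and calibrate.

    Returns ``(net, ranking, field, traits)`` with the focal-species traits
    resolved against the network's nearest-neighbour distance.
    """
    if cfg.network_file is not None:
        from .network_gen import read_network

        net = read_network(cfg.network_file)
        if net.area is None:
            from .network_gen import compute_contributing_area

            net.area = compute_contributing_area(net)
    else:
        net = generate_network(cfg.n_nodes, cfg.cell_size, seed=_seed(cfg, _NET), style=cfg.style)
    if net.slope is None:
        net.slope = assign_slopes(
            net, seed=_seed(cfg, _SLOPE), exponent=cfg.slope_exponent,
            noise_sd=cfg.slope_noise_sd, s0=cfg.slope_s0,
        )
    if net.twi is None:
        net.twi = compute_twi(net)
    if net.width is None:
        net.width = compute_width(net, k_w=cfg.k_w, b_w=cfg.b_w)
    ranking = proxy_ranking(net, cfg.scenario, seed=_seed(cfg, _RANK))
    field = calibrate_thresholds(net, ranking, cfg.resolve_reference(), rank_offset=cfg.rank_offset)
    traits = SpeciesTraits(c=cfg.c, e=cfg.e, delta=cfg.delta_nnd * net.nnd)
    return net, ranking, field, traits


def occupancy_fraction(traj: Union[OccupancyTrajectory, np.ndarray], net: StreamNetwork) -> np.ndarray:
    """Ω(t): occupied length over *total* network length, so Ω=1 means every
    reach is occupied and Ω=0 means network-wide extinction."""
    w = traj.w if isinstance(traj, OccupancyTrajectory) else np.asarray(traj)
    return (w @ net.reach_length) / net.total_length


def survival_probability(final_omegas: np.ndarray) -> float:
    """Fraction of replicates still extant (Ω > 0) at the end of the run."""
    final_omegas = np.asarray(final_omegas, dtype=float)
    if final_omegas.size < 1:
        raise ParameterError("need at least one replicate")
    return float(np.mean(final_omegas > 0))


def temporal_cv(omega: np.ndarray, skip_first: int = 1) -> tuple[float, int]:
    """Mean over replicates of the temporal CV of Ω(t).

    ``omega`` is (replicates, days); the first ``skip_first`` days (the
    imposed initial condition) are dropped. Replicates that go extinct
    during the run are excluded — their CV is dominated by the decay to
    zero rather than by occupancy fluctuations — and the inclusion count is
    returned alongside. Returns (nan, 0) when no replicate survives.
    """
    om = np.atleast_2d(np.asarray(omega, dtype=float))[:, skip_first:]
    include = om[:, -1] > 0
    means = om.mean(axis=1)
    if not include.any():
        return float("nan"), 0
    cv = om[include].std(axis=1, ddof=0) / means[include]
    return float(cv.mean()), int(include.sum())


def local_occupancy(trajs) -> np.ndarray:
    """Fraction of time each node is occupied, ensemble-averaged over replicates."""
    ws = [t.w if isinstance(t, OccupancyTrajectory) else np.asarray(t) for t in trajs]
    return np.mean([w.mean(axis=0) for w in ws], axis=0)


@dataclasses.dataclass
class ScenarioResult:
    """Monte-Carlo ensemble of one scenario with its summary statistics."""

    config: ScenarioConfig
    net: StreamNetwork
    field: PersistencyField
    traits: SpeciesTraits
    omega_dynamic: np.ndarray  # (n_mc, T+1)
    omega_static: Optional[np.ndarray]
    lcp: np.ndarray  # (n_mc, T+1) per-day LCP length, m
    active_length: np.ndarray  # (n_mc, T+1) L(t), m
    local_occ_dynamic: np.ndarray
    local_occ_static: Optional[np.ndarray]
    static_target_length: Optional[float]

    @property
    def survival_dynamic(self) -> float:
        return survival_probability(self.omega_dynamic[:, -1])

    @property
    def survival_static(self) -> Optional[float]:
        if self.omega_static is None:
            return None
        return survival_probability(self.omega_static[:, -1])

    @property
    def cv_dynamic(self) -> tuple[float, int]:
        return temporal_cv(self.omega_dynamic)

    @property
    def cv_static(self) -> Optional[tuple[float, int]]:
        if self.omega_static is None:
            return None
        return temporal_cv(self.omega_static)

    def lcp_duration_curve(self):
        """Duration curve of the LCP length pooled over all replicates."""
        return duration_curve(self.lcp.ravel())

    def summary(self) -> dict:
        cvd, nd = self.cv_dynamic
        out = {
            "climate": self.config.resolve_climate().label,
            "scenario": self.config.scenario,
            "n_mc": self.config.n_mc,
            "T": self.config.T,
            "survival_dynamic": self.survival_dynamic,
            "mean_omega_dynamic": float(self.omega_dynamic[:, 1:].mean()),
            "cv_dynamic": cvd,
            "cv_dynamic_n": nd,
            "mean_active_length_m": float(self.active_length.mean()),
            "mean_lcp_m": float(self.lcp.mean()),
            "mean_persistency": float(
                persistency_under(self.field, self.config.resolve_climate()).mean()
            ),
            "config_hash": self.config.config_hash(),
            "base_seed": self.config.base_seed,
            "version": __version__,
        }
        if self.omega_static is not None:
            cvs, ns = self.cv_static
            out.update(
                survival_static=self.survival_static,
                mean_omega_static=float(self.omega_static[:, 1:].mean()),
                cv_static=cvs,
                cv_static_n=ns,
                static_target_length_m=self.static_target_length,
            )
        return out

    def save(self, outdir) -> None:
        """Write omega_timeseries.csv, local_occupancy.csv and summary.json."""
        import os

        os.makedirs(outdir, exist_ok=True)
        n_mc, days = self.omega_dynamic.shape
        rep = np.repeat(np.arange(n_mc), days)
        day = np.tile(np.arange(days), n_mc)
        frame = {
            "replicate": rep,
            "day": day,
            "omega_dynamic": self.omega_dynamic.ravel(),
        }
        if self.omega_static is not None:
            frame["omega_static"] = self.omega_static.ravel()
        pd.DataFrame(frame).to_csv(os.path.join(outdir, "omega_timeseries.csv"), index=False)
        occ = {"node_id": np.arange(self.net.n_nodes), "occupancy_dynamic": self.local_occ_dynamic}
        if self.local_occ_static is not None:
            occ["occupancy_static"] = self.local_occ_static
        pd.DataFrame(occ).to_csv(os.path.join(outdir, "local_occupancy.csv"), index=False)
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _simulate_activations(cfg: ScenarioConfig, climate, field) -> list[ActivationSeries]:
    """One discharge + activation realization per replicate (first pass)."""
    days = cfg.T + 1  # day 0 carries the initial condition
    acts = []
    for r in range(cfg.n_mc):
        rain = effective_rainfall(climate, days, seed=_seed(cfg, _RAIN, r))
        q = simulate_discharge(rain, q0="stationary", seed=_seed(cfg, _Q0, r))
        acts.append(activate(q, field))
    return acts


def run_scenario(cfg: ScenarioConfig, cache: DispersalCache | None = None) -> ScenarioResult:
    """Run the full Monte-Carlo ensemble for one scenario.

    Two passes: the activation ensemble is simulated first to fix the
    static-equivalent length (ensemble mean of the time-mean active length);
    then each replicate's dynamic SPOM and its static twin are run.
    """
    climate = cfg.resolve_climate()
    net, ranking, field, traits = build_network(cfg)
    if cache is None:
        cache = DispersalCache(net, field.order_desc)
    act_list = _simulate_activations(cfg, climate, field)
    mean_L = float(np.mean([a.L.mean() for a in act_list]))
    days = cfg.T + 1

    static_acts = None
    if cfg.static:
        target = min(max(mean_L, net.reach_length.min()), net.total_length)
        static_acts = static_equivalent(net, field, target, T=days)

    omega_d = np.empty((cfg.n_mc, days))
    omega_s = np.empty((cfg.n_mc, days)) if cfg.static else None
    lcp = np.empty((cfg.n_mc, days))
    L = np.empty((cfg.n_mc, days))
    trajs_d, trajs_s = [], []
    for r, a in enumerate(act_list):
        traj = simulate_spom(net, a, traits, seed=_seed(cfg, _SPOM_DYN, r), cache=cache)
        trajs_d.append(traj)
        omega_d[r] = occupancy_fraction(traj, net)
        lcp[r] = lcp_series(net, a)
        L[r] = a.L
        if cfg.static:
            traj_s = simulate_spom(net, static_acts, traits, seed=_seed(cfg, _SPOM_STA, r), cache=cache)
            trajs_s.append(traj_s)
            omega_s[r] = occupancy_fraction(traj_s, net)

    return ScenarioResult(
        config=cfg,
        net=net,
        field=field,
        traits=traits,
        omega_dynamic=omega_d,
        omega_static=omega_s,
        lcp=lcp,
        active_length=L,
        local_occ_dynamic=local_occupancy(trajs_d),
        local_occ_static=local_occupancy(trajs_s) if cfg.static else None,
        static_target_length=float(static_acts.L[0]) if cfg.static else None,
    )


def sensitivity_analysis(
    cfg: ScenarioConfig,
    c_grid=None,
    e_grid=None,
    n_mc: int | None = None,
    cache: DispersalCache | None = None,
) -> pd.DataFrame:
    """Survival probability over a (c, e) trait grid, dynamic and static.

    δ stays fixed at the configured multiple of NND. Each grid cell gets its
    own ``n_mc`` fresh discharge realizations; the static-equivalent network
    is fixed once per climate from a trait-independent activation ensemble.
    Returns a tidy frame with columns c, e, survival_dynamic, survival_static.
    """
    if c_grid is None:
        c_grid = np.logspace(-5, 2, 8)
    if e_grid is None:
        e_grid = np.logspace(-3, 3, 7)
    c_grid = np.asarray(c_grid, dtype=float)
    e_grid = np.asarray(e_grid, dtype=float)
    if c_grid.size == 0 or e_grid.size == 0:
        raise ParameterError("trait grids must be non-empty")
    n_mc = cfg.n_mc if n_mc is None else int(n_mc)
    climate = cfg.resolve_climate()
    net, ranking, field, _ = build_network(cfg)
    if cache is None:
        cache = DispersalCache(net, field.order_desc)
    days = cfg.T + 1

    # static-equivalent length from a trait-independent activation ensemble
    base = dataclasses.replace(cfg, n_mc=n_mc)
    base_acts = _simulate_activations(base, climate, field)
    mean_L = float(np.mean([a.L.mean() for a in base_acts]))
    target = min(max(mean_L, net.reach_length.min()), net.total_length)
    static_acts = static_equivalent(net, field, target, T=days)

    rows = []
    import warnings as _warnings

    for ci, c in enumerate(c_grid):
        for ei, e in enumerate(e_grid):
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # corner traits touch the soft bounds
                traits = SpeciesTraits(c=float(c), e=float(e), delta=cfg.delta_nnd * net.nnd)
            surv_d = np.empty(n_mc, dtype=bool)
            surv_s = np.empty(n_mc, dtype=bool)
            for r in range(n_mc):
                rain = effective_rainfall(climate, days, seed=_seed(cfg, _CELL, ci, ei, 0, r))
                q = simulate_discharge(rain, q0="stationary", seed=_seed(cfg, _CELL, ci, ei, 1, r))
                a = activate(q, field)
                traj = simulate_spom(
                    net, a, traits, seed=_seed(cfg, _CELL, ci, ei, 2, r), cache=cache
                )
                surv_d[r] = traj.w[-1].any()
                traj_s = simulate_spom(
                    net, static_acts, traits, seed=_seed(cfg, _CELL, ci, ei, 3, r), cache=cache
                )
                surv_s[r] = traj_s.w[-1].any()
            rows.append(
                dict(
                    c=float(c),
                    e=float(e),
                    survival_dynamic=float(surv_d.mean()),
                    survival_static=float(surv_s.mean()),
                    n_mc=n_mc,
                )
            )
    return pd.DataFrame(rows)


def species_pool(n: int, net: StreamNetwork, seed=0) -> list[SpeciesTraits]:
    """Random virtual-species pool: δ ~ U[1,10]·NND, c and e log-uniform over
    [1e-5, 1e2] and [1e-3, 1e3]."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    nnd = net.nnd
    deltas = rng.uniform(1.0, 10.0, n) * nnd
    cs = 10.0 ** rng.uniform(-5.0, 2.0, n)
    es = 10.0 ** rng.uniform(-3.0, 3.0, n)
    return [SpeciesTraits(c=float(c), e=float(e), delta=float(d)) for c, e, d in zip(cs, es, deltas)]
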