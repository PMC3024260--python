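"""Two-stage parameter estimation.

Stage 1 searches the *discrete* space of blocks (one interval index per
unknown parameter) with a stochastic-ranking evolution strategy (SRES),
scoring each block by clamping it as t=0 parameter evidence on the DBN,
running factored-frontier inference, and computing the weighted sum of squared
errors between the (max-normalised) data and expected value series.  Small
block spaces are enumerated exhaustively instead.

Stage 2 searches continuously *inside* the winning block, scoring candidate
parameter vectors by direct ODE simulation — a search space 1/I^m the volume
of the original box for m unknowns with I intervals each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dbn_build import DBN
from .ff_infer import ContradictoryEvidence, Evidence, expected_series, ff_forward
from .model_core import Condition, ModelError, ReactionNetwork, apply_condition
from .ode_sim import IntegrationError, TimeGrid, simulate


@dataclass
class Dataset:
    """Calibration observations: (condition, species, time_s) -> value.

    ``conditions`` optionally maps condition names to :class:`Condition`
    objects (needed for ODE-based objectives on multi-condition data);
    ``weights`` are per-species nonnegative weights applied after the
    max-normalisation of each (condition, species) series.
    """

    observations: dict
    weights: dict = field(default_factory=dict)
    conditions: dict = field(default_factory=dict)
    #: max-normalise each (condition, species) series and its model
    #: counterpart before residuals (the densitometry arbitrary-unit bridge);
    #: disable when data and model share units
    normalize: bool = True

    def condition_names(self):
        return sorted({c for c, _, _ in self.observations})

    def species_names(self):
        return sorted({s for _, s, _ in self.observations})

    def series(self, condition, species):
        pts = sorted((t, v) for (c, s, t), v in self.observations.items()
                     if c == condition and s == species)
        times = np.array([t for t, _ in pts])
        vals = np.array([v for _, v in pts])
        return times, vals


def _normalise(v: np.ndarray) -> np.ndarray:
    m = np.max(np.abs(v))
    return v / m if m > 0 else v


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def objective_block(block, dbns, dataset: Dataset) -> float:
    """Weighted SSE of FF expected-value series against the data under a
    block of parameter intervals.

    *block*: {parameter: interval index}; *dbns*: one DBN (applied to every
    condition in the data) or {condition: DBN}.
    """
    total = 0.0
    for cond in dataset.condition_names():
        dbn = dbns[cond] if isinstance(dbns, dict) else dbns
        ev = Evidence.parameter_block(
            {p: iv for p, iv in block.items()
             if p in dbn.structure.parameter_nodes})
        marg = ff_forward(dbn, ev)
        for sp in dataset.species_names():
            t_obs, d_obs = dataset.series(cond, sp)
            if len(t_obs) == 0:
                continue
            if sp not in marg.marginals:
                raise ModelError(f"dataset species {sp!r} is not a DBN node")
            exp_series = expected_series(marg, dbn.discretization, sp,
                                         dbn.representatives)
            idx = [dbn.grid.index_of(t) for t in t_obs]
            y = exp_series[idx]
            w = dataset.weights.get(sp, 1.0)
            if dataset.normalize:
                d_obs, y = _normalise(d_obs), _normalise(y)
            total += w * float(np.sum((d_obs - y) ** 2))
    return total


def objective_continuous(theta, network: ReactionNetwork, dataset: Dataset,
                         grid: TimeGrid, unknown_names=None,
                         affinity_model=None,
                         penalty: float = 1e12) -> float:
    """Weighted SSE of simulated series against the data for a parameter
    vector *theta* over the unknown parameters (registry order by default).
    Integration failures score the configured penalty."""
    unknown_names = unknown_names or network.params.unknown_names
    theta = np.asarray(theta, dtype=float)
    total = 0.0
    for cond_name in dataset.condition_names():
        net = network.copy()
        for n, v in zip(unknown_names, theta):
            net.set_param(n, v)
        cond = dataset.conditions.get(cond_name)
        if cond is not None:
            net = apply_condition(net, cond, affinity_model)
        try:
            tr = simulate(net, grid, rtol=1e-7, atol=1e-10)
        except IntegrationError:
            return penalty
        for sp in dataset.species_names():
            t_obs, d_obs = dataset.series(cond_name, sp)
            if len(t_obs) == 0:
                continue
            target = net.observables.get(sp, sp)
            y = tr.series(target)[[grid.index_of(t) for t in t_obs]]
            w = dataset.weights.get(sp, 1.0)
            if dataset.normalize:
                d_obs, y = _normalise(d_obs), _normalise(y)
            total += w * float(np.sum((d_obs - y) ** 2))
    return total


# ---------------------------------------------------------------------------
# stochastic ranking evolution strategy
# ---------------------------------------------------------------------------

@dataclass
class SRESConfig:
    population: int = 200     # lambda
    parents: int = 30         # mu
    generations: int = 500
    rank_prob: float = 0.45   # P_f: probability of objective-based comparison
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.parents < self.population):
            raise ModelError("require 0 < mu < lambda")
        if not (0.0 < self.rank_prob < 1.0):
            raise ModelError("require 0 < P_f < 1")


@dataclass
class SRESResult:
    best_x: np.ndarray
    best_f: float
    history: list  # best-ever objective per generation


def _stochastic_rank(f, penalties, rank_prob, rng):
    """Stochastic-ranking bubble sort of Runarsson & Yao.  With no constraint
    violations it degenerates to an objective sort, but the randomized sweep
    is implemented in full."""
    n = len(f)
    idx = list(range(n))
    for _ in range(n):
        swapped = False
        for j in range(n - 1):
            a, b = idx[j], idx[j + 1]
            u = rng.random()
            if (penalties[a] == penalties[b] == 0.0) or (u < rank_prob):
                if f[a] > f[b]:
                    idx[j], idx[j + 1] = b, a
                    swapped = True
            else:
                if penalties[a] > penalties[b]:
                    idx[j], idx[j + 1] = b, a
                    swapped = True
        if not swapped:
            break
    return idx


def sres_minimize(lower, upper, objective, config: SRESConfig,
                  discrete: bool = False, penalty_fn=None,
                  x0=None) -> SRESResult:
    """(mu, lambda) evolution strategy with log-normal self-adaptive step
    sizes and stochastic-ranking selection.

    *lower*/*upper*: box bounds (inclusive).  In discrete mode the bounds are
    integer index grids and mutated coordinates are rounded to the nearest
    valid index.  *x0* optionally seeds one individual of the initial
    population (warm start).
    """
    rng = np.random.default_rng(config.seed)
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    n = len(lo)
    lam, mu = config.population, config.parents
    tau = 1.0 / math.sqrt(2.0 * math.sqrt(n))
    tau_p = 1.0 / math.sqrt(2.0 * n)

    def _repair(x):
        x = np.clip(x, lo, hi)
        return np.rint(x) if discrete else x

    X = rng.uniform(lo, hi, size=(lam, n))
    if x0 is not None:
        X[0] = np.asarray(x0, dtype=float)
    X = np.array([_repair(x) for x in X])
    S = np.tile((hi - lo) / math.sqrt(n) / 2.0, (lam, 1))
    f = np.array([objective(x) for x in X])
    if not np.any(np.isfinite(f)):
        raise ModelError("objective non-finite for every initial individual")
    pen = np.array([penalty_fn(x) if penalty_fn else 0.0 for x in X])

    best_i = int(np.nanargmin(np.where(pen == 0, f, np.inf)))
    best_x, best_f = X[best_i].copy(), float(f[best_i])
    history = [best_f]

    for _ in range(config.generations):
        order = _stochastic_rank(f, pen, config.rank_prob, rng)
        parents_X = X[order[:mu]]
        parents_S = S[order[:mu]]
        pick = rng.integers(0, mu, size=lam)
        g = rng.normal(size=lam)
        Xn = np.empty_like(X)
        Sn = np.empty_like(S)
        for i in range(lam):
            s = parents_S[pick[i]] * np.exp(tau_p * g[i]
                                            + tau * rng.normal(size=n))
            s = np.minimum(s, hi - lo)
            x = parents_X[pick[i]] + s * rng.normal(size=n)
            Xn[i] = _repair(x)
            Sn[i] = s
        X, S = Xn, Sn
        f = np.array([objective(x) for x in X])
        pen = np.array([penalty_fn(x) if penalty_fn else 0.0 for x in X])
        feas = np.where(pen == 0, f, np.inf)
        i = int(np.argmin(feas))
        if feas[i] < best_f:
            best_x, best_f = X[i].copy(), float(feas[i])
        history.append(best_f)
    return SRESResult(best_x, best_f, history)


# ---------------------------------------------------------------------------
# two-stage estimation
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    best_block: dict          # parameter -> interval index
    best_theta: dict          # parameter -> value
    stage1_objective: float
    stage2_objective: float
    stage1_history: list
    stage2_history: list
    search_space_reduction: float  # stage-2 volume / original volume

    def to_dict(self):
        return {"best_block": self.best_block, "best_theta": self.best_theta,
                "stage1_objective": self.stage1_objective,
                "stage2_objective": self.stage2_objective,
                "stage1_history": self.stage1_history,
                "stage2_history": self.stage2_history,
                "search_space_reduction": self.search_space_reduction}


def search_space_reduction(n_unknowns: int, n_intervals: int = 5) -> float:
    """Stage-2 box volume as a fraction of the original search volume."""
    return float(n_intervals) ** (-n_unknowns)


def estimate_two_stage(network: ReactionNetwork, dbns, dataset: Dataset,
                       grid: TimeGrid,
                       stage1_config: SRESConfig | None = None,
                       stage2_config: SRESConfig | None = None,
                       exhaustive_limit: int = 10_000,
                       affinity_model=None) -> FitResult:
    """Stage 1: SRES (or exhaustive enumeration for small spaces) over blocks
    scored by :func:`objective_block`; stage 2: continuous SRES inside the
    winning block scored by :func:`objective_continuous`."""
    unknowns = network.params.unknown_names
    dbn0 = next(iter(dbns.values())) if isinstance(dbns, dict) else dbns
    est_params = [p for p in unknowns if p in dbn0.structure.parameter_nodes]
    n_iv = {p: dbn0.n_intervals(p) for p in est_params}
    n_blocks = float(np.prod([n_iv[p] for p in est_params]))

    def block_of(vec):
        return {p: int(vec[i]) for i, p in enumerate(est_params)}

    def f1(vec):
        return objective_block(block_of(vec), dbns, dataset)

    history1 = []
    if n_blocks <= exhaustive_limit:
        import itertools
        best_f, best_vec = np.inf, None
        for combo in itertools.product(*[range(n_iv[p]) for p in est_params]):
            try:
                f = f1(np.asarray(combo))
            except ContradictoryEvidence:
                continue
            history1.append(min(f, history1[-1]) if history1 else f)
            if f < best_f:
                best_f, best_vec = f, np.asarray(combo, dtype=float)
        if best_vec is None:
            raise ModelError("every block contradicted the DBN support")
        res1 = SRESResult(best_vec, best_f, history1)
    else:
        cfg = stage1_config or SRESConfig()
        res1 = sres_minimize(np.zeros(len(est_params)),
                             np.array([n_iv[p] - 1 for p in est_params],
                                      dtype=float),
                             f1, cfg, discrete=True)
    best_block = block_of(res1.best_x)

    # stage 2: continuous search inside the winning block
    lo = np.empty(len(est_params))
    hi = np.empty(len(est_params))
    for i, p in enumerate(est_params):
        b = dbn0.discretization.boundaries[p]
        iv = best_block[p]
        lo[i], hi[i] = b[iv], b[iv + 1]

    def f2(theta):
        return objective_continuous(theta, network, dataset, grid,
                                    unknown_names=est_params,
                                    affinity_model=affinity_model)

    cfg2 = stage2_config or SRESConfig(population=60, parents=10,
                                       generations=80)
    res2 = sres_minimize(lo, hi, f2, cfg2, x0=0.5 * (lo + hi))
    return FitResult(
        best_block=best_block,
        best_theta={p: float(v) for p, v in zip(est_params, res2.best_x)},
        stage1_objective=float(res1.best_f),
        stage2_objective=float(res2.best_f),
        stage1_history=list(res1.history),
        stage2_history=list(res2.history),
        search_space_reduction=search_space_reduction(
            len(est_params), n_iv[est_params[0]] if est_params else 5),
    )
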