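"""Dynamic-Bayesian-network approximation of ODE dynamics.

The network ODEs are approximated by a time-variant two-slice DBN: every
variable (species) and parameter becomes a node per time slice; variable value
ranges are discretized into 6 non-equal (equal-frequency) intervals and
parameter ranges into 5 equal intervals; an ensemble of trajectories is
integrated from sampled initial states and parameters, and the conditional
probability tables are filled by simple counting of interval transitions.

A variable node's parents at slice t are itself plus every species and
parameter appearing on the right-hand side of its equation; a parameter node's
only parent is itself (its value never changes, so its CPT is the identity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model_core import ModelError, ReactionNetwork
from .ode_sim import IntegrationError, TimeGrid, simulate, simulate_ensemble

DEFAULT_SAMPLE_CAP = 10_000_000


def required_samples(intervals_per_param: int, max_unknowns_per_equation: int,
                     coverage: int = 5, cap: int = DEFAULT_SAMPLE_CAP) -> int:
    """Per-equation coverage heuristic J = K * I**u.

    Guarantees at least *coverage* samples for each combination of parameter
    intervals appearing in any single equation.
    """
    if intervals_per_param < 2 or max_unknowns_per_equation < 0 or coverage < 1:
        raise ModelError("require I >= 2, u >= 0, K >= 1")
    J = coverage * intervals_per_param ** max_unknowns_per_equation
    if J > cap:
        raise ModelError(
            f"required sample count {J} exceeds the cap {cap}; "
            "raise the cap explicitly to override")
    return J


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass
class Discretization:
    """Per-node ordered interval boundaries.

    ``boundaries[node]`` has length ``n_intervals + 1``; a degenerate node
    (constant value) has a single zero-width interval and appears in
    ``degenerate``.
    """

    boundaries: dict[str, np.ndarray]
    degenerate: set[str] = field(default_factory=set)

    def n_intervals(self, node: str) -> int:
        return max(len(self.boundaries[node]) - 1, 1)

    def index(self, node: str, value) -> np.ndarray | int:
        """Interval index of *value*, clamping out-of-range values into the
        nearest boundary interval."""
        b = self.boundaries[node]
        if node in self.degenerate:
            return np.zeros_like(np.asarray(value), dtype=np.int64) \
                if np.ndim(value) else 0
        idx = np.searchsorted(b, value, side="right") - 1
        return np.clip(idx, 0, len(b) - 2)

    def midpoints(self, node: str) -> np.ndarray:
        b = self.boundaries[node]
        if node in self.degenerate:
            return np.array([b[0]])
        return 0.5 * (b[:-1] + b[1:])


def _variable_boundaries(values: np.ndarray, n: int):
    """Equal-frequency boundaries of pooled values; duplicates collapsed."""
    vals = np.asarray(values, dtype=float).ravel()
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return np.array([lo, lo]), True
    qs = np.quantile(vals, np.linspace(0.0, 1.0, n + 1))
    qs[0], qs[-1] = lo, hi
    # collapse (near-)duplicate quantiles; the interval count drops when the
    # pooled values cannot support n distinct intervals
    tol = 1e-6 * (hi - lo)
    b = [qs[0]]
    for q in qs[1:]:
        if q - b[-1] > tol:
            b.append(q)
    b = np.asarray(b)
    if len(b) < 3:
        b = np.array([lo, hi])
    b[-1] = hi
    return b, False


def make_discretization(variable_values: dict[str, np.ndarray] | None = None,
                        param_bounds: dict[str, tuple] | None = None,
                        param_values: dict[str, float] | None = None,
                        n_var: int = 6, n_param: int = 5) -> Discretization:
    """Variable intervals at equal-frequency boundaries of pooled trajectory
    values (count reduced when the data cannot support 6 distinct intervals);
    parameter intervals equal-width over declared bounds.  Parameters given a
    point value (known constants) become degenerate single-interval nodes."""
    boundaries: dict[str, np.ndarray] = {}
    degenerate: set[str] = set()
    for node, vals in (variable_values or {}).items():
        b, degen = _variable_boundaries(vals, n_var)
        boundaries[node] = b
        if degen:
            degenerate.add(node)
    for node, (lo, hi) in (param_bounds or {}).items():
        boundaries[node] = np.linspace(float(lo), float(hi), n_param + 1)
    for node, v in (param_values or {}).items():
        boundaries[node] = np.array([float(v), float(v)])
        degenerate.add(node)
    return Discretization(boundaries, degenerate)


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

@dataclass
class DBNStructure:
    parents: dict[str, tuple[str, ...]]  # node at t+1 -> parents at t
    variable_nodes: tuple[str, ...]
    parameter_nodes: tuple[str, ...]


def derive_structure(network: ReactionNetwork) -> DBNStructure:
    """Parents = self + right-hand-side dependencies; parameters are their own
    single parent."""
    deps = network.rhs_dependencies()
    param_nodes = tuple(network.params.names)
    parents = {}
    for sp in network.species_names:
        # deterministic order: self first, then sorted
        others = sorted(deps[sp] - {sp})
        parents[sp] = (sp, *others)
    for p in param_nodes:
        parents[p] = (p,)
    return DBNStructure(parents, tuple(network.species_names), param_nodes)


# ---------------------------------------------------------------------------
# trajectory sampling
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryEnsemble:
    grid: TimeGrid
    species_names: list[str]
    param_names: list[str]          # parameter *nodes* (appear in equations)
    values: np.ndarray              # (J, n_species, T)
    thetas: np.ndarray              # (J, n_param_nodes)
    redraws: int = 0

    @property
    def J(self) -> int:
        return self.values.shape[0]


def _draw_within_intervals(rng, boundaries, probs, size):
    """Sample values: pick an interval by *probs*, then uniform within it."""
    b = np.asarray(boundaries)
    if len(b) < 2 or b[0] == b[-1]:
        return np.full(size, b[0])
    k = rng.choice(len(b) - 1, size=size, p=probs)
    return rng.uniform(b[k], b[k + 1])


def sample_trajectories(network: ReactionNetwork, prior: dict,
                        discretization: Discretization, J: int,
                        grid: TimeGrid, seed: int,
                        method: str = "LSODA", batch: bool = False,
                        max_redraws: int = 100) -> TrajectoryEnsemble:
    """Draw J initial states/parameters from *prior* (probability vectors over
    discretization intervals; value uniform within the selected interval) and
    integrate a trajectory for each.  Integration failures are redrawn and
    counted."""
    rng = np.random.default_rng(seed)
    species = network.species_names
    structure_params = [p for p in network.params if p in prior or
                        p in discretization.boundaries]
    param_names = [p for p in structure_params]
    full_names = network.params.names
    theta_full = np.empty(len(full_names))
    for i, n in enumerate(full_names):
        v = network.params[n].value
        theta_full[i] = np.nan if v is None else v

    x0_base = network.initial_state()
    X0 = np.tile(x0_base[:, None], (1, J))
    TH = np.tile(theta_full[:, None], (1, J))
    thetas_nodes = np.empty((J, len(param_names)))
    fidx = {n: i for i, n in enumerate(full_names)}
    sidx = {n: i for i, n in enumerate(species)}
    for node, pv in prior.items():
        b = discretization.boundaries[node]
        draws = _draw_within_intervals(rng, b, np.asarray(pv, float), J)
        if node in sidx:
            X0[sidx[node]] = draws
        elif node in fidx:
            TH[fidx[node]] = draws
        else:
            raise ModelError(f"prior names unknown node {node!r}")
    if np.isnan(TH).any():
        bad = [full_names[i] for i in np.unique(np.where(np.isnan(TH))[0])]
        raise ModelError(f"unresolved parameters without prior: {bad}")
    for j, p in enumerate(param_names):
        thetas_nodes[:, j] = TH[fidx[p]]

    T = len(grid)
    values = np.empty((J, len(species), T))
    redraws = 0
    if batch:
        values = simulate_ensemble(network, grid, X0, TH, method=method)
    else:
        for j in range(J):
            attempts = 0
            while True:
                try:
                    tr = simulate(network, grid, param_values=TH[:, j],
                                  initial_overrides={
                                      sp: X0[sidx[sp], j] for sp in prior
                                      if sp in sidx},
                                  rtol=1e-6, atol=1e-9, method=method)
                    values[j] = tr.values
                    break
                except IntegrationError:
                    attempts += 1
                    redraws += 1
                    if attempts > max_redraws:
                        raise
                    for node, pv in prior.items():  # redraw this sample
                        b = discretization.boundaries[node]
                        d = _draw_within_intervals(rng, b, np.asarray(pv, float), 1)[0]
                        if node in sidx:
                            X0[sidx[node], j] = d
                        else:
                            TH[fidx[node], j] = d
                    for jj, p in enumerate(param_names):
                        thetas_nodes[j, jj] = TH[fidx[p]]
    return TrajectoryEnsemble(grid, list(species), param_names, values,
                              thetas_nodes, redraws)


def code_ensemble(ensemble: TrajectoryEnsemble, disc: Discretization):
    """Interval coding: (J, n_species, T) int8 codes + (J, n_params) codes."""
    J, S, T = ensemble.values.shape
    var_codes = np.empty((J, S, T), dtype=np.int8)
    for i, sp in enumerate(ensemble.species_names):
        var_codes[:, i, :] = disc.index(sp, ensemble.values[:, i, :])
    par_codes = np.empty((J, len(ensemble.param_names)), dtype=np.int8)
    for j, p in enumerate(ensemble.param_names):
        par_codes[:, j] = disc.index(p, ensemble.thetas[:, j])
    return var_codes, par_codes


# ---------------------------------------------------------------------------
# CPT counting
# ---------------------------------------------------------------------------

@dataclass
class CPT:
    """Sparse per-slice conditional probability table of one node.

    ``rows[t]`` is (parent_codes (R, P) int8, probs (R, C), support (R,)):
    only parent assignments observed in the ensemble are stored; unseen
    assignments are handled by the inference-time uniform fallback.
    """

    parents: tuple[str, ...]
    n_intervals: int
    rows: list[tuple[np.ndarray, np.ndarray, np.ndarray]]

    def lookup(self, t: int, assignment: tuple[int, ...]):
        codes, probs, supp = self.rows[t]
        match = np.all(codes == np.asarray(assignment, dtype=np.int8), axis=1)
        idx = np.where(match)[0]
        return (probs[idx[0]], int(supp[idx[0]])) if len(idx) else (None, 0)


@dataclass
class DBN:
    structure: DBNStructure
    discretization: Discretization
    prior: dict[str, np.ndarray]
    cpts: dict[str, CPT]
    grid: TimeGrid
    sample_count: int
    node_order: tuple[str, ...] = ()
    #: optional empirical interval representatives: node -> (T, n_intervals)
    #: per-slice conditional means of the counted ensemble (falls back to
    #: interval midpoints where absent/unsupported)
    representatives: dict | None = None
    #: the counted trajectory ensemble (kept in memory only; not serialized)
    ensemble: "TrajectoryEnsemble | None" = None

    def __post_init__(self):
        if not self.node_order:
            self.node_order = (self.structure.variable_nodes
                               + self.structure.parameter_nodes)

    def n_intervals(self, node):
        return self.discretization.n_intervals(node)


def _group_rows(mat: np.ndarray, child: np.ndarray, n_child: int):
    """Aggregate (parent assignment -> child interval distribution) counts."""
    full = np.column_stack([mat, child]).astype(np.int8)
    keyed = np.ascontiguousarray(full).view(
        np.dtype((np.void, full.dtype.itemsize * full.shape[1]))).ravel()
    uniq, counts = np.unique(keyed, return_counts=True)
    rows_full = uniq.view(np.int8).reshape(-1, full.shape[1])
    pcodes = rows_full[:, :-1]
    ccode = rows_full[:, -1]
    # group by parent part
    pkey = np.ascontiguousarray(pcodes).view(
        np.dtype((np.void, pcodes.dtype.itemsize * pcodes.shape[1]))).ravel()
    puniq, pinv = np.unique(pkey, return_inverse=True)
    R = len(puniq)
    probs = np.zeros((R, n_child))
    supp = np.zeros(R)
    np.add.at(probs, (pinv, ccode.astype(int)), counts)
    np.add.at(supp, pinv, counts)
    probs /= supp[:, None]
    parent_codes = puniq.view(np.int8).reshape(-1, pcodes.shape[1])
    return parent_codes, probs, supp


def count_cpts(ensemble: TrajectoryEnsemble, structure: DBNStructure,
               disc: Discretization, prior: dict | None = None,
               count_parameter_cpts: bool = False) -> DBN:
    """Fill conditional probability tables by counting interval transitions.

    Parameter-node CPTs are exact identities (their value never changes);
    counting them instead is available behind ``count_parameter_cpts`` for
    cross-validation.
    """
    var_codes, par_codes = code_ensemble(ensemble, disc)
    J, S, T = var_codes.shape
    sidx = {sp: i for i, sp in enumerate(ensemble.species_names)}
    pidx = {p: i for i, p in enumerate(ensemble.param_names)}

    cpts: dict[str, CPT] = {}
    for sp in structure.variable_nodes:
        parents = structure.parents[sp]
        cols = []
        for pa in parents:
            if pa in sidx:
                cols.append(("v", sidx[pa]))
            else:
                cols.append(("p", pidx[pa]))
        n_child = disc.n_intervals(sp)
        rows = []
        for t in range(T - 1):
            mat = np.column_stack([
                var_codes[:, c, t] if kind == "v" else par_codes[:, c]
                for kind, c in cols])
            rows.append(_group_rows(mat, var_codes[:, sidx[sp], t + 1], n_child))
        cpts[sp] = CPT(parents, n_child, rows)
    for p in structure.parameter_nodes:
        n = disc.n_intervals(p)
        if count_parameter_cpts:
            rows = []
            for t in range(T - 1):
                rows.append(_group_rows(par_codes[:, [pidx[p]]],
                                        par_codes[:, pidx[p]], n))
            cpts[p] = CPT((p,), n, rows)
        else:
            eye_rows = (np.arange(n, dtype=np.int8)[:, None], np.eye(n),
                        np.full(n, np.inf))
            cpts[p] = CPT((p,), n, [eye_rows] * (T - 1))

    if prior is None:
        prior = {}
        for sp in structure.variable_nodes:
            n = disc.n_intervals(sp)
            prior[sp] = np.bincount(var_codes[:, sidx[sp], 0],
                                    minlength=n).astype(float) / J
        for p in structure.parameter_nodes:
            n = disc.n_intervals(p)
            prior[p] = np.bincount(par_codes[:, pidx[p]],
                                   minlength=n).astype(float) / J

    # empirical per-slice interval representatives (conditional means)
    reps: dict[str, np.ndarray] = {}
    for sp in structure.variable_nodes:
        n = disc.n_intervals(sp)
        mids = disc.midpoints(sp)
        rep = np.tile(mids, (T, 1))
        vals = ensemble.values[:, sidx[sp], :]
        codes = var_codes[:, sidx[sp], :]
        for t in range(T):
            sums = np.zeros(n)
            cnts = np.zeros(n)
            np.add.at(sums, codes[:, t], vals[:, t])
            np.add.at(cnts, codes[:, t], 1.0)
            nz = cnts > 0
            rep[t, nz] = sums[nz] / cnts[nz]
        reps[sp] = rep
    for p in structure.parameter_nodes:
        n = disc.n_intervals(p)
        mids = disc.midpoints(p)
        sums = np.zeros(n)
        cnts = np.zeros(n)
        np.add.at(sums, par_codes[:, pidx[p]], ensemble.thetas[:, pidx[p]])
        np.add.at(cnts, par_codes[:, pidx[p]], 1.0)
        rep = np.tile(mids, (T, 1))
        nz = cnts > 0
        rep[:, nz] = (sums[nz] / cnts[nz])[None, :]
        reps[p] = rep
    return DBN(structure, disc, prior, cpts, ensemble.grid, J,
               representatives=reps, ensemble=ensemble)


# ---------------------------------------------------------------------------
# one-call builder
# ---------------------------------------------------------------------------

def uniform_parameter_prior(network: ReactionNetwork, n_param: int = 5) -> dict:
    """Uniform prior over the 5 equal intervals of every unknown parameter;
    known parameters are degenerate point nodes."""
    prior = {}
    for name, e in network.params.items():
        if e.known:
            prior[name] = np.array([1.0])
        else:
            prior[name] = np.full(n_param, 1.0 / n_param)
    return prior


def build_dbn(network: ReactionNetwork, J: int, grid: TimeGrid, seed: int,
              n_var: int = 6, n_param: int = 5, init_spread: float = 0.0,
              method: str = "LSODA", batch: bool = False,
              variable_boundaries: dict | None = None) -> DBN:
    """End-to-end DBN construction from a network.

    Unknown parameters are sampled uniformly over their bounds (equivalently,
    uniformly over their 5 equal intervals); initial species values are fixed
    at their registered initials, or uniform within +/- *init_spread*
    (fractional) around them.  Variable interval boundaries come from the
    pooled ensemble (equal frequency) unless given explicitly.
    """
    structure = derive_structure(network)
    # parameters: bounds for unknowns, point for knowns (only equation nodes)
    pb, pv = {}, {}
    for p in structure.parameter_nodes:
        e = network.params[p]
        if e.known:
            pv[p] = e.value
        else:
            pb[p] = e.bounds
    disc0 = make_discretization(param_bounds=pb, param_values=pv,
                                n_param=n_param)
    prior = {p: (np.full(n_param, 1.0 / n_param) if p in pb else np.array([1.0]))
             for p in structure.parameter_nodes}
    for sp in network.species_names:
        x0 = network.species[network.species_index(sp)].initial_concentration
        if init_spread > 0 and x0 > 0:
            disc0.boundaries[sp] = np.array([x0 * (1 - init_spread),
                                             x0 * (1 + init_spread)])
            prior[sp] = np.array([1.0])
        else:
            disc0.boundaries[sp] = np.array([x0, x0])
            disc0.degenerate.add(sp)
            prior[sp] = np.array([1.0])
    ensemble = sample_trajectories(network, prior, disc0, J, grid, seed,
                                   method=method, batch=batch)
    var_vals = {sp: ensemble.values[:, i, :]
                for i, sp in enumerate(ensemble.species_names)}
    disc = make_discretization(variable_values=var_vals, param_bounds=pb,
                               param_values=pv, n_var=n_var, n_param=n_param)
    if variable_boundaries:
        for sp, b in variable_boundaries.items():
            disc.boundaries[sp] = np.asarray(b, dtype=float)
            disc.degenerate.discard(sp)
    return count_cpts(ensemble, structure, disc)


# ---------------------------------------------------------------------------
# serialization (JSON; schema version 1)
# ---------------------------------------------------------------------------

def dbn_to_json(dbn: DBN, path) -> None:
    doc = {
        "schema_version": 1,
        "grid": list(dbn.grid.points),
        "sample_count": dbn.sample_count,
        "variable_nodes": list(dbn.structure.variable_nodes),
        "parameter_nodes": list(dbn.structure.parameter_nodes),
        "parents": {k: list(v) for k, v in dbn.structure.parents.items()},
        "boundaries": {k: np.asarray(v).tolist()
                       for k, v in dbn.discretization.boundaries.items()},
        "degenerate": sorted(dbn.discretization.degenerate),
        "prior": {k: np.asarray(v).tolist() for k, v in dbn.prior.items()},
        "cpts": {
            node: [{"codes": r[0].tolist(), "probs": r[1].tolist(),
                    "support": [None if not np.isfinite(s) else s
                                for s in r[2]]}
                   for r in cpt.rows]
            for node, cpt in dbn.cpts.items()},
        "representatives": {k: np.asarray(v).tolist()
                            for k, v in (dbn.representatives or {}).items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def dbn_from_json(path) -> DBN:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != 1:
        raise ModelError("unsupported DBN schema version")
    structure = DBNStructure(
        {k: tuple(v) for k, v in doc["parents"].items()},
        tuple(doc["variable_nodes"]), tuple(doc["parameter_nodes"]))
    disc = Discretization(
        {k: np.asarray(v, dtype=float) for k, v in doc["boundaries"].items()},
        set(doc["degenerate"]))
    prior = {k: np.asarray(v, dtype=float) for k, v in doc["prior"].items()}
    cpts = {}
    for node, slices in doc["cpts"].items():
        rows = []
        for r in slices:
            supp = np.array([np.inf if s is None else s for s in r["support"]])
            rows.append((np.asarray(r["codes"], dtype=np.int8),
                         np.asarray(r["probs"], dtype=float), supp))
        cpts[node] = CPT(structure.parents[node], disc.n_intervals(node), rows)
    reps = {k: np.asarray(v, dtype=float)
            for k, v in doc.get("representatives", {}).items()} or None
    return DBN(structure, disc, prior, cpts,
               TimeGrid(tuple(doc["grid"])), doc["sample_count"],
               representatives=reps)
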