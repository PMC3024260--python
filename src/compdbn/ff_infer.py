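"""Factored Frontier inference on the DBN approximation.

The Factored Frontier (FF) algorithm propagates *per-node* marginal interval
distributions through the two-slice DBN, approximating the joint distribution
over a node's parents by the product of their marginals:

    P(X^{t+1} = v)  =  sum_u  CPT_t(v | u) * prod_{Y in Pa(X)} P(Y^t = u_Y)

Only parent assignments observed during CPT counting are stored; the residual
product-of-marginals mass of unseen assignments falls back to a uniform
distribution over the child's intervals (counted and reported).  Evidence is
incorporated by filtering: marginals are multiplied by the evidence indicator
and renormalised before propagation.

For test oracles on tiny networks, :func:`enumerate_exact` performs exact
inference by dense enumeration of the joint interval distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .dbn_build import DBN
from .model_core import ModelError


class ContradictoryEvidence(ValueError):
    pass


@dataclass
class Evidence:
    """Clamps: (node, time) -> interval index, or numeric value (mapped to its
    containing interval at application time)."""

    clamps: dict = field(default_factory=dict)

    @classmethod
    def parameter_block(cls, block: dict) -> "Evidence":
        """Clamp parameter nodes at t = 0 to the given interval indices."""
        return cls({(node, 0.0): int(iv) for node, iv in block.items()})

    def interval_at(self, dbn: DBN, node: str, time: float, raw):
        if isinstance(raw, (int, np.integer)):
            iv = int(raw)
            if not (0 <= iv < dbn.n_intervals(node)):
                raise ModelError(f"clamp interval {iv} out of range for {node!r}")
            return iv
        return int(dbn.discretization.index(node, float(raw)))


@dataclass
class MarginalSeries:
    """Per node, per grid time: probability vector over the node's intervals."""

    grid: tuple
    marginals: dict[str, np.ndarray]  # node -> (T, n_intervals)
    unseen_mass: float = 0.0          # accumulated uniform-fallback mass

    def at(self, node: str, t_index: int) -> np.ndarray:
        return self.marginals[node][t_index]


def _apply_clamp(vec: np.ndarray, iv: int, node, t):
    masked = np.zeros_like(vec)
    masked[iv] = vec[iv]
    z = masked.sum()
    if z <= 0:
        raise ContradictoryEvidence(
            f"evidence on {node!r} at t={t} has zero probability")
    return masked / z


#: discrete kernel bandwidth for the sparse-CPT backoff: when a node's
#: stored rows are all incompatible with the exact parent product, rows are
#: re-weighted by SMOOTH_RHO ** (interval distance summed over parents)
SMOOTH_RHO = 0.3


def ff_forward(dbn: DBN, evidence: Evidence | None = None,
               smooth_rho: float = SMOOTH_RHO) -> MarginalSeries:
    """Propagate per-node marginals through the DBN (filtering).

    The step rule weights each stored CPT row by the product of its parents'
    marginal probabilities and renormalises over that (seen) mass.  When no
    stored row is compatible — common for high-order equations under a full
    parameter clamp at practical sample counts — the rows are instead
    weighted by a discrete kernel over interval distance (bandwidth
    *smooth_rho*), which preserves a graded dependence on the clamped
    parameter intervals; with ``smooth_rho = 0`` this degrades to the plain
    uniform fallback.  Both backoff events are accumulated in the returned
    ``unseen_mass`` counter.
    """
    evidence = evidence or Evidence()
    T = len(dbn.grid)
    times = np.asarray(dbn.grid.points)
    nodes = list(dbn.node_order)
    clamp_by_step: dict[int, list] = {}
    for (node, t), raw in evidence.clamps.items():
        ti = dbn.grid.index_of(t)
        clamp_by_step.setdefault(ti, []).append(
            (node, evidence.interval_at(dbn, node, t, raw)))

    marg = {n: np.zeros((T, dbn.n_intervals(n))) for n in nodes}
    cur = {n: np.asarray(dbn.prior[n], dtype=float).copy() for n in nodes}
    unseen = 0.0
    for node, iv in clamp_by_step.get(0, []):
        cur[node] = _apply_clamp(cur[node], iv, node, times[0])
    for n in nodes:
        marg[n][0] = cur[n]

    param_set = set(dbn.structure.parameter_nodes)
    for t in range(1, T):
        nxt = {}
        for n in nodes:
            if n in param_set:
                nxt[n] = cur[n]  # identity CPT
                continue
            codes, probs, _ = dbn.cpts[n].rows[t - 1]
            if len(codes) == 0:
                nxt[n] = np.full(dbn.n_intervals(n), 1.0 / dbn.n_intervals(n))
                unseen += 1.0
                continue
            w = np.ones(len(codes))
            for j, pa in enumerate(dbn.cpts[n].parents):
                w *= cur[pa][codes[:, j]]
            seen = w.sum()
            if seen <= 0.0:
                unseen += 1.0
                if smooth_rho > 0.0:
                    # kernel backoff: weight rows by interval distance to the
                    # most probable assignment of each parent
                    w = np.ones(len(codes))
                    for j, pa in enumerate(dbn.cpts[n].parents):
                        mode = int(np.argmax(cur[pa]))
                        w *= smooth_rho ** np.abs(codes[:, j].astype(int)
                                                  - mode)
                    out = w @ probs
                    nxt[n] = out / out.sum()
                else:
                    nxt[n] = np.full(dbn.n_intervals(n),
                                     1.0 / dbn.n_intervals(n))
                continue
            # renormalise over the seen mass: stored rows stand in for the
            # unseen assignments; the discarded mass is reported
            unseen += max(1.0 - seen, 0.0)
            out = w @ probs
            nxt[n] = out / out.sum()
        cur = nxt
        for node, iv in clamp_by_step.get(t, []):
            cur[node] = _apply_clamp(cur[node], iv, node, times[t])
        for n in nodes:
            marg[n][t] = cur[n]
    return MarginalSeries(tuple(times), marg, unseen)


def expected_series(marginals: MarginalSeries, discretization,
                    node: str, representatives=None) -> np.ndarray:
    """Expected value time course: E[t] = sum_v rep(v, t) * P(X^t = v).

    The interval representative rep(v, t) is the interval midpoint, or the
    counted ensemble's per-slice conditional mean when *representatives*
    (as stored on a :class:`~compdbn.dbn_build.DBN`) is given.
    """
    if node not in marginals.marginals:
        raise ModelError(f"node {node!r} not in marginal series")
    M = marginals.marginals[node]
    if representatives and node in representatives:
        rep = np.asarray(representatives[node])
        return np.einsum("tv,tv->t", M, rep)
    mids = discretization.midpoints(node)
    return M @ mids


# ---------------------------------------------------------------------------
# exact enumeration oracle (tiny networks only)
# ---------------------------------------------------------------------------

def enumerate_exact(dbn: DBN, evidence: Evidence | None = None,
                    max_states: int = 100_000) -> MarginalSeries:
    """Exact filtering by dense enumeration of the joint interval
    distribution.  Intended as an independent oracle on small DBNs."""
    evidence = evidence or Evidence()
    nodes = list(dbn.node_order)
    sizes = [dbn.n_intervals(n) for n in nodes]
    n_states = int(np.prod(sizes))
    if n_states > max_states:
        raise ModelError(f"state space too large for enumeration ({n_states})")
    T = len(dbn.grid)
    times = np.asarray(dbn.grid.points)
    nidx = {n: i for i, n in enumerate(nodes)}
    states = list(itertools.product(*[range(s) for s in sizes]))
    joint = np.array([np.prod([dbn.prior[n][s[nidx[n]]] for n in nodes])
                      for s in states])

    clamp_by_step: dict[int, list] = {}
    for (node, t), raw in evidence.clamps.items():
        ti = dbn.grid.index_of(t)
        clamp_by_step.setdefault(ti, []).append(
            (node, evidence.interval_at(dbn, node, t, raw)))

    def clamp_joint(joint, t):
        for node, iv in clamp_by_step.get(t, []):
            keep = np.array([s[nidx[node]] == iv for s in states])
            joint = joint * keep
            z = joint.sum()
            if z <= 0:
                raise ContradictoryEvidence(
                    f"evidence on {node!r} at step {t} has zero probability")
            joint = joint / z
        return joint

    def cond_prob(node, t, u_state, v):
        cpt = dbn.cpts[node]
        assignment = tuple(int(u_state[nidx[pa]]) for pa in cpt.parents)
        row, supp = cpt.lookup(t, assignment)
        if row is None:
            return 1.0 / dbn.n_intervals(node)
        return row[v]

    marg = {n: np.zeros((T, dbn.n_intervals(n))) for n in nodes}

    def record(joint, t):
        for n in nodes:
            for si, s in enumerate(states):
                marg[n][t, s[nidx[n]]] += joint[si]

    joint = clamp_joint(joint, 0)
    record(joint, 0)
    for t in range(1, T):
        new = np.zeros_like(joint)
        for ui, u in enumerate(states):
            pu = joint[ui]
            if pu == 0:
                continue
            for vi, v in enumerate(states):
                p = pu
                for n in nodes:
                    p *= cond_prob(n, t - 1, u, v[nidx[n]])
                    if p == 0.0:
                        break
                new[vi] += p
        joint = new / new.sum()
        joint = clamp_joint(joint, t)
        record(joint, t)
    return MarginalSeries(tuple(times), marg)
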