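"""Local and global (MPSA) sensitivity analysis.

Local: scaled absolute sensitivity coefficients |(p/y) dy/dp| of response
summaries (peak amplitude, integrated response of the readout species) with
respect to initial concentrations, by central finite differences.

Global: multi-parametric sensitivity analysis (MPSA) on the DBN — sample
parameter blocks (Latin hypercube over interval indices), score each by the
DBN/FF weighted SSE against the data, classify samples into good/bad by a
threshold, and score each parameter by the Kolmogorov-Smirnov distance between
the two classes' cumulative frequency curves of its sampled interval indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dbn_build import DBN
from .estimate import Dataset, objective_block
from .ff_infer import ContradictoryEvidence
from .model_core import Condition, ModelError, ReactionNetwork, apply_condition
from .ode_sim import TimeGrid, simulate, summarize


@dataclass
class LocalSensitivityResult:
    coefficients: dict   # (input species, output name) -> coefficient
    undefined: list      # inputs with zero baseline output, flagged

    def to_dict(self):
        return {"coefficients": {f"{i}|{o}": v
                                 for (i, o), v in self.coefficients.items()},
                "undefined": self.undefined}


def local_scaled_sensitivity(network: ReactionNetwork, condition: Condition,
                             inputs, readout: str,
                             outputs=("peak_amplitude", "integrated_response"),
                             delta: float = 0.01,
                             grid: TimeGrid | None = None,
                             affinity_model=None) -> LocalSensitivityResult:
    """Central-difference scaled sensitivity of summary outputs to initial
    concentrations: |(p0/y0) * (y(p0(1+d)) - y(p0(1-d))) / (2 d p0)|."""
    if delta <= 0:
        raise ModelError("delta must be > 0")
    grid = grid or TimeGrid.regular(12600, 100)
    base_net = apply_condition(network, condition, affinity_model)
    target = base_net.observables.get(readout, readout)

    def summaries(overrides):
        tr = simulate(base_net, grid, initial_overrides=overrides,
                      rtol=1e-8, atol=1e-12)
        st = summarize(tr, target)
        return {"peak_amplitude": st.peak_amplitude,
                "peak_time": st.peak_time,
                "integrated_response": st.integrated_response}

    y0 = summaries(None)
    coeffs = {}
    undefined = []
    for sp in inputs:
        p0 = base_net.species[base_net.species_index(sp)].initial_concentration
        if p0 <= 0:
            raise ModelError(f"input {sp!r} has zero initial concentration")
        up = summaries({sp: p0 * (1 + delta)})
        dn = summaries({sp: p0 * (1 - delta)})
        for out in outputs:
            if y0[out] == 0:
                undefined.append((sp, out))
                coeffs[(sp, out)] = np.nan
                continue
            coeffs[(sp, out)] = abs(
                (up[out] - dn[out]) / (2.0 * delta * y0[out]))
    return LocalSensitivityResult(coeffs, undefined)


@dataclass
class MPSAResult:
    ks: dict                 # parameter -> KS statistic in [0, 1]
    threshold: float
    n_samples: int
    n_good: int
    n_bad: int

    def ranking(self):
        return sorted(self.ks, key=self.ks.get, reverse=True)

    def to_dict(self):
        return {"ks": self.ks, "threshold": self.threshold,
                "n_samples": self.n_samples, "n_good": self.n_good,
                "n_bad": self.n_bad}


def _latin_hypercube_indices(rng, n_samples: int, n_intervals: int):
    """Stratified (Latin-hypercube style) draw of interval indices."""
    reps = int(np.ceil(n_samples / n_intervals))
    col = np.tile(np.arange(n_intervals), reps)[:n_samples]
    rng.shuffle(col)
    return col


def mpsa(dbn: DBN | dict, dataset: Dataset, n_samples: int = 500,
         threshold_rule="median", seed: int = 0,
         parameters=None) -> MPSAResult:
    """Kolmogorov-Smirnov global sensitivity of unknown parameters.

    *threshold_rule*: "median" (balanced classes) or a numeric absolute
    objective threshold.
    """
    if n_samples < 100:
        raise ModelError("MPSA needs at least 100 samples")
    rng = np.random.default_rng(seed)
    dbn0 = next(iter(dbn.values())) if isinstance(dbn, dict) else dbn
    params = list(parameters or
                  [p for p in dbn0.structure.parameter_nodes
                   if dbn0.n_intervals(p) > 1])
    samples = np.column_stack([
        _latin_hypercube_indices(rng, n_samples, dbn0.n_intervals(p))
        for p in params])

    objs = np.empty(n_samples)
    for i in range(n_samples):
        block = {p: int(samples[i, j]) for j, p in enumerate(params)}
        try:
            objs[i] = objective_block(block, dbn, dataset)
        except ContradictoryEvidence:
            objs[i] = np.inf

    thr = float(np.median(objs)) if threshold_rule == "median" \
        else float(threshold_rule)
    good = objs <= thr
    bad = ~good
    if good.sum() == 0 or bad.sum() == 0:
        raise ModelError(f"threshold {thr} left one class empty")

    ks = {}
    for j, p in enumerate(params):
        n_iv = dbn0.n_intervals(p)
        cg = np.cumsum(np.bincount(samples[good, j], minlength=n_iv)) / good.sum()
        cb = np.cumsum(np.bincount(samples[bad, j], minlength=n_iv)) / bad.sum()
        ks[p] = float(np.max(np.abs(cg - cb)))
    return MPSAResult(ks, thr, n_samples, int(good.sum()), int(bad.sum()))
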