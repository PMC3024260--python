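"""Synthetic calibration data and a small library of test models.

``generate_dataset`` emulates the study's densitometry-style measurements:
deposited species sampled at 8 time points over 0-3.5 h under PC- and
GlcNAc-initiated conditions (normal and inflammation), from known ground-truth
parameters, with multiplicative lognormal noise (default CV 10%, a plausible
figure for Western-blot densitometry; the real data's error model is
uncharacterised).

The toy models (2-, 3- and 6-species cascades) keep DBN/inference/estimation
tests independent of the full 42-species complement model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimate import Dataset
from .model_core import Condition, ModelError, ReactionNetwork, apply_condition
from .ode_sim import TimeGrid, simulate

#: the study's sampling design: 8 equally spaced points over 0 - 3.5 h
STUDY_SAMPLE_TIMES = tuple(float(t) for t in np.linspace(0.0, 12600.0, 8))

#: deposited species observed per initiating ligand
OBSERVED_SPECIES = {
    "PC": ("CRP_dep", "C4_dep", "C3_dep", "C4BP_dep"),
    "GlcNAc": ("MASP2_dep", "C4_dep", "C3_dep", "C4BP_dep"),
}


@dataclass(frozen=True)
class NoiseModel:
    kind: str = "multiplicative-lognormal"  # or "additive-gaussian"
    cv: float = 0.10
    sd: float = 0.0

    def __post_init__(self):
        if self.cv < 0 or self.sd < 0:
            raise ModelError("noise magnitude must be >= 0")
        if self.kind not in ("multiplicative-lognormal", "additive-gaussian"):
            raise ModelError(f"unknown noise kind {self.kind!r}")

    def apply(self, values: np.ndarray, rng) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.kind == "multiplicative-lognormal":
            if self.cv == 0:
                return values.copy()
            sigma = np.sqrt(np.log1p(self.cv ** 2))
            # unit-mean lognormal factors
            f = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                              size=values.shape)
            return values * f
        out = values + rng.normal(0.0, self.sd, size=values.shape)
        return np.clip(out, 0.0, None)


@dataclass
class SyntheticDataset:
    dataset: Dataset
    theta_true: dict          # unknown parameter -> generating value
    conditions: dict          # condition name -> Condition
    seed: int
    noise: NoiseModel = field(default_factory=NoiseModel)


def study_conditions() -> dict:
    """The four calibration conditions of the measurement design."""
    return {
        "PC_inflammation": Condition(initiation="PC", pH=6.5, calcium=2.0),
        "PC_normal": Condition(initiation="PC", pH=7.4, calcium=2.5),
        "GlcNAc_inflammation": Condition(initiation="GlcNAc", pH=6.5,
                                         calcium=2.0),
        "GlcNAc_normal": Condition(initiation="GlcNAc", pH=7.4, calcium=2.5),
    }


def generate_dataset(network: ReactionNetwork, theta_true: dict | None = None,
                     conditions: dict | None = None,
                     sample_times=STUDY_SAMPLE_TIMES,
                     noise: NoiseModel = NoiseModel(), seed: int = 0,
                     observed: dict | None = None,
                     grid: TimeGrid | None = None,
                     affinity_model=None) -> SyntheticDataset:
    """Simulate each condition at the ground-truth parameters, sample at the
    study's 8 time points, apply the noise model, and record ground truth.

    *observed* maps condition name -> tuple of observed quantities (defaults
    to the study design via each condition's initiating ligand, falling back
    to every species with a registered observable).
    """
    rng = np.random.default_rng(seed)
    conditions = dict(conditions) if conditions is not None else study_conditions()
    theta_true = dict(theta_true or {})
    grid = grid or TimeGrid.regular(max(12600.0, max(sample_times)), 100.0)
    for t in sample_times:
        grid.index_of(t)  # raises if off-grid

    observations = {}
    for cname, cond in conditions.items():
        net = network.copy()
        for p, v in theta_true.items():
            net.set_param(p, v)
        if cond is not None:
            net = apply_condition(net, cond, affinity_model)
        tr = simulate(net, grid)
        if observed and cname in observed:
            obs_names = observed[cname]
        elif cond is not None and cond.initiation in OBSERVED_SPECIES \
                and network.observables:
            obs_names = OBSERVED_SPECIES[cond.initiation]
        elif network.observables:
            obs_names = tuple(network.observables)
        else:
            obs_names = tuple(network.species_names)
        for name in obs_names:
            # observations are keyed by the model species realising the
            # measurement (deposited forms), i.e. by DBN node names
            target = net.observables.get(name, name)
            y = tr.series(target)[[grid.index_of(t) for t in sample_times]]
            y = noise.apply(y, rng)
            for t, v in zip(sample_times, y):
                observations[(cname, target, float(t))] = float(v)

    ds = Dataset(observations=observations,
                 weights={},
                 conditions=conditions)
    if not theta_true:
        theta_true = {p: network.params[p].value
                      for p in network.params.unknown_names}
    return SyntheticDataset(ds, theta_true, conditions, seed, noise)


# ---------------------------------------------------------------------------
# small test-model library
# ---------------------------------------------------------------------------

def two_species_decay(k: float = 1e-3, x0: float = 100.0,
                      bounds=(1e-4, 1e-2)) -> ReactionNetwork:
    """A -> B, single unknown mass-action constant (closed form available)."""
    return _build_toy(
        species=[("A", x0), ("B", 0.0)],
        reactions=[("r1", ["A"], ["B"], "k1")],
        params={"k1": (k, bounds)},
        conservation={"total": ["A", "B"]},
        name="two_species_decay")


def three_species_cascade(k=(2e-3, 1e-3, 5e-4, 3e-4), x0: float = 100.0
                          ) -> ReactionNetwork:
    """Linear cascade S1 -> S2 -> S3 with first-order losses from S2 and S3;
    4 unknown parameters, used for parameter-recovery experiments.

    Bounds span 0.25x - 1.75x of each generating value, so with 5 equal
    parameter intervals the truth sits at the centre of the middle interval
    (the usual design for recovery studies: the prior brackets the truth).
    """
    def _b(v):
        return (v, (0.25 * v, 1.75 * v))

    k1, k2, k3, k4 = k
    return _build_toy(
        species=[("S1", x0), ("S2", 0.0), ("S3", 0.0)],
        reactions=[("r1", ["S1"], ["S2"], "k1"),
                   ("r2", ["S2"], ["S3"], "k2"),
                   ("r3", ["S2"], [], "k3"),
                   ("r4", ["S3"], [], "k4")],
        params={"k1": _b(k1), "k2": _b(k2), "k3": _b(k3), "k4": _b(k4)},
        name="three_species_cascade")


def six_species_cascade(seed: int = 0) -> ReactionNetwork:
    """Six-species chain with one Michaelis-Menten step and losses; a larger
    (still cheap) DBN/inference test bed."""
    rng = np.random.default_rng(seed)
    ks = 10 ** rng.uniform(-3.3, -2.7, size=5)
    return _build_toy(
        species=[("X1", 120.0), ("X2", 0.0), ("X3", 0.0), ("X4", 0.0),
                 ("X5", 0.0), ("E", 10.0)],
        reactions=[("r1", ["X1"], ["X2"], ks[0]),
                   ("r2", ["X2"], ["X3"], ks[1]),
                   ("r3", ["X3"], ["X4"], ks[2], "E"),   # MM step
                   ("r4", ["X4"], ["X5"], ks[3]),
                   ("r5", ["X5"], [], ks[4])],
        params=None,
        name="six_species_cascade")


def _build_toy(species, reactions, params, conservation=None, name="toy"):
    spec = {"name": name,
            "species": [{"name": n, "initial": v} for n, v in species],
            "parameters": [], "reactions": []}
    if params is None:
        params = {}
    for r in reactions:
        if len(r) == 5:  # MM step: (id, [sub], [prod], c_value, enzyme)
            rid, subs, prods, cval, enz = r
            cname, chname = f"{rid}_c", f"{rid}_ch"
            params[cname] = (float(cval), (cval / 5, cval * 5))
            params[chname] = (50.0, (10.0, 250.0))
            spec["reactions"].append(
                {"id": rid, "reactants": subs, "products": prods,
                 "modifiers": [enz],
                 "law": {"kind": "michaelis_menten", "c": cname,
                         "c_half": chname}})
        else:
            rid, subs, prods, k = r
            if isinstance(k, str):
                kname = k
            else:
                kname = f"{rid}_k"
                params[kname] = (float(k), (k / 5, k * 5))
            spec["reactions"].append(
                {"id": rid, "reactants": subs, "products": prods,
                 "law": {"kind": "mass_action", "k": kname}})
    for pname, (v, b) in params.items():
        spec["parameters"].append({"name": pname, "value": float(v),
                                   "bounds": [float(b[0]), float(b[1])]})
    if conservation:
        spec["conservation"] = {g: {s: 1.0 for s in m}
                                for g, m in conservation.items()}
    from .model_core import build_network
    return build_network(spec)
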