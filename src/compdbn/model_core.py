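"""Reaction-network core: species, rate laws, parameters, conditions.

The central object is :class:`ReactionNetwork`, an ODE-ready description of a
biochemical reaction system built from mass-action and Michaelis-Menten rate
laws.  The module also hosts the pH/calcium-dependent CRP:L-ficolin binding
affinity model and the machinery that applies an experimental
:class:`Condition` (initiating ligand, pH, calcium, depletions, knockouts,
concentration scalings) to a network.

Concentrations are in nM, time in seconds, throughout.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

UNKNOWN = None  # sentinel for "no literature value"

MASS_ACTION = "mass_action"
MICHAELIS_MENTEN = "michaelis_menten"

#: knockout letters accepted by :class:`Condition` (C4BP mechanisms)
KNOCKOUT_TAGS = ("a", "b", "c", "d")


class ModelError(ValueError):
    """Raised for structural problems in a model specification."""


@dataclass(frozen=True)
class SpeciesDef:
    name: str
    role: str = "fluid-phase"  # fluid-phase | surface-bound | ligand | complex
    initial_concentration: float = 0.0

    def __post_init__(self):
        if self.initial_concentration < 0:
            raise ModelError(
                f"species {self.name!r}: negative initial concentration"
            )


@dataclass(frozen=True)
class RateLaw:
    """A rate law referencing parameters *by name*.

    mass_action:       rate = k * prod(reactant concentrations ** stoich)
    michaelis_menten:  rate = c * [enzyme] * [substrate] / (c_half + [substrate])
    """

    kind: str
    k: str | None = None        # mass-action rate constant (parameter name)
    c: str | None = None        # MM catalytic constant
    c_half: str | None = None   # MM half-saturation constant

    def __post_init__(self):
        if self.kind == MASS_ACTION:
            if not self.k:
                raise ModelError("mass_action law requires a rate constant")
        elif self.kind == MICHAELIS_MENTEN:
            if not (self.c and self.c_half):
                raise ModelError("michaelis_menten law requires c and c_half")
        else:
            raise ModelError(f"unknown rate-law kind {self.kind!r}")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        if self.kind == MASS_ACTION:
            return (self.k,)
        return (self.c, self.c_half)


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_law: RateLaw
    modifiers: tuple[str, ...] = ()
    reversible: bool = False
    k_reverse: str | None = None  # backward constant (reversible mass action)
    tags: frozenset = frozenset()

    def __post_init__(self):
        if self.reversible:
            if self.rate_law.kind != MASS_ACTION or not self.k_reverse:
                raise ModelError(
                    f"reaction {self.id!r}: reversible reactions must be "
                    "mass action with a k_reverse constant"
                )
        if self.rate_law.kind == MICHAELIS_MENTEN and len(self.modifiers) != 1:
            raise ModelError(
                f"reaction {self.id!r}: Michaelis-Menten law needs exactly "
                "one modifier (the enzyme)"
            )

    @property
    def parameter_names(self) -> tuple[str, ...]:
        names = self.rate_law.parameter_names
        if self.reversible:
            names = names + (self.k_reverse,)
        return names


@dataclass
class ParameterEntry:
    value: float | None          # None == UNKNOWN (no resolved value)
    bounds: tuple[float, float] | None
    known: bool

    def __post_init__(self):
        if self.value is not None and self.value < 0:
            raise ModelError("negative rate constant")
        if not self.known:
            if self.bounds is None:
                raise ModelError("unknown parameter requires bounds")
            lo, hi = self.bounds
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ModelError("unknown parameter requires finite lo < hi bounds")


class ParameterRegistry:
    """Flat name -> (value, bounds, known) registry."""

    def __init__(self):
        self._entries: dict[str, ParameterEntry] = {}

    def add(self, name, value=UNKNOWN, bounds=None, known=False):
        if name in self._entries:
            raise ModelError(f"duplicate parameter {name!r}")
        self._entries[name] = ParameterEntry(value, bounds, known)

    def __contains__(self, name):
        return name in self._entries

    def __getitem__(self, name) -> ParameterEntry:
        return self._entries[name]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self):
        return len(self._entries)

    def items(self):
        return self._entries.items()

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    @property
    def unknown_names(self) -> list[str]:
        return [n for n, e in self._entries.items() if not e.known]

    @property
    def n_known(self) -> int:
        return sum(e.known for e in self._entries.values())

    def values_vector(self, names=None) -> np.ndarray:
        names = self.names if names is None else names
        out = np.empty(len(names))
        for i, n in enumerate(names):
            v = self._entries[n].value
            if v is None:
                raise ModelError(f"parameter {n!r} is UNKNOWN and unresolved")
            out[i] = v
        return out

    def copy(self) -> "ParameterRegistry":
        new = ParameterRegistry()
        new._entries = {n: replace(e) for n, e in self._entries.items()}
        return new


@dataclass
class ConditionHooks:
    """Model-declared attachment points for condition-dependent scaling.

    ``crosstalk_params`` are association constants of the CRP/L-ficolin
    interaction, multiplied directly by the affinity factor a(pH, Ca).
    ``recruitment`` maps a rate constant to the name of a registered exponent
    parameter gamma; the constant is multiplied by a(pH, Ca) ** gamma.  This
    encodes that the same conformational change driving the CRP:L-ficolin
    interaction also modulates (much more weakly) how efficiently the
    surface-bound initiators recruit their proteases.
    """

    crosstalk_params: tuple[str, ...] = ()
    recruitment: dict = field(default_factory=dict)  # param -> exponent param
    branch_species: dict = field(default_factory=dict)  # "PC"/"GlcNAc" -> ligand
    competition_tags: tuple[str, ...] = ("simultaneous",)


@dataclass(frozen=True)
class Condition:
    """An experimental scenario applied to a network."""

    initiation: str = "both"          # PC | GlcNAc | both
    pH: float = 7.4
    calcium: float = 2.5              # mM
    c4bp_scale: float = 1.0
    crp_scale: float = 1.0
    depleted: frozenset = frozenset()  # subset of {"CRP", "L-ficolin"}
    knockouts: frozenset = frozenset()  # subset of {"a","b","c","d"}
    competition_mode: bool = False

    def __post_init__(self):
        if self.initiation not in ("PC", "GlcNAc", "both"):
            raise ModelError(f"bad initiation {self.initiation!r}")
        if not (5.5 <= self.pH <= 7.4):
            raise ModelError("pH outside [5.5, 7.4]")
        if self.c4bp_scale < 0 or self.crp_scale < 0:
            raise ModelError("scales must be >= 0")
        bad = set(self.knockouts) - set(KNOCKOUT_TAGS)
        if bad:
            raise ModelError(f"unknown knockout letters {sorted(bad)}")


# condition presets used throughout the study
NORMAL = Condition(pH=7.4, calcium=2.5)
INFLAMMATION = Condition(pH=6.5, calcium=2.0)


class ReactionNetwork:
    """Species + reactions + parameter registry (the ODE system)."""

    def __init__(self, species, reactions, params, conservation=None,
                 observables=None, hooks=None, declared_counts=None,
                 name="network"):
        self.name = name
        self.species: list[SpeciesDef] = list(species)
        self.reactions: list[Reaction] = list(reactions)
        self.params: ParameterRegistry = params
        #: group name -> {species: weight}; each group's weighted total is
        #: conserved by every reaction
        self.conservation: dict[str, dict[str, float]] = conservation or {}
        #: measured quantity -> model species (e.g. "C3dep" -> "C3bd")
        self.observables: dict[str, str] = observables or {}
        self.hooks: ConditionHooks = hooks or ConditionHooks()
        self._inactive: set[str] = set()  # reaction ids switched off
        self._validate(declared_counts)

    # -- validation ---------------------------------------------------------

    def _validate(self, declared_counts):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ModelError("duplicate species names")
        sset = set(names)
        rids = set()
        for r in self.reactions:
            if r.id in rids:
                raise ModelError(f"duplicate reaction id {r.id!r}")
            rids.add(r.id)
            for sp, e in r.reactants + r.products:
                if sp not in sset:
                    raise ModelError(f"reaction {r.id!r}: unknown species {sp!r}")
                if e <= 0 or int(e) != e:
                    raise ModelError(f"reaction {r.id!r}: bad stoichiometry {e}")
            for m in r.modifiers:
                if m not in sset:
                    raise ModelError(f"reaction {r.id!r}: unknown modifier {m!r}")
            for p in r.parameter_names:
                if p not in self.params:
                    raise ModelError(f"reaction {r.id!r}: unregistered parameter {p!r}")
        for g, members in self.conservation.items():
            for sp in members:
                if sp not in sset:
                    raise ModelError(f"conservation group {g!r}: unknown species {sp!r}")
        if declared_counts:
            actual = (len(self.species), len(self.reactions),
                      len(self.params), len(self.params.unknown_names))
            declared = tuple(declared_counts)
            if actual != declared:
                msg = (f"model {self.name!r}: declared counts "
                       f"(species, reactions, params, unknown) {declared} "
                       f"!= actual {actual}")
                if self.name == "complement":
                    raise ModelError(msg)
                warnings.warn(msg)
        self.check_conservation()

    def check_conservation(self):
        """Symbolic check: every declared group is closed under every reaction."""
        for g, members in self.conservation.items():
            for r in self.reactions:
                net = 0.0
                for sp, e in r.products:
                    net += members.get(sp, 0.0) * e
                for sp, e in r.reactants:
                    net -= members.get(sp, 0.0) * e
                if abs(net) > 1e-12:
                    raise ModelError(
                        f"conservation group {g!r} broken by reaction {r.id!r} "
                        f"(net {net:+g})")
                if r.reversible and abs(net) > 1e-12:  # pragma: no cover
                    raise ModelError(g)

    # -- introspection ------------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise ModelError(f"unknown species {name!r}") from None

    @property
    def active_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.id not in self._inactive]

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species])

    def reactions_with_tag(self, tag: str) -> list[Reaction]:
        return [r for r in self.reactions if tag in r.tags]

    def rhs_dependencies(self) -> dict[str, set[str]]:
        """Per species, the set of species and parameters on the right-hand
        side of its ODE (used for the DBN parent structure)."""
        deps: dict[str, set[str]] = {s.name: set() for s in self.species}
        for r in self.active_reactions:
            involved = set()
            involved.update(sp for sp, _ in r.reactants)
            involved.update(r.modifiers)
            involved.update(r.rate_law.parameter_names)
            rev_involved = None
            if r.reversible:
                rev_involved = set(sp for sp, _ in r.products) | {r.k_reverse}
            touched = {sp for sp, _ in r.reactants} | {sp for sp, _ in r.products}
            for sp in touched:
                deps[sp].update(involved)
                if rev_involved:
                    deps[sp].update(rev_involved)
        return deps

    # -- mutation via copies -------------------------------------------------

    def copy(self) -> "ReactionNetwork":
        new = ReactionNetwork.__new__(ReactionNetwork)
        new.name = self.name
        new.species = list(self.species)
        new.reactions = list(self.reactions)
        new.params = self.params.copy()
        new.conservation = copy.deepcopy(self.conservation)
        new.observables = dict(self.observables)
        new.hooks = copy.deepcopy(self.hooks)
        new._inactive = set(self._inactive)
        return new

    def set_initial(self, species: str, value: float) -> None:
        i = self.species_index(species)
        self.species[i] = replace(self.species[i], initial_concentration=value)

    def set_param(self, name: str, value: float) -> None:
        if name not in self.params:
            raise ModelError(f"unknown parameter {name!r}")
        self.params[name].value = float(value)

    def scale_param(self, name: str, factor: float) -> None:
        """Multiply a parameter's value *and* its bounds (so prior boxes
        follow condition-dependent rescaling)."""
        e = self.params[name]
        self.set_param(name, e.value * factor)
        if e.bounds is not None:
            e.bounds = (e.bounds[0] * factor, e.bounds[1] * factor)

    def deactivate(self, reaction_ids) -> None:
        known = {r.id for r in self.reactions}
        for rid in reaction_ids:
            if rid not in known:
                raise ModelError(f"unknown reaction id {rid!r}")
        self._inactive.update(reaction_ids)


# ---------------------------------------------------------------------------
# Building a network from a parsed model specification (dict)
# ---------------------------------------------------------------------------

def _parse_side(entries):
    out = []
    for e in entries or ():
        if isinstance(e, str):
            out.append((e, 1))
        else:
            out.append((e["species"], int(e.get("stoich", 1))))
    return tuple(out)


def build_network(model_spec: dict) -> ReactionNetwork:
    """Assemble and validate a :class:`ReactionNetwork` from a model spec
    dictionary (the parsed form of the native YAML model dialect)."""
    species = [SpeciesDef(s["name"], s.get("role", "fluid-phase"),
                          float(s.get("initial", 0.0)))
               for s in model_spec["species"]]
    params = ParameterRegistry()
    for p in model_spec["parameters"]:
        known = bool(p.get("known", False))
        bounds = tuple(p["bounds"]) if "bounds" in p else None
        value = p.get("value", UNKNOWN)
        params.add(p["name"], value=value, bounds=bounds, known=known)
    reactions = []
    for r in model_spec["reactions"]:
        law = r["law"]
        kind = law["kind"]
        rate_law = RateLaw(kind, k=law.get("k"), c=law.get("c"),
                           c_half=law.get("c_half"))
        reactions.append(Reaction(
            id=r["id"],
            reactants=_parse_side(r.get("reactants")),
            products=_parse_side(r.get("products")),
            rate_law=rate_law,
            modifiers=tuple(r.get("modifiers", ())),
            reversible=bool(r.get("reversible", False)),
            k_reverse=law.get("k_reverse"),
            tags=frozenset(r.get("tags", ())),
        ))
    hooks_spec = model_spec.get("hooks", {})
    hooks = ConditionHooks(
        crosstalk_params=tuple(hooks_spec.get("crosstalk", ())),
        recruitment=dict(hooks_spec.get("recruitment", {})),
        branch_species=dict(hooks_spec.get("branches", {})),
    )
    counts = model_spec.get("counts")
    declared = None
    if counts:
        declared = (counts["species"], counts["reactions"],
                    counts["parameters"], counts["unknown"])
    return ReactionNetwork(
        species, reactions, params,
        conservation=model_spec.get("conservation"),
        observables=model_spec.get("observables"),
        hooks=hooks,
        declared_counts=declared,
        name=model_spec.get("name", "network"),
    )


# ---------------------------------------------------------------------------
# ODE right-hand side
# ---------------------------------------------------------------------------

def _compile(network: ReactionNetwork, param_names: list[str]):
    """Precompute index structures for fast, batch-capable rate evaluation."""
    sidx = {s.name: i for i, s in enumerate(network.species)}
    pidx = {n: i for i, n in enumerate(param_names)}
    steps = []  # (kind, data) per internal irreversible step
    for r in network.active_reactions:
        re_idx = [(sidx[sp], e) for sp, e in r.reactants]
        pr_idx = [(sidx[sp], e) for sp, e in r.products]
        if r.rate_law.kind == MASS_ACTION:
            steps.append(("ma", re_idx, pr_idx, pidx[r.rate_law.k]))
            if r.reversible:
                steps.append(("ma", pr_idx, re_idx, pidx[r.k_reverse]))
        else:
            sub, e = r.reactants[0]
            if len(r.reactants) != 1 or e != 1:
                raise ModelError(
                    f"reaction {r.id!r}: MM law supports a single substrate")
            steps.append(("mm", re_idx, pr_idx, pidx[r.rate_law.c],
                          pidx[r.rate_law.c_half], sidx[r.modifiers[0]]))
    return steps


def ode_rhs(network: ReactionNetwork, param_names=None):
    """Build ``f(x, theta) -> dx/dt`` for the active reactions of *network*.

    ``x`` may be a vector (n_species,) or a batch matrix (n_species, B);
    ``theta`` correspondingly (n_params,) or (n_params, B).  The derivative of
    each species is the sum of producing rates minus consuming rates, weighted
    by stoichiometry.  Rate evaluation is fully vectorised across reactions:
    mass-action factors are gathered through an index table (a virtual
    constant-one species pads reactions with fewer factors), Michaelis-Menten
    steps are evaluated in one shot, and the stoichiometric matrix maps rates
    to derivatives.
    """
    if param_names is None:
        param_names = network.params.names
    steps = _compile(network, list(param_names))
    n = len(network.species)
    R = len(steps)

    ma = [(i, s) for i, s in enumerate(steps) if s[0] == "ma"]
    mm = [(i, s) for i, s in enumerate(steps) if s[0] == "mm"]
    # factor table for mass action: reactant indices repeated by stoichiometry,
    # padded with the virtual species n (constant 1)
    max_ord = 1
    for _, s in ma:
        max_ord = max(max_ord, sum(e for _, e in s[1]))
    ma_rows = np.array([i for i, _ in ma], dtype=np.intp)
    ma_k = np.array([s[3] for _, s in ma], dtype=np.intp)
    ma_fac = np.full((len(ma), max_ord), n, dtype=np.intp)
    for row, (_, s) in enumerate(ma):
        col = 0
        for si, e in s[1]:
            for _ in range(e):
                ma_fac[row, col] = si
                col += 1
    mm_rows = np.array([i for i, _ in mm], dtype=np.intp)
    mm_c = np.array([s[3] for _, s in mm], dtype=np.intp)
    mm_ch = np.array([s[4] for _, s in mm], dtype=np.intp)
    mm_e = np.array([s[5] for _, s in mm], dtype=np.intp)
    mm_s = np.array([s[1][0][0] for _, s in mm], dtype=np.intp)

    N = np.zeros((n, R))
    for i, s in enumerate(steps):
        for si, e in s[1]:
            N[si, i] -= e
        for si, e in s[2]:
            N[si, i] += e

    def rhs(x, theta):
        x = np.asarray(x, dtype=float)
        theta = np.asarray(theta, dtype=float)
        vec = x.ndim == 1
        X = x[:, None] if vec else x
        TH = theta[:, None] if (vec or theta.ndim == 1) else theta
        Xa = np.concatenate([X, np.ones((1, X.shape[1]))], axis=0)
        rates = np.empty((R, X.shape[1]))
        if len(ma):
            r = TH[ma_k] * Xa[ma_fac[:, 0]]
            for c in range(1, max_ord):
                r = r * Xa[ma_fac[:, c]]
            rates[ma_rows] = r
        if len(mm):
            S = X[mm_s]
            rates[mm_rows] = TH[mm_c] * X[mm_e] * S / (TH[mm_ch] + S)
        dx = N @ rates
        return dx[:, 0] if vec else dx

    rhs.n_species = n
    rhs.param_names = list(param_names)
    return rhs


# ---------------------------------------------------------------------------
# CRP : L-ficolin binding affinity as a function of pH and calcium
# ---------------------------------------------------------------------------

class AffinityModel:
    """Polynomial (in pH) binding-affinity surface, one polynomial per
    calcium level, normalised so affinity(7.4, 2.5 mM) = 1 and rescaled so
    affinity(6.5, 2.0) / affinity(7.4, 2.5) = 100 (the reported fold change
    between infection-inflammation and normal conditions).

    Between tabulated calcium levels the log-affinity is linearly
    interpolated; outside, the nearest level is used.
    """

    REF_PH, REF_CA = 7.4, 2.5
    INFLAM_PH, INFLAM_CA = 6.5, 2.0
    TARGET_RATIO = 100.0

    def __init__(self, polys: dict[float, np.poly1d], ph_range=(5.5, 7.4)):
        self.polys = dict(sorted(polys.items()))
        self.ph_range = ph_range
        self._check_positive()

    def _check_positive(self):
        grid = np.linspace(*self.ph_range, 191)
        for ca, p in self.polys.items():
            vals = p(grid)
            if np.any(vals <= 0):
                raise ModelError(
                    f"fitted affinity polynomial at Ca={ca} mM is non-positive "
                    "inside the pH domain")

    def value(self, pH: float, calcium: float) -> float:
        lo, hi = self.ph_range
        if not (lo - 1e-9 <= pH <= hi + 1e-9):
            raise ModelError(f"pH {pH} outside affinity domain {self.ph_range}")
        cas = np.array(list(self.polys))
        logs = np.array([math.log(p(pH)) for p in self.polys.values()])
        if calcium <= cas[0]:
            return math.exp(logs[0])
        if calcium >= cas[-1]:
            return math.exp(logs[-1])
        return math.exp(float(np.interp(calcium, cas, logs)))

    def fold_change(self) -> float:
        """affinity(6.5, 2.0) / affinity(7.4, 2.5)."""
        return (self.value(self.INFLAM_PH, self.INFLAM_CA)
                / self.value(self.REF_PH, self.REF_CA))


def fit_affinity(anchors, degree: int = 3) -> AffinityModel:
    """Least-squares polynomial fit of normalised affinity anchors.

    *anchors*: iterable of (pH, calcium_mM, affinity) with affinity normalised
    to 1 at (7.4, 2.5).  One polynomial of the given degree is fitted per
    calcium level; the surface is then rescaled so the inflammation/normal
    ratio is exactly 100.
    """
    by_ca: dict[float, list[tuple[float, float]]] = {}
    for ph, ca, val in anchors:
        by_ca.setdefault(float(ca), []).append((float(ph), float(val)))
    polys = {}
    for ca, pts in by_ca.items():
        if len(pts) < degree + 1:
            raise ModelError(
                f"need >= {degree + 1} anchors at Ca={ca} mM, got {len(pts)}")
        phs = np.array([p for p, _ in pts])
        vals = np.array([v for _, v in pts])
        polys[ca] = np.poly1d(np.polyfit(phs, vals, degree))
    model = AffinityModel(polys)
    # pin the reference point to exactly 1 ...
    ref = model.value(AffinityModel.REF_PH, AffinityModel.REF_CA)
    polys = {ca: p / ref for ca, p in model.polys.items()}
    model = AffinityModel(polys)
    # ... and, when the table covers both reference calcium levels, the
    # inflammation/normal ratio to exactly 100 by adjusting the low-calcium
    # polynomial (a small correction when the anchors honour the ratio).
    if AffinityModel.INFLAM_CA in model.polys \
            and AffinityModel.REF_CA in model.polys:
        ratio = model.fold_change()
        polys = dict(model.polys)
        polys[AffinityModel.INFLAM_CA] = (
            polys[AffinityModel.INFLAM_CA]
            * (AffinityModel.TARGET_RATIO / ratio))
        model = AffinityModel(polys)
        if abs(model.fold_change() / AffinityModel.TARGET_RATIO - 1) > 0.01:
            raise ModelError("affinity rescaling failed to pin the 100x ratio")
    return model


#: synthetic default anchor table (pH, calcium mM, normalised affinity).
#: These are NOT literature numbers: they are samples of monotone-decreasing
#: cubics in pH, one per calcium level, constrained to the reported 100-fold
#: inflammation (pH 6.5, 2.0 mM) vs normal (pH 7.4, 2.5 mM) ratio and to a
#: flattening *relative* change toward pH 5.5.
DEFAULT_AFFINITY_ANCHORS = (
    (5.5, 2.5, 203.82464096749797), (6.0, 2.5, 90.60846560846554),
    (6.5, 2.5, 30.0), (7.0, 2.5, 5.559334845049121), (7.4, 2.5, 1.0),
    (5.5, 2.0, 681.4134542705966), (6.0, 2.0, 302.72486772486747),
    (6.5, 2.0, 100.0), (7.0, 2.0, 18.250188964474646), (7.4, 2.0, 3.0),
)


def default_affinity_model() -> AffinityModel:
    return fit_affinity(DEFAULT_AFFINITY_ANCHORS)


# ---------------------------------------------------------------------------
# Applying a condition
# ---------------------------------------------------------------------------

_DEPLETABLE = {"CRP": "CRP", "L-ficolin": "Lfic"}


def apply_condition(network: ReactionNetwork, condition: Condition,
                    affinity_model: AffinityModel | None = None
                    ) -> ReactionNetwork:
    """Return a modified copy of *network* under *condition*.

    The affinity factor a(pH, Ca) multiplies the CRP:L-ficolin association
    constants; initiator-recruitment constants are scaled by a**gamma with
    model-registered exponents; initial concentrations are scaled or zeroed;
    knockout-tagged and suppressed-branch reactions are deactivated.
    """
    net = network.copy()
    hooks = net.hooks

    if affinity_model is None:
        affinity_model = default_affinity_model()
    a = affinity_model.value(condition.pH, condition.calcium)
    for p in hooks.crosstalk_params:
        net.scale_param(p, a)
    for p, gamma_name in hooks.recruitment.items():
        gamma = net.params[gamma_name].value
        net.scale_param(p, a ** gamma)

    # branch suppression: zero the other branch's initiating ligand and mark
    # that branch's reactions inactive (parameters keep their numbering), so
    # the suppressed branch's rate expressions are identically zero
    if condition.initiation != "both":
        branch_tags = {"PC": ("classical", "amplification-PC"),
                       "GlcNAc": ("lectin", "amplification-GlcNAc")}
        for branch, ligand in hooks.branch_species.items():
            if branch != condition.initiation:
                net.set_initial(ligand, 0.0)
                for tag in branch_tags.get(branch, ()):
                    net.deactivate([r.id for r in net.reactions_with_tag(tag)])

    # concentration scalings / depletions
    if condition.crp_scale != 1.0 and "CRP" not in condition.depleted:
        i = net.species_index("CRP")
        net.set_initial("CRP",
                        net.species[i].initial_concentration * condition.crp_scale)
    if condition.c4bp_scale != 1.0:
        i = net.species_index("C4BP")
        net.set_initial("C4BP",
                        net.species[i].initial_concentration * condition.c4bp_scale)
    for label in condition.depleted:
        if label not in _DEPLETABLE:
            raise ModelError(f"cannot deplete {label!r}")
        net.set_initial(_DEPLETABLE[label], 0.0)

    # knockouts: remove only reactions carrying the matching C4BP tag
    for letter in sorted(condition.knockouts):
        tagged = net.reactions_with_tag(f"C4BP-{letter}")
        if not tagged:
            raise ModelError(f"knockout {letter!r}: no tagged reaction")
        net.deactivate([r.id for r in tagged])

    if condition.competition_mode:
        for tag in hooks.competition_tags:
            tagged = net.reactions_with_tag(tag)
            net.deactivate([r.id for r in tagged])

    return net
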