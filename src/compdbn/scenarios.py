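"""The study's in-silico experiments as scripted, seedable pipelines.

Conditions: the *normal* serum condition is pH 7.4 / 2.5 mM calcium; the
*patient* (infection-inflammation) condition is pH 6.5 / 2.0 mM calcium with
acute-phase-elevated CRP (10x baseline).  All scenarios read deposited C3 as
the antibacterial-activity readout and are pure functions of (network, theta,
configuration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import (Condition, ModelError, ReactionNetwork,
                         apply_condition, default_affinity_model)
from .ode_sim import TimeGrid, killing_panel, simulate, summarize

#: acute-phase CRP elevation used for the patient serum and high-CRP checks
HIGH_CRP_SCALE = 10.0

PATIENT = dict(pH=6.5, calcium=2.0, crp_scale=HIGH_CRP_SCALE)
NORMAL = dict(pH=7.4, calcium=2.5)

C3_READOUT = "C3_dep"


@dataclass
class ScenarioReport:
    scenario: str
    conditions: dict = field(default_factory=dict)   # name -> condition fields
    results: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def to_dict(self):
        return {"scenario": self.scenario, "conditions": self.conditions,
                "results": self.results, "flags": self.flags}


def _theta_net(network: ReactionNetwork, theta: dict | None):
    net = network.copy()
    for p, v in (theta or {}).items():
        net.set_param(p, v)
    return net


def _readout(net):
    return net.observables.get(C3_READOUT, C3_READOUT)


def _cond_dict(c: Condition):
    return {"initiation": c.initiation, "pH": c.pH, "calcium": c.calcium,
            "c4bp_scale": c.c4bp_scale, "crp_scale": c.crp_scale,
            "depleted": sorted(c.depleted), "knockouts": sorted(c.knockouts),
            "competition_mode": c.competition_mode}


# ---------------------------------------------------------------------------

def killing_panel_conditions() -> dict:
    """{patient, normal} x {whole, CRP-, ficolin-, both-} plus high-CRP."""
    out = {}
    for serum, base in (("patient", PATIENT), ("normal", NORMAL)):
        out[f"{serum}_whole"] = Condition(**base)
        out[f"{serum}_crp_depleted"] = Condition(
            **base, depleted=frozenset({"CRP"}))
        out[f"{serum}_ficolin_depleted"] = Condition(
            **base, depleted=frozenset({"L-ficolin"}))
        out[f"{serum}_both_depleted"] = Condition(
            **base, depleted=frozenset({"CRP", "L-ficolin"}))
    out["normal_high_crp"] = Condition(**NORMAL | {"crp_scale": HIGH_CRP_SCALE})
    return out


def run_killing_panel(network: ReactionNetwork, theta: dict | None = None,
                      endpoint_s: float = 3600.0,
                      affinity_model=None) -> ScenarioReport:
    """Deposited C3 at the endpoint across the serum/depletion panel,
    normalised so the panel maximum equals a 95% killing rate."""
    net = _theta_net(network, theta)
    aff = affinity_model or default_affinity_model()
    grid = TimeGrid.regular(endpoint_s, 100.0)
    conds = killing_panel_conditions()
    endpoints = {}
    for name, cond in conds.items():
        tr = simulate(apply_condition(net, cond, aff), grid)
        endpoints[name] = float(tr.series(_readout(net))[-1])
    rates, argmax = killing_panel(endpoints)
    # synergy diagnostic: share of the patient killing not explained by the
    # two single pathways (reported, not asserted)
    synergy = (rates["patient_whole"] - rates["patient_crp_depleted"]
               - rates["patient_ficolin_depleted"]
               + rates["patient_both_depleted"]) / rates["patient_whole"]
    return ScenarioReport(
        scenario="killing_panel",
        conditions={k: _cond_dict(c) for k, c in conds.items()},
        results={"endpoint_nM": endpoints, "rates_percent": rates},
        flags={"argmax_condition": argmax,
               "crosstalk_share_of_patient_killing": synergy,
               "endpoint_s": endpoint_s})


def run_ph_ca_grid(network: ReactionNetwork, theta: dict | None = None,
                   ph_values=None, calcium_values=(2.0, 2.5),
                   horizon_s: float = 12600.0,
                   dose_response_endpoint_s: float = 5400.0,
                   affinity_model=None) -> ScenarioReport:
    """C3-deposition profiles across a pH x calcium grid plus the 1.5 h
    endpoint dose-response curves."""
    net = _theta_net(network, theta)
    aff = affinity_model or default_affinity_model()
    ph_values = list(ph_values if ph_values is not None
                     else np.round(np.arange(5.5, 7.45, 0.1), 2))
    grid = TimeGrid.regular(horizon_s, 100.0)
    e_idx = grid.index_of(dose_response_endpoint_s)
    profiles = {}
    summaries = {}
    dose_response = {ca: [] for ca in calcium_values}
    for ca in calcium_values:
        for ph in ph_values:
            cond = Condition(pH=float(ph), calcium=float(ca),
                             crp_scale=HIGH_CRP_SCALE)
            tr = simulate(apply_condition(net, cond, aff), grid)
            y = tr.series(_readout(net))
            st = summarize(tr, _readout(net))
            key = f"pH{ph}_Ca{ca}"
            profiles[key] = y.tolist()
            summaries[key] = st.to_dict()
            dose_response[ca].append(float(y[e_idx]))
    return ScenarioReport(
        scenario="ph_ca_grid",
        conditions={"pH": list(map(float, ph_values)),
                    "calcium_mM": list(map(float, calcium_values))},
        results={"summaries": summaries,
                 "dose_response": {str(k): v for k, v in dose_response.items()},
                 "grid_s": list(grid.points), "profiles": profiles},
        flags={"dose_response_endpoint_s": dose_response_endpoint_s})


def run_c4bp_titration(network: ReactionNetwork, theta: dict | None = None,
                       initiation: str = "PC",
                       c4bp_scales=(0.5, 1.0, 2.0),
                       horizon_s: float = 18000.0,
                       affinity_model=None) -> ScenarioReport:
    """Vary initial C4BP around its plasma level under inflammation and
    summarise the C3-deposition response (5 h horizon)."""
    net = _theta_net(network, theta)
    aff = affinity_model or default_affinity_model()
    grid = TimeGrid.regular(horizon_s, 100.0)
    base = {k: v for k, v in PATIENT.items()}
    rows = {}
    for s in c4bp_scales:
        if s < 0:
            raise ModelError("c4bp_scale must be >= 0")
        cond = Condition(**base, initiation=initiation, c4bp_scale=float(s))
        tr = simulate(apply_condition(net, cond, aff), grid)
        rows[s] = summarize(tr, _readout(net)).to_dict()
    scales = sorted(rows)
    pt = [rows[s]["peak_time"] for s in scales]
    pa = [rows[s]["peak_amplitude"] for s in scales]
    return ScenarioReport(
        scenario=f"c4bp_titration_{initiation}",
        conditions={"initiation": initiation, "c4bp_scales": list(scales),
                    **base},
        results={"summaries": {str(s): rows[s] for s in scales}},
        flags={"peak_time_increasing": bool(np.all(np.diff(pt) > 0)),
               "amplitude_rel_spread": float((max(pa) - min(pa)) / max(pa)),
               "peak_time_spread_s": float(max(pt) - min(pt))})


def run_knockouts(network: ReactionNetwork, theta: dict | None = None,
                  initiation: str = "PC", horizon_s: float = 12600.0,
                  affinity_model=None) -> ScenarioReport:
    """Baseline + single knockouts of the four C4BP mechanisms; AUC deltas of
    C3 deposition and the maximal enhancer flag."""
    net = _theta_net(network, theta)
    aff = affinity_model or default_affinity_model()
    grid = TimeGrid.regular(horizon_s, 100.0)
    base = dict(PATIENT, initiation=initiation)
    aucs = {}
    for ko in ("baseline", "a", "b", "c", "d"):
        kos = frozenset() if ko == "baseline" else frozenset({ko})
        cond = Condition(**base, knockouts=kos)
        tr = simulate(apply_condition(net, cond, aff), grid)
        aucs[ko] = summarize(tr, _readout(net)).integrated_response
    deltas = {k: aucs[k] - aucs["baseline"] for k in ("a", "b", "c", "d")}
    return ScenarioReport(
        scenario=f"knockouts_{initiation}",
        conditions={"initiation": initiation, **base},
        results={"auc": aucs, "auc_delta": deltas},
        flags={"max_enhancer": max(deltas, key=deltas.get)})


def run_competition_variants(network: ReactionNetwork,
                             theta: dict | None = None,
                             horizon_s: float = 12600.0,
                             affinity_sweep=(1.0, 3.0, 10.0, 30.0, 100.0),
                             affinity_model=None) -> ScenarioReport:
    """Simultaneous-binding vs competitive-binding crosstalk under
    inflammation, plus a sweep of the crosstalk strength for the competitive
    variant (classifying no-effect / up- / down-regulation)."""
    net = _theta_net(network, theta)
    aff = affinity_model or default_affinity_model()
    grid = TimeGrid.regular(horizon_s, 100.0)

    def auc(cond):
        tr = simulate(apply_condition(net, cond, aff), grid)
        return summarize(tr, _readout(net)).integrated_response

    results = {
        "normal_simultaneous": auc(Condition(**NORMAL)),
        "normal_competitive": auc(Condition(**NORMAL, competition_mode=True)),
        "patient_simultaneous": auc(Condition(**PATIENT)),
        "patient_competitive": auc(Condition(**PATIENT,
                                             competition_mode=True)),
    }
    # sweep crosstalk strength in the competitive variant by scaling the
    # crosstalk on-rates directly (strength 1 = no crosstalk enhancement)
    sweep = {}
    base_norm = results["normal_competitive"]
    for s in affinity_sweep:
        net_s = net.copy()
        for p in net_s.hooks.crosstalk_params:
            net_s.set_param(p, net_s.params[p].value * s)
        cond = Condition(**NORMAL, competition_mode=True)
        tr = simulate(apply_condition(net_s, cond, aff), grid)
        a = summarize(tr, _readout(net_s)).integrated_response
        rel = (a - base_norm) / base_norm
        cls = "no_effect" if abs(rel) < 0.02 else ("up" if rel > 0 else "down")
        sweep[s] = {"auc": a, "relative_change": rel, "class": cls}
    enh_sim = results["patient_simultaneous"] / results["normal_simultaneous"]
    enh_comp = results["patient_competitive"] / results["normal_competitive"]
    return ScenarioReport(
        scenario="competition_variants",
        conditions={"affinity_sweep": list(affinity_sweep)},
        results={"auc": results, "sweep": {str(k): v for k, v in sweep.items()}},
        flags={"enhancement_simultaneous": enh_sim,
               "enhancement_competitive": enh_comp,
               "competitive_reduces_enhancement": enh_comp < enh_sim,
               "sweep_classes": sorted({v["class"] for v in sweep.values()})})
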