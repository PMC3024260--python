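"""Model, dataset and report I/O.

Models are stored in a native YAML dialect (species / parameters / reactions
blocks) with lossless import/export to a restricted SBML Level 3 subset
covering mass-action and Michaelis-Menten kinetic laws.  Metadata that SBML
has no native slot for (parameter bounds and known flags, reaction tags,
conservation groups, condition hooks) travels in a single JSON annotation
element so the round trip is exact.
"""

from __future__ import annotations

import json
import pathlib
import xml.etree.ElementTree as ET

import numpy as np
import pandas as pd
import yaml

from .model_core import (MASS_ACTION, MICHAELIS_MENTEN, ModelError,
                         ReactionNetwork, build_network)

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_TAG = "compdbnModelMetadata"


# ---------------------------------------------------------------------------
# native YAML dialect
# ---------------------------------------------------------------------------

def network_to_spec(network: ReactionNetwork) -> dict:
    """Serialise a network back to the model-spec dictionary form."""
    spec: dict = {"name": network.name}
    spec["counts"] = {
        "species": len(network.species),
        "reactions": len(network.reactions),
        "parameters": len(network.params),
        "unknown": len(network.params.unknown_names),
    }
    spec["species"] = [
        {"name": s.name, "role": s.role, "initial": float(s.initial_concentration)}
        for s in network.species
    ]
    spec["parameters"] = []
    for name, e in network.params.items():
        d: dict = {"name": name}
        if e.value is not None:
            d["value"] = float(e.value)
        if e.known:
            d["known"] = True
        if e.bounds is not None:
            d["bounds"] = [float(e.bounds[0]), float(e.bounds[1])]
        spec["parameters"].append(d)
    spec["reactions"] = []
    for r in network.reactions:
        law = {"kind": r.rate_law.kind}
        if r.rate_law.kind == MASS_ACTION:
            law["k"] = r.rate_law.k
            if r.reversible:
                law["k_reverse"] = r.k_reverse
        else:
            law["c"] = r.rate_law.c
            law["c_half"] = r.rate_law.c_half
        d = {"id": r.id,
             "reactants": [sp if e == 1 else {"species": sp, "stoich": e}
                           for sp, e in r.reactants],
             "products": [sp if e == 1 else {"species": sp, "stoich": e}
                          for sp, e in r.products],
             "law": law}
        if r.modifiers:
            d["modifiers"] = list(r.modifiers)
        if r.reversible:
            d["reversible"] = True
        if r.tags:
            d["tags"] = sorted(r.tags)
        spec["reactions"].append(d)
    if network.conservation:
        spec["conservation"] = {g: dict(m) for g, m in network.conservation.items()}
    if network.observables:
        spec["observables"] = dict(network.observables)
    h = network.hooks
    if h.crosstalk_params or h.recruitment or h.branch_species:
        spec["hooks"] = {"crosstalk": list(h.crosstalk_params),
                         "recruitment": dict(h.recruitment),
                         "branches": dict(h.branch_species)}
    return spec


def write_model_yaml(network: ReactionNetwork, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_spec(network), fh, sort_keys=False)


def read_model(path) -> ReactionNetwork:
    """Read a model file, autodetecting YAML vs SBML."""
    path = pathlib.Path(path)
    head = path.read_text()[:200].lstrip()
    if head.startswith("<?xml") or head.startswith("<sbml"):
        return read_sbml(path)
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return build_network(spec)


# ---------------------------------------------------------------------------
# SBML level 3 (restricted subset)
# ---------------------------------------------------------------------------

def _mathml_ci(name):
    el = ET.Element(f"{{{MATHML_NS}}}ci")
    el.text = f" {name} "
    return el


def _mathml_times(names):
    ap = ET.Element(f"{{{MATHML_NS}}}apply")
    ET.SubElement(ap, f"{{{MATHML_NS}}}times")
    for n in names:
        ap.append(_mathml_ci(n))
    return ap


def _law_math(r) -> ET.Element:
    """MathML for the reaction's kinetic law (our two supported forms)."""
    if r.rate_law.kind == MASS_ACTION:
        fwd = _mathml_times([r.rate_law.k] + [sp for sp, e in r.reactants
                                              for _ in range(e)])
        if not r.reversible:
            return fwd
        back = _mathml_times([r.k_reverse] + [sp for sp, e in r.products
                                              for _ in range(e)])
        ap = ET.Element(f"{{{MATHML_NS}}}apply")
        ET.SubElement(ap, f"{{{MATHML_NS}}}minus")
        ap.append(fwd)
        ap.append(back)
        return ap
    sub = r.reactants[0][0]
    top = _mathml_times([r.rate_law.c, r.modifiers[0], sub])
    den = ET.Element(f"{{{MATHML_NS}}}apply")
    ET.SubElement(den, f"{{{MATHML_NS}}}plus")
    den.append(_mathml_ci(r.rate_law.c_half))
    den.append(_mathml_ci(sub))
    ap = ET.Element(f"{{{MATHML_NS}}}apply")
    ET.SubElement(ap, f"{{{MATHML_NS}}}divide")
    ap.append(top)
    ap.append(den)
    return ap


def write_sbml(network: ReactionNetwork, path) -> None:
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": network.name})

    spec = network_to_spec(network)
    meta = {"parameters": spec["parameters"],
            "species_roles": {s.name: s.role for s in network.species},
            "tags": {r.id: sorted(r.tags) for r in network.reactions if r.tags},
            "conservation": spec.get("conservation", {}),
            "observables": spec.get("observables", {}),
            "hooks": spec.get("hooks", {}),
            "counts": spec["counts"]}
    annot = ET.SubElement(model, f"{{{SBML_NS}}}annotation")
    annot_el = ET.SubElement(annot, ANNOT_TAG)
    annot_el.text = json.dumps(meta)

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                  {"id": "serum", "constant": "true", "size": "1"})
    lspecies = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for s in network.species:
        ET.SubElement(lspecies, f"{{{SBML_NS}}}species",
                      {"id": s.name, "compartment": "serum",
                       "initialConcentration": repr(s.initial_concentration),
                       "hasOnlySubstanceUnits": "false",
                       "boundaryCondition": "false", "constant": "false"})
    lparams = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for name, e in network.params.items():
        attrs = {"id": name, "constant": "true"}
        if e.value is not None:
            attrs["value"] = repr(float(e.value))
        ET.SubElement(lparams, f"{{{SBML_NS}}}parameter", attrs)
    lreact = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for r in network.reactions:
        rel = ET.SubElement(lreact, f"{{{SBML_NS}}}reaction",
                            {"id": r.id,
                             "reversible": "true" if r.reversible else "false"})
        lre = ET.SubElement(rel, f"{{{SBML_NS}}}listOfReactants")
        for sp, e in r.reactants:
            ET.SubElement(lre, f"{{{SBML_NS}}}speciesReference",
                          {"species": sp, "stoichiometry": str(e),
                           "constant": "true"})
        lpr = ET.SubElement(rel, f"{{{SBML_NS}}}listOfProducts")
        for sp, e in r.products:
            ET.SubElement(lpr, f"{{{SBML_NS}}}speciesReference",
                          {"species": sp, "stoichiometry": str(e),
                           "constant": "true"})
        if r.modifiers:
            lmo = ET.SubElement(rel, f"{{{SBML_NS}}}listOfModifiers")
            for m in r.modifiers:
                ET.SubElement(lmo, f"{{{SBML_NS}}}modifierSpeciesReference",
                              {"species": m})
        klaw = ET.SubElement(rel, f"{{{SBML_NS}}}kineticLaw")
        math = ET.SubElement(klaw, f"{{{MATHML_NS}}}math")
        math.append(_law_math(r))
    ET.ElementTree(sbml).write(path, xml_declaration=True, encoding="unicode")


def _strip(tag):
    return tag.rsplit("}", 1)[-1]


def _parse_times(apply_el):
    """Parse <apply><times/><ci>...</ci>...</apply> -> list of names."""
    kids = list(apply_el)
    if _strip(kids[0].tag) != "times":
        raise ModelError("unsupported kinetic law (expected a product)")
    names = []
    for el in kids[1:]:
        if _strip(el.tag) != "ci":
            raise ModelError("unsupported kinetic law (non-ci factor)")
        names.append(el.text.strip())
    return names


def read_sbml(path) -> ReactionNetwork:
    tree = ET.parse(path)
    model = tree.getroot().find(f"{{{SBML_NS}}}model")
    if model is None:
        raise ModelError("no <model> element found")
    annot = model.find(f"{{{SBML_NS}}}annotation/{{{SBML_NS}}}{ANNOT_TAG}")
    if annot is None:
        annot = model.find(f"{{{SBML_NS}}}annotation/{ANNOT_TAG}")
    meta = json.loads(annot.text) if annot is not None else {}
    roles = meta.get("species_roles", {})
    tags = meta.get("tags", {})

    spec: dict = {"name": model.get("id", "network")}
    spec["species"] = [
        {"name": s.get("id"), "role": roles.get(s.get("id"), "fluid-phase"),
         "initial": float(s.get("initialConcentration", 0.0))}
        for s in model.find(f"{{{SBML_NS}}}listOfSpecies")
    ]
    if "parameters" in meta:
        spec["parameters"] = meta["parameters"]
    else:
        spec["parameters"] = [
            {"name": p.get("id"), "value": float(p.get("value")),
             "known": True}
            for p in model.find(f"{{{SBML_NS}}}listOfParameters")
        ]
    spec["reactions"] = []
    for rel in model.find(f"{{{SBML_NS}}}listOfReactions"):
        rid = rel.get("id")
        reversible = rel.get("reversible") == "true"

        def _side(tag):
            lst = rel.find(f"{{{SBML_NS}}}{tag}")
            out = []
            for ref in lst if lst is not None else ():
                e = int(float(ref.get("stoichiometry", 1)))
                sp = ref.get("species")
                out.append(sp if e == 1 else {"species": sp, "stoich": e})
            return out

        modifiers = [m.get("species") for m in
                     rel.find(f"{{{SBML_NS}}}listOfModifiers") or ()]
        math = rel.find(f"{{{SBML_NS}}}kineticLaw/{{{MATHML_NS}}}math")
        top = list(math)[0]
        op = _strip(list(top)[0].tag) if _strip(top.tag) == "apply" else None
        if op == "times":  # irreversible mass action
            names = _parse_times(top)
            law = {"kind": MASS_ACTION, "k": names[0]}
        elif op == "minus":  # reversible mass action
            fwd, back = list(top)[1], list(top)[2]
            law = {"kind": MASS_ACTION, "k": _parse_times(fwd)[0],
                   "k_reverse": _parse_times(back)[0]}
        elif op == "divide":  # Michaelis-Menten
            num, den = list(top)[1], list(top)[2]
            names = _parse_times(num)
            den_kids = list(den)
            if _strip(den_kids[0].tag) != "plus":
                raise ModelError(f"reaction {rid!r}: unsupported kinetic law")
            law = {"kind": MICHAELIS_MENTEN, "c": names[0],
                   "c_half": den_kids[1].text.strip()}
        else:
            raise ModelError(f"reaction {rid!r}: unsupported kinetic law")
        d = {"id": rid, "reactants": _side("listOfReactants"),
             "products": _side("listOfProducts"), "law": law}
        if modifiers:
            d["modifiers"] = modifiers
        if reversible:
            d["reversible"] = True
        if rid in tags:
            d["tags"] = tags[rid]
        spec["reactions"].append(d)
    for key in ("conservation", "observables", "hooks", "counts"):
        if meta.get(key):
            spec[key] = meta[key]
    return build_network(spec)


# ---------------------------------------------------------------------------
# time-series datasets and reports
# ---------------------------------------------------------------------------

DATASET_COLUMNS = ["condition", "species", "time_s", "value", "weight"]


def read_timeseries(path):
    """Read a calibration dataset CSV -> :class:`compdbn.estimate.Dataset`."""
    from .estimate import Dataset

    df = pd.read_csv(path)
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ModelError(f"dataset missing columns {sorted(missing)}")
    if (df["value"] < 0).any():
        raise ModelError("dataset contains negative concentrations")
    observations = {}
    weights = {}
    for row in df.itertuples(index=False):
        observations[(row.condition, row.species, float(row.time_s))] = float(row.value)
        weights[row.species] = float(row.weight)
    return Dataset(observations=observations, weights=weights)


def write_timeseries(dataset, path) -> None:
    rows = [{"condition": c, "species": s, "time_s": t, "value": v,
             "weight": dataset.weights.get(s, 1.0)}
            for (c, s, t), v in dataset.observations.items()]
    pd.DataFrame(rows, columns=DATASET_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def read_affinity_anchors(path):
    """Read a (pH, calcium_mM, affinity) anchor table CSV -> list of tuples
    suitable for :func:`compdbn.model_core.fit_affinity`."""
    df = pd.read_csv(path)
    missing = {"pH", "calcium_mM", "affinity"} - set(df.columns)
    if missing:
        raise ModelError(f"anchor table missing columns {sorted(missing)}")
    return [(float(r.pH), float(r.calcium_mM), float(r.affinity))
            for r in df.itertuples(index=False)]


def trajectory_to_frame(trajectory, species_names) -> pd.DataFrame:
    """Tidy (time_s, species, concentration_nM) export of a trajectory."""
    t = np.asarray(trajectory.grid.points)
    recs = []
    for i, sp in enumerate(species_names):
        for j, tj in enumerate(t):
            recs.append((tj, sp, trajectory.values[i, j]))
    return pd.DataFrame(recs, columns=["time_s", "species", "concentration_nM"])


def write_report(report, path) -> None:
    """Write a JSON report (dict or dataclass-like with to_dict())."""
    if hasattr(report, "to_dict"):
        report = report.to_dict()

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o).__name__)

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)
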