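"""Genome-scale metabolic model (GEM) container and readers/writers.

A GEM here is the minimal structure constraint-based analysis needs: a
stoichiometric matrix S (metabolites x reactions), per-reaction flux bounds
in mmol gDW^-1 h^-1, one objective (the biomass reaction), and a registry of
exchange reactions — boundary reactions with single-metabolite stoichiometry
whose negative flux is uptake.

Two on-disk formats are supported: a native JSON schema deliberately
compatible with the cobrapy JSON layout (so toy models round-trip through
other tools), and the SBML Level 3 ``fbc`` subset (species, reactions,
stoichiometry, flux bounds, objectives) via libsbml.  Unknown SBML
constructs are ignored with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["GEM", "load_gem", "builtin_gem", "save_gem_json", "save_gem_sbml", "BUILTIN_GEMS"]

#: Packaged toy models: linear chain, branched biomass, parallel pathways,
#: redundant substrates, and three strain-like essentiality patterns
#: (am_like: three essential inputs; bt_like: two limiting substrate pools;
#: fp_like: three essential inputs with a redundant energy pool).
BUILTIN_GEMS = (
    "toynet_linear",
    "toynet_branch",
    "toynet_parallel",
    "toynet_redundant",
    "am_like",
    "bt_like",
    "fp_like",
)


@dataclass
class GEM:
    """Stoichiometric model with bounds and a biomass objective."""

    metabolites: list[str]
    reactions: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    objective: np.ndarray
    model_id: str = "model"
    exchanges: dict[str, str] = field(default_factory=dict)  # reaction -> metabolite

    def __post_init__(self) -> None:
        m, n = len(self.metabolites), len(self.reactions)
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.objective = np.asarray(self.objective, dtype=float)
        if self.S.shape != (m, n):
            raise ValueError(f"S has shape {self.S.shape}, expected ({m}, {n})")
        if self.lb.shape != (n,) or self.ub.shape != (n,) or self.objective.shape != (n,):
            raise ValueError("bounds/objective length must equal the number of reactions")
        bad = np.where(self.lb > self.ub)[0]
        if bad.size:
            names = [self.reactions[i] for i in bad]
            raise ValueError(f"lower bound exceeds upper bound for reactions: {names}")
        if not np.any(self.objective):
            raise ValueError("model has no objective (no nonzero objective coefficient)")
        zero_stoich = [self.reactions[j] for j in range(n) if not np.any(self.S[:, j])]
        if zero_stoich:
            raise ValueError(f"reactions with empty stoichiometry: {zero_stoich}")
        if not self.exchanges:
            self.exchanges = self._detect_exchanges()

    def _detect_exchanges(self) -> dict[str, str]:
        out = {}
        for j, rxn in enumerate(self.reactions):
            nz = np.nonzero(self.S[:, j])[0]
            if nz.size == 1:
                out[rxn] = self.metabolites[nz[0]]
        return out

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def reaction_index(self, rxn: str) -> int:
        try:
            return self.reactions.index(rxn)
        except ValueError:
            raise KeyError(f"no reaction {rxn!r} in model {self.model_id!r}") from None

    def exchange_for_metabolite(self, metabolite: str) -> str:
        for rxn, met in self.exchanges.items():
            if met == metabolite:
                return rxn
        raise KeyError(f"no exchange reaction for metabolite {metabolite!r}")

    def with_bounds(self, rxn: str, lb: float, ub: float) -> "GEM":
        """A copy with one reaction's bounds replaced."""
        j = self.reaction_index(rxn)
        new_lb, new_ub = self.lb.copy(), self.ub.copy()
        new_lb[j], new_ub[j] = lb, ub
        return replace(self, lb=new_lb, ub=new_ub)

    def copy(self) -> "GEM":
        return replace(self, S=self.S.copy(), lb=self.lb.copy(), ub=self.ub.copy(),
                       objective=self.objective.copy(), exchanges=dict(self.exchanges))


def load_gem(path, fmt: str | None = None) -> GEM:
    """Load a GEM from native JSON or SBML-fbc; format inferred from suffix."""
    path = Path(path)
    if fmt is None:
        fmt = {"json": "json", "xml": "sbml", "sbml": "sbml"}.get(path.suffix.lstrip("."))
    if fmt == "json":
        return _load_json(path)
    if fmt == "sbml":
        return _load_sbml(path)
    raise ValueError(f"cannot infer GEM format from {path.name!r}; pass fmt='json' or 'sbml'")


def builtin_gem(name: str) -> GEM:
    """Load one of the packaged toy GEMs by name (see ``BUILTIN_GEMS``)."""
    from importlib import resources

    if name not in BUILTIN_GEMS:
        raise ValueError(f"unknown builtin GEM {name!r}; valid: {', '.join(BUILTIN_GEMS)}")
    ref = resources.files("calorimix.data") / "gems" / f"{name}.json"
    with resources.as_file(ref) as path:
        return load_gem(path)


def _load_json(path: Path) -> GEM:
    doc = json.loads(Path(path).read_text())
    met_ids = [m["id"] if isinstance(m, dict) else m for m in doc["metabolites"]]
    met_idx = {m: i for i, m in enumerate(met_ids)}
    rxns = doc["reactions"]
    rxn_ids = [r["id"] for r in rxns]
    S = np.zeros((len(met_ids), len(rxn_ids)))
    lb = np.zeros(len(rxn_ids))
    ub = np.zeros(len(rxn_ids))
    obj = np.zeros(len(rxn_ids))
    for j, r in enumerate(rxns):
        for met, coeff in r["metabolites"].items():
            if met not in met_idx:
                raise ValueError(f"reaction {r['id']!r} references unknown metabolite {met!r}")
            S[met_idx[met], j] = coeff
        lb[j] = r.get("lower_bound", -1000.0)
        ub[j] = r.get("upper_bound", 1000.0)
        obj[j] = r.get("objective_coefficient", 0.0)
    return GEM(
        metabolites=met_ids, reactions=rxn_ids, S=S, lb=lb, ub=ub, objective=obj,
        model_id=doc.get("id", path.stem),
    )


def _load_sbml(path: Path) -> GEM:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(f"SBML parse errors in {path}: {doc.getErrorLog().toString()}")
    model = doc.getModel()
    if model is None:
        raise ValueError(f"{path} contains no SBML model")
    fbc = model.getPlugin("fbc")

    met_ids = [model.getSpecies(i).getId() for i in range(model.getNumSpecies())]
    met_idx = {m: i for i, m in enumerate(met_ids)}
    n = model.getNumReactions()
    rxn_ids, lb, ub = [], np.zeros(n), np.zeros(n)
    S = np.zeros((len(met_ids), n))
    obj = np.zeros(n)

    params = {
        model.getParameter(i).getId(): model.getParameter(i).getValue()
        for i in range(model.getNumParameters())
    }
    for j in range(n):
        rxn = model.getReaction(j)
        rxn_ids.append(rxn.getId())
        for i in range(rxn.getNumReactants()):
            sr = rxn.getReactant(i)
            S[met_idx[sr.getSpecies()], j] -= sr.getStoichiometry()
        for i in range(rxn.getNumProducts()):
            sr = rxn.getProduct(i)
            S[met_idx[sr.getSpecies()], j] += sr.getStoichiometry()
        rfbc = rxn.getPlugin("fbc")
        if rfbc is not None and rfbc.isSetLowerFluxBound():
            lb[j] = params[rfbc.getLowerFluxBound()]
            ub[j] = params[rfbc.getUpperFluxBound()]
        else:
            warnings.warn(f"reaction {rxn.getId()!r} has no fbc bounds; using [-1000, 1000]")
            lb[j], ub[j] = -1000.0, 1000.0
    if fbc is None or fbc.getNumObjectives() == 0:
        raise ValueError(f"{path}: SBML model has no fbc objective")
    active = fbc.getActiveObjective()
    for i in range(active.getNumFluxObjectives()):
        fo = active.getFluxObjective(i)
        obj[rxn_ids.index(fo.getReaction())] = fo.getCoefficient()
    return GEM(
        metabolites=met_ids, reactions=rxn_ids, S=S, lb=lb, ub=ub, objective=obj,
        model_id=model.getId() or path.stem,
    )


def save_gem_json(gem: GEM, path) -> None:
    """Write a GEM to the native (cobrapy-compatible) JSON layout."""
    doc = {
        "id": gem.model_id,
        "version": "1",
        "metabolites": [{"id": m, "compartment": "e" if m.endswith("_e") else "c"} for m in gem.metabolites],
        "reactions": [
            {
                "id": rxn,
                "name": rxn,
                "metabolites": {
                    gem.metabolites[i]: float(gem.S[i, j]) for i in np.nonzero(gem.S[:, j])[0]
                },
                "lower_bound": float(gem.lb[j]),
                "upper_bound": float(gem.ub[j]),
                "objective_coefficient": float(gem.objective[j]),
                "gene_reaction_rule": "",
            }
            for j, rxn in enumerate(gem.reactions)
        ],
        "genes": [],
        "compartments": {"c": "cytosol", "e": "extracellular"},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def save_gem_sbml(gem: GEM, path) -> None:
    """Write a GEM as SBML Level 3 with the fbc (version 2) package."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(gem.model_id)
    mplug = model.getPlugin("fbc")
    mplug.setStrict(True)

    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    for m in gem.metabolites:
        sp = model.createSpecies()
        sp.setId(m)
        sp.setCompartment("c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    bound_params = {}

    def bound_param(value: float) -> str:
        key = f"b_{value}".replace("-", "m").replace(".", "_")
        if key not in bound_params:
            par = model.createParameter()
            par.setId(key)
            par.setValue(float(value))
            par.setConstant(True)
            bound_params[key] = value
        return key

    for j, rxn_id in enumerate(gem.reactions):
        rxn = model.createReaction()
        rxn.setId(rxn_id)
        rxn.setFast(False)
        rxn.setReversible(bool(gem.lb[j] < 0))
        for i in np.nonzero(gem.S[:, j])[0]:
            coeff = gem.S[i, j]
            sr = rxn.createReactant() if coeff < 0 else rxn.createProduct()
            sr.setSpecies(gem.metabolites[i])
            sr.setStoichiometry(abs(float(coeff)))
            sr.setConstant(True)
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(gem.lb[j]))
        rplug.setUpperFluxBound(bound_param(gem.ub[j]))

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    for j in np.nonzero(gem.objective)[0]:
        fo = objective.createFluxObjective()
        fo.setReaction(gem.reactions[j])
        fo.setCoefficient(float(gem.objective[j]))
    mplug.setActiveObjectiveId("obj")
    libsbml.writeSBMLToFile(doc, str(path))
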