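"""Stoichiometric model container and I/O.

Models are held as a light dataclass around a sparse stoichiometric matrix;
SBML and JSON reading/writing go through cobrapy.  The shipped fixture
``ecoli_central`` is a curated central E. coli network (glycolysis + PTS,
pentose phosphate pathway, TCA cycle, anaplerosis, lumped oxidative
phosphorylation, fermentative secretion routes, exchanges and a lumped
biomass drain); its composition is documented inside the fixture file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

FIXTURES = ("ecoli_central",)

#: map between kinetic-model metabolite ids (mM namespace) and fixture
#: network metabolite ids
KINETIC_TO_NETWORK_MET = {
    "glc": "glc__D_e", "g6p": "g6p_c", "f6p": "f6p_c", "fdp": "fdp_c",
    "dhap": "dhap_c", "gap": "gap_c", "13dpg": "13dpg_c", "3pg": "3pg_c",
    "2pg": "2pg_c", "pep": "pep_c", "pyr": "pyr_c", "6pg": "6pg_c",
    "ru5pD": "ru5pD_c", "xu5pD": "xu5pD_c", "r5p": "r5p_c", "s7p": "s7p_c",
    "e4p": "e4p_c", "atp": "atp_c", "adp": "adp_c", "amp": "amp_c",
    "nad": "nad_c", "nadh": "nadh_c", "nadp": "nadp_c", "nadph": "nadph_c",
}


class ModelValidationError(ValueError):
    pass


@dataclass
class StoichiometricModel:
    """Sparse stoichiometric model with flux bounds and designations.

    ``S`` is metabolites x reactions; flux bounds are in mmol/gDW/h.
    """

    metabolites: list[str]
    reactions: list[str]
    S: sparse.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    reversible: np.ndarray
    biomass_rxn: str
    glucose_uptake_rxn: str
    kinetic_rxns: list[str] = field(default_factory=list)
    fermentation_rxns: list[str] = field(default_factory=list)
    compartments: dict[str, str] = field(default_factory=dict)
    reaction_names: dict[str, str] = field(default_factory=dict)
    metabolite_names: dict[str, str] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self._rxn_index = {r: j for j, r in enumerate(self.reactions)}
        self._met_index = {m: i for i, m in enumerate(self.metabolites)}
        self.validate()

    # -- lookups ----------------------------------------------------------
    def rxn_index(self, rxn_id: str) -> int:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction {rxn_id!r}") from None

    def met_index(self, met_id: str) -> int:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite {met_id!r}") from None

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def bounds_array(self) -> list[tuple[float, float]]:
        return list(zip(self.lb, self.ub))

    def reaction_stoichiometry(self, rxn_id: str) -> dict[str, float]:
        j = self.rxn_index(rxn_id)
        col = self.S.getcol(j).tocoo()
        return {self.metabolites[i]: v for i, v in zip(col.row, col.data)}

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        nm, nr = self.S.shape
        if nm != len(self.metabolites) or nr != len(self.reactions):
            raise ModelValidationError("S shape does not match id lists")
        if nr == 0:
            raise ModelValidationError("model has zero reactions")
        if np.any(self.lb > self.ub):
            bad = [self.reactions[j]
                   for j in np.nonzero(self.lb > self.ub)[0]]
            raise ModelValidationError(f"lb > ub for {bad}")
        irrev = ~self.reversible
        if np.any(self.lb[irrev] < 0):
            bad = [self.reactions[j] for j in np.nonzero(irrev)[0]
                   if self.lb[j] < 0]
            raise ModelValidationError(
                f"irreversible reactions with lb < 0: {bad}")
        for rid in (self.biomass_rxn, self.glucose_uptake_rxn):
            if rid not in self._rxn_index:
                raise ModelValidationError(
                    f"designated reaction {rid!r} not in model")
        for rid in self.kinetic_rxns:
            if rid not in self._rxn_index:
                raise ModelValidationError(
                    f"kinetic reaction {rid!r} not in model")

    # -- manipulation -----------------------------------------------------
    def copy(self) -> "StoichiometricModel":
        return replace(self, lb=self.lb.copy(), ub=self.ub.copy(),
                       reversible=self.reversible.copy(), S=self.S.copy(),
                       kinetic_rxns=list(self.kinetic_rxns),
                       fermentation_rxns=list(self.fermentation_rxns))

    def with_growth_rate(self, rate: float) -> "StoichiometricModel":
        m = self.copy()
        j = m.rxn_index(m.biomass_rxn)
        m.lb[j] = m.ub[j] = rate
        return m


def block_reactions(model: StoichiometricModel,
                    rxn_ids) -> StoichiometricModel:
    """Return a copy with lb = ub = 0 for every listed reaction."""
    out = model.copy()
    for rid in rxn_ids:
        j = out.rxn_index(rid)
        out.lb[j] = out.ub[j] = 0.0
    return out


def block_fermentation(model: StoichiometricModel) -> StoichiometricModel:
    return block_reactions(model, model.fermentation_rxns)


# --------------------------------------------------------------------------
# cobra converters and I/O
# --------------------------------------------------------------------------

def from_cobra(cm, biomass_rxn: str | None = None,
               glucose_uptake_rxn: str | None = None) -> StoichiometricModel:
    """Convert a cobra.Model, reading designations from model notes."""
    from cobra.util.array import create_stoichiometric_matrix

    notes = {k: str(v) for k, v in (cm.notes or {}).items()}
    if biomass_rxn is None:
        biomass_rxn = notes.get("biomass_rxn")
    if biomass_rxn is None:
        # fall back to the objective reaction
        obj = [r.id for r in cm.reactions
               if r.objective_coefficient not in (0, None)]
        if not obj:
            raise ModelValidationError(
                "no biomass reaction designated (notes or objective)")
        biomass_rxn = obj[0]
    if glucose_uptake_rxn is None:
        glucose_uptake_rxn = notes.get("glucose_uptake_rxn", biomass_rxn)
    kinetic = [s for s in notes.get("kinetic_rxns", "").split(",") if s]
    ferm = [s for s in notes.get("fermentation_rxns", "").split(",") if s]
    S = sparse.csr_matrix(create_stoichiometric_matrix(cm, "lil"))
    lb = np.array([r.lower_bound for r in cm.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cm.reactions], dtype=float)
    return StoichiometricModel(
        metabolites=[m.id for m in cm.metabolites],
        reactions=[r.id for r in cm.reactions],
        S=S, lb=lb, ub=ub,
        reversible=lb < 0,
        biomass_rxn=biomass_rxn,
        glucose_uptake_rxn=glucose_uptake_rxn,
        kinetic_rxns=kinetic,
        fermentation_rxns=ferm,
        compartments={m.id: m.compartment for m in cm.metabolites},
        reaction_names={r.id: r.name for r in cm.reactions},
        metabolite_names={m.id: m.name for m in cm.metabolites},
        notes=notes,
    )


def to_cobra(model: StoichiometricModel):
    import cobra

    cm = cobra.Model("kinfba_model")
    mets = [cobra.Metabolite(m, name=model.metabolite_names.get(m, m),
                             compartment=model.compartments.get(m, "c"))
            for m in model.metabolites]
    cm.add_metabolites(mets)
    rxns = []
    for j, rid in enumerate(model.reactions):
        r = cobra.Reaction(rid, name=model.reaction_names.get(rid, rid),
                           lower_bound=float(model.lb[j]),
                           upper_bound=float(model.ub[j]))
        rxns.append(r)
    cm.add_reactions(rxns)
    coo = model.S.tocoo()
    per_rxn: dict[int, dict] = {}
    for i, j, v in zip(coo.row, coo.col, coo.data):
        per_rxn.setdefault(j, {})[cm.metabolites[int(i)]] = float(v)
    for j, stoich in per_rxn.items():
        cm.reactions[int(j)].add_metabolites(stoich)
    cm.notes.update(model.notes)
    cm.notes["biomass_rxn"] = model.biomass_rxn
    cm.notes["glucose_uptake_rxn"] = model.glucose_uptake_rxn
    cm.notes["kinetic_rxns"] = ",".join(model.kinetic_rxns)
    cm.notes["fermentation_rxns"] = ",".join(model.fermentation_rxns)
    if model.biomass_rxn in [r.id for r in cm.reactions]:
        cm.objective = model.biomass_rxn
    return cm


def load_sbml(path) -> StoichiometricModel:
    """Load an SBML Level 2/3 model (fbc bounds honored via cobrapy)."""
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a grab-bag of parse errors
        raise ModelValidationError(f"could not parse SBML {path}: {exc}")
    if len(cm.reactions) == 0:
        raise ModelValidationError(f"{path}: model has zero reactions")
    return from_cobra(cm)


def write_sbml(model: StoichiometricModel, path) -> None:
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(model), str(path))


def load_fixture(name: str = "ecoli_central") -> StoichiometricModel:
    """Load a shipped fixture network by name."""
    import cobra.io

    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    ref = importlib.resources.files("kinfba.data") / f"{name}.json"
    with importlib.resources.as_file(ref) as p:
        cm = cobra.io.load_json_model(str(p))
    return from_cobra(cm)
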