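"""SBML import/export for NetworkModel, plus structural summaries.

Models are emitted as SBML Level 3 Version 1 with one compartment and
per-reaction (local) kinetic-law parameters named ``kf``/``kr`` (mass
action), ``vmax``/``km`` (saturable) and ``ki_<species>`` (noncompetitive
inhibition divisors).  On read, Level 2 and Level 3 documents are both
accepted; kinetic laws are verified symbolically against the mass-action
form, and anything that cannot be expressed as
``kf*prod(reactants) - kr*prod(products)`` (optionally divided by
``prod(1 + ki*[inhibitor])``) raises an explicit unsupported-feature
error naming the reaction.

Parameter counts follow the convention global + reaction-local, applied
identically to in-memory models and to parsed files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import libsbml
import pandas as pd
import sympy

from .reaction_network import (
    AssignmentRule,
    NetworkModel,
    ReactionDef,
    SpeciesDef,
    validate_model,
)

__all__ = [
    "ModelSummary",
    "NameMap",
    "SBMLError",
    "UnsupportedKineticLawError",
    "read_sbml",
    "write_sbml",
    "model_summary",
    "summary_from_file",
    "map_names",
    "default_name_map",
    "default_readouts",
    "CANONICAL_READOUTS",
]


class SBMLError(RuntimeError):
    pass


class UnsupportedKineticLawError(SBMLError):
    pass


@dataclass
class ModelSummary:
    n_species: int
    n_reactions: int
    n_parameters: int
    n_rules: int
    source: str = "builder"

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_species, self.n_reactions, self.n_parameters, self.n_rules)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def model_summary(model: NetworkModel, source: str = "builder") -> ModelSummary:
    return ModelSummary(
        n_species=len(model.species),
        n_reactions=len(model.reactions),
        n_parameters=model.n_parameters(),
        n_rules=len(model.rules),
        source=source,
    )


def _check(doc_or_code, context: str):
    if isinstance(doc_or_code, int) and doc_or_code != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise SBMLError(f"libsbml error {doc_or_code} while {context}")


def write_sbml(model: NetworkModel, path: str) -> None:
    """Serialize a NetworkModel as SBML L3V1."""
    report = validate_model(model)
    if not report.ok:
        raise SBMLError(f"model does not validate: {report.errors}")
    doc = libsbml.SBMLDocument(3, 1)
    m = doc.createModel()
    m.setId(re.sub(r"\W", "_", model.name) or "model")
    comp = m.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)
    comp.setSize(1.0)
    comp.setSpatialDimensions(3)
    for s in model.species:
        sp = m.createSpecies()
        sp.setId(s.id)
        sp.setName(s.display_name)
        sp.setCompartment("cell")
        sp.setInitialAmount(float(s.initial_amount))
        sp.setHasOnlySubstanceUnits(True)
        sp.setBoundaryCondition(bool(s.constant))
        sp.setConstant(bool(s.constant))
    rule_targets = {r.target for r in model.rules}
    for name, value in model.global_parameters.items():
        p = m.createParameter()
        p.setId(name)
        p.setValue(float(value))
        p.setConstant(name not in rule_targets)
    for rxn in model.reactions:
        r = m.createReaction()
        r.setId(rxn.id)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        for sid, coeff in rxn.reactants:
            ref = r.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        for sid, coeff in rxn.products:
            ref = r.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        for sid, _ in rxn.inhibitors:
            mod = r.createModifier()
            mod.setSpecies(sid)
        kl = r.createKineticLaw()
        if rxn.rate_form == "mass_action":
            fwd = " * ".join(
                ["kf"] + [sid if c == 1 else f"{sid}^{c}" for sid, c in rxn.reactants]
            )
            formula = fwd
            if rxn.reversible:
                rev = " * ".join(
                    ["kr"] + [sid if c == 1 else f"{sid}^{c}" for sid, c in rxn.products]
                )
                formula = f"{fwd} - {rev}"
        else:
            sub = rxn.reactants[0][0]
            formula = f"vmax * {sub} / (km + {sub})"
        for sid, strength in rxn.inhibitors:
            formula = f"({formula}) / (1 + ki_{sid} * {sid})"
        params = {"kf": rxn.kf}
        if rxn.reversible:
            params["kr"] = rxn.kr
        if rxn.rate_form == "michaelis_menten":
            params = {"vmax": rxn.vmax, "km": rxn.km}
        for sid, strength in rxn.inhibitors:
            params[f"ki_{sid}"] = strength
        for pname, pval in params.items():
            lp = kl.createLocalParameter()
            lp.setId(pname)
            lp.setValue(float(pval))
        ast = libsbml.parseL3Formula(formula)
        if ast is None:
            raise SBMLError(f"could not build kinetic law for reaction {rxn.id!r}")
        kl.setMath(ast)
    for rule in model.rules:
        ar = m.createAssignmentRule()
        ar.setVariable(rule.target)
        ast = libsbml.parseL3Formula(rule.formula)
        if ast is None:
            raise SBMLError(f"could not parse rule formula for {rule.target!r}")
        ar.setMath(ast)
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise SBMLError(f"could not write SBML to {path}")


def _species_amount(sp) -> float:
    if sp.isSetInitialAmount():
        return float(sp.getInitialAmount())
    if sp.isSetInitialConcentration():
        return float(sp.getInitialConcentration())
    return 0.0


def _match_mass_action(rxn, formula: str, local_params: dict[str, float],
                       global_params: dict[str, float]) -> ReactionDef | None:
    """Symbolically verify a kinetic law against the mass-action dialect."""
    reactants = [(rxn.getReactant(i).getSpecies(),
                  int(round(rxn.getReactant(i).getStoichiometry() or 1)))
                 for i in range(rxn.getNumReactants())]
    products = [(rxn.getProduct(i).getSpecies(),
                 int(round(rxn.getProduct(i).getStoichiometry() or 1)))
                for i in range(rxn.getNumProducts())]
    params = {**global_params, **local_params}
    syms = {name: sympy.Symbol(name) for name in params}
    try:
        expr = sympy.sympify(formula.replace("^", "**"), locals=dict(syms))
    except (sympy.SympifyError, SyntaxError, TypeError):
        return None
    expr = expr.subs([(syms[name], params[name]) for name in params])
    kf = local_params.get("kf", global_params.get("kf"))
    kr = local_params.get("kr", 0.0)
    vmax, km = local_params.get("vmax"), local_params.get("km")
    inhibitors = sorted(
        (name[3:], val) for name, val in local_params.items() if name.startswith("ki_")
    )
    sp_syms = {s: sympy.Symbol(s) for s, _ in reactants + products}
    for sid, _ in inhibitors:
        sp_syms.setdefault(sid, sympy.Symbol(sid))

    def build(defn: ReactionDef):
        if defn.rate_form == "mass_action":
            fwd = sympy.Float(defn.kf)
            for s, c in defn.reactants:
                fwd *= sp_syms[s] ** c
            rate = fwd
            if defn.kr > 0:
                rev = sympy.Float(defn.kr)
                for s, c in defn.products:
                    rev *= sp_syms[s] ** c
                rate = fwd - rev
        else:
            s = sp_syms[defn.reactants[0][0]]
            rate = sympy.Float(defn.vmax) * s / (sympy.Float(defn.km) + s)
        for s, strength in defn.inhibitors:
            rate /= 1 + sympy.Float(strength) * sp_syms[s]
        return rate

    candidates = []
    if vmax is not None and km is not None and len(reactants) == 1:
        candidates.append(ReactionDef(
            id=rxn.getId(), reactants=reactants, products=products,
            rate_form="michaelis_menten", kf=0.0, vmax=vmax, km=km,
            inhibitors=inhibitors))
    if kf is not None:
        try:
            candidates.append(ReactionDef(
                id=rxn.getId(), reactants=reactants, products=products,
                kf=kf, kr=kr if rxn.getReversible() else 0.0,
                inhibitors=inhibitors))
        except ValueError:
            pass
    for cand in candidates:
        try:
            if sympy.simplify(expr - build(cand)) == 0:
                return cand
        except (TypeError, ValueError):
            continue
    return None


def read_sbml(path: str) -> NetworkModel:
    """Parse an SBML file into a NetworkModel.

    Malformed XML raises :class:`SBMLError` with line information;
    kinetic laws outside the supported mass-action/saturable dialect
    raise :class:`UnsupportedKineticLawError` naming the reaction.
    """
    reader = libsbml.SBMLReader()
    doc = reader.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLError(
            f"SBML parse error in {path} at line {err.getLine()}: {err.getMessage()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise SBMLError(f"{path} contains no SBML model")
    model = NetworkModel(name=sm.getId() or "sbml_model")
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        model.species.append(SpeciesDef(
            id=sp.getId(),
            display_name=sp.getName() or sp.getId(),
            initial_amount=_species_amount(sp),
            constant=bool(sp.getConstant() or sp.getBoundaryCondition()),
        ))
    global_params = {}
    for i in range(sm.getNumParameters()):
        p = sm.getParameter(i)
        global_params[p.getId()] = float(p.getValue()) if p.isSetValue() else 0.0
    model.global_parameters = global_params
    for i in range(sm.getNumReactions()):
        rxn = sm.getReaction(i)
        kl = rxn.getKineticLaw()
        if kl is None or kl.getMath() is None:
            raise UnsupportedKineticLawError(
                f"reaction {rxn.getId()!r} has no kinetic law"
            )
        local = {}
        for j in range(kl.getNumLocalParameters()):
            lp = kl.getLocalParameter(j)
            local[lp.getId()] = float(lp.getValue())
        for j in range(kl.getNumParameters()):  # SBML L2 stores them as parameters
            lp = kl.getParameter(j)
            local.setdefault(lp.getId(), float(lp.getValue()))
        formula = libsbml.formulaToL3String(kl.getMath())
        defn = _match_mass_action(rxn, formula, local, global_params)
        if defn is None:
            raise UnsupportedKineticLawError(
                f"reaction {rxn.getId()!r}: kinetic law {formula!r} is not "
                f"in the supported mass-action/Michaelis-Menten dialect"
            )
        model.reactions.append(defn)
    for i in range(sm.getNumRules()):
        rule = sm.getRule(i)
        if not rule.isAssignment():
            raise UnsupportedKineticLawError(
                f"rule for {rule.getVariable()!r} is not an assignment rule"
            )
        model.rules.append(AssignmentRule(
            target=rule.getVariable(),
            formula=libsbml.formulaToL3String(rule.getMath()),
        ))
    return model


def summary_from_file(path: str) -> ModelSummary:
    """Structural counts straight from an SBML file (no kinetic-law parsing).

    Local (per-reaction) parameters are counted in ``n_parameters``
    alongside the globals.
    """
    reader = libsbml.SBMLReader()
    doc = reader.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLError(
            f"SBML parse error in {path} at line {err.getLine()}: {err.getMessage()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise SBMLError(f"{path} contains no SBML model")
    n_local = 0
    for i in range(sm.getNumReactions()):
        kl = sm.getReaction(i).getKineticLaw()
        if kl is not None:
            # L3 stores LocalParameters; L2 stores Parameters — and in L3
            # getNumParameters aliases the local list, so take the max.
            n_local += max(kl.getNumLocalParameters(), kl.getNumParameters())
    return ModelSummary(
        n_species=sm.getNumSpecies(),
        n_reactions=sm.getNumReactions(),
        n_parameters=sm.getNumParameters() + n_local,
        n_rules=sm.getNumRules(),
        source=str(path),
    )


# --- canonical readout names ---------------------------------------------

CANONICAL_READOUTS = [
    "TEK", "ANGPT1_TEK_p", "RasGTP", "Raf1_active", "ppMEK", "ppERK",
    "pMYC", "MYC_total", "pIRS1", "PI3K", "pAkt", "pCREB", "pMcl1",
    "pmTORC1", "pEIF4EBP1",
]

_DEFAULT_PATTERNS: dict[str, list[str]] = {
    "TEK": [r"(?i)^tek$"],
    "ANGPT1_TEK_p": [r"(?i)^prec$", r"(?i)^p+[_-]?angpt?1[_-]?tek"],
    "RasGTP": [r"(?i)^ras[_-]?gtp$"],
    "Raf1_active": [r"(?i)^araf1?$", r"(?i)^(active[_-]?raf1?|raf1?[_-]?act\w*)$"],
    "ppMEK": [r"(?i)^ppmek(_|$)"],
    "ppERK": [r"(?i)^pperk(_|$)"],
    "pMYC": [r"(?i)^ppmyc(_|$)"],
    "MYC_total": [r"(?i)^myc$", r"(?i)^p?p?myc$"],
    "pIRS1": [r"(?i)^pirs1$"],
    "PI3K": [r"(?i)^pi3k[_-]?act\w*$", r"(?i)^active[_-]?pi3k$"],
    "pAkt": [r"(?i)^pakt$"],
    "pCREB": [r"(?i)^pcreb$"],
    "pMcl1": [r"(?i)^pmcl1$"],
    "pmTORC1": [r"(?i)^pmtorc1$"],
    "pEIF4EBP1": [r"(?i)^peif4ebp1$"],
}


@dataclass
class NameMap:
    """Pattern-based, many-to-one mapping from species ids to readout names."""

    patterns: dict[str, list[str]] = field(default_factory=lambda: {
        k: list(v) for k, v in _DEFAULT_PATTERNS.items()
    })

    def members(self, readout: str, species_ids: list[str]) -> set[str]:
        pats = [re.compile(p) for p in self.patterns.get(readout, [])]
        return {sid for sid in species_ids if any(p.match(sid) for p in pats)}


def default_name_map() -> NameMap:
    return NameMap()


@dataclass
class NameMapReport:
    resolved: dict[str, set[str]]
    unresolved: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"readout": k, "species": ";".join(sorted(v)), "resolved": True}
            for k, v in self.resolved.items()
        ] + [{"readout": k, "species": "", "resolved": False} for k in self.unresolved]
        return pd.DataFrame(rows)


def map_names(model: NetworkModel, name_map: NameMap | None = None) -> NameMapReport:
    """Resolve every canonical readout to species ids, reporting misses."""
    nm = name_map or default_name_map()
    ids = model.species_ids()
    resolved, unresolved = {}, []
    for readout in nm.patterns:
        members = nm.members(readout, ids)
        if members:
            resolved[readout] = members
        else:
            unresolved.append(readout)
    return NameMapReport(resolved=resolved, unresolved=unresolved)


def default_readouts(model: NetworkModel, name_map: NameMap | None = None):
    """Canonical readouts as kinetics-analysis Readout objects."""
    from .kinetics_analysis import Readout

    report = map_names(model, name_map)
    return {name: Readout(name=name, member_species=members)
            for name, members in report.resolved.items()}
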