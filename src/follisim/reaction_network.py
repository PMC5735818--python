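"""Mass-action reaction networks and their ODE right-hand sides.

A :class:`NetworkModel` is an ordered collection of species, elementary
reactions, global parameters and assignment rules.  Reversible reactions are
stored as single entities with a forward rate constant ``kf`` and a reverse
rate constant ``kr`` (``kr == 0`` means irreversible), so the net flux of a
binding step ``A + B <-> AB`` is ``kf*[A]*[B] - kr*[AB]``.

Concentrations are dimensionless model units and time is in seconds, so
first-order constants are per second and second-order constants are per
(concentration unit * second).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import sympy

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "AssignmentRule",
    "NetworkModel",
    "StoichiometricMatrix",
    "ValidationReport",
    "ModelConsistencyError",
    "mass_action_rate",
    "stoichiometric_matrix",
    "build_ode_rhs",
    "conserved_moieties",
    "validate_model",
]

MAX_ELEMENTARY_ORDER = 2


class ModelConsistencyError(ValueError):
    """A model refers to an unknown species/symbol or violates a contract."""


@dataclass
class SpeciesDef:
    """One chemical species.

    ``constant=True`` marks a boundary species (e.g. a constitutively
    supplied miRNA pool): it may appear in reactions but its net rate in the
    generated ODE system is forced to zero.
    """

    id: str
    display_name: str = ""
    initial_amount: float = 0.0
    constant: bool = False

    def __post_init__(self) -> None:
        if not self.display_name:
            self.display_name = self.id
        if self.initial_amount < 0:
            raise ValueError(
                f"species {self.id!r}: initial_amount must be >= 0, "
                f"got {self.initial_amount}"
            )


@dataclass
class ReactionDef:
    """One elementary step with mass-action (or optionally saturable) kinetics.

    ``reactants``/``products`` are ``(species_id, stoichiometric_coefficient)``
    pairs with coefficients >= 1.  ``inhibitors`` is an optional list of
    ``(species_id, strength)`` pairs; each divides the reaction flux by
    ``1 + strength*[inhibitor]`` (noncompetitive repression, used for
    miRNA translational blocks).
    """

    id: str
    reactants: list[tuple[str, int]] = field(default_factory=list)
    products: list[tuple[str, int]] = field(default_factory=list)
    kf: float = 0.0
    kr: float = 0.0
    rate_form: str = "mass_action"
    km: float | None = None
    vmax: float | None = None
    inhibitors: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kf < 0 or self.kr < 0:
            raise ValueError(f"reaction {self.id!r}: rate constants must be >= 0")
        if self.rate_form not in ("mass_action", "michaelis_menten"):
            raise ValueError(f"reaction {self.id!r}: unknown rate_form {self.rate_form!r}")
        for sid, coeff in self.reactants + self.products:
            if coeff < 1:
                raise ValueError(
                    f"reaction {self.id!r}: stoichiometric coefficient of "
                    f"{sid!r} must be >= 1"
                )
        for _, strength in self.inhibitors:
            if strength < 0:
                raise ValueError(f"reaction {self.id!r}: inhibitor strength must be >= 0")
        if self.rate_form == "mass_action":
            if sum(c for _, c in self.reactants) > MAX_ELEMENTARY_ORDER:
                raise ValueError(
                    f"reaction {self.id!r}: mass-action order > "
                    f"{MAX_ELEMENTARY_ORDER} on reactant side"
                )
            if self.kr > 0 and sum(c for _, c in self.products) > MAX_ELEMENTARY_ORDER:
                raise ValueError(
                    f"reaction {self.id!r}: reversible mass-action order > "
                    f"{MAX_ELEMENTARY_ORDER} on product side"
                )
        if self.rate_form == "michaelis_menten":
            if self.km is None or self.vmax is None:
                raise ValueError(f"reaction {self.id!r}: michaelis_menten needs km and vmax")
            if len(self.reactants) != 1:
                raise ValueError(
                    f"reaction {self.id!r}: michaelis_menten supports one substrate"
                )

    @property
    def reversible(self) -> bool:
        return self.kr > 0

    def local_parameter_names(self) -> list[str]:
        """Names of the per-reaction constants, as counted in summaries."""
        names = []
        if self.rate_form == "mass_action":
            names.append("kf")
            if self.reversible:
                names.append("kr")
        else:
            names.extend(["vmax", "km"])
        for sid, _ in self.inhibitors:
            names.append(f"ki_{sid}")
        return names


@dataclass
class AssignmentRule:
    """``target := formula`` evaluated from the instantaneous state.

    The target may be a global parameter (an observable) or a species; a
    rule-targeted species has its value overwritten before flux evaluation
    and carries no ODE of its own.
    """

    target: str
    formula: str


@dataclass
class NetworkModel:
    species: list[SpeciesDef] = field(default_factory=list)
    reactions: list[ReactionDef] = field(default_factory=list)
    global_parameters: dict[str, float] = field(default_factory=dict)
    rules: list[AssignmentRule] = field(default_factory=list)
    scenario_tag: str = "custom"
    name: str = "model"

    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def get_species(self, sid: str) -> SpeciesDef:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def get_reaction(self, rid: str) -> ReactionDef:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species], dtype=float)

    def n_parameters(self) -> int:
        """Global plus per-reaction (local) parameter count."""
        return len(self.global_parameters) + sum(
            len(r.local_parameter_names()) for r in self.reactions
        )

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            species=[replace(s) for s in self.species],
            reactions=[
                replace(r, reactants=list(r.reactants), products=list(r.products),
                        inhibitors=list(r.inhibitors))
                for r in self.reactions
            ],
            global_parameters=dict(self.global_parameters),
            rules=[replace(ru) for ru in self.rules],
            scenario_tag=self.scenario_tag,
            name=self.name,
        )


@dataclass
class StoichiometricMatrix:
    """Species x reactions matrix N of net stoichiometric change (dx/dt = N v)."""

    matrix: np.ndarray
    row_ids: list[str]
    col_ids: list[str]


def mass_action_rate(reaction: ReactionDef, state: dict[str, float]) -> float:
    """Signed net flux ``kf*prod([reactants]) - kr*prod([products])``.

    The flux is divided by ``prod(1 + strength*[inhibitor])`` when the
    reaction carries inhibitors.
    """
    if reaction.rate_form != "mass_action":
        raise ValueError(f"reaction {reaction.id!r} is not mass_action")
    for sid, _ in reaction.reactants + reaction.products + reaction.inhibitors:
        if sid not in state:
            raise ModelConsistencyError(
                f"reaction {reaction.id!r} references unknown species {sid!r}"
            )
    for sid, conc in state.items():
        if conc < 0:
            raise ValueError(f"negative concentration for species {sid!r}: {conc}")
    fwd = reaction.kf
    for sid, coeff in reaction.reactants:
        fwd *= state[sid] ** coeff
    rev = reaction.kr
    for sid, coeff in reaction.products:
        rev *= state[sid] ** coeff
    flux = fwd - (rev if reaction.kr > 0 else 0.0)
    for sid, strength in reaction.inhibitors:
        flux /= 1.0 + strength * state[sid]
    return flux


def stoichiometric_matrix(model: NetworkModel) -> StoichiometricMatrix:
    idx = model.species_index()
    n = np.zeros((len(model.species), len(model.reactions)), dtype=int)
    for j, rxn in enumerate(model.reactions):
        for sid, coeff in rxn.reactants:
            n[idx[sid], j] -= coeff
        for sid, coeff in rxn.products:
            n[idx[sid], j] += coeff
    return StoichiometricMatrix(
        matrix=n, row_ids=model.species_ids(), col_ids=[r.id for r in model.reactions]
    )


def _compile_rules(model: NetworkModel):
    """Compile assignment rules to callables over the species state vector.

    Returns (species_rule_targets, param_rule_targets) where each entry is
    (target index or name, callable(state_vector, params_dict) -> float).
    """
    idx = model.species_index()
    known = set(idx) | set(model.global_parameters)
    species_syms = {sid: sympy.Symbol(sid) for sid in idx}
    species_rules, param_rules = [], []
    for rule in model.rules:
        if rule.target not in known:
            raise ModelConsistencyError(f"rule target {rule.target!r} is unknown")
        expr = sympy.sympify(rule.formula, locals=dict(species_syms))
        free = {str(s) for s in expr.free_symbols}
        unknown = free - known
        if unknown:
            raise ModelConsistencyError(
                f"rule for {rule.target!r} references unknown symbols {sorted(unknown)}"
            )
        args = sorted(free)
        fn = sympy.lambdify([sympy.Symbol(a) for a in args], expr, modules="numpy")
        arg_idx = [(a, idx.get(a)) for a in args]

        def evaluate(y, params, _fn=fn, _args=arg_idx):
            vals = [y[i] if i is not None else params[a] for a, i in _args]
            return float(_fn(*vals))

        if rule.target in idx:
            species_rules.append((idx[rule.target], evaluate))
        else:
            param_rules.append((rule.target, evaluate))
    return species_rules, param_rules


def build_ode_rhs(model: NetworkModel):
    """Compile the model to a derivative function ``f(t, y) -> dy/dt``.

    ``dy/dt = N . v(y)`` with constant species and rule-targeted species
    forced to zero derivative; assignment rules are applied to a working
    copy of the state before flux evaluation.
    """
    idx = model.species_index()
    smat = stoichiometric_matrix(model).matrix.astype(float)
    species_rules, param_rules = _compile_rules(model)

    frozen = np.array(
        [s.constant for s in model.species], dtype=bool
    )
    for i, _ in species_rules:
        frozen[i] = True
    smat[frozen, :] = 0.0

    # Pre-resolve reaction structure into index arrays.
    compiled = []
    for rxn in model.reactions:
        for sid, _ in rxn.reactants + rxn.products + rxn.inhibitors:
            if sid not in idx:
                raise ModelConsistencyError(
                    f"reaction {rxn.id!r} references unknown species {sid!r}"
                )
        compiled.append(
            (
                rxn,
                [(idx[s], c) for s, c in rxn.reactants],
                [(idx[s], c) for s, c in rxn.products],
                [(idx[s], st) for s, st in rxn.inhibitors],
            )
        )
    params = dict(model.global_parameters)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        work = y.copy()
        for i, fn in species_rules:
            work[i] = fn(work, params)
        for name, fn in param_rules:
            params[name] = fn(work, params)
        v = np.empty(len(compiled))
        for j, (rxn, re_ix, pr_ix, in_ix) in enumerate(compiled):
            if rxn.rate_form == "mass_action":
                fwd = rxn.kf
                for i, c in re_ix:
                    fwd *= work[i] ** c if c != 1 else work[i]
                if rxn.kr > 0:
                    rev = rxn.kr
                    for i, c in pr_ix:
                        rev *= work[i] ** c if c != 1 else work[i]
                    flux = fwd - rev
                else:
                    flux = fwd
            else:  # michaelis_menten, single substrate
                s = work[re_ix[0][0]]
                flux = rxn.vmax * s / (rxn.km + s)
            for i, st in in_ix:
                flux /= 1.0 + st * work[i]
            v[j] = flux
        return smat @ v

    return rhs


def conserved_moieties(model: NetworkModel) -> list[dict[str, int]]:
    """Integer basis of the left null space of N over non-constant species.

    Each returned mapping ``{species_id: coefficient}`` satisfies
    ``c^T N = 0`` exactly, i.e. the weighted total is invariant under the
    dynamics.  Constant (boundary) species are excluded: their totals are
    pinned by fiat, not by stoichiometry.
    """
    smat = stoichiometric_matrix(model)
    free = [i for i, s in enumerate(model.species) if not s.constant]
    if not free:
        return []
    sub = sympy.Matrix(smat.matrix[free, :])
    basis = sub.T.nullspace()
    vectors = []
    for vec in basis:
        denoms = [sympy.fraction(sympy.nsimplify(x))[1] for x in vec]
        scale = sympy.lcm([sympy.Integer(d) for d in denoms]) if denoms else 1
        ints = [int(x * scale) for x in vec]
        g = math.gcd(*[abs(v) for v in ints]) if any(ints) else 1
        ints = [v // g for v in ints]
        if sum(1 for v in ints if v < 0) > sum(1 for v in ints if v > 0):
            ints = [-v for v in ints]
        vectors.append(ints)
    # prefer non-negative combinations (chemically meaningful totals):
    # repair mixed-sign vectors by adding integer multiples of other basis
    # vectors; the span is unchanged
    for _ in range(len(vectors)):
        changed = False
        for v in vectors:
            for i, vi in enumerate(v):
                if vi >= 0:
                    continue
                for u in vectors:
                    if u is v or u[i] <= 0 or any(x < 0 for x in u):
                        continue
                    mult = math.ceil(-vi / u[i])
                    for j in range(len(v)):
                        v[j] += mult * u[j]
                    changed = True
                    break
        if not changed:
            break
    out = []
    for ints in vectors:
        g = math.gcd(*[abs(v) for v in ints]) if any(ints) else 1
        ints = [v // g for v in ints]
        out.append(
            {model.species[free[i]].id: ints[i] for i in range(len(free)) if ints[i] != 0}
        )
    return out


@dataclass
class ValidationReport:
    n_species: int
    n_reactions: int
    n_parameters: int
    n_rules: int
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_model(model: NetworkModel) -> ValidationReport:
    """Structural validation: counts, dangling references, duplicates."""
    errors: list[str] = []
    warnings: list[str] = []
    ids = model.species_ids()
    seen = set()
    for sid in ids:
        if sid in seen:
            errors.append(f"duplicate species id {sid!r}")
        seen.add(sid)
    rids = set()
    for rxn in model.reactions:
        if rxn.id in rids:
            errors.append(f"duplicate reaction id {rxn.id!r}")
        rids.add(rxn.id)
        for sid, _ in rxn.reactants + rxn.products + rxn.inhibitors:
            if sid not in seen:
                errors.append(
                    f"reaction {rxn.id!r} references undeclared species {sid!r}"
                )
    for name, value in model.global_parameters.items():
        if not np.isfinite(value):
            errors.append(f"global parameter {name!r} is not finite")
    rule_targets = set()
    for rule in model.rules:
        if rule.target in rule_targets:
            errors.append(f"duplicate rule target {rule.target!r}")
        rule_targets.add(rule.target)
        if rule.target not in seen and rule.target not in model.global_parameters:
            errors.append(f"rule target {rule.target!r} is unknown")
    for s in model.species:
        if s.constant and s.id in rule_targets:
            errors.append(f"species {s.id!r} is both constant and a rule target")
    touched = set()
    for rxn in model.reactions:
        for sid, _ in rxn.reactants + rxn.products:
            touched.add(sid)
    for sid in ids:
        if sid not in touched and sid not in rule_targets:
            warnings.append(f"species {sid!r} participates in no reaction")
    return ValidationReport(
        n_species=len(model.species),
        n_reactions=len(model.reactions),
        n_parameters=model.n_parameters(),
        n_rules=len(model.rules),
        errors=errors,
        warnings=warnings,
    )
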