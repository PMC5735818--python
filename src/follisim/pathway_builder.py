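"""Programmatic construction of the follicle signaling scenario models.

Three scenarios are built from one shared topology:

* ``SF``       — subordinate follicle: baseline expression everywhere.
* ``DF``       — dominant follicle: identical reactions, but elevated
  ANGPT1/TEK-axis abundances (and reduced ANGPT2) in the initial values.
* ``DF_miRNA`` — the DF model plus four constitutively supplied miRNA
  species and their repression reactions: hsa-miR-30d-3p and hsa-miR-451a
  block MYC translation; hsa-miR-548v and bta-miR-22-3p enhance removal of
  the TEK receptor.

The cascade runs ANGPT1/ANGPT2 -> TEK -> Shc/Grb2/SOS -> Ras -> Raf ->
MEK -> ERK -> MYC on one branch and TEK -> p85/p110 (PI3K) -> PIP3 ->
PDK1 -> Akt -> {CREB -> Mcl1, mTORC1 -> EIF4EBP1} on the other.  MEK, ERK
and MYC phosphorylation are two-site and distributive; MYC additionally
turns over (synthesis and decay, with faster decay of its phospho-forms)
so that translational repression can lower its total.

Rate constants and initial amounts live in a :class:`ParameterLedger`;
the shipped defaults are the package's own calibration of the
under-determined kinetics (see docs/methods.md), with provenance
"literature-default".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .reaction_network import (
    AssignmentRule,
    NetworkModel,
    ReactionDef,
    SpeciesDef,
    validate_model,
)

__all__ = [
    "ScenarioSpec",
    "LedgerEntry",
    "ParameterLedger",
    "default_ledger",
    "build_receptor_module",
    "build_adaptor_ras_module",
    "build_mapk_myc_module",
    "build_pi3k_akt_module",
    "add_mirna_repression",
    "build_scenario",
    "sample_parameters",
    "merge_models",
    "MIRNA_IDS",
    "AXIS_SPECIES",
]

SCENARIOS = ("SF", "DF", "DF_miRNA")

MIRNA_IDS = ("hsa_miR_30d_3p", "hsa_miR_451a", "hsa_miR_548v", "bta_miR_22_3p")

#: Expression axes a scenario may scale, mapped to the species they control.
AXIS_SPECIES = {
    "ANGPT1": "ANGPT1",
    "ANGPT2": "ANGPT2",
    "TEK": "TEK",
    "RAS": "Ras_GDP",
    "PIK3R1": "p85",
}

#: DF fold-changes relative to SF: ANGPT1/TEK up, ANGPT2 down, with the
#: Ras and PI3K regulatory-subunit axes modestly elevated.
DF_MULTIPLIERS = {"ANGPT1": 2.0, "ANGPT2": 0.5, "TEK": 2.0, "RAS": 1.5, "PIK3R1": 1.5}

#: DF+miRNA initial pools (constant species, concentration units).
DF_MIRNA_LEVELS = {m: 1.0 for m in MIRNA_IDS}

#: Repression strengths: translational block divisor coefficients for the
#: MYC-targeting miRNAs and the catalytic TEK-removal rate for the
#: receptor-targeting pair (kept weak: these miRNAs are down-regulated in
#: dominant follicles, and the reported ppMEK/ppERK curves for DF and
#: DF+miRNA overlap).
MIRNA_ACTION = {
    "hsa_miR_30d_3p": ("MYC", "translation_block", 1.5),
    "hsa_miR_451a": ("MYC", "translation_block", 1.5),
    "hsa_miR_548v": ("TEK", "receptor_suppression", 2e-4),
    "bta_miR_22_3p": ("TEK", "receptor_suppression", 2e-4),
}


@dataclass
class ScenarioSpec:
    """Declarative description of how a scenario differs from baseline."""

    scenario: str = "SF"
    expression_multipliers: dict[str, float] = field(default_factory=dict)
    mirna_levels: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS and self.scenario != "custom":
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for axis in self.expression_multipliers:
            if axis not in AXIS_SPECIES:
                raise ValueError(f"unknown expression axis {axis!r}")
        for fold in self.expression_multipliers.values():
            if fold <= 0:
                raise ValueError("expression multipliers must be positive")
        for mid, level in self.mirna_levels.items():
            if mid not in MIRNA_IDS:
                raise ValueError(f"unknown miRNA {mid!r}")
            if level < 0:
                raise ValueError("miRNA levels must be non-negative")
        if self.scenario == "SF":
            if any(v != 1.0 for v in self.expression_multipliers.values()):
                raise ValueError("SF must have all expression multipliers equal to 1")
            if any(v != 0.0 for v in self.mirna_levels.values()):
                raise ValueError("SF must have zero miRNA levels")
        if self.scenario == "DF" and any(self.mirna_levels.values()):
            raise ValueError("DF carries no miRNA species; use DF_miRNA")
        if self.scenario == "DF_miRNA":
            missing = [m for m in MIRNA_IDS if self.mirna_levels.get(m, 0.0) <= 0]
            if missing:
                raise ValueError(
                    f"DF_miRNA requires strictly positive levels for {missing}"
                )

    @classmethod
    def sf(cls, seed: int = 0) -> "ScenarioSpec":
        return cls(scenario="SF", seed=seed)

    @classmethod
    def df(cls, seed: int = 0) -> "ScenarioSpec":
        return cls(scenario="DF", expression_multipliers=dict(DF_MULTIPLIERS), seed=seed)

    @classmethod
    def df_mirna(cls, seed: int = 0) -> "ScenarioSpec":
        return cls(
            scenario="DF_miRNA",
            expression_multipliers=dict(DF_MULTIPLIERS),
            mirna_levels=dict(DF_MIRNA_LEVELS),
            seed=seed,
        )

    @classmethod
    def for_scenario(cls, name: str, seed: int = 0) -> "ScenarioSpec":
        try:
            return {"SF": cls.sf, "DF": cls.df, "DF_miRNA": cls.df_mirna}[name](seed)
        except KeyError:
            raise ValueError(f"unknown scenario {name!r}") from None


@dataclass
class LedgerEntry:
    value: float
    provenance: str = "literature-default"


@dataclass
class ParameterLedger:
    """Baseline rate constants (keyed ``reaction_id.kf``/``.kr``) and
    initial amounts (keyed by species id), each with a provenance note."""

    rates: dict[str, LedgerEntry] = field(default_factory=dict)
    initials: dict[str, LedgerEntry] = field(default_factory=dict)

    def rate(self, reaction_id: str, which: str = "kf") -> float:
        return self.rates[f"{reaction_id}.{which}"].value

    def initial(self, species_id: str) -> float:
        entry = self.initials.get(species_id)
        return entry.value if entry is not None else 0.0

    def copy(self) -> "ParameterLedger":
        return ParameterLedger(
            rates={k: replace(v) for k, v in self.rates.items()},
            initials={k: replace(v) for k, v in self.initials.items()},
        )


# --- calibrated defaults -------------------------------------------------
# Second-order constants are per (concentration unit * second), first-order
# per second.  Receptor-level steps are fast (the ligand/receptor events
# play out within ~70 s); phosphatase and turnover steps are slow (hundreds
# of seconds), which is what staggers the downstream peaks.

_DEFAULT_INITIALS = {
    "ANGPT1": 1.0,
    "ANGPT2": 0.5,
    "TEK": 1.0,
    "Shc": 1.0,
    "Grb2": 1.0,
    "SOS": 0.5,
    "Ras_GDP": 1.0,
    "Raf1": 1.0,
    "MEK": 2.0,
    "ERK": 2.0,
    "MYC": 1.0,
    "IRS1": 1.0,
    "p85": 1.0,
    "p110": 1.0,
    "PIP2": 2.0,
    "PTEN": 0.5,
    "PDK1": 0.5,
    "Akt": 2.0,
    "CREB": 1.0,
    "Mcl1": 1.0,
    "mTORC1": 1.0,
    "EIF4EBP1": 1.0,
}

_DEFAULT_RATES = {
    # receptor module: ligand binding and dimerization play out within
    # ~70 s; internalization of the phospho-receptor (tau ~54 s on the
    # free pool) makes the downstream drive transient
    "bind_angpt1_tek.kf": 0.2, "bind_angpt1_tek.kr": 0.01,
    "bind_angpt2_tek.kf": 0.2, "bind_angpt2_tek.kr": 0.01,
    "dimerize_a1_tek.kf": 0.1, "dimerize_a1_tek.kr": 0.01,
    "autophos_dimer.kf": 0.1,
    "internalize_prec.kf": 0.0185,
    # adaptor / Ras
    "bind_prec_shc.kf": 0.05, "bind_prec_shc.kr": 0.05,
    "bind_shc_grb2.kf": 0.05, "bind_shc_grb2.kr": 0.05,
    "bind_prec_grb2.kf": 0.02, "bind_prec_grb2.kr": 0.05,
    "bind_shc_grb2_sos.kf": 0.05, "bind_shc_grb2_sos.kr": 0.05,
    "bind_grb2_sos.kf": 0.05, "bind_grb2_sos.kr": 0.05,
    "ras_exchange_shc.kf": 0.1,
    "ras_exchange_direct.kf": 0.1,
    "ras_gap.kf": 0.0293,
    # Raf / MEK / ERK / MYC: phosphatase rates fall tier by tier, which
    # staggers the peaks (ppMEK minutes, ppERK/ppMYC 10-15 minutes)
    "raf_activation.kf": 0.0712,
    "raf_deactivation.kf": 0.012,
    "mek_phos_1.kf": 0.0702,
    "mek_phos_2.kf": 0.0702,
    "mek_dephos_2.kf": 0.0257,
    "mek_dephos_1.kf": 0.0257,
    "erk_phos_1.kf": 0.021,
    "erk_phos_2.kf": 0.021,
    "erk_dephos_2.kf": 0.000664,
    "erk_dephos_1.kf": 0.000664,
    "myc_synthesis.kf": 0.008,
    "myc_decay.kf": 0.0005,
    "myc_phos_1.kf": 0.00881,
    "myc_phos_2.kf": 0.00881,
    "myc_dephos_2.kf": 0.001,
    "myc_dephos_1.kf": 0.001,
    "pmyc_decay.kf": 0.00312,
    "ppmyc_decay.kf": 0.00312,
    # PI3K / Akt / mTORC1
    "bind_prec_p85.kf": 0.05, "bind_prec_p85.kr": 0.02,
    "bind_p85_p110.kf": 0.05, "bind_p85_p110.kr": 0.02,
    "irs1_phos.kf": 0.02,
    "irs1_dephos.kf": 0.004,
    "pip2_to_pip3.kf": 0.03,
    "pip3_to_pip2.kf": 0.05,
    "pdk1_activation.kf": 0.05,
    "pdk1_deactivation.kf": 0.02,
    "akt_phos.kf": 0.008,
    "akt_dephos.kf": 0.006,
    "creb_phos.kf": 0.005,
    "creb_dephos.kf": 0.005,
    "mcl1_phos.kf": 0.005,
    "mcl1_dephos.kf": 0.005,
    "mtorc1_phos.kf": 0.004,
    "mtorc1_dephos.kf": 0.005,
    "eif4ebp1_phos.kf": 0.004,
    "eif4ebp1_dephos.kf": 0.005,
}


def default_ledger() -> ParameterLedger:
    """The calibrated baseline ledger shared by all three scenarios."""
    return ParameterLedger(
        rates={k: LedgerEntry(v) for k, v in _DEFAULT_RATES.items()},
        initials={k: LedgerEntry(v) for k, v in _DEFAULT_INITIALS.items()},
    )


def _sp(ledger: ParameterLedger, sid: str, name: str = "") -> SpeciesDef:
    return SpeciesDef(id=sid, display_name=name or sid,
                      initial_amount=ledger.initial(sid))


def _rxn(ledger: ParameterLedger, rid: str, reactants, products) -> ReactionDef:
    kr_entry = ledger.rates.get(f"{rid}.kr")
    return ReactionDef(
        id=rid,
        reactants=reactants,
        products=products,
        kf=ledger.rate(rid, "kf"),
        kr=kr_entry.value if kr_entry is not None else 0.0,
    )


def build_receptor_module(ledger: ParameterLedger | None = None) -> NetworkModel:
    """Ligand binding, competitive ANGPT2 antagonism, dimerization,
    autophosphorylation and internalization of the TEK receptor.

    ANGPT2 binds TEK but its complex emits no phospho-receptor, so it acts
    purely by sequestering receptor.  The phosphorylated ANGPT1-TEK dimer
    is slowly internalized (removed), which makes the downstream drive
    transient and keeps total receptor non-conserved.
    """
    led = ledger or default_ledger()
    species = [
        _sp(led, "ANGPT1"), _sp(led, "ANGPT2"), _sp(led, "TEK"),
        _sp(led, "A1_TEK", "ANGPT1-TEK"), _sp(led, "A2_TEK", "ANGPT2-TEK"),
        _sp(led, "A1_TEK_dimer", "(ANGPT1-TEK)2"),
        _sp(led, "pRec", "phospho-ANGPT1-TEK dimer"),
    ]
    reactions = [
        _rxn(led, "bind_angpt1_tek", [("ANGPT1", 1), ("TEK", 1)], [("A1_TEK", 1)]),
        _rxn(led, "bind_angpt2_tek", [("ANGPT2", 1), ("TEK", 1)], [("A2_TEK", 1)]),
        _rxn(led, "dimerize_a1_tek", [("A1_TEK", 2)], [("A1_TEK_dimer", 1)]),
        _rxn(led, "autophos_dimer", [("A1_TEK_dimer", 1)], [("pRec", 1)]),
        _rxn(led, "internalize_prec", [("pRec", 1)], []),
    ]
    return NetworkModel(species=species, reactions=reactions, name="receptor")


def build_adaptor_ras_module(ledger: ParameterLedger | None = None) -> NetworkModel:
    """Shc/Grb2/SOS adaptor recruitment and the Ras GDP/GTP cycle.

    SOS reaches the receptor along two arms (receptor->Shc->Grb2->SOS and
    receptor->Grb2->SOS); either SOS complex catalyses Ras-GDP->Ras-GTP
    exchange, and a first-order GAP-like step returns Ras-GTP to Ras-GDP,
    so total Ras is conserved.
    """
    led = ledger or default_ledger()
    species = [
        _sp(led, "pRec"), _sp(led, "Shc"), _sp(led, "Grb2"), _sp(led, "SOS"),
        _sp(led, "pRec_Shc"), _sp(led, "pRec_Shc_Grb2"), _sp(led, "pRec_Shc_Grb2_SOS"),
        _sp(led, "pRec_Grb2"), _sp(led, "pRec_Grb2_SOS"),
        _sp(led, "Ras_GDP"), _sp(led, "Ras_GTP"),
    ]
    reactions = [
        _rxn(led, "bind_prec_shc", [("pRec", 1), ("Shc", 1)], [("pRec_Shc", 1)]),
        _rxn(led, "bind_shc_grb2", [("pRec_Shc", 1), ("Grb2", 1)], [("pRec_Shc_Grb2", 1)]),
        _rxn(led, "bind_prec_grb2", [("pRec", 1), ("Grb2", 1)], [("pRec_Grb2", 1)]),
        _rxn(led, "bind_shc_grb2_sos",
             [("pRec_Shc_Grb2", 1), ("SOS", 1)], [("pRec_Shc_Grb2_SOS", 1)]),
        _rxn(led, "bind_grb2_sos", [("pRec_Grb2", 1), ("SOS", 1)], [("pRec_Grb2_SOS", 1)]),
        _rxn(led, "ras_exchange_shc",
             [("Ras_GDP", 1), ("pRec_Shc_Grb2_SOS", 1)],
             [("Ras_GTP", 1), ("pRec_Shc_Grb2_SOS", 1)]),
        _rxn(led, "ras_exchange_direct",
             [("Ras_GDP", 1), ("pRec_Grb2_SOS", 1)],
             [("Ras_GTP", 1), ("pRec_Grb2_SOS", 1)]),
        _rxn(led, "ras_gap", [("Ras_GTP", 1)], [("Ras_GDP", 1)]),
    ]
    return NetworkModel(species=species, reactions=reactions, name="adaptor_ras")


def build_mapk_myc_module(ledger: ParameterLedger | None = None) -> NetworkModel:
    """Raf -> MEK -> ERK cascade (two-site distributive at MEK and ERK) and
    ERK-driven two-site MYC phosphorylation with MYC turnover.

    MEK and ERK are strictly conserved (phosphorylation cycles only); MYC
    is synthesised from a source and decays, with its phospho-forms
    decaying faster (phosphorylation-primed degradation).  The synthesis
    step is where miRNA translational repression attaches.
    """
    led = ledger or default_ledger()
    species = [
        _sp(led, "Ras_GTP"),
        _sp(led, "Raf1"), _sp(led, "aRaf1", "active Raf1"),
        _sp(led, "MEK"), _sp(led, "pMEK"), _sp(led, "ppMEK"),
        _sp(led, "ERK"), _sp(led, "pERK"), _sp(led, "ppERK"),
        _sp(led, "MYC"), _sp(led, "pMYC"), _sp(led, "ppMYC"),
    ]
    cat = [
        ("raf_activation", [("Raf1", 1), ("Ras_GTP", 1)], [("aRaf1", 1), ("Ras_GTP", 1)]),
        ("raf_deactivation", [("aRaf1", 1)], [("Raf1", 1)]),
        ("mek_phos_1", [("MEK", 1), ("aRaf1", 1)], [("pMEK", 1), ("aRaf1", 1)]),
        ("mek_phos_2", [("pMEK", 1), ("aRaf1", 1)], [("ppMEK", 1), ("aRaf1", 1)]),
        ("mek_dephos_2", [("ppMEK", 1)], [("pMEK", 1)]),
        ("mek_dephos_1", [("pMEK", 1)], [("MEK", 1)]),
        ("erk_phos_1", [("ERK", 1), ("ppMEK", 1)], [("pERK", 1), ("ppMEK", 1)]),
        ("erk_phos_2", [("pERK", 1), ("ppMEK", 1)], [("ppERK", 1), ("ppMEK", 1)]),
        ("erk_dephos_2", [("ppERK", 1)], [("pERK", 1)]),
        ("erk_dephos_1", [("pERK", 1)], [("ERK", 1)]),
        ("myc_synthesis", [], [("MYC", 1)]),
        ("myc_decay", [("MYC", 1)], []),
        ("myc_phos_1", [("MYC", 1), ("ppERK", 1)], [("pMYC", 1), ("ppERK", 1)]),
        ("myc_phos_2", [("pMYC", 1), ("ppERK", 1)], [("ppMYC", 1), ("ppERK", 1)]),
        ("myc_dephos_2", [("ppMYC", 1)], [("pMYC", 1)]),
        ("myc_dephos_1", [("pMYC", 1)], [("MYC", 1)]),
        ("pmyc_decay", [("pMYC", 1)], []),
        ("ppmyc_decay", [("ppMYC", 1)], []),
    ]
    reactions = [_rxn(led, rid, r, p) for rid, r, p in cat]
    return NetworkModel(species=species, reactions=reactions, name="mapk_myc")


def build_pi3k_akt_module(ledger: ParameterLedger | None = None) -> NetworkModel:
    """PI3K assembly on the phospho-receptor, PIP2/PIP3 cycling against
    PTEN, PDK1-mediated Akt activation, and the CREB->Mcl1 and
    mTORC1->EIF4EBP1 branches downstream of pAkt.

    PIP2+PIP3 and each phosphorylation cycle (IRS1, Akt, CREB, Mcl1,
    mTORC1, EIF4EBP1) are conserved by construction.
    """
    led = ledger or default_ledger()
    species = [
        _sp(led, "pRec"),
        _sp(led, "IRS1"), _sp(led, "pIRS1"),
        _sp(led, "p85", "PI3K regulatory subunit"),
        _sp(led, "p110", "PI3K catalytic subunit"),
        _sp(led, "pRec_p85"), _sp(led, "PI3K_act", "active PI3K complex"),
        _sp(led, "PIP2"), _sp(led, "PIP3"), _sp(led, "PTEN"),
        _sp(led, "PDK1"), _sp(led, "aPDK1", "membrane-recruited PDK1"),
        _sp(led, "Akt"), _sp(led, "pAkt"),
        _sp(led, "CREB"), _sp(led, "pCREB"),
        _sp(led, "Mcl1"), _sp(led, "pMcl1"),
        _sp(led, "mTORC1"), _sp(led, "pmTORC1"),
        _sp(led, "EIF4EBP1"), _sp(led, "pEIF4EBP1"),
    ]
    cat = [
        ("bind_prec_p85", [("pRec", 1), ("p85", 1)], [("pRec_p85", 1)]),
        ("bind_p85_p110", [("pRec_p85", 1), ("p110", 1)], [("PI3K_act", 1)]),
        ("irs1_phos", [("IRS1", 1), ("pRec", 1)], [("pIRS1", 1), ("pRec", 1)]),
        ("irs1_dephos", [("pIRS1", 1)], [("IRS1", 1)]),
        ("pip2_to_pip3", [("PIP2", 1), ("PI3K_act", 1)], [("PIP3", 1), ("PI3K_act", 1)]),
        ("pip3_to_pip2", [("PIP3", 1), ("PTEN", 1)], [("PIP2", 1), ("PTEN", 1)]),
        ("pdk1_activation", [("PDK1", 1), ("PIP3", 1)], [("aPDK1", 1), ("PIP3", 1)]),
        ("pdk1_deactivation", [("aPDK1", 1)], [("PDK1", 1)]),
        ("akt_phos", [("Akt", 1), ("aPDK1", 1)], [("pAkt", 1), ("aPDK1", 1)]),
        ("akt_dephos", [("pAkt", 1)], [("Akt", 1)]),
        ("creb_phos", [("CREB", 1), ("pAkt", 1)], [("pCREB", 1), ("pAkt", 1)]),
        ("creb_dephos", [("pCREB", 1)], [("CREB", 1)]),
        ("mcl1_phos", [("Mcl1", 1), ("pCREB", 1)], [("pMcl1", 1), ("pCREB", 1)]),
        ("mcl1_dephos", [("pMcl1", 1)], [("Mcl1", 1)]),
        ("mtorc1_phos", [("mTORC1", 1), ("pAkt", 1)], [("pmTORC1", 1), ("pAkt", 1)]),
        ("mtorc1_dephos", [("pmTORC1", 1)], [("mTORC1", 1)]),
        ("eif4ebp1_phos",
         [("EIF4EBP1", 1), ("pmTORC1", 1)], [("pEIF4EBP1", 1), ("pmTORC1", 1)]),
        ("eif4ebp1_dephos", [("pEIF4EBP1", 1)], [("EIF4EBP1", 1)]),
    ]
    reactions = [_rxn(led, rid, r, p) for rid, r, p in cat]
    return NetworkModel(species=species, reactions=reactions, name="pi3k_akt")


def merge_models(*parts: NetworkModel, name: str = "model") -> NetworkModel:
    """Union of partial models; shared species are declared once (the first
    declaration with a non-zero initial amount wins)."""
    merged = NetworkModel(name=name)
    seen: dict[str, SpeciesDef] = {}
    for part in parts:
        for s in part.species:
            if s.id not in seen:
                seen[s.id] = replace(s)
                merged.species.append(seen[s.id])
            elif seen[s.id].initial_amount == 0.0 and s.initial_amount > 0:
                seen[s.id].initial_amount = s.initial_amount
        for r in part.reactions:
            if any(r.id == existing.id for existing in merged.reactions):
                raise ValueError(f"duplicate reaction id {r.id!r} across modules")
            merged.reactions.append(
                replace(r, reactants=list(r.reactants), products=list(r.products),
                        inhibitors=list(r.inhibitors))
            )
        merged.global_parameters.update(part.global_parameters)
        merged.rules.extend(part.rules)
    return merged


def add_mirna_repression(
    model: NetworkModel,
    mirna_id: str,
    target_id: str,
    mode: str,
    strength: float,
    level: float = 1.0,
) -> NetworkModel:
    """Return a copy of ``model`` with one miRNA repression motif added.

    ``translation_block`` divides the target's synthesis flux by
    ``1 + strength*[miRNA]``; ``receptor_suppression`` adds a
    miRNA-dependent first-order removal of the target.  The miRNA itself
    is added as a constant (constitutively supplied) species.
    """
    if strength < 0:
        raise ValueError("repression strength must be >= 0")
    if mode not in ("translation_block", "receptor_suppression"):
        raise ValueError(f"unknown repression mode {mode!r}")
    ids = set(model.species_ids())
    if target_id not in ids:
        raise KeyError(f"unknown repression target {target_id!r}")
    out = model.copy()
    if mirna_id not in ids:
        out.species.append(
            SpeciesDef(id=mirna_id, display_name=mirna_id.replace("_", "-"),
                       initial_amount=level, constant=True)
        )
    if mode == "translation_block":
        synth = [
            r for r in out.reactions
            if not r.reactants and any(sid == target_id for sid, _ in r.products)
        ]
        if not synth:
            raise ValueError(
                f"target {target_id!r} has no synthesis (source) reaction to block"
            )
        for r in synth:
            r.inhibitors.append((mirna_id, strength))
    else:
        out.reactions.append(
            ReactionDef(
                id=f"suppress_{target_id}_{mirna_id}",
                reactants=[(target_id, 1), (mirna_id, 1)],
                products=[(mirna_id, 1)],
                kf=strength,
            )
        )
    return out


def build_scenario(
    spec: ScenarioSpec, ledger: ParameterLedger | None = None
) -> NetworkModel:
    """Assemble the full model for one scenario.

    SF and DF share identical topology (reaction-for-reaction); scenarios
    differ in initial amounts via the expression multipliers, and DF_miRNA
    additionally carries the four miRNA species and their repression
    reactions.  The assembled model always passes validation with zero
    errors.
    """
    led = ledger or default_ledger()
    model = merge_models(
        build_receptor_module(led),
        build_adaptor_ras_module(led),
        build_mapk_myc_module(led),
        build_pi3k_akt_module(led),
        name=spec.scenario,
    )
    model.scenario_tag = spec.scenario
    for axis, fold in spec.expression_multipliers.items():
        sp = model.get_species(AXIS_SPECIES[axis])
        sp.initial_amount *= fold
    for mid, level in spec.mirna_levels.items():
        if level <= 0:
            continue
        target, mode, strength = MIRNA_ACTION[mid]
        model = add_mirna_repression(model, mid, target, mode, strength, level=level)
    # The single assignment rule: a total-active-ERK observable parameter.
    model.global_parameters["ERK_active_total"] = 0.0
    model.rules.append(AssignmentRule(target="ERK_active_total",
                                      formula="pERK + ppERK"))
    report = validate_model(model)
    if not report.ok:
        raise ValueError(f"scenario {spec.scenario}: invalid model: {report.errors}")
    return model


def sample_parameters(
    ledger: ParameterLedger, seed: int, coefficient_of_variation: float
) -> ParameterLedger:
    """Log-normal perturbation of every rate constant (unit mean factor).

    Deterministic for a fixed seed; ``coefficient_of_variation = 0``
    returns an unchanged copy.  Initial amounts are left untouched.
    """
    if coefficient_of_variation < 0:
        raise ValueError("coefficient_of_variation must be >= 0")
    out = ledger.copy()
    if coefficient_of_variation == 0:
        return out
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(coefficient_of_variation**2)))
    for key in sorted(out.rates):
        factor = float(rng.lognormal(mean=-sigma**2 / 2, sigma=sigma))
        entry = out.rates[key]
        out.rates[key] = LedgerEntry(
            value=entry.value * factor, provenance=f"sampled(seed={seed})"
        )
    return out
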