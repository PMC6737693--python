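"""Kinetic ODE model of the ER/EGFR/Notch1/GSK3β–β-Catenin signaling network.

The model describes receptor crosstalk in non-small-cell lung cancer cells:
estrogen receptor (ER, lumping ERα/ERβ) activity feeds into the EGFR, Notch1
and GSK3β/β-Catenin arms through redundant and positive-feedback routes.
Reactions follow three rate-law families — Henri–Michaelis–Menten kinetics,
mass-action, and constant-flux — plus two compositions of them for regulated
protein synthesis (basal + saturating induction, and Hill repression).

State variables are relative abundances (arbitrary units); time is in hours.
The three ligands EGF, 17β-E2 and Dll1 are boundary species held fixed at
their scenario levels.  The four model outputs are pAkt, pERK, β-Catenin and
Hes1.  Kinase pools (Akt, ERK, GSK3β) interconvert between phospho- and
dephospho-forms only, so each pool total is conserved; receptor and effector
species (ER, Notch1, NICD, Hes1, PTEN, β-Catenin) have explicit synthesis and
degradation.

Drug action is multiplicative: Gefitinib scales every EGFR-phosphorylation
rate by 1/(1 + dose/Ki_gef); Fulvestrant scales ER activation by
1/(1 + dose/Ki_ful) and accelerates ER degradation by (1 + dose/Ki_ful).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Species",
    "Reaction",
    "NetworkModel",
    "Scenario",
    "Trajectory",
    "ConstraintReport",
    "OUTPUT_SPECIES",
    "SCENARIO_PRESETS",
    "INPUT_LOW",
    "INPUT_HIGH",
    "build_reference_model",
    "load_default_parameters",
    "reaction_rate",
    "rhs",
    "equilibrate",
    "simulate",
    "output_indicators",
    "run_scenario_panel",
    "apply_treatment",
    "check_qualitative_constraints",
    "remove_reaction",
]

# ---------------------------------------------------------------------------
# Model data structures
# ---------------------------------------------------------------------------

RATE_LAWS = (
    "michaelis_menten",
    "mass_action",
    "constant_flux",
    "inducible_synthesis",
    "repressible_synthesis",
)

#: Species whose levels are read out as the model's output indicators.
OUTPUT_SPECIES = ("pAkt", "pERK", "bCatenin", "Hes1")

#: Ligand levels for the two-level stimulation design (arbitrary units).
INPUT_LOW = 0.01
INPUT_HIGH = 1.0

#: Kinase pools whose totals the reaction network must conserve.
CONSERVATION_POOLS = {
    "Akt": ("Akt", "pAkt"),
    "ERK": ("ERK", "pERK"),
    "GSK3b": ("GSK3b", "pGSK3b"),
}


@dataclass(frozen=True)
class Species:
    """A model state variable (or fixed boundary input)."""

    name: str
    role: str = "scaffold"
    initial_value: float = 0.0

    def __post_init__(self):
        if self.initial_value < 0:
            raise ValueError(f"initial value of {self.name} must be >= 0")


@dataclass(frozen=True)
class Reaction:
    """A typed reaction: rate-law family, connectivity and parameter names.

    ``parameters`` maps rate-law slots (``k``, ``K``, ``k_basal``, ``k_ind``,
    ``n``) to entries of a flat :class:`ParameterSet`-style mapping, so that
    parameters are data, shared between reactions where appropriate.
    ``tags`` mark drug sensitivity: ``gefitinib_inhibited``,
    ``fulvestrant_inhibited``, ``fulvestrant_enhanced``.
    """

    name: str
    law: str
    substrates: tuple = ()
    products: tuple = ()
    modifiers: tuple = ()
    parameters: Mapping[str, str] = field(default_factory=dict)
    tags: tuple = ()

    def __post_init__(self):
        if self.law not in RATE_LAWS:
            raise ValueError(f"unknown rate law {self.law!r} in {self.name}")
        if self.law == "michaelis_menten" and len(self.substrates) != 1:
            raise ValueError(f"{self.name}: michaelis_menten needs exactly one substrate")
        if self.law == "constant_flux" and self.substrates:
            raise ValueError(f"{self.name}: constant_flux has no substrate dependence")
        if self.law in ("inducible_synthesis", "repressible_synthesis") and len(self.modifiers) != 1:
            raise ValueError(f"{self.name}: {self.law} needs exactly one modifier")


@dataclass
class NetworkModel:
    """Species list, reaction list and declared conservation pools."""

    species: list
    reactions: list
    conservation_pools: dict = field(default_factory=lambda: dict(CONSERVATION_POOLS))
    output_species: tuple = OUTPUT_SPECIES

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        declared = set(names)
        for r in self.reactions:
            for s in (*r.substrates, *r.products, *r.modifiers):
                if s not in declared:
                    raise ValueError(f"reaction {r.name} references undeclared species {s!r}")

    # -- lookups ----------------------------------------------------------
    @property
    def species_names(self) -> list:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def reaction(self, name: str) -> Reaction:
        for r in self.reactions:
            if r.name == name:
                return r
        raise KeyError(name)

    def stoichiometry(self) -> np.ndarray:
        """Stoichiometry matrix, species x reactions (integer entries)."""
        idx = {s.name: i for i, s in enumerate(self.species)}
        n = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for s in r.substrates:
                n[idx[s], j] -= 1
            for s in r.products:
                n[idx[s], j] += 1
        return n

    def pool_stoichiometry_closed(self) -> bool:
        """True iff each declared conservation pool has zero net stoichiometry
        in every reaction (symbolic closure, independent of parameters)."""
        n = self.stoichiometry()
        idx = {s.name: i for i, s in enumerate(self.species)}
        for members in self.conservation_pools.values():
            rows = [idx[m] for m in members]
            if np.any(n[rows, :].sum(axis=0) != 0):
                return False
        return True

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "species": [asdict(s) for s in self.species],
            "reactions": [
                {
                    "name": r.name,
                    "law": r.law,
                    "substrates": list(r.substrates),
                    "products": list(r.products),
                    "modifiers": list(r.modifiers),
                    "parameters": dict(r.parameters),
                    "tags": list(r.tags),
                }
                for r in self.reactions
            ],
            "conservation_pools": {k: list(v) for k, v in self.conservation_pools.items()},
            "output_species": list(self.output_species),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        return cls(
            species=[Species(**s) for s in d["species"]],
            reactions=[
                Reaction(
                    name=r["name"],
                    law=r["law"],
                    substrates=tuple(r["substrates"]),
                    products=tuple(r["products"]),
                    modifiers=tuple(r["modifiers"]),
                    parameters=dict(r["parameters"]),
                    tags=tuple(r["tags"]),
                )
                for r in d["reactions"]
            ],
            conservation_pools={k: tuple(v) for k, v in d["conservation_pools"].items()},
            output_species=tuple(d["output_species"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "NetworkModel":
        return cls.from_dict(json.loads(s))

    def __eq__(self, other):
        return isinstance(other, NetworkModel) and self.to_dict() == other.to_dict()


@dataclass(frozen=True)
class Scenario:
    """One simulation condition: ligand levels plus drug doses.

    Ligand levels are in arbitrary units (presets: low = 0.01, high = 1.0);
    drug doses are in μM.
    """

    label: str
    egf_level: float = INPUT_LOW
    e2_level: float = INPUT_LOW
    dll1_level: float = INPUT_LOW
    gefitinib_dose: float = 0.0
    fulvestrant_dose: float = 0.0

    def __post_init__(self):
        for f in ("egf_level", "e2_level", "dll1_level", "gefitinib_dose", "fulvestrant_dose"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


def _preset(label, egf, e2, dll1):
    return Scenario(label=label, egf_level=egf, e2_level=e2, dll1_level=dll1)


#: The five stimulation presets of the two-level design.
SCENARIO_PRESETS = {
    "All-Low": _preset("All-Low", INPUT_LOW, INPUT_LOW, INPUT_LOW),
    "High-EGF": _preset("High-EGF", INPUT_HIGH, INPUT_LOW, INPUT_LOW),
    "High-Dll1": _preset("High-Dll1", INPUT_LOW, INPUT_LOW, INPUT_HIGH),
    "High-E2": _preset("High-E2", INPUT_LOW, INPUT_HIGH, INPUT_LOW),
    "All-High": _preset("All-High", INPUT_HIGH, INPUT_HIGH, INPUT_HIGH),
}

PRESET_ORDER = tuple(SCENARIO_PRESETS)


def apply_treatment(scenario: Scenario, gefitinib_dose: float = 0.0,
                    fulvestrant_dose: float = 0.0) -> Scenario:
    """Return a copy of ``scenario`` with drug doses set (μM); zero dose is identity."""
    if gefitinib_dose < 0 or fulvestrant_dose < 0:
        raise ValueError("drug doses must be >= 0")
    if gefitinib_dose == 0 and fulvestrant_dose == 0:
        return scenario
    label = scenario.label
    parts = []
    if gefitinib_dose > 0:
        parts.append(f"Gef{gefitinib_dose:g}")
    if fulvestrant_dose > 0:
        parts.append(f"Ful{fulvestrant_dose:g}")
    label = f"{label}+{'+'.join(parts)}"
    return Scenario(
        label=label,
        egf_level=scenario.egf_level,
        e2_level=scenario.e2_level,
        dll1_level=scenario.dll1_level,
        gefitinib_dose=gefitinib_dose,
        fulvestrant_dose=fulvestrant_dose,
    )


# ---------------------------------------------------------------------------
# Reference topology
# ---------------------------------------------------------------------------

def build_reference_model() -> NetworkModel:
    """Construct the reference network topology.

    Edges, by pathway arm:

    * **ER**: E2-induced ER synthesis (positive feedback) with first-order
      degradation (Fulvestrant-accelerated); E2-driven ER activation to ERa
      (Fulvestrant-inhibited); first-order ERa decay.
    * **EGFR**: EGF-driven and ERa-driven (transactivation) EGFR
      phosphorylation, both Gefitinib-inhibited; first-order dephosphorylation.
      No ERK→SOS negative feedback: ERK stays continuously activated.
    * **PI3K/Akt**: pEGFR-driven PIP3 production; PTEN-catalyzed PIP3 removal
      plus basal PIP3 turnover; PIP3-driven Akt phosphorylation; Hes1-repressed
      PTEN synthesis with first-order PTEN turnover (the Hes1/PTEN/PIP3 route).
    * **ERK**: pEGFR-driven ERK phosphorylation, first-order dephosphorylation.
    * **Notch1**: ERa-induced Notch1 synthesis; Dll1-catalyzed cleavage to NICD
      consuming Notch1 (the source of the Hes1 transient); NICD-induced Hes1
      synthesis; first-order Notch1/NICD/Hes1 decay.
    * **GSK3β/β-Catenin**: pAkt- and pERK-catalyzed GSK3β phosphorylation
      (inactivation) with dephosphorylation; β-Catenin synthesis = basal +
      ERa-induced (the GSK3β bypass); GSK3β-catalyzed β-Catenin degradation
      plus slow basal turnover.
    """
    species = [
        Species("EGF", "input"),
        Species("E2", "input"),
        Species("Dll1", "input"),
        Species("EGFR", "receptor", 1.0),
        Species("pEGFR", "active_receptor", 0.0),
        Species("ER", "receptor", 0.3),
        Species("ERa", "active_receptor", 0.0),
        Species("Notch1", "receptor", 1.0),
        Species("NICD", "transcriptional_effector", 0.0),
        Species("Hes1", "transcriptional_effector", 0.1),
        Species("PTEN", "scaffold", 1.0),
        Species("PIP3", "scaffold", 0.0),
        Species("Akt", "kinase", 1.0),
        Species("pAkt", "phospho_kinase", 0.0),
        Species("ERK", "kinase", 1.0),
        Species("pERK", "phospho_kinase", 0.0),
        Species("GSK3b", "kinase", 1.0),
        Species("pGSK3b", "phospho_kinase", 0.0),
        Species("bCatenin", "transcriptional_effector", 0.1),
    ]

    R = Reaction
    reactions = [
        # --- ER arm ---
        R("er_synthesis", "inducible_synthesis", products=("ER",), modifiers=("E2",),
          parameters={"k_basal": "kb_er_syn", "k_ind": "ki_er_syn", "K": "K_er_syn"}),
        R("er_degradation", "mass_action", substrates=("ER",),
          parameters={"k": "kdeg_er"}, tags=("fulvestrant_enhanced",)),
        R("er_activation", "mass_action", substrates=("ER",), products=("ERa",),
          modifiers=("E2",), parameters={"k": "k_er_act"}, tags=("fulvestrant_inhibited",)),
        R("era_degradation", "mass_action", substrates=("ERa",),
          parameters={"k": "kdeg_era"}),
        # --- EGFR arm ---
        R("egfr_phos_by_egf", "michaelis_menten", substrates=("EGFR",), products=("pEGFR",),
          modifiers=("EGF",), parameters={"k": "k_egfr_phos_egf", "K": "K_egfr_phos"},
          tags=("gefitinib_inhibited",)),
        R("egfr_phos_by_er", "michaelis_menten", substrates=("EGFR",), products=("pEGFR",),
          modifiers=("ERa",), parameters={"k": "k_egfr_phos_er", "K": "K_egfr_phos"},
          tags=("gefitinib_inhibited",)),
        R("egfr_dephos", "mass_action", substrates=("pEGFR",), products=("EGFR",),
          parameters={"k": "kdeph_egfr"}),
        # --- ERK arm (no ERK->SOS feedback) ---
        R("erk_phos", "michaelis_menten", substrates=("ERK",), products=("pERK",),
          modifiers=("pEGFR",), parameters={"k": "k_erk_phos", "K": "K_erk_phos"}),
        R("erk_dephos", "mass_action", substrates=("pERK",), products=("ERK",),
          parameters={"k": "kdeph_erk"}),
        # --- PI3K / Akt arm ---
        R("pip3_production", "mass_action", products=("PIP3",), modifiers=("pEGFR",),
          parameters={"k": "k_pip3_prod"}),
        R("pip3_decay", "mass_action", substrates=("PIP3",),
          parameters={"k": "kdeg_pip3"}),
        R("pip3_removal_by_pten", "michaelis_menten", substrates=("PIP3",),
          modifiers=("PTEN",), parameters={"k": "k_pip3_rem", "K": "K_pip3_rem"}),
        R("akt_phos", "michaelis_menten", substrates=("Akt",), products=("pAkt",),
          modifiers=("PIP3",), parameters={"k": "k_akt_phos", "K": "K_akt_phos"}),
        R("akt_dephos", "mass_action", substrates=("pAkt",), products=("Akt",),
          parameters={"k": "kdeph_akt"}),
        # --- PTEN (Hes1-repressed) ---
        R("pten_synthesis", "repressible_synthesis", products=("PTEN",), modifiers=("Hes1",),
          parameters={"k": "k_pten_syn", "K": "K_pten_syn", "n": "n_pten"}),
        R("pten_degradation", "mass_action", substrates=("PTEN",),
          parameters={"k": "kdeg_pten"}),
        # --- Notch arm ---
        R("notch1_synthesis", "inducible_synthesis", products=("Notch1",), modifiers=("ERa",),
          parameters={"k_basal": "kb_notch_syn", "k_ind": "ki_notch_syn", "K": "K_notch_syn"}),
        R("notch1_degradation", "mass_action", substrates=("Notch1",),
          parameters={"k": "kdeg_notch"}),
        R("notch1_cleavage", "mass_action", substrates=("Notch1",), products=("NICD",),
          modifiers=("Dll1",), parameters={"k": "k_notch_cleave"}),
        R("nicd_degradation", "mass_action", substrates=("NICD",),
          parameters={"k": "kdeg_nicd"}),
        R("hes1_synthesis", "inducible_synthesis", products=("Hes1",), modifiers=("NICD",),
          parameters={"k_basal": "kb_hes_syn", "k_ind": "ki_hes_syn", "K": "K_hes_syn"}),
        R("hes1_degradation", "mass_action", substrates=("Hes1",),
          parameters={"k": "kdeg_hes1"}),
        # --- GSK3b / b-Catenin arm ---
        R("gsk3b_phos_by_akt", "michaelis_menten", substrates=("GSK3b",), products=("pGSK3b",),
          modifiers=("pAkt",), parameters={"k": "k_gsk_phos_akt", "K": "K_gsk_phos"}),
        R("gsk3b_phos_by_erk", "michaelis_menten", substrates=("GSK3b",), products=("pGSK3b",),
          modifiers=("pERK",), parameters={"k": "k_gsk_phos_erk", "K": "K_gsk_phos"}),
        R("gsk3b_dephos", "mass_action", substrates=("pGSK3b",), products=("GSK3b",),
          parameters={"k": "kdeph_gsk"}),
        R("bcat_synthesis", "inducible_synthesis", products=("bCatenin",), modifiers=("ERa",),
          parameters={"k_basal": "kb_bcat_syn", "k_ind": "ki_bcat_syn", "K": "K_bcat_syn"}),
        R("bcat_degradation_by_gsk3b", "michaelis_menten", substrates=("bCatenin",),
          modifiers=("GSK3b",), parameters={"k": "k_bcat_deg", "K": "K_bcat_deg"}),
        R("bcat_decay_basal", "mass_action", substrates=("bCatenin",),
          parameters={"k": "kdeg_bcat_basal"}),
    ]
    return NetworkModel(species=species, reactions=reactions)


def load_default_parameters() -> dict:
    """Load the shipped default parameterization (calibrated to the five-scenario
    qualitative behavior; see ``docs/methods.md``)."""
    text = resources.files("ernet.data").joinpath("default_params.json").read_text()
    return json.loads(text)


def remove_reaction(model: NetworkModel, name: str) -> NetworkModel:
    """Return a copy of ``model`` without the named reaction (ablation helper)."""
    model.reaction(name)  # KeyError if absent
    out = copy.deepcopy(model)
    out.reactions = [r for r in out.reactions if r.name != name]
    return out


# ---------------------------------------------------------------------------
# Rate laws and right-hand side
# ---------------------------------------------------------------------------

def _drug_factor(reaction: Reaction, scenario: Scenario, params: Mapping[str, float]) -> float:
    f = 1.0
    if "gefitinib_inhibited" in reaction.tags and scenario.gefitinib_dose > 0:
        f /= 1.0 + scenario.gefitinib_dose / params["Ki_gef"]
    if "fulvestrant_inhibited" in reaction.tags and scenario.fulvestrant_dose > 0:
        f /= 1.0 + scenario.fulvestrant_dose / params["Ki_ful"]
    if "fulvestrant_enhanced" in reaction.tags and scenario.fulvestrant_dose > 0:
        f *= 1.0 + scenario.fulvestrant_dose / params["Ki_ful"]
    return f


def reaction_rate(reaction: Reaction, state: Mapping[str, float],
                  params: Mapping[str, float], scenario: Scenario | None = None) -> float:
    """Evaluate one reaction's flux (a.u./h) at a named state.

    Convenience scalar form used for inspection and testing; `rhs` uses a
    compiled vectorized equivalent.
    """
    for s in (*reaction.substrates, *reaction.modifiers):
        if state[s] < 0:
            raise ValueError(f"negative state for {s} in reaction {reaction.name}")
    p = {slot: params[name] for slot, name in reaction.parameters.items()}
    mod = 1.0
    for m in reaction.modifiers:
        mod *= state[m]
    if reaction.law == "michaelis_menten":
        s_val = state[reaction.substrates[0]]
        v = p["k"] * mod * s_val / (p["K"] + s_val)
    elif reaction.law == "mass_action":
        v = p["k"] * mod
        for s in reaction.substrates:
            v *= state[s]
    elif reaction.law == "constant_flux":
        v = p["k"]
    elif reaction.law == "inducible_synthesis":
        m_val = state[reaction.modifiers[0]]
        v = p["k_basal"] + p["k_ind"] * m_val / (p["K"] + m_val)
    elif reaction.law == "repressible_synthesis":
        m_val = state[reaction.modifiers[0]]
        v = p["k"] / (1.0 + (m_val / p["K"]) ** p["n"])
    else:  # pragma: no cover - guarded by Reaction.__post_init__
        raise ValueError(reaction.law)
    if scenario is not None:
        v *= _drug_factor(reaction, scenario, params)
    return v


class _CompiledModel:
    """Index-resolved model bound to one scenario and parameter set.

    Pre-resolves species indices, parameter values and drug factors so the
    ODE right-hand side is a tight loop over reactions.
    """

    LAW_CODE = {law: i for i, law in enumerate(RATE_LAWS)}

    def __init__(self, model: NetworkModel, params: Mapping[str, float], scenario: Scenario):
        self.model = model
        self.scenario = scenario
        idx = {s.name: i for i, s in enumerate(model.species)}
        levels = {"EGF": scenario.egf_level, "E2": scenario.e2_level,
                  "Dll1": scenario.dll1_level}
        self.input_indices = {idx[n]: lv for n, lv in levels.items() if n in idx}
        self.n_species = len(model.species)
        self.stoich = model.stoichiometry()
        self.compiled = []
        missing = [n for r in model.reactions for n in r.parameters.values() if n not in params]
        if missing:
            raise KeyError(f"parameter set incomplete: missing {sorted(set(missing))}")
        for r in model.reactions:
            p = {slot: float(params[name]) for slot, name in r.parameters.items()}
            fac = _drug_factor(r, scenario, params)
            subs = tuple(idx[s] for s in r.substrates)
            mods = tuple(idx[m] for m in r.modifiers)
            self.compiled.append((r.name, self.LAW_CODE[r.law], subs, mods, p, fac))
        self._build_vectorized()

    def _build_vectorized(self):
        """Index-array fast path for models where every reaction has at most
        one substrate and one modifier (true of the reference topology);
        absent slots point at a trailing constant-one state entry."""
        self._vectorized = all(len(s) <= 1 and len(m) <= 1
                               for _, _, s, m, _, _ in self.compiled)
        if not self._vectorized:
            return
        nr = len(self.compiled)
        one = self.n_species  # index of the appended 1.0 slot
        self._sub = np.array([s[0] if s else one for _, _, s, _, _, _ in self.compiled])
        self._mod = np.array([m[0] if m else one for _, _, _, m, _, _ in self.compiled])
        self._law = np.array([law for _, law, _, _, _, _ in self.compiled])
        self._k = np.zeros(nr)
        self._K = np.ones(nr)
        self._kb = np.zeros(nr)
        self._n = np.ones(nr)
        self._fac = np.array([fac for *_, fac in self.compiled])
        for j, (_, law, _, _, p, _) in enumerate(self.compiled):
            if law == 3:  # inducible_synthesis: k_basal + k_ind*M/(K+M)
                self._kb[j] = p["k_basal"]
                self._k[j] = p["k_ind"]
                self._K[j] = p["K"]
            else:
                self._k[j] = p["k"]
                self._K[j] = p.get("K", 1.0)
                self._n[j] = p.get("n", 1.0)
        self._is_mm = self._law == 0
        self._is_ma = self._law == 1
        self._is_rep = self._law == 4
        self._names = [name for name, *_ in self.compiled]

    def initial_state(self, x0: np.ndarray | None = None) -> np.ndarray:
        if x0 is None:
            x = np.array([s.initial_value for s in self.model.species], float)
        else:
            x = np.asarray(x0, float).copy()
        for i, level in self.input_indices.items():
            x[i] = level
        return x

    def rates(self, x: np.ndarray) -> np.ndarray:
        xc = np.maximum(x, 0.0)  # tolerate solver round-off below zero
        if self._vectorized:
            xe = np.append(xc, 1.0)
            s = xe[self._sub]
            m = xe[self._mod]
            # start from the inducible/constant-flux form, overwrite per law
            v = self._kb + self._k * m / (self._K + m)
            mm = self._is_mm
            v[mm] = self._k[mm] * m[mm] * s[mm] / (self._K[mm] + s[mm])
            ma = self._is_ma
            v[ma] = self._k[ma] * s[ma] * m[ma]
            cf = self._law == 2
            v[cf] = self._k[cf]
            rp = self._is_rep
            v[rp] = self._k[rp] / (1.0 + (m[rp] / self._K[rp]) ** self._n[rp])
            v *= self._fac
            if not np.all(np.isfinite(v)):
                bad = self._names[int(np.argmin(np.isfinite(v)))]
                raise FloatingPointError(f"non-finite rate in reaction {bad}")
            return v
        v = np.empty(len(self.compiled))
        for j, (name, law, subs, mods, p, fac) in enumerate(self.compiled):
            mod = 1.0
            for m in mods:
                mod *= xc[m]
            if law == 0:  # michaelis_menten
                s = xc[subs[0]]
                val = p["k"] * mod * s / (p["K"] + s)
            elif law == 1:  # mass_action
                val = p["k"] * mod
                for si in subs:
                    val *= xc[si]
            elif law == 2:  # constant_flux
                val = p["k"]
            elif law == 3:  # inducible_synthesis
                m = xc[mods[0]]
                val = p["k_basal"] + p["k_ind"] * m / (p["K"] + m)
            else:  # repressible_synthesis
                m = xc[mods[0]]
                val = p["k"] / (1.0 + (m / p["K"]) ** p["n"])
            v[j] = val * fac
            if not np.isfinite(v[j]):
                raise FloatingPointError(f"non-finite rate in reaction {name}")
        return v

    def __call__(self, t, x):
        dx = self.stoich @ self.rates(x)
        for i in self.input_indices:
            dx[i] = 0.0  # boundary species held at scenario level
        return dx


def rhs(model: NetworkModel, state: np.ndarray, scenario: Scenario,
        params: Mapping[str, float], t: float = 0.0) -> np.ndarray:
    """dx/dt = stoichiometry · rates, with ligand inputs held fixed."""
    return _CompiledModel(model, params, scenario)(t, np.asarray(state, float))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Dense solution of one scenario simulation."""

    times: np.ndarray
    states: np.ndarray  # species x time
    species_names: list
    scenario: Scenario

    def value(self, species: str, t) -> np.ndarray | float:
        row = self.states[self.species_names.index(species)]
        return np.interp(t, self.times, row)

    def series(self, species: str) -> np.ndarray:
        return self.states[self.species_names.index(species)]

    def pool_drift(self, pool_members: Sequence[str]) -> float:
        """Max relative deviation of a pool total from its initial value."""
        rows = [self.species_names.index(m) for m in pool_members]
        total = self.states[rows].sum(axis=0)
        return float(np.max(np.abs(total - total[0])) / total[0])

    def to_frame(self):
        import pandas as pd

        recs = []
        for i, name in enumerate(self.species_names):
            for t, v in zip(self.times, self.states[i]):
                recs.append((self.scenario.label, name, t, v))
        return pd.DataFrame(recs, columns=["scenario", "species", "time_h", "value"])


class SimulationError(RuntimeError):
    pass


DEFAULT_BURN_IN_H = 200.0


def equilibrate(model: NetworkModel, params: Mapping[str, float],
                t_burn: float = DEFAULT_BURN_IN_H, rtol: float = 1e-8,
                atol: float = 1e-10, method: str = "LSODA",
                polish: bool = True) -> np.ndarray:
    """Burn in the untreated All-Low condition and return the resting state.

    This pre-equilibrated state is the model's definition of the inactive
    network baseline; every scenario simulation starts from it.  A Newton
    polish after the burn-in pins the slowest species (protein turnover on
    the tens-of-hours scale) to the exact fixed point; if the polish fails
    or wanders, the integrated endpoint is returned as is.
    """
    comp = _CompiledModel(model, params, SCENARIO_PRESETS["All-Low"])
    x0 = comp.initial_state()
    sol = solve_ivp(comp, (0.0, t_burn), x0, method=method, rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(f"burn-in failed: {sol.message}")
    x_end = sol.y[:, -1]
    if not polish:
        return x_end
    from scipy.optimize import least_squares as _lsq

    free = np.array([i for i in range(comp.n_species) if i not in comp.input_indices])

    def f(y):
        x = x_end.copy()
        x[free] = y
        return comp(0.0, x)[free]

    res = _lsq(f, np.maximum(x_end[free], 0.0), bounds=(0.0, np.inf),
               xtol=1e-14, ftol=1e-14, gtol=1e-14)
    x_fix = x_end.copy()
    x_fix[free] = res.x
    # accept only a nearby fixed point (trust-region keeps it local, but guard)
    if (np.max(np.abs(comp(0.0, x_fix))) < 1e-10
            and np.all(np.abs(x_fix - x_end) <= 1e-3 + 0.05 * np.abs(x_end))):
        return x_fix
    return x_end


def simulate(model: NetworkModel, scenario: Scenario, params: Mapping[str, float],
             t_end: float = 48.0, n_points: int = 241, rtol: float = 1e-8,
             atol: float = 1e-10, method: str = "LSODA",
             x0: np.ndarray | None = None, burn_in: float | None = None) -> Trajectory:
    """Integrate one scenario for ``t_end`` hours from the pre-equilibrated state.

    ``x0`` overrides the initial state (ligand inputs are still reset to the
    scenario's levels); otherwise a burn-in of ``burn_in`` hours (default
    200 h) under untreated All-Low conditions supplies it.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if x0 is None:
        x0 = equilibrate(model, params, DEFAULT_BURN_IN_H if burn_in is None else burn_in,
                         rtol=rtol, atol=atol, method=method)
    comp = _CompiledModel(model, params, scenario)
    x0 = comp.initial_state(x0)
    times = np.linspace(0.0, t_end, max(int(n_points), 200))
    sol = solve_ivp(comp, (0.0, t_end), x0, method=method, rtol=rtol, atol=atol,
                    t_eval=times)
    if not sol.success:
        reached = sol.t[-1] if sol.t.size else 0.0
        raise SimulationError(
            f"scenario {scenario.label!r}: solver failed at t={reached:.3g} h: {sol.message}")
    states = sol.y
    if states.min() < -1e-9:
        raise SimulationError(
            f"scenario {scenario.label!r}: state fell below -1e-9 ({states.min():.3g})")
    return Trajectory(times=sol.t, states=states,
                      species_names=model.species_names, scenario=scenario)


# ---------------------------------------------------------------------------
# Scenario panel and qualitative constraints
# ---------------------------------------------------------------------------

def output_indicators(traj: Trajectory, t_readout: float = 48.0,
                      outputs: Iterable[str] = OUTPUT_SPECIES) -> dict:
    """Readout value at ``t_readout`` plus peak value/time per output species."""
    if t_readout > traj.times[-1] + 1e-12:
        raise ValueError(f"readout time {t_readout} beyond trajectory horizon {traj.times[-1]}")
    row = {"scenario": traj.scenario.label}
    for sp in outputs:
        series = traj.series(sp)
        k = int(np.argmax(series))
        row[f"{sp}_readout"] = float(np.interp(t_readout, traj.times, series))
        row[f"{sp}_peak"] = float(series[k])
        row[f"{sp}_peak_time"] = float(traj.times[k])
    return row


def run_scenario_panel(model: NetworkModel, params: Mapping[str, float],
                       scenarios: Mapping[str, Scenario] | None = None,
                       t_end: float = 48.0, t_readout: float = 48.0,
                       rtol: float = 1e-8, atol: float = 1e-10):
    """Simulate each scenario from a shared baseline; return a panel DataFrame.

    The burn-in is computed once and reused across scenarios. The returned
    frame is indexed by scenario label and carries the baseline output values
    in ``.attrs['baseline']``.
    """
    import pandas as pd

    if scenarios is None:
        scenarios = SCENARIO_PRESETS
    x0 = equilibrate(model, params, rtol=rtol, atol=atol)
    names = model.species_names
    baseline = {sp: float(x0[names.index(sp)]) for sp in model.output_species}
    rows = []
    for sc in scenarios.values():
        traj = simulate(model, sc, params, t_end=t_end, x0=x0, rtol=rtol, atol=atol)
        rows.append(output_indicators(traj, t_readout, model.output_species))
    panel = pd.DataFrame(rows).set_index("scenario")
    panel.attrs["baseline"] = baseline
    return panel


@dataclass
class ConstraintReport:
    """Boolean verdicts for the qualitative scenario-panel constraints."""

    results: dict
    details: dict

    @property
    def all_pass(self) -> bool:
        return all(self.results.values())

    def __iter__(self):
        return iter(self.results.items())


#: Operationalization constants for the qualitative constraints (ratios vs the
#: pre-equilibrated baseline). See docs/methods.md for how they were fixed.
QUALITATIVE_THRESHOLDS = {
    "baseline_band": (0.8, 1.25),   # C1: All-Low stays at baseline
    "strong_activation": 2.0,       # C2: High-EGF pAkt/pERK fold rise
    "unaffected_max": 1.2,          # C2: High-EGF bCatenin/Hes1 cap; C4 floor
    "transient_peak_time_h": 12.0,  # C3: Hes1 peak must occur this early
    "transient_decay": 0.5,         # C3: Hes1(48 h) below this fraction of peak
    "slight_band": (1.0, 2.0),      # C3: High-Dll1 pAkt rise is "slight"
    "reactivation_ratio": 2.0,      # C6: pAkt(High-E2+Gef) / pAkt(All-Low+Gef)
}


def check_qualitative_constraints(panel, treated_panel=None, baseline=None,
                                  thresholds: Mapping | None = None) -> ConstraintReport:
    """Check the six qualitative constraints on a five-preset scenario panel.

    ``panel`` is the output of :func:`run_scenario_panel` over the presets;
    ``treated_panel`` must contain rows ``High-E2+Gef20`` and ``All-Low+Gef20``
    for the Gefitinib-reactivation check (C6), which is skipped (reported
    False) when absent. ``baseline`` defaults to ``panel.attrs['baseline']``.
    """
    th = dict(QUALITATIVE_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    if baseline is None:
        baseline = panel.attrs.get("baseline")
    if baseline is None:
        raise ValueError("baseline output values required")
    missing = [s for s in PRESET_ORDER if s not in panel.index]
    if missing:
        raise ValueError(f"panel missing scenario rows: {missing}")

    def ratio(scen, sp):
        return panel.loc[scen, f"{sp}_readout"] / baseline[sp]

    results, details = {}, {}

    lo, hi = th["baseline_band"]
    c1 = {sp: ratio("All-Low", sp) for sp in OUTPUT_SPECIES}
    results["C1_all_low_inactive"] = bool(all(lo <= r <= hi for r in c1.values()))
    details["C1_all_low_inactive"] = c1

    c2 = {sp: ratio("High-EGF", sp) for sp in OUTPUT_SPECIES}
    results["C2_egf_activates_akt_erk_only"] = bool(
        c2["pAkt"] >= th["strong_activation"]
        and c2["pERK"] >= th["strong_activation"]
        and c2["bCatenin"] <= th["unaffected_max"]
        and c2["Hes1"] <= th["unaffected_max"]
    )
    details["C2_egf_activates_akt_erk_only"] = c2

    hes_peak = panel.loc["High-Dll1", "Hes1_peak"]
    hes_pt = panel.loc["High-Dll1", "Hes1_peak_time"]
    hes_48 = panel.loc["High-Dll1", "Hes1_readout"]
    pakt_r = ratio("High-Dll1", "pAkt")
    slo, shi = th["slight_band"]
    results["C3_dll1_transient_hes1"] = bool(
        hes_pt < th["transient_peak_time_h"]
        and hes_48 < th["transient_decay"] * hes_peak
        and slo < pakt_r < shi
    )
    details["C3_dll1_transient_hes1"] = {
        "Hes1_peak_time": hes_pt, "Hes1_48_over_peak": hes_48 / hes_peak,
        "pAkt_ratio": pakt_r,
    }

    c4 = {sp: ratio("High-E2", sp) for sp in OUTPUT_SPECIES}
    results["C4_e2_raises_all_outputs"] = bool(all(r > th["unaffected_max"] for r in c4.values()))
    details["C4_e2_raises_all_outputs"] = c4

    others = [s for s in PRESET_ORDER if s != "All-High"]
    c5 = {
        sp: bool(panel.loc["All-High", f"{sp}_readout"]
                 >= max(panel.loc[o, f"{sp}_readout"] for o in others))
        for sp in OUTPUT_SPECIES
    }
    results["C5_all_high_maximal"] = bool(all(c5.values()))
    details["C5_all_high_maximal"] = c5

    if treated_panel is not None and {"High-E2+Gef20", "All-Low+Gef20"} <= set(treated_panel.index):
        r = (treated_panel.loc["High-E2+Gef20", "pAkt_readout"]
             / treated_panel.loc["All-Low+Gef20", "pAkt_readout"])
        results["C6_er_reactivates_egfr_under_gefitinib"] = bool(r > th["reactivation_ratio"])
        details["C6_er_reactivates_egfr_under_gefitinib"] = {"pAkt_ratio": r}
    else:
        results["C6_er_reactivates_egfr_under_gefitinib"] = False
        details["C6_er_reactivates_egfr_under_gefitinib"] = {"pAkt_ratio": None}

    return ConstraintReport(results=results, details=details)


def run_treated_panel(model: NetworkModel, params: Mapping[str, float],
                      gefitinib_dose: float = 20.0, fulvestrant_dose: float = 0.0,
                      scenarios: Iterable[str] = ("All-Low", "High-E2"),
                      rtol: float = 1e-8, atol: float = 1e-10):
    """Scenario panel under drug treatment (default: Gefitinib 20 μM)."""
    treated = {}
    for name in scenarios:
        sc = apply_treatment(SCENARIO_PRESETS[name], gefitinib_dose, fulvestrant_dose)
        treated[sc.label] = sc
    return run_scenario_panel(model, params, treated, rtol=rtol, atol=atol)
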