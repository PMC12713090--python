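"""Graftable biosynthesis chemistry and strain-design interventions.

This module encodes, as self-contained reaction sets (:class:`PathwayModule`):

* the spinosad biosynthetic module — polyketide aglycone assembly from
  acyl-CoA precursors (acetyl-CoA start for spinosyn A, propionyl-CoA start
  for the extra 6-methyl of spinosyn D), the TDP-L-rhamnose branch (gtt /
  gdh / epi / kre), a lumped TDP-D-forosamine branch, O-glycosylation to the
  pseudoaglycone, rhamnose tri-O-methylation and forosaminylation to the
  spinosyns, and demand reactions for the products;

* the artificial NCM pathway — a non-carboxylative C3→C3 route from
  pyruvate to malonyl-CoA via 3-oxopropanoate (malonate semialdehyde),
  catalysed by BauA and MCR-C, with no CO2 release, no carbon loss, and no
  ATP consumption, bypassing the ATP-dependent, CO2-cycling ACC route.

Cofactor stoichiometries (NADPH, SAM, CoA release, CO2 from decarboxylative
PKS condensations) are documented defaults carried in each reaction's note
and overridable; pathway topology, not coefficient detail, is what the
downstream flux analysis consumes. NAD(P)H species are modeled in their
proton-lumped form (NADPH·H+), so no free-proton bookkeeping is needed.

Interventions (:class:`InterventionSpec`) encode the engineering strategies
as model edits: bound amplification (cluster copy-number increase), module
grafting, knockout (competing-cluster elimination), and opening stored-lipid
degradation (a static stand-in for dynamic late-phase TAG mobilization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core import (
    DEFAULT_BOUND,
    Metabolite,
    MetabolicModel,
    ModelError,
    Reaction,
)
from .lp import FluxDistribution, maximize_flux

#: id prefixes reserved for grafted module content
RESERVED_PREFIXES = ("SPN_", "NCM_")


class MappingError(ModelError):
    """A module species could not be resolved to a host metabolite."""


@dataclass
class PathwayModule:
    """A self-contained reaction set ready to graft onto a host model."""

    name: str
    reactions: List[Reaction]
    new_metabolites: List[Metabolite]
    notes: Dict[str, str] = field(default_factory=dict)

    @property
    def new_metabolite_ids(self) -> List[str]:
        return [m.id for m in self.new_metabolites]

    def currency_metabolites(self) -> List[str]:
        """Species the module expects the host to provide (or absorb)."""
        new = set(self.new_metabolite_ids)
        seen: Dict[str, None] = {}
        for r in self.reactions:
            for met in r.stoichiometry:
                if met not in new:
                    seen.setdefault(met, None)
        return list(seen)


@dataclass
class InterventionSpec:
    """One engineering edit applied to a model.

    kind:
        "amplify" — multiply |bounds| of the target reactions by ``factor``
        (gene-cluster copy-number increase); "knockout" — zero both bounds;
        "add_module" — graft ``module``; "enable_degradation" — open the
        target reactions' upper bounds (stored-pool mobilization).
    """

    kind: str
    target_reaction_ids: Tuple[str, ...] = ()
    module: Optional[PathwayModule] = None
    factor: float = 1.0
    mapping: Optional[Dict[str, str]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("amplify", "add_module", "knockout", "enable_degradation"):
            raise ModelError(f"unknown intervention kind {self.kind!r}")
        if self.factor <= 0:
            raise ModelError("intervention factor must be positive")
        if self.kind == "add_module" and self.module is None:
            raise ModelError("add_module intervention requires a module")
        self.target_reaction_ids = tuple(self.target_reaction_ids)


@dataclass
class ScenarioResult:
    scenario: str
    max_target_flux: float
    yield_per_substrate: float
    delta_vs_base: float
    status: str = "optimal"


# ---------------------------------------------------------------------------
# Module builders
# ---------------------------------------------------------------------------

# currency species every builder assumes the host can supply/absorb;
# ids are the shipped toy-host vocabulary, remappable at graft time
_SPN_GENES_PKS = "spnA and spnB and spnC and spnD and spnE"


def _mets(*specs: Tuple[str, str, Optional[str]]) -> List[Metabolite]:
    return [Metabolite(id=i, name=n, compartment="c", formula=f) for i, n, f in specs]


def build_spinosad_module(granularity: str = "branch") -> PathwayModule:
    """The spinosad biosynthetic module.

    ``branch`` granularity keeps the four rhamnose-branch reactions as
    separate gene-tagged steps (gtt, gdh, epi, kre); ``lumped`` collapses
    each precursor branch to a single mass-balanced reaction. Both include
    aglycone assembly for the A (acetyl-CoA-started) and D
    (propionyl-CoA-started) congeners, pseudoaglycone formation, conversion
    to spinosyn A/D, and demand reactions for both products.
    """
    if granularity not in ("lumped", "branch"):
        raise ModelError(f"unknown granularity {granularity!r}")

    new_mets = _mets(
        ("SPN_tdpglc", "TDP-D-glucose", None),
        ("SPN_tdp46dg", "TDP-4-keto-6-deoxyglucose", None),
        ("SPN_tdp4krha", "TDP-4-keto-rhamnose", None),
        ("SPN_tdprha", "TDP-L-rhamnose", None),
        ("SPN_tdpfor", "TDP-D-forosamine", None),
        ("SPN_aglyA", "spinosyn aglycone (acetyl start)", None),
        ("SPN_aglyD", "spinosyn aglycone (propionyl start)", None),
        ("SPN_psaA", "pseudoaglycone A", None),
        ("SPN_psaD", "pseudoaglycone D", None),
        ("SPN_spnA", "spinosyn A", None),
        ("SPN_spnD", "spinosyn D", None),
    )

    rxns: List[Reaction] = []
    notes: Dict[str, str] = {}

    def add(rid, stoich, gpr="", note=""):
        rxns.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
                gene_rule=gpr,
                subsystem="spinosad biosynthesis",
            )
        )
        notes[rid] = note

    if granularity == "branch":
        add(
            "SPN_RHAM_gtt",
            {"g1p": -1, "dttp": -1, "SPN_tdpglc": 1, "ppi": 1},
            "gtt",
            "glucose-1-phosphate thymidylyltransferase",
        )
        add(
            "SPN_RHAM_gdh",
            {"SPN_tdpglc": -1, "SPN_tdp46dg": 1, "h2o": 1},
            "gdh",
            "TDP-glucose 4,6-dehydratase",
        )
        add(
            "SPN_RHAM_epi",
            {"SPN_tdp46dg": -1, "SPN_tdp4krha": 1},
            "epi",
            "TDP-4-keto-6-deoxyglucose 3,5-epimerase",
        )
        add(
            "SPN_RHAM_kre",
            {"SPN_tdp4krha": -1, "nadph": -1, "SPN_tdprha": 1, "nadp": 1},
            "kre",
            "TDP-4-keto-rhamnose 4-ketoreductase (NADPH)",
        )
    else:
        add(
            "SPN_RHAM_LUMP",
            {
                "g1p": -1,
                "dttp": -1,
                "nadph": -1,
                "SPN_tdprha": 1,
                "ppi": 1,
                "nadp": 1,
                "h2o": 1,
            },
            "gtt and gdh and epi and kre",
            "lumped TDP-L-rhamnose branch",
        )

    add(
        "SPN_FORO_SYN",
        {
            "g1p": -1,
            "dttp": -1,
            "nadph": -2,
            "glu": -1,
            "sam": -2,
            "SPN_tdpfor": 1,
            "ppi": 1,
            "h2o": 1,
            "nadp": 2,
            "akg": 1,
            "sah": 2,
        },
        "spnO and spnN and spnQ and spnR and spnS",
        "lumped TDP-D-forosamine branch: deoxygenation (2 NADPH), "
        "transamination (glutamate), N,N-dimethylation (2 SAM)",
    )

    # 9-extension type-I PKS: starter-CoA + 7 malonyl-CoA + 2 methylmalonyl-CoA;
    # each extension is a decarboxylative condensation releasing CO2 and CoA,
    # 10 NADPH for ketoreductions / the cross-bridging reductions (default)
    pks_core = {
        "malcoa": -7,
        "mmcoa": -2,
        "nadph": -10,
        "co2": 9,
        "coa": 10,
        "nadp": 10,
    }
    add(
        "SPN_AGL_SYN_A",
        {"accoa": -1, "SPN_aglyA": 1, **pks_core},
        _SPN_GENES_PKS,
        "aglycone assembly, acetyl-CoA starter (spinosyn A series)",
    )
    add(
        "SPN_AGL_SYN_D",
        {"ppcoa": -1, "SPN_aglyD": 1, **pks_core},
        _SPN_GENES_PKS,
        "aglycone assembly, propionyl-CoA starter (6-methyl, spinosyn D series)",
    )
    add(
        "SPN_PSA_SYN_A",
        {"SPN_aglyA": -1, "SPN_tdprha": -1, "SPN_psaA": 1, "tdp": 1},
        "spnG",
        "rhamnosyltransferase",
    )
    add(
        "SPN_PSA_SYN_D",
        {"SPN_aglyD": -1, "SPN_tdprha": -1, "SPN_psaD": 1, "tdp": 1},
        "spnG",
        "rhamnosyltransferase",
    )
    tailoring = "spnH and spnI and spnK and spnP"
    add(
        "SPN_SPNA_SYN",
        {
            "SPN_psaA": -1,
            "sam": -3,
            "SPN_tdpfor": -1,
            "SPN_spnA": 1,
            "sah": 3,
            "tdp": 1,
        },
        tailoring,
        "rhamnose 2',3',4'-tri-O-methylation (3 SAM) + forosaminylation",
    )
    add(
        "SPN_SPND_SYN",
        {
            "SPN_psaD": -1,
            "sam": -3,
            "SPN_tdpfor": -1,
            "SPN_spnD": 1,
            "sah": 3,
            "tdp": 1,
        },
        tailoring,
        "rhamnose tri-O-methylation + forosaminylation (D congener)",
    )
    add("SPN_DM_spnA", {"SPN_spnA": -1}, "", "spinosyn A demand/exchange")
    add("SPN_DM_spnD", {"SPN_spnD": -1}, "", "spinosyn D demand/exchange")
    # optional combined product sink reflecting the ~85:15 A:D mixture
    add(
        "SPN_DM_spinosad",
        {"SPN_spnA": -0.85, "SPN_spnD": -0.15},
        "",
        "combined spinosad demand (0.85 A + 0.15 D); closed by default",
    )
    rxns[-1].upper_bound = 0.0

    return PathwayModule(
        name=f"spinosad ({granularity})",
        reactions=rxns,
        new_metabolites=new_mets,
        notes=notes,
    )


#: default FSEOF target in a spinosad-grafted model
SPINOSYN_A_DEMAND = "SPN_DM_spnA"


def build_ncm_module() -> PathwayModule:
    """The artificial non-carboxylative malonyl-CoA (NCM) pathway.

    Two reactions: BauA isomerizes pyruvate to 3-oxopropanoate (malonate
    semialdehyde); MCR-C condenses it with CoA under NADP+ to malonyl-CoA.
    The route conserves all three carbons, releases no CO2, and consumes no
    ATP — unlike the ACC route (acetyl-CoA + ATP + CO2). Reductant choice
    (NADP couple, proton-lumped formulas) is a recorded default.
    """
    new_mets = _mets(
        ("NCM_msa", "3-oxopropanoate (malonate semialdehyde)", "C3H4O3"),
    )
    rxns = [
        Reaction(
            id="NCM_BauA",
            stoichiometry={"pyr": -1, "NCM_msa": 1},
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
            gene_rule="BauA",
            subsystem="NCM pathway",
        ),
        Reaction(
            id="NCM_MCRC",
            stoichiometry={"NCM_msa": -1, "coa": -1, "nadp": -1, "malcoa": 1, "nadph": 1},
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
            gene_rule="MCR_C",
            subsystem="NCM pathway",
        ),
    ]
    notes = {
        "NCM_BauA": "pyruvate -> malonate semialdehyde; net isomerization, "
        "C3 conserved (C3H4O3 -> C3H4O3)",
        "NCM_MCRC": "malonate semialdehyde + CoA + NADP+ -> malonyl-CoA + NADPH; "
        "oxidative thioesterification, no ATP",
        "formulas": "currency formulas assumed at graft: pyr C3H4O3, "
        "coa C21H36N7O16P3S, malcoa C24H38N7O19P3S, nadp C21H28N7O17P3, "
        "nadph C21H30N7O17P3 (NADPH·H+ lumped)",
    }
    return PathwayModule(
        name="NCM", reactions=rxns, new_metabolites=new_mets, notes=notes
    )


#: currency formulas the NCM module assumes, used by its structural checks
NCM_CURRENCY_FORMULAS = {
    "pyr": "C3H4O3",
    "coa": "C21H36N7O16P3S",
    "malcoa": "C24H38N7O19P3S",
    "nadp": "C21H28N7O17P3",
    "nadph": "C21H30N7O17P3",
}


def module_element_balance(
    module: PathwayModule,
    currency_formulas: Dict[str, str],
    element: str = "C",
) -> Dict[str, float]:
    """Net production of one element per module reaction.

    Formulas come from the module's own declared metabolites, supplemented by
    ``currency_formulas`` for host-supplied species. A conserved element nets
    to zero in every reaction. Raises if any participant lacks a formula.
    """
    from .core import parse_formula

    formulas = dict(currency_formulas)
    for m in module.new_metabolites:
        if m.formula is not None:
            formulas[m.id] = m.formula
    out: Dict[str, float] = {}
    for r in module.reactions:
        net = 0.0
        for met, coef in r.stoichiometry.items():
            if met not in formulas:
                raise ModelError(
                    f"no formula for {met!r} in module {module.name!r}"
                )
            net += coef * parse_formula(formulas[met]).get(element, 0.0)
        out[r.id] = net
    return out


def module_species_present(module: PathwayModule, species_ids: Sequence[str]) -> bool:
    """True iff any of the given species ids appears in any module reaction."""
    wanted = {s.lower() for s in species_ids}
    for r in module.reactions:
        for met in r.stoichiometry:
            if met.lower() in wanted:
                return True
    return False


# ---------------------------------------------------------------------------
# Grafting and interventions
# ---------------------------------------------------------------------------

#: identity mapping for the shipped toy host (module currency == host ids)
DEFAULT_TOY_MAPPING: Dict[str, str] = {}

#: mapping from module currency ids onto BiGG-style cytosolic ids
BIGG_MAPPING: Dict[str, str] = {
    "g1p": "g1p_c",
    "dttp": "dttp_c",
    "tdp": "dtdp_c",
    "ppi": "ppi_c",
    "nadph": "nadph_c",
    "nadp": "nadp_c",
    "h2o": "h2o_c",
    "glu": "glu__L_c",
    "akg": "akg_c",
    "sam": "amet_c",
    "sah": "ahcys_c",
    "accoa": "accoa_c",
    "malcoa": "malcoa_c",
    "mmcoa": "mmcoa__S_c",
    "ppcoa": "ppcoa_c",
    "coa": "coa_c",
    "co2": "co2_c",
    "pyr": "pyr_c",
}


def graft_module(
    model: MetabolicModel,
    module: PathwayModule,
    mapping: Optional[Dict[str, str]] = None,
) -> MetabolicModel:
    """Return a copy of ``model`` extended with the module's reactions.

    Module species declared in ``new_metabolites`` are added; every other
    species must resolve to a host metabolite, either through ``mapping``
    (module id → host id) or by identical id. Unresolvable species raise
    :class:`MappingError` listing every orphan. Host reactions are never
    modified, so any host maximum is preserved (and can only grow).
    """
    mapping = mapping or {}
    new_ids = set(module.new_metabolite_ids)

    orphans = []
    resolved: Dict[str, str] = {}
    for met in module.currency_metabolites():
        host_id = mapping.get(met, met)
        if model.has_metabolite(host_id):
            resolved[met] = host_id
        else:
            orphans.append(met)
    if orphans:
        raise MappingError(
            f"module {module.name!r}: unresolved currency species "
            f"{sorted(orphans)}; provide a mapping onto host metabolites"
        )

    out = model.copy()
    for m in module.new_metabolites:
        if out.has_metabolite(m.id):
            raise ModelError(f"module metabolite {m.id!r} collides with host")
        out.metabolites.append(
            Metabolite(m.id, m.name, m.compartment, m.formula, m.charge)
        )
    for r in module.reactions:
        if out.has_reaction(r.id):
            raise ModelError(f"module reaction {r.id!r} collides with host")
        stoich = {
            (met if met in new_ids else resolved[met]): coef
            for met, coef in r.stoichiometry.items()
        }
        out.reactions.append(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                name=r.name,
                gene_rule=r.gene_rule,
                subsystem=r.subsystem,
            )
        )
    return MetabolicModel(
        metabolites=out.metabolites,
        reactions=out.reactions,
        biomass_reaction_id=out.biomass_reaction_id,
        objective_reaction_id=out.objective_reaction_id,
        id=out.id,
    )


def apply_intervention(model: MetabolicModel, spec: InterventionSpec) -> MetabolicModel:
    """Apply one engineering edit; returns an edited copy."""
    if spec.kind == "add_module":
        return graft_module(model, spec.module, spec.mapping)
    for rid in spec.target_reaction_ids:
        if not model.has_reaction(rid):
            raise KeyError(f"unknown reaction {rid!r}")
    out = model.copy()
    for rid in spec.target_reaction_ids:
        r = out.reaction(rid)
        if spec.kind == "amplify":
            r.lower_bound *= spec.factor
            r.upper_bound *= spec.factor
        elif spec.kind == "knockout":
            r.lower_bound = 0.0
            r.upper_bound = 0.0
        elif spec.kind == "enable_degradation":
            r.upper_bound = max(r.upper_bound, DEFAULT_BOUND)
    return out


def compare_scenarios(
    model: MetabolicModel,
    scenarios: Sequence[Tuple[str, Sequence[InterventionSpec]]],
    target_reaction_id: str,
    substrate_exchange_id: str,
    growth_floor_fraction: float = 0.1,
) -> List[ScenarioResult]:
    """Evaluate intervention combinations by maximum product flux.

    Each scenario's interventions are applied in order; the target is then
    maximized with growth held at or above ``growth_floor_fraction`` of that
    scenario's own maximum. A "base" scenario (no edits) is prepended when
    absent; deltas are against it. Infeasible scenarios are flagged, never
    dropped.
    """
    scen = list(scenarios)
    if not scen or scen[0][0] != "base":
        scen.insert(0, ("base", ()))

    results: List[ScenarioResult] = []
    base_flux: Optional[float] = None
    for name, specs in scen:
        try:
            m = model
            for s in specs:
                m = apply_intervention(m, s)
        except (KeyError, ModelError) as exc:
            results.append(ScenarioResult(name, float("nan"), float("nan"),
                                          float("nan"), f"error: {exc}"))
            continue
        growth = maximize_flux(m, m.biomass_reaction_id)
        if not growth.ok:
            results.append(
                ScenarioResult(name, float("nan"), float("nan"), float("nan"),
                               growth.status)
            )
            continue
        floored = m.copy()
        bio = floored.reaction(m.biomass_reaction_id)
        bio.lower_bound = max(bio.lower_bound, growth_floor_fraction * growth.objective_value)
        sol = maximize_flux(floored, target_reaction_id)
        if not sol.ok:
            results.append(
                ScenarioResult(name, float("nan"), float("nan"), float("nan"), sol.status)
            )
            continue
        uptake = abs(sol.fluxes.get(substrate_exchange_id, float("nan")))
        yld = sol.objective_value / uptake if uptake > 0 else 0.0
        if base_flux is None:
            base_flux = sol.objective_value
        results.append(
            ScenarioResult(
                scenario=name,
                max_target_flux=sol.objective_value,
                yield_per_substrate=yld,
                delta_vs_base=sol.objective_value - base_flux,
            )
        )
    return results
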