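"""Toy metabolic models with known ground truth, plus an independent oracle.

The generators emulate, at desk scale, the structure the target-scanning
analysis assumes of a real host: a single carbon-source uptake, a biomass
objective, redundant internal routes (to exercise parsimonious FBA), and a
secondary-metabolite branch drawing a capacity-limited precursor that
competes with growth.

Fixtures
--------
T1 (``make_linear_toy``)
    A 4-reaction linear chain: carbon uptake (capacity 10) feeding either
    biomass or a product branch. Every scan quantity has a closed form:
    max biomass 10, envelope max product 10(1−f), uptake score exactly 1,
    biomass score mean(fractions).
T3 (``make_redundant_toy``)
    Two parallel A→P routes of length 1 and 2; plain FBA is degenerate
    between them, pFBA must put all flux on the short route.
T2 family (``make_branched_toy``)
    Seeded random models with a planted precursor bottleneck (expected up
    target), a planted growth-only competing branch (expected down target),
    and a redundant pyruvate→acetyl-CoA pair of routes. Bound draws are
    log-uniform so the bottleneck stands out from background by construction,
    and redundant routes have strictly different lengths so the pFBA optimum
    is a unique vertex (scores are then solver-independent).

``oracle_scores`` re-derives FSEOF scores through an independently coded
dense LP path and is used only in tests and cross-checks.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
from scipy.optimize import linprog

from .core import DEFAULT_BOUND, Metabolite, MetabolicModel, ModelError, Reaction
from .io import _model_from_dict
from .lp import FixedConstraint, maximize_flux
from .scan import ReactionScore, ScanConfig, ScanError


def _load_fixture(name: str) -> MetabolicModel:
    ref = importlib.resources.files("fseof.data") / name
    return _model_from_dict(json.loads(ref.read_text()), source=name)


def make_linear_toy() -> MetabolicModel:
    """Fixture T1 — the 4-reaction linear chain (frozen in-repo)."""
    return _load_fixture("t1.json")


def make_redundant_toy() -> MetabolicModel:
    """Fixture T3 — redundant short/long routes (frozen in-repo)."""
    return _load_fixture("t3.json")


# ---------------------------------------------------------------------------
# T2: branched toys with planted ground truth
# ---------------------------------------------------------------------------


@dataclass
class ToySpec:
    """Specification of one branched toy; a fixed seed fixes the model."""

    n_core_reactions: int = 4
    n_competing_branches: int = 1
    bottleneck_position: Optional[int] = None
    seed: int = 0
    bound_range: Tuple[float, float] = (5.0, 15.0)
    bottleneck_ub: Optional[float] = None  # override, for degeneracy tests

    def __post_init__(self) -> None:
        if self.n_core_reactions < 2:
            raise ModelError("need at least 2 core reactions")
        if self.n_competing_branches < 1:
            raise ModelError("need at least 1 competing branch")
        lo, hi = self.bound_range
        if lo <= 0 or hi < lo:
            raise ModelError("bound_range must be positive and ordered")


@dataclass
class GroundTruth:
    """Planted targets of a branched toy."""

    expected_up: Set[str]
    expected_down: Set[str]
    rationale: Dict[str, str] = field(default_factory=dict)


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def make_branched_toy(spec: ToySpec) -> Tuple[MetabolicModel, GroundTruth]:
    """Generate one branched toy with planted up/down targets.

    Construction (per-unit-growth demand: 1 acetyl-CoA + 0.1 precursor):
    uptake capacity U is drawn log-uniform from ``bound_range``; the
    precursor branch capacity b is drawn log-uniform in (0.11·U, 0.16·U).
    Since max growth is U/1.1, the control precursor flux is 0.0909·U < b
    (the bottleneck is slack under pure growth) while under enforced
    production the product pulls the branch to saturation at every level
    (b < 0.173·U keeps it the binding constraint) — so the bottleneck's
    score lands in (1.21, 1.76), the competing branch's at mean(fractions).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.bound_range
    U = _loguniform(rng, lo, hi)
    b = spec.bottleneck_ub if spec.bottleneck_ub is not None else _loguniform(
        rng, 0.11 * U, 0.16 * U
    )
    big = lambda: _loguniform(rng, 3 * U, 30 * U)  # noqa: E731 - non-binding bound

    mets = [Metabolite("glc"), Metabolite("g6p"), Metabolite("pyr"),
            Metabolite("accoa"), Metabolite("alt"), Metabolite("prec"),
            Metabolite("sug"), Metabolite("P"), Metabolite("bmx")]
    rxns: List[Reaction] = [
        Reaction("EX_glc", {"glc": 1.0}, 0.0, U, subsystem="exchange"),
    ]

    # core chain glc -> ... -> g6p with padding to n_core_reactions
    n_pad = spec.n_core_reactions - 2
    prev = "glc"
    for i in range(n_pad):
        mid = f"c{i + 1}"
        mets.append(Metabolite(mid))
        rxns.append(Reaction(f"R_core{i + 1}", {prev: -1.0, mid: 1.0}, 0.0, big(),
                             gene_rule=f"gc{i + 1}"))
        prev = mid
    rxns.append(Reaction("R_g6p", {prev: -1.0, "g6p": 1.0}, 0.0, big(), gene_rule="gG"))
    rxns.append(Reaction("R_pyr", {"g6p": -1.0, "pyr": 1.0}, 0.0, big(), gene_rule="gY"))
    # redundant pyr -> accoa routes: direct (length 1) and detour (length 2)
    rxns.append(Reaction("R_pdh", {"pyr": -1.0, "accoa": 1.0}, 0.0, big(), gene_rule="gPDH"))
    rxns.append(Reaction("R_alt1", {"pyr": -1.0, "alt": 1.0}, 0.0, big(), gene_rule="gA1"))
    rxns.append(Reaction("R_alt2", {"alt": -1.0, "accoa": 1.0}, 0.0, big(), gene_rule="gA2"))

    # precursor branch with the planted bottleneck
    depth = max(1, spec.bottleneck_position or 1)
    prev = "accoa"
    branch_ids = []
    for i in range(depth):
        out = "prec" if i == depth - 1 else f"pb{i + 1}"
        if out != "prec":
            mets.append(Metabolite(out))
        rid = f"R_prec{i + 1}" if depth > 1 else "R_prec"
        cap = b if i == depth - 1 else big()
        rxns.append(Reaction(rid, {prev: -1.0, out: 1.0}, 0.0, cap,
                             gene_rule=f"gB{i + 1}"))
        branch_ids.append(rid)
        prev = out
    bottleneck_id = branch_ids[-1]

    # competing growth-only branch(es); extras are longer, so pFBA-idle
    rxns.append(Reaction("R_comp", {"prec": -1.0, "bmx": 1.0}, 0.0, big(), gene_rule="gC"))
    for j in range(1, spec.n_competing_branches):
        mid = f"cc{j}"
        mets.append(Metabolite(mid))
        rxns.append(Reaction(f"R_comp{j}a", {"prec": -1.0, mid: 1.0}, 0.0, big()))
        rxns.append(Reaction(f"R_comp{j}b", {mid: -1.0, "bmx": 1.0}, 0.0, big()))

    # product module: aglycone-like (precursor) + sugar-like merge
    rxns.append(Reaction("R_sugar", {"g6p": -1.0, "sug": 1.0}, 0.0, big(), gene_rule="gS"))
    rxns.append(Reaction("R_merge", {"prec": -1.0, "sug": -1.0, "P": 1.0}, 0.0, big(),
                         gene_rule="gM"))
    rxns.append(Reaction("EX_p", {"P": -1.0}, 0.0, DEFAULT_BOUND, subsystem="exchange"))
    rxns.append(Reaction("R_bio", {"accoa": -1.0, "bmx": -0.1}, 0.0, DEFAULT_BOUND,
                         subsystem="biomass"))

    model = MetabolicModel(mets, rxns, biomass_reaction_id="R_bio",
                           id=f"T2_seed{spec.seed}")

    sol = maximize_flux(model, "EX_p")
    if not sol.ok or sol.objective_value <= 1e-9:
        raise ModelError("degenerate toy spec: no feasible product route")

    truth = GroundTruth(
        expected_up={bottleneck_id, "R_merge", "R_sugar"},
        expected_down={"R_comp"},
        rationale={
            bottleneck_id: "capacity-limited precursor supply, saturated "
            "under enforced production but slack under pure growth",
            "R_merge": "product-module assembly, silent in control",
            "R_sugar": "product-module sugar feed, silent in control",
            "R_comp": "growth-only consumer of the contested precursor; its "
            "flux shrinks proportionally with enforced growth",
        },
    )
    return model, truth


# ---------------------------------------------------------------------------
# Host toy for pathway grafting
# ---------------------------------------------------------------------------


def make_host_toy(glucose_uptake: float = 10.0) -> MetabolicModel:
    """A small host with the precursor pools the biosynthesis modules draw:
    acyl-CoA pools (acetyl/malonyl/methylmalonyl/propionyl-CoA), the
    glucose-1-phosphate node for nucleotide sugars, NADPH/ATP/SAM currency
    cycles, a CO2 exchange, and a bounded stored-lipid (TAG) pool whose
    degradation reaction is closed until the ddTAG intervention opens it.
    Cofactor cycles are lumped pseudo-reactions; element formulas are
    deliberately omitted (topology, not chemistry, is what matters here).
    """
    ids = ["glc", "g6p", "g1p", "pyr", "accoa", "malcoa", "mmcoa", "ppcoa",
           "coa", "nadph", "nadp", "atp", "adp", "pi", "ppi", "dttp", "tdp",
           "sam", "sah", "glu", "akg", "co2", "tag", "h2o"]
    mets = [Metabolite(i) for i in ids]
    B = DEFAULT_BOUND
    r = [
        Reaction("EX_glc", {"glc": 1.0}, 0.0, glucose_uptake, subsystem="exchange"),
        Reaction("HK", {"glc": -1, "atp": -1, "g6p": 1, "adp": 1}, 0, B, gene_rule="glk"),
        Reaction("PGM", {"g6p": -1, "g1p": 1}, 0, B, gene_rule="pgm"),
        Reaction("GLYC", {"g6p": -1, "adp": -2, "pi": -2, "nadp": -2,
                          "pyr": 2, "atp": 2, "nadph": 2}, 0, B, gene_rule="pyk"),
        Reaction("PDH", {"pyr": -1, "coa": -1, "nadp": -1,
                         "accoa": 1, "co2": 1, "nadph": 1}, 0, B, gene_rule="pdh"),
        Reaction("ACC", {"accoa": -1, "atp": -1, "co2": -1,
                         "malcoa": 1, "adp": 1, "pi": 1}, 0, B, gene_rule="accA"),
        Reaction("PPS", {"pyr": -1, "coa": -1, "nadph": -2,
                         "ppcoa": 1, "nadp": 2}, 0, B, gene_rule="pcs"),
        Reaction("PCC", {"ppcoa": -1, "atp": -1, "co2": -1,
                         "mmcoa": 1, "adp": 1, "pi": 1}, 0, B, gene_rule="pccA"),
        Reaction("ATP_SYN", {"adp": -1, "pi": -1, "nadph": -1,
                             "atp": 1, "nadp": 1}, 0, B, gene_rule="atpA"),
        Reaction("ATPM", {"atp": -1, "adp": 1, "pi": 1}, 0, B,
                 subsystem="maintenance"),
        Reaction("NADPH_OX", {"nadph": -1, "nadp": 1}, 0, B, gene_rule="ndh",
                 subsystem="maintenance"),
        Reaction("AKG_SYN", {"accoa": -1, "pyr": -1, "akg": 1, "coa": 1}, 0, B,
                 gene_rule="icd"),
        Reaction("GLU_SYN", {"akg": -1, "nadph": -1, "glu": 1, "nadp": 1}, 0, B,
                 gene_rule="gdhA"),
        Reaction("SAM_CYCLE", {"sah": -1, "atp": -1, "sam": 1, "adp": 1, "pi": 1},
                 0, B, gene_rule="metK"),
        Reaction("TDP_RECYCLE", {"tdp": -1, "atp": -1, "dttp": 1, "adp": 1}, 0, B,
                 gene_rule="tmk"),
        Reaction("PPA", {"ppi": -1, "pi": 2}, 0, B, gene_rule="ppa"),
        Reaction("COA_SUPPLY", {"coa": 1.0}, 0, B, subsystem="exchange"),
        Reaction("PI_SUPPLY", {"pi": 1.0}, 0, B, subsystem="exchange"),
        Reaction("EX_co2", {"co2": -1.0}, -B, B, subsystem="exchange"),
        Reaction("EX_h2o", {"h2o": -1.0}, -B, B, subsystem="exchange"),
        Reaction("TAG_STORE", {"tag": 1.0}, 0.0, 1.0, subsystem="storage"),
        Reaction("TAG_DEG", {"tag": -1, "coa": -3, "accoa": 3}, 0.0, 0.0,
                 gene_rule="sco6196", subsystem="storage"),
        Reaction("R_bio", {"accoa": -1.0, "g6p": -0.2, "glu": -0.1,
                           "atp": -0.5, "adp": 0.5, "pi": 0.5}, 0, B,
                 subsystem="biomass"),
    ]
    return MetabolicModel(mets, r, biomass_reaction_id="R_bio", id="host_toy")


# ---------------------------------------------------------------------------
# Independent brute-force oracle
# ---------------------------------------------------------------------------

_ORACLE_MAX_REACTIONS = 25
_ORACLE_STEP = 0.01


def _oracle_dense_matrix(model: MetabolicModel) -> np.ndarray:
    met_pos = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoichiometry.items():
            S[met_pos[met], j] = coef
    return S


def _oracle_lp(S, c, bounds):
    return linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                   method="highs-ds",
                   options={"primal_feasibility_tolerance": 1e-9,
                            "dual_feasibility_tolerance": 1e-9})


def _oracle_pin(bounds, j, value):
    half = 1e-9 * max(1.0, abs(value))
    lo = max(bounds[j][0], value - half)
    hi = min(bounds[j][1], value + half)
    out = list(bounds)
    out[j] = (lo, hi)
    return out


def _oracle_max(S, bounds, j):
    c = np.zeros(S.shape[1])
    c[j] = -1.0
    res = _oracle_lp(S, c, bounds)
    if res.status != 0:
        return None, None
    return -res.fun, res.x


def _oracle_pfba(S, bounds):
    n = S.shape[1]
    S2 = np.hstack([S, -S])
    b2 = [(max(0.0, lb), max(0.0, ub)) for lb, ub in bounds]
    b2 += [(max(0.0, -ub), max(0.0, -lb)) for lb, ub in bounds]
    res = _oracle_lp(S2, np.ones(2 * n), b2)
    if res.status != 0:
        return None
    return res.x[:n] - res.x[n:]


def oracle_scores(model: MetabolicModel, config: ScanConfig) -> List[ReactionScore]:
    """Brute-force FSEOF scores through an independent dense LP path.

    Solves the whole enforcement range on a dense 0.01-step grid with the
    dual-simplex interface and dense matrices (no shared code with the main
    scan), then scores on the grid points coinciding with the configured
    fractions. Restricted to small models; used only for verification.
    """
    if len(model.reactions) > _ORACLE_MAX_REACTIONS:
        raise ScanError(
            f"oracle limited to {_ORACLE_MAX_REACTIONS} reactions "
            f"(got {len(model.reactions)})"
        )
    for f in config.fractions:
        if abs(round(f / _ORACLE_STEP) * _ORACLE_STEP - f) > 1e-9:
            raise ScanError(f"fraction {f} not on the oracle's 0.01 grid")

    S = _oracle_dense_matrix(model)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    j_bio = model.reaction_index(config.biomass_reaction_id)
    j_tgt = model.reaction_index(config.target_reaction_id)

    mu_max, _ = _oracle_max(S, bounds, j_bio)
    if mu_max is None:
        raise ScanError("oracle: model infeasible")
    if config.use_pfba_for_control:
        ctrl = _oracle_pfba(S, _oracle_pin(bounds, j_bio, mu_max))
    else:
        _, ctrl = _oracle_max(S, bounds, j_bio)

    lo = round(min(config.fractions) / _ORACLE_STEP)
    hi = round(max(config.fractions) / _ORACLE_STEP)
    fine: Dict[int, Optional[np.ndarray]] = {}
    for k in range(lo, hi + 1):
        f = k * _ORACLE_STEP
        pinned = _oracle_pin(bounds, j_bio, f * mu_max)
        t, _x = _oracle_max(S, pinned, j_tgt)
        if t is None:
            fine[k] = None
            continue
        fine[k] = _oracle_pfba(S, _oracle_pin(pinned, j_tgt, t))

    keys = [round(f / _ORACLE_STEP) for f in config.fractions]
    level_vs = {f: fine[k] for f, k in zip(config.fractions, keys)}
    ok_fracs = [f for f in config.fractions if level_vs[f] is not None]
    if not ok_fracs:
        raise ScanError("oracle: no feasible level")

    eps = config.activation_epsilon
    out: List[ReactionScore] = []
    for j, rxn in enumerate(model.reactions):
        ctrl_flux = float(ctrl[j])
        lvl = {f: float(level_vs[f][j]) for f in ok_fracs}
        mean_flux = sum(lvl.values()) / len(lvl)
        if abs(ctrl_flux) <= eps and abs(mean_flux) <= eps:
            score, activated, consistent, reason = 0.0, False, True, "inactive"
        elif abs(ctrl_flux) <= eps:
            score, activated, consistent, reason = None, True, True, "activated"
        elif (mean_flux > 0) != (ctrl_flux > 0) and abs(mean_flux) > eps:
            score, activated, consistent, reason = None, False, False, "direction flip"
        else:
            score, activated, consistent, reason = (
                abs(mean_flux) / abs(ctrl_flux), False, True, "")
        out.append(ReactionScore(
            reaction_id=rxn.id, score=score, activated=activated,
            production_flux_mean=mean_flux, control_flux=ctrl_flux,
            direction_consistent=consistent, reason=reason, level_fluxes=lvl,
        ))
    return out
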