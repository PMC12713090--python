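"""Core data model for genome-scale metabolic networks.

A :class:`MetabolicModel` is a stoichiometric reconstruction: metabolites,
reactions with flux bounds and gene-protein-reaction (GPR) rules, and a
biomass objective. Fluxes are in mmol·gDW⁻¹·h⁻¹ throughout; the biomass
reaction's flux is the specific growth rate (h⁻¹) by the usual convention.

Equality of coefficients and bounds is judged at an absolute tolerance of
1e-9 (``COEF_TOL``), the round-trip precision the JSON and SBML writers
guarantee.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

#: absolute tolerance for coefficient / bound equality
COEF_TOL = 1e-9

#: default flux bounds when a format omits them (community convention)
DEFAULT_BOUND = 1000.0

#: exchange metabolites never treated as carbon sources by :func:`set_medium`
#: even though their formula contains carbon (CO2 fixation is not "feeding").
DEFAULT_INORGANIC_WHITELIST = frozenset({"co2", "hco3", "co3"})


class ModelError(ValueError):
    """Structural problem in a model definition."""


class GPRError(ModelError):
    """Unparsable gene-protein-reaction rule."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[A-Za-z0-9_.\-]+")


def parse_gpr(rule: str) -> List[str]:
    """Validate a boolean AND/OR gene rule and return the gene ids it names.

    The grammar is ``expr := term (or term)* ; term := factor (and factor)* ;
    factor := gene | '(' expr ')'``. An empty rule is valid and names no genes.

    Raises :class:`GPRError` on malformed rules.
    """
    rule = rule.strip()
    if not rule:
        return []
    tokens = _GPR_TOKEN.findall(rule)
    # ensure tokenisation consumed everything except whitespace/parens
    residue = _GPR_TOKEN.sub("", rule).strip()
    if residue.strip("() \t"):
        raise GPRError(f"unexpected characters in gene rule: {rule!r}")

    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    genes: List[str] = []

    def factor() -> None:
        tok = peek()
        if tok is None:
            raise GPRError(f"unexpected end of gene rule: {rule!r}")
        if tok == "(":
            take()
            expr()
            if peek() != ")":
                raise GPRError(f"unbalanced parentheses in gene rule: {rule!r}")
            take()
        elif tok in ("and", "or", ")"):
            raise GPRError(f"misplaced {tok!r} in gene rule: {rule!r}")
        else:
            genes.append(take())

    def expr() -> None:
        factor()
        while peek() in ("and", "or"):
            take()
            factor()

    expr()
    if pos != len(tokens):
        raise GPRError(f"trailing tokens in gene rule: {rule!r}")
    # stable order, deduplicated
    seen = {}
    for g in genes:
        seen.setdefault(g, None)
    return list(seen)


# ---------------------------------------------------------------------------
# Elemental formulas
# ---------------------------------------------------------------------------

_ELEMENT = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> Dict[str, float]:
    """Parse an elemental formula string such as ``C6H12O6`` into counts."""
    counts: Dict[str, float] = {}
    matched = ""
    for elem, num in _ELEMENT.findall(formula):
        if not elem:
            continue
        matched += elem + num
        counts[elem] = counts.get(elem, 0.0) + (float(num) if num else 1.0)
    if matched != formula.replace(" ", ""):
        raise ModelError(f"cannot parse formula {formula!r}")
    return counts


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    """A chemical species in one compartment."""

    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    charge: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelError(f"metabolite {self.id}: compartment must be non-empty")

    def element_counts(self) -> Optional[Dict[str, float]]:
        if self.formula is None:
            return None
        return parse_formula(self.formula)


@dataclass
class Reaction:
    """A (pseudo-)reaction: signed stoichiometry plus flux bounds.

    Negative coefficients are consumed, positive produced. A reaction touching
    exactly one metabolite is a boundary (exchange/demand/sink) reaction.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    gene_rule: str = ""
    subsystem: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id}: stoichiometry must be non-empty")
        for met, coef in self.stoichiometry.items():
            if coef == 0:
                raise ModelError(f"reaction {self.id}: zero coefficient for {met}")
        if self.lower_bound > self.upper_bound + COEF_TOL:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def genes(self) -> List[str]:
        return parse_gpr(self.gene_rule)

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            name=self.name,
            gene_rule=self.gene_rule,
            subsystem=self.subsystem,
        )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_model`; problems are the payload, not errors."""

    dangling_metabolites: List[str] = field(default_factory=list)
    unbalanced_reactions: List[Tuple[str, str, float]] = field(default_factory=list)
    bound_violations: List[str] = field(default_factory=list)
    gpr_parse_errors: List[Tuple[str, str]] = field(default_factory=list)
    is_solvable: bool = True

    @property
    def is_clean(self) -> bool:
        return (
            not self.dangling_metabolites
            and not self.unbalanced_reactions
            and not self.bound_violations
            and not self.gpr_parse_errors
            and self.is_solvable
        )


class MetabolicModel:
    """A genome-scale (or toy-scale) metabolic network.

    Parameters
    ----------
    metabolites, reactions:
        Model content; insertion order is preserved and defines the stable
        row/column ordering of :func:`stoichiometric_matrix`.
    biomass_reaction_id:
        The growth pseudo-reaction.
    objective_reaction_id:
        The default FBA objective (usually biomass). Defaults to the biomass
        reaction when omitted.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        biomass_reaction_id: str,
        objective_reaction_id: Optional[str] = None,
        id: str = "model",
    ) -> None:
        self.id = id
        self.metabolites: List[Metabolite] = list(metabolites)
        self.reactions: List[Reaction] = list(reactions)
        self.biomass_reaction_id = biomass_reaction_id
        self.objective_reaction_id = objective_reaction_id or biomass_reaction_id
        self._reindex()
        self._check_invariants()

    # -- indexing ----------------------------------------------------------
    def _reindex(self) -> None:
        self._met_index: Dict[str, int] = {}
        for i, m in enumerate(self.metabolites):
            if m.id in self._met_index:
                raise ModelError(f"duplicate metabolite id {m.id!r}")
            self._met_index[m.id] = i
        self._rxn_index: Dict[str, int] = {}
        for j, r in enumerate(self.reactions):
            if r.id in self._rxn_index:
                raise ModelError(f"duplicate reaction id {r.id!r}")
            self._rxn_index[r.id] = j

    def _check_invariants(self) -> None:
        for r in self.reactions:
            for met in r.stoichiometry:
                if met not in self._met_index:
                    raise ModelError(
                        f"reaction {r.id} references unknown metabolite {met!r}"
                    )
        for attr in ("biomass_reaction_id", "objective_reaction_id"):
            rid = getattr(self, attr)
            if rid not in self._rxn_index:
                raise ModelError(f"{attr} {rid!r} does not resolve to a reaction")

    # -- accessors ---------------------------------------------------------
    @property
    def genes(self) -> List[str]:
        """All gene ids appearing in any reaction's rule, in stable order."""
        seen: Dict[str, None] = {}
        for r in self.reactions:
            try:
                for g in r.genes:
                    seen.setdefault(g, None)
            except GPRError:
                continue
        return list(seen)

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[_copy.copy(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            biomass_reaction_id=self.biomass_reaction_id,
            objective_reaction_id=self.objective_reaction_id,
            id=self.id,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def stoichiometric_matrix(model: MetabolicModel) -> sparse.csr_matrix:
    """The sparse stoichiometric matrix S.

    Rows follow ``model.metabolites`` order, columns ``model.reactions``
    order — both stable under insertion, so grafting k reactions appends
    exactly k columns and leaves existing entries untouched.
    """
    rows: List[int] = []
    cols: List[int] = []
    data: List[float] = []
    for j, r in enumerate(model.reactions):
        for met, coef in r.stoichiometry.items():
            rows.append(model._met_index[met])
            cols.append(j)
            data.append(coef)
    return sparse.csr_matrix(
        (data, (rows, cols)),
        shape=(len(model.metabolites), len(model.reactions)),
    )


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Structural health check.

    Reports dangling metabolites, elementally unbalanced internal reactions
    (only when every participant carries a formula; boundary reactions and the
    biomass pseudo-reaction are exempt), inverted bounds, and unparsable gene
    rules. ``is_solvable`` is true iff the all-zero flux vector is feasible,
    i.e. every reaction's bounds straddle zero.
    """
    report = ValidationReport()

    used = set()
    for r in model.reactions:
        used.update(r.stoichiometry)
    report.dangling_metabolites = [m.id for m in model.metabolites if m.id not in used]

    for r in model.reactions:
        if r.is_exchange or r.id == model.biomass_reaction_id:
            continue
        counts = {m: model.metabolite(m).element_counts() for m in r.stoichiometry}
        if any(c is None for c in counts.values()):
            continue
        balance: Dict[str, float] = {}
        for met, coef in r.stoichiometry.items():
            for elem, n in counts[met].items():  # type: ignore[union-attr]
                balance[elem] = balance.get(elem, 0.0) + coef * n
        for elem in sorted(balance):
            if abs(balance[elem]) > 1e-6:
                report.unbalanced_reactions.append((r.id, elem, balance[elem]))

    for r in model.reactions:
        if r.lower_bound > r.upper_bound + COEF_TOL:
            report.bound_violations.append(r.id)
        try:
            parse_gpr(r.gene_rule)
        except GPRError as exc:
            report.gpr_parse_errors.append((r.id, str(exc)))

    report.is_solvable = all(
        r.lower_bound <= COEF_TOL and r.upper_bound >= -COEF_TOL
        for r in model.reactions
    ) and not report.bound_violations
    return report


def _is_carbon_source_exchange(
    model: MetabolicModel,
    reaction: Reaction,
    inorganic_whitelist: frozenset,
) -> bool:
    """An exchange feeds carbon iff its metabolite's formula contains C and the
    species is not inorganic-whitelisted. A metabolite with no formula is
    conservatively treated as organic."""
    (met_id,) = reaction.stoichiometry
    met = model.metabolite(met_id)
    base = re.sub(r"_[a-z]{1,2}$", "", met.id.lower())  # strip compartment tag
    if base in inorganic_whitelist or met.id.lower() in inorganic_whitelist:
        return False
    counts = met.element_counts()
    if counts is None:
        return True
    return counts.get("C", 0.0) > 0


def set_medium(
    model: MetabolicModel,
    uptake_bounds: Dict[str, float],
    inorganic_whitelist: frozenset = DEFAULT_INORGANIC_WHITELIST,
) -> MetabolicModel:
    """Define the growth medium by bounding carbon uptake.

    Listed exchange reactions get their uptake capacity set to the given rate;
    every *other* carbon-source exchange is closed to uptake. Non-carbon
    exchanges (water, phosphate, ions, ammonium, oxygen, whitelisted CO2) are
    untouched. Returns a modified copy; stoichiometry is never altered.

    Uptake direction is orientation-aware: for the conventional ``met -> ∅``
    exchange uptake is negative flux (sets ``lower_bound = -rate``); for an
    ``∅ -> met`` import reaction uptake is positive flux (sets
    ``upper_bound = +rate``).
    """
    for rid, rate in uptake_bounds.items():
        if not model.has_reaction(rid):
            raise KeyError(f"unknown exchange reaction {rid!r}")
        if not model.reaction(rid).is_exchange:
            raise KeyError(f"reaction {rid!r} is not an exchange reaction")
        if rate < 0:
            raise ModelError(f"uptake rate for {rid!r} must be non-negative")

    out = model.copy()
    for r in out.reactions:
        if not r.is_exchange:
            continue
        (met_id,) = r.stoichiometry
        coef = r.stoichiometry[met_id]
        importing = coef > 0  # positive flux brings the metabolite in
        if r.id in uptake_bounds:
            rate = uptake_bounds[r.id]
            if importing:
                r.upper_bound = rate
                r.lower_bound = min(r.lower_bound, rate)
            else:
                r.lower_bound = -rate
        elif _is_carbon_source_exchange(out, r, inorganic_whitelist):
            if importing:
                r.upper_bound = min(r.upper_bound, 0.0)
                r.lower_bound = min(r.lower_bound, 0.0)
            else:
                r.lower_bound = max(r.lower_bound, 0.0)
                r.upper_bound = max(r.upper_bound, 0.0)
    return out
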