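"""FSEOF: flux scanning based on enforced objective flux.

The scan identifies metabolic-engineering targets for overproduction of a
secondary metabolite. Growth (the biomass flux) is enforced stepwise at
fractions of its theoretical maximum (default 20%–80% in 10% steps); at each
level the product flux is maximized, then pinned, and parsimonious FBA
minimizes total flux to obtain one representative distribution. Each
reaction's score is the ratio of its mean flux over the production levels to
its flux under pure growth maximization (the control):

    score(A) = |mean_f v_A(f)| / |v_A(control)|

A score above 1 means flux through the reaction rises when production is
enforced — an overexpression (up) candidate; below 1, an attenuation (down)
candidate. Reactions with zero control flux that switch on under production
(the heterologous product module itself, typically) are classed ACTIVATED
and ranked at the top of the up list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core import MetabolicModel
from .lp import (
    OPTIMAL,
    FixedConstraint,
    FluxDistribution,
    maximize_flux,
    pfba,
)

DEFAULT_FRACTIONS = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)

#: sentinel score class for reactions silent in control but active in production
ACTIVATED = "ACTIVATED"


class ScanError(ValueError):
    """Contract violation in scan inputs."""


@dataclass
class ScanConfig:
    """Configuration of one FSEOF scan.

    Parameters
    ----------
    biomass_reaction_id, target_reaction_id:
        Growth pseudo-reaction and the product flux to enforce.
    fractions:
        Strictly increasing enforcement levels in (0, 1); default 0.2–0.8
        step 0.1, the smallest round grid spanning the stated range.
    use_pfba_for_control:
        Whether the pure-growth control is also pFBA-minimal (default), for
        comparability with the production levels.
    activation_epsilon:
        Flux below which a reaction counts as silent (mmol·gDW⁻¹·h⁻¹).
    dead_band:
        Half-width δ of the neutral band around score 1; suppresses
        numerically neutral calls.
    aggregation:
        How level fluxes are combined: "mean_flux" (default; mean signed
        flux over levels, then ratio to control), "mean_ratio" (per-level
        ratios averaged), or "max_flux".
    gene_only:
        When true, reactions without a gene rule are excluded from targets.
    """

    biomass_reaction_id: str
    target_reaction_id: str
    fractions: Tuple[float, ...] = DEFAULT_FRACTIONS
    use_pfba_for_control: bool = True
    activation_epsilon: float = 1e-6
    dead_band: float = 0.05
    aggregation: str = "mean_flux"
    gene_only: bool = False

    def __post_init__(self) -> None:
        fr = tuple(self.fractions)
        if not fr:
            raise ScanError("fractions must be non-empty")
        if any(not (0.0 < f < 1.0) for f in fr):
            raise ScanError("fractions must lie strictly inside (0, 1)")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ScanError("fractions must be strictly increasing")
        if self.activation_epsilon <= 0:
            raise ScanError("activation_epsilon must be positive")
        if self.aggregation not in ("mean_flux", "mean_ratio", "max_flux"):
            raise ScanError(f"unknown aggregation {self.aggregation!r}")
        self.fractions = fr


@dataclass
class ScanResult:
    """Flux distributions over enforced-production levels plus the control."""

    config: ScanConfig
    control: FluxDistribution
    levels: Dict[float, FluxDistribution]
    max_biomass: float
    target_max_per_level: Dict[float, float]
    warnings: List[str] = field(default_factory=list)

    @property
    def optimal_fractions(self) -> List[float]:
        return [f for f in self.config.fractions if self.levels[f].ok]


@dataclass
class ReactionScore:
    """The FSEOF score of one reaction."""

    reaction_id: str
    score: Optional[float]  # None when ACTIVATED or withheld
    activated: bool
    production_flux_mean: float
    control_flux: float
    direction_consistent: bool
    reason: str = ""
    level_fluxes: Dict[float, float] = field(default_factory=dict)

    @property
    def score_label(self) -> str:
        if self.activated:
            return ACTIVATED
        if self.score is None:
            return "withheld"
        return f"{self.score:.6g}"


@dataclass
class TargetEntry:
    reaction_id: str
    score: Optional[float]
    activated: bool
    gene_ids: List[str]
    control_flux: float
    production_flux_mean: float
    level_fluxes: Dict[float, float] = field(default_factory=dict)


@dataclass
class TargetTable:
    """Classified targets: up (overexpress), down (attenuate), excluded."""

    up: List[TargetEntry]
    down: List[TargetEntry]
    excluded: List[Tuple[str, str]]  # (reaction id, reason)

    def up_ids(self) -> List[str]:
        return [e.reaction_id for e in self.up]

    def down_ids(self) -> List[str]:
        return [e.reaction_id for e in self.down]


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------


def run_control(model: MetabolicModel, config: ScanConfig) -> FluxDistribution:
    """The 0%-production / 100%-growth reference distribution.

    Biomass is maximized with production unconstrained; when
    ``use_pfba_for_control`` the distribution is additionally pFBA-minimal
    with biomass pinned at its maximum.
    """
    base = maximize_flux(model, config.biomass_reaction_id)
    if not base.ok:
        return base
    if not config.use_pfba_for_control:
        return base
    sol = pfba(
        model, [FixedConstraint(config.biomass_reaction_id, base.objective_value)]
    )
    if sol.ok:
        # report the biomass optimum, not Σ|v|, as the headline objective
        return FluxDistribution(sol.fluxes, base.objective_value, OPTIMAL)
    return base


def run_scan(model: MetabolicModel, config: ScanConfig) -> ScanResult:
    """Run the enforced-production scan.

    For each fraction f: biomass is pinned at f × max biomass, the target
    flux maximized, then pinned at that optimum, and pFBA minimizes total
    flux. Infeasible levels are recorded per level and the scan continues.
    """
    control = run_control(model, config)
    if not control.ok:
        raise ScanError(f"model infeasible on its medium (status {control.status})")
    mu_max = control.objective_value

    levels: Dict[float, FluxDistribution] = {}
    target_max: Dict[float, float] = {}
    warnings: List[str] = []
    for f in config.fractions:
        pin_bio = FixedConstraint(config.biomass_reaction_id, f * mu_max)
        best = maximize_flux(model, config.target_reaction_id, [pin_bio])
        if not best.ok:
            levels[f] = best
            target_max[f] = float("nan")
            warnings.append(f"level {f}: target maximization {best.status}")
            continue
        t = best.objective_value
        target_max[f] = t
        sol = pfba(
            model, [pin_bio, FixedConstraint(config.target_reaction_id, t)]
        )
        levels[f] = sol if sol.ok else best
        if not sol.ok:
            warnings.append(f"level {f}: pFBA {sol.status}, kept FBA optimum")

    first = config.fractions[0]
    if first in target_max and not math.isnan(target_max[first]):
        if target_max[first] <= config.activation_epsilon:
            warnings.append(
                "target unreachable: max target flux ~ 0 at the lowest fraction"
            )
    return ScanResult(
        config=config,
        control=control,
        levels=levels,
        max_biomass=mu_max,
        target_max_per_level=target_max,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _score_from_stats(
    mean_flux: float,
    control_flux: float,
    eps: float,
    per_level_ratio: Optional[float] = None,
) -> Tuple[Optional[float], bool, bool, str]:
    """Shared scoring semantics: (score, activated, direction_consistent, reason)."""
    silent_mean = abs(mean_flux) <= eps
    silent_ctrl = abs(control_flux) <= eps
    if silent_ctrl and silent_mean:
        return 0.0, False, True, "inactive"
    if silent_ctrl and not silent_mean:
        return None, True, True, "activated"
    if not silent_mean and (mean_flux > 0) != (control_flux > 0):
        return None, False, False, "direction flip"
    value = per_level_ratio if per_level_ratio is not None else abs(mean_flux) / abs(control_flux)
    return value, False, True, ""


def score_reactions(scan: ScanResult) -> List[ReactionScore]:
    """Score every reaction from the scan's level and control distributions.

    Default aggregation: mean signed flux over the optimal levels divided by
    the absolute control flux. Zero-control reactions that activate under
    production are flagged ACTIVATED; sign flips between regimes withhold
    the score (the ratio's sign semantics would be ambiguous).
    """
    if not scan.control.ok:
        raise ScanError("scan has no optimal control distribution")
    fr_ok = scan.optimal_fractions
    if not fr_ok:
        raise ScanError("scan has no optimal production level")
    cfg = scan.config
    eps = cfg.activation_epsilon

    scores: List[ReactionScore] = []
    for rid, ctrl_flux in scan.control.fluxes.items():
        lvl = {f: scan.levels[f].fluxes[rid] for f in fr_ok}
        mean_flux = sum(lvl.values()) / len(lvl)
        per_level_ratio: Optional[float] = None
        if abs(ctrl_flux) > eps:
            if cfg.aggregation == "mean_ratio":
                same_sign = [v for v in lvl.values()]
                per_level_ratio = sum(abs(v) for v in same_sign) / len(same_sign) / abs(
                    ctrl_flux
                )
            elif cfg.aggregation == "max_flux":
                per_level_ratio = max(abs(v) for v in lvl.values()) / abs(ctrl_flux)
        score, activated, consistent, reason = _score_from_stats(
            mean_flux, ctrl_flux, eps, per_level_ratio
        )
        scores.append(
            ReactionScore(
                reaction_id=rid,
                score=score,
                activated=activated,
                production_flux_mean=mean_flux,
                control_flux=ctrl_flux,
                direction_consistent=consistent,
                reason=reason,
                level_fluxes=lvl,
            )
        )
    return scores


def classify_targets(
    scores: Sequence[ReactionScore],
    model: MetabolicModel,
    config: ScanConfig,
) -> TargetTable:
    """Partition scored reactions into up/down targets and exclusions.

    up: ACTIVATED reactions (ranked first, by production flux) then scores
    above 1+δ, descending. down: scores strictly between 0 and 1−δ with
    non-zero control flux, ascending. The biomass reaction, the enforced
    target, exchange reactions, direction-inconsistent reactions, inactive
    reactions, and (when ``gene_only``) gene-less reactions are excluded.
    """
    delta = config.dead_band
    up: List[TargetEntry] = []
    down: List[TargetEntry] = []
    excluded: List[Tuple[str, str]] = []

    for s in scores:
        rid = s.reaction_id
        rxn = model.reaction(rid)
        entry = TargetEntry(
            reaction_id=rid,
            score=s.score,
            activated=s.activated,
            gene_ids=rxn.genes,
            control_flux=s.control_flux,
            production_flux_mean=s.production_flux_mean,
            level_fluxes=dict(s.level_fluxes),
        )
        if rid == config.biomass_reaction_id:
            excluded.append((rid, "biomass reaction"))
        elif rid == config.target_reaction_id:
            excluded.append((rid, "enforced target"))
        elif rxn.is_exchange:
            excluded.append((rid, "exchange reaction"))
        elif not s.direction_consistent:
            excluded.append((rid, "direction flip between regimes"))
        elif s.reason == "inactive":
            excluded.append((rid, "inactive in both regimes"))
        elif config.gene_only and not rxn.genes:
            excluded.append((rid, "no gene association"))
        elif s.activated:
            up.append(entry)
        elif s.score is not None and s.score > 1.0 + delta:
            up.append(entry)
        elif s.score is not None and 0.0 < s.score < 1.0 - delta:
            down.append(entry)
        else:
            excluded.append((rid, "neutral score"))

    activated = [e for e in up if e.activated]
    numeric = [e for e in up if not e.activated]
    activated.sort(key=lambda e: (-abs(e.production_flux_mean), e.reaction_id))
    numeric.sort(key=lambda e: (-(e.score or 0.0), e.reaction_id))
    down.sort(key=lambda e: (e.score or 0.0, e.reaction_id))
    return TargetTable(up=activated + numeric, down=down, excluded=excluded)


@dataclass
class GeneScore:
    gene_id: str
    score: Optional[float]  # None == ACTIVATED
    activated: bool
    supporting_reactions: List[str]


def score_genes(
    model: MetabolicModel,
    scores: Sequence[ReactionScore],
    direction: str = "up",
) -> List[GeneScore]:
    """Fold reaction scores onto genes through the GPR rules.

    A gene's score is the extremal score among reactions whose rule names
    it: the maximum for the up direction, the minimum for down. ACTIVATED
    dominates any numeric score in the up direction. Genes appearing in no
    rule are omitted; every contributing reaction is listed as support.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    by_rxn = {s.reaction_id: s for s in scores}
    gene_rxns: Dict[str, List[str]] = {}
    for r in model.reactions:
        if r.id not in by_rxn:
            continue
        for g in r.genes:
            gene_rxns.setdefault(g, []).append(r.id)

    out: List[GeneScore] = []
    for g, rids in gene_rxns.items():
        cands = [by_rxn[rid] for rid in rids]
        numeric = [c for c in cands if c.score is not None and not c.activated]
        has_activated = any(c.activated for c in cands)
        if direction == "up" and has_activated:
            out.append(GeneScore(g, None, True, rids))
            continue
        if not numeric:
            if has_activated:  # down direction, only activated support
                out.append(GeneScore(g, None, True, rids))
            continue
        agg = max if direction == "up" else min
        out.append(GeneScore(g, agg(c.score for c in numeric), False, rids))
    return out


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def export_target_table(table: TargetTable, path, fractions: Sequence[float] = ()) -> None:
    """Write the classified targets as a deterministic TSV.

    Columns: rank, reaction_id, gene_ids, direction, score, control_flux,
    production_flux_mean, then one column per enforcement level. Re-export
    of an identical table is byte-identical.
    """
    frs = list(fractions)
    if not frs:
        seen: Dict[float, None] = {}
        for e in table.up + table.down:
            for f in e.level_fluxes:
                seen.setdefault(f, None)
        frs = sorted(seen)
    header = [
        "rank",
        "reaction_id",
        "gene_ids",
        "direction",
        "score",
        "control_flux",
        "production_flux_mean",
    ] + [f"flux_f{_fmt(f)}" for f in frs]
    lines = ["\t".join(header)]
    for direction, entries in (("up", table.up), ("down", table.down)):
        for rank, e in enumerate(entries, start=1):
            score = ACTIVATED if e.activated else _fmt(e.score if e.score is not None else float("nan"))
            row = [
                str(rank),
                e.reaction_id,
                ";".join(e.gene_ids),
                direction,
                score,
                _fmt(e.control_flux),
                _fmt(e.production_flux_mean),
            ] + [_fmt(e.level_fluxes.get(f, float("nan"))) for f in frs]
            lines.append("\t".join(row))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def export_scan_matrix(scan: ScanResult, path) -> None:
    """Write the full reactions × (control + levels) flux matrix as TSV."""
    frs = scan.optimal_fractions
    header = ["reaction_id", "control"] + [f"f{_fmt(f)}" for f in frs]
    lines = ["\t".join(header)]
    for rid in scan.control.fluxes:
        row = [rid, _fmt(scan.control.fluxes[rid])]
        row += [_fmt(scan.levels[f].fluxes[rid]) for f in frs]
        lines.append("\t".join(row))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
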