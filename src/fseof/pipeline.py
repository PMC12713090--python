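"""End-to-end pipeline: read → graft → medium → scan → score → classify →
export, with a run manifest for reproducibility auditing.

Identical configuration and inputs produce byte-identical target tables;
the manifest records input/output checksums so silent drift is detectable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import __version__
from .core import MetabolicModel, ModelError, set_medium, validate_model
from .io import FormatError, model_checksum, read_model, write_model
from .pathway import (
    InterventionSpec,
    PathwayModule,
    build_ncm_module,
    build_spinosad_module,
    compare_scenarios,
    graft_module,
)
from .scan import (
    ScanConfig,
    ScanError,
    classify_targets,
    export_scan_matrix,
    export_target_table,
    run_scan,
    score_genes,
    score_reactions,
)

_MODULE_BUILDERS = {
    "spinosad": lambda: build_spinosad_module("branch"),
    "spinosad_lumped": lambda: build_spinosad_module("lumped"),
    "ncm": build_ncm_module,
}


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; loadable from YAML/JSON."""

    model_path: str
    scan: ScanConfig
    model_format: Optional[str] = None
    grafts: Tuple[str, ...] = ()  # names in _MODULE_BUILDERS
    medium: Dict[str, float] = field(default_factory=dict)
    scenarios: Tuple[Tuple[str, Tuple[dict, ...]], ...] = ()
    substrate_exchange_id: Optional[str] = None
    output_dir: str = "fseof_out"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        scan = ScanConfig(**doc["scan"])
        return cls(
            model_path=doc["model_path"],
            model_format=doc.get("model_format"),
            scan=scan,
            grafts=tuple(doc.get("grafts", ())),
            medium=dict(doc.get("medium", {})),
            scenarios=tuple(
                (s["name"], tuple(s.get("interventions", ())))
                for s in doc.get("scenarios", ())
            ),
            substrate_exchange_id=doc.get("substrate_exchange_id"),
            output_dir=doc.get("output_dir", "fseof_out"),
        )

    def validate(self) -> None:
        if not Path(self.model_path).exists():
            raise FileNotFoundError(self.model_path)
        for g in self.grafts:
            if g not in _MODULE_BUILDERS:
                raise ModelError(f"unknown graft module {g!r}")


@dataclass
class RunManifest:
    tool_version: str
    config_echo: dict
    input_checksums: Dict[str, str] = field(default_factory=dict)
    output_checksums: Dict[str, str] = field(default_factory=dict)
    stages: List[Dict[str, object]] = field(default_factory=list)

    def record(self, stage: str, status: str, seconds: float, detail: str = "") -> None:
        self.stages.append(
            {"stage": stage, "status": status, "wall_time_s": round(seconds, 4),
             "detail": detail}
        )

    @property
    def ok(self) -> bool:
        return all(s["status"] == "ok" for s in self.stages)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True,
                                         default=str) + "\n")


def _intervention_from_dict(doc: dict) -> InterventionSpec:
    module = None
    if doc.get("module"):
        module = _MODULE_BUILDERS[doc["module"]]()
    return InterventionSpec(
        kind=doc["kind"],
        target_reaction_ids=tuple(doc.get("targets", ())),
        module=module,
        factor=float(doc.get("factor", 1.0)),
        mapping=doc.get("mapping"),
    )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages; a stage failure is recorded and downstream stages
    are skipped (the manifest is always returned and written)."""
    manifest = RunManifest(
        tool_version=__version__,
        config_echo={
            "model_path": config.model_path,
            "grafts": list(config.grafts),
            "medium": config.medium,
            "scan": config.scan.__dict__,
        },
    )
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    model: Optional[MetabolicModel] = None
    failed = False

    def stage(name):
        def deco(fn):
            nonlocal failed
            if failed:
                manifest.record(name, "skipped", 0.0)
                return None
            t0 = time.perf_counter()
            try:
                result = fn()
                manifest.record(name, "ok", time.perf_counter() - t0)
                return result
            except (ModelError, ScanError, FormatError, FileNotFoundError,
                    KeyError) as exc:
                manifest.record(name, "failed", time.perf_counter() - t0, str(exc))
                failed = True
                return None
        return deco

    @stage("validate_config")
    def _cfg():
        config.validate()
        manifest.input_checksums[config.model_path] = model_checksum(config.model_path)

    @stage("read_model")
    def model():  # noqa: F811 - stage result
        return read_model(config.model_path, config.model_format)

    @stage("graft")
    def model_grafted():
        m = model
        for g in config.grafts:
            m = graft_module(m, _MODULE_BUILDERS[g]())
        return m

    current = model_grafted if model_grafted is not None else model

    @stage("set_medium")
    def model_fed():
        if not config.medium:
            return current
        return set_medium(current, config.medium)

    current = model_fed if model_fed is not None else current

    @stage("scan")
    def scan():
        return run_scan(current, config.scan)

    @stage("score")
    def scores():
        return score_reactions(scan)

    @stage("classify")
    def table():
        return classify_targets(scores, current, config.scan)

    @stage("gene_scores")
    def genes():
        up = score_genes(current, scores, "up")
        down = score_genes(current, scores, "down")
        return up, down

    @stage("export")
    def _export():
        export_target_table(table, out_dir / "targets.tsv",
                            fractions=scan.optimal_fractions)
        export_scan_matrix(scan, out_dir / "scan_matrix.tsv")
        up, down = genes
        gene_lines = ["gene_id\tdirection\tscore\tsupporting_reactions"]
        for direction, lst in (("up", up), ("down", down)):
            for g in sorted(lst, key=lambda x: x.gene_id):
                s = "ACTIVATED" if g.activated else f"{g.score:.10g}"
                gene_lines.append(
                    f"{g.gene_id}\t{direction}\t{s}\t{';'.join(g.supporting_reactions)}"
                )
        (out_dir / "gene_scores.tsv").write_text("\n".join(gene_lines) + "\n")
        summary = {
            "model_checksum": manifest.input_checksums.get(config.model_path),
            "solver": "scipy-highs",
            "tolerances": {"feasibility": 1e-9, "mass_balance": 1e-6},
            "max_biomass": scan.max_biomass,
            "target_max_per_level": {str(k): v for k, v in
                                     scan.target_max_per_level.items()},
            "n_up": len(table.up),
            "n_down": len(table.down),
            "warnings": scan.warnings,
            "config": manifest.config_echo,
        }
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n")

    if config.scenarios:
        @stage("scenarios")
        def _scen():
            scen = [(name, [_intervention_from_dict(d) for d in specs])
                    for name, specs in config.scenarios]
            results = compare_scenarios(
                current, scen, config.scan.target_reaction_id,
                config.substrate_exchange_id or "EX_glc")
            lines = ["scenario\tmax_target_flux\tyield_per_substrate\tdelta_vs_base\tstatus"]
            for r in results:
                lines.append(f"{r.scenario}\t{r.max_target_flux:.10g}\t"
                             f"{r.yield_per_substrate:.10g}\t{r.delta_vs_base:.10g}\t"
                             f"{r.status}")
            (out_dir / "scenarios.tsv").write_text("\n".join(lines) + "\n")

    for fname in ("targets.tsv", "scan_matrix.tsv", "gene_scores.tsv",
                  "summary.json", "scenarios.tsv"):
        fpath = out_dir / fname
        if fpath.exists():
            manifest.output_checksums[fname] = hashlib.sha256(
                fpath.read_bytes()).hexdigest()
    manifest.write(out_dir / "manifest.json")
    return manifest
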