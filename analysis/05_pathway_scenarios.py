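#!/usr/bin/env python
"""Graft the spinosad module onto the toy host, scan it, and compare
engineering scenarios.

Scenarios mirror classic strain-engineering moves: amplifying the rhamnose
branch, adding the carbon-conserving malonyl-CoA route, mobilizing the
triacylglycerol storage pool, and knocking out an essential biosynthetic
branch as a negative control.
"""

import argparse
from pathlib import Path

from fseof.lp import maximize_flux
from fseof.pathway import (
    SPINOSYN_A_DEMAND,
    InterventionSpec,
    build_ncm_module,
    build_spinosad_module,
    compare_scenarios,
    graft_module,
)
from fseof.scan import (
    ScanConfig,
    classify_targets,
    export_target_table,
    run_scan,
    score_reactions,
)
from fseof.toys import make_host_toy


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    host = make_host_toy()
    grafted = graft_module(host, build_spinosad_module())
    mu = maximize_flux(grafted, "R_bio").objective_value
    spn = maximize_flux(grafted, SPINOSYN_A_DEMAND).objective_value
    print(f"grafted host: max growth {mu:.6g}, max spinosyn A {spn:.6g}\n")

    cfg = ScanConfig("R_bio", SPINOSYN_A_DEMAND)
    scan = run_scan(grafted, cfg)
    table = classify_targets(score_reactions(scan), grafted, cfg)
    export_target_table(table, args.out / "host_targets.tsv",
                        fractions=scan.optimal_fractions)
    print(f"scan targets: {len(table.up)} up, {len(table.down)} down "
          f"(written to host_targets.tsv)")

    scenarios = [
        ("rham_amplify",
         [InterventionSpec("amplify",
                           ("SPN_RHAM_gtt", "SPN_RHAM_gdh",
                            "SPN_RHAM_epi", "SPN_RHAM_kre"), factor=2.0)]),
        ("ncm_route",
         [InterventionSpec("add_module", module=build_ncm_module())]),
        ("tag_mobilize",
         [InterventionSpec("enable_degradation", ("TAG_DEG",))]),
        ("ncm_plus_tag",
         [InterventionSpec("add_module", module=build_ncm_module()),
          InterventionSpec("enable_degradation", ("TAG_DEG",))]),
        ("no_forosamine_ko",
         [InterventionSpec("knockout", ("SPN_FORO_SYN",))]),
    ]
    results = compare_scenarios(grafted, scenarios, SPINOSYN_A_DEMAND, "EX_glc")
    rows = ["scenario\tmax_spinosyn_a\tyield_per_glucose\tdelta_vs_base\tstatus"]
    for r in results:
        rows.append(f"{r.scenario}\t{r.max_target_flux:.6g}\t"
                    f"{r.yield_per_substrate:.6g}\t{r.delta_vs_base:.6g}\t{r.status}")
    out = "\n".join(rows) + "\n"
    (args.out / "scenarios.tsv").write_text(out)
    print("\n" + out, end="")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
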