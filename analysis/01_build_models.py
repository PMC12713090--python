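#!/usr/bin/env python
"""Build every model used downstream and write them under results/models/.

Emits the two closed-form fixtures, one seeded branched toy, the toy host,
and the host with the spinosad module grafted on, then prints a validation
and capability summary for each.
"""

import argparse
from pathlib import Path

from fseof.core import validate_model
from fseof.io import write_model
from fseof.lp import maximize_flux
from fseof.pathway import SPINOSYN_A_DEMAND, build_spinosad_module, graft_module
from fseof.toys import (
    ToySpec,
    make_branched_toy,
    make_host_toy,
    make_linear_toy,
    make_redundant_toy,
)


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/models"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    host = make_host_toy()
    grafted = graft_module(host, build_spinosad_module())
    models = {
        "t1_linear": make_linear_toy(),
        "t3_redundant": make_redundant_toy(),
        f"t2_branched_seed{args.seed}": make_branched_toy(ToySpec(seed=args.seed))[0],
        "host": host,
        "host_spinosad": grafted,
    }

    rows = ["model\tn_mets\tn_rxns\tsolvable\tmax_biomass"]
    for name, model in models.items():
        write_model(model, args.out / f"{name}.json")
        report = validate_model(model)
        mu = maximize_flux(model, model.biomass_reaction_id).objective_value
        rows.append(
            f"{name}\t{len(model.metabolites)}\t{len(model.reactions)}\t"
            f"{report.is_solvable}\t{mu:.6g}"
        )
    summary = "\n".join(rows) + "\n"
    (args.out / "model_summary.tsv").write_text(summary)
    print(summary, end="")
    spn = maximize_flux(grafted, SPINOSYN_A_DEMAND).objective_value
    print(f"\nmax spinosyn A on grafted host: {spn:.6g}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
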