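#!/usr/bin/env python
"""Cross-check the production scan against the brute-force oracle.

The oracle solves the whole enforcement range on a dense grid through an
independent dense-matrix, dual-simplex code path and re-derives every
score; agreement within 1e-6 on the fixtures plus seeded branched toys is
the correctness evidence for the scan implementation.
"""

import argparse
from pathlib import Path

import numpy as np

from fseof.scan import ScanConfig, run_scan, score_reactions
from fseof.toys import (
    ToySpec,
    make_branched_toy,
    make_linear_toy,
    make_redundant_toy,
    oracle_scores,
)


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-toys", type=int, default=50)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(args.seed)
    cfg = ScanConfig("R_bio", "EX_p")
    cases = [("t1_linear", make_linear_toy()), ("t3_redundant", make_redundant_toy())]
    for s in rng.integers(0, 2**31 - 1, size=args.n_toys):
        cases.append((f"t2_seed{s}", make_branched_toy(ToySpec(seed=int(s)))[0]))

    rows = ["model\tn_scored\tmax_abs_score_diff\tactivation_flags_agree"]
    worst = 0.0
    for name, model in cases:
        ours = {s.reaction_id: s for s in score_reactions(run_scan(model, cfg))}
        ref = {s.reaction_id: s for s in oracle_scores(model, cfg)}
        diffs = [
            abs(ours[r].score - ref[r].score)
            for r in ours
            if ours[r].score is not None and ref[r].score is not None
        ]
        flags = all(ours[r].activated == ref[r].activated for r in ours)
        d = max(diffs) if diffs else 0.0
        worst = max(worst, d)
        rows.append(f"{name}\t{len(diffs)}\t{d:.3e}\t{flags}")
    out = "\n".join(rows) + "\n"
    (args.out / "oracle_crosscheck.tsv").write_text(out)
    print(out, end="")
    print(f"\nworst score difference over {len(cases)} models: {worst:.3e}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
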