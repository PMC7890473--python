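"""Combinatorics of the D=3 ordinal alphabet and its legal-transition graph.

Writes results/transition_structure.json and results/legal_transitions.csv.

Findings at a glance: each of the six D=3 patterns has exactly 3 legal
one-step successors (half the alphabet); the reachable fraction D/D! decays
fast (0.5 at D=3, 0.04 at D=5), only the two monotone patterns self-loop,
and two of the three legal successors of {0,1,2} imply the next raw value
goes down.
"""

import json
from pathlib import Path

import pandas as pd

from ordpred import (
    PATTERNS_D3,
    encode_series,
    legal_successors,
    next_step_direction,
    pattern_code,
    reachable_fraction,
    self_loop_patterns,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def fmt(p):
    return "{" + ",".join(map(str, p)) + "}"


def main() -> None:
    rows = []
    for p in PATTERNS_D3:
        succ = sorted(legal_successors(p))
        rows.append(
            {
                "pattern": fmt(p),
                "code": pattern_code(p),
                "successors": " ".join(fmt(q) for q in succ),
                "n_successors": len(succ),
            }
        )
    pd.DataFrame(rows).to_csv(OUT / "legal_transitions.csv", index=False)

    demo = [34, 3, 5, 23, 247, 234, 12, 1, 2, 3]
    seq = encode_series(demo)
    succ1 = sorted(legal_successors((0, 1, 2)))
    down = [q for q in succ1 if next_step_direction(q) == "decrease"]
    summary = {
        "demo_series": demo,
        "demo_patterns": [fmt(seq[s]) for s in range(len(seq))],
        "reachable_fraction": {D: reachable_fraction(D) for D in range(2, 6)},
        "self_loops_D3": [fmt(p) for p in sorted(self_loop_patterns(3))],
        "decrease_share_after_012": f"{len(down)}/{len(succ1)}",
    }
    (OUT / "transition_structure.json").write_text(json.dumps(summary, indent=2))
    print("wrote", OUT / "legal_transitions.csv")
    print("reachable fraction by D:", {d: round(v, 4) for d, v in summary["reachable_fraction"].items()})
    print("successors of {0,1,2} implying a decrease:", summary["decrease_share_after_012"])


if __name__ == "__main__":
    main()
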