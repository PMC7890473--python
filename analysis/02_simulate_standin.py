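"""Generate the synthetic stand-in for the minute-price study series.

A pattern-level Markov chain seeded with the transition matrix measured on
a year of minute-resolution Bitcoin closing prices is rendered into real
values, then summarised the way the study data is: pattern frequencies and
the conditional transition table.  Writes the series and both tables under
results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ordpred import encode_series, pattern_distribution, transition_matrix
from ordpred.io import series_from_values, write_price_csv
from ordpred.synth import BITCOIN_MINUTE_TPM, gen_pattern_markov

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)
SCRATCH = ROOT / "scratch"  # the full series is bulky and regenerable
SCRATCH.mkdir(exist_ok=True)

N = 100_000
SEED = 2018

LABELS = ["{0,1,2}", "{0,2,1}", "{1,0,2}", "{1,2,0}", "{2,0,1}", "{2,1,0}"]


def main() -> None:
    values = gen_pattern_markov(N, SEED)
    write_price_csv(series_from_values(values), SCRATCH / "standin_series.csv")
    seq = encode_series(values)
    freq = pattern_distribution(seq)
    tm = transition_matrix(seq)
    pd.DataFrame({"pattern": LABELS, "frequency": freq}).to_csv(
        OUT / "standin_frequencies.csv", index=False
    )
    pd.DataFrame(tm.conditional, index=LABELS, columns=LABELS).to_csv(
        OUT / "standin_transitions.csv"
    )
    ref = BITCOIN_MINUTE_TPM / BITCOIN_MINUTE_TPM.sum(axis=1, keepdims=True)
    dev = np.abs(tm.conditional - ref).max()
    print(f"n={N} seed={SEED}")
    print("pattern frequencies:", np.round(freq, 3))
    print(f"max |empirical - reference| conditional cell: {dev:.4f}")


if __name__ == "__main__":
    main()
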