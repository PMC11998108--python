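#!/usr/bin/env python
"""Fit ultra-fast release kinetics on aliquot-sampled replicate series.

Simulates five replicate release runs (14 mL chamber, 1 mL aliquots
replaced with buffer, sampling every 10 min to 1 h then out to 24 h,
release rate constant 0.056 min^-1, 3 % measurement CV), applies the
aliquot-replacement correction, normalises to the 24-h total and fits the
saturating model y = k*t/(1 + a*t) by the linearised 1/t-vs-1/y
regression.  Writes results/release_params.csv.

Found: the correction-then-fit pipeline recovers the generating rate
constant to a few percent, most of the 24-h total is released within the
first two hours, and the linearised r^2 stays near 1, consistent with an
ultra-fast, burst-dominated release profile.
"""

import sys
from pathlib import Path

import pandas as pd

from mnswell import release as rl
from mnswell.pipeline import summarize_replicates
from mnswell.synthetic import SimSpec, gen_release_series

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20250927
N_REPLICATES = 5
NOISE_CV = 0.03


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for i in range(N_REPLICATES):
        series, truth = gen_release_series(
            SimSpec(model="taolu_release", seed=SEED + i, noise_cv=NOISE_CV))
        C_cum = rl.cumulative_correct(series)
        C_pct = rl.cumulative_percent(C_cum, float(C_cum[-1]))
        fit = rl.taolu_fit(series.t, C_cum / C_cum[-1])
        rows.append({
            "replicate": i + 1, "seed": truth["seed"],
            "k_per_min": fit.k, "a_per_min": fit.a, "r2": fit.r2,
            "plateau": fit.plateau,
            "released_at_120min_pct": float(C_pct[series.t == 120.0][0]),
            "release_rate_pct_per_min": rl.release_rate(C_pct, series.t, 120.0),
        })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "release_params.csv", index=False)

    k = summarize_replicates(df["k_per_min"].tolist())
    at120 = summarize_replicates(df["released_at_120min_pct"].tolist())
    print(f"k = {k.mean*1e2:.1f} +/- {k.sem*1e2:.1f} x10^-2 min^-1 "
          f"(n={k.n}; truth {0.056*1e2:.1f})")
    print(f"released at 120 min: {at120.mean:.1f} +/- {at120.sem:.1f} % of the 24-h total")
    print(f"mean linearised r^2: {df['r2'].mean():.3f}")
    print(f"wrote {OUT / 'release_params.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
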