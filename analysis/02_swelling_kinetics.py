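#!/usr/bin/env python
"""Fit pseudo-second-order swelling kinetics on replicate mass series.

Simulates six replicate arrays (260 mg dry mass, equilibrium swelling
714 %, rate constant 5.35e-5 %^-1 min^-1, 5 % measurement CV, weighed
every 10 min for 3 h), fits each by the linearised t/S-vs-t regression
and by nonlinear least squares, and adds the gel characterisation
formulas (EWC, gel fraction, porosity) on the scalar mass records.
Writes results/swelling_params.csv.

Found: the linearised fit recovers the generating parameters well within
their replicate scatter (mean S_inf within ~1 % of truth), and the
linearised and nonlinear routes agree to ~1 % under this noise level, so
the conventional linearised analysis is adequate for balance-grade data.
"""

import sys
from pathlib import Path

import pandas as pd

from mnswell import swelling as sw
from mnswell.pipeline import summarize_replicates
from mnswell.synthetic import SimSpec, gen_swelling_series

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20250927
N_REPLICATES = 6
NOISE_CV = 0.05


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for i in range(N_REPLICATES):
        series, truth = gen_swelling_series(
            SimSpec(model="pso_swelling", seed=SEED + i, noise_cv=NOISE_CV))
        t, S = sw.swelling_percent_series(series)
        lin = sw.pso_fit(t, S)
        nls = sw.pso_fit_nls(t, S)
        rows.append({
            "replicate": i + 1, "seed": truth["seed"],
            "S_at_180min_pct": S[-1],
            "S_inf_pct": lin.S_inf, "k_s": lin.k_s, "r2": lin.r2,
            "S_inf_nls_pct": nls.S_inf, "k_s_nls": nls.k_s,
            "m_inf_mg": sw.mass_at_equilibrium(series.m0, lin.S_inf),
        })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "swelling_params.csv", index=False)

    truth_S, truth_k = 714.0, 5.35e-5
    s = summarize_replicates(df["S_inf_pct"].tolist())
    k = summarize_replicates(df["k_s"].tolist())
    print(f"S_inf = {s.mean:.0f} +/- {s.sem:.0f} % (n={s.n}; truth {truth_S:.0f})")
    print(f"k_s   = {k.mean*1e5:.2f} +/- {k.sem*1e5:.2f} x10^-5 %^-1 min^-1 "
          f"(truth {truth_k*1e5:.2f})")
    print(f"linearised vs nonlinear S_inf mean rel diff: "
          f"{(abs(df.S_inf_pct - df.S_inf_nls_pct) / df.S_inf_nls_pct).mean():.3%}")

    # gel characterisation on the scalar mass records
    masses = sw.GelMasses(m0=100.0, m_inf=683.0, m_x=97.0,
                          m_EtOH=218.35, V_T=1.0)
    print(f"EWC = {sw.ewc(masses):.0f} %, GF = {sw.gel_fraction(masses):.0f} %, "
          f"porosity = {sw.porosity(masses)*100:.0f} %")
    print(f"wrote {OUT / 'swelling_params.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
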