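"""Standardize heterogeneous trend datatypes to annual rates of change.

Demonstrates the conversion layer on simulated records of every
supported datatype — OU-correlated abundance time series (fitted by
GLS log-linear regression), finite rates, total percent changes and
per-year change series — and tabulates the recovered annual rates.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from carnitrend import synthetic, trends


def main() -> None:
    out = common.ensure_results()
    rows = []

    # abundance series: simulate with known rate, refit with the OU-GLS model
    r_true = 0.03
    fits = []
    for k in range(200):
        series = synthetic.generate_abundance_series(
            r_true=r_true, n_years=15, ou_theta=0.5, ou_sigma=0.15,
            seed=common.GLOBAL_SEED + k)
        fits.append(trends.fit_loglinear_ou(series))
    r_hat = np.array([f.r for f in fits])
    rows.append({
        "datatype": "abundance_series (200 OU simulations, r_true=0.03)",
        "r": r_hat.mean(), "pct": 100 * (np.exp(r_hat.mean()) - 1),
        "note": f"mean ou_theta_hat={np.mean([f.ou_theta_hat for f in fits]):.2f}",
    })

    for label, est in [
        ("finite_rate lambda=1.05", trends.rate_from_finite_rate(1.05)),
        ("percent_change -50% over 10y", trends.rate_from_percent_change(-50, 10)),
        ("change_series doubled then halved",
         trends.rate_from_change_series([2.0, 0.5])),
    ]:
        rows.append({"datatype": label, "r": est.r, "pct": est.pct, "note": ""})

    table = pd.DataFrame(rows)
    table.to_csv(out / "trend_conversions.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v: .4f}"))
    mc_se = r_hat.std(ddof=1) / np.sqrt(r_hat.size)
    print(f"\nOU-GLS recovery: mean r_hat = {r_hat.mean():.4f} "
          f"(truth 0.0300, MC se {mc_se:.4f})")


if __name__ == "__main__":
    main()
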