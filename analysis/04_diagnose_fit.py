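"""Convergence, residual, spatial and phylogenetic diagnostics of the fit.

Reloads the posterior from 03_fit_model.py and checks what the model
assumes: chains agree (split-R-hat), residuals carry no spatial
(Moran's I) or phylogenetic (Pagel's lambda on the genus/species
taxonomy) autocorrelation, replicate data resemble the observations
(posterior predictive check), and how much variance the model explains
(conditional / marginal R-squared).
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from carnitrend import diagnostics, model


def main() -> None:
    out = common.ensure_results()
    trend = pd.read_csv(out / "trend.csv", float_precision="round_trip")
    cov = pd.read_csv(out / "covariates_imputed.csv", float_precision="round_trip")
    inputs = model.build_design(trend, cov)
    samples = model.PosteriorSamples.load(out / "posterior")

    mu = diagnostics._mu_matrix(samples, inputs)
    resid = inputs.y - np.median(mu, axis=0)
    quant = ~inputs.is_censored

    morans = diagnostics.morans_i(
        resid[quant], inputs.latitude[quant], inputs.longitude[quant],
        n_permutations=499, seed=common.GLOBAL_SEED + 4, jitter=True)
    sp_labels, sp_res = diagnostics.species_residuals(
        resid[quant], trend.loc[quant, "species"].to_numpy())
    lam, lam_p = diagnostics.pagels_lambda(
        sp_res, species=sp_labels,
        species_to_genus=dict(zip(trend["species"], trend["genus"])))
    ppc = diagnostics.posterior_predictive_check(samples, inputs,
                                                 seed=common.GLOBAL_SEED + 5)
    r2c, r2m = diagnostics.conditional_r2(samples, inputs)

    report = diagnostics.DiagnosticsReport(
        rhat={"max_monitored": samples.max_rhat},
        ess={"alpha": diagnostics.ess(samples.alpha)},
        morans=morans, pagel=(lam, lam_p), ppc=ppc,
        r2_conditional=r2c, r2_marginal=r2m)
    (out / "diagnostics.json").write_text(json.dumps(report.to_dict(), indent=2))
    ppc.to_csv(out / "ppc.csv", index=False)

    print(f"Moran's I on quantitative residuals: I={morans[0]:.4f} "
          f"(E[I]={morans[1]:.4f}), permutation p={morans[2]:.3f} "
          f"-> {'no' if morans[2] > 0.05 else 'SOME'} spatial autocorrelation")
    print(f"Pagel's lambda on per-species residuals: {lam:.3f} (p={lam_p:.3f}) "
          f"-> {'no' if lam_p > 0.05 else 'SOME'} phylogenetic signal")
    print(f"posterior predictive check: {int(ppc['within_95'].sum())}/{len(ppc)} "
          f"statistics inside their replicate 95% bands")
    print(f"conditional R2 = {r2c:.2f}, marginal R2 = {r2m:.2f}")


if __name__ == "__main__":
    main()
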