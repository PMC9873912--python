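"""Simulate the study dataset: trends, covariates, missingness, imputation.

Generates a synthetic carnivore-trend dataset with known ground truth
(hierarchical structure, 16 z-scale covariates, quality-weighted
quantitative rates, a qualitative subset), blanks covariate cells at
random, imputes them with uncertainty, and writes the tables that the
model-fitting script consumes.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from carnitrend import synthetic
from carnitrend.covariates import impute_covariates, sd_columns


def main() -> None:
    out = common.ensure_results()
    cfg = common.DATA_CONFIG
    trend, cov, truth = synthetic.generate_dataset(cfg)
    cov_missing = synthetic.inject_missingness(cov, cfg.missing_rate,
                                               seed=common.GLOBAL_SEED + 2)
    cov_imputed = impute_covariates(cov_missing, seed=common.GLOBAL_SEED + 3)

    trend.to_csv(out / "trend.csv", index=False)
    cov_missing.to_csv(out / "covariates_missing.csv", index=False)
    cov_imputed.to_csv(out / "covariates_imputed.csv", index=False)
    (out / "truth.json").write_text(json.dumps(
        {"params": truth.params(), "true_rate": truth.true_rate.tolist()},
        indent=2))

    n_qual = int((trend["response_kind"] == "qualitative").sum())
    pct = trend["pct"].dropna()
    n_missing = int(cov_missing.drop(columns="population_id").isna().sum().sum())
    print(f"simulated {len(trend)} populations "
          f"({len(trend) - n_qual} quantitative, {n_qual} qualitative)")
    print(f"quantitative rates: median {pct.median():.2f} %/yr, "
          f"range {pct.min():.1f} to {pct.max():.1f}")
    print(f"blanked {n_missing} covariate cells; imputed with uncertainty in "
          f"{len(sd_columns(cov_imputed))} columns")
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
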