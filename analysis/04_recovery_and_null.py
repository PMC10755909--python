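#!/usr/bin/env python
"""Parameter-recovery and null-calibration study.

Twenty seeded replicates of the full synthetic design are fit and the
recovered asymptote at the reference spectrum / 700 PPFD is compared with
its generating value; Wald-interval coverage is tallied over all 48 fixed
effects. A second set of twenty replicates with every treatment offset
collapsed to zero (a null model) measures how often the Tukey-adjusted
letter stage declares spectrum pairs different when no difference exists.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import co2resp as cr
from co2resp.letters import pairwise_letters
from co2resp.nlme import _combo_weights, marginal_estimates, theta_from_effects

OUT = Path(__file__).resolve().parents[1] / "results"
N_REPLICATES = 20
TRUTH_D700 = 12.01


def main() -> None:
    truth_ref = cr.SimulationTruth(seed=0)
    eff = truth_ref.effects
    eff.sigma_u, eff.residual_sds = truth_ref.sigma_u, truth_ref.residual_sds

    rows = []
    inside_all = []
    for seed in range(1, N_REPLICATES + 1):
        df = cr.simulate_experiment(cr.SimulationTruth(seed=seed))
        fit = cr.fit_model(df, cr.FitConfig(maxiter=5000))
        w = _combo_weights(fit.design, "d", "37R36G27B", 700.0)
        est, se = fit.linear_combo(w)
        th = theta_from_effects(eff, fit.design)
        nf = fit.design.n_fixed
        inside = np.abs(fit.theta[:nf] - th[:nf]) <= 1.96 * fit.standard_errors[:nf]
        inside_all.append(inside)
        rows.append((seed, est, se, abs(est - TRUTH_D700) <= 2 * se,
                     inside.mean(), fit.converged))
    rec = pd.DataFrame(rows, columns=["seed", "d700_estimate", "d700_se",
                                      "within_2se", "wald_coverage", "converged"])
    rec.to_csv(OUT / "recovery_study.csv", index=False)
    pooled = float(np.mean(inside_all))
    print(f"recovery: d(ref,700) within 2 SE of {TRUTH_D700} in "
          f"{int(rec.within_2se.sum())}/{N_REPLICATES} replicates; "
          f"mean estimate {rec.d700_estimate.mean():.3f}")
    print(f"pooled 95% Wald coverage of the 48 fixed effects: {pooled:.3f}")
    print("note: plain-ML sigma_u is biased low with 3 plants/spectrum "
          "(plant means partly absorbed by the spectrum effects), so Wald "
          "coverage sits below nominal — see docs/methods.md")

    null_rows = []
    for seed in range(1, N_REPLICATES + 1):
        truth = cr.perturb_truth(cr.SimulationTruth(seed=1000 + seed), 0.0)
        df = cr.simulate_experiment(truth)
        fit = cr.fit_model(df, cr.FitConfig(maxiter=5000))
        lvls, est, V = marginal_estimates(fit, "spectrum", "d")
        grp = pairwise_letters(lvls, est, V, alpha=0.05, adjustment="tukey")
        n_sig = int((grp.pairwise.p_adj < 0.05).sum())
        null_rows.append((seed, n_sig, len(grp.pairwise)))
    null = pd.DataFrame(null_rows, columns=["seed", "pairs_significant", "pairs_total"])
    null.to_csv(OUT / "null_calibration.csv", index=False)
    frac = null.pairs_significant.sum() / null.pairs_total.sum()
    print(f"null calibration: {null.pairs_significant.sum()}/{null.pairs_total.sum()} "
          f"spectrum pairs declared different at alpha 0.05 "
          f"({100 * frac:.1f}%, Tukey adjustment)")


if __name__ == "__main__":
    main()
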