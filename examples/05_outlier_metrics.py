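"""Outlier-detection metrics on synthetic scores: grid, rates, calibration.

Uses hand-made scores so the metric semantics are easy to follow: errors
and uncertainties are correlated but noisy, as for a real UQ method.
"""

import numpy as np

from pesuq.uq_eval import (
    ScoredTestSet,
    calibration_curve,
    classify_predictions,
    outlier_grid,
    rates,
)

rng = np.random.default_rng(0)
n = 2000
variance = rng.lognormal(-1, 1.2, n)
squared_error = variance * rng.chisquare(1, n)  # perfectly calibrated
scored = ScoredTestSet(np.arange(n), squared_error, variance)

grid = outlier_grid(scored, [25, 100, 1000], [25, 100, 1000])
print("top-k detection accuracy (rows N_err, cols N_var):")
print(np.round(grid.accuracy, 2))

counts = classify_predictions(scored)  # thresholds: mean error / variance
r = rates(counts)
print(f"\nat (ε*=MSE, σ*=MV): TP={counts.n_tp} FP={counts.n_fp} "
      f"TN={counts.n_tn} FN={counts.n_fn}")
print(f"sensitivity R_TP={r.r_tp:.2f}  precision P_TP={r.p_tp:.2f}  "
      f"fall-out R_FP={r.r_fp:.2f}  miss rate R_FN={r.r_fn:.2f}")

curve = calibration_curve(scored, n_bins=8)
print("\ncalibration (per-bin RMV vs RMSE — equal means perfect):")
for rmv, rmse, count in zip(curve.rmv, curve.rmse, curve.counts):
    print(f"  RMV {rmv:6.3f}  RMSE {rmse:6.3f}  (n={count})")
# With chi-square errors the RMSE tracks the RMV bin-by-bin; a real model
# whose RMSE curve sits above the RMV diagonal is overconfident.
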