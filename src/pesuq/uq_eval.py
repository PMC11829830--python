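"""Outlier-detection and calibration analysis of uncertainty estimates.

Given per-structure squared errors and uncertainty scores (an energy
variance for ensembles/DER, an NLL for the GMM), this module evaluates

* top-k outlier-detection accuracy — the overlap between the N_err
  largest-error structures and the N_var largest-uncertainty structures,
  normalized by min(N_err, N_var) so a perfect detector scores 1 in every
  cell of the 2-D reliability grid,
* threshold classification (TP/FP/TN/FN) with sensitivity, precision,
  false-positive and false-negative rates,
* RMSE-versus-RMV calibration curves over equal-count variance bins,
* distribution/extreme-value reports for errors and uncertainties.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


@dataclasses.dataclass
class ScoredTestSet:
    """Per-structure squared error and uncertainty for one method.

    ``uncertainty_is_variance`` distinguishes variance-valued scores
    (kcal²/mol²) from rank-only scores such as the GMM NLL.
    """

    indices: np.ndarray
    squared_error: np.ndarray   # kcal^2/mol^2
    uncertainty: np.ndarray     # variance or NLL
    method: str = ""
    uncertainty_is_variance: bool = True

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.squared_error = np.asarray(self.squared_error, dtype=float)
        self.uncertainty = np.asarray(self.uncertainty, dtype=float)
        if len(set(self.indices.tolist())) != len(self.indices):
            raise ValueError("structure indices must be unique")
        if np.any(self.squared_error < 0):
            raise ValueError("squared errors must be non-negative")
        if not (
            len(self.indices)
            == len(self.squared_error)
            == len(self.uncertainty)
        ):
            raise ValueError("field lengths differ")

    def __len__(self):
        return len(self.indices)


@dataclasses.dataclass
class OutlierGrid:
    n_err_values: list
    n_var_values: list
    accuracy: np.ndarray  # (len(n_err), len(n_var)); NaN outside the triangle

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "n_err": ne,
                "n_var": nv,
                "accuracy": self.accuracy[i, j],
            }
            for i, ne in enumerate(self.n_err_values)
            for j, nv in enumerate(self.n_var_values)
            if np.isfinite(self.accuracy[i, j])
        ]
        return pd.DataFrame(rows)


@dataclasses.dataclass
class ConfusionCounts:
    n_tp: int
    n_fp: int
    n_tn: int
    n_fn: int
    epsilon_star: float
    sigma_star: float
    n_ties: int = 0

    @property
    def total(self) -> int:
        return self.n_tp + self.n_fp + self.n_tn + self.n_fn


@dataclasses.dataclass
class Rates:
    """Sensitivity, precision, false-positive and false-negative rates."""

    r_tp: float
    p_tp: float
    r_fp: float
    r_fn: float
    undefined: tuple = ()


@dataclasses.dataclass
class CalibrationCurve:
    rmv: np.ndarray
    rmse: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rmv": self.rmv, "rmse": self.rmse, "count": self.counts}
        )


def _top_k(values: np.ndarray, k: int) -> set:
    """Indices (positions) of the k largest values; ties broken by index."""
    order = np.lexsort((np.arange(len(values)), -values))
    return set(order[:k].tolist())


def outlier_accuracy(
    scored: ScoredTestSet,
    n_err: int,
    n_var: int,
    normalization: str = "min",
) -> float:
    """Top-k detection accuracy.

    Acc = |TopErr(n_err) ∩ TopVar(n_var)| / min(n_err, n_var) by default;
    ``normalization="n_var"`` divides by n_var instead (under which a
    perfect detector scores below 1 whenever n_err < n_var).
    """
    if n_err < 1 or n_var < 1:
        raise ValueError("n_err and n_var must be >= 1")
    if n_err > len(scored) or n_var > len(scored):
        raise ValueError("top-k larger than the scored set")
    top_err = _top_k(scored.squared_error, n_err)
    top_var = _top_k(scored.uncertainty, n_var)
    inter = len(top_err & top_var)
    denom = min(n_err, n_var) if normalization == "min" else n_var
    return inter / denom


DEFAULT_TOPK = [25, 50, 100, 200, 400, 800, 1000]


def outlier_grid(
    scored: ScoredTestSet,
    n_err_values=None,
    n_var_values=None,
    normalization: str = "min",
) -> OutlierGrid:
    """The triangular N_err × N_var reliability grid (N_err ≤ N_var)."""
    n_err_values = list(n_err_values or DEFAULT_TOPK)
    n_var_values = list(n_var_values or DEFAULT_TOPK)
    if n_err_values != sorted(n_err_values) or n_var_values != sorted(
        n_var_values
    ):
        raise ValueError("value lists must be sorted ascending")
    acc = np.full((len(n_err_values), len(n_var_values)), np.nan)
    for i, ne in enumerate(n_err_values):
        for j, nv in enumerate(n_var_values):
            if ne <= nv:
                acc[i, j] = outlier_accuracy(
                    scored, ne, nv, normalization=normalization
                )
    return OutlierGrid(n_err_values, n_var_values, acc)


def classify_predictions(
    scored: ScoredTestSet,
    epsilon_star: float | None = None,
    sigma_star: float | None = None,
) -> ConfusionCounts:
    """Threshold classification of predictions.

    TP: error > ε* and uncertainty > σ*; FP: error < ε* and uncertainty >
    σ*; TN: both below; FN: error > ε* and uncertainty < σ*. Comparisons
    are strict; values exactly at a threshold count as below it (tallied
    in ``n_ties``). Defaults: ε* = mean squared error, σ* = mean
    uncertainty of the scored set.
    """
    eps = (
        float(np.mean(scored.squared_error))
        if epsilon_star is None
        else epsilon_star
    )
    sig = (
        float(np.mean(scored.uncertainty))
        if sigma_star is None
        else sigma_star
    )
    if eps < 0 or (scored.uncertainty_is_variance and sig < 0):
        raise ValueError("thresholds must be non-negative")
    err_hi = scored.squared_error > eps
    var_hi = scored.uncertainty > sig
    ties = int(
        np.sum(scored.squared_error == eps)
        + np.sum(scored.uncertainty == sig)
    )
    return ConfusionCounts(
        n_tp=int(np.sum(err_hi & var_hi)),
        n_fp=int(np.sum(~err_hi & var_hi)),
        n_tn=int(np.sum(~err_hi & ~var_hi)),
        n_fn=int(np.sum(err_hi & ~var_hi)),
        epsilon_star=eps,
        sigma_star=sig,
        n_ties=ties,
    )


def rates(counts: ConfusionCounts) -> Rates:
    """Sensitivity R_TP, precision P_TP, fall-out R_FP, miss rate R_FN.

    Undefined ratios (zero denominators) come back as NaN with the
    affected names listed in ``undefined`` — never an exception.
    """
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    r_tp = ratio(counts.n_tp, counts.n_tp + counts.n_fn, "r_tp")
    p_tp = ratio(counts.n_tp, counts.n_tp + counts.n_fp, "p_tp")
    r_fp = ratio(counts.n_fp, counts.n_fp + counts.n_tn, "r_fp")
    r_fn = ratio(counts.n_fn, counts.n_tp + counts.n_fn, "r_fn")
    return Rates(r_tp, p_tp, r_fp, r_fn, undefined=tuple(undefined))


def threshold_sweep(
    scored: ScoredTestSet, n_points: int = 20
) -> pd.DataFrame:
    """Rates over a logarithmic grid of (ε*, σ*) decision boundaries."""
    def log_grid(v):
        pos = v[v > 0]
        lo, hi = np.quantile(pos, [0.02, 0.98])
        return np.geomspace(max(lo, 1e-12), hi, n_points)

    rows = []
    for eps in log_grid(scored.squared_error):
        for sig in log_grid(scored.uncertainty):
            counts = classify_predictions(scored, eps, sig)
            r = rates(counts)
            rows.append(
                {
                    "epsilon_star": eps,
                    "sigma_star": sig,
                    "r_tp": r.r_tp,
                    "p_tp": r.p_tp,
                    "r_fp": r.r_fp,
                    "r_fn": r.r_fn,
                }
            )
    return pd.DataFrame(rows)


def calibration_curve(scored: ScoredTestSet, n_bins: int = 10) -> CalibrationCurve:
    """RMSE vs root-mean-variance over equal-count bins of ascending variance.

    Only variance-valued uncertainties are admissible: an NLL (the GMM
    score) has no variance scale, so calibration is undefined for it.
    """
    if not scored.uncertainty_is_variance:
        raise TypeError(
            "calibration needs a variance-valued uncertainty; the GMM NLL "
            "is a rank score and cannot be placed on an RMSE scale"
        )
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_bins > len(scored):
        raise ValueError("more bins than samples")
    order = np.argsort(scored.uncertainty, kind="stable")
    chunks = np.array_split(order, n_bins)
    rmv = np.array(
        [np.sqrt(np.mean(scored.uncertainty[c])) for c in chunks]
    )
    rmse = np.array(
        [np.sqrt(np.mean(scored.squared_error[c])) for c in chunks]
    )
    counts = np.array([len(c) for c in chunks])
    return CalibrationCurve(rmv=rmv, rmse=rmse, counts=counts)


def error_distribution_report(
    scored: ScoredTestSet,
    reference_energies: np.ndarray | None = None,
    n_hist_bins: int = 40,
    n_flagged: int = 1000,
) -> dict:
    """Histograms and extreme-value tables for errors and uncertainties.

    Returns a dict of DataFrames: ``error_hist`` / ``uncertainty_hist``
    (log10-scale histograms), ``summary`` (min/max/mean), and
    ``residuals`` — per-structure table with the ``n_flagged``
    largest-uncertainty structures marked.
    """
    if len(scored) == 0:
        raise ValueError("empty scored set")

    def log_hist(v):
        pos = v[v > 0]
        if len(pos) == 0 or np.all(pos == pos[0]):
            centers = np.array([np.log10(pos[0]) if len(pos) else 0.0])
            return pd.DataFrame(
                {"log10_center": centers, "count": [len(pos)]}
            )
        logs = np.log10(pos)
        counts, edges = np.histogram(logs, bins=n_hist_bins)
        return pd.DataFrame(
            {
                "log10_center": 0.5 * (edges[:-1] + edges[1:]),
                "count": counts,
            }
        )

    n_flag = min(n_flagged, len(scored))
    flagged = np.zeros(len(scored), dtype=bool)
    flagged[list(_top_k(scored.uncertainty, n_flag))] = True
    residuals = pd.DataFrame(
        {
            "index": scored.indices,
            "squared_error": scored.squared_error,
            "uncertainty": scored.uncertainty,
            "top_uncertainty": flagged,
        }
    )
    if reference_energies is not None:
        residuals["reference_energy"] = np.asarray(reference_energies)
    summary = pd.DataFrame(
        {
            "quantity": ["squared_error", "uncertainty"],
            "min": [scored.squared_error.min(), scored.uncertainty.min()],
            "max": [scored.squared_error.max(), scored.uncertainty.max()],
            "mean": [scored.squared_error.mean(), scored.uncertainty.mean()],
        }
    )
    return {
        "error_hist": log_hist(scored.squared_error),
        "uncertainty_hist": log_hist(scored.uncertainty),
        "summary": summary,
        "residuals": residuals,
    }
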