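"""Anatomically constrained linear connectome dynamics (LCD) model.

A lagged multivariate autoregressive model over ROI current time courses in
which inter-regional terms exist only along anatomical fiber edges, each at a
single delay fixed by its fiber length over the axonal conduction velocity
(order one per direction), while each ROI keeps a second-order
self-interaction:

    S_i(t) = a1_i S_i(t-1) + a2_i S_i(t-2) + sum_j w_ij S_j(t - tau_ij) + e_i(t)

Coefficients are estimated per target ROI by L2-regularized least squares,
``w = (X'X + lambda I)^-1 X'y`` with the default penalty ``lambda = 0.01``
applied to unstandardized predictors and no intercept (signals are
baseline-corrected, hence treated as zero-mean). One-step prediction uses
observed history only (no recursive feedback), i.e. a 2 ms horizon at 512 Hz.

Model/Results layout follows statsmodels:

>>> res = LinearConnectomeDynamics(roi_ts, network).fit()
>>> fit = res.score(roi_ts_heldout)      # DynamicsFit with VAF_S(t)
>>> res.count_interactions(parcellation)
>>> print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FiberNetwork, Parcellation, SourceActivity, sample_var


@dataclass
class DesignProblem:
    """Regression problem for one target ROI."""

    target: int
    X: np.ndarray  # rows x (2 + degree)
    y: np.ndarray
    predictors: list[tuple[int, int]]  # (source ROI, lag) per column
    burn_in: int  # first valid time index of y within the series


def build_design(
    roi_ts: SourceActivity, net: FiberNetwork, n_rois: int | None = None
) -> list[DesignProblem]:
    """Per-target regression problems under the anatomical mask.

    For target ROI ``i`` the predictors are ``S_i(t-1)``, ``S_i(t-2)`` and
    ``S_j(t-tau_ij)`` for every anatomical neighbor ``j``; rows are restricted
    to ``t`` for which every lag is available, so the first valid index equals
    the target's maximum lag (at least 2).
    """
    S = roi_ts.currents
    if not np.all(np.isfinite(S)):
        raise ValueError("non-finite ROI time courses")
    n = n_rois if n_rois is not None else S.shape[0]
    T = S.shape[1]
    nbrs = net.neighbors(n)
    problems = []
    for i in range(n):
        preds: list[tuple[int, int]] = [(i, 1), (i, 2)]
        preds += [(int(j), int(lag)) for j, lag in nbrs[i]]
        burn = max(lag for _, lag in preds)
        if T <= burn + 2:
            raise ValueError(
                f"window of {T} samples too short for max lag {burn} (target {i})"
            )
        t = np.arange(burn, T)
        X = np.column_stack([S[j, t - lag] for j, lag in preds])
        problems.append(DesignProblem(i, X, S[i, t], preds, burn))
    return problems


def ridge_solve(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """``(X'X + lam I)^-1 X'y`` — no intercept, unstandardized predictors."""
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite design")
    p = X.shape[1]
    return np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ y)


class LinearConnectomeDynamics:
    """LCD model for one ROI time-course matrix and fiber network.

    Parameters
    ----------
    roi_ts : SourceActivity
        ROI x time currents (the series to fit, normally the 0–200 ms
        post-stimulus window of the source estimate).
    network : FiberNetwork
        Anatomical edges with sample lags (the sparsity mask).
    lam : float
        Ridge penalty, default 0.01.
    """

    def __init__(
        self,
        roi_ts: SourceActivity,
        network: FiberNetwork,
        lam: float = 0.01,
        n_rois: int | None = None,
    ):
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        self.roi_ts = roi_ts
        self.network = network
        self.lam = lam
        self.n_rois = n_rois if n_rois is not None else roi_ts.n_units

    def fit(self) -> "LCDResults":
        problems = build_design(self.roi_ts, self.network, self.n_rois)
        intra = np.zeros((self.n_rois, 2))
        inter: dict[tuple[int, int], tuple[float, int]] = {}
        for prob in problems:
            w = ridge_solve(prob.X, prob.y, self.lam)
            intra[prob.target] = w[:2]
            for (j, lag), wj in zip(prob.predictors[2:], w[2:]):
                inter[(j, prob.target)] = (float(wj), int(lag))
        res = LCDResults(
            model=self,
            intra=intra,
            inter=inter,
            lam=self.lam,
        )
        res._assert_mask()
        return res


@dataclass
class LCDResults:
    """Fitted LCD coefficients plus prediction/evaluation methods."""

    model: LinearConnectomeDynamics
    intra: np.ndarray  # (n_rois, 2)
    inter: dict[tuple[int, int], tuple[float, int]]  # (from, to) -> (weight, lag)
    lam: float

    @property
    def n_rois(self) -> int:
        return self.intra.shape[0]

    def _assert_mask(self) -> None:
        """No coefficient outside the directed anatomical mask."""
        allowed = set()
        for a, b in zip(
            self.model.network.edges["roi_a"], self.model.network.edges["roi_b"]
        ):
            allowed.add((int(a), int(b)))
            allowed.add((int(b), int(a)))
        extra = set(self.inter) - allowed
        if extra:
            raise AssertionError(f"coefficients outside anatomical mask: {extra}")
        for (a, b), (_, lag) in self.inter.items():
            pass  # lags are taken from the network by construction

    # -- prediction -------------------------------------------------------
    def predict_one_step(self, roi_ts: SourceActivity) -> tuple[SourceActivity, int]:
        """One-step-ahead prediction from observed history only.

        Returns ``(S_hat, burn_in)``: predictions are defined for
        ``t >= burn_in`` (the model's maximum lag) and the returned activity
        covers exactly those samples.
        """
        S = roi_ts.currents
        n, T = S.shape
        if n != self.n_rois:
            raise ValueError("ROI count mismatch")
        max_lag = 2
        if self.inter:
            max_lag = max(max_lag, max(lag for _, lag in self.inter.values()))
        if T <= max_lag:
            raise ValueError("series shorter than model burn-in")
        t = np.arange(max_lag, T)
        S_hat = (
            self.intra[:, 0:1] * S[:, t - 1] + self.intra[:, 1:2] * S[:, t - 2]
        )
        for (j, i), (w, lag) in self.inter.items():
            S_hat[i] += w * S[j, t - lag]
        pred = SourceActivity(
            S_hat, roi_ts.fs, roi_ts.time_zero - max_lag, kind="roi"
        )
        return pred, max_lag

    def score(self, roi_ts: SourceActivity) -> "DynamicsFit":
        """VAF_S(t) of one-step prediction on ``roi_ts`` (see :func:`vaf_sources`)."""
        pred, burn = self.predict_one_step(roi_ts)
        actual = SourceActivity(
            roi_ts.currents[:, burn:], roi_ts.fs, roi_ts.time_zero - burn, kind="roi"
        )
        fit = vaf_sources(actual.currents, pred.currents)
        fit.cross_validated = False
        return fit

    # -- reporting --------------------------------------------------------
    def count_interactions(self, parc: Parcellation) -> dict:
        """Classify every directed inter-ROI coefficient by hemisphere.

        Intra-ROI (self) terms are excluded; percentages are of the total
        directed inter-ROI coefficient count permitted by the mask.
        """
        hemi = parc.hemisphere
        if len(hemi) < self.n_rois:
            raise ValueError("hemisphere labels missing for some ROIs")
        intra_h = sum(1 for (a, b) in self.inter if hemi[a] == hemi[b])
        inter_h = len(self.inter) - intra_h
        return interaction_percentages(intra_h, inter_h)

    def coefficient_table(self) -> pd.DataFrame:
        rows = [
            {"from_roi": a, "to_roi": b, "weight": w, "lag_samples": lag}
            for (a, b), (w, lag) in sorted(self.inter.items())
        ]
        return pd.DataFrame(rows, columns=["from_roi", "to_roi", "weight", "lag_samples"])

    def summary(self) -> str:
        insample = self.score(self.model.roi_ts)
        lines = [
            "Linear connectome dynamics fit",
            "=" * 45,
            f"ROIs:                    {self.n_rois}",
            f"anatomical edges:        {self.model.network.n_edges}"
            f" ({len(self.inter)} directed coefficients)",
            f"ridge lambda:            {self.lam}",
            f"in-sample mean VAF_S:    {insample.vaf_mean:.2f} %"
            f" (sd {insample.vaf_std:.2f})",
            f"one-step horizon:        {1000.0 / self.model.roi_ts.fs:.2f} ms",
        ]
        return "\n".join(lines)


def interaction_percentages(n_intra: int, n_inter: int) -> dict:
    """Counts and percentages of intra-/inter-hemispheric directed terms."""
    total = n_intra + n_inter
    if total == 0:
        return {
            "intra_count": 0,
            "inter_count": 0,
            "intra_percent": float("nan"),
            "inter_percent": float("nan"),
        }
    return {
        "intra_count": int(n_intra),
        "inter_count": int(n_inter),
        "intra_percent": 100.0 * n_intra / total,
        "inter_percent": 100.0 * n_inter / total,
    }


@dataclass
class DynamicsFit:
    """VAF_S(t) profile with its mean/std summary."""

    vaf_t: np.ndarray  # % per time point (NaN where undefined)
    vaf_mean: float
    vaf_std: float
    cross_validated: bool = False


def vaf_sources(S: np.ndarray, S_hat: np.ndarray) -> DynamicsFit:
    """``VAF_S(t) = (1 − var(S(t)−S_hat(t)) / var(S(t)))·100`` per time point.

    Variances are taken across the ROI dimension at fixed ``t`` (sample
    variance, ddof=1); time points with zero cross-ROI signal variance are
    excluded from the mean/std with a warning.
    """
    S = np.asarray(S, dtype=float)
    S_hat = np.asarray(S_hat, dtype=float)
    if S.shape != S_hat.shape:
        raise ValueError("S and S_hat must align")
    var_s = sample_var(S, axis=0)
    var_d = sample_var(S - S_hat, axis=0)
    vaf = np.full(S.shape[1], np.nan)
    ok = var_s > 0
    if not np.all(ok):
        warnings.warn("time point(s) with zero cross-ROI variance excluded")
    vaf[ok] = (1.0 - var_d[ok] / var_s[ok]) * 100.0
    valid = vaf[ok]
    std = float(np.std(valid, ddof=1)) if valid.size > 1 else float("nan")
    return DynamicsFit(vaf, float(np.mean(valid)), std)


def fit_lcd(
    roi_ts: SourceActivity, net: FiberNetwork, lam: float = 0.01
) -> LCDResults:
    """Functional wrapper around :class:`LinearConnectomeDynamics`."""
    return LinearConnectomeDynamics(roi_ts, net, lam).fit()


def cross_validated_vaf(
    train: SourceActivity,
    test: SourceActivity,
    net: FiberNetwork,
    lam: float = 0.01,
) -> DynamicsFit:
    """Fit on one fold, score one-step prediction on the other."""
    res = LinearConnectomeDynamics(train, net, lam).fit()
    fit = res.score(test)
    fit.cross_validated = True
    return fit


def split_halves(roi_ts: SourceActivity) -> tuple[SourceActivity, SourceActivity]:
    """Two-fold split of a trial-less series: first vs second half of the window."""
    T = roi_ts.n_times
    half = T // 2
    a = SourceActivity(roi_ts.currents[:, :half], roi_ts.fs, roi_ts.time_zero, "roi")
    b = SourceActivity(
        roi_ts.currents[:, half:], roi_ts.fs, roi_ts.time_zero - half, "roi"
    )
    return a, b


def noise_baseline(
    net: FiberNetwork,
    n_rois: int,
    n_samples: int = 102,
    n_realizations: int = 100,
    noise_rms: float = 1.0,
    lam: float = 0.01,
    fs: float = 512.0,
    seed: int = 0,
) -> dict:
    """White-noise null: replace the ROI series by noise, fit, cross-validate.

    Each realization draws an i.i.d. Gaussian ROI series of the analysis
    window length, splits it into halves (the trial-less two-fold scheme),
    fits the LCD on the first half and scores one-step prediction on the
    second. Returns the mean and dispersion of the per-realization mean VAF_S
    across realizations.
    """
    rng = np.random.default_rng(seed)
    means = np.empty(n_realizations)
    for k in range(n_realizations):
        series = SourceActivity(
            noise_rms * rng.standard_normal((n_rois, n_samples)), fs, 0, "roi"
        )
        a, b = split_halves(series)
        fit = cross_validated_vaf(a, b, net, lam)
        means[k] = fit.vaf_mean
    std = float(np.std(means, ddof=1)) if n_realizations > 1 else float("nan")
    return {
        "vaf_mean": float(np.mean(means)),
        "vaf_std": std,
        "stderr": std / float(np.sqrt(n_realizations)),
        "n_realizations": int(n_realizations),
        "per_realization": means,
    }
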