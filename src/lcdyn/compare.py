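"""Correlation-metric connectivity and false-discovery scoring vs anatomy.

The conventional comparator estimates functional connectivity from pairwise
linear correlation of ROI time courses, with no anatomical constraint. Scoring
treats the tractography edge set as the operative truth: a detected pair with
a fiber connection is a true positive, one without is a false positive, and
the false discovery rate is FP/(FP+TP)·100 %.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import FiberNetwork, SourceActivity


@dataclass
class ConnectivityResult:
    """Detected edge set with (optional) anatomical scoring."""

    detected_edges: set[frozenset]
    method: str
    threshold: str
    r: np.ndarray | None = None  # pairwise correlation matrix
    p: np.ndarray | None = None  # pairwise p-values
    fp: int | None = None
    tp: int | None = None
    fdr_percent: float | None = None

    def __post_init__(self) -> None:
        if self.fp is not None and self.tp is not None:
            assert self.fp + self.tp == len(self.detected_edges)
            if self.fdr_percent is not None:
                assert 0.0 <= self.fdr_percent <= 100.0


def correlation_connectivity(
    roi_ts: SourceActivity,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> ConnectivityResult:
    """Detect pairs whose linear correlation passes a two-sided test.

    Pearson correlation over the analysis window; the default criterion is
    ``p < alpha`` after Bonferroni correction over all ROI pairs. Constant
    traces cannot be correlated — their pairs are excluded with a warning.
    """
    S = roi_ts.currents
    n, T = S.shape
    if T < 3:
        raise ValueError("need at least 3 time samples for a correlation test")
    sd = S.std(axis=1)
    constant = sd == 0
    if np.any(constant):
        warnings.warn(f"{int(constant.sum())} constant ROI trace(s) excluded")

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(S)
    np.fill_diagonal(r, 1.0)

    n_pairs = n * (n - 1) // 2
    thresh = alpha / n_pairs if correction == "bonferroni" else alpha
    # two-sided p from the exact t transform of r under H0
    rr = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t_stat = rr * np.sqrt((T - 2) / (1.0 - rr**2))
    p = 2.0 * stats.t.sf(np.abs(t_stat), df=T - 2)

    detected = set()
    for a in range(n):
        if constant[a]:
            continue
        for b in range(a + 1, n):
            if constant[b]:
                continue
            if p[a, b] < thresh:
                detected.add(frozenset((a, b)))
    label = f"two-sided p < {alpha}" + (
        f" Bonferroni/{n_pairs}" if correction == "bonferroni" else ""
    )
    return ConnectivityResult(detected, "pearson-correlation", label, r=r, p=p)


def score_against_anatomy(
    result: ConnectivityResult, net: FiberNetwork
) -> ConnectivityResult:
    """Fill FP / TP / FDR using the anatomical edge set as truth."""
    truth = net.edge_set()
    tp = sum(1 for e in result.detected_edges if e in truth)
    fp = len(result.detected_edges) - tp
    if fp + tp == 0:
        warnings.warn("empty detection: FDR undefined")
        fdr = None
    else:
        fdr = 100.0 * fp / (fp + tp)
    return ConnectivityResult(
        result.detected_edges,
        result.method,
        result.threshold,
        r=result.r,
        p=result.p,
        fp=fp,
        tp=tp,
        fdr_percent=fdr,
    )


def fdr_percent(fp: int, tp: int) -> float:
    """FP/(FP+TP)·100 %."""
    if fp + tp == 0:
        raise ValueError("FDR undefined for empty detection")
    return 100.0 * fp / (fp + tp)
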