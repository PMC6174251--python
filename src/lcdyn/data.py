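"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Sensor data are in microvolts, time in milliseconds relative to stimulus
  onset, sampling rates in Hz.
* Epoch windows are given as ``(pre_ms, post_ms)`` with both values positive:
  an epoch spans ``[-pre_ms, +post_ms)`` around the stimulus.
* Source currents are dimensionless "current units" (see docs/methods.md for
  the unit convention); the leadfield carries the µV-per-current-unit gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


def ms_to_samples(ms: float, fs: float) -> int:
    """Convert a latency in ms to a sample count (half-up rounding)."""
    return int(np.floor(ms * fs / 1000.0 + 0.5))


@dataclass
class EEGData:
    """Multichannel EEG record (continuous or epoch-concatenated).

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Potentials in µV.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    positions : ndarray, shape (n_channels, 3)
        Electrode coordinates (RAS, mm).
    events : list of (int, str)
        ``(sample_index, condition_label)`` stimulus markers.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    positions: np.ndarray | None = None
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        n_t = self.samples.shape[1]
        for idx, _ in self.events:
            if not 0 <= idx < n_t:
                raise ValueError(f"event index {idx} outside record")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    def copy(self) -> "EEGData":
        return EEGData(
            self.samples.copy(),
            self.fs,
            list(self.channel_names),
            None if self.positions is None else self.positions.copy(),
            list(self.events),
        )


@dataclass
class EpochSet:
    """Stack of stimulus-locked epochs: trials x channels x time."""

    epochs: np.ndarray
    fs: float
    window_ms: tuple[float, float] = (50.0, 200.0)
    condition: str = "stim"
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trials x channels x time")
        expected = ms_to_samples(self.window_ms[0] + self.window_ms[1], self.fs)
        if self.n_trials and self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} != window implies {expected}"
            )

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_times(self) -> int:
        return self.epochs.shape[2]

    @property
    def pre_samples(self) -> int:
        """Index of the stimulus-onset (t = 0) sample."""
        return ms_to_samples(self.window_ms[0], self.fs)

    def times_ms(self) -> np.ndarray:
        return (np.arange(self.n_times) - self.pre_samples) / self.fs * 1000.0

    def sample_range(self, start_ms: float, stop_ms: float) -> tuple[int, int]:
        """Half-open sample index range covering ``t in [start_ms, stop_ms]``."""
        t = self.times_ms()
        mask = (t >= start_ms - 1e-9) & (t <= stop_ms + 1e-9)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError(f"window [{start_ms}, {stop_ms}] ms outside epoch")
        return int(idx[0]), int(idx[-1] + 1)

    def copy(self) -> "EpochSet":
        return replace(self, epochs=self.epochs.copy())


@dataclass
class ERP:
    """Trial-averaged event-related potential."""

    mean: np.ndarray
    n_trials: int
    fs: float
    window_ms: tuple[float, float] = (50.0, 200.0)
    channel_names: list[str] | None = None
    condition: str = "stim"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        if self.mean.ndim != 2:
            raise ValueError("ERP mean must be channels x time")

    @property
    def pre_samples(self) -> int:
        return ms_to_samples(self.window_ms[0], self.fs)

    @property
    def n_channels(self) -> int:
        return self.mean.shape[0]

    @property
    def n_times(self) -> int:
        return self.mean.shape[1]

    def times_ms(self) -> np.ndarray:
        return (np.arange(self.n_times) - self.pre_samples) / self.fs * 1000.0

    def sample_range(self, start_ms: float, stop_ms: float) -> tuple[int, int]:
        t = self.times_ms()
        mask = (t >= start_ms - 1e-9) & (t <= stop_ms + 1e-9)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError(f"window [{start_ms}, {stop_ms}] ms outside epoch")
        return int(idx[0]), int(idx[-1] + 1)

    def plot(self, channel: int | str = 0, ax=None):
        """Quick ERP trace plot for one channel."""
        import matplotlib.pyplot as plt

        if isinstance(channel, str):
            channel = (self.channel_names or []).index(channel)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times_ms(), self.mean[channel])
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("amplitude (µV)")
        return ax


@dataclass
class SNRReport:
    """RMS-amplitude signal-to-noise summary of an epoch set.

    ``snr_db = 10 * log10(arms_signal / arms_noise)`` — the power-style dB
    applied to the amplitude ratio; this is the convention under which the
    signal-percentage and dB columns of evoked-response SNR tables are
    mutually consistent (85.30 % <-> 7.64 dB).
    """

    arms_signal: float
    arms_noise: float
    snr_db: float
    signal_percent: float
    infinite: bool = False

    def __post_init__(self) -> None:
        if not self.infinite:
            r = self.arms_signal / self.arms_noise
            assert abs(self.snr_db - 10.0 * np.log10(r)) < 1e-8
            assert abs(self.signal_percent - 100.0 * r / (1.0 + r)) < 1e-8
            assert 0.0 <= self.signal_percent <= 100.0


@dataclass
class Leadfield:
    """Forward gain matrix: sensor potentials per unit source current."""

    gain: np.ndarray
    channel_names: list[str] | None = None
    source_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise ValueError("leadfield gain must be channels x sources")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("leadfield contains non-finite entries")
        norms = np.linalg.norm(self.gain, axis=0)
        if np.any(norms == 0):
            raise ValueError("leadfield has all-zero source column(s)")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class SourceActivity:
    """Source- or ROI-level current time courses."""

    currents: np.ndarray
    fs: float
    time_zero: int
    kind: str = "source"  # "source" | "roi"

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float)
        if self.currents.ndim != 2:
            raise ValueError("currents must be units x time")
        if not np.all(np.isfinite(self.currents)):
            raise ValueError("currents contain non-finite values")

    @property
    def n_units(self) -> int:
        return self.currents.shape[0]

    @property
    def n_times(self) -> int:
        return self.currents.shape[1]

    def times_ms(self) -> np.ndarray:
        return (np.arange(self.n_times) - self.time_zero) / self.fs * 1000.0

    def window(self, start_ms: float, stop_ms: float) -> "SourceActivity":
        t = self.times_ms()
        mask = (t >= start_ms - 1e-9) & (t <= stop_ms + 1e-9)
        idx = np.nonzero(mask)[0]
        return SourceActivity(
            self.currents[:, idx[0] : idx[-1] + 1],
            self.fs,
            self.time_zero - int(idx[0]),
            self.kind,
        )


@dataclass
class Parcellation:
    """Assignment of source vertices to regions of interest."""

    assignment: np.ndarray  # (n_sources,) int ROI ids 0..n_rois-1
    roi_centroids: np.ndarray  # (n_rois, 3) mm, RAS
    hemisphere: np.ndarray  # (n_rois,) "left"/"right"
    n_rois: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.roi_centroids = np.asarray(self.roi_centroids, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere)
        counts = np.bincount(self.assignment, minlength=self.n_rois)
        if np.any(counts == 0):
            raise ValueError("parcellation contains empty ROI(s)")
        if self.assignment.min() < 0 or self.assignment.max() >= self.n_rois:
            raise ValueError("assignment references unknown ROI ids")
        bad = set(np.unique(self.hemisphere)) - {"left", "right"}
        if bad:
            raise ValueError(f"unknown hemisphere labels: {bad}")

    @property
    def n_sources(self) -> int:
        return self.assignment.shape[0]

    def roi_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_rois)


@dataclass
class FiberNetwork:
    """Undirected ROI-pair fiber connections with lengths and sample lags.

    Edges are stored once (``roi_a < roi_b``); model fitting expands each to
    two directed coefficients sharing the edge's lag.
    """

    edges: pd.DataFrame  # columns: roi_a, roi_b, n_fibers, mean_length_mm[, lag_samples]
    velocity_mps: float = 6.0
    fs: float = 512.0

    REQUIRED = ("roi_a", "roi_b", "n_fibers", "mean_length_mm")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.edges.columns]
        if missing:
            raise ValueError(f"fiber table missing columns: {missing}")
        e = self.edges
        if len(e) and np.any(e["roi_a"].to_numpy() == e["roi_b"].to_numpy()):
            raise ValueError("fiber table contains self-loop edges")
        if len(e) and np.any(e["mean_length_mm"].to_numpy() <= 0):
            raise ValueError("fiber lengths must be positive")
        if "lag_samples" in e.columns and len(e):
            if np.any(e["lag_samples"].to_numpy() < 1):
                raise ValueError("lag_samples must be >= 1")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def has_lags(self) -> bool:
        return "lag_samples" in self.edges.columns

    def edge_set(self) -> set[frozenset]:
        return {
            frozenset((int(a), int(b)))
            for a, b in zip(self.edges["roi_a"], self.edges["roi_b"])
        }

    def directed(self) -> pd.DataFrame:
        """Directed expansion: one row per (from_roi -> to_roi) coefficient."""
        e = self.edges
        fwd = e.rename(columns={"roi_a": "from_roi", "roi_b": "to_roi"})
        bwd = e.rename(columns={"roi_b": "from_roi", "roi_a": "to_roi"})
        cols = ["from_roi", "to_roi", "n_fibers", "mean_length_mm"]
        if self.has_lags:
            cols.append("lag_samples")
        out = pd.concat([fwd[cols], bwd[cols]], ignore_index=True)
        return out.sort_values(["to_roi", "from_roi"], ignore_index=True)

    def neighbors(self, n_rois: int) -> list[np.ndarray]:
        """Per-ROI arrays of (neighbor, lag) pairs, sorted by neighbor id."""
        if not self.has_lags:
            raise ValueError("lags not computed; call lags_from_lengths first")
        nbrs: list[list[tuple[int, int]]] = [[] for _ in range(n_rois)]
        for a, b, lag in zip(
            self.edges["roi_a"], self.edges["roi_b"], self.edges["lag_samples"]
        ):
            nbrs[int(b)].append((int(a), int(lag)))
            nbrs[int(a)].append((int(b), int(lag)))
        return [np.array(sorted(x), dtype=int).reshape(-1, 2) for x in nbrs]


@dataclass
class GroundTruth:
    """Everything the generator knows: network, dynamics, sources, forward model."""

    intra: np.ndarray  # (n_rois, 2) AR coefficients at lags 1, 2
    inter: pd.DataFrame  # columns: from_roi, to_roi, weight, lag_samples
    leadfield: Leadfield
    parcellation: Parcellation
    fiber_network: FiberNetwork
    true_sources: SourceActivity | None = None

    @property
    def n_rois(self) -> int:
        return self.parcellation.n_rois

    def lag_matrices(self) -> np.ndarray:
        """Stack A_k (k = 1..p) with S(t) = sum_k A_k S(t-k) + drive."""
        p = max(2, int(self.inter["lag_samples"].max()) if len(self.inter) else 2)
        n = self.n_rois
        A = np.zeros((p, n, n))
        A[0][np.diag_indices(n)] = self.intra[:, 0]
        A[1][np.diag_indices(n)] = self.intra[:, 1]
        for row in self.inter.itertuples(index=False):
            A[int(row.lag_samples) - 1, int(row.to_roi), int(row.from_roi)] += row.weight
        return A

    def companion_spectral_radius(self) -> float:
        A = self.lag_matrices()
        p, n, _ = A.shape
        comp = np.zeros((p * n, p * n))
        comp[:n, :] = np.concatenate(list(A), axis=1)
        comp[n:, : (p - 1) * n] = np.eye((p - 1) * n)
        return float(np.max(np.abs(np.linalg.eigvals(comp))))


def sample_var(x: np.ndarray, axis=None) -> np.ndarray:
    """Sample variance (ddof=1), the convention used by every VAF here."""
    return np.var(np.asarray(x, dtype=float), axis=axis, ddof=1)
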