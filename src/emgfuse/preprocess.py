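"""Filtering, train-statistics normalization and sliding-window segmentation.

The processing order is fixed: bandpass filter the raw streams, z-score
each channel with statistics fitted on training samples only (no test
leakage), then cut fixed-length windows with a fixed stride.  Window
geometry follows the sampling rate: a window of T ms at F Hz spans
L = T*F/1000 samples and advances by Ld = S*F/1000 samples, so the same
(T, S) setting adapts to down-sampled synthetic sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfilt, sosfiltfilt

from emgfuse.ninapro_io import (
    DEFAULT_TEST_REPS,
    DEFAULT_TRAIN_REPS,
    RecordingSession,
    split_by_repetition,
)


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass Butterworth design: order 4, passband 10-500 Hz by default.

    Applied identically to the EMG and accelerometer streams.  The band
    must satisfy 0 < low < high < fs/2 for the sampling rate it is used
    with; down-sampled sessions therefore need a proportionally lowered
    high edge (see :func:`default_filter_for_fs`).
    """

    order: int = 4
    band_hz: tuple[float, float] = (10.0, 500.0)

    def validate(self, fs: float) -> None:
        low, high = self.band_hz
        if not (0 < low < high):
            raise ValueError(f"band edges must satisfy 0 < low < high, got {self.band_hz}")
        if high >= fs / 2:
            raise ValueError(
                f"band high edge {high} Hz must be below the Nyquist frequency "
                f"{fs / 2} Hz for fs={fs} Hz"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


def default_filter_for_fs(fs: float) -> FilterSpec:
    """The 10-500 Hz design when fs allows it, else the high edge drops to 0.45*fs."""
    high = min(500.0, 0.45 * fs)
    return FilterSpec(order=4, band_hz=(10.0, high))


def bandpass_filter(
    signal: np.ndarray,
    spec: FilterSpec = FilterSpec(),
    fs: float = 2000.0,
    zero_phase: bool = True,
) -> np.ndarray:
    """Bandpass-filter every channel of a (n_samples, n_channels) matrix.

    Zero-phase (forward-backward) application by default so the EMG and
    accelerometer streams stay phase-aligned; ``zero_phase=False`` gives
    the causal filter for real-time emulation.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2:
        raise ValueError(f"signal must be 2-D (n_samples, n_channels), got {signal.shape}")
    spec.validate(fs)
    sos = butter(spec.order, spec.band_hz, btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        n_sections = sos.shape[0]
        padlen = 3 * (2 * n_sections + 1)
        if signal.shape[0] <= padlen:
            raise ValueError(
                f"signal length {signal.shape[0]} does not exceed the filter "
                f"warm-up length {padlen}"
            )
        return sosfiltfilt(sos, signal, axis=0)
    return sosfilt(sos, signal, axis=0)


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean and standard deviation fitted on training data.

    ``std`` uses the population convention (divide by n); at the sample
    counts involved the distinction from the n-1 convention is negligible.
    """

    mean: np.ndarray
    std: np.ndarray
    ddof: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float).ravel())
        object.__setattr__(self, "std", np.asarray(self.std, dtype=float).ravel())
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std must have the same length")
        if np.any(self.std <= 0):
            bad = np.flatnonzero(self.std <= 0)
            raise ValueError(f"std must be strictly positive; offending channel(s): {bad.tolist()}")

    @property
    def n_channels(self) -> int:
        return self.mean.shape[0]


def fit_normalizer(train_signal: np.ndarray) -> ChannelStats:
    """Per-channel mean/std over training samples only."""
    x = np.asarray(train_signal, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=0)
    zero = np.flatnonzero(std == 0)
    if zero.size:
        raise ValueError(
            f"channel(s) {zero.tolist()} are constant; z-scoring is undefined"
        )
    return ChannelStats(mean=mean, std=std)


def apply_normalizer(signal: np.ndarray, stats: ChannelStats) -> np.ndarray:
    """y = (x - mean) / std, channel-wise."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 2 or x.shape[1] != stats.n_channels:
        raise ValueError(
            f"signal has {x.shape[1] if x.ndim == 2 else '?'} channels, "
            f"stats were fitted on {stats.n_channels}"
        )
    return (x - stats.mean) / stats.std


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: T ms window advanced by S ms at F Hz.

    L = T*F/1000 and Ld = S*F/1000 must be exact integers with L >= Ld >= 1.
    """

    T_ms: float = 200.0
    S_ms: float = 50.0
    sampling_rate_hz: float = 2000.0

    def __post_init__(self) -> None:
        L, Ld = self.T_ms * self.sampling_rate_hz / 1000.0, self.S_ms * self.sampling_rate_hz / 1000.0
        for name, v in (("L", L), ("Ld", Ld)):
            if abs(v - round(v)) > 1e-9:
                raise ValueError(
                    f"{name} = {v} is not an integer number of samples for "
                    f"T={self.T_ms} ms, S={self.S_ms} ms at {self.sampling_rate_hz} Hz"
                )
        if not (round(L) >= round(Ld) >= 1):
            raise ValueError(f"need L >= Ld >= 1, got L={L}, Ld={Ld}")

    @property
    def L(self) -> int:
        """Window length in samples."""
        return round(self.T_ms * self.sampling_rate_hz / 1000.0)

    @property
    def Ld(self) -> int:
        """Step in samples."""
        return round(self.S_ms * self.sampling_rate_hz / 1000.0)


@dataclass
class WindowSet:
    """Supervised dataset of windows: x is (n_windows, n_channels, L)."""

    x: np.ndarray
    labels: np.ndarray
    channel_kind: str = "emg"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.labels = np.asarray(self.labels).astype(np.int64).ravel()
        if self.x.ndim != 3:
            raise ValueError(f"x must be (n_windows, n_channels, L), got {self.x.shape}")
        if self.x.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per window required")

    @property
    def n_windows(self) -> int:
        return self.x.shape[0]


def window_count(n_samples: int, L: int, Ld: int) -> int:
    """Number of windows a signal of n_samples yields: floor((n-L)/Ld)+1, 0 if n < L."""
    if n_samples < L:
        return 0
    return (n_samples - L) // Ld + 1


def segment_windows(
    signal: np.ndarray,
    labels: np.ndarray,
    spec: WindowSpec,
    labeling: str = "majority",
    channel_kind: str = "emg",
) -> WindowSet:
    """Cut a labelled multichannel signal into overlapping windows.

    Windows start at offsets 0, Ld, 2*Ld, ... while offset+L <= n_samples;
    each is transposed to (n_channels, L).  Labelling policies:

    - ``"majority"`` (default): the window's label is the majority of its
      per-sample labels, ties broken toward the lower label; windows mixing
      rest (0) with movement are dropped.
    - ``"strict"``: any window containing more than one distinct label is
      dropped.

    A signal shorter than one window yields an empty WindowSet with a
    warning (short rest segments are tolerated, not fatal).
    """
    if labeling not in ("majority", "strict"):
        raise ValueError(f"unknown labeling policy {labeling!r}")
    x = np.asarray(signal, dtype=float)
    lab = np.asarray(labels).astype(np.int64).ravel()
    if x.ndim != 2 or x.shape[0] != lab.shape[0]:
        raise ValueError("signal must be (n_samples, n_channels) aligned with labels")
    L, Ld = spec.L, spec.Ld
    n = x.shape[0]
    if n < L:
        warnings.warn(
            f"signal of {n} samples is shorter than one window (L={L}); "
            "returning an empty WindowSet",
            stacklevel=2,
        )
        return WindowSet(
            x=np.empty((0, x.shape[1], L)), labels=np.empty(0, dtype=np.int64),
            channel_kind=channel_kind,
        )
    starts = np.arange(0, n - L + 1, Ld)
    wins, wlabs = [], []
    for s in starts:
        seg_lab = lab[s : s + L]
        uniq = np.unique(seg_lab)
        if labeling == "strict" and uniq.size > 1:
            continue
        if uniq.size > 1 and uniq[0] == 0:  # mixes rest with movement
            continue
        counts = np.bincount(seg_lab)
        wins.append(x[s : s + L].T)
        wlabs.append(int(counts.argmax()))  # argmax ties break toward lower label
    if not wins:
        return WindowSet(
            x=np.empty((0, x.shape[1], L)), labels=np.empty(0, dtype=np.int64),
            channel_kind=channel_kind,
        )
    return WindowSet(x=np.stack(wins), labels=np.asarray(wlabs), channel_kind=channel_kind)


@dataclass
class PairedWindows:
    """Aligned EMG and ACC window sets sharing one label vector."""

    emg: WindowSet
    acc: WindowSet

    def __post_init__(self) -> None:
        if self.emg.n_windows != self.acc.n_windows:
            raise ValueError("EMG and ACC window sets must have equal n_windows")
        if not np.array_equal(self.emg.labels, self.acc.labels):
            raise ValueError("EMG and ACC window labels must be aligned")

    @property
    def labels(self) -> np.ndarray:
        return self.emg.labels

    @property
    def n_windows(self) -> int:
        return self.emg.n_windows

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, idx: np.ndarray) -> "PairedWindows":
        return PairedWindows(
            emg=WindowSet(self.emg.x[idx], self.emg.labels[idx], self.emg.channel_kind),
            acc=WindowSet(self.acc.x[idx], self.acc.labels[idx], self.acc.channel_kind),
        )


@dataclass
class SessionDatasets:
    """Train/test paired windows plus the fitted normalizers."""

    train: PairedWindows
    test: PairedWindows
    emg_stats: ChannelStats
    acc_stats: ChannelStats


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), stops.tolist()))


def build_datasets(
    session: RecordingSession,
    wspec: WindowSpec | None = None,
    fspec: FilterSpec | None = None,
    train_reps: frozenset[int] | set[int] = DEFAULT_TRAIN_REPS,
    test_reps: frozenset[int] | set[int] = DEFAULT_TEST_REPS,
    include_rest: bool = False,
    labeling: str = "majority",
    zero_phase: bool = True,
) -> SessionDatasets:
    """Full preprocessing chain for one session.

    Filter both streams, fit per-channel z-score statistics on the
    training samples only, apply them to everything, then window each
    contiguous run of the train/test masks separately so no window spans
    a split boundary.  EMG and ACC are windowed with identical offsets,
    keeping the two streams paired window-for-window.
    """
    fs = session.sampling_rate_hz
    wspec = wspec or WindowSpec(sampling_rate_hz=fs)
    if wspec.sampling_rate_hz != fs:
        wspec = WindowSpec(wspec.T_ms, wspec.S_ms, fs)
    fspec = fspec or default_filter_for_fs(fs)

    emg_f = bandpass_filter(session.emg, fspec, fs, zero_phase=zero_phase)
    acc_f = bandpass_filter(session.acc, fspec, fs, zero_phase=zero_phase)

    train_mask, test_mask = split_by_repetition(
        session, train_reps, test_reps, include_rest=include_rest
    )
    if not train_mask.any():
        raise ValueError("training mask selects no samples")

    emg_stats = fit_normalizer(emg_f[train_mask])
    acc_stats = fit_normalizer(acc_f[train_mask])
    emg_n = apply_normalizer(emg_f, emg_stats)
    acc_n = apply_normalizer(acc_f, acc_stats)

    def _windows(mask: np.ndarray) -> PairedWindows:
        ew, aw, labs = [], [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sub-window runs are expected here
            for s, t in _contiguous_runs(mask):
                we = segment_windows(emg_n[s:t], session.stimulus[s:t], wspec,
                                     labeling, "emg")
                wa = segment_windows(acc_n[s:t], session.stimulus[s:t], wspec,
                                     labeling, "acc")
                ew.append(we.x)
                aw.append(wa.x)
                labs.append(we.labels)
        L = wspec.L
        if not ew:
            ew, aw = [np.empty((0, 12, L))], [np.empty((0, 36, L))]
            labs = [np.empty(0, dtype=np.int64)]
        return PairedWindows(
            emg=WindowSet(np.concatenate(ew), np.concatenate(labs), "emg"),
            acc=WindowSet(np.concatenate(aw), np.concatenate(labs), "acc"),
        )

    return SessionDatasets(
        train=_windows(train_mask),
        test=_windows(test_mask),
        emg_stats=emg_stats,
        acc_stats=acc_stats,
    )
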