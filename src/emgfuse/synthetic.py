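"""Synthetic multimodal gesture sessions in the DB2 layout.

The generator emulates the statistical structure the pipeline relies on,
not muscle physiology.  Surface EMG is modelled as amplitude-modulated
band-limited Gaussian noise — the standard phenomenological picture of an
interference EMG — with a class-specific gain per electrode channel, so
each gesture has a distinct spatial activation signature.  Accelerometer
channels carry class-specific sums of tones placed at 12-40 Hz, above the
10 Hz low edge of the pipeline's bandpass so the kinematic class
information survives filtering, plus Gaussian noise at a configurable
SNR.  The schedule copies the acquisition protocol: each gesture repeated
six times, five seconds of movement followed by three seconds of rest,
with per-sample stimulus/repetition annotation (0 = rest).

Sessions are deterministic given (seed, subject_id) and serialize through
:func:`emgfuse.ninapro_io.write_fixture` to the same ``.mat`` dialect as
real recordings.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from emgfuse.ninapro_io import N_ACC_CHANNELS, N_EMG_CHANNELS, RecordingSession

# EMG carrier band at the reference 2 kHz rate; scaled proportionally when
# the sampling rate is lowered.
_EMG_CARRIER_BAND_2K = (20.0, 450.0)
_REFERENCE_FS = 2000.0
_REST_EMG_STD = 0.05
_TONES_PER_CLASS = 2


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for generated sessions.

    Defaults mirror the acquisition protocol of the real dataset:
    6 repetitions x (5 s movement + 3 s rest) per gesture at 2000 Hz.
    ``snr_db`` is the accelerometer tone-to-noise ratio during movement.
    """

    n_classes: int = 8
    n_subjects: int = 1
    fs_hz: float = 2000.0
    reps: int = 6
    movement_s: float = 5.0
    rest_s: float = 3.0
    emg_pattern: np.ndarray | None = None
    acc_pattern: np.ndarray | None = None
    acc_tone_band_hz: tuple[float, float] = (12.0, 40.0)
    snr_db: float = 10.0
    seed: int = 0
    split_information: bool = False

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_classes > 49:
            raise ValueError("n_classes must be <= 49 (labels 1..49; 0 is rest)")
        if not self.fs_hz > 2 * self.acc_tone_band_hz[1]:
            raise ValueError(
                "fs_hz must exceed twice the accelerometer tone band's high edge"
            )
        if self.reps < 1 or self.reps > 6:
            raise ValueError("reps must be in 1..6")

    def resolved_patterns(self) -> tuple[np.ndarray, np.ndarray]:
        if self.emg_pattern is not None and self.acc_pattern is not None:
            return np.asarray(self.emg_pattern, float), np.asarray(self.acc_pattern, float)
        return make_class_patterns(
            self.n_classes, self.seed, split_information=self.split_information
        )


def desk_config(**overrides) -> SyntheticConfig:
    """Desk-scale preset: 500 Hz, 1 s movement / 0.5 s rest, 8 classes.

    Keeps the full 6-repetition protocol but shrinks sampling rate and
    block durations so end-to-end runs fit a single CPU.
    """
    params = dict(fs_hz=500.0, movement_s=1.0, rest_s=0.5)
    params.update(overrides)
    return SyntheticConfig(**params)


def make_class_patterns(
    n_classes: int, seed: int, split_information: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class channel activation gains for EMG (x12) and ACC tones (x36).

    Deterministic given the seed; rows are pairwise distinct.  With
    ``split_information=True`` the first half of the classes share one
    common ACC row (they are separable through EMG only) and the second
    half share one common EMG row (separable through ACC only) — the
    designed benchmark for the fusion-advantage comparison.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = np.random.default_rng([int(seed) % (2**31), 0xEC4])
    emg = rng.uniform(0.5, 2.0, size=(n_classes, N_EMG_CHANNELS))
    acc = rng.uniform(0.5, 2.0, size=(n_classes, N_ACC_CHANNELS))
    if split_information:
        h = n_classes // 2
        acc[:h] = acc[0]   # EMG-only classes: identical ACC signature
        emg[h:] = emg[h]   # ACC-only classes: identical EMG signature
    return emg, acc


def _subject_key(subject_id) -> int:
    return zlib.crc32(str(subject_id).encode()) % (2**31)


def _emg_carrier_sos(fs: float):
    scale = fs / _REFERENCE_FS
    low, high = (b * scale for b in _EMG_CARRIER_BAND_2K)
    return butter(4, (low, high), btype="bandpass", fs=fs, output="sos")


def generate_session(config: SyntheticConfig, subject_id="S0") -> RecordingSession:
    """Generate one subject's synthetic recording.

    Schedule: for every gesture class g in 1..n_classes, ``reps`` blocks of
    (movement + rest).  During movement, EMG channel c carries
    ``emg_pattern[g-1, c]`` times a band-limited Gaussian carrier; ACC
    channel c carries ``acc_pattern[g-1, c]``-scaled class tones plus noise
    at ``snr_db``.  Rest is low-amplitude noise with stimulus and
    repetition annotated 0.
    """
    emg_pat, acc_pat = config.resolved_patterns()
    fs = config.fs_hz
    n_mov = int(round(config.movement_s * fs))
    n_rest = int(round(config.rest_s * fs))
    block = n_mov + n_rest
    n_total = config.n_classes * config.reps * block

    rng = np.random.default_rng([config.seed % (2**31), _subject_key(subject_id)])

    emg = np.empty((n_total, N_EMG_CHANNELS))
    acc = np.empty((n_total, N_ACC_CHANNELS))
    stimulus = np.zeros(n_total, dtype=np.int64)
    repetition = np.zeros(n_total, dtype=np.int64)

    # class-specific tone frequencies inside the accelerometer band
    lo, hi = config.acc_tone_band_hz
    tone_f = rng.uniform(lo, hi, size=(config.n_classes, _TONES_PER_CLASS))

    sos = _emg_carrier_sos(fs)
    t_mov = np.arange(n_mov) / fs

    pos = 0
    for g in range(1, config.n_classes + 1):
        for rep in range(1, config.reps + 1):
            # --- movement block ---
            carrier = sosfiltfilt(sos, rng.standard_normal((n_mov, N_EMG_CHANNELS)), axis=0)
            emg_blk = carrier * emg_pat[g - 1]
            phases = rng.uniform(0, 2 * np.pi, size=_TONES_PER_CLASS)
            tones = np.sin(2 * np.pi * tone_f[g - 1][None, :] * t_mov[:, None] + phases)
            clean = tones.sum(axis=1)[:, None] * acc_pat[g - 1]
            tone_rms = np.sqrt(np.mean(clean**2, axis=0))
            noise_std = tone_rms * 10 ** (-config.snr_db / 20)
            acc_blk = clean + rng.standard_normal((n_mov, N_ACC_CHANNELS)) * noise_std
            sl = slice(pos, pos + n_mov)
            emg[sl], acc[sl] = emg_blk, acc_blk
            stimulus[sl], repetition[sl] = g, rep
            pos += n_mov
            # --- rest block ---
            sl = slice(pos, pos + n_rest)
            emg[sl] = rng.standard_normal((n_rest, N_EMG_CHANNELS)) * _REST_EMG_STD
            acc[sl] = rng.standard_normal((n_rest, N_ACC_CHANNELS)) * float(noise_std.mean())
            pos += n_rest

    return RecordingSession(
        emg=emg,
        acc=acc,
        stimulus=stimulus,
        repetition=repetition,
        sampling_rate_hz=fs,
        subject_id=str(subject_id),
        annotation_source="raw",
    )
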