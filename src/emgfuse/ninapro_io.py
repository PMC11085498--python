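"""Reading, writing and splitting recordings in the NinaPro DB2 layout.

A DB2-style file is a MATLAB matrix archive holding, per subject, the
synchronized streams of one acquisition: a 12-channel surface-EMG matrix
sampled at 2 kHz, a 36-channel accelerometer matrix (one tri-axial
accelerometer per electrode), a per-sample gesture label (``stimulus``,
0 = rest, 1-49 = movements) and a per-sample repetition index
(``repetition``, 0 = rest, 1-6 = the six repetitions of each movement).
NinaPro distributions additionally carry movement-onset-corrected
annotations under ``restimulus``/``rerepetition``; when present these are
preferred, which is the convention in the DB2 classification literature.

Train/test partitioning is by repetition index — repetitions {1, 3, 4, 6}
train, {2, 5} test — rather than by random windows, so that no window of a
test repetition ever overlaps training data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.io import loadmat, savemat

N_EMG_CHANNELS = 12
N_ACC_CHANNELS = 36  # 12 electrodes x 3 axes
MAX_STIMULUS = 49
MAX_REPETITION = 6

DEFAULT_TRAIN_REPS = frozenset({1, 3, 4, 6})
DEFAULT_TEST_REPS = frozenset({2, 5})


class FormatError(ValueError):
    """A file does not conform to the DB2 matrix-archive layout."""


@dataclass
class RecordingSession:
    """One subject's synchronized EMG/ACC/label/repetition streams.

    Attributes
    ----------
    emg : (n_samples, 12) float array, unnormalized mV-scale EMG.
    acc : (n_samples, 36) float array, accelerometer channels.
    stimulus : (n_samples,) int array, gesture label in [0, 49] (0 = rest).
    repetition : (n_samples,) int array, repetition index in [0, 6]
        (0 = rest periods).
    sampling_rate_hz : sampling frequency, default 2000.
    subject_id : subject identifier.
    annotation_source : "relabeled" when movement-onset-corrected
        (restimulus/rerepetition) annotations were used, else "raw".
    """

    emg: np.ndarray
    acc: np.ndarray
    stimulus: np.ndarray
    repetition: np.ndarray
    sampling_rate_hz: float = 2000.0
    subject_id: str = "S0"
    annotation_source: str = "raw"

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.stimulus = np.asarray(self.stimulus).astype(np.int64).ravel()
        self.repetition = np.asarray(self.repetition).astype(np.int64).ravel()
        self.subject_id = str(self.subject_id)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]

    def validate(self) -> None:
        if self.emg.ndim != 2 or self.emg.shape[1] != N_EMG_CHANNELS:
            raise ValueError(
                f"emg must be (n_samples, {N_EMG_CHANNELS}), got {self.emg.shape}"
            )
        if self.acc.ndim != 2 or self.acc.shape[1] != N_ACC_CHANNELS:
            raise ValueError(
                f"acc must be (n_samples, {N_ACC_CHANNELS}), got {self.acc.shape}"
            )
        n = self.emg.shape[0]
        if n == 0:
            raise ValueError("session must contain at least one sample")
        for name, arr in (
            ("acc", self.acc),
            ("stimulus", self.stimulus),
            ("repetition", self.repetition),
        ):
            if arr.shape[0] != n:
                raise ValueError(
                    f"length mismatch: emg has {n} samples but {name} has {arr.shape[0]}"
                )
        if self.stimulus.min() < 0 or self.stimulus.max() > MAX_STIMULUS:
            raise ValueError(
                f"stimulus values must lie in [0, {MAX_STIMULUS}]; "
                f"found range [{self.stimulus.min()}, {self.stimulus.max()}]"
            )
        if self.repetition.min() < 0 or self.repetition.max() > MAX_REPETITION:
            raise ValueError(
                f"repetition values must lie in [0, {MAX_REPETITION}]; "
                f"found range [{self.repetition.min()}, {self.repetition.max()}]"
            )
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")


def read_session(path: str | os.PathLike) -> RecordingSession:
    """Load a DB2-layout ``.mat`` file into a validated :class:`RecordingSession`.

    Movement-onset-corrected annotations (``restimulus``/``rerepetition``)
    are preferred over the raw ones when both are present; the choice is
    recorded in ``annotation_source``.

    Raises
    ------
    FormatError
        If a required field (emg, acc, stimulus/restimulus,
        repetition/rerepetition) is missing.
    ValueError
        If the streams fail session validation (length mismatch,
        out-of-range labels, ...).
    """
    raw = loadmat(str(path), squeeze_me=False)
    missing = [k for k in ("emg", "acc") if k not in raw]
    if "stimulus" not in raw and "restimulus" not in raw:
        missing.append("stimulus")
    if "repetition" not in raw and "rerepetition" not in raw:
        missing.append("repetition")
    if missing:
        raise FormatError(
            f"{path}: missing required field(s): {', '.join(missing)}"
        )

    if "restimulus" in raw and "rerepetition" in raw:
        stim, rep, source = raw["restimulus"], raw["rerepetition"], "relabeled"
    else:
        stim, rep, source = raw["stimulus"], raw["repetition"], "raw"

    fs = float(np.asarray(raw.get("frequency", 2000.0)).ravel()[0])
    subject = raw.get("subject", "S0")
    subject = str(np.asarray(subject).ravel()[0]) if not isinstance(subject, str) else subject
    return RecordingSession(
        emg=raw["emg"],
        acc=raw["acc"],
        stimulus=stim,
        repetition=rep,
        sampling_rate_hz=fs,
        subject_id=subject,
        annotation_source=source,
    )


def write_fixture(session: RecordingSession, path: str | os.PathLike) -> str:
    """Serialize a session to the DB2 ``.mat`` dialect; round-trips exactly.

    Annotations are written under the raw field names (``stimulus``,
    ``repetition``); ``read_session(write_fixture(s))`` reproduces all
    streams (bit-exact on the integer vectors, to machine precision on the
    float matrices).
    """
    session.validate()
    payload = {
        "emg": session.emg,
        "acc": session.acc,
        "stimulus": session.stimulus.reshape(-1, 1),
        "repetition": session.repetition.reshape(-1, 1),
        "frequency": float(session.sampling_rate_hz),
        "subject": session.subject_id,
    }
    savemat(str(path), payload, do_compression=False)
    return str(path)


def split_by_repetition(
    session: RecordingSession,
    train_reps: frozenset[int] | set[int] = DEFAULT_TRAIN_REPS,
    test_reps: frozenset[int] | set[int] = DEFAULT_TEST_REPS,
    include_rest: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean train/test sample masks from the repetition index.

    A sample belongs to a mask iff its repetition value is in the
    corresponding set.  With ``include_rest=False`` (default, the 49-class
    task) samples whose stimulus is 0 are removed from both masks; rest
    periods also carry repetition index 0, so including them requires both
    ``include_rest=True`` and 0 in one of the sets.
    """
    train_reps, test_reps = set(train_reps), set(test_reps)
    if train_reps & test_reps:
        raise ValueError(
            f"train and test repetition sets overlap: {sorted(train_reps & test_reps)}"
        )
    train_mask = np.isin(session.repetition, sorted(train_reps))
    test_mask = np.isin(session.repetition, sorted(test_reps))
    if not include_rest:
        movement = session.stimulus != 0
        train_mask &= movement
        test_mask &= movement
    return train_mask, test_mask
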