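"""Raw EEG containers and plain-text dataset readers.

Two public single-channel EEG layouts are supported:

* **Bonn epilepsy layout** — five class directories (sets A–E), each holding
  100 ASCII files with one integer sample per line (4097 samples at
  173.61 Hz).  Sets A/B are surface recordings from healthy volunteers,
  C/D inter-ictal intracranial recordings, and E ictal (seizure) activity.
* **Bern–Barcelona focal/non-focal layout** — text files with two
  comma-separated real columns ``x`` (focal channel, FC) and ``y``
  (neighbouring non-focal channel, NFC), 10 240 samples at 512 Hz.

Both readers return :class:`RawChannel` objects; nothing here filters or
rejects artefacts — the source datasets are pre-screened visually.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import InvalidArgumentError

logger = logging.getLogger("covdet")

BONN_FS = 173.61
BERN_FS = 512.0

BONN_CLASSES = ("A", "B", "C", "D", "E")


@dataclass
class RawChannel:
    """One EEG trace with its sampling rate and identity.

    Parameters
    ----------
    samples : array-like
        Ordered real-valued samples (µV-scaled, units immaterial downstream).
    fs : float
        Sampling rate in Hz, strictly positive.
    label : str
        Class tag — a Bonn set letter, ``FC``/``NFC``, or a synthetic tag.
    subject_id, channel_id : str
        Provenance identifiers; used by leave-one-subject-out evaluation.
    """

    samples: np.ndarray
    fs: float
    label: str
    subject_id: str = ""
    channel_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise InvalidArgumentError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("samples must all be finite")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise InvalidArgumentError(f"fs must be > 0, got {self.fs!r}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return len(self) / self.fs


def read_bonn_file(path: str | Path, label: str, fs: float = BONN_FS,
                   subject_id: str = "") -> RawChannel:
    """Read one Bonn-layout ASCII file (one integer sample per line)."""
    path = Path(path)
    samples = np.loadtxt(path, dtype=float, ndmin=1)
    return RawChannel(samples=samples, fs=fs, label=label,
                      subject_id=subject_id or path.stem,
                      channel_id=path.stem)


def read_bonn_dir(path: str | Path, label: str, fs: float = BONN_FS) -> list[RawChannel]:
    """Read every ``*.txt``/``*.TXT`` file of one Bonn class directory.

    Files are read in sorted order; each file stem becomes the channel id.
    """
    path = Path(path)
    if not path.is_dir():
        raise InvalidArgumentError(f"not a directory: {path}")
    files = sorted(p for p in path.iterdir()
                   if p.is_file() and p.suffix.lower() in {".txt", ""})
    if not files:
        raise InvalidArgumentError(f"no text files under {path}")
    return [read_bonn_file(p, label=label, fs=fs) for p in files]


def read_bonn_dataset(root: str | Path,
                      classes: tuple[str, ...] = BONN_CLASSES,
                      fs: float = BONN_FS) -> list[RawChannel]:
    """Read a Bonn-layout dataset rooted at *root* with one subdir per class."""
    root = Path(root)
    channels: list[RawChannel] = []
    for cls in classes:
        sub = root / cls
        if not sub.is_dir():
            raise InvalidArgumentError(f"missing class directory: {sub}")
        channels.extend(read_bonn_dir(sub, label=cls, fs=fs))
    logger.info("read %d channels from %s (classes %s)", len(channels), root,
                ",".join(classes))
    return channels


def read_bern_file(path: str | Path, fs: float = BERN_FS,
                   subject_id: str = "") -> tuple[RawChannel, RawChannel]:
    """Read one Bern–Barcelona pair file → (focal ``FC``, non-focal ``NFC``).

    The file holds two comma-separated real columns; an optional non-numeric
    header line (``x,y``) is skipped.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    try:
        [float(tok) for tok in first.replace(",", " ").split()]
    except ValueError:
        skip = 1
    data = np.loadtxt(path, delimiter=",", skiprows=skip, ndmin=2)
    if data.shape[1] != 2:
        raise InvalidArgumentError(
            f"expected two comma-separated columns in {path}, got {data.shape[1]}")
    sid = subject_id or path.stem
    fc = RawChannel(data[:, 0], fs=fs, label="FC", subject_id=sid,
                    channel_id=path.stem + ":x")
    nfc = RawChannel(data[:, 1], fs=fs, label="NFC", subject_id=sid,
                     channel_id=path.stem + ":y")
    return fc, nfc


def read_bern_dir(path: str | Path, fs: float = BERN_FS) -> list[RawChannel]:
    """Read every pair file of a Bern–Barcelona directory, flattened."""
    path = Path(path)
    if not path.is_dir():
        raise InvalidArgumentError(f"not a directory: {path}")
    files = sorted(p for p in path.iterdir()
                   if p.is_file() and p.suffix.lower() in {".txt", ".csv"})
    if not files:
        raise InvalidArgumentError(f"no text files under {path}")
    channels: list[RawChannel] = []
    for p in files:
        channels.extend(read_bern_file(p, fs=fs))
    return channels
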