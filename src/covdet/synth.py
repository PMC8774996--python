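"""Seeded two-class synthetic EEG generator and fixture writers.

The generator emulates the statistical contrast the detection method relies
on, at the Bonn recording geometry (4097 samples at 173.61 Hz, 100 channels
per class):

* **background** — 1/f-weighted Gaussian noise (its sample standard
  deviation normalised to ``noise_sd``) plus a moderate alpha-band
  sinusoid (default 10 Hz, amplitude ``noise_sd``) with random phase;
* **seizure** — the same background process plus a high-amplitude rhythmic
  spike-wave train: a sawtooth at ``spike_rate`` (default 3 Hz) with a
  sharp Gaussian spike per cycle, the whole train scaled by
  ``seizure_amp_gain × noise_sd``.

Channels are assigned round-robin to ``n_subjects`` synthetic subjects so
leave-one-subject-out evaluation is exercised.  Everything is deterministic
under the seed.  No claim of clinical realism is made — the signal model
has face validity for ictal EEG (high-amplitude rhythmic spiking) and is
fully parametric.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .exceptions import InvalidArgumentError
from .io import BONN_FS, RawChannel

logger = logging.getLogger("covdet")

LABEL_SEIZURE = "seizure"
LABEL_BACKGROUND = "background"


@dataclass
class SynthConfig:
    """Generator parameters (defaults = the study conditions)."""

    n_per_class: int = 100
    length: int = 4097
    fs: float = BONN_FS
    seizure_amp_gain: float = 3.0
    spike_rate: float = 3.0
    background_alpha_freq: float = 10.0
    noise_sd: float = 1.0
    n_subjects: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_class, self.length, self.n_subjects) < 1:
            raise InvalidArgumentError("counts must be positive")
        if min(self.fs, self.seizure_amp_gain, self.spike_rate,
               self.background_alpha_freq, self.noise_sd) <= 0:
            raise InvalidArgumentError("rates/amplitudes must be positive")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-weighted Gaussian noise, unit sample standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    weights = np.ones_like(freqs)
    weights[1:] = 1.0 / np.sqrt(freqs[1:])
    weights[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * weights, n)
    return x / x.std()


def gen_background(cfg: SynthConfig, rng: np.random.Generator,
                   subject_id: str = "", channel_id: str = "") -> RawChannel:
    """One background channel: pink noise plus a random-phase alpha sinusoid."""
    t = np.arange(cfg.length) / cfg.fs
    noise = cfg.noise_sd * _pink_noise(cfg.length, rng)
    phase = rng.uniform(0, 2 * np.pi)
    alpha = cfg.noise_sd * np.sin(2 * np.pi * cfg.background_alpha_freq * t + phase)
    return RawChannel(noise + alpha, fs=cfg.fs, label=LABEL_BACKGROUND,
                      subject_id=subject_id, channel_id=channel_id)


def _spike_wave(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Rhythmic sawtooth-plus-spike train, one spike per cycle."""
    t = np.arange(cfg.length) / cfg.fs
    phase = rng.uniform(0, 1.0 / cfg.spike_rate)
    wave = 0.5 * sps.sawtooth(2 * np.pi * cfg.spike_rate * (t - phase), width=0.5)
    duration = cfg.length / cfg.fs
    # one spike per cycle, riding the crest of the slow wave
    n_spikes = int(np.floor((duration - phase) * cfg.spike_rate)) + 1
    spike_times = phase + (np.arange(n_spikes) + 0.5) / cfg.spike_rate
    spike_times = spike_times[spike_times < duration]
    width = 0.02  # 20 ms spikes
    spikes = np.zeros_like(t)
    for ts in spike_times:
        spikes += np.exp(-0.5 * ((t - ts) / width) ** 2)
    return wave + spikes


def gen_seizure(cfg: SynthConfig, rng: np.random.Generator,
                subject_id: str = "", channel_id: str = "") -> RawChannel:
    """One seizure channel: background plus the scaled spike-wave train."""
    bg = gen_background(cfg, rng)
    train = cfg.seizure_amp_gain * cfg.noise_sd * _spike_wave(cfg, rng)
    return RawChannel(bg.samples + train, fs=cfg.fs, label=LABEL_SEIZURE,
                      subject_id=subject_id, channel_id=channel_id)


def gen_dataset(cfg: SynthConfig) -> list[RawChannel]:
    """``n_per_class`` channels of each class, round-robin over subjects."""
    rng = np.random.default_rng(cfg.seed)
    channels: list[RawChannel] = []
    for label, gen in ((LABEL_BACKGROUND, gen_background),
                       (LABEL_SEIZURE, gen_seizure)):
        for i in range(cfg.n_per_class):
            subject = f"S{i % cfg.n_subjects:02d}"
            cid = f"{label[:3]}{i:03d}"
            channels.append(gen(cfg, rng, subject_id=subject, channel_id=cid))
    logger.info("generated %d synthetic channels (seed %d)", len(channels), cfg.seed)
    return channels


# ---------------------------------------------------------------------------
# Fixture writers
# ---------------------------------------------------------------------------

def write_fixture(dataset: list[RawChannel], layout: str, path) -> list[Path]:
    """Write channels to disk in the ``bonn`` or ``bern`` plain-text layout.

    Bonn: one ASCII file per channel under a subdirectory per label, one
    sample per line.  Bern: consecutive (seizure, background) channel pairs
    become two-column comma-separated files with an ``x,y`` header.
    A ``manifest.json`` recording labels, subjects and the layout is written
    alongside.  Returns the list of written sample files.
    """
    if not dataset:
        raise InvalidArgumentError("dataset is empty")
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {"layout": layout, "fs": dataset[0].fs, "channels": []}
    if layout == "bonn":
        for ch in dataset:
            sub = root / ch.label
            sub.mkdir(exist_ok=True)
            f = sub / f"{ch.channel_id}.txt"
            np.savetxt(f, ch.samples, fmt="%.6f")
            written.append(f)
            manifest["channels"].append({"file": str(f.relative_to(root)),
                                         "label": ch.label,
                                         "subject_id": ch.subject_id,
                                         "channel_id": ch.channel_id})
    elif layout == "bern":
        by_label: dict[str, list[RawChannel]] = {}
        for ch in dataset:
            by_label.setdefault(ch.label, []).append(ch)
        labels = sorted(by_label)
        if len(labels) != 2:
            raise InvalidArgumentError("bern layout needs exactly two classes")
        x_label, y_label = labels[-1], labels[0]  # seizure-like as column x
        pairs = zip(by_label[x_label], by_label[y_label])
        for i, (cx, cy) in enumerate(pairs):
            f = root / f"pair{i:04d}.txt"
            n = min(len(cx), len(cy))
            data = np.column_stack([cx.samples[:n], cy.samples[:n]])
            np.savetxt(f, data, fmt="%.6f", delimiter=",", header="x,y", comments="")
            written.append(f)
            manifest["channels"].append({"file": f.name, "x_label": x_label,
                                         "y_label": y_label,
                                         "x_channel": cx.channel_id,
                                         "y_channel": cy.channel_id})
    else:
        raise InvalidArgumentError(f"unknown layout {layout!r}")
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return written


def labels_binary(channels: list[RawChannel],
                  positive_label: str = LABEL_SEIZURE) -> np.ndarray:
    """0/1 label vector over channels (1 = positive/seizure-like class)."""
    return np.array([1 if ch.label == positive_label else 0 for ch in channels])
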