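"""Phone posteriorgrams and the acoustic-model contract.

A posteriorgram is a T x 45 row-stochastic matrix: per frame, a posterior
probability over 44 ARPAbet phone classes (BEEP-dictionary British English
inventory) plus one silence class.  Any acoustic model mapping a feature
sequence to such a matrix can drive the verifier; a deterministic mock model
based on spectral-band energies stands in for a trained network so the full
audio pipeline is testable without any speech corpus.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
import scipy.fft

from .frontend import FeatureSequence, FrameSpec, _lifter_weights

__all__ = [
    "DEFAULT_PHONES",
    "SILENCE",
    "PhoneInventory",
    "Posteriorgram",
    "AcousticModel",
    "MockBandModel",
    "mock_band_model",
    "posteriorize",
    "read_posteriorgram",
    "write_posteriorgram",
    "TemplateSet",
]

SILENCE = "sil"

# 44 ARPAbet phone symbols of the BEEP British English dictionary,
# alphabetical; silence is appended as the final class.
DEFAULT_PHONES = (
    "aa ae ah ao aw ax ay b ch d dh ea eh er ey f g hh ia ih iy jh k l "
    "m n ng oh ow oy p r s sh t th ua uh uw v w y z zh"
).split()

ROW_SUM_TOL = 1e-3


@dataclass(frozen=True)
class PhoneInventory:
    """Ordered phone-class labels defining posteriorgram columns."""

    labels: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("phone labels must be unique")
        if SILENCE not in self.labels:
            raise ValueError(f"inventory must contain the silence class {SILENCE!r}")

    @classmethod
    def default(cls) -> "PhoneInventory":
        return cls(tuple(DEFAULT_PHONES) + (SILENCE,))

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown phone label {label!r}") from None

    @property
    def silence_index(self) -> int:
        return self.labels.index(SILENCE)


def _validate_rows(probs: np.ndarray, tol: float = ROW_SUM_TOL) -> np.ndarray:
    """Check non-negativity and row sums; renormalize within tolerance."""
    if np.any(probs < 0):
        row = int(np.argwhere(probs < 0)[0, 0])
        raise ValueError(f"negative posterior probability in row {row}")
    sums = probs.sum(axis=1)
    off = np.abs(sums - 1.0)
    if np.any(off > tol):
        row = int(np.argmax(off))
        raise ValueError(
            f"row {row} sums to {sums[row]:.6f}, outside tolerance {tol}"
        )
    return probs / sums[:, None]


@dataclass(frozen=True)
class Posteriorgram:
    """T x K row-stochastic matrix of phone posteriors over an utterance."""

    probs: np.ndarray
    inventory: PhoneInventory
    frame_rate: float = 100.0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        if probs.ndim != 2 or probs.shape[0] < 1:
            raise ValueError("posteriorgram must be a 2-D matrix with T >= 1")
        if probs.shape[1] != len(self.inventory):
            raise ValueError(
                f"posteriorgram has {probs.shape[1]} columns but the "
                f"inventory defines {len(self.inventory)} classes"
            )
        object.__setattr__(self, "probs", _validate_rows(probs))

    @property
    def n_frames(self) -> int:
        return self.probs.shape[0]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]

    def argmax_labels(self) -> list:
        return [self.inventory.labels[i] for i in self.probs.argmax(axis=1)]


@runtime_checkable
class AcousticModel(Protocol):
    """Maps a FeatureSequence to a Posteriorgram with matching frame count."""

    inventory: PhoneInventory
    deterministic: bool

    def __call__(self, features: FeatureSequence) -> Posteriorgram: ...


def posteriorize(features: FeatureSequence, model: AcousticModel) -> Posteriorgram:
    """Apply an acoustic model, enforcing the posteriorgram contract."""
    if features.n_frames == 0:
        raise ValueError("cannot posteriorize an empty feature sequence")
    pg = model(features)
    probs = np.asarray(pg.probs, dtype=np.float64)
    if probs.shape[0] != features.n_frames:
        raise ValueError(
            f"acoustic model returned {probs.shape[0]} rows for "
            f"{features.n_frames} input frames"
        )
    # Posteriorgram construction re-validates simplex membership.
    return Posteriorgram(probs, pg.inventory, pg.frame_rate)


class MockBandModel:
    """Deterministic stand-in acoustic model keyed to spectral bands.

    Reconstructs a smoothed log-mel envelope from the frame's cepstra
    (inverse DCT after un-liftering) and scores each "tone phone" by the
    envelope value in its assigned mel band, softmax-normalized.  Frames
    whose log-energy falls below ``silence_log_energy`` concentrate mass on
    the silence class.  Distinct tones therefore map to distinct phone
    classes, which lets end-to-end audio tests run without trained weights.
    """

    deterministic = True

    def __init__(self, inventory: PhoneInventory | None = None,
                 spec: FrameSpec = FrameSpec(),
                 temperature: float = 2.0,
                 silence_log_energy: float = np.log(1e-6)):
        self.inventory = inventory or PhoneInventory.default()
        self.spec = spec
        self.temperature = temperature
        self.silence_log_energy = silence_log_energy
        non_sil = [l for l in self.inventory.labels if l != SILENCE]
        # one mel band per tone phone; interior bands 1..n_mels-1
        n_tone = min(len(non_sil), spec.n_mels - 1)
        self.tone_phones = {non_sil[i]: i + 1 for i in range(n_tone)}

    def band_of(self, phone: str) -> int:
        if phone not in self.tone_phones:
            raise KeyError(f"{phone!r} has no assigned tone band")
        return self.tone_phones[phone]

    def __call__(self, features: FeatureSequence) -> Posteriorgram:
        vals = features.values
        n_mfcc = self.spec.n_mfcc
        mfcc = vals[:, :n_mfcc] / _lifter_weights(n_mfcc, self.spec.lifter)
        log_energy = vals[:, n_mfcc]

        cep = np.zeros((vals.shape[0], self.spec.n_mels))
        cep[:, 1:n_mfcc + 1] = mfcc
        envelope = scipy.fft.idct(cep, type=2, axis=1, norm="ortho")

        k = len(self.inventory)
        scores = np.full((vals.shape[0], k), -50.0)
        for phone, band in self.tone_phones.items():
            scores[:, self.inventory.index(phone)] = (
                envelope[:, band] / self.temperature
            )
        silent = log_energy < self.silence_log_energy
        scores[silent, :] = -50.0
        scores[silent, self.inventory.silence_index] = 10.0

        scores -= scores.max(axis=1, keepdims=True)
        probs = np.exp(scores)
        probs /= probs.sum(axis=1, keepdims=True)
        return Posteriorgram(probs, self.inventory, features.frame_rate)


def mock_band_model(inventory: PhoneInventory | None = None, **kwargs) -> MockBandModel:
    return MockBandModel(inventory, **kwargs)


def write_posteriorgram(pg: Posteriorgram, path) -> None:
    """Headered text format: metadata line, label line, one row per frame."""
    with open(path, "w") as fh:
        fh.write(f"# frame_rate={pg.frame_rate}\n")
        fh.write(" ".join(pg.inventory.labels) + "\n")
        for row in pg.probs:
            fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


def read_posteriorgram(path) -> Posteriorgram:
    with open(path) as fh:
        first = fh.readline().strip()
        frame_rate = 100.0
        if first.startswith("#"):
            meta = dict(kv.split("=") for kv in first.lstrip("# ").split())
            frame_rate = float(meta.get("frame_rate", frame_rate))
            labels = fh.readline().split()
        else:
            labels = first.split()
        rows = [[float(v) for v in line.split()] for line in fh if line.strip()]
    if not rows:
        raise ValueError(f"{path}: no posteriorgram rows")
    probs = np.asarray(rows)
    inventory = PhoneInventory(labels)
    return Posteriorgram(probs, inventory, frame_rate)


class TemplateSet:
    """Healthy-speaker reference posteriorgrams, keyed by target word.

    On disk: a directory per word, one posteriorgram file per speaker
    (``<root>/<word>/<speaker_id>.pgm``).
    """

    def __init__(self, templates: dict | None = None):
        self._templates: dict = dict(templates or {})

    def add(self, word: str, pg: Posteriorgram) -> None:
        self._templates.setdefault(word, []).append(pg)

    def __getitem__(self, word: str) -> list:
        if word not in self._templates or not self._templates[word]:
            raise KeyError(f"no templates for word {word!r}")
        return self._templates[word]

    def __contains__(self, word: str) -> bool:
        return word in self._templates

    def words(self) -> list:
        return sorted(self._templates)

    def __len__(self) -> int:
        return len(self._templates)

    def save(self, root) -> None:
        for word, pgs in self._templates.items():
            word_dir = os.path.join(root, word)
            os.makedirs(word_dir, exist_ok=True)
            for i, pg in enumerate(pgs):
                write_posteriorgram(pg, os.path.join(word_dir, f"speaker{i}.pgm"))

    @classmethod
    def load(cls, root) -> "TemplateSet":
        templates: dict = {}
        for word in sorted(os.listdir(root)):
            word_dir = os.path.join(root, word)
            if not os.path.isdir(word_dir):
                continue
            for fname in sorted(os.listdir(word_dir)):
                templates.setdefault(word, []).append(
                    read_posteriorgram(os.path.join(word_dir, fname))
                )
        return cls(templates)
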