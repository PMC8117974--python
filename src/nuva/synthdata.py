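"""Synthetic templates, attempts, and full study replicas.

Real aphasic naming recordings cannot be redistributed, so every layer of
the verifier is exercised on synthetic posteriorgrams instead.  A target
word is a short pseudo-phone sequence; a healthy template renders each
phone as a run of frames whose posterior row is a concentration-weighted
mixture of the phone's one-hot vector and the uniform vector (which gives
exact control of expected inner products).  Patient attempts follow the
clinical response taxonomy:

* Correct             — same phone sequence, tempo-warped and noisier;
* Phonological Error  — some phones substituted or deleted;
* Circumlocution      — a multi-word-length different sequence;
* Other               — a different word's sequence;
* Filler              — a short neutral-vowel run ("ah");
* No Response         — silence-class frames.

An attempt is truly "correct" iff its category is Correct.  A full study
replica draws one attempt per (patient, word) with per-patient category
mixes ("severity"), defaulting to 220 words x 8 patients x 2 healthy
templates.  ``synth_audio`` additionally renders a word as a sequence of
pure tones at the mel-band frequencies the mock acoustic model listens to,
for end-to-end audio tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frontend import AudioSignal, FrameSpec, mel_filterbank
from .posteriorgram import (SILENCE, MockBandModel, PhoneInventory,
                            Posteriorgram, TemplateSet)

__all__ = [
    "CATEGORIES",
    "SEVERITY_PRESETS",
    "SynthConfig",
    "SynthAttempt",
    "StudyData",
    "synth_template",
    "synth_attempt",
    "synth_study",
    "synth_audio",
    "tone_frequency",
]

CATEGORIES = ("Correct", "No Response", "Filler", "Phonological Error",
              "Circumlocution", "Other")

# Category mixes loosely spanning the clinical range from mildly to
# severely anomic patients; the first entry is the Correct proportion.
SEVERITY_PRESETS = {
    "mild": (0.75, 0.05, 0.05, 0.08, 0.04, 0.03),
    "moderate": (0.55, 0.10, 0.10, 0.12, 0.08, 0.05),
    "severe": (0.35, 0.15, 0.15, 0.17, 0.10, 0.08),
}


@dataclass(frozen=True)
class SynthConfig:
    """Study-replica parameters.

    Defaults replicate the study design: 220 target words, 8 patients,
    2 healthy templates per word, words of 2-6 pseudo-phones rendered at
    5-15 frames per phone.  ``concentration`` c mixes each posterior row as
    w * onehot + (1 - w) * uniform with w = c / (c + 1) (c = inf gives
    one-hot rows); ``noise`` mixes in a random simplex vector per attempt
    frame; ``warp`` bounds the tempo distortion of correct attempts.
    """

    n_words: int = 220
    n_patients: int = 8
    templates_per_word: int = 2
    phones_per_word: tuple = (2, 6)
    frames_per_phone: tuple = (5, 15)
    concentration: float = 12.0
    noise: float = 0.05
    warp: float = 0.3
    severity: tuple | None = None  # per-patient 6-vectors; None -> presets
    seed: int = 0
    inventory: PhoneInventory = field(default_factory=PhoneInventory.default)

    def __post_init__(self) -> None:
        if min(self.n_words, self.n_patients, self.templates_per_word) < 1:
            raise ValueError("counts must be positive")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.severity is not None:
            for row in self.severity:
                if abs(sum(row) - 1.0) > 1e-9:
                    raise ValueError("severity rows must sum to 1")

    @property
    def onehot_weight(self) -> float:
        c = self.concentration
        return 1.0 if np.isinf(c) else c / (c + 1.0)

    def patient_severity(self, patient_index: int) -> np.ndarray:
        if self.severity is not None:
            return np.asarray(self.severity[patient_index], dtype=float)
        preset = list(SEVERITY_PRESETS)[patient_index % len(SEVERITY_PRESETS)]
        return np.asarray(SEVERITY_PRESETS[preset], dtype=float)


@dataclass(frozen=True)
class SynthAttempt:
    """One simulated naming attempt with its ground truth."""

    patient_id: str
    item_id: str
    word: str
    category: str
    truth: str  # "correct" | "incorrect"
    posteriorgram: Posteriorgram


def _phone_rows(phones, durations, cfg: SynthConfig, rng=None) -> Posteriorgram:
    """Render a phone sequence as mixture rows, optionally noised."""
    inv = cfg.inventory
    k = len(inv)
    w = cfg.onehot_weight
    rows = []
    for phone, dur in zip(phones, durations):
        col = inv.index(phone)  # raises KeyError for unknown phones
        base = np.full(k, (1.0 - w) / k)
        base[col] += w
        block = np.tile(base, (dur, 1))
        rows.append(block)
    probs = np.vstack(rows)
    if rng is not None and cfg.noise > 0:
        jitter = rng.dirichlet(np.ones(k), size=probs.shape[0])
        probs = (1.0 - cfg.noise) * probs + cfg.noise * jitter
    return Posteriorgram(probs, inv)


def _durations(n_phones: int, cfg: SynthConfig, rng) -> np.ndarray:
    lo, hi = cfg.frames_per_phone
    return rng.integers(lo, hi + 1, size=n_phones)


def _random_word(cfg: SynthConfig, rng, exclude=()) -> tuple:
    lo, hi = cfg.phones_per_word
    pool = [p for p in cfg.inventory.labels if p != SILENCE]
    while True:
        n = int(rng.integers(lo, hi + 1))
        phones = tuple(rng.choice(pool, size=n))
        if phones not in exclude:
            return phones


def synth_template(word, cfg: SynthConfig, rng) -> Posteriorgram:
    """Healthy-speaker template: clean mixture rows, random durations."""
    phones = tuple(word)
    if not phones:
        raise ValueError("word must contain at least one phone")
    return _phone_rows(phones, _durations(len(phones), cfg, rng), cfg)


def synth_attempt(word, category: str, cfg: SynthConfig, rng,
                  patient_id: str = "P0", item_id: str = "i0",
                  word_label: str | None = None) -> SynthAttempt:
    """Simulate one naming attempt of the given response category."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    phones = tuple(word)
    inv = cfg.inventory

    if category == "Correct":
        scale = 1.0 + cfg.warp * (2.0 * rng.random() - 1.0)
        durs = np.maximum(1, np.round(
            _durations(len(phones), cfg, rng) * scale)).astype(int)
        pg = _phone_rows(phones, durs, cfg, rng)
    elif category == "Phonological Error":
        pool = [p for p in inv.labels if p != SILENCE]
        out = list(phones)
        n_sub = max(1, len(out) // 2)
        for pos in rng.choice(len(out), size=min(n_sub, len(out)), replace=False):
            out[pos] = str(rng.choice([p for p in pool if p != out[pos]]))
        if len(out) > 2 and rng.random() < 0.3:
            out.pop(int(rng.integers(len(out))))
        pg = _phone_rows(out, _durations(len(out), cfg, rng), cfg, rng)
    elif category == "Circumlocution":
        seq = []
        for _ in range(int(rng.integers(2, 5))):
            seq.extend(_random_word(cfg, rng, exclude=(phones,)))
        pg = _phone_rows(seq, _durations(len(seq), cfg, rng), cfg, rng)
    elif category == "Other":
        other = _random_word(cfg, rng, exclude=(phones,))
        pg = _phone_rows(other, _durations(len(other), cfg, rng), cfg, rng)
    elif category == "Filler":
        dur = int(rng.integers(3, 9))
        pg = _phone_rows(("ah",), (dur,), cfg, rng)
    else:  # No Response
        dur = int(rng.integers(5, 16))
        pg = _phone_rows((SILENCE,), (dur,), cfg)

    truth = "correct" if category == "Correct" else "incorrect"
    return SynthAttempt(patient_id, item_id, word_label or "-".join(phones),
                        category, truth, pg)


@dataclass(frozen=True)
class StudyData:
    """A complete synthetic study: lexicon, templates, and attempts."""

    words: dict           # word label -> phone tuple
    templates: TemplateSet
    attempts: tuple       # SynthAttempt records
    config: SynthConfig

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.patient_id, a.item_id, a.word, a.category, a.truth)
             for a in self.attempts],
            columns=["patient_id", "item_id", "word", "category", "truth"],
        )

    def __len__(self) -> int:
        return len(self.attempts)


def synth_study(cfg: SynthConfig = SynthConfig()) -> StudyData:
    """Generate a full study replica, reproducible from ``cfg.seed``.

    One attempt per (patient, word); the per-patient category mix is drawn
    from that patient's severity vector.
    """
    rng = np.random.default_rng(cfg.seed)
    width = len(str(cfg.n_words - 1))
    words: dict = {}
    seen: set = set()
    for i in range(cfg.n_words):
        phones = _random_word(cfg, rng, exclude=seen)
        seen.add(phones)
        words[f"w{i:0{width}d}"] = phones

    templates = TemplateSet()
    for label, phones in words.items():
        for _ in range(cfg.templates_per_word):
            templates.add(label, synth_template(phones, cfg, rng))

    attempts = []
    for p in range(cfg.n_patients):
        pid = f"P{p + 1}"
        severity = cfg.patient_severity(p)
        cats = rng.choice(len(CATEGORIES), size=cfg.n_words, p=severity)
        for (label, phones), cat_idx in zip(words.items(), cats):
            attempts.append(synth_attempt(
                phones, CATEGORIES[cat_idx], cfg, rng,
                patient_id=pid, item_id=label, word_label=label))
    return StudyData(words, templates, tuple(attempts), cfg)


def tone_frequency(band: int, spec: FrameSpec = FrameSpec(),
                   sample_rate: int = 16000) -> float:
    """Centre frequency (Hz) of a mel filterbank band, matching the mock model."""
    n_fft = spec.fft_samples(sample_rate)
    fb = mel_filterbank(spec.n_mels, n_fft, sample_rate)
    centre_bin = int(np.argmax(fb[band]))
    return centre_bin * sample_rate / n_fft


def synth_audio(word, cfg: SynthConfig, rng,
                model: MockBandModel | None = None,
                spec: FrameSpec = FrameSpec(),
                sample_rate: int = 16000,
                amplitude: float = 0.3,
                max_seconds: float = 6.0) -> AudioSignal:
    """Render a word as a sequence of pure tones, one per pseudo-phone.

    Each phone must have a tone band assigned by the mock acoustic model;
    the segment is a sine at that band's centre frequency, with duration
    drawn from ``frames_per_phone``.  Output is capped at ``max_seconds``
    (the attempt-length limit), truncating with a warning.
    """
    model = model or MockBandModel(cfg.inventory, spec)
    hop = spec.hop_samples(sample_rate)
    window = spec.window_samples(sample_rate)
    segments = []
    for phone, dur in zip(word, _durations(len(word), cfg, rng)):
        freq = tone_frequency(model.band_of(phone), spec, sample_rate)
        n = int(dur) * hop + (window - hop)
        t = np.arange(n) / sample_rate
        segments.append(amplitude * np.sin(2 * np.pi * freq * t))
    samples = np.concatenate(segments)
    limit = int(max_seconds * sample_rate)
    if len(samples) > limit:
        warnings.warn(f"attempt exceeds {max_seconds} s; truncating")
        samples = samples[:limit]
    return AudioSignal(samples, sample_rate)
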