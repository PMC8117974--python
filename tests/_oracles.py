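"""Independent brute-force oracles used to check the implementation.

These are deliberately naive (enumeration, direct formula evaluation,
loop-based DSP) and share no code with the package.
"""

import numpy as np


def brute_force_dtw(local: np.ndarray) -> float:
    """Minimum accumulated cost over all monotone paths (1,1)->(n,m),
    steps {(1,0),(0,1),(1,1)}, by exhaustive recursion."""
    n, m = local.shape

    def rec(i, j):
        if i == 0 and j == 0:
            return local[0, 0]
        best = np.inf
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        return best + local[i, j]

    return rec(n - 1, m - 1)


def brute_force_delta(static: np.ndarray, halfwidth: int = 2) -> np.ndarray:
    """Direct per-element evaluation of the delta regression sum."""
    t, d = static.shape
    out = np.zeros_like(static, dtype=float)
    denom = 2 * sum(k * k for k in range(1, halfwidth + 1))
    for i in range(t):
        for j in range(d):
            acc = 0.0
            for k in range(1, halfwidth + 1):
                hi = static[min(i + k, t - 1), j]
                lo = static[max(i - k, 0), j]
                acc += k * (hi - lo)
            out[i, j] = acc / denom
    return out


def reference_mfcc(samples: np.ndarray, sample_rate: int = 16000) -> np.ndarray:
    """Independently coded MFCC front-end (loops and explicit formulas).

    Same nominal configuration as the package default: pre-emphasis 0.95,
    30/10 ms frames, Hamming window, 1024-point FFT, 26 triangular mel
    filters 0-8000 Hz, DCT-II (ortho), cepstra c1..c12 with sinusoidal
    lifter L=23, log frame energy floored at 1e-10.
    """
    x = np.array(samples, dtype=float)
    y = np.empty_like(x)
    y[0] = x[0]
    for t in range(1, len(x)):
        y[t] = x[t] - 0.95 * x[t - 1]

    w, h, n_fft, n_mels, n_ceps, lifter = 480, 160, 1024, 26, 12, 23.0
    n_frames = (len(y) - w) // h + 1
    ham = np.array([0.54 - 0.46 * np.cos(2 * np.pi * i / (w - 1))
                    for i in range(w)])

    def mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def imel(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    pts = [imel(mel(0.0) + i * (mel(sample_rate / 2) - mel(0.0)) / (n_mels + 1))
           for i in range(n_mels + 2)]
    bins = [int(np.floor((n_fft + 1) * p / sample_rate)) for p in pts]
    fbank = np.zeros((n_mels, n_fft // 2 + 1))
    for i in range(n_mels):
        for k in range(bins[i], bins[i + 1]):
            fbank[i, k] = (k - bins[i]) / max(bins[i + 1] - bins[i], 1)
        for k in range(bins[i + 1], bins[i + 2]):
            fbank[i, k] = (bins[i + 2] - k) / max(bins[i + 2] - bins[i + 1], 1)

    lift = np.array([1.0 + (lifter / 2.0) * np.sin(np.pi * (n + 1) / lifter)
                     for n in range(n_ceps)])

    out = np.zeros((n_frames, n_ceps + 1))
    for f in range(n_frames):
        frame = y[f * h:f * h + w]
        energy = float(np.sum(frame ** 2))
        log_e = np.log(max(energy, 1e-10))
        spec = np.fft.rfft(frame * ham, n=n_fft)
        power = np.abs(spec) ** 2
        melspec = fbank @ power
        logmel = np.log(np.maximum(melspec, 1e-10))
        ceps = np.zeros(n_ceps)
        for c in range(1, n_ceps + 1):
            s = 0.0
            for k in range(n_mels):
                s += logmel[k] * np.cos(np.pi * c * (2 * k + 1) / (2 * n_mels))
            ceps[c - 1] = np.sqrt(2.0 / n_mels) * s
        out[f, :n_ceps] = ceps * lift
        out[f, n_ceps] = log_e
    return out


def confusion_table_metric(distances, truth, threshold, metric):
    """Direct confusion-table evaluation for the threshold sweep oracle."""
    pred = [1 if d < threshold else 0 for d in distances]
    tp = sum(1 for p, t in zip(pred, truth) if p == 1 and t == 1)
    tn = sum(1 for p, t in zip(pred, truth) if p == 0 and t == 0)
    fp = sum(1 for p, t in zip(pred, truth) if p == 1 and t == 0)
    fn = sum(1 for p, t in zip(pred, truth) if p == 0 and t == 1)
    n = len(pred)
    if metric == "accuracy":
        return (tp + tn) / n
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return np.nan
    return (tp * tn - fp * fn) / np.sqrt(denom)


def cochran_q_direct(x: np.ndarray) -> float:
    """Cochran's Q by the textbook formula."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    num = (k - 1) * (k * np.sum(col ** 2) - np.sum(col) ** 2)
    den = k * np.sum(row) - np.sum(row ** 2)
    return num / den
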