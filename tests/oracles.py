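"""Independent brute-force transcriptions of the closed-form features.

Each function here is a literal, unoptimized rendering of the defining
formula, kept deliberately separate from the package implementation so
the two can be compared on random inputs.
"""

import numpy as np
from scipy.signal import periodogram


def spectral_entropy_oracle(x, fs, f1, f2):
    freqs, psd = periodogram(x, fs=fs, window="hann")
    sel = [(f, p) for f, p in zip(freqs, psd) if f1 <= f <= f2]
    p = np.array([v for _, v in sel])
    if p.sum() == 0:
        return 0.0
    p = p / p.sum()
    h = -sum(v * np.log(v) for v in p if v > 0)
    return h / np.log(len(p))


def renyi_oracle(x, alpha, n_bins):
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts / counts.sum()
    return np.log(sum(v ** alpha for v in p if v > 0)) / (1 - alpha)


def apen_oracle(x, m, r_mult):
    """Chebyshev pattern counting by blocked broadcasting."""
    x = np.asarray(x, dtype=float)
    n = x.size
    r = r_mult * x.std()

    def phi(mm):
        w = np.lib.stride_tricks.sliding_window_view(x, mm)
        nw = w.shape[0]
        logs = np.empty(nw)
        block = 256
        for s in range(0, nw, block):
            d = np.abs(w[s:s + block, None, :] - w[None, :, :]).max(axis=2)
            c = (d <= r).sum(axis=1)
            logs[s:s + block] = np.log(c / nw)
        return logs.mean()

    return phi(m) - phi(m + 1)


def permen_oracle(x, m):
    """Exhaustive ordinal-pattern counting (stable ranks)."""
    x = np.asarray(x, dtype=float)
    t = x.size
    counts: dict[tuple, int] = {}
    for i in range(t - m + 1):
        w = x[i:i + m]
        pattern = tuple(sorted(range(m), key=lambda j: (w[j], j)))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = t - (m - 1)
    return -sum((c / total) * np.log(c / total) for c in counts.values())


def petrosian_oracle(x):
    x = np.asarray(x, dtype=float)
    n = len(x)
    d = [x[i + 1] - x[i] for i in range(n - 1)]
    n_delta = sum(
        1 for i in range(len(d) - 1) if np.sign(d[i]) * np.sign(d[i + 1]) < 0
    )
    return np.log10(n) / (np.log10(n) + np.log10(n / (n + 0.4 * n_delta)))


def teager_oracle(x):
    x = np.asarray(x, dtype=float)
    vals = [x[i] ** 2 - x[i - 1] * x[i + 1] for i in range(1, len(x) - 1)]
    return float(np.mean(vals))


def curve_length_oracle(x):
    x = np.asarray(x, dtype=float)
    return float(sum(abs(x[i] - x[i - 1]) for i in range(1, len(x))))


def hurst_oracle(x):
    x = np.asarray(x, dtype=float)
    s = x.std()
    if s == 0:
        return 0.0
    z = np.cumsum(x - x.mean())
    rs = (z.max() - z.min()) / s
    return np.log(rs) / np.log(len(x))


def hjorth_oracle(x):
    x = np.asarray(x, dtype=float)
    s0 = np.var(x)
    if s0 == 0:
        return 0.0, 0.0, 0.0
    d1 = np.array([x[i + 1] - x[i] for i in range(len(x) - 1)])
    d2 = np.array([d1[i + 1] - d1[i] for i in range(len(d1) - 1)])
    s1, s2 = np.var(d1), np.var(d2)
    mob = np.sqrt(s1 / s0)
    comp = np.sqrt(s2 / s1) / np.sqrt(s1 / s0)
    return s0, mob, comp


def standardize_oracle(col):
    col = np.asarray(col, dtype=float)
    sd = np.sqrt(np.mean((col - col.mean()) ** 2))
    if sd == 0:
        return np.zeros_like(col)
    return (col - col.mean()) / sd


def zcr_oracle(x):
    x = np.asarray(x, dtype=float)
    signs = [v < 0 for v in x]
    return sum(1 for i in range(1, len(x)) if signs[i] != signs[i - 1])


def cmim_oracle(cols, y):
    """Brute-force CMIM ordering (no incremental-min shortcut)."""
    from psgrank.ranking import conditional_mutual_information, mutual_information
    p = len(cols)
    remaining = list(range(p))
    selected = []
    while remaining:
        if not selected:
            crit = {j: mutual_information(cols[j], y) for j in remaining}
        else:
            crit = {
                j: min(
                    conditional_mutual_information(cols[j], y, cols[g])
                    for g in selected
                )
                for j in remaining
            }
        best = min(remaining, key=lambda j: (-crit[j], j))
        selected.append(best)
        remaining.remove(best)
    return selected


def mrmr_oracle(cols, y, variant):
    """Brute-force MRMR ordering (recomputes redundancy every step)."""
    from psgrank.ranking import mutual_information
    p = len(cols)
    remaining = list(range(p))
    selected = []
    rel = {j: mutual_information(cols[j], y) for j in range(p)}
    while remaining:
        if not selected:
            crit = dict(rel)
        else:
            crit = {}
            for j in remaining:
                red = np.mean([
                    mutual_information(cols[j], cols[g]) for g in selected
                ])
                if variant == "MID":
                    crit[j] = rel[j] - red
                else:
                    crit[j] = rel[j] / max(red, 1e-12)
        best = min(remaining, key=lambda j: (-crit[j], j))
        selected.append(best)
        remaining.remove(best)
    return selected
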