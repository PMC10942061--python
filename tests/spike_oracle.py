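"""Independent brute-force spike caller used as the test oracle.

Written as plain index-by-index enumeration, deliberately sharing no code
with the package implementation: every index is visited, peaks and troughs
are classified with explicit loops, and both qualifying criteria are tested
directly from their definitions.
"""

from __future__ import annotations


def pct_change(prev: float, cur: float) -> float:
    if prev == 0:
        return float("inf") if cur > 0 else 0.0
    return 100.0 * (cur - prev) / prev


def is_peak_start(v, t) -> bool:
    """True when t is the first index of a maximal equal-value run that sits
    strictly above both flanks (interior peaks only)."""
    n = len(v)
    if t <= 0 or t >= n - 1:
        return False
    if v[t] <= v[t - 1]:
        return False
    j = t
    while j + 1 < n and v[j + 1] == v[t]:
        j += 1
    return j < n - 1 and v[t] > v[j + 1]


def is_trough_start(v, t) -> bool:
    n = len(v)
    if t <= 0 or t >= n - 1:
        return False
    if v[t] >= v[t - 1]:
        return False
    j = t
    while j + 1 < n and v[j + 1] == v[t]:
        j += 1
    return j < n - 1 and v[t] < v[j + 1]


def oracle_spikes(v, threshold_pct: float):
    """Return [(peak_index, rule, magnitude_pct), ...] for one trace."""
    v = list(map(float, v))
    n = len(v)
    peaks = [t for t in range(n) if is_peak_start(v, t)]
    if n >= 2 and v[-1] > v[-2]:
        peaks.append(n - 1)
    troughs = [t for t in range(n) if is_trough_start(v, t)]

    out = []
    for t in peaks:
        step = pct_change(v[t - 1], v[t])
        if step >= threshold_pct:
            out.append((t, "single_step", step))
            continue
        start = 0
        for m in troughs:
            if m < t:
                start = m
        cum = 0.0
        for s in range(start + 1, t + 1):
            cum += pct_change(v[s - 1], v[s])
        if cum >= threshold_pct:
            out.append((t, "cumulative", cum))
    return out
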