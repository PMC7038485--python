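"""Independent naive reference implementations of the 53 features.

Written with plain Python loops and the statistics module, deliberately
sharing no code with the package: these are the oracles the optimized
implementations are checked against (1e-9 relative tolerance).
"""

import math
from statistics import median


def _sign(d):
    return (d > 0) - (d < 0)


def naive_runs(xs):
    """(sign, start_idx, end_idx) triples of maximal monotone stretches."""
    diffs = [xs[i + 1] - xs[i] for i in range(len(xs) - 1)]
    segs = []
    start = 0
    for i in range(1, len(diffs) + 1):
        if i == len(diffs) or _sign(diffs[i]) != _sign(diffs[start]):
            segs.append((_sign(diffs[start]), start, i))
            start = i
    return segs


def naive_five(vals):
    """max/min/median/mean/population-std of a list; zeros when empty."""
    if not vals:
        return {"max": 0.0, "min": 0.0, "median": 0.0, "mean": 0.0, "std": 0.0}
    m = sum(vals) / len(vals)
    return {
        "max": max(vals),
        "min": min(vals),
        "median": float(median(vals)),
        "mean": m,
        "std": math.sqrt(sum((v - m) ** 2 for v in vals) / len(vals)),
    }


def naive_entropy(xs, log_base=2.0):
    counts = {}
    for x in xs:
        key = round(float(x))
        counts[key] = counts.get(key, 0) + 1
    n = len(xs)
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * math.log(p)
    return h / math.log(log_base)


def naive_mean_diff(diffs, absolute):
    vals = [abs(d) for d in diffs] if absolute else list(diffs)
    return sum(vals) / len(vals)


def naive_original_features(xs, dt=1.0, diff_absolute=True, log_base=2.0):
    """The 22 original-signal features from a plain list of BPM values."""
    n = len(xs)
    d1 = [xs[i + 1] - xs[i] for i in range(n - 1)]
    d2 = [xs[i + 2] - xs[i] for i in range(n - 2)]
    out = {
        "rate_diff1_mean": naive_mean_diff(d1, diff_absolute),
        "rate_diff2_mean": naive_mean_diff(d2, diff_absolute),
        "rate_range": max(xs) - min(xs),
        "rate_data_entropy": naive_entropy(xs, log_base),
        "max_ratio": max(xs) / n,
        "min_ratio": min(xs) / n,
        "rate_adjacent_data_root_mean": math.sqrt(
            sum(d * d for d in d1) / len(d1)
        ),
    }
    segs = naive_runs(xs)
    for sign, prefix in ((-1, "rate_down_time"), (1, "rate_up_time"),
                         (0, "rate_time_continue")):
        durations = [(b - a) * dt for s, a, b in segs if s == sign]
        for stat, value in naive_five(durations).items():
            out[f"{prefix}_{stat}"] = value
    return out


def naive_normalized_features(norm, dt=1.0, diff_absolute=True, window=25):
    """The 31 normalized-signal features from a plain list of BPM deltas."""
    n = len(norm)
    segs = naive_runs(norm)
    down = [(a, b) for s, a, b in segs if s == -1]
    up = [(a, b) for s, a, b in segs if s == 1]
    down_amp = [abs(norm[b] - norm[a]) for a, b in down]
    down_slope = [abs(norm[b] - norm[a]) / ((b - a) * dt) for a, b in down]
    up_amp = [norm[b] - norm[a] for a, b in up]
    ma = [sum(norm[i:i + window]) / window for i in range(n - window + 1)]
    d1 = [norm[i + 1] - norm[i] for i in range(n - 1)]
    d2 = [norm[i + 2] - norm[i] for i in range(n - 2)]
    mean = sum(norm) / n
    out = {}
    for stat, value in naive_five(down_slope).items():
        out[f"rate_down_slope_{stat}"] = value
    for stat, value in naive_five(up_amp).items():
        if stat != "min":
            out[f"rate_up_amplitude_{stat}"] = value
    for stat, value in naive_five(down_amp).items():
        out[f"rate_down_amplitude_{stat}"] = value
    for stat, value in naive_five(ma).items():
        out[f"25_mean_{stat}"] = value
    out["rate_data_mean"] = mean
    out["rate_data_var"] = sum((v - mean) ** 2 for v in norm) / (n - 1)
    for diffs, prefix in ((d1, "rate_data_normalized_diff1"),
                          (d2, "rate_data_normalized_diff2")):
        for stat, value in naive_five(diffs).items():
            out[f"{prefix}_{stat}"] = value
        out[f"{prefix}_mean"] = naive_mean_diff(diffs, diff_absolute)
    return out


def naive_all_features(target, baseline, dt=1.0, diff_absolute=True,
                       log_base=2.0, window=25):
    """All 53 features of a target segment given its neutral baseline."""
    out = naive_original_features(target, dt, diff_absolute, log_base)
    norm = [v - baseline for v in target]
    out.update(naive_normalized_features(norm, dt, diff_absolute, window))
    return out
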