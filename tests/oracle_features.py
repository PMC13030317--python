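"""Independent brute-force oracle for the 81 expression-sequence features.

Deliberately written with plain Python loops and first-principles
definitions, sharing no code with the package implementation.
"""

import math

CLASSES = ["neutral", "smile", "frown", "raised_eyebrow"]
NONNEUTRAL = ["frown", "smile", "raised_eyebrow"]  # registry order for 3-packs


def runs_of(seq):
    out = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        out.append((seq[i], j - i))
        i = j
    return out


def pop_std(values):
    n = len(values)
    mu = sum(values) / n
    return math.sqrt(sum((v - mu) ** 2 for v in values) / n)


def median(values):
    v = sorted(values)
    n = len(v)
    return v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2


def oracle_features(seq):
    seq = list(seq)
    T = len(seq)
    out = {}
    for c in CLASSES:
        cnt = sum(1 for s in seq if s == c)
        out[f"count_{c}"] = float(cnt)
        out[f"ratio_{c}"] = cnt / T
    out["total_frames"] = float(T)

    # transitions over adjacent ordered pairs
    for a in CLASSES:
        for b in CLASSES:
            out[f"trans_count_{a}_to_{b}"] = float(
                sum(1 for i in range(T - 1) if seq[i] == a and seq[i + 1] == b)
            )
    for a in CLASSES:
        row = sum(out[f"trans_count_{a}_to_{b}"] for b in CLASSES)
        for b in CLASSES:
            out[f"trans_prob_{a}_to_{b}"] = (
                out[f"trans_count_{a}_to_{b}"] / row if row > 0 else 0.0
            )
    for c in ("frown", "smile", "raised_eyebrow"):
        out[f"neutral_to_{c}"] = out[f"trans_count_neutral_to_{c}"]

    # bursts
    runs = runs_of(seq)
    for c in CLASSES:
        lens = [ln for lbl, ln in runs if lbl == c]
        if lens:
            out[f"burst_{c}_count"] = float(len(lens))
            out[f"burst_{c}_mean"] = sum(lens) / len(lens)
            out[f"burst_{c}_median"] = float(median(lens))
            out[f"burst_{c}_min"] = float(min(lens))
            out[f"burst_{c}_max"] = float(max(lens))
            out[f"burst_{c}_std"] = pop_std(lens)
        else:
            for s in ("count", "mean", "median", "min", "max", "std"):
                out[f"burst_{c}_{s}"] = 0.0
    for c in ("frown", "smile", "raised_eyebrow"):
        out[f"avg_burst_{c}"] = out[f"burst_{c}_mean"]

    # entropy
    h = 0.0
    for c in CLASSES:
        p = out[f"ratio_{c}"]
        if p > 0:
            h -= p * math.log2(p)
    out["entropy"] = h
    out["entropy_norm"] = h / 2.0

    # dynamics
    sw = sum(1 for i in range(T - 1) if seq[i] != seq[i + 1])
    out["switches"] = float(sw)
    out["switch_rate"] = sw / (T - 1) if T >= 2 else 0.0
    out["persistence"] = T / len(runs)

    # dominance / inequality over non-neutral proportions
    p = [out[f"ratio_{c}"] for c in ("smile", "frown", "raised_eyebrow")]
    tot = sum(p)
    if tot == 0:
        out["dominance"] = 0.0
        out["gini_inequality"] = 0.0
    else:
        out["dominance"] = max(p) / tot
        out["gini_inequality"] = sum(
            abs(pi - pj) for pi in p for pj in p
        ) / (2 * 3 * tot)

    # latency after neutral
    for c in ("frown", "smile", "raised_eyebrow"):
        lat = 1.0
        for i in range(T):
            if seq[i] == c and any(seq[j] == "neutral" for j in range(i)):
                lat = i / T
                break
        out[f"latency_{c}"] = lat
    return out
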