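"""Expression-dynamics features of a categorical label sequence.

One participant x scene expression sequence (one label per retained window)
is summarized by 81 named scalar features covering static prevalence and
temporal organisation:

=========================  =====
ratios                     4
counts (+ total frames)    5
neutral -> X transitions   3
average burst lengths      3
entropy (raw, normalized)  2
sequence dynamics          3
dominance / inequality     2
latency after neutral      3
transition counts 4x4      16
transition probabilities   16
burst statistics 4x6       24
=========================  =====

A *burst* is a maximal run of identical consecutive labels; the minimum
burst length is one window.  Empty-class conventions keep every vector
finite: descriptors of a class that never occurs are 0, dominance and the
Gini-like inequality are 0 when no non-neutral frame exists, and latency
uses the sentinel 1.0.  Burst-length standard deviations use the population
convention (divide by n), so a single run yields 0.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np

from .types import LABEL_NAMES, LABEL_TO_ID, N_CLASSES, NON_NEUTRAL

_BURST_STATS = ("count", "mean", "median", "min", "max", "std")


def _build_feature_names() -> list[str]:
    names: list[str] = []
    names += [f"ratio_{c}" for c in LABEL_NAMES]
    names += [f"count_{c}" for c in LABEL_NAMES]
    names.append("total_frames")
    names += [f"neutral_to_{c}" for c in ("frown", "smile", "raised_eyebrow")]
    names += [f"avg_burst_{c}" for c in ("frown", "smile", "raised_eyebrow")]
    names += ["entropy", "entropy_norm"]
    names += ["switches", "switch_rate", "persistence"]
    names += ["dominance", "gini_inequality"]
    names += [f"latency_{c}" for c in ("frown", "smile", "raised_eyebrow")]
    names += [f"trans_count_{a}_to_{b}" for a in LABEL_NAMES for b in LABEL_NAMES]
    names += [f"trans_prob_{a}_to_{b}" for a in LABEL_NAMES for b in LABEL_NAMES]
    names += [f"burst_{c}_{s}" for c in LABEL_NAMES for s in _BURST_STATS]
    return names


#: Fixed, versioned registry of the 81 feature names (order defines vectors).
FEATURE_NAMES: tuple[str, ...] = tuple(_build_feature_names())

assert len(FEATURE_NAMES) == 81


def feature_registry() -> list[dict[str, str]]:
    """Machine-readable registry: name, category and a short definition."""
    cats: list[tuple[str, str, str]] = []
    for name in FEATURE_NAMES:
        if name.startswith("ratio_"):
            cats.append((name, "ratios", "proportion of windows in this state"))
        elif name.startswith("count_") or name == "total_frames":
            cats.append((name, "counts", "number of windows (frames) in this state"))
        elif name.startswith("neutral_to_"):
            cats.append((name, "neutral_transitions", "count of neutral -> state transitions"))
        elif name.startswith("avg_burst_"):
            cats.append((name, "average_burst_lengths", "mean run length of this state"))
        elif name.startswith("entropy"):
            cats.append((name, "entropy", "Shannon entropy of the 4-class distribution (bits)"))
        elif name in ("switches", "switch_rate", "persistence"):
            cats.append((name, "sequence_dynamics", "global temporal dynamics of the sequence"))
        elif name in ("dominance", "gini_inequality"):
            cats.append((name, "dominance_balance", "balance of non-neutral expression mass"))
        elif name.startswith("latency_"):
            cats.append((name, "latency", "relative index of first occurrence after neutral"))
        elif name.startswith("trans_count_"):
            cats.append((name, "transition_counts", "count of this ordered adjacent pair"))
        elif name.startswith("trans_prob_"):
            cats.append((name, "transition_probabilities", "row-normalized transition probability"))
        else:
            cats.append((name, "burst_statistics", "run-length distribution descriptor"))
    return [{"name": n, "category": c, "definition": d} for n, c, d in cats]


def _as_ids(seq: Sequence[str] | np.ndarray) -> np.ndarray:
    if isinstance(seq, np.ndarray) and np.issubdtype(seq.dtype, np.integer):
        ids = seq.astype(np.int64)
        if ids.size and (ids.min() < 0 or ids.max() >= N_CLASSES):
            raise ValueError("label ids out of range")
        return ids
    return np.array([LABEL_TO_ID[str(lbl)] for lbl in seq], dtype=np.int64)


def _runs(ids: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of identical consecutive labels as (class_id, length)."""
    if ids.size == 0:
        return []
    change = np.flatnonzero(np.diff(ids)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [ids.size]))
    return [(int(ids[s]), int(e - s)) for s, e in zip(starts, ends)]


def compute_ratios_counts(seq: Sequence[str] | np.ndarray) -> dict[str, float]:
    """Per-class frame counts, total frames T, and occupancy ratios."""
    ids = _as_ids(seq)
    T = ids.size
    if T == 0:
        raise ValueError("empty sequence")
    counts = np.bincount(ids, minlength=N_CLASSES)
    out: dict[str, float] = {}
    for c, name in enumerate(LABEL_NAMES):
        out[f"ratio_{name}"] = counts[c] / T
        out[f"count_{name}"] = float(counts[c])
    out["total_frames"] = float(T)
    return out


def compute_transition_matrix(
    seq: Sequence[str] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Adjacent-pair transition counts (including self-transitions), the
    row-normalized probability matrix (all-zero rows stay zero), and the
    three neutral -> non-neutral counts."""
    ids = _as_ids(seq)
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=float)
    if ids.size >= 2:
        np.add.at(counts, (ids[:-1], ids[1:]), 1.0)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row_sums > 0, counts / np.where(row_sums == 0, 1, row_sums), 0.0)
    n2x = {
        f"neutral_to_{name}": counts[LABEL_TO_ID["neutral"], LABEL_TO_ID[name]]
        for name in ("frown", "smile", "raised_eyebrow")
    }
    return counts, probs, n2x


def compute_burst_statistics(seq: Sequence[str] | np.ndarray) -> dict[str, float]:
    """Run-length descriptors per class plus the three non-neutral average
    burst lengths.  Classes with no runs get all-zero descriptors."""
    ids = _as_ids(seq)
    if ids.size == 0:
        raise ValueError("empty sequence")
    per_class: dict[int, list[int]] = {c: [] for c in range(N_CLASSES)}
    for c, length in _runs(ids):
        per_class[c].append(length)
    out: dict[str, float] = {}
    for c, name in enumerate(LABEL_NAMES):
        lens = np.asarray(per_class[c], dtype=float)
        if lens.size == 0:
            stats = dict.fromkeys(_BURST_STATS, 0.0)
        else:
            stats = {
                "count": float(lens.size),
                "mean": float(lens.mean()),
                "median": float(np.median(lens)),
                "min": float(lens.min()),
                "max": float(lens.max()),
                "std": float(lens.std()),  # population convention
            }
        for s in _BURST_STATS:
            out[f"burst_{name}_{s}"] = stats[s]
    for name in ("frown", "smile", "raised_eyebrow"):
        out[f"avg_burst_{name}"] = out[f"burst_{name}_mean"]
    return out


def compute_entropy(seq: Sequence[str] | np.ndarray) -> tuple[float, float]:
    """Shannon entropy (bits) of the empirical 4-class distribution, with
    0*log0 = 0, and its normalized form H / log2(4)."""
    ids = _as_ids(seq)
    if ids.size == 0:
        raise ValueError("empty sequence")
    p = np.bincount(ids, minlength=N_CLASSES) / ids.size
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    return h, h / math.log2(N_CLASSES)


def compute_dynamics(seq: Sequence[str] | np.ndarray) -> tuple[float, float, float]:
    """(switches, switch_rate, persistence).

    switches counts adjacent label changes; switch_rate divides by T-1 (0 for
    T=1); persistence is the global mean run length T / #runs.
    """
    ids = _as_ids(seq)
    T = ids.size
    if T == 0:
        raise ValueError("empty sequence")
    switches = int(np.count_nonzero(ids[:-1] != ids[1:]))
    rate = switches / (T - 1) if T >= 2 else 0.0
    persistence = T / (switches + 1)
    return float(switches), float(rate), float(persistence)


def compute_dominance(seq: Sequence[str] | np.ndarray) -> tuple[float, float]:
    """Dominance and Gini-like inequality of the three non-neutral occupancy
    proportions; both 0 by convention when no non-neutral frame exists.
    The inequality index lies in [0, 2/3]."""
    ids = _as_ids(seq)
    if ids.size == 0:
        raise ValueError("empty sequence")
    p = np.bincount(ids, minlength=N_CLASSES)[1:] / ids.size
    total = p.sum()
    if total == 0:
        return 0.0, 0.0
    dominance = float(p.max() / total)
    gini = float(np.abs(p[:, None] - p[None, :]).sum() / (2 * p.size * total))
    return dominance, gini


def compute_latency(seq: Sequence[str] | np.ndarray) -> dict[str, float]:
    """Relative index (index / T) of the first window of each non-neutral
    class that is preceded anywhere earlier by a neutral window; sentinel 1.0
    when no qualifying occurrence exists."""
    ids = _as_ids(seq)
    T = ids.size
    if T == 0:
        raise ValueError("empty sequence")
    neutral_seen = np.concatenate(([False], np.cumsum(ids == 0)[:-1] > 0))
    out: dict[str, float] = {}
    for name in ("frown", "smile", "raised_eyebrow"):
        c = LABEL_TO_ID[name]
        idx = np.flatnonzero((ids == c) & neutral_seen)
        out[f"latency_{name}"] = float(idx[0] / T) if idx.size else 1.0
    return out


def compute_feature_vector(seq: Sequence[str] | np.ndarray) -> dict[str, float]:
    """All 81 features of one expression sequence, keyed by FEATURE_NAMES."""
    ids = _as_ids(seq)
    if ids.size == 0:
        raise ValueError("empty sequence")
    out = compute_ratios_counts(ids)
    counts, probs, n2x = compute_transition_matrix(ids)
    out.update(n2x)
    for a, an in enumerate(LABEL_NAMES):
        for b, bn in enumerate(LABEL_NAMES):
            out[f"trans_count_{an}_to_{bn}"] = float(counts[a, b])
            out[f"trans_prob_{an}_to_{bn}"] = float(probs[a, b])
    out.update(compute_burst_statistics(ids))
    h, hn = compute_entropy(ids)
    out["entropy"], out["entropy_norm"] = h, hn
    sw, rate, pers = compute_dynamics(ids)
    out["switches"], out["switch_rate"], out["persistence"] = sw, rate, pers
    dom, gini = compute_dominance(ids)
    out["dominance"], out["gini_inequality"] = dom, gini
    out.update(compute_latency(ids))
    vec = {name: float(out[name]) for name in FEATURE_NAMES}
    return vec


def feature_vector_array(seq: Sequence[str] | np.ndarray) -> np.ndarray:
    """The 81-vector as a numpy array in FEATURE_NAMES order."""
    vec = compute_feature_vector(seq)
    return np.array([vec[name] for name in FEATURE_NAMES], dtype=float)
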