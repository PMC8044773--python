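"""Independent brute-force oracles used to check the statistical primitives.

Each function here is a deliberately naive re-derivation (explicit loops,
closed-form textbook formulas) kept separate from the package's own code
paths so agreement between the two is meaningful evidence.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from scipy import stats


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up by the definition: q(i) = min_{j≥i} p_(j)·m/j."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def pooled_t_p(a, b) -> float:
    """Two-sided pooled-variance two-sample t-test from the textbook formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * stats.t.sf(abs(t), na + nb - 2)


def welch_t_p(a, b) -> float:
    """Two-sided Welch t-test with Welch–Satterthwaite degrees of freedom."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return 2 * stats.t.sf(abs(t), df)


def plugin_mi_bits(x_codes, y_codes) -> float:
    """Plug-in discrete MI in bits by direct summation over the joint table."""
    x_codes, y_codes = list(x_codes), list(y_codes)
    n = len(x_codes)
    joint = Counter(zip(x_codes, y_codes))
    px = Counter(x_codes)
    py = Counter(y_codes)
    total = 0.0
    for (xv, yv), c in joint.items():
        pxy = c / n
        total += pxy * math.log2(pxy / ((px[xv] / n) * (py[yv] / n)))
    return total


def pair_counting_auc(scores, truth) -> float:
    """AUC by exhaustive enumeration of positive–negative pairs (ties → 1/2)."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, int)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def confusion_metrics(tp, fp, tn, fn) -> dict[str, float]:
    """Accuracy/precision/recall/F1 straight from the defining ratios."""
    total = tp + fp + tn + fn
    acc = (tp + tn) / total
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}
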