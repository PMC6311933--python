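"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own vectorized code paths:
everything is explicit Python loops over definitions.
"""

from __future__ import annotations

import math

import numpy as np

_ONE_HOT = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "C": (0.0, 1.0, 0.0, 0.0),
    "G": (0.0, 0.0, 1.0, 0.0),
    "U": (0.0, 0.0, 0.0, 1.0),
    "N": (0.0, 0.0, 0.0, 0.0),
}


def brute_force_motifs(
    filters: np.ndarray,
    biases: np.ndarray,
    sequences: list[str],
    activation_fraction: float = 0.0,
):
    """Scan-accumulate-normalize re-implementation of filter->PWM.

    `filters`: (K, 4, l); activation = ReLU(conv) with symmetric zero
    padding of floor(l/2).  Returns (cumulative, pwm_or_None, support)
    per filter.
    """
    n_filters, _, flen = filters.shape
    pad = flen // 2
    results = []
    # pass 1: per-filter global max activation
    all_alphas = [[] for _ in range(n_filters)]
    all_positions = [[] for _ in range(n_filters)]
    padded_seqs = []
    for seq in sequences:
        cols = [(0.0, 0.0, 0.0, 0.0)] * pad
        cols += [_ONE_HOT[b] for b in seq]
        cols += [(0.0, 0.0, 0.0, 0.0)] * pad
        padded_seqs.append(cols)
        for k in range(n_filters):
            best_alpha, best_pos = -math.inf, 0
            for start in range(len(cols) - flen + 1):
                total = biases[k]
                for offset in range(flen):
                    for channel in range(4):
                        total += (
                            filters[k, channel, offset]
                            * cols[start + offset][channel]
                        )
                activation = max(total, 0.0)
                if activation > best_alpha:
                    best_alpha, best_pos = activation, start
            all_alphas[k].append(best_alpha)
            all_positions[k].append(best_pos)
    for k in range(n_filters):
        global_max = max(all_alphas[k]) if all_alphas[k] else 0.0
        cutoff = activation_fraction * global_max
        cumulative = np.zeros((flen, 4))
        support = 0
        for i, cols in enumerate(padded_seqs):
            alpha = all_alphas[k][i]
            if alpha <= 0 or alpha < cutoff:
                continue
            start = all_positions[k][i]
            for offset in range(flen):
                for channel in range(4):
                    cumulative[offset, channel] += (
                        alpha * cols[start + offset][channel]
                    )
            support += 1
        if support == 0:
            pwm = None
        else:
            pwm = np.zeros((flen, 4))
            for row in range(flen):
                total = cumulative[row].sum()
                pwm[row] = cumulative[row] / total if total > 0 else 0.25
        results.append((cumulative, pwm, support))
    return results


def mann_whitney_auroc(scores, labels) -> float:
    """AUROC as the pairwise probability P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def metric_formulas(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Direct transcription of the five printed metric formulas."""
    out = {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan"),
    }
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    out["mcc"] = (tp * tn - fp * fn) / den if den else 0.0
    return out
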