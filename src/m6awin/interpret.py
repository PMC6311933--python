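"""Model introspection: filter-to-motif conversion and saliency maps.

Motifs: for every first-layer filter, the maximally activating
subsequence of each positive sequence is extracted as a one-hot matrix,
weighted by its post-ReLU activation, accumulated, and row-normalized
into a PWM.

Saliency: the gradient of the positive-class logit with respect to the
one-hot input, taken elementwise-absolute and masked by the input, gives
one nonnegative score per position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .encode import encode_batch, pad_width
from .model import SequenceClassifier


@dataclass
class LearnedMotif:
    filter_index: int
    filter_length: int
    cumulative: np.ndarray  # (l, 4), activation-weighted one-hot sum
    pwm: np.ndarray | None  # (l, 4) row-stochastic; None when support == 0
    support: int


@dataclass
class SaliencyTrack:
    window_id: str
    sequence: str
    scores: np.ndarray  # (L,) nonnegative
    class_score: float  # pre-sigmoid logit
    gradient: np.ndarray  # (4, L), pad columns stripped
    site_offsets: list[int] = field(default_factory=list)


def filters_to_motifs(
    model: SequenceClassifier,
    positive_sequences: list[str],
    activation_fraction: float = 0.0,
) -> list[LearnedMotif]:
    """Convert first-layer filters to PWMs over `positive_sequences`.

    For filter k and sequence i, the position with maximal post-ReLU
    activation contributes ``alpha * one_hot_subsequence`` to the
    cumulative matrix when alpha > 0.  Subsequence columns that fall in
    the zero pad contribute zero rows and stay in the normalization.
    Filters never active on any sequence get support 0 and pwm None.

    `activation_fraction` optionally raises the contribution cutoff to
    that fraction of the filter's maximal activation over the whole
    sequence set (0.5 is the usual convention for selecting selective
    filters; batch-normalized models activate nearly everywhere, so the
    default alpha > 0 rule makes support saturate at n).
    """
    if not positive_sequences:
        raise ValueError("no sequences supplied")
    if not 0.0 <= activation_fraction < 1.0:
        raise ValueError("activation_fraction must be in [0, 1)")
    f1 = model.config.filter_sizes[0]
    pad = pad_width(f1)
    activations = model.first_layer_activations(positive_sequences)
    encoded, lengths = encode_batch(positive_sequences, f1)
    n_filters = activations.shape[1]
    motifs: list[LearnedMotif] = []
    for k in range(n_filters):
        cumulative = np.zeros((f1, 4))
        support = 0
        global_max = float(activations[:, k, :].max())
        cutoff = activation_fraction * global_max
        for i in range(len(positive_sequences)):
            t_valid = lengths[i] + 2 * pad - f1 + 1
            row = activations[i, k, :t_valid]
            pos = int(row.argmax())
            alpha = float(row[pos])
            if alpha <= 0 or alpha < cutoff:
                continue
            subseq = encoded[i, :, pos : pos + f1].T  # (l, 4)
            cumulative += alpha * subseq
            support += 1
        if support == 0:
            pwm = None
        else:
            row_sums = cumulative.sum(axis=1, keepdims=True)
            pwm = np.where(row_sums > 0, cumulative / np.where(row_sums > 0,
                                                               row_sums, 1.0),
                           0.25)
        motifs.append(
            LearnedMotif(
                filter_index=k,
                filter_length=f1,
                cumulative=cumulative,
                pwm=pwm,
                support=support,
            )
        )
    return motifs


def information_content(pwm: np.ndarray) -> float:
    """Total information content of a row-stochastic PWM, in bits."""
    p = np.clip(np.asarray(pwm, dtype=float), 1e-12, 1.0)
    return float((2.0 + (p * np.log2(p)).sum(axis=1)).sum())


def rank_motifs(
    motifs: list[LearnedMotif], by: str = "support"
) -> list[LearnedMotif]:
    """Rank supported motifs, best first.

    ``by="support"``: contributing-sequence count.  ``by="information"``:
    PWM information content — the useful ranking for batch-normalized
    models, where nearly every filter activates on every sequence and
    support saturates while only committed filters build sharp PWMs.
    """
    supported = [m for m in motifs if m.pwm is not None and m.support > 0]
    if by == "support":
        return sorted(supported, key=lambda m: m.support, reverse=True)
    if by == "information":
        return sorted(
            supported, key=lambda m: information_content(m.pwm), reverse=True
        )
    raise ValueError("by must be 'support' or 'information'")


def saliency(
    model: SequenceClassifier,
    sequence: str,
    window_id: str = "window",
    site_offsets: list[int] | None = None,
) -> SaliencyTrack:
    """Per-position saliency of `sequence` under `model`.

    score[j] = |d logit / d x[:, j]| at the observed base; positions with
    N (all-zero one-hot column) score 0.  Pad columns are dropped.
    """
    logit, grad = model.logit_and_input_gradient(sequence)
    pad = pad_width(model.config.filter_sizes[0])
    core_grad = grad[:, pad : pad + len(sequence)]
    x, _ = encode_batch([sequence], model.config.filter_sizes[0])
    core_x = x[0, :, pad : pad + len(sequence)]
    scores = (np.abs(core_grad) * core_x).sum(axis=0)
    return SaliencyTrack(
        window_id=window_id,
        sequence=sequence,
        scores=scores,
        class_score=logit,
        gradient=core_grad,
        site_offsets=list(site_offsets or []),
    )


def most_salient_nucleotide(track: SaliencyTrack):
    """(position, base, score) of the saliency argmax; leftmost on ties.

    Returns None for an all-zero track.
    """
    if track.scores.size == 0 or not np.any(track.scores > 0):
        return None
    pos = int(track.scores.argmax())
    return pos, track.sequence[pos], float(track.scores[pos])


def site_saliency_percentile(
    track: SaliencyTrack, site_offsets: list[int]
) -> list[tuple[int, float, bool]]:
    """Mid-rank percentile of each site's score among all A positions.

    percentile = (#A-scores strictly below + 0.5 * #ties incl. self) / #A,
    in [0, 1].  A site not on an A is computed among ALL positions
    instead and flagged True (with a warning).
    """
    a_positions = [i for i, b in enumerate(track.sequence) if b == "A"]
    results = []
    for off in site_offsets:
        if not 0 <= off < len(track.sequence):
            raise ValueError(f"site offset {off} outside window")
        flagged = track.sequence[off] != "A"
        if flagged:
            warnings.warn(
                f"{track.window_id}: site at offset {off} is "
                f"{track.sequence[off]!r}, not A; percentile computed "
                "among all positions"
            )
            pool = track.scores
        else:
            pool = track.scores[a_positions]
        score = track.scores[off]
        below = float(np.sum(pool < score))
        ties = float(np.sum(pool == score))
        results.append((off, (below + 0.5 * ties) / len(pool), flagged))
    return results


def distance_to_nearest_site(position: int, site_offsets: list[int]):
    """Signed distance (position - nearest site); exact ties go negative.

    Returns None when no sites are given.
    """
    if not site_offsets:
        return None
    best = None
    for site in site_offsets:
        d = position - site
        if best is None or abs(d) < abs(best) or (abs(d) == abs(best) and d < best):
            best = d
    return best
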