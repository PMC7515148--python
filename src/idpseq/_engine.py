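"""Vectorized numeric cores shared by the predictor and permutation machinery.

Sequences are encoded as integer index arrays over the fixed alphabet and all
per-residue computations operate on ``(n_sequences, length)`` batches, so that
the permutation experiment can score hundreds of shuffles of a sequence in one
pass.  The public module APIs wrap these cores with single-row batches, which
guarantees that batched and scalar results are bit-identical.

Label encoding: H=0, E=1, C=2 throughout.
"""

from __future__ import annotations

import numpy as np

from .seqio import AMINO_ACIDS

SS_LABELS = "HEC"

_ENCODE_LUT = np.full(128, -1, dtype=np.int64)
for _i, _aa in enumerate(AMINO_ACIDS):
    _ENCODE_LUT[ord(_aa)] = _i


def encode(sequence: str) -> np.ndarray:
    """Encode a residue string as alphabet indices (int64)."""
    idx = _ENCODE_LUT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (idx < 0).any():
        bad = int(np.argmax(idx < 0))
        raise ValueError(
            f"non-standard residue {sequence[bad]!r} at position {bad + 1}"
        )
    return idx


def decode_labels(labels: np.ndarray) -> str:
    """Render an int label vector (H=0, E=1, C=2) as a string."""
    return "".join(SS_LABELS[i] for i in labels)


def window_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean along the last axis, truncated at the termini.

    `values` has shape (..., L); windows near either end shrink to the
    in-range positions instead of padding.
    """
    half = window // 2
    length = values.shape[-1]
    cs = np.concatenate(
        [np.zeros(values.shape[:-1] + (1,), dtype=float), np.cumsum(values, axis=-1)],
        axis=-1,
    )
    idx = np.arange(length)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, length)
    return (np.take(cs, hi, axis=-1) - np.take(cs, lo, axis=-1)) / (hi - lo)


def argmax_label(scores: np.ndarray) -> np.ndarray:
    """Per-position label from (..., 3) class scores; ties resolve C, then H, then E.

    Coil is the unconditional fallback state, so it wins all ties it is part
    of; between helix and sheet, helix wins.
    """
    s_h, s_e, s_c = scores[..., 0], scores[..., 1], scores[..., 2]
    labels = np.full(s_h.shape, 2, dtype=np.int64)  # C
    h_wins = (s_h > s_c) & (s_h >= s_e)
    e_wins = (s_e > s_c) & (s_e > s_h)
    labels[h_wins] = 0
    labels[e_wins] = 1
    return labels


def propensity_labels(batch: np.ndarray, scale: np.ndarray, window: int) -> np.ndarray:
    """Windowed-propensity prediction for an (m, L) batch.

    `scale` is a (20, 3) table of per-residue (H, E, C) propensities; each
    channel is averaged over the centered window and the per-position label is
    the tie-broken argmax.
    """
    per_residue = scale[batch]  # (m, L, 3)
    means = window_mean(np.moveaxis(per_residue, -1, -2), window)  # (m, 3, L)
    return argmax_label(np.moveaxis(means, -2, -1))


def gor_labels(batch: np.ndarray, info: np.ndarray) -> np.ndarray:
    """GOR-style prediction for an (m, L) batch.

    `info` is a (3, window, 20) table of information values; the score of
    class s at position i sums ``info[s, d, residue(i+d)]`` over in-range
    window offsets d.
    """
    n_class, window, _ = info.shape
    half = window // 2
    m, length = batch.shape
    scores = np.zeros((m, length, n_class), dtype=float)
    for d_idx in range(window):
        offset = d_idx - half
        src_lo = max(0, offset)
        src_hi = min(length, length + offset)
        if src_lo >= src_hi:
            continue
        dst_lo = src_lo - offset
        dst_hi = src_hi - offset
        contrib = info[:, d_idx, :][:, batch[:, src_lo:src_hi]]  # (3, m, span)
        scores[:, dst_lo:dst_hi, :] += np.moveaxis(contrib, 0, -1)
    return argmax_label(scores)


def consensus_labels(tracks: np.ndarray, priority_order: np.ndarray) -> np.ndarray:
    """Majority-vote consensus over a (k, ..., L) stack of label arrays.

    The most frequently voted label wins at each position.  When two or more
    labels tie for the maximum count, the winner is the vote of the
    highest-priority predictor among those voting for a tied label.
    `priority_order` gives track indices from highest to lowest priority.
    """
    counts = np.stack([(tracks == lab).sum(axis=0) for lab in range(3)], axis=-1)
    max_count = counts.max(axis=-1)
    tied = counts == max_count[..., None]  # (..., L, 3) labels at the top count
    out = np.full(tracks.shape[1:], -1, dtype=np.int64)
    unresolved = np.ones(tracks.shape[1:], dtype=bool)
    for track_idx in priority_order:
        vote = tracks[track_idx]
        vote_is_tied = np.take_along_axis(tied, vote[..., None], axis=-1)[..., 0]
        take = unresolved & vote_is_tied
        out[take] = vote[take]
        unresolved &= ~take
        if not unresolved.any():
            break
    return out


def aggregation_prone_mask(batch: np.ndarray, scale: np.ndarray,
                           window: int, threshold: float) -> np.ndarray:
    """Boolean (m, L) mask of residues inside >=1 aggregation-prone window.

    Windows are the full-length sliding windows of size `window`; a window is
    prone when its mean scale value reaches `threshold`.  Sequences shorter
    than the window are scored from the single whole-sequence window.
    """
    values = scale[batch]  # (m, L)
    m, length = values.shape
    eff_window = min(window, length)
    cs = np.concatenate([np.zeros((m, 1)), np.cumsum(values, axis=1)], axis=1)
    win_scores = (cs[:, eff_window:] - cs[:, :-eff_window]) / eff_window  # (m, L-w+1)
    prone_win = win_scores >= threshold
    # residue i is prone iff some prone window [j, j+w-1] covers it
    pw_cs = np.concatenate(
        [np.zeros((m, 1), dtype=np.int64), np.cumsum(prone_win, axis=1)], axis=1
    )
    n_win = prone_win.shape[1]
    idx = np.arange(length)
    lo = np.maximum(idx - eff_window + 1, 0)
    hi = np.minimum(idx + 1, n_win)
    covered = np.take(pw_cs, np.maximum(hi, lo), axis=1) - np.take(pw_cs, lo, axis=1)
    return covered > 0


def window_scores(batch: np.ndarray, scale: np.ndarray, window: int) -> np.ndarray:
    """Mean scale value of each full sliding window, shape (m, L - w + 1)."""
    values = scale[batch]
    m, length = values.shape
    eff_window = min(window, length)
    cs = np.concatenate([np.zeros((m, 1)), np.cumsum(values, axis=1)], axis=1)
    return (cs[:, eff_window:] - cs[:, :-eff_window]) / eff_window
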