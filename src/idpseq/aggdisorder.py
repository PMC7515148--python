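"""Aggregation-propensity scoring and the disorder index.

The built-in aggregation scorer slides a window over the sequence, averages a
per-residue scale (default: a hydrophobicity + beta-propensity composite
shipped with the package), marks every residue covered by at least one window
whose mean reaches the threshold as aggregation-prone, and reports the prone
fraction of the protein together with the maximal prone segments.  Externally
computed aggregation profiles can be supplied as score tracks and summarized
the same way.

The disorder index of a sequence (or a sub-region of it) is simply the mean of
a per-residue disorder track — in the original study, the mean of
consensus-disorder predictor scores over the annotated region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import _engine
from .seqio import AMINO_ACIDS, ScoreTrack, SequenceRecord

logger = logging.getLogger(__name__)

#: Defaults documented in the shipped scale file: 7-residue windows, and a
#: threshold calibrated once so that roughly 10% of residues of random
#: globular-composition sequences fall inside a prone window.
DEFAULT_WINDOW = 7
DEFAULT_THRESHOLD: float | None = None  # resolved lazily from the scale file


@dataclass(frozen=True)
class AggregationResult:
    """Aggregation summary for one protein."""

    id: str
    protein_score: float
    window_scores: list[float]
    prone_segments: list[tuple[int, int]]


@dataclass(frozen=True)
class DisorderIndex:
    """Mean per-residue disorder over a sequence region."""

    id: str
    value: float


def load_aggregation_scale(path: str | Path | None = None) -> tuple[dict[str, float], float]:
    """Load a residue -> scale table and its documented default threshold.

    Returns ``(scale, threshold)``; the threshold is parsed from a
    ``threshold=`` token in the file's comment header.
    """
    if path is None:
        source = resources.files("idpseq.data").joinpath("aggregation_scale.tsv")
        with resources.as_file(source) as p:
            return _parse_scale(p)
    return _parse_scale(Path(path))


def _parse_scale(path: Path) -> tuple[dict[str, float], float]:
    threshold = math.nan
    with open(path) as handle:
        for line in handle:
            if line.startswith("#") and "threshold=" in line:
                token = line.split("threshold=")[1].split(",")[0].split()[0]
                threshold = float(token)
    df = pd.read_csv(path, sep="\t", comment="#")
    scale = dict(zip(df["residue"], df["value"].astype(float)))
    missing = set(AMINO_ACIDS) - set(scale)
    if missing:
        raise ValueError(f"aggregation scale missing residues: {sorted(missing)}")
    return scale, threshold


def _scale_vector(scale: dict[str, float]) -> np.ndarray:
    missing = set(AMINO_ACIDS) - set(scale)
    if missing:
        raise ValueError(f"aggregation scale missing residues: {sorted(missing)}")
    return np.array([scale[aa] for aa in AMINO_ACIDS], dtype=float)


def _default_scale_threshold() -> tuple[np.ndarray, float]:
    global DEFAULT_THRESHOLD
    scale, threshold = load_aggregation_scale()
    if DEFAULT_THRESHOLD is None:
        DEFAULT_THRESHOLD = threshold
    return _scale_vector(scale), threshold


def aggregation_score(
    record: SequenceRecord,
    scale: dict[str, float] | None = None,
    window: int = DEFAULT_WINDOW,
    threshold: float | None = None,
) -> AggregationResult:
    """Windowed aggregation-propensity score of one protein.

    ``window_scores[i]`` is the mean scale value of residues ``i..i+window-1``
    (1-based window start ``i+1``); a residue is aggregation-prone when it lies
    in at least one window with score >= `threshold`; the protein score is the
    prone fraction of residues, and prone segments are the maximal runs of
    prone residues.  A sequence shorter than the window is scored from the
    single whole-sequence window (logged).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if scale is None:
        vec, default_threshold = _default_scale_threshold()
    else:
        vec = _scale_vector(scale)
        default_threshold = None
    if threshold is None:
        if default_threshold is None or math.isnan(default_threshold):
            raise ValueError("threshold required when a custom scale carries none")
        threshold = default_threshold
    if len(record) < window:
        logger.info(
            "record %r: length %d < window %d, scoring the whole-sequence window",
            record.id, len(record), window,
        )
    batch = _engine.encode(record.sequence)[None, :]
    win_scores = _engine.window_scores(batch, vec, window)[0]
    prone = _engine.aggregation_prone_mask(batch, vec, window, threshold)[0]
    segments: list[tuple[int, int]] = []
    start = None
    for pos, flag in enumerate(prone, start=1):
        if flag and start is None:
            start = pos
        elif not flag and start is not None:
            segments.append((start, pos - 1))
            start = None
    if start is not None:
        segments.append((start, len(prone)))
    return AggregationResult(
        id=record.id,
        protein_score=float(prone.mean()),
        window_scores=[float(s) for s in win_scores],
        prone_segments=segments,
    )


def disorder_index(track: ScoreTrack, region: tuple[int, int] | None = None) -> DisorderIndex:
    """Mean disorder score over `region` (1-based inclusive; whole track if absent)."""
    length = len(track)
    if region is None:
        start, end = 1, length
    else:
        start, end = region
        if not (1 <= start <= end <= length):
            raise ValueError(
                f"track {track.id!r}: region ({start}, {end}) invalid for length {length}"
            )
    values = track.values[start - 1 : end]
    if not values:
        raise ValueError(f"track {track.id!r}: empty region")
    if all(v == values[0] for v in values):
        return DisorderIndex(id=track.id, value=float(values[0]))  # exactly
    return DisorderIndex(id=track.id, value=float(np.mean(values)))
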