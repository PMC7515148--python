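"""Three-state secondary-structure prediction and majority-vote consensus.

The consensus scheme takes per-residue H/E/C tracks from an ensemble of
predictors and assigns, at each position, the most frequently predicted state;
when vote counts tie, the vote of the highest-priority predictor among those
voting for a tied state wins, with predictor priority given by the listed
order of the ensemble.

Two predictors are built in so the whole pipeline runs with no external
binaries: a windowed propensity-table predictor and a GOR-style predictor that
learns per-class information values for residues at window offsets from a
labeled corpus.  Outputs of external predictors enter through
:func:`read_external_track`, with 8-state labels reduced to 3 states by the
standard DSSP reduction (G,H,I -> H; E,B -> E; rest -> C).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from . import _engine
from ._engine import SS_LABELS
from .seqio import AMINO_ACIDS, SequenceRecord

logger = logging.getLogger(__name__)

_SS_SET = frozenset(SS_LABELS)
_LABEL_INDEX = {lab: i for i, lab in enumerate(SS_LABELS)}


@dataclass
class SSTrack:
    """Per-residue three-state secondary-structure labels for one sequence."""

    id: str
    labels: str

    def __post_init__(self) -> None:
        bad = set(self.labels) - _SS_SET
        if bad:
            raise ValueError(f"track {self.id!r}: labels outside H/E/C: {sorted(bad)}")
        if not self.labels:
            raise ValueError(f"track {self.id!r}: empty label string")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class PredictorSpec:
    """Identity and tie-break priority of one ensemble member (1 = highest)."""

    name: str
    priority: int
    source: Literal["builtin_propensity", "builtin_gor", "external_track"]


@dataclass(frozen=True)
class SSContent:
    """Fractional secondary-structure content of one sequence."""

    helix_frac: float
    sheet_frac: float
    coil_frac: float
    structured_frac: float


def load_propensity_scale(path: str | Path | None = None) -> dict[str, tuple[float, float, float]]:
    """Load a residue -> (pH, pE, pC) propensity table (default: shipped scale)."""
    if path is None:
        source = resources.files("idpseq.data").joinpath("ss_propensity_scale.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    table = {
        row.residue: (row.p_helix, row.p_sheet, row.p_coil) for row in df.itertuples()
    }
    missing = set(AMINO_ACIDS) - set(table)
    if missing:
        raise ValueError(f"propensity scale missing residues: {sorted(missing)}")
    return table


def _scale_matrix(scale: dict[str, tuple[float, float, float]]) -> np.ndarray:
    missing = set(AMINO_ACIDS) - set(scale)
    if missing:
        raise ValueError(f"propensity scale missing residues: {sorted(missing)}")
    return np.array([scale[aa] for aa in AMINO_ACIDS], dtype=float)


def predict_propensity(
    record: SequenceRecord,
    scale: dict[str, tuple[float, float, float]] | None = None,
    window: int = 7,
) -> SSTrack:
    """Windowed propensity-table prediction.

    Each class propensity is averaged over the centered window (truncated at
    the termini) and the per-position label is the argmax, with ties resolving
    coil, then helix, then sheet.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    matrix = _scale_matrix(scale if scale is not None else load_propensity_scale())
    batch = _engine.encode(record.sequence)[None, :]
    labels = _engine.propensity_labels(batch, matrix, window)[0]
    return SSTrack(id=record.id, labels=_engine.decode_labels(labels))


class GORModel:
    """GOR-style per-class information values for residues at window offsets.

    For class s, window offset d and residue a, the model stores

        I(s; a, d) = log[(n(s,a,d) + c) / (n(!s,a,d) + c)]
                   - log[(n(s) + c) / (n(!s) + c)]

    with counts n pooled over all positions of a labeled training corpus and
    pseudocount c.  Prediction sums the information values of the residues in
    the window around each position and takes the tie-broken argmax class.
    """

    def __init__(self, info: np.ndarray, window: int) -> None:
        if info.shape != (3, window, 20):
            raise ValueError(f"info table has shape {info.shape}, expected (3, {window}, 20)")
        self.info = info
        self.window = window

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as a plain text table class/offset/residue/information_value."""
        half = self.window // 2
        with open(path, "w") as handle:
            handle.write("class\toffset\tresidue\tinformation_value\n")
            for s_idx, s in enumerate(SS_LABELS):
                for d_idx in range(self.window):
                    for a_idx, a in enumerate(AMINO_ACIDS):
                        handle.write(
                            f"{s}\t{d_idx - half}\t{a}\t"
                            f"{float(self.info[s_idx, d_idx, a_idx])!r}\n"
                        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GORModel":
        df = pd.read_csv(path, sep="\t")
        window = df["offset"].nunique()
        half = window // 2
        info = np.zeros((3, window, 20))
        for s, offset, residue, value in zip(
            df["class"], df["offset"], df["residue"], df["information_value"]
        ):
            info[_LABEL_INDEX[s], int(offset) + half, AMINO_ACIDS.index(residue)] = value
        return cls(info, window)


def train_gor(
    corpus: Sequence[tuple[SequenceRecord, SSTrack]],
    window: int = 17,
    pseudocount: float = 1.0,
) -> GORModel:
    """Fit a :class:`GORModel` from a labeled corpus.

    The default window of 17 residues (8 on each side) follows the GOR-family
    convention; the pseudocount regularizes unseen residue/offset cells.
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    half = window // 2
    counts = np.zeros((3, window, 20))
    class_totals = np.zeros(3)
    for record, track in corpus:
        if len(record) != len(track):
            raise ValueError(
                f"record {record.id!r}: sequence length {len(record)} != "
                f"track length {len(track)}"
            )
        enc = _engine.encode(record.sequence)
        labels = np.array([_LABEL_INDEX[lab] for lab in track.labels])
        length = len(enc)
        np.add.at(class_totals, labels, 1)
        for d_idx in range(window):
            offset = d_idx - half
            src_lo, src_hi = max(0, offset), min(length, length + offset)
            if src_lo >= src_hi:
                continue
            pos_labels = labels[src_lo - offset : src_hi - offset]
            residues = enc[src_lo:src_hi]
            np.add.at(counts[:, d_idx, :], (pos_labels, residues), 1)
    missing = [SS_LABELS[i] for i in range(3) if class_totals[i] == 0]
    if missing:
        raise ValueError(
            f"class(es) {missing} never observed in the corpus; "
            "train on a larger or more diverse corpus"
        )
    not_counts = counts.sum(axis=0, keepdims=True) - counts
    not_totals = class_totals.sum() - class_totals
    info = (
        np.log((counts + pseudocount) / (not_counts + pseudocount))
        - np.log((class_totals + pseudocount) / (not_totals + pseudocount))[:, None, None]
    )
    return GORModel(info, window)


def predict_gor(model: GORModel, record: SequenceRecord) -> SSTrack:
    """Predict a track with a trained :class:`GORModel`."""
    batch = _engine.encode(record.sequence)[None, :]
    labels = _engine.gor_labels(batch, model.info)[0]
    return SSTrack(id=record.id, labels=_engine.decode_labels(labels))


def _check_priorities(priorities: Sequence[PredictorSpec]) -> list[int]:
    """Validate unique contiguous-from-1 priorities; return track indices in priority order."""
    ranks = [p.priority for p in priorities]
    if sorted(ranks) != list(range(1, len(ranks) + 1)):
        raise ValueError(
            f"priorities must be unique and contiguous from 1, got {ranks}"
        )
    return [i for i, _ in sorted(enumerate(priorities), key=lambda t: t[1].priority)]


def consensus(tracks: Sequence[SSTrack], priorities: Sequence[PredictorSpec]) -> SSTrack:
    """Majority-vote consensus of aligned tracks with listed-order tie-breaking.

    At each position the most frequently predicted state is assigned.  With
    ambivalent counts, the winner is the state voted by the highest-priority
    predictor among those voting for a tied state.
    """
    if len(tracks) != len(priorities):
        raise ValueError("one PredictorSpec required per track")
    if not tracks:
        raise ValueError("consensus of zero tracks")
    length = len(tracks[0])
    for track, spec in zip(tracks, priorities):
        if len(track) != length:
            raise ValueError(
                f"track {track.id!r} (predictor {spec.name!r}) has length "
                f"{len(track)}, expected {length}"
            )
    order = np.array(_check_priorities(priorities))
    stack = np.array([[_LABEL_INDEX[lab] for lab in t.labels] for t in tracks])
    labels = _engine.consensus_labels(stack, order)
    return SSTrack(id=tracks[0].id, labels=_engine.decode_labels(labels))


def ss_content(track: SSTrack) -> SSContent:
    """Fractions of helix, sheet and coil labels; structured = helix + sheet."""
    length = len(track)
    h = track.labels.count("H") / length
    e = track.labels.count("E") / length
    c = track.labels.count("C") / length
    return SSContent(helix_frac=h, sheet_frac=e, coil_frac=c, structured_frac=h + e)


def q3(predicted: SSTrack, reference: SSTrack) -> float:
    """Fraction of positions whose predicted state matches the reference (Q3)."""
    if len(predicted) != len(reference):
        raise ValueError(
            f"length mismatch: {predicted.id!r} has {len(predicted)} labels, "
            f"{reference.id!r} has {len(reference)}"
        )
    matches = sum(p == r for p, r in zip(predicted.labels, reference.labels))
    return matches / len(predicted)


def load_ss8_reduction(path: str | Path | None = None) -> dict[str, str]:
    """Load the 8-state to 3-state label reduction table (default: shipped)."""
    if path is None:
        source = resources.files("idpseq.data").joinpath("ss8_reduction.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["label8"], df["label3"]))


def read_external_track(path: str | Path, reduction: dict[str, str] | None = None) -> list[SSTrack]:
    """Read external predictor output (TSV id/position/label) as 3-state tracks.

    Labels may be 8-state (reduced via the standard mapping, logged) or
    already 3-state; case is normalized to upper.  Positions must form 1..L
    per id.
    """
    if reduction is None:
        reduction = load_ss8_reduction()
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "label": str})
    required = {"id", "position", "label"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: external track TSV must have columns id, position, label"
        )
    tracks: list[SSTrack] = []
    for track_id, group in df.groupby("id", sort=False):
        group = group.sort_values("position")
        labels = []
        expected = 1
        for row in group.itertuples():
            if row.position != expected:
                kind = "duplicate" if row.position < expected else "gap at"
                raise ValueError(
                    f"{path}: track {track_id!r}: {kind} position "
                    f"{min(expected, int(row.position))}"
                )
            lab = str(row.label).upper()
            if lab in reduction:
                if reduction[lab] != lab:
                    logger.debug("track %r pos %d: reducing %s -> %s",
                                 track_id, expected, lab, reduction[lab])
                lab = reduction[lab]
            elif lab not in _SS_SET:
                raise ValueError(
                    f"{path}: track {track_id!r}: unknown label {row.label!r} "
                    f"at position {expected}"
                )
            labels.append(lab)
            expected += 1
        tracks.append(SSTrack(id=str(track_id), labels="".join(labels)))
    return tracks


def write_ss_tracks(tracks: Iterable[SSTrack], path: str | Path) -> None:
    """Write tracks as the canonical id/position/label TSV."""
    with open(path, "w") as handle:
        handle.write("id\tposition\tlabel\n")
        for track in tracks:
            for pos, lab in enumerate(track.labels, start=1):
                handle.write(f"{track.id}\t{pos}\t{lab}\n")
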