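"""Sequence records, FASTA and score-track I/O, and dataset filtering.

The analysis operates on two protein sets — disordered regions and folded
chains — carried as :class:`SequenceRecord` objects over the strict 20-letter
amino-acid alphabet.  Per-residue score tracks (disorder predictions and other
externally computed profiles) travel as :class:`ScoreTrack` objects read from
plain tab-separated tables, so that every downstream stage can be exercised
without any third-party predictor binaries.

Coordinates are 1-based inclusive throughout, matching the convention used in
disorder-region annotation databases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: The canonical amino-acid alphabet, in fixed alphabetical order.  All
#: composition vectors and substitution tables index residues in this order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)

#: Conservative replacements for ambiguity codes and rare residues, applied
#: only in lenient mode: B (Asx)->N, Z (Glx)->Q, U (Sec)->C, O (Pyl)->K,
#: X (unknown)->A.  Strict mode rejects all of them.
LENIENT_SUBSTITUTIONS = {"B": "N", "Z": "Q", "U": "C", "O": "K", "X": "A"}

Dataset = Literal["disordered", "folded", "other"]
TrackKind = Literal["disorder", "custom"]


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


class AlphabetError(ValueError):
    """Raised when a sequence contains residues outside the 20-letter alphabet."""


@dataclass
class SequenceRecord:
    """One protein or region sequence.

    Parameters
    ----------
    id:
        Unique identifier within a dataset.
    sequence:
        Residues over ``ACDEFGHIKLMNPQRSTVWY``.
    dataset:
        Which side of the comparison the record belongs to.
    region:
        Optional ``(start, end)`` 1-based inclusive coordinates within a
        parent sequence (e.g. a disordered region inside a full protein).
    meta:
        Free-form string metadata.  Structural selection criteria that in the
        original datasets were judged from deposited structure files (absence
        of cysteine bridges or ligands, few missing terminal residues) are
        represented here as boolean-valued flags.
    """

    id: str
    sequence: str
    dataset: Dataset = "other"
    region: tuple[int, int] | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if set(self.sequence) - _AA_SET:  # fast path; locate the offender only on failure
            for pos, aa in enumerate(self.sequence, start=1):
                if aa not in _AA_SET:
                    raise AlphabetError(
                        f"record {self.id!r}: non-standard residue {aa!r} "
                        f"at position {pos}"
                    )
        if self.region is not None:
            start, end = self.region
            if end - start + 1 != len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: region ({start}, {end}) does not span "
                    f"the {len(self.sequence)}-residue sequence"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ScoreTrack:
    """A per-residue real-valued profile aligned to one sequence record."""

    id: str
    values: list[float]
    kind: TrackKind = "custom"

    def __post_init__(self) -> None:
        if self.kind == "disorder":
            for pos, v in enumerate(self.values, start=1):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(
                        f"track {self.id!r}: disorder score {v} at position {pos} "
                        "outside [0, 1]"
                    )

    def __len__(self) -> int:
        return len(self.values)


def _sanitize_sequence(seq: str, rec_id: str, alphabet: str) -> str:
    """Uppercase and validate a raw sequence; map ambiguity codes in lenient mode."""
    seq = seq.upper()
    if alphabet == "strict":
        return seq  # validated by SequenceRecord
    chars = []
    for pos, aa in enumerate(seq, start=1):
        if aa in LENIENT_SUBSTITUTIONS:
            sub = LENIENT_SUBSTITUTIONS[aa]
            logger.info(
                "record %r: substituting %s -> %s at position %d (lenient mode)",
                rec_id, aa, sub, pos,
            )
            aa = sub
        chars.append(aa)
    return "".join(chars)


def _parse_header(header: str) -> tuple[str, dict[str, str]]:
    """Split a FASTA header into an id and ``key=value`` metadata tokens."""
    tokens = header.split()
    rec_id = tokens[0]
    meta: dict[str, str] = {}
    for tok in tokens[1:]:
        if "=" in tok:
            key, _, value = tok.partition("=")
            meta[key] = value
        else:
            meta[tok] = ""
    return rec_id, meta


def read_fasta(
    path: str | Path,
    alphabet: Literal["strict", "lenient"] = "strict",
    dataset: Dataset | None = None,
) -> list[SequenceRecord]:
    """Read FASTA into :class:`SequenceRecord` objects, order preserved.

    Headers are parsed as ``id [key=value ...]``.  A ``dataset=`` metadata
    token, or the explicit `dataset` argument (which wins), sets the record's
    dataset label; a ``region=start-end`` token sets its parent coordinates.

    Raises
    ------
    FastaParseError
        If the file contains text before the first ``>`` header (the error
        names the offending line) or a header with no identifier.
    AlphabetError
        In strict mode, for any residue outside the 20-letter alphabet.
    """
    path = Path(path)
    with open(path) as handle:
        lines = handle.readlines()
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno}: expected a '>' header before sequence data"
            )
        break

    records: list[SequenceRecord] = []
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            if not header.strip():
                raise FastaParseError(f"{path}: FASTA header with empty identifier")
            rec_id, meta = _parse_header(header)
            seq = _sanitize_sequence(seq, rec_id, alphabet)
            region = None
            if "region" in meta:
                try:
                    start_s, _, end_s = meta["region"].partition("-")
                    region = (int(start_s), int(end_s))
                except ValueError as exc:
                    raise FastaParseError(
                        f"{path}: record {rec_id!r}: malformed region token "
                        f"{meta['region']!r}"
                    ) from exc
            ds: Dataset = dataset or meta.get("dataset", "other")  # type: ignore[assignment]
            if ds not in ("disordered", "folded", "other"):
                raise FastaParseError(
                    f"{path}: record {rec_id!r}: unknown dataset label {ds!r}"
                )
            records.append(
                SequenceRecord(id=rec_id, sequence=seq, dataset=ds, region=region, meta=meta)
            )
    if not records:
        logger.warning("%s: empty FASTA file, returning no records", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA with `wrap`-column line folding.

    Metadata (including the dataset label and region coordinates) is emitted
    as ``key=value`` header tokens so that :func:`read_fasta` round-trips.
    """
    path = Path(path)
    with open(path, "w") as handle:
        for rec in records:
            meta = dict(rec.meta)
            if rec.dataset != "other":
                meta.setdefault("dataset", rec.dataset)
            if rec.region is not None:
                meta["region"] = f"{rec.region[0]}-{rec.region[1]}"
            tokens = [rec.id] + [f"{k}={v}" if v else k for k, v in meta.items()]
            handle.write(">" + " ".join(tokens) + "\n")
            for i in range(0, len(rec.sequence), wrap):
                handle.write(rec.sequence[i : i + wrap] + "\n")


def filter_by_length(
    records: Sequence[SequenceRecord], min_len: int, max_len: int
) -> list[SequenceRecord]:
    """Keep records with ``min_len <= length <= max_len`` (both inclusive).

    The 50–150 residue window applied to both study datasets is the intended
    use; the bounds are explicit so other windows can be explored.
    """
    if not (1 <= min_len <= max_len):
        raise ValueError(f"invalid length window ({min_len}, {max_len})")
    kept = [r for r in records if min_len <= len(r) <= max_len]
    removed = len(records) - len(kept)
    if removed:
        logger.info(
            "length filter [%d, %d]: removed %d of %d records",
            min_len, max_len, removed, len(records),
        )
    return kept


def filter_by_meta(
    records: Sequence[SequenceRecord],
    predicate: Callable[[dict[str, str]], bool],
) -> list[SequenceRecord]:
    """Keep records whose metadata satisfies `predicate`.

    Used for structure-derived selection criteria carried as metadata flags
    (e.g. ``predicate=lambda m: m.get("cys_bridge") == "false"``).
    """
    kept = [r for r in records if predicate(r.meta)]
    removed = len(records) - len(kept)
    if removed:
        logger.info("metadata filter: removed %d of %d records", removed, len(records))
    return kept


def read_score_track(path: str | Path, kind: TrackKind = "custom") -> list[ScoreTrack]:
    """Read per-residue score tracks from a TSV with columns id, position, score.

    Positions for each id must form a complete 1..L run (in any row order);
    gaps or duplicates raise with the offending id and position.  Disorder
    tracks additionally require scores in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "position", "score"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: score-track TSV must have columns id, position, score "
            f"(found {list(df.columns)})"
        )
    tracks: list[ScoreTrack] = []
    for track_id, group in df.groupby("id", sort=False):
        group = group.sort_values("position")
        positions = group["position"].to_numpy()
        expected = 1
        for pos in positions:
            if pos > expected:
                raise ValueError(
                    f"{path}: track {track_id!r}: missing position {expected}"
                )
            if pos < expected:
                raise ValueError(
                    f"{path}: track {track_id!r}: duplicate position {pos}"
                )
            expected += 1
        tracks.append(
            ScoreTrack(id=str(track_id), values=group["score"].astype(float).tolist(), kind=kind)
        )
    return tracks


def write_score_track(tracks: Iterable[ScoreTrack], path: str | Path) -> None:
    """Write score tracks as the canonical id/position/score TSV."""
    with open(path, "w") as handle:
        handle.write("id\tposition\tscore\n")
        for track in tracks:
            for pos, value in enumerate(track.values, start=1):
                handle.write(f"{track.id}\t{pos}\t{value:.6g}\n")
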