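"""Exhaustive ungapped overlap survey between disorder regions and structure chains.

Every region sequence is compared against every chain sequence for maximal
ungapped overlaps in which all aligned residues match exactly, except that
mismatches are tolerated at the first and last three positions of the chain
(deposited chain termini — cloning tags, engineered residues — may differ from
the native sequence).  Overlaps longer than 20 residues are candidate hits; a
hit is accepted when the overlap covers the whole region, covers the whole
chain, or runs conflict-free from a terminus of one sequence into a terminus
of the other (a chain starting or ending inside a region).

Accepted hits rank the fold-on-binding ("induced fold") candidates; regions
with no accepted hit and the highest disorder indices form the "unfoldable"
subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import pandas as pd

from .aggdisorder import DisorderIndex
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

#: Overlaps must be longer than 20 residues to be considered.
DEFAULT_MIN_LEN = 21

#: Mismatches are tolerated at this many positions from each chain terminus.
CHAIN_TERMINAL_TOLERANCE = 3

AcceptRule = Literal["covers_region", "covers_chain", "no_conflict_extension"]


@dataclass(frozen=True)
class OverlapHit:
    """One maximal ungapped overlap between a region and a chain.

    Spans are 1-based inclusive in each sequence; `mismatches` lists
    ``(region_pos, chain_pos, region_res, chain_res)`` for the tolerated
    chain-terminal mismatches inside the overlap.
    """

    region_id: str
    chain_id: str
    region_span: tuple[int, int]
    chain_span: tuple[int, int]
    overlap_len: int
    mismatches: tuple[tuple[int, int, str, str], ...] = ()
    accepted: bool = False
    rule: AcceptRule | None = None


@dataclass(frozen=True)
class SubsetSelection:
    """Induced-fold candidates and the unfoldable subset."""

    induced_candidates: tuple[str, ...]
    unfoldable: tuple[str, ...]


def _tolerant(chain_pos0: int, chain_len: int) -> bool:
    return (
        chain_pos0 < CHAIN_TERMINAL_TOLERANCE
        or chain_pos0 >= chain_len - CHAIN_TERMINAL_TOLERANCE
    )


def _scan_diagonal(
    region: SequenceRecord, chain: SequenceRecord, diag: int, min_len: int
) -> list[OverlapHit]:
    """Maximal allowed runs along one diagonal (chain_pos0 = region_pos0 + diag)."""
    r_seq, c_seq = region.sequence, chain.sequence
    lr, lc = len(r_seq), len(c_seq)
    i_lo = max(0, -diag)
    i_hi = min(lr, lc - diag)  # exclusive
    hits: list[OverlapHit] = []
    run_start: int | None = None
    run_mismatches: list[tuple[int, int, str, str]] = []

    def close(end_excl: int) -> None:
        nonlocal run_start, run_mismatches
        if run_start is not None and end_excl - run_start >= min_len:
            hits.append(
                OverlapHit(
                    region_id=region.id,
                    chain_id=chain.id,
                    region_span=(run_start + 1, end_excl),
                    chain_span=(run_start + diag + 1, end_excl + diag),
                    overlap_len=end_excl - run_start,
                    mismatches=tuple(run_mismatches),
                )
            )
        run_start = None
        run_mismatches = []

    for i in range(i_lo, i_hi):
        j = i + diag
        match = r_seq[i] == c_seq[j]
        if match or _tolerant(j, lc):
            if run_start is None:
                run_start = i
            if not match:
                run_mismatches.append((i + 1, j + 1, r_seq[i], c_seq[j]))
        else:
            close(i)
    close(i_hi)
    return hits


def find_overlaps(
    region: SequenceRecord, chain: SequenceRecord, min_len: int = DEFAULT_MIN_LEN
) -> list[OverlapHit]:
    """All maximal ungapped overlaps of length >= `min_len` between two sequences.

    Exact matches are required at every aligned position except the first and
    last three chain positions.  Runs are maximal: no tolerated extension
    exists on either side of a reported overlap.

    Candidate diagonals are located by exact k-mer seeding (k = 12) inside the
    overlap's guaranteed exact core and then scanned in full, which leaves the
    hit set identical to an all-diagonals scan; for parameters where the core
    guarantee does not hold, every diagonal is scanned directly.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    lr, lc = len(region), len(chain)
    # an accepted run of length m has a contiguous exact stretch of at least
    # m - 2*tolerance positions; seeds of size k <= min_len - 6 cannot miss it
    k = min(12, min_len - 2 * CHAIN_TERMINAL_TOLERANCE)
    if k >= 8 and lr >= k and lc >= k:
        index: dict[str, list[int]] = {}
        for i in range(lr - k + 1):
            index.setdefault(region.sequence[i : i + k], []).append(i)
        diagonals: set[int] = set()
        for j in range(lc - k + 1):
            for i in index.get(chain.sequence[j : j + k], ()):
                diagonals.add(j - i)
    else:
        diagonals = set(range(-(lr - 1), lc))
    hits: list[OverlapHit] = []
    for diag in sorted(diagonals):
        hits.extend(_scan_diagonal(region, chain, diag, min_len))
    return hits


def accept_hit(hit: OverlapHit, region_len: int, chain_len: int) -> OverlapHit:
    """Apply the hit-acceptance rules to an overlap.

    Accepted when the overlap includes the whole region (`covers_region`), the
    whole chain (`covers_chain`), or reaches a terminus of each sequence on
    opposite ends with no conflicting aligned residues outside the tolerated
    chain termini (`no_conflict_extension`); otherwise rejected.
    """
    rs, re_ = hit.region_span
    cs, ce = hit.chain_span
    if (rs, re_) == (1, region_len):
        return replace(hit, accepted=True, rule="covers_region")
    if (cs, ce) == (1, chain_len):
        return replace(hit, accepted=True, rule="covers_chain")
    # the overlap is conflict-free by construction; terminal anchoring on
    # opposite ends means a chain started or ended within the region
    if (rs == 1 and ce == chain_len) or (cs == 1 and re_ == region_len):
        return replace(hit, accepted=True, rule="no_conflict_extension")
    return replace(hit, accepted=False, rule=None)


def survey(
    regions: Sequence[SequenceRecord],
    chains: Sequence[SequenceRecord],
    min_len: int = DEFAULT_MIN_LEN,
) -> list[OverlapHit]:
    """All-pairs overlap survey with acceptance rules applied."""
    out: list[OverlapHit] = []
    for region in regions:
        for chain in chains:
            for hit in find_overlaps(region, chain, min_len):
                out.append(accept_hit(hit, len(region), len(chain)))
    return out


def select_subsets(
    regions: Sequence[SequenceRecord],
    hits: Sequence[OverlapHit],
    disorder: Sequence[DisorderIndex],
    n: int = 30,
) -> SubsetSelection:
    """Rank induced-fold candidates and pick the unfoldable subset.

    Induced-fold candidates are regions with >= 1 accepted hit, ranked by the
    total accepted overlap length (descending).  The unfoldable subset is the
    top-`n` regions by disorder index among those with zero accepted hits —
    highly disordered sequences with no structural record.  All ties break by
    lexicographic id (logged).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    disorder_map = {d.id: d.value for d in disorder}
    missing = [r.id for r in regions if r.id not in disorder_map]
    if missing:
        raise ValueError(f"disorder index missing for regions: {missing[:5]}")
    accepted_len: dict[str, int] = {}
    for hit in hits:
        if hit.accepted:
            accepted_len[hit.region_id] = (
                accepted_len.get(hit.region_id, 0) + hit.overlap_len
            )
    induced = tuple(
        sorted(accepted_len, key=lambda rid: (-accepted_len[rid], rid))
    )
    hitless = [r.id for r in regions if r.id not in accepted_len]
    ranked = sorted(hitless, key=lambda rid: (-disorder_map[rid], rid))
    if len(ranked) < n:
        logger.info(
            "only %d hit-free regions available for the unfoldable subset "
            "(requested %d)", len(ranked), n,
        )
    return SubsetSelection(induced_candidates=induced, unfoldable=tuple(ranked[:n]))


def hits_table(hits: Sequence[OverlapHit]) -> pd.DataFrame:
    """Hits as a TSV-ready table."""
    return pd.DataFrame(
        {
            "region_id": [h.region_id for h in hits],
            "chain_id": [h.chain_id for h in hits],
            "region_start": [h.region_span[0] for h in hits],
            "region_end": [h.region_span[1] for h in hits],
            "chain_start": [h.chain_span[0] for h in hits],
            "chain_end": [h.chain_span[1] for h in hits],
            "len": [h.overlap_len for h in hits],
            "mismatches": [
                ";".join(f"{rp}:{cp}:{rr}>{cr}" for rp, cp, rr, cr in h.mismatches)
                for h in hits
            ],
            "accepted": [h.accepted for h in hits],
            "rule": [h.rule or "" for h in hits],
        }
    )
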