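"""Seeded generators for every input the pipeline consumes.

Real runs of the analysis start from curated disorder-region and folded-chain
sequence sets plus externally predicted per-residue tracks.  These generators
emulate those inputs so the whole pipeline (and its tests) runs standalone:

* compositional sequence sets drawn from documented residue-frequency
  profiles — a globular background, a G/P/S/Q-rich polar-tract profile and an
  E/K/A-rich charged profile mirroring the compositional axes that separate
  disordered from globular sequences;
* secondary-structure-labeled corpora from a hidden-state Markov emitter,
  providing ground truth for training and scoring predictors;
* per-residue disorder tracks at profile-dependent levels with Gaussian noise;
* region/chain pairs with planted exact overlaps in known terminal or
  containment configurations, with optional chain-terminal mutations.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._engine import SS_LABELS
from .overlapmap import OverlapHit
from .seqio import AMINO_ACIDS, ScoreTrack, SequenceRecord
from .sspredict import SSTrack, load_propensity_scale

#: Dirichlet concentration of per-sequence compositions around the profile
#: base frequencies.  300 gives each class a visible compositional scatter
#: (roughly 1-2 percentage points per residue on top of finite-length
#: sampling noise) while keeping the three profile classes in distinct
#: regions of composition space, as the generated fixtures are required to.
DEFAULT_CONCENTRATION = 300.0

#: Default per-residue disorder levels by profile: globular sequences predict
#: ordered, the disordered-profile sequences predict strongly disordered.
DEFAULT_DISORDER_LEVELS = {
    "globular": 0.1,
    "polar_tract": 0.85,
    "charged": 0.9,
}


@dataclass(frozen=True)
class CompositionProfile:
    """A residue-frequency profile with a Dirichlet spread around it."""

    name: str
    base_freqs: tuple[float, ...]
    concentration: float = DEFAULT_CONCENTRATION

    def __post_init__(self) -> None:
        if len(self.base_freqs) != 20:
            raise ValueError("base_freqs must have 20 entries")
        if abs(sum(self.base_freqs) - 1.0) > 1e-6:
            raise ValueError(f"base_freqs sum to {sum(self.base_freqs)}, not 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")


def load_profiles(path: str | Path | None = None) -> dict[str, CompositionProfile]:
    """Load the shipped (or a custom) profile table as name -> profile."""
    if path is None:
        source = resources.files("idpseq.data").joinpath("composition_profiles.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index("residue").loc[list(AMINO_ACIDS)]
    profiles = {}
    for name in df.columns:
        freqs = df[name].to_numpy(dtype=float)
        freqs = freqs / freqs.sum()
        profiles[name] = CompositionProfile(name=name, base_freqs=tuple(freqs))
    return profiles


def get_profile(name: str) -> CompositionProfile:
    profiles = load_profiles()
    if name not in profiles:
        raise KeyError(f"unknown profile {name!r}; available: {sorted(profiles)}")
    return profiles[name]


def generate_sequences(
    profile: CompositionProfile,
    n: int,
    length_range: tuple[int, int] = (50, 150),
    seed: int = 0,
    dataset: str | None = None,
    id_prefix: str | None = None,
) -> list[SequenceRecord]:
    """Draw `n` sequences from a compositional profile.

    Per sequence: a composition is drawn from
    Dirichlet(concentration x base_freqs), a length uniformly from
    `length_range` (inclusive), and residues i.i.d. from that composition.
    The default length window matches the 50-150 residue selection applied to
    the study datasets.  Globular-profile records are labeled ``folded``,
    all others ``disordered``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    alpha = profile.concentration * np.array(profile.base_freqs)
    if dataset is None:
        dataset = "folded" if profile.name == "globular" else "disordered"
    prefix = id_prefix if id_prefix is not None else profile.name
    records = []
    for i in range(n):
        comp = rng.dirichlet(alpha)
        length = int(rng.integers(lo, hi + 1))
        residues = rng.choice(20, size=length, p=comp)
        records.append(
            SequenceRecord(
                id=f"{prefix}_{i + 1:04d}",
                sequence="".join(AMINO_ACIDS[r] for r in residues),
                dataset=dataset,  # type: ignore[arg-type]
                meta={"profile": profile.name},
            )
        )
    return records


@dataclass(frozen=True)
class SSEmissionModel:
    """Hidden-state emitter of secondary-structure-labeled sequences.

    States follow a first-order Markov chain over H/E/C (a state change is
    suppressed until the current segment has reached `min_segment` positions,
    keeping helices and strands structurally plausible); each state emits
    residues from its own distribution.
    """

    transition: tuple[tuple[float, ...], ...]
    emission: tuple[tuple[float, ...], ...]
    min_segment: int = 3

    def __post_init__(self) -> None:
        t = np.array(self.transition)
        e = np.array(self.emission)
        if t.shape != (3, 3) or not np.allclose(t.sum(axis=1), 1.0):
            raise ValueError("transition must be a 3x3 stochastic matrix")
        if e.shape != (3, 20) or not np.allclose(e.sum(axis=1), 1.0):
            raise ValueError("emission must be 3 distributions over 20 residues")

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the transition matrix."""
        t = np.array(self.transition)
        w, v = np.linalg.eig(t.T)
        vec = np.real(v[:, np.argmin(np.abs(w - 1.0))])
        return vec / vec.sum()


def default_ss_emission_model(
    self_transition: float = 0.9, emission_sharpness: float = 2.0
) -> SSEmissionModel:
    """The default labeled-corpus emitter.

    Transitions: `self_transition` on the diagonal, the remainder split
    evenly.  Emissions: the globular background reweighted by each state's
    conformational propensity raised to `emission_sharpness` — helix states
    favor A/E/L/M-type residues, strand states V/I/Y/F-type, coil G/P/S/N/D —
    a state-residue coupling strong enough to be learnable but far from
    deterministic.
    """
    off = (1.0 - self_transition) / 2.0
    transition = tuple(
        tuple(self_transition if i == j else off for j in range(3)) for i in range(3)
    )
    background = np.array(get_profile("globular").base_freqs)
    scale = load_propensity_scale()
    prop = np.array([scale[aa] for aa in AMINO_ACIDS])  # (20, 3): H, E, C channels
    emission = []
    for state in range(3):
        weights = background * prop[:, state] ** emission_sharpness
        emission.append(tuple(weights / weights.sum()))
    return SSEmissionModel(transition=transition, emission=tuple(emission))


def generate_labeled_corpus(
    model: SSEmissionModel,
    n: int,
    length_range: tuple[int, int] = (50, 150),
    seed: int = 0,
    id_prefix: str = "ss",
) -> list[tuple[SequenceRecord, SSTrack]]:
    """Sample `n` (sequence, true-label) pairs from the emitter."""
    rng = np.random.default_rng(seed)
    transition = np.array(model.transition)
    emission = np.array(model.emission)
    stationary = model.stationary()
    lo, hi = length_range
    corpus = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        states = np.empty(length, dtype=np.int64)
        states[0] = rng.choice(3, p=stationary)
        run = 1
        for pos in range(1, length):
            if run < model.min_segment:
                states[pos] = states[pos - 1]
            else:
                states[pos] = rng.choice(3, p=transition[states[pos - 1]])
            run = run + 1 if states[pos] == states[pos - 1] else 1
        residues = np.array(
            [rng.choice(20, p=emission[s]) for s in states], dtype=np.int64
        )
        rec_id = f"{id_prefix}_{i + 1:04d}"
        corpus.append(
            (
                SequenceRecord(
                    id=rec_id,
                    sequence="".join(AMINO_ACIDS[r] for r in residues),
                    dataset="other",
                ),
                SSTrack(id=rec_id, labels="".join(SS_LABELS[s] for s in states)),
            )
        )
    return corpus


def generate_disorder_tracks(
    records: list[SequenceRecord],
    levels: dict[str, float] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> list[ScoreTrack]:
    """Per-residue disorder tracks: clip(level + Gaussian noise, 0, 1).

    The level of each record is looked up by its ``profile`` metadata (falling
    back to its dataset label) in `levels`; defaults give globular sequences
    low and disordered-profile sequences high disorder.
    """
    if levels is None:
        levels = dict(DEFAULT_DISORDER_LEVELS)
    for key, level in levels.items():
        if not 0.0 <= level <= 1.0:
            raise ValueError(f"level for {key!r} outside [0, 1]: {level}")
    rng = np.random.default_rng(seed)
    tracks = []
    for rec in records:
        key = rec.meta.get("profile", rec.dataset)
        if key not in levels:
            key = {"folded": "globular", "disordered": "charged"}.get(rec.dataset, key)
        level = levels.get(key, 0.5)
        values = np.clip(level + rng.normal(0.0, noise_sd, size=len(rec)), 0.0, 1.0)
        tracks.append(ScoreTrack(id=rec.id, values=[float(v) for v in values],
                                 kind="disorder"))
    return tracks


def _random_residues(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def generate_overlap_pairs(
    n: int,
    planted_len_range: tuple[int, int] = (21, 80),
    terminal_mutations: int = 0,
    seed: int = 0,
    min_accept_len: int = 21,
) -> list[tuple[SequenceRecord, SequenceRecord, OverlapHit]]:
    """Region/chain pairs sharing one planted segment, with the true hit.

    Each pair uses a randomly chosen configuration: the chain contained in the
    region (whole-chain coverage), the region contained in the chain
    (whole-region coverage), or a terminal chain-into-region extension in
    either orientation.  `terminal_mutations` (at most 3) mutates that many
    residues at a chain terminus lying inside the overlap — exactly the
    positions the matcher must tolerate.  The truth records the planted spans,
    the introduced mismatches, and whether the hit should be accepted (planted
    length >= `min_accept_len`).
    """
    if terminal_mutations > 3 or terminal_mutations < 0:
        raise ValueError("terminal_mutations must be in 0..3")
    lo, hi = planted_len_range
    if lo < 1 or lo > hi:
        raise ValueError(f"invalid planted length range {planted_len_range}")
    rng = np.random.default_rng(seed)
    configs = ("covers_chain", "covers_region", "chain_ends_in_region",
               "chain_starts_in_region")
    pairs = []
    for i in range(n):
        planted_len = int(rng.integers(lo, hi + 1))
        config = configs[int(rng.integers(len(configs)))]
        segment = _random_residues(rng, planted_len)
        flank_a = _random_residues(rng, int(rng.integers(4, 31)))
        flank_b = _random_residues(rng, int(rng.integers(4, 31)))
        flank_c = _random_residues(rng, int(rng.integers(4, 31)))
        region_id, chain_id = f"region_{i + 1:04d}", f"chain_{i + 1:04d}"
        mismatches: list[tuple[int, int, str, str]] = []

        if config == "covers_chain":
            region_seq = flank_a + segment + flank_b
            chain_seq = segment
            region_span = (len(flank_a) + 1, len(flank_a) + planted_len)
            chain_span = (1, planted_len)
            mutable = list(range(1, min(3, planted_len) + 1)) + \
                list(range(max(1, planted_len - 2), planted_len + 1))
        elif config == "covers_region":
            region_seq = segment
            chain_seq = flank_a + segment + flank_b
            region_span = (1, planted_len)
            chain_span = (len(flank_a) + 1, len(flank_a) + planted_len)
            mutable = []  # chain termini lie outside the overlap here
        elif config == "chain_ends_in_region":
            # chain = flank + segment; region = segment + flank
            region_seq = segment + flank_b
            chain_seq = flank_c + segment
            region_span = (1, planted_len)
            chain_span = (len(flank_c) + 1, len(flank_c) + planted_len)
            last = len(chain_seq)
            mutable = [p for p in range(last - 2, last + 1) if p >= chain_span[0]]
        else:  # chain_starts_in_region
            region_seq = flank_a + segment
            chain_seq = segment + flank_c
            region_span = (len(flank_a) + 1, len(flank_a) + planted_len)
            chain_span = (1, planted_len)
            mutable = [p for p in (1, 2, 3) if p <= planted_len]

        if terminal_mutations and mutable:
            chosen = sorted(
                rng.choice(sorted(set(mutable)),
                           size=min(terminal_mutations, len(set(mutable))),
                           replace=False).tolist()
            )
            chain_list = list(chain_seq)
            for cpos in chosen:
                rpos = region_span[0] + (cpos - chain_span[0])
                original = chain_list[cpos - 1]
                alternatives = [aa for aa in AMINO_ACIDS if aa != original]
                chain_list[cpos - 1] = alternatives[int(rng.integers(19))]
                mismatches.append(
                    (rpos, cpos, region_seq[rpos - 1], chain_list[cpos - 1])
                )
            chain_seq = "".join(chain_list)

        accepted = planted_len >= min_accept_len
        rule_map = {
            "covers_chain": "covers_chain",
            "covers_region": "covers_region",
            "chain_ends_in_region": "no_conflict_extension",
            "chain_starts_in_region": "no_conflict_extension",
        }
        truth = OverlapHit(
            region_id=region_id,
            chain_id=chain_id,
            region_span=region_span,
            chain_span=chain_span,
            overlap_len=planted_len,
            mismatches=tuple(sorted(mismatches)),
            accepted=accepted,
            rule=rule_map[config] if accepted else None,  # type: ignore[arg-type]
        )
        pairs.append(
            (
                SequenceRecord(id=region_id, sequence=region_seq, dataset="disordered"),
                SequenceRecord(id=chain_id, sequence=chain_seq, dataset="folded"),
                truth,
            )
        )
    return pairs
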