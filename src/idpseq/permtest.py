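"""Composition-preserving permutation nulls and their statistics.

A full-sequence shuffle rearranges every residue at once, producing a totally
random sequence of identical amino-acid composition.  Repeating the shuffle
many times (1000 by default) and re-evaluating a sequence property on each
variant yields a per-sequence null distribution; the property of the native
sequence is then located in that null by a z-score, and dataset-level
agreement between native and shuffled values is summarized by Pearson's r
between the native values and the per-sequence null means.  Properties that
depend only on composition are shuffle-invariant: their null spread is exactly
zero and the z-score is undefined rather than zero.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _engine, aggdisorder, sspredict
from .seqio import SequenceRecord
from .sspredict import GORModel, PredictorSpec

logger = logging.getLogger(__name__)

PropertyFn = Callable[[str], float]


@dataclass(frozen=True)
class PermutationResult:
    """Null-distribution summary of one property for one sequence.

    `z` is ``None`` (undefined) when the null standard deviation is exactly
    zero, as happens for homopolymers and for composition-only properties;
    such entries are excluded from dataset correlations, never coerced to 0.
    """

    id: str
    property: str
    original: float
    null_mean: float
    null_sd: float
    z: float | None
    n_perm: int


@dataclass(frozen=True)
class PermutationDatasetStats:
    """Pearson correlation of native property values vs per-sequence null means."""

    property: str
    pearson_r: float
    n_sequences: int


def derive_subseed(seed: int, record_id: str) -> int:
    """Stable 63-bit per-sequence seed from the global seed and the record id.

    Hash-derived, so per-sequence results do not depend on dataset ordering or
    on how work is scheduled across workers.
    """
    digest = hashlib.sha256(f"{seed}:{record_id}".encode()).digest()
    return int.from_bytes(digest[:8], "big") & (2**63 - 1)


def shuffle_sequence(
    record: SequenceRecord,
    rng: np.random.Generator,
    index: int | None = None,
) -> SequenceRecord:
    """Uniformly random permutation of the record's residues.

    All L! orderings are equiprobable (Fisher-Yates via the generator's
    ``permutation``); the residue multiset is conserved by construction.  When
    `index` is given the returned id carries a ``|perm{index}`` suffix.
    """
    perm = rng.permutation(len(record.sequence))
    shuffled = "".join(record.sequence[i] for i in perm)
    new_id = record.id if index is None else f"{record.id}|perm{index}"
    return SequenceRecord(
        id=new_id, sequence=shuffled, dataset=record.dataset, meta=dict(record.meta)
    )


def _null_summary(
    record_id: str, name: str, original: float, null_values: np.ndarray, n_perm: int
) -> PermutationResult:
    # exact-tie fast path: bit-identical null values mean a truly degenerate
    # null; avoid float-summation residue that would fabricate a tiny sd
    if np.all(null_values == null_values[0]):
        null_mean = float(null_values[0])
        null_sd = 0.0
    else:
        null_mean = float(np.mean(null_values))
        null_sd = float(np.std(null_values, ddof=1))
    z = None if null_sd == 0.0 else (original - null_mean) / null_sd
    return PermutationResult(
        id=record_id, property=name, original=float(original),
        null_mean=null_mean, null_sd=null_sd, z=z, n_perm=n_perm,
    )


def permutation_null(
    record: SequenceRecord,
    property_fn: PropertyFn,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    property_name: str = "property",
) -> PermutationResult:
    """Null distribution of one scalar property under full-sequence shuffling.

    The native sequence is never added to its own null; the z-score locates it
    in the distribution of the `n_perm` shuffled variants (sample sd, n-1
    denominator).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    original = float(property_fn(record.sequence))
    null_values = np.empty(n_perm)
    for k in range(n_perm):
        variant = shuffle_sequence(record, rng, index=k + 1)
        try:
            null_values[k] = float(property_fn(variant.sequence))
        except Exception as exc:  # noqa: BLE001 - annotate replay context
            raise RuntimeError(
                f"property {property_name!r} failed on permutation {k + 1} of "
                f"record {record.id!r}: {exc}"
            ) from exc
    return _null_summary(record.id, property_name, original, null_values, n_perm)


class ConsensusPropertySuite:
    """Batched evaluator of the standard permutation properties.

    Computes, for every row of an encoded sequence batch, the consensus
    secondary-structure fractions (structured/helix/sheet, via the built-in
    propensity and GOR predictors combined by the majority-vote rule) and the
    windowed aggregation score.  The scalar per-sequence path and this batched
    path share one numeric core, so their results are bit-identical.
    """

    DEFAULT_PROPERTIES = ("structured_frac", "helix_frac", "sheet_frac", "aggregation")

    def __init__(
        self,
        gor_model: GORModel,
        propensity_scale: Mapping[str, tuple[float, float, float]] | None = None,
        propensity_window: int = 7,
        aggregation_scale: Mapping[str, float] | None = None,
        aggregation_window: int = aggdisorder.DEFAULT_WINDOW,
        aggregation_threshold: float | None = None,
        properties: Sequence[str] = DEFAULT_PROPERTIES,
    ) -> None:
        scale = dict(propensity_scale) if propensity_scale is not None \
            else sspredict.load_propensity_scale()
        self.propensity_matrix = sspredict._scale_matrix(scale)
        self.propensity_window = propensity_window
        self.gor_model = gor_model
        if aggregation_scale is None:
            agg_scale, default_threshold = aggdisorder.load_aggregation_scale()
        else:
            agg_scale, default_threshold = dict(aggregation_scale), None
        self.aggregation_vector = aggdisorder._scale_vector(agg_scale)
        self.aggregation_window = aggregation_window
        if aggregation_threshold is None:
            if default_threshold is None:
                raise ValueError("aggregation_threshold required with a custom scale")
            aggregation_threshold = default_threshold
        self.aggregation_threshold = aggregation_threshold
        # built-in ensemble, listed order = priority order
        self.ensemble = (
            PredictorSpec("propensity", 1, "builtin_propensity"),
            PredictorSpec("gor", 2, "builtin_gor"),
        )
        unknown = set(properties) - set(self.DEFAULT_PROPERTIES)
        if unknown:
            raise ValueError(f"unknown properties: {sorted(unknown)}")
        self.names = tuple(properties)

    def evaluate_batch(self, batch: np.ndarray) -> dict[str, np.ndarray]:
        """Property values for an (m, L) encoded batch, one array per property."""
        prop_labels = _engine.propensity_labels(
            batch, self.propensity_matrix, self.propensity_window
        )
        gor_labels = _engine.gor_labels(batch, self.gor_model.info)
        cons = _engine.consensus_labels(
            np.stack([prop_labels, gor_labels]), np.array([0, 1])
        )
        helix = (cons == 0).mean(axis=1)
        sheet = (cons == 1).mean(axis=1)
        prone = _engine.aggregation_prone_mask(
            batch, self.aggregation_vector,
            self.aggregation_window, self.aggregation_threshold,
        )
        values = {
            "structured_frac": helix + sheet,
            "helix_frac": helix,
            "sheet_frac": sheet,
            "aggregation": prone.mean(axis=1),
        }
        return {name: values[name] for name in self.names}

    def property_fns(self) -> dict[str, PropertyFn]:
        """Scalar closures over the same core, for use with :func:`permutation_null`."""
        def make(name: str) -> PropertyFn:
            def fn(sequence: str) -> float:
                batch = _engine.encode(sequence)[None, :]
                return float(self.evaluate_batch(batch)[name][0])
            return fn
        return {name: make(name) for name in self.names}


_DEFAULT_GOR_CORPUS_SEED = 20190703  # fixed: the default model is part of the pipeline
_default_suite_cache: ConsensusPropertySuite | None = None


def default_property_suite() -> ConsensusPropertySuite:
    """The standard property suite with a GOR model trained on the default
    synthetic labeled corpus (fixed internal seed, so the model is a
    deterministic part of the pipeline)."""
    global _default_suite_cache
    if _default_suite_cache is None:
        from . import synthetic_data

        corpus = synthetic_data.generate_labeled_corpus(
            synthetic_data.default_ss_emission_model(),
            n=200, length_range=(80, 150), seed=_DEFAULT_GOR_CORPUS_SEED,
        )
        model = sspredict.train_gor(corpus)
        _default_suite_cache = ConsensusPropertySuite(gor_model=model)
    return _default_suite_cache


def dataset_correlation(results: Sequence[PermutationResult]) -> PermutationDatasetStats:
    """Pearson's r between native values and null means across one property.

    Sequences with non-finite native values or null means are excluded (and
    counted out of `n_sequences`); undefined z-scores do not exclude a
    sequence, since both its native value and null mean are still defined.
    """
    if not results:
        raise ValueError("no permutation results")
    names = {r.property for r in results}
    if len(names) != 1:
        raise ValueError(f"results mix properties: {sorted(names)}")
    originals = np.array([r.original for r in results])
    null_means = np.array([r.null_mean for r in results])
    usable = np.isfinite(originals) & np.isfinite(null_means)
    originals, null_means = originals[usable], null_means[usable]
    if len(originals) < 3:
        raise ValueError(
            f"need >= 3 usable sequences for a correlation, have {len(originals)}"
        )
    if np.array_equal(originals, null_means):
        r = 1.0  # exactly, including constant vectors from degenerate nulls
    elif np.all(originals == originals[0]) or np.all(null_means == null_means[0]):
        logger.info(
            "property %r: constant values across sequences, correlation undefined",
            results[0].property,
        )
        r = float("nan")
    else:
        r = float(stats.pearsonr(originals, null_means)[0])
    return PermutationDatasetStats(
        property=names.pop(), pearson_r=r, n_sequences=int(len(originals))
    )


def run_permutation_experiment(
    records: Sequence[SequenceRecord],
    properties: ConsensusPropertySuite | Mapping[str, PropertyFn] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Permute every record `n_perm` times and summarize all properties.

    Returns the per-sequence result table (columns id, property, original,
    null_mean, null_sd, z, n_perm) and the per-property Pearson table
    (property, pearson_r, n).  Deterministic given `seed`; per-sequence
    sub-seeds are hash-derived from (seed, id), so rows are independent of
    dataset ordering.
    """
    if properties is None:
        properties = default_property_suite()
    rows: list[PermutationResult] = []
    for record in records:
        rng = np.random.default_rng(derive_subseed(seed, record.id))
        if isinstance(properties, ConsensusPropertySuite):
            enc = _engine.encode(record.sequence)
            batch = np.empty((n_perm + 1, len(enc)), dtype=enc.dtype)
            batch[0] = enc
            for k in range(n_perm):
                batch[k + 1] = enc[rng.permutation(len(enc))]
            values = properties.evaluate_batch(batch)
            for name in properties.names:
                rows.append(
                    _null_summary(record.id, name, float(values[name][0]),
                                  values[name][1:], n_perm)
                )
        else:
            perms = [rng.permutation(len(record.sequence)) for _ in range(n_perm)]
            variants = ["".join(record.sequence[i] for i in perm) for perm in perms]
            for name, fn in properties.items():
                original = float(fn(record.sequence))
                null_values = np.array([float(fn(v)) for v in variants])
                rows.append(
                    _null_summary(record.id, name, original, null_values, n_perm)
                )
    results_df = pd.DataFrame(
        {
            "id": [r.id for r in rows],
            "property": [r.property for r in rows],
            "original": [r.original for r in rows],
            "null_mean": [r.null_mean for r in rows],
            "null_sd": [r.null_sd for r in rows],
            "z": [np.nan if r.z is None else r.z for r in rows],
            "n_perm": [r.n_perm for r in rows],
        }
    )
    stats_rows = []
    for name in dict.fromkeys(r.property for r in rows):
        subset = [r for r in rows if r.property == name]
        ds = dataset_correlation(subset)
        stats_rows.append(
            {"property": ds.property, "pearson_r": ds.pearson_r, "n": ds.n_sequences}
        )
    stats_df = pd.DataFrame(stats_rows)
    return results_df, stats_df
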