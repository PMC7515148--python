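"""Amino-acid composition vectors and principal component analysis.

Each sequence is reduced to its normalized residue frequencies — a point in
the 20-simplex — and PCA of the centered (covariance, unscaled) frequency
matrix gives the dominant compositional axes of a dataset.  Disordered
sequence sets typically separate from globular ones along components loaded
with the classic disorder-promoting residues (G/P/S/Q-rich polar axes,
E/K/A-rich charged axes).

Eigenvector sign is arbitrary, so a deterministic convention is imposed:
within each component, the loading of largest absolute value is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .seqio import AMINO_ACIDS, SequenceRecord


@dataclass(frozen=True)
class CompositionVector:
    """Normalized residue frequencies, indexed alphabetically (ACDEFGHIKLMNPQRSTVWY)."""

    id: str
    freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.freqs) != 20:
            raise ValueError(f"{self.id!r}: expected 20 frequencies, got {len(self.freqs)}")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError(f"{self.id!r}: frequencies sum to {sum(self.freqs)}, not 1")


@dataclass(frozen=True)
class PCAResult:
    """Fitted composition PCA: mean, orthonormal loadings, variance ratios, projections."""

    ids: tuple[str, ...]
    mean_vector: np.ndarray           # (20,)
    loadings: np.ndarray              # (k, 20), rows orthonormal
    explained_variance_ratio: np.ndarray  # (k,), non-increasing
    projections: np.ndarray           # (n, k)


def composition(record: SequenceRecord) -> CompositionVector:
    """Residue counts divided by sequence length."""
    length = len(record)
    counts = [record.sequence.count(aa) for aa in AMINO_ACIDS]
    return CompositionVector(id=record.id, freqs=tuple(c / length for c in counts))


def fit_pca(vectors: Sequence[CompositionVector], k: int = 2,
            standardize: bool = False) -> PCAResult:
    """PCA of composition vectors.

    Centering by the dataset mean, no variance scaling by default
    (frequencies already share a common scale; standardizing would inflate
    rare-residue noise — `standardize` exists for sensitivity checks).  At
    most ``min(n_samples - 1, 20)`` components can be extracted; asking for
    more raises with the achievable number.  Data directions of zero variance
    yield zero-variance components, which keeps full-dimensional
    reconstruction exact.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(vectors)
    achievable = min(n - 1, 20)
    if k > achievable:
        raise ValueError(
            f"k={k} exceeds the {achievable} components achievable from "
            f"{n} vectors in 20 dimensions"
        )
    matrix = np.array([v.freqs for v in vectors])
    if standardize:
        sd = matrix.std(axis=0, ddof=0)
        matrix = matrix / np.where(sd > 0, sd, 1.0)  # PCA centers; scale only here
    pca = PCA(n_components=k, svd_solver="full")
    projections = pca.fit_transform(matrix)
    loadings = pca.components_.copy()
    # deterministic sign: the largest-|.| loading of each component is positive
    for row in range(k):
        pivot = int(np.argmax(np.abs(loadings[row])))
        if loadings[row, pivot] < 0:
            loadings[row] *= -1.0
            projections[:, row] *= -1.0
    return PCAResult(
        ids=tuple(v.id for v in vectors),
        mean_vector=pca.mean_.copy(),
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        projections=projections,
    )


@dataclass(frozen=True)
class EnrichmentSummary:
    """Residues with the strongest positive and negative loadings on one component."""

    component: int
    positive: tuple[tuple[str, float], ...]
    negative: tuple[tuple[str, float], ...]


def enrichment_summary(result: PCAResult, component: int = 1,
                       top_n: int = 6) -> EnrichmentSummary:
    """Rank residues by signed loading on a component (1-based: 1 = PC1).

    Returns the `top_n` most positive and `top_n` most negative loadings;
    equal loadings order alphabetically.
    """
    if not 1 <= component <= result.loadings.shape[0]:
        raise ValueError(
            f"component {component} outside 1..{result.loadings.shape[0]}"
        )
    loadings = result.loadings[component - 1]
    ranked = sorted(zip(AMINO_ACIDS, loadings), key=lambda t: (-t[1], t[0]))
    positive = tuple((aa, float(v)) for aa, v in ranked[:top_n])
    negative = tuple(
        (aa, float(v))
        for aa, v in sorted(ranked[-top_n:], key=lambda t: (t[1], t[0]))
    )
    return EnrichmentSummary(component=component, positive=positive, negative=negative)


def projections_table(result: PCAResult,
                      datasets: dict[str, str] | None = None) -> pd.DataFrame:
    """Projections as a TSV-ready table: id, dataset, PC1..PCk."""
    k = result.loadings.shape[0]
    data = {"id": list(result.ids)}
    if datasets is not None:
        data["dataset"] = [datasets.get(i, "other") for i in result.ids]
    for j in range(k):
        data[f"PC{j + 1}"] = result.projections[:, j]
    return pd.DataFrame(data)


def loadings_table(result: PCAResult) -> pd.DataFrame:
    """Loadings as a TSV-ready table: residue, PC1..PCk."""
    k = result.loadings.shape[0]
    data = {"residue": list(AMINO_ACIDS)}
    for j in range(k):
        data[f"PC{j + 1}"] = result.loadings[j]
    return pd.DataFrame(data)
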