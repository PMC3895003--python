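"""Intra-cohort Hamming structure matrices and mean-distance reordering.

The structure matrix of a cohort is the n x n matrix of pairwise Hamming
distances between its sequences restricted to the selected loci.  Ordering
samples by ascending mean distance to all others exposes block structure
(potential sub-types) when the reordered matrix is rendered as an image,
and the same ordering applied to the agreement scores yields a generally
decreasing trace for a well-separated disease cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .modal import LocusSelection
from .standard_form import AlleleMatrix, MISSING


@dataclass
class StructureMatrix:
    distances: np.ndarray        # n x n symmetric int matrix
    cohort: str | None
    sample_ids: list[str]
    n_loci: int                  # L of the selection
    ordering: np.ndarray | None = None  # original indices in display order

    def mean_distances(self) -> np.ndarray:
        """Mean Hamming distance of each sequence to all others (self excluded)."""
        n = self.distances.shape[0]
        if n < 2:
            return np.zeros(n)
        return self.distances.sum(axis=1) / (n - 1)


def hamming_matrix(
    m: AlleleMatrix | np.ndarray,
    selection: LocusSelection | None = None,
    cohort: str | None = None,
) -> StructureMatrix:
    """Pairwise Hamming distance matrix on the selected loci.

    ``m`` is an AlleleMatrix (with ``cohort`` naming which rows to use) or
    a plain symbol array.
    """
    if isinstance(m, AlleleMatrix):
        if cohort is not None:
            mask = m.labels == cohort
            sym = m.symbols[mask]
            ids = [s for s, k in zip(m.sample_ids, mask) if k]
        else:
            sym = m.symbols
            ids = list(m.sample_ids)
    else:
        sym = np.asarray(m)
        ids = [f"S{i + 1:05d}" for i in range(sym.shape[0])]
    if sym.shape[0] == 0:
        raise ValueError(f"cohort {cohort!r} is empty")
    if selection is not None:
        sym = sym[:, selection.indices]
    if (sym == MISSING).any():
        raise ValueError("missing symbols; impute before computing distances")
    L = sym.shape[1]
    d = squareform(np.rint(pdist(sym, metric="hamming") * L).astype(np.int64))
    return StructureMatrix(d, cohort, ids, L)


def distance_histogram(s: StructureMatrix, bins: int = 100):
    """Histogram and gaussian fit of the upper-triangle distances.

    Returns ``(counts, edges, mean, sd)`` with the unbiased SD.
    """
    iu = np.triu_indices_from(s.distances, k=1)
    vals = s.distances[iu].astype(float)
    counts, edges = np.histogram(vals, bins=bins)
    return counts, edges, float(vals.mean()), float(vals.std(ddof=1))


def reorder_by_mean_distance(s: StructureMatrix) -> StructureMatrix:
    """Sort rows/columns by ascending mean distance, ties by original index."""
    md = s.mean_distances()
    order = np.argsort(md, kind="stable")
    if s.ordering is not None:
        # matrix already permuted: compose with the existing ordering
        orig = np.asarray(s.ordering)[order]
    else:
        orig = order
    d = s.distances[np.ix_(order, order)]
    ids = [s.sample_ids[i] for i in order]
    return StructureMatrix(d, s.cohort, ids, s.n_loci, ordering=orig)


def reordered_scores(
    scores: np.ndarray,
    ordering: np.ndarray,
    exclude: np.ndarray | list[int] = (),
) -> np.ndarray:
    """Scores listed in the structure ordering.

    ``exclude`` lists *original* sample indices to drop from the trace
    (display trimming is always an explicit caller decision).
    """
    scores = np.asarray(scores)
    ordering = np.asarray(ordering)
    if scores.shape[0] != ordering.shape[0]:
        raise ValueError("scores and ordering must cover the same cohort")
    excl = set(int(i) for i in np.asarray(exclude, dtype=int).ravel())
    keep = [i for i in ordering if int(i) not in excl]
    return scores[np.asarray(keep, dtype=int)]
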