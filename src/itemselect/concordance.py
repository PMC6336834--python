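"""Rank-agreement statistics for item-selection orderings.

An *ordering* is a sequence of distinct item labels; the rank of an item is
its 1-based position (the step at which it was added or removed).  Because
orderings are strict permutations by construction, no tie corrections are
applied anywhere.

``kendall_tau`` measures agreement between two orderings of the same items
by pair concordance, ``tau = (C - D) / (n (n - 1) / 2)``.  ``kendall_w``
measures agreement of one procedure's orderings across many replications,
``W = 12 S / (m^2 (n^3 - n))`` with ``S`` the sum of squared deviations of
the items' total ranks from their mean.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .selection import SelectionTrace

__all__ = ["kendall_tau", "kendall_w", "trace_to_ranks"]


def _as_labels(ordering: Iterable[int]) -> np.ndarray:
    labels = np.asarray([int(l) for l in ordering])
    if np.unique(labels).size != labels.size:
        raise ValueError("ordering contains duplicate labels")
    return labels


def _ranks_of(ordering: np.ndarray, by: np.ndarray) -> np.ndarray:
    """1-based rank of each label in ``by`` within ``ordering``."""
    rank = {int(l): i + 1 for i, l in enumerate(ordering)}
    return np.array([rank[int(l)] for l in by])


def kendall_tau(a: Sequence[int], b: Sequence[int]) -> float:
    """Kendall's tau between two orderings of the same item set.

    A pair of items is concordant when both orderings agree on which member
    comes first, discordant otherwise.
    """
    a = _as_labels(a)
    b = _as_labels(b)
    if set(a.tolist()) != set(b.tolist()):
        raise ValueError("orderings must cover the same item set")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 items")
    ra = np.arange(1, n + 1)
    rb = _ranks_of(b, by=a)
    iu, ju = np.triu_indices(n, k=1)
    signs = np.sign((ra[iu] - ra[ju]) * (rb[iu] - rb[ju]))
    return float(signs.sum() / (n * (n - 1) / 2))


def kendall_w(ranks: np.ndarray) -> float:
    """Kendall's coefficient of concordance over an m x n rank matrix.

    Row ``j`` holds the ranks of the n items in replication ``j`` and must
    be a permutation of 1..n.
    """
    ranks = np.asarray(ranks)
    if ranks.ndim != 2:
        raise ValueError("rank matrix must be two-dimensional")
    m, n = ranks.shape
    if m < 2:
        raise ValueError("need at least 2 rank rows")
    expected = np.arange(1, n + 1)
    if not np.array_equal(np.sort(ranks, axis=1), np.tile(expected, (m, 1))):
        raise ValueError("every row must be a permutation of 1..n")
    R = ranks.sum(axis=0)
    S = float(((R - R.mean()) ** 2).sum())
    return 12.0 * S / (m * m * (n**3 - n))


def trace_to_ranks(
    traces: Sequence[SelectionTrace], reference: Sequence[int]
) -> np.ndarray:
    """Rank matrix of selection traces against a reference ordering.

    Row ``j`` assigns each reference item the step number at which trace
    ``j`` selected (bottom-up) or removed (top-down) it; columns follow the
    reference label order.  Top-down traces whose survivors fall inside the
    reference set are completed via
    :meth:`itemselect.selection.SelectionTrace.ordering_over`.
    """
    reference = _as_labels(reference)
    if not traces:
        raise ValueError("need at least one trace")
    procedures = {t.procedure for t in traces}
    if len(procedures) > 1:
        raise ValueError("all traces must share one procedure")
    rows = [
        _ranks_of(np.asarray(t.ordering_over(reference)), by=reference)
        for t in traces
    ]
    return np.vstack(rows)
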