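"""Primary and secondary reference selection.

The primary reference anchors both the Procrustes alignment and the
embedding center set: it is the sample with the most unique cell types
(ties: larger cell count, then input order), unless the user names one.
Secondary references are the minimum set of further samples whose types,
together with the primary's, cover every type in the collection — a set
cover, solved exactly by exhaustive search for small collections and by
the greedy heuristic otherwise.
"""

from __future__ import annotations

from itertools import combinations

from .core import SampleCollection

#: Below this many candidate samples, set cover is solved exhaustively.
EXHAUSTIVE_LIMIT = 12


def select_primary(collection: SampleCollection,
                   user_choice: str | None = None) -> str:
    """Pick the primary reference sample id."""
    if user_choice is not None:
        if user_choice not in collection.sample_ids:
            raise ValueError(f"unknown sample id {user_choice!r}")
        return user_choice
    if not collection.all_labeled:
        raise ValueError("reference selection requires labeled samples")
    best = max(collection.samples,
               key=lambda s: (len(s.label_set()), s.n))
    return best.sample_id


def _greedy_cover(uncovered: set[int], candidates: list) -> list[str]:
    order = []
    remaining = list(candidates)
    uncovered = set(uncovered)
    while uncovered:
        best = max(remaining,
                   key=lambda s: (len(s.label_set() & uncovered), s.n))
        gain = best.label_set() & uncovered
        if not gain:
            break  # unreachable: vocabulary is built from the samples
        order.append(best.sample_id)
        uncovered -= gain
        remaining.remove(best)
    return order


def _exhaustive_cover(uncovered: set[int], candidates: list) -> list[str]:
    """Smallest covering subset; among equal sizes, first in greedy-style
    preference order (larger joint n, then input order)."""
    for size in range(1, len(candidates) + 1):
        best_combo = None
        best_n = -1
        for combo in combinations(candidates, size):
            covered = set().union(*(s.label_set() for s in combo))
            if uncovered <= covered:
                total_n = sum(s.n for s in combo)
                if total_n > best_n:
                    best_combo, best_n = combo, total_n
        if best_combo is not None:
            # order the chosen subset greedily so chaining adds the most
            # new types first
            return _greedy_cover(uncovered, list(best_combo))
    return []


def select_secondary(collection: SampleCollection,
                     primary: str) -> list[str]:
    """Ordered minimal set of secondary references completing type coverage.

    Empty when the primary already covers every type.  Exact (exhaustive)
    for up to :data:`EXHAUSTIVE_LIMIT` candidate samples, greedy beyond.
    """
    primary_types = collection[primary].label_set()
    uncovered = collection.all_types() - primary_types
    if not uncovered:
        return []
    candidates = [s for s in collection.samples if s.sample_id != primary]
    if len(candidates) <= EXHAUSTIVE_LIMIT:
        return _exhaustive_cover(uncovered, candidates)
    return _greedy_cover(uncovered, candidates)
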