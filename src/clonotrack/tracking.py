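"""Longitudinal and cross-compartment clone tracking.

Because a clone's receptor is fixed for life, the same clonotype key seen in
two samples — different timepoints, sorted subsets, tissues, or
transcriptomic clusters — identifies the same clone. This module provides
the set arithmetic of that tracking: which expanded clones at a later
timepoint were already detectable earlier (persistence), which clones moved
between sorted phenotypes (transitions), how a reference cluster's clones
distribute over earlier clusters, and exact multiway intersection tables
(upset-style) over named clone sets.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import CellClonotype, Repertoire

logger = logging.getLogger(__name__)

__all__ = [
    "IntersectionTable",
    "expanded_clones",
    "clone_sizes",
    "persistence_fraction",
    "transition_clones",
    "cluster_overlap_with_reference",
    "intersection_table",
]


def clone_sizes(source, level: str = "nt", use_vj: bool = True) -> Counter:
    """Clone-size spectrum of a repertoire (reads) or cell list (cells)."""
    if isinstance(source, Repertoire):
        return Counter(source.clonotypes)
    sizes: Counter = Counter()
    for cell in source:
        sizes[cell.paired_key(level=level, use_vj=use_vj)] += 1
    return sizes


def expanded_clones(source, min_size: int = 2, level: str = "nt", use_vj: bool = True) -> frozenset:
    """Keys of clones with size >= ``min_size``.

    ``source`` is a :class:`Repertoire` (size = read count) or an iterable
    of :class:`CellClonotype` (size = cell count). ``min_size=1`` returns
    every observed key.
    """
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    sizes = clone_sizes(source, level=level, use_vj=use_vj)
    return frozenset(k for k, s in sizes.items() if s >= min_size)


def persistence_fraction(expanded_at_t2: Iterable, observed_at_t1: Iterable) -> float:
    """Fraction of later-expanded clones already detected at an earlier time.

    ``|expanded_at_t2 & observed_at_t1| / |expanded_at_t2|``. Both arguments
    are key sets in the same key mode. Undefined (NaN) when no clones are
    expanded at the later timepoint.
    """
    expanded = frozenset(expanded_at_t2)
    if not expanded:
        logger.warning("persistence undefined: no expanded clones at the later timepoint")
        return float("nan")
    observed = frozenset(observed_at_t1)
    return len(expanded & observed) / len(expanded)


def transition_clones(
    source_subset_t0: Iterable,
    excluded_subset_t0: Iterable,
    target_subset_t1: Iterable,
) -> tuple[frozenset, float]:
    """Clones unique to one subset at baseline later seen in another subset.

    Returns ``((source_t0 \\ excluded_t0) & target_t1`` and that set's size
    as a fraction of ``source_t0 \\ excluded_t0``. A baseline-unique pool
    that is empty yields an empty set and NaN fraction.
    """
    unique_t0 = frozenset(source_subset_t0) - frozenset(excluded_subset_t0)
    if not unique_t0:
        logger.warning("no clones unique to the source subset at baseline")
        return frozenset(), float("nan")
    moved = unique_t0 & frozenset(target_subset_t1)
    return frozenset(moved), len(moved) / len(unique_t0)


def cluster_overlap_with_reference(
    reference_cells: Sequence[CellClonotype],
    comparison_groups: Mapping[str, Sequence[CellClonotype]],
    level: str = "nt",
    use_vj: bool = True,
) -> pd.DataFrame:
    """Per-group fraction of a reference cluster's clonotypes seen in each group.

    For each comparison group ``g`` the fraction is
    ``|keys(reference) & keys(g)| / |keys(reference)|``. The returned frame
    is sorted by descending overlap, with a ``rank`` column (1 = highest).
    Raises on an empty reference.
    """
    ref_keys = frozenset(c.paired_key(level=level, use_vj=use_vj) for c in reference_cells)
    if not ref_keys:
        raise ValueError("reference cluster has no cells")
    rows = []
    for name, cells in comparison_groups.items():
        keys = frozenset(c.paired_key(level=level, use_vj=use_vj) for c in cells)
        shared = len(ref_keys & keys)
        rows.append({"group": name, "n_shared": shared, "fraction": shared / len(ref_keys)})
    df = pd.DataFrame(rows).sort_values(
        ["fraction", "group"], ascending=[False, True], ignore_index=True
    )
    df["rank"] = range(1, len(df) + 1)
    return df


@dataclass
class IntersectionTable:
    """Exact-membership intersection counts over named clone sets."""

    table: pd.DataFrame  # columns: combination (tuple of set names), count
    union_size: int
    n_sets: int

    def count(self, *names: str) -> int:
        combo = tuple(sorted(names))
        hit = self.table.loc[self.table["combination"] == combo, "count"]
        return int(hit.iloc[0]) if len(hit) else 0


def intersection_table(named_sets: Mapping[str, Iterable], top_k: int | None = None) -> IntersectionTable:
    """Upset-style table: for each combination of set names, the number of
    keys belonging to exactly that combination.

    Counts over all combinations sum to the union cardinality (asserted).
    ``top_k`` truncates to the most populous combinations after sorting by
    descending count; the conservation check runs before truncation.
    """
    sets = {name: frozenset(s) for name, s in named_sets.items()}
    if len(sets) < 2:
        raise ValueError("need at least two named sets")
    membership: Counter = Counter()
    union = frozenset().union(*sets.values())
    for key in union:
        combo = tuple(sorted(name for name, s in sets.items() if key in s))
        membership[combo] += 1
    assert sum(membership.values()) == len(union), "intersection counts must sum to |union|"
    df = pd.DataFrame(
        [{"combination": combo, "degree": len(combo), "count": n} for combo, n in membership.items()]
    ).sort_values(["count", "combination"], ascending=[False, True], ignore_index=True)
    if top_k is not None:
        df = df.head(top_k).reset_index(drop=True)
    return IntersectionTable(table=df, union_size=len(union), n_sets=len(sets))
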