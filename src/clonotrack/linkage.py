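"""Linking single-cell clonotypes to bulk sorted-pool repertoires.

Single-cell data yields paired alpha/beta clonotypes with transcriptomic
cluster labels; bulk sorted-pool data is beta-chain only. The bridge is a
beta-chain projection of the paired key — by default CDR3 amino acid plus
TRB V/J, since bulk genomic DNA and single-cell cDNA platforms can disagree
at the nucleotide junction level while agreeing on the translated CDR3.

Two complementary quantities are computed per cluster:

* ``detection_fraction`` — the fraction of the cluster's *distinct*
  clonotypes found in a bulk pool (clonotype-level);
* ``pool_ratio`` — the fraction of a bulk pool's *reads* carried by
  cluster-matching clonotypes in one pool relative to another (read-level).
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .diversity import inverse_simpson
from .types import BetaKey, CellClonotype, Repertoire

logger = logging.getLogger(__name__)

__all__ = [
    "LinkageResult",
    "project_key",
    "detection_fraction",
    "pool_ratio",
    "per_cluster_clonality",
]


def project_key(cell_or_key, level: str = "aa", use_vj: bool = True) -> BetaKey:
    """Project a paired alpha/beta clonotype onto a beta-only bulk key.

    Accepts a :class:`CellClonotype`, a paired key tuple produced by
    :meth:`CellClonotype.paired_key`, or an already-projected
    :class:`BetaKey` (idempotent). Cells sharing a TRB but differing in TRA
    project to the same bulk key.
    """
    if isinstance(cell_or_key, BetaKey):
        return cell_or_key
    if isinstance(cell_or_key, CellClonotype):
        return cell_or_key.beta_key(level=level, use_vj=use_vj)
    if isinstance(cell_or_key, tuple) and len(cell_or_key) == 3 and cell_or_key[0] == "paired_ab":
        trb = cell_or_key[2]
        if not trb or not trb.cdr3:
            raise ValueError("paired key has no TRB chain to project")
        return BetaKey(*trb)
    raise TypeError(f"cannot project {cell_or_key!r} onto a bulk beta key")


@dataclass
class LinkageResult:
    """Detection of one single-cell cluster's clonotypes in one bulk pool."""

    cluster: str
    pool: str
    n_cluster_clonotypes: int
    n_detected: int
    detection_fraction: float
    #: per projected clonotype: bulk read frequency (0 when undetected)
    bulk_frequencies: dict = field(default_factory=dict)
    #: per-replicate detection fractions, when replicates were supplied
    per_replicate: dict = field(default_factory=dict)


def _bulk_frequency(pool: Repertoire, key: BetaKey) -> float:
    total = pool.total_reads
    return pool.clonotypes.get(key, 0) / total if total else 0.0


def detection_fraction(
    cluster_cells: Sequence[CellClonotype],
    bulk_pool: Repertoire | Sequence[Repertoire],
    level: str = "aa",
    use_vj: bool = True,
    cluster: str = "",
) -> LinkageResult:
    """Fraction of a cluster's distinct clonotypes present in a bulk pool.

    ``bulk_pool`` may be a single repertoire or a sequence of technical
    replicates; with replicates a clonotype counts as detected if present
    in *either* replicate, and per-replicate fractions are also reported.
    Raises on an empty cluster. The bulk pool must be keyed at the same
    sequence level as the projection (checked).
    """
    if not cluster_cells:
        raise ValueError("empty cluster: detection fraction undefined")
    replicates = [bulk_pool] if isinstance(bulk_pool, Repertoire) else list(bulk_pool)
    for rep in replicates:
        if rep.key_level != level:
            raise ValueError(
                f"bulk pool keyed at {rep.key_level!r} but projection level is {level!r}"
            )
    keys = sorted({project_key(c, level=level, use_vj=use_vj) for c in cluster_cells})
    union_keys = set().union(*(r.key_set() for r in replicates))
    detected = [k for k in keys if k in union_keys]
    merged_total = sum(r.total_reads for r in replicates)
    freqs = {
        k: sum(r.clonotypes.get(k, 0) for r in replicates) / merged_total if merged_total else 0.0
        for k in keys
    }
    per_rep = {}
    if len(replicates) > 1:
        for rep in replicates:
            hit = sum(1 for k in keys if k in rep.clonotypes)
            per_rep[rep.replicate or rep.sample_id] = hit / len(keys)
    pool_label = replicates[0].subset or replicates[0].sample_id
    if not cluster and cluster_cells[0].cluster:
        cluster = cluster_cells[0].cluster
    return LinkageResult(
        cluster=cluster,
        pool=pool_label,
        n_cluster_clonotypes=len(keys),
        n_detected=len(detected),
        detection_fraction=len(detected) / len(keys),
        bulk_frequencies=freqs,
        per_replicate=per_rep,
    )


def pool_ratio(
    cluster_cells: Sequence[CellClonotype],
    pool_x: Repertoire,
    pool_y: Repertoire,
    level: str = "aa",
    use_vj: bool = True,
) -> float:
    """Read-level pool ratio for one cluster.

    Numerator: fraction of ``pool_x`` reads belonging to clonotypes that
    match the cluster; denominator: the same for ``pool_y``. A zero
    denominator with nonzero numerator returns ``inf`` (flagged via log);
    zero over zero is NaN. Exchanging the pools yields the exact
    reciprocal.
    """
    keys = {project_key(c, level=level, use_vj=use_vj) for c in cluster_cells}

    def matched_read_fraction(pool: Repertoire) -> float:
        total = pool.total_reads
        if total == 0:
            return 0.0
        return sum(n for k, n in pool.clonotypes.items() if k in keys) / total

    fx, fy = matched_read_fraction(pool_x), matched_read_fraction(pool_y)
    if fy == 0.0:
        if fx == 0.0:
            logger.warning("cluster matches no reads in either pool; ratio undefined")
            return float("nan")
        logger.warning("cluster matches no reads in pool %s; ratio infinite", pool_y.sample_id)
        return math.inf
    return fx / fy


def per_cluster_clonality(
    cells: Sequence[CellClonotype],
    group_by: tuple[str, ...] = ("cluster", "sorted_gate"),
    level: str = "nt",
    use_vj: bool = True,
) -> pd.DataFrame:
    """Inverse Simpson clonality of the cell-level clone-size spectrum per group.

    Cells are grouped by the given metadata fields (default cluster x sorted
    gate); within each group clone sizes are cell counts per paired
    clonotype, converted to relative abundances.
    """
    groups: dict[tuple, list[CellClonotype]] = defaultdict(list)
    for cell in cells:
        groups[tuple(getattr(cell, f) for f in group_by)].append(cell)
    rows = []
    for gkey in sorted(groups):
        members = groups[gkey]
        sizes: dict = defaultdict(int)
        for c in members:
            sizes[c.paired_key(level=level, use_vj=use_vj)] += 1
        row = dict(zip(group_by, gkey))
        row["n_cells"] = len(members)
        row["n_clones"] = len(sizes)
        row["inverse_simpson"] = inverse_simpson(sizes.values())
        rows.append(row)
    return pd.DataFrame(rows)
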