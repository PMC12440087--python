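"""Depth-normalized clonality and pairwise repertoire overlap.

Clonality is summarized by the inverse Simpson index ``1 / sum_i p_i**2``
(the effective number of clones; 1 for a monoclonal sample, K for K equal
clones). Because diversity estimates are depth-dependent, repertoires are
rarefied — reads drawn without replacement — to a common depth (default
5000 reads) before comparison, and technical replicates are averaged.

Overlap between two repertoires is reported as the Morisita-Horn index

    MH(x, y) = 2 * sum_i p_i q_i / (sum_i p_i**2 + sum_i q_i**2)

over the union of clonotype keys (abundance-weighted, in [0, 1], 1 iff the
relative-abundance vectors coincide), alongside the presence/absence
Jaccard index and the raw shared-clone count.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .types import Repertoire

logger = logging.getLogger(__name__)

__all__ = [
    "DiversityResult",
    "OverlapMatrix",
    "downsample",
    "inverse_simpson",
    "clonality_with_replicates",
    "morisita_horn",
    "shared_clones",
    "jaccard",
    "overlap_matrix",
]

DEFAULT_DEPTH = 5000


@dataclass
class DiversityResult:
    """Replicate-averaged, depth-normalized inverse Simpson clonality."""

    sample_id: str
    depth: int
    n_iterations: int
    inverse_simpson_mean: float
    per_iteration: list[float] = field(default_factory=list)
    shallow_replicates: int = 0


@dataclass
class OverlapMatrix:
    """Symmetric pairwise overlap statistic with labeled axes."""

    statistic: str
    values: pd.DataFrame  # square, index == columns == sample ids
    sample_labels: pd.DataFrame  # one row of provenance labels per sample

    def value(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])


def downsample(repertoire: Repertoire, depth: int, seed=None) -> Repertoire:
    """Rarefy a repertoire to exactly ``depth`` reads without replacement.

    Draws follow the multivariate hypergeometric distribution over the read
    multiset, so the expected drawn count of a clone is
    ``depth * count / total_reads``. Repertoires shallower than ``depth``
    are returned unchanged with ``meta['shallow'] = True`` rather than
    rejected.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    total = repertoire.total_reads
    if total < depth:
        logger.warning(
            "%s: %d reads < target depth %d; analyzed at full depth",
            repertoire.sample_id or "<sample>", total, depth,
        )
        return repertoire.with_counts(repertoire.clonotypes, shallow=True)
    if total == depth:
        return repertoire.with_counts(repertoire.clonotypes, shallow=False, downsampled_to=depth)
    rng = np.random.default_rng(seed)
    keys = list(repertoire.clonotypes)
    counts = np.fromiter((repertoire.clonotypes[k] for k in keys), dtype=np.int64)
    drawn = rng.multivariate_hypergeometric(counts, depth)
    new_counts = Counter({k: int(c) for k, c in zip(keys, drawn) if c > 0})
    return repertoire.with_counts(new_counts, shallow=False, downsampled_to=depth)


def _inverse_simpson_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        raise ValueError("empty repertoire: inverse Simpson undefined")
    p = counts / total
    return float(1.0 / np.sum(p * p))


def inverse_simpson(repertoire) -> float:
    """Inverse Simpson index ``1 / sum p_i**2`` of a repertoire or counts."""
    if isinstance(repertoire, Repertoire):
        counts = np.fromiter(repertoire.clonotypes.values(), dtype=float)
    else:
        counts = np.asarray(list(repertoire), dtype=float)
    return _inverse_simpson_from_counts(counts)


def clonality_with_replicates(
    replicates: Sequence[Repertoire],
    depth: int = DEFAULT_DEPTH,
    n_iter: int = 10,
    seed=None,
) -> DiversityResult:
    """Mean downsampled inverse Simpson over replicates and iterations.

    For each technical replicate the index is computed on ``n_iter``
    independent rarefactions to ``depth`` reads; the summary is the grand
    mean. Replicates shallower than ``depth`` contribute at full depth and
    are counted in ``shallow_replicates``.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    values: list[float] = []
    n_shallow = 0
    for rep in replicates:
        if rep.total_reads <= depth:
            if rep.total_reads < depth:
                n_shallow += 1
                logger.warning(
                    "%s below target depth; computed at full depth", rep.sample_id or "<sample>"
                )
            values.extend([inverse_simpson(rep)] * n_iter)
            continue
        for _ in range(n_iter):
            values.append(inverse_simpson(downsample(rep, depth, seed=rng)))
    sample_id = replicates[0].sample_id
    return DiversityResult(
        sample_id=sample_id,
        depth=depth,
        n_iterations=n_iter,
        inverse_simpson_mean=float(np.mean(values)),
        per_iteration=values,
        shallow_replicates=n_shallow,
    )


def _aligned_abundances(rep_x: Repertoire, rep_y: Repertoire):
    keys = sorted(set(rep_x.clonotypes) | set(rep_y.clonotypes))
    x = np.fromiter((rep_x.clonotypes.get(k, 0) for k in keys), dtype=float)
    y = np.fromiter((rep_y.clonotypes.get(k, 0) for k in keys), dtype=float)
    return x, y


def morisita_horn(rep_x: Repertoire, rep_y: Repertoire) -> float:
    """Morisita-Horn overlap of two repertoires over their key union."""
    if rep_x.n_clones == 0 or rep_y.n_clones == 0:
        logger.warning("Morisita-Horn undefined for an empty repertoire")
        return float("nan")
    x, y = _aligned_abundances(rep_x, rep_y)
    p, q = x / x.sum(), y / y.sum()
    denom = np.sum(p * p) + np.sum(q * q)
    return float(2.0 * np.sum(p * q) / denom)


def shared_clones(rep_x: Repertoire, rep_y: Repertoire) -> tuple[int, frozenset]:
    """Count and set of clonotype keys present in both repertoires."""
    inter = rep_x.key_set() & rep_y.key_set()
    return len(inter), inter


def jaccard(rep_x: Repertoire, rep_y: Repertoire) -> float:
    """Presence/absence Jaccard index |intersection| / |union|."""
    a, b = rep_x.key_set(), rep_y.key_set()
    union = a | b
    if not union:
        return float("nan")
    return len(a & b) / len(union)


_STATISTICS = {
    "morisita_horn": morisita_horn,
    "jaccard": jaccard,
    "shared_count": lambda x, y: float(shared_clones(x, y)[0]),
}


def overlap_matrix(
    samples: Sequence[Repertoire],
    statistic: str = "morisita_horn",
    downsample_depth: int | None = None,
    seed=None,
) -> OverlapMatrix:
    """All-pairs overlap across samples, optionally on rarefied repertoires.

    Each sample is rarefied once (seeded) before the pairwise sweep so every
    pair sees the same draw. The result is symmetric by construction.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {sorted(_STATISTICS)}")
    fn = _STATISTICS[statistic]
    rng = np.random.default_rng(seed)
    if downsample_depth is not None:
        samples = [downsample(s, downsample_depth, seed=rng) for s in samples]
    ids = [s.sample_id or f"sample_{i}" for i, s in enumerate(samples)]
    if len(set(ids)) != len(ids):
        ids = [f"{sid}#{i}" for i, sid in enumerate(ids)]
    n = len(samples)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            v = fn(samples[i], samples[j])
            mat[i, j] = mat[j, i] = v
    values = pd.DataFrame(mat, index=ids, columns=ids)
    labels = pd.DataFrame([s.labels() for s in samples], index=ids)
    return OverlapMatrix(statistic=statistic, values=values, sample_labels=labels)
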