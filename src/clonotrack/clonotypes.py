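"""Clonotype identity, filtering, and expansion binning.

A *clone* is the set of cells descending from one thymic emigrant; its
receptor sequence is the heritable barcode. For bulk TCRbeta data the clone
key is the CDR3 junction plus V/J gene calls; for paired single-cell data
both chains must match (identical V/J genes and CDR3 junctions). Clone sizes
are binned into the conventional five expansion classes:

====== =============== =========
label  size range      boundary
====== =============== =========
single s = 1
small  1 < s <= 5
medium 5 < s <= 20
large  20 < s <= 100
hyper  s > 100         (printed cap 500; larger clones stay "hyperexpanded")
====== =============== =========
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .types import CellClonotype, ChainInfo, ClonotypeRecord, ContigRecord, Repertoire

logger = logging.getLogger(__name__)

__all__ = [
    "filter_productive",
    "build_bulk_clonotypes",
    "pair_cells",
    "merge_replicates",
    "assign_expansion_bin",
    "EXPANSION_BINS",
    "qc_filter_cells",
]


def filter_productive(records: Sequence) -> list:
    """Drop non-productive rearrangements (out-of-frame, stop-containing).

    Works for both :class:`ClonotypeRecord` and :class:`ContigRecord`.
    """
    kept = [r for r in records if r.productive]
    n_removed = len(records) - len(kept)
    if n_removed:
        logger.info("removed %d non-productive record(s) of %d", n_removed, len(records))
    if records and not kept:
        logger.warning("all %d record(s) were non-productive", len(records))
    return kept


def build_bulk_clonotypes(
    records: Iterable[ClonotypeRecord],
    key_level: str = "nt",
    use_vj: bool = True,
) -> Repertoire:
    """Aggregate records into a repertoire keyed by CDR3(+V/J).

    Read counts are summed per key; total reads are conserved. The first
    record seen for a key supplies its annotations (nt/aa junction, D call)
    for lossless write-back.
    """
    counts: Counter = Counter()
    annotations: dict = {}
    for rec in records:
        key = rec.key(level=key_level, use_vj=use_vj)
        counts[key] += rec.read_count
        if key not in annotations:
            annotations[key] = {
                "cdr3_nt": rec.cdr3_nt,
                "cdr3_aa": rec.cdr3_aa,
                "v_call": rec.v_call,
                "d_call": rec.d_call,
                "j_call": rec.j_call,
                "productive": rec.productive,
            }
    return Repertoire(key_level=key_level, clonotypes=counts, annotations=annotations)


def pair_cells(
    contigs: Sequence[ContigRecord],
    metadata: pd.DataFrame | None = None,
    multi_chain: str = "max_umi",
) -> list[CellClonotype]:
    """Assemble per-cell paired alpha/beta clonotypes.

    Cells lacking either a productive TRA or a productive TRB are removed.
    When a barcode carries more than one productive contig for a locus, the
    ``multi_chain`` policy decides: ``"max_umi"`` keeps the highest-UMI
    contig (ties broken lexicographically by CDR3 nt), ``"drop"`` discards
    the cell as ambiguous. Barcodes absent from ``metadata`` (when given)
    are dropped with a warning. Output is sorted by barcode and independent
    of the input row order.
    """
    if multi_chain not in ("max_umi", "drop"):
        raise ValueError(f"unknown multi_chain policy: {multi_chain!r}")
    by_cell: dict[str, dict[str, list[ContigRecord]]] = defaultdict(lambda: {"TRA": [], "TRB": []})
    for c in contigs:
        if not c.productive:
            continue
        by_cell[c.barcode][c.chain].append(c)

    cells: list[CellClonotype] = []
    n_single = n_multi_dropped = n_unmatched = 0
    for barcode in sorted(by_cell):
        chains = by_cell[barcode]
        if not chains["TRA"] or not chains["TRB"]:
            n_single += 1
            continue
        if multi_chain == "drop" and (len(chains["TRA"]) > 1 or len(chains["TRB"]) > 1):
            n_multi_dropped += 1
            continue
        tra = min(chains["TRA"], key=lambda c: (-c.umi_count, c.cdr3_nt))
        trb = min(chains["TRB"], key=lambda c: (-c.umi_count, c.cdr3_nt))
        meta = {}
        if metadata is not None:
            if barcode not in metadata.index:
                n_unmatched += 1
                continue
            row = metadata.loc[barcode]
            meta = {
                "donor": row.get("donor", ""),
                "sorted_gate": row.get("sorted_gate", ""),
                "tissue": row.get("tissue", ""),
                "timepoint": row.get("timepoint", ""),
                "cluster": row.get("cluster", ""),
            }
        cells.append(
            CellClonotype(
                barcode=barcode,
                tra=ChainInfo(tra.cdr3_nt, tra.cdr3_aa, tra.v_call, tra.j_call),
                trb=ChainInfo(trb.cdr3_nt, trb.cdr3_aa, trb.v_call, trb.j_call),
                **meta,
            )
        )
    if n_single:
        logger.info("dropped %d cell(s) with a single TCR alpha or beta chain", n_single)
    if n_multi_dropped:
        logger.info("dropped %d ambiguous multi-chain cell(s)", n_multi_dropped)
    if n_unmatched:
        logger.warning("dropped %d cell(s) with barcode absent from metadata", n_unmatched)
    return cells


def merge_replicates(rep_a: Repertoire, rep_b: Repertoire) -> Repertoire:
    """Merge two technical replicates of the same sample (counts summed).

    The replicates must agree on donor/subset/timepoint/tissue and key
    level; they originate from one lysate split into two libraries.
    """
    for field in ("donor", "subset", "timepoint", "tissue", "key_level"):
        a, b = getattr(rep_a, field), getattr(rep_b, field)
        if a != b:
            raise ValueError(f"replicate label mismatch on {field}: {a!r} != {b!r}")
    merged = rep_a.with_counts(rep_a.clonotypes + rep_b.clonotypes)
    merged.replicate = "merged"
    merged.annotations = {**rep_b.annotations, **rep_a.annotations}
    return merged


#: (label, low-exclusive, high-inclusive) bins partitioning clone sizes
EXPANSION_BINS = (
    ("single", 0, 1),
    ("small", 1, 5),
    ("medium", 5, 20),
    ("large", 20, 100),
    ("hyperexpanded", 100, np.inf),
)


def assign_expansion_bin(clone_size: int) -> str:
    """Map a clone size to its expansion bin label.

    Sizes above the printed cap of 500 remain "hyperexpanded" so the bins
    partition all positive integers.
    """
    if clone_size < 1:
        raise ValueError(f"clone size must be >= 1, got {clone_size}")
    for label, low, high in EXPANSION_BINS:
        if low < clone_size <= high:
            return label
    raise AssertionError("unreachable: bins partition the positive integers")


def qc_filter_cells(
    adata: ad.AnnData,
    mito_genes: Iterable[str] = (),
    min_genes: int = 200,
    max_genes: int = 3000,
    max_mito_frac: float = 0.10,
) -> np.ndarray:
    """Standard droplet QC on a raw cells x genes count matrix.

    Removes cells expressing fewer than ``min_genes`` genes, more than
    ``max_genes`` genes, or with more than ``max_mito_frac`` of total UMIs
    from mitochondrial genes. Returns a boolean keep-mask aligned to
    ``adata.obs_names``.
    """
    X = adata.X
    if hasattr(X, "toarray"):
        n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
        total = np.asarray(X.sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        n_genes = (X > 0).sum(axis=1)
        total = X.sum(axis=1)
    mito_mask = adata.var_names.isin(list(mito_genes))
    if mito_mask.any():
        sub = X[:, mito_mask]
        mito_total = np.asarray(sub.sum(axis=1)).ravel()
    else:
        mito_total = np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)
    keep = (n_genes >= min_genes) & (n_genes <= max_genes) & (mito_frac <= max_mito_frac)
    logger.info("QC retained %d / %d cells", int(keep.sum()), adata.n_obs)
    return keep
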