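"""Readers and writers for the tabular formats the pipeline touches.

Canonical on-disk formats:

* bulk clonotype tables — AIRR Rearrangement TSV (columns ``junction``,
  ``junction_aa``, ``v_call``, ``d_call``, ``j_call``, ``duplicate_count``,
  ``productive``); an iRepertoire-like CSV dialect is mapped onto the same
  schema at read time.
* single-cell contigs — 10x ``filtered_contig_annotations.csv`` dialect.
* cell metadata — TSV keyed by barcode.
* expression counts — MatrixMarket MTX with feature/barcode sidecars
  (genes x cells on disk, following the 10x convention; returned as a
  cells x genes :class:`anndata.AnnData`).

Sample provenance (donor/subset/timepoint/tissue/replicate) comes from a
manifest TSV mapping file paths to labels, never from filename parsing.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import ClonotypeRecord, ContigRecord, Repertoire

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_bulk_records",
    "read_bulk_repertoire",
    "write_airr",
    "read_sc_contigs",
    "write_contigs",
    "read_cell_metadata",
    "read_expression_mtx",
    "write_expression_mtx",
    "read_manifest",
    "load_manifest_repertoires",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


AIRR_COLUMNS = (
    "junction",
    "junction_aa",
    "v_call",
    "d_call",
    "j_call",
    "duplicate_count",
    "productive",
)

# iRepertoire-like CSV column names -> AIRR Rearrangement names
IREP_TO_AIRR = {
    "cdr3_nt": "junction",
    "cdr3_aa": "junction_aa",
    "v_gene": "v_call",
    "d_gene": "d_call",
    "j_gene": "j_call",
    "read_count": "duplicate_count",
    "productive": "productive",
}

CONTIG_COLUMNS = ("barcode", "chain", "cdr3_nt", "cdr3", "v_gene", "j_gene", "umis", "productive")

_TRUE_STRINGS = {"true", "t", "yes", "1"}


def _parse_bool(value) -> bool:
    """Normalize 10x/AIRR productivity flags ('True', 'TRUE', 'None', NaN...)."""
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    return str(value).strip().lower() in _TRUE_STRINGS


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_bulk_records(path, dialect: str = "airr") -> tuple[list[ClonotypeRecord], int]:
    """Read a bulk clonotype table into records.

    Returns ``(records, n_rejected)`` where rejected rows are those with a
    read count below 1. Counts are never altered: the sum of record counts
    equals the column sum of the source file minus rejected rows.
    """
    if dialect not in ("airr", "irepertoire"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    sep = "\t" if dialect == "airr" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if dialect == "irepertoire":
        _require_columns(df, IREP_TO_AIRR, path)
        df = df.rename(columns=IREP_TO_AIRR)
    _require_columns(df, AIRR_COLUMNS, path)
    if df.empty:
        logger.warning("%s: empty clonotype table", path)
        return [], 0

    counts = pd.to_numeric(df["duplicate_count"], errors="coerce")
    bad = ~(counts >= 1)
    n_rejected = int(bad.sum())
    if n_rejected:
        logger.warning("%s: rejected %d row(s) with read count < 1", path, n_rejected)
        df = df.loc[~bad.values]
        counts = counts.loc[~bad.values]

    records = [
        ClonotypeRecord(
            cdr3_nt=row.junction,
            cdr3_aa=row.junction_aa,
            v_call=row.v_call,
            d_call=row.d_call,
            j_call=row.j_call,
            read_count=int(c),
            productive=_parse_bool(row.productive),
        )
        for row, c in zip(df.itertuples(index=False), counts)
    ]
    return records, n_rejected


def read_bulk_repertoire(
    path,
    dialect: str = "airr",
    labels: dict | None = None,
    key_level: str = "nt",
    use_vj: bool = True,
    productive_only: bool = False,
) -> Repertoire:
    """Read one file into a :class:`Repertoire`, aggregating duplicate keys.

    ``labels`` supplies the provenance fields (donor/subset/timepoint/tissue/
    replicate), normally taken from a manifest row. With ``productive_only``
    the non-productive rearrangements are removed before aggregation, as in
    repertoire analyses of genomic TCRbeta data.
    """
    from .clonotypes import build_bulk_clonotypes, filter_productive

    records, n_rejected = read_bulk_records(path, dialect)
    if productive_only:
        records = filter_productive(records)
    rep = build_bulk_clonotypes(records, key_level=key_level, use_vj=use_vj)
    for k, v in (labels or {}).items():
        setattr(rep, k, v)
    rep.meta["source_path"] = str(path)
    rep.meta["n_rejected_rows"] = n_rejected
    if rep.n_clones == 0:
        logger.warning("%s: empty repertoire", path)
    return rep


def write_airr(repertoire: Repertoire, path) -> None:
    """Write a repertoire as AIRR Rearrangement TSV.

    Per-key annotations (CDR3 at the other sequence level, D call,
    productivity) captured at read/build time are emitted when available so
    that read -> write -> read round-trips key-for-key and count-for-count.
    """
    rows = []
    for key, count in sorted(repertoire.clonotypes.items()):
        ann = repertoire.annotations.get(key, {})
        nt = ann.get("cdr3_nt", key.cdr3 if repertoire.key_level == "nt" else "")
        aa = ann.get("cdr3_aa", key.cdr3 if repertoire.key_level == "aa" else "")
        rows.append(
            {
                "junction": nt,
                "junction_aa": aa,
                "v_call": key.v_call or ann.get("v_call", ""),
                "d_call": ann.get("d_call", ""),
                "j_call": key.j_call or ann.get("j_call", ""),
                "duplicate_count": count,
                "productive": ann.get("productive", True),
            }
        )
    pd.DataFrame(rows, columns=list(AIRR_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_sc_contigs(path) -> list[ContigRecord]:
    """Read a 10x-style contig annotation CSV.

    Rows with a chain other than TRA/TRB (e.g. "Multi") are skipped and the
    skip count logged. The productivity flag is normalized to a boolean
    ("None" and blanks count as non-productive).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, CONTIG_COLUMNS, path)
    records: list[ContigRecord] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        if row.chain not in ("TRA", "TRB"):
            n_skipped += 1
            continue
        records.append(
            ContigRecord(
                barcode=row.barcode,
                chain=row.chain,
                cdr3_nt=row.cdr3_nt,
                cdr3_aa=row.cdr3,
                v_call=row.v_gene,
                j_call=row.j_gene,
                umi_count=int(float(row.umis)) if row.umis != "" else 0,
                productive=_parse_bool(row.productive),
            )
        )
    if n_skipped:
        logger.info("%s: skipped %d contig(s) with non-TRA/TRB chain", path, n_skipped)
    return records


def write_contigs(contigs: Sequence[ContigRecord], path) -> None:
    """Write contigs in the 10x filtered_contig_annotations.csv dialect."""
    df = pd.DataFrame(
        {
            "barcode": [c.barcode for c in contigs],
            "chain": [c.chain for c in contigs],
            "cdr3": [c.cdr3_aa for c in contigs],
            "cdr3_nt": [c.cdr3_nt for c in contigs],
            "v_gene": [c.v_call for c in contigs],
            "j_gene": [c.j_call for c in contigs],
            "umis": [c.umi_count for c in contigs],
            "productive": ["True" if c.productive else "False" for c in contigs],
        }
    )
    df.to_csv(path, index=False)


METADATA_COLUMNS = ("barcode", "donor", "sorted_gate", "tissue", "timepoint", "cluster")


def read_cell_metadata(path) -> pd.DataFrame:
    """Read the barcode -> (donor, gate, tissue, timepoint, cluster) table."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, METADATA_COLUMNS, path)
    if df["barcode"].duplicated().any():
        dupes = df.loc[df["barcode"].duplicated(), "barcode"].head(3).tolist()
        raise FormatError(f"{path}: duplicate barcode(s), e.g. {dupes}")
    return df.set_index("barcode", drop=False)


def _dedupe(names: Sequence[str]) -> list[str]:
    """Append .1, .2 ... to repeated names, in file order."""
    seen: Counter = Counter()
    out = []
    for name in names:
        if seen[name]:
            out.append(f"{name}.{seen[name]}")
        else:
            out.append(name)
        seen[name] += 1
    return out


def read_expression_mtx(source) -> ad.AnnData:
    """Read an MTX count matrix with sidecars into a cells x genes AnnData.

    ``source`` is either a directory containing ``matrix.mtx``,
    ``features.tsv``, ``barcodes.tsv`` or a triple of the three paths.
    On disk the matrix is genes x cells (10x convention); the returned
    AnnData is transposed to cells x genes. Duplicate gene names are
    de-duplicated deterministically by suffixing ``.1``, ``.2``.
    """
    if isinstance(source, (str, os.PathLike)):
        d = Path(source)
        mtx, features, barcodes = d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv"
    else:
        mtx, features, barcodes = source
    mat = sp.csr_matrix(scipy.io.mmread(mtx)).T  # -> cells x genes
    genes = pd.read_csv(features, sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape != (len(cells), len(genes)):
        raise FormatError(
            f"{mtx}: matrix is {mat.shape[1]} genes x {mat.shape[0]} cells but sidecars "
            f"list {len(genes)} genes and {len(cells)} cells"
        )
    adata = ad.AnnData(
        X=mat,
        obs=pd.DataFrame(index=pd.Index(cells, name="barcode")),
        var=pd.DataFrame(index=pd.Index(_dedupe(genes), name="gene")),
    )
    return adata


def write_expression_mtx(adata: ad.AnnData, out_dir) -> None:
    """Write a cells x genes AnnData as genes x cells MTX plus sidecars."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(adata.X).T  # genes x cells on disk
    scipy.io.mmwrite(str(d / "matrix.mtx"), mat, field="integer")
    pd.Series(adata.var_names).to_csv(d / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(d / "barcodes.tsv", sep="\t", header=False, index=False)


MANIFEST_COLUMNS = ("path", "donor", "subset", "timepoint", "tissue", "replicate")


def read_manifest(path) -> pd.DataFrame:
    """Read the sample manifest mapping file paths to provenance labels."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, MANIFEST_COLUMNS, path)
    return df


def load_manifest_repertoires(
    manifest_path,
    dialect: str = "airr",
    key_level: str = "nt",
    productive_only: bool = True,
) -> list[Repertoire]:
    """Load every repertoire listed in a manifest.

    Relative paths in the manifest are resolved against the manifest's own
    directory. Missing files raise a :class:`FormatError` naming the file.
    """
    base = Path(manifest_path).parent
    manifest = read_manifest(manifest_path)
    reps = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FormatError(f"manifest references missing file: {p}")
        labels = {
            "donor": row.donor,
            "subset": row.subset,
            "timepoint": row.timepoint,
            "tissue": row.tissue,
            "replicate": row.replicate,
        }
        reps.append(
            read_bulk_repertoire(
                p, dialect=dialect, labels=labels, key_level=key_level,
                productive_only=productive_only,
            )
        )
    return reps
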