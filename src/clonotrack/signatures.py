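"""Marker-gene signature derivation and bin-controlled module scoring.

A signature is the top-N genes distinctively up-regulated in a target cell
group: per-gene two-sided Wilcoxon rank-sum (target vs rest) with
Benjamini-Hochberg correction, restricted to positive log fold-change,
ranked by adjusted p then by descending logFC.

Cells are scored against a signature with an expression-bin-controlled
module score: genes are binned by average expression across all cells
(equal-count bins), each signature gene draws control genes from its own
bin, and the score is the per-cell mean signature expression minus the mean
over the pooled control genes. Matching controls on average expression
removes the depth/abundance component, so a constant matrix scores exactly
zero and an additive per-cell offset cancels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "ModuleScoreResult",
    "lognormalize",
    "derive_marker_signature",
    "module_score",
    "compare_scores",
]


@dataclass
class GeneSignature:
    name: str
    genes: list[str]
    source_label: str = ""
    ranking: str = "wilcoxon_bh_logfc"
    n_requested: int = 0
    #: full per-gene statistics table (gene, logfc, pvalue, padj)
    table: pd.DataFrame | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ModuleScoreResult:
    scores: pd.Series  # indexed by cell barcode
    signature: str
    n_bins: int
    n_ctrl: int
    seed: int | None
    control_genes: list[str] = field(default_factory=list, repr=False)


def _dense(X) -> np.ndarray:
    return np.asarray(X.toarray() if hasattr(X, "toarray") else X, dtype=float)


def lognormalize(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Depth-normalize to ``target_sum`` counts per cell and log1p-transform."""
    import scanpy as sc

    out = adata.copy()
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    return out


def derive_marker_signature(
    adata: ad.AnnData,
    labels,
    target_label: str,
    n_top: int = 100,
    alpha: float = 0.05,
    name: str | None = None,
) -> GeneSignature:
    """Top-N marker genes of ``target_label`` cells versus all other cells.

    ``adata.X`` must be log-normalized. ``labels`` is a per-cell label
    vector or the name of an ``adata.obs`` column. Only genes that pass BH
    at ``alpha`` with positive logFC are eligible; when fewer than ``n_top``
    qualify the list is shorter (with a warning).
    """
    if isinstance(labels, str):
        labels = adata.obs[labels]
    labels = np.asarray(labels)
    mask = labels == target_label
    n_target = int(mask.sum())
    if n_target == 0:
        raise ValueError(f"no cells labeled {target_label!r}")
    if n_target < 3:
        raise ValueError(f"need >= 3 target cells, got {n_target}")
    if (~mask).sum() == 0:
        raise ValueError("no reference cells: every cell carries the target label")

    X = _dense(adata.X)
    target, rest = X[mask], X[~mask]
    stat = mannwhitneyu(target, rest, axis=0, alternative="two-sided", method="asymptotic")
    pvals = np.nan_to_num(stat.pvalue, nan=1.0)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    logfc = target.mean(axis=0) - rest.mean(axis=0)

    table = pd.DataFrame(
        {"gene": adata.var_names, "logfc": logfc, "pvalue": pvals, "padj": padj}
    )
    eligible = table[(table.padj < alpha) & (table.logfc > 0)]
    ranked = eligible.sort_values(["padj", "logfc"], ascending=[True, False], kind="mergesort")
    genes = ranked["gene"].head(n_top).tolist()
    if len(genes) < n_top:
        logger.warning(
            "only %d of %d requested genes pass BH(%.2g) with positive logFC",
            len(genes), n_top, alpha,
        )
    return GeneSignature(
        name=name or f"{target_label}_top{n_top}",
        genes=genes,
        source_label=str(target_label),
        n_requested=n_top,
        table=table.sort_values(["padj", "logfc"], ascending=[True, False], kind="mergesort"),
    )


def module_score(
    adata: ad.AnnData,
    signature,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int | None = 0,
) -> ModuleScoreResult:
    """Expression-bin-controlled module score per cell.

    Genes are binned into ``n_bins`` equal-count bins by average expression
    over all cells. For each signature gene, up to ``n_ctrl`` control genes
    are drawn (seeded, without replacement) from its bin, excluding
    signature genes themselves; the score is
    ``mean(signature genes) - mean(pooled control genes)`` per cell.
    Signature genes absent from the matrix are dropped with a warning; an
    empty intersection is an error.
    """
    genes = list(signature.genes) if isinstance(signature, GeneSignature) else list(signature)
    present = [g for g in genes if g in adata.var_names]
    missing = sorted(set(genes) - set(present))
    if missing:
        logger.warning("%d signature gene(s) absent from the matrix: %s ...",
                       len(missing), missing[:5])
    if not present:
        raise ValueError("no signature genes present in the matrix")

    X = _dense(adata.X)
    var_names = pd.Index(adata.var_names)
    avg = pd.Series(X.mean(axis=0), index=var_names)
    n_bins_eff = min(n_bins, adata.n_vars)
    bins = pd.qcut(avg.rank(method="first"), n_bins_eff, labels=False)

    rng = np.random.default_rng(seed)
    sig_set = set(present)
    non_sig = bins.index[~bins.index.isin(sig_set)]
    if len(non_sig) == 0:
        raise ValueError("every gene is in the signature; no control genes available")
    controls: set[str] = set()
    for gene in sorted(present):
        pool = non_sig[(bins[non_sig] == bins[gene]).to_numpy()]
        if len(pool) == 0:
            # bin exhausted by signature genes: fall back to the nearest
            # non-signature genes by average expression (deterministic)
            order = (avg[non_sig] - avg[gene]).abs().sort_values(kind="mergesort")
            pool = order.index[:n_ctrl]
        take = min(n_ctrl, len(pool))
        controls.update(rng.choice(np.asarray(pool), size=take, replace=False))

    sig_idx = var_names.get_indexer(present)
    ctrl_idx = var_names.get_indexer(sorted(controls))
    scores = X[:, sig_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    name = signature.name if isinstance(signature, GeneSignature) else "signature"
    return ModuleScoreResult(
        scores=pd.Series(scores, index=adata.obs_names, name=f"{name}_score"),
        signature=name,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
        control_genes=sorted(controls),
    )


def compare_scores(scores: pd.Series, group_labels) -> pd.DataFrame:
    """Per-group summary (mean/median/IQR) of module scores, ranked by mean.

    Groups with no scored cells are omitted with a warning.
    """
    groups = pd.Series(np.asarray(group_labels), index=scores.index, name="group")
    df = pd.DataFrame({"score": scores, "group": groups})
    rows = []
    for name, sub in df.groupby("group", observed=False):
        if len(sub) == 0:
            logger.warning("group %r has no scored cells; omitted", name)
            continue
        s = sub["score"]
        rows.append(
            {
                "group": name,
                "n": len(s),
                "mean": s.mean(),
                "median": s.median(),
                "q25": s.quantile(0.25),
                "q75": s.quantile(0.75),
            }
        )
    out = pd.DataFrame(rows).sort_values("mean", ascending=False, ignore_index=True)
    out["rank"] = range(1, len(out) + 1)
    return out
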