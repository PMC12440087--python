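"""End-to-end pipeline orchestration.

Stages (each consuming only on-disk artifacts of earlier stages):

``simulate -> validate -> diversity -> overlap -> track -> link -> score``

driven by a single YAML config with named seeds. Every output table carries
a provenance header (package version, config hash, seed) and identical
config + seed reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io as ctio
from .clonotypes import merge_replicates, pair_cells, filter_productive
from .diversity import clonality_with_replicates, overlap_matrix
from .linkage import detection_fraction, per_cluster_clonality, pool_ratio
from .signatures import compare_scores, derive_marker_signature, lognormalize, module_score
from .simulate import CohortConfig, generate_cohort, generate_sc_dataset, TPH_GATE, TFH_GATE
from .tracking import expanded_clones, intersection_table, persistence_fraction, transition_clones
from .types import Repertoire

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "default_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


def default_config() -> dict:
    return {
        "seed": 0,
        "output_dir": "clonotrack_out",
        "simulate": {"enabled": True},
        "inputs": {},
        "key_level": "nt",
        "linkage_level": "aa",
        "depth": 5000,
        "n_iter": 10,
        "statistic": "morisita_horn",
        "min_expansion_size": 2,
        "signature": {"target_cluster": "C5", "n_top": 20, "n_bins": 25, "n_ctrl": 100},
        "stages": ["diversity", "overlap", "track", "link", "score"],
    }


def _config_hash(config: dict) -> str:
    # hash only the scientific configuration, not filesystem locations,
    # so identical analyses in different directories share a hash
    stable = {k: v for k, v in config.items() if k not in ("inputs", "output_dir")}
    return hashlib.sha256(json.dumps(stable, sort_keys=True).encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, config: dict) -> None:
    header = (
        f"# clonotrack {__version__}\n"
        f"# config_hash {_config_hash(config)}\n"
        f"# seed {config.get('seed', 0)}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _merged_by_sample(reps: list[Repertoire]) -> dict[tuple, Repertoire]:
    groups: dict[tuple, list[Repertoire]] = defaultdict(list)
    for r in reps:
        groups[(r.donor, r.subset, r.timepoint, r.tissue)].append(r)
    out = {}
    for key, members in groups.items():
        merged = members[0]
        for other in members[1:]:
            merged = merge_replicates(merged, other)
        out[key] = merged
    return out


def run_pipeline(config: dict, output_dir=None) -> dict:
    """Run the configured stages; returns a dict of written artifact paths.

    Raises :class:`PipelineError` naming the failing stage on any error.
    """
    cfg = default_config()
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    artifacts: dict[str, str] = {}
    stage = "setup"

    def record(name: str, path: Path):
        artifacts[name] = str(path)

    try:
        # ------------------------------------------------ simulate / inputs
        if cfg["simulate"].get("enabled", False):
            stage = "simulate"
            sim_opts = {k: v for k, v in cfg["simulate"].items() if k != "enabled"}
            if "sharing" in sim_opts:
                sim_opts["sharing"] = {tuple(k.split("|")): v
                                       for k, v in sim_opts["sharing"].items()}
            for tuple_key in ("subsets", "timepoints", "ctl_size_range"):
                if tuple_key in sim_opts:
                    sim_opts[tuple_key] = tuple(sim_opts[tuple_key])
            sim_cfg = CohortConfig(seed=seed, **sim_opts)
            data_dir = out / "synthetic_data"
            cohort = generate_cohort(sim_cfg, out_dir=data_dir)
            generate_sc_dataset(sim_cfg, cohort, out_dir=data_dir)
            cfg["inputs"] = {
                "manifest": str(data_dir / "manifest.tsv"),
                "contigs": str(data_dir / "filtered_contig_annotations.csv"),
                "cell_metadata": str(data_dir / "cell_metadata.tsv"),
                "expression_dir": str(data_dir / "matrix"),
            }
            record("synthetic_data", data_dir)

        stage = "validate"
        inputs = cfg["inputs"]
        if "manifest" not in inputs:
            raise PipelineError("no input manifest configured")
        reps = ctio.load_manifest_repertoires(
            inputs["manifest"], key_level=cfg["key_level"], productive_only=True
        )
        merged = _merged_by_sample(reps)

        # ------------------------------------------------------- diversity
        if "diversity" in cfg["stages"]:
            stage = "diversity"
            groups: dict[tuple, list[Repertoire]] = defaultdict(list)
            for r in reps:
                groups[(r.donor, r.subset, r.timepoint, r.tissue)].append(r)
            rows = []
            for i, (key, members) in enumerate(sorted(groups.items())):
                res = clonality_with_replicates(
                    members, depth=cfg["depth"], n_iter=cfg["n_iter"], seed=seed + i
                )
                donor, subset, timepoint, tissue = key
                rows.append({
                    "donor": donor, "subset": subset, "timepoint": timepoint,
                    "tissue": tissue, "depth": res.depth, "n_iterations": res.n_iterations,
                    "inverse_simpson_mean": res.inverse_simpson_mean,
                    "shallow_replicates": res.shallow_replicates,
                })
            path = out / "diversity.tsv"
            _write_table(pd.DataFrame(rows), path, cfg)
            record("diversity", path)

        # --------------------------------------------------------- overlap
        if "overlap" in cfg["stages"]:
            stage = "overlap"
            rows = []
            for donor in sorted({r.donor for r in reps}):
                samples = [m for k, m in sorted(merged.items()) if k[0] == donor]
                om = overlap_matrix(samples, statistic=cfg["statistic"],
                                    downsample_depth=cfg["depth"], seed=seed)
                ids = list(om.values.index)
                for i, a in enumerate(ids):
                    for b in ids[i + 1:]:
                        la, lb = om.sample_labels.loc[a], om.sample_labels.loc[b]
                        rows.append({
                            "donor": donor,
                            "subset_a": la.subset, "timepoint_a": la.timepoint,
                            "subset_b": lb.subset, "timepoint_b": lb.timepoint,
                            "statistic": om.statistic, "value": om.value(a, b),
                        })
            path = out / "overlap.tsv"
            _write_table(pd.DataFrame(rows), path, cfg)
            record("overlap", path)

        # ----------------------------------------------------------- track
        if "track" in cfg["stages"]:
            stage = "track"
            donors = sorted({k[0] for k in merged})
            timepoints = sorted({k[2] for k in merged})
            subsets = sorted({k[1] for k in merged})
            pers_rows, trans_rows, inter_rows = [], [], []
            for donor in donors:
                for t_prev, t_next in zip(timepoints, timepoints[1:]):
                    observed_prev = frozenset().union(*(
                        merged[k].key_set() for k in merged
                        if k[0] == donor and k[2] == t_prev
                    ))
                    for subset in subsets:
                        key = next((k for k in merged
                                    if k[0] == donor and k[1] == subset and k[2] == t_next), None)
                        if key is None:
                            continue
                        expanded = expanded_clones(merged[key], min_size=cfg["min_expansion_size"])
                        frac = persistence_fraction(expanded, observed_prev)
                        pers_rows.append({
                            "donor": donor, "subset": subset,
                            "timepoint_expanded": t_next, "timepoint_observed": t_prev,
                            "n_expanded": len(expanded), "persistence_fraction": frac,
                        })
                # subset-transition detection between first two timepoints
                if len(timepoints) >= 2 and {"Tph", "Tfh"} <= set(subsets):
                    t0, t1 = timepoints[0], timepoints[1]
                    pools = {
                        (s, t): merged[(donor, s, t, "blood")].key_set()
                        for s in ("Tph", "Tfh") for t in (t0, t1)
                        if (donor, s, t, "blood") in merged
                    }
                    if len(pools) == 4:
                        for src, other in (("Tfh", "Tph"), ("Tph", "Tfh")):
                            moved, frac = transition_clones(
                                pools[(src, t0)], pools[(other, t0)], pools[(other, t1)]
                            )
                            trans_rows.append({
                                "donor": donor, "source_subset": src, "target_subset": other,
                                "timepoint_baseline": t0, "timepoint_later": t1,
                                "n_transitioned": len(moved), "fraction": frac,
                            })
                t0 = timepoints[0]
                named = {s: merged[(donor, s, t0, "blood")].key_set()
                         for s in subsets if (donor, s, t0, "blood") in merged}
                if len(named) >= 2:
                    it = intersection_table(named)
                    for row in it.table.itertuples(index=False):
                        inter_rows.append({
                            "donor": donor, "timepoint": t0,
                            "combination": "&".join(row.combination),
                            "degree": row.degree, "count": row.count,
                        })
            _write_table(pd.DataFrame(pers_rows), out / "persistence.tsv", cfg)
            _write_table(pd.DataFrame(trans_rows), out / "transitions.tsv", cfg)
            _write_table(pd.DataFrame(inter_rows), out / "intersections.tsv", cfg)
            record("persistence", out / "persistence.tsv")
            record("transitions", out / "transitions.tsv")
            record("intersections", out / "intersections.tsv")

        # ------------------------------------------------------------ link
        cells = None
        if "link" in cfg["stages"] and inputs.get("contigs"):
            stage = "link"
            contigs = filter_productive(ctio.read_sc_contigs(inputs["contigs"]))
            metadata = ctio.read_cell_metadata(inputs["cell_metadata"])
            cells = pair_cells(contigs, metadata)
            level = cfg["linkage_level"]
            aa_reps = ctio.load_manifest_repertoires(
                inputs["manifest"], key_level=level, productive_only=True
            )
            link_rows, ratio_rows = [], []
            by_donor_cluster: dict[tuple, list] = defaultdict(list)
            for cell in cells:
                by_donor_cluster[(cell.donor, cell.cluster)].append(cell)
            timepoint0 = sorted({r.timepoint for r in aa_reps})[0]
            for (donor, cluster), group in sorted(by_donor_cluster.items()):
                pools = {}
                for subset, gate in (("Tph", TPH_GATE), ("Tfh", TFH_GATE)):
                    replicates = [r for r in aa_reps if r.donor == donor
                                  and r.subset == subset and r.timepoint == timepoint0]
                    if not replicates:
                        continue
                    res = detection_fraction(group, replicates, level=level, cluster=cluster)
                    res.pool = subset
                    pools[subset] = replicates
                    row = {"donor": donor, "cluster": cluster, "pool": subset,
                           "n_cluster_clonotypes": res.n_cluster_clonotypes,
                           "n_detected": res.n_detected,
                           "detection_fraction": res.detection_fraction}
                    for rep_label, frac in res.per_replicate.items():
                        row[f"detection_{rep_label}"] = frac
                    link_rows.append(row)
                if {"Tph", "Tfh"} <= set(pools):
                    def merge(rs):
                        merged_rep = rs[0]
                        for other in rs[1:]:
                            merged_rep = merge_replicates(merged_rep, other)
                        return merged_rep
                    ratio = pool_ratio(group, merge(pools["Tph"]), merge(pools["Tfh"]), level=level)
                    ratio_rows.append({"donor": donor, "cluster": cluster,
                                       "timepoint": timepoint0, "pool_ratio": ratio})
            _write_table(pd.DataFrame(link_rows), out / "linkage.tsv", cfg)
            _write_table(pd.DataFrame(ratio_rows), out / "pool_ratio.tsv", cfg)
            clon = per_cluster_clonality(cells)
            _write_table(clon, out / "sc_cluster_clonality.tsv", cfg)
            record("linkage", out / "linkage.tsv")
            record("pool_ratio", out / "pool_ratio.tsv")
            record("sc_cluster_clonality", out / "sc_cluster_clonality.tsv")

        # ----------------------------------------------------------- score
        if "score" in cfg["stages"] and inputs.get("expression_dir"):
            stage = "score"
            adata = ctio.read_expression_mtx(inputs["expression_dir"])
            metadata = ctio.read_cell_metadata(inputs["cell_metadata"])
            common = adata.obs_names.intersection(metadata.index)
            adata = adata[common].copy()
            adata.obs["cluster"] = metadata.loc[common, "cluster"]
            norm = lognormalize(adata)
            sig_cfg = cfg["signature"]
            sig = derive_marker_signature(
                norm, "cluster", sig_cfg["target_cluster"], n_top=sig_cfg["n_top"]
            )
            score = module_score(norm, sig, n_bins=sig_cfg["n_bins"],
                                 n_ctrl=sig_cfg["n_ctrl"], seed=seed)
            summary = compare_scores(score.scores, norm.obs["cluster"])
            genes_df = pd.DataFrame({"gene": sig.genes, "rank": range(1, len(sig.genes) + 1)})
            scores_df = pd.DataFrame({"barcode": score.scores.index, "score": score.scores.values})
            _write_table(genes_df, out / "signature_genes.tsv", cfg)
            _write_table(scores_df, out / "signature_scores.tsv", cfg)
            _write_table(summary, out / "score_summary.tsv", cfg)
            record("signature_genes", out / "signature_genes.tsv")
            record("signature_scores", out / "signature_scores.tsv")
            record("score_summary", out / "score_summary.tsv")

        stage = "report"
        run_manifest = {
            "version": __version__,
            "seed": seed,
            "config_hash": _config_hash(cfg),
            "stages": cfg["stages"],
            "artifacts": artifacts,
        }
        (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=1, sort_keys=True))
        artifacts["run_manifest"] = str(out / "run_manifest.json")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return artifacts


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
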