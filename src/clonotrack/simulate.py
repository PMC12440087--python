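"""Synthetic paired bulk + single-cell TCR cohorts with planted ground truth.

The generator emulates the study design the pipeline is built for: per
donor, sorted CD4 subsets (Tph, Tfh, Treg by default) are profiled by bulk
TCRbeta sequencing in technical duplicate across several timepoints, and a
single-cell RNA/TCR dataset with transcriptomic cluster labels links paired
clonotypes back to the bulk pools.

Planted structure (all recoverable from the emitted ground truth):

* **clone sizes** — truncated discrete power law, ``P(s) ~ s**-alpha`` for
  ``s`` in ``1..cap`` (default alpha 2.5, cap 500);
* **subset sharing** — for each subset pair a planted count
  ``K ~ Binomial(N, S_ij)`` of clones is present in both subsets and the
  remainder private, so the observed shared-clone fraction ``|A & B| / N``
  is a binomial estimator of ``S_ij``;
* **persistence** — each clone persists to the next timepoint with
  probability ``rho``; pools are topped up with novel clones to constant
  size, so the persister fraction of any later pool estimates ``rho``;
* **a private CTL clone set** — a handful of very large clones confined to
  one sorted subset (default Tph), driving that pool's oligoclonality, and
  forming a single-cell CTL cluster private to one sorted gate;
* **a shared activated B-cell-helper cluster** — single cells drawn from
  clones shared between the Tph and Tfh pools, sorted into both PD-1hi
  gates, with a planted expression signature (+delta log2 fold-change on a
  known gene set) on a negative-binomial count baseline.

Reads are allocated multinomially at the configured depth and split into
two replicates by binomial thinning, emulating one lysate split into two
libraries. A small fraction of non-productive rows exercises productive
filtering. All randomness flows from the config seed; identical configs
produce byte-identical files.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from . import io as ctio
from .types import ChainInfo, ClonotypeRecord, Repertoire
from .clonotypes import build_bulk_clonotypes

logger = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "SyntheticGroundTruth",
    "CohortResult",
    "ScDataset",
    "sample_clone_sizes",
    "generate_cohort",
    "generate_sc_dataset",
]

TPH_GATE = "CXCR5-PD-1hi"
TFH_GATE = "CXCR5+PD-1hi"

_TRBV = ["TRBV2", "TRBV5-1", "TRBV6-1", "TRBV7-2", "TRBV9", "TRBV12-3",
         "TRBV19", "TRBV20-1", "TRBV28", "TRBV30"]
_TRBJ = ["TRBJ1-1", "TRBJ1-2", "TRBJ2-1", "TRBJ2-3", "TRBJ2-7"]
_TRAV = ["TRAV1-2", "TRAV8-1", "TRAV12-1", "TRAV13-1", "TRAV17", "TRAV21",
         "TRAV26-1", "TRAV29", "TRAV38-1", "TRAV41"]
_TRAJ = ["TRAJ9", "TRAJ23", "TRAJ33", "TRAJ42", "TRAJ49"]

# amino acid -> codons, standard table (for back-translating CDR3s)
_BACK_TABLE: dict[str, list[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _BACK_TABLE.setdefault(aa, []).append(codon)
_CDR3_ALPHABET = sorted(set(_BACK_TABLE) - {"C", "F"})


@dataclass
class CohortConfig:
    """Study-design parameters for one synthetic cohort."""

    n_donors: int = 3
    subsets: tuple[str, ...] = ("Tph", "Tfh", "Treg")
    timepoints: tuple[str, ...] = ("T0", "T1", "T2")
    clones_per_subset: int = 400
    alpha: float = 2.5
    size_cap: int = 500
    #: sharing probability per unordered subset pair; unlisted pairs are 0
    sharing: dict = field(default_factory=lambda: {("Tph", "Tfh"): 0.3})
    persistence: float = 0.7
    bulk_depth: int = 20000
    replicate_p: float = 0.5
    nonproductive_frac: float = 0.02
    #: private hyperexpanded CTL clones confined to one subset
    n_ctl_clones: int = 6
    ctl_size_range: tuple[int, int] = (100, 400)
    ctl_subset: str = "Tph"
    # --- single-cell layer ---
    sc_timepoint: str | None = None  # default: last timepoint
    cells_per_cluster: int = 80
    n_genes: int = 300
    n_signature_genes: int = 20
    signature_effect: float = 1.5  # log2 fold-change planted on C5 cells
    nb_dispersion: float = 2.0
    seed: int = 0

    def pair_sharing(self) -> dict[frozenset, float]:
        out = {}
        for pair, p in self.sharing.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"sharing probability out of [0,1]: {pair}={p}")
            a, b = pair
            if a not in self.subsets or b not in self.subsets:
                raise ValueError(f"sharing pair {pair} not in subsets {self.subsets}")
            out[frozenset(pair)] = p
        return out

    def validate(self) -> None:
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be in [0,1]")
        if self.alpha <= 1.0:
            raise ValueError("power-law exponent alpha must be > 1")
        if self.ctl_subset not in self.subsets:
            raise ValueError(f"ctl_subset {self.ctl_subset!r} not in subsets")
        per_subset_shared = {s: 0.0 for s in self.subsets}
        for pair, p in self.pair_sharing().items():
            for s in pair:
                per_subset_shared[s] += p
        if max(per_subset_shared.values()) > 0.9:
            raise ValueError("total sharing probability per subset must stay below 0.9")

    @property
    def sc_tp(self) -> str:
        return self.sc_timepoint or self.timepoints[-1]


def sample_clone_sizes(n_clones: int, alpha: float, cap: int, rng) -> np.ndarray:
    """Draw i.i.d. clone sizes from ``P(s) ~ s**-alpha``, ``s`` in ``1..cap``."""
    if alpha <= 1.0:
        raise ValueError("alpha must be > 1")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = np.random.default_rng(rng)
    s = np.arange(1, cap + 1, dtype=float)
    pmf = s ** (-alpha)
    pmf /= pmf.sum()
    return rng.choice(np.arange(1, cap + 1), size=n_clones, p=pmf)


@dataclass
class _Clone:
    clone_id: str
    donor: str
    beta: ChainInfo
    alpha_chain: ChainInfo
    subsets: frozenset
    is_ctl: bool = False
    present: set = field(default_factory=set)      # timepoints
    persisted: set = field(default_factory=set)    # timepoints reached by persistence
    sc_cluster: str = ""


@dataclass
class SyntheticGroundTruth:
    """Planted parameters plus the full per-clone truth table."""

    clones: pd.DataFrame
    sharing: dict
    persistence: float
    signature_genes: list[str] = field(default_factory=list)
    signature_effect: float = 0.0
    config: dict = field(default_factory=dict)

    def clone_keys(self, donor: str, subset: str | None = None, timepoint: str | None = None,
                   ctl: bool | None = None) -> set:
        """Ground-truth beta keys (nt level) filtered by donor/subset/timepoint."""
        df = self.clones[self.clones.donor == donor]
        if subset is not None:
            df = df[df.subsets.str.split(";").map(lambda ss: subset in ss)]
        if timepoint is not None:
            df = df[df.timepoints.str.split(";").map(lambda ts: timepoint in ts)]
        if ctl is not None:
            df = df[df.is_ctl == ctl]
        return {(r.cdr3_nt, r.v_call, r.j_call) for r in df.itertuples()}

    def to_json(self, path) -> None:
        payload = {
            "sharing": {"|".join(sorted(k)): v for k, v in self.sharing.items()},
            "persistence": self.persistence,
            "signature_genes": self.signature_genes,
            "signature_effect": self.signature_effect,
            "config": self.config,
            "clones": self.clones.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticGroundTruth":
        payload = json.loads(Path(path).read_text())
        sharing = {tuple(k.split("|")): v for k, v in payload["sharing"].items()}
        return cls(
            clones=pd.DataFrame(payload["clones"]),
            sharing=sharing,
            persistence=payload["persistence"],
            signature_genes=payload["signature_genes"],
            signature_effect=payload["signature_effect"],
            config=payload["config"],
        )


def _random_cdr3(rng, used: set) -> tuple[str, str]:
    """Unique random CDR3: aa with canonical C...F anchors, nt back-translated."""
    while True:
        n_mid = int(rng.integers(8, 15))
        aa = "C" + "".join(rng.choice(_CDR3_ALPHABET, size=n_mid)) + "F"
        nt = "".join(_BACK_TABLE[a][int(rng.integers(0, len(_BACK_TABLE[a])))] for a in aa)
        if nt not in used:
            used.add(nt)
            return nt, aa


def _new_clone(rng, used: set, donor: str, idx: int, subsets: frozenset,
               is_ctl: bool = False) -> _Clone:
    b_nt, b_aa = _random_cdr3(rng, used)
    a_nt, a_aa = _random_cdr3(rng, used)
    return _Clone(
        clone_id=f"{donor}_cl{idx:05d}",
        donor=donor,
        beta=ChainInfo(b_nt, b_aa,
                       str(rng.choice(_TRBV)), str(rng.choice(_TRBJ))),
        alpha_chain=ChainInfo(a_nt, a_aa,
                              str(rng.choice(_TRAV)), str(rng.choice(_TRAJ))),
        subsets=subsets,
        is_ctl=is_ctl,
    )


def _build_donor_clones(cfg: CohortConfig, donor: str, rng) -> list[_Clone]:
    """Plant the clone universe of one donor across all timepoints."""
    N = cfg.clones_per_subset
    sharing = cfg.pair_sharing()
    used: set = set()
    clones: list[_Clone] = []
    counter = itertools.count()

    def add(subsets: frozenset, t0: str, is_ctl: bool = False) -> _Clone:
        c = _new_clone(rng, used, donor, next(counter), subsets, is_ctl)
        c.present.add(t0)
        clones.append(c)
        return c

    # baseline timepoint: shared clones per pair, then fill each subset to N
    t0 = cfg.timepoints[0]
    for pair in sorted(sharing, key=sorted):
        k = int(rng.binomial(N, sharing[pair]))
        for _ in range(k):
            add(pair, t0)
    for subset in cfg.subsets:
        have = sum(1 for c in clones if subset in c.subsets)
        for _ in range(N - have):
            add(frozenset({subset}), t0)
    for _ in range(cfg.n_ctl_clones):
        add(frozenset({cfg.ctl_subset}), t0, is_ctl=True)

    # later timepoints: persistence thinning + top-up to constant pool sizes
    for prev, t in zip(cfg.timepoints, cfg.timepoints[1:]):
        for c in clones:
            if prev not in c.present:
                continue
            if c.is_ctl or rng.random() < cfg.persistence:
                c.present.add(t)
                c.persisted.add(t)
        for pair in sorted(sharing, key=sorted):
            k_target = int(rng.binomial(N, sharing[pair]))
            k_have = sum(1 for c in clones if t in c.present and c.subsets == pair)
            for _ in range(max(0, k_target - k_have)):
                add(pair, t)
        for subset in cfg.subsets:
            have = sum(1 for c in clones if t in c.present and subset in c.subsets
                       and not c.is_ctl)
            for _ in range(N - have):
                add(frozenset({subset}), t)
    return clones


def _draw_sizes(cfg: CohortConfig, clones: list[_Clone], rng) -> dict:
    """Per (clone, timepoint) abundance weights; fresh draw each timepoint."""
    sizes: dict[tuple[str, str], int] = {}
    for t in cfg.timepoints:
        present = [c for c in clones if t in c.present]
        regular = [c for c in present if not c.is_ctl]
        drawn = sample_clone_sizes(len(regular), cfg.alpha, cfg.size_cap, rng)
        for c, s in zip(regular, drawn):
            sizes[(c.clone_id, t)] = int(s)
        lo, hi = cfg.ctl_size_range
        for c in present:
            if c.is_ctl:
                sizes[(c.clone_id, t)] = int(rng.integers(lo, hi + 1))
    return sizes


def _emit_bulk_sample(cfg, clones, sizes, donor, subset, t, rng):
    """Multinomial read allocation + binomial replicate split -> 2 replicates."""
    members = [c for c in clones if t in c.present and subset in c.subsets]
    weights = np.array([sizes[(c.clone_id, t)] for c in members], dtype=float)
    reads = rng.multinomial(cfg.bulk_depth, weights / weights.sum())
    rep1 = rng.binomial(reads, cfg.replicate_p)
    rep2 = reads - rep1
    out = []
    for rep_label, rep_counts in (("r1", rep1), ("r2", rep2)):
        records = [
            ClonotypeRecord(
                cdr3_nt=c.beta.cdr3_nt, cdr3_aa=c.beta.cdr3_aa,
                v_call=c.beta.v_call, d_call="", j_call=c.beta.j_call,
                read_count=int(n), productive=True,
            )
            for c, n in zip(members, rep_counts) if n > 0
        ]
        # sprinkle non-productive rearrangements (frame-shifted junctions)
        n_np = rng.binomial(len(records), cfg.nonproductive_frac)
        used: set = set()
        for _ in range(n_np):
            nt, aa = _random_cdr3(rng, used)
            records.append(
                ClonotypeRecord(
                    cdr3_nt=nt[:-1], cdr3_aa="", v_call=str(rng.choice(_TRBV)),
                    d_call="", j_call=str(rng.choice(_TRBJ)),
                    read_count=int(rng.integers(1, 5)), productive=False,
                )
            )
        rep = build_bulk_clonotypes([r for r in records if r.productive], key_level="nt")
        rep.donor, rep.subset, rep.timepoint = donor, subset, t
        rep.tissue, rep.replicate = "blood", rep_label
        out.append((rep, records))
    return out


def _ground_truth_frame(cfg: CohortConfig, clones: list[_Clone]) -> pd.DataFrame:
    rows = []
    for c in clones:
        rows.append(
            {
                "donor": c.donor,
                "clone_id": c.clone_id,
                "cdr3_nt": c.beta.cdr3_nt,
                "cdr3_aa": c.beta.cdr3_aa,
                "v_call": c.beta.v_call,
                "j_call": c.beta.j_call,
                "tra_cdr3_nt": c.alpha_chain.cdr3_nt,
                "tra_cdr3_aa": c.alpha_chain.cdr3_aa,
                "tra_v_call": c.alpha_chain.v_call,
                "tra_j_call": c.alpha_chain.j_call,
                "subsets": ";".join(sorted(c.subsets)),
                "timepoints": ";".join(t for t in cfg.timepoints if t in c.present),
                "persisted_timepoints": ";".join(t for t in cfg.timepoints if t in c.persisted),
                "is_ctl": c.is_ctl,
                "sc_cluster": c.sc_cluster,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CohortResult:
    repertoires: list[Repertoire]
    manifest: pd.DataFrame
    ground_truth: SyntheticGroundTruth
    clones: list = field(default_factory=list, repr=False)
    sizes: dict = field(default_factory=dict, repr=False)


def generate_cohort(config: CohortConfig, out_dir=None) -> CohortResult:
    """Generate the bulk arm of a synthetic cohort.

    Returns in-memory repertoires (productive clonotypes, nt-level keys) for
    every donor x subset x timepoint x replicate plus the ground truth; when
    ``out_dir`` is given, also writes one AIRR TSV per sample, a manifest
    TSV, and the ground truth as JSON.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    all_reps: list[Repertoire] = []
    all_clones: list[_Clone] = []
    all_sizes: dict = {}
    manifest_rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for d in range(config.n_donors):
        donor = f"D{d + 1}"
        clones = _build_donor_clones(config, donor, rng)
        sizes = _draw_sizes(config, clones, rng)
        all_clones.extend(clones)
        all_sizes.update(sizes)
        for t in config.timepoints:
            for subset in config.subsets:
                for rep, records in _emit_bulk_sample(config, clones, sizes, donor, subset, t, rng):
                    all_reps.append(rep)
                    fname = f"{donor}_{subset}_{t}_{rep.replicate}.tsv"
                    manifest_rows.append(
                        {"path": fname, "donor": donor, "subset": subset,
                         "timepoint": t, "tissue": "blood", "replicate": rep.replicate}
                    )
                    if out is not None:
                        _write_airr_records(records, out / fname)

    manifest = pd.DataFrame(manifest_rows)
    gt = SyntheticGroundTruth(
        clones=_ground_truth_frame(config, all_clones),
        sharing={tuple(sorted(k)): v for k, v in config.pair_sharing().items()},
        persistence=config.persistence,
        config=_config_dict(config),
    )
    if out is not None:
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        gt.to_json(out / "ground_truth.json")
    return CohortResult(repertoires=all_reps, manifest=manifest, ground_truth=gt,
                        clones=all_clones, sizes=all_sizes)


def _config_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["sharing"] = {"|".join(sorted(k)): v for k, v in config.pair_sharing().items()}
    return d


def _write_airr_records(records: Sequence[ClonotypeRecord], path) -> None:
    pd.DataFrame(
        {
            "junction": [r.cdr3_nt for r in records],
            "junction_aa": [r.cdr3_aa for r in records],
            "v_call": [r.v_call for r in records],
            "d_call": [r.d_call for r in records],
            "j_call": [r.j_call for r in records],
            "duplicate_count": [r.read_count for r in records],
            "productive": ["T" if r.productive else "F" for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


@dataclass
class ScDataset:
    contigs: list
    metadata: pd.DataFrame
    adata: ad.AnnData
    ground_truth: SyntheticGroundTruth


#: single-cell cluster blueprint: (cluster label, clone source, sorted gates)
_SC_CLUSTERS = (
    ("C0", "tfh_only", (TFH_GATE,)),
    ("C1", "tph_only", (TPH_GATE,)),
    ("C3", "ctl", (TPH_GATE,)),
    ("C5", "shared", (TPH_GATE, TFH_GATE)),
)


def _cluster_clone_pool(cluster_source: str, clones: list[_Clone], tp: str) -> list[_Clone]:
    present = [c for c in clones if tp in c.present]
    if cluster_source == "ctl":
        return [c for c in present if c.is_ctl]
    if cluster_source == "shared":
        return [c for c in present if {"Tph", "Tfh"} <= set(c.subsets)]
    if cluster_source == "tfh_only":
        return [c for c in present if c.subsets == frozenset({"Tfh"})]
    if cluster_source == "tph_only":
        return [c for c in present if c.subsets == frozenset({"Tph"}) and not c.is_ctl]
    raise ValueError(cluster_source)


def generate_sc_dataset(
    config: CohortConfig,
    cohort: CohortResult | None = None,
    out_dir=None,
) -> ScDataset:
    """Generate the single-cell arm consistent with a bulk cohort.

    Clusters: C0 (Tfh-like; clones private to the Tfh pool, sorted
    CXCR5+PD-1hi), C1 (Th1-like; Tph-private clones, CXCR5-PD-1hi), C3
    (CTL; the planted private hyperexpanded clones, CXCR5-PD-1hi only) and
    C5 (activated B-cell-helper; Tph/Tfh-shared clones, sorted into both
    PD-1hi gates). Each cell contributes one TRA and one TRB contig whose
    beta chain matches the bulk clone exactly; the count matrix is a
    negative-binomial baseline with a +delta log2FC shift on the planted
    signature genes in C5 cells.

    When ``out_dir`` is given, writes the contig CSV, cell metadata TSV,
    MTX matrix directory, and ground-truth JSON.
    """
    from .types import ContigRecord

    config.validate()
    if cohort is None:
        cohort = generate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    tp = config.sc_tp

    contigs: list[ContigRecord] = []
    meta_rows = []
    cell_cluster: list[str] = []
    barcode_i = itertools.count(1)
    by_donor: dict[str, list[_Clone]] = {}
    for c in cohort.clones:
        by_donor.setdefault(c.donor, []).append(c)

    for donor in sorted(by_donor):
        clones = by_donor[donor]
        for cluster, source, gates in _SC_CLUSTERS:
            pool = _cluster_clone_pool(source, clones, tp)
            if not pool:
                logger.warning("%s/%s: no clones available; cluster skipped", donor, cluster)
                continue
            weights = np.array([cohort.sizes[(c.clone_id, tp)] for c in pool], dtype=float)
            weights /= weights.sum()
            picks = rng.choice(len(pool), size=config.cells_per_cluster, p=weights)
            for i in picks:
                clone = pool[int(i)]
                clone.sc_cluster = clone.sc_cluster or cluster
                barcode = f"{donor}-{next(barcode_i):05d}-1"
                gate = gates[int(rng.integers(0, len(gates)))]
                umi_a = int(rng.integers(2, 30))
                umi_b = int(rng.integers(2, 30))
                contigs.append(ContigRecord(barcode, "TRA", clone.alpha_chain.cdr3_nt,
                                            clone.alpha_chain.cdr3_aa, clone.alpha_chain.v_call,
                                            clone.alpha_chain.j_call, umi_a, True))
                contigs.append(ContigRecord(barcode, "TRB", clone.beta.cdr3_nt,
                                            clone.beta.cdr3_aa, clone.beta.v_call,
                                            clone.beta.j_call, umi_b, True))
                meta_rows.append({"barcode": barcode, "donor": donor, "sorted_gate": gate,
                                  "tissue": "blood", "timepoint": tp, "cluster": cluster})
                cell_cluster.append(cluster)

    metadata = pd.DataFrame(meta_rows).set_index("barcode", drop=False)

    # --- expression layer: NB baseline, +delta log2FC on signature genes in C5
    n_cells = len(metadata)
    genes = [f"g{i:04d}" for i in range(1, config.n_genes + 1)]
    sig_genes = genes[: config.n_signature_genes]
    base_mu = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    mu = np.tile(base_mu, (n_cells, 1))
    c5_mask = np.array([cl == "C5" for cl in cell_cluster])
    if config.signature_effect != 0.0:
        mu[np.ix_(c5_mask, np.arange(config.n_signature_genes))] *= 2.0 ** config.signature_effect
    r = config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    adata = ad.AnnData(
        X=counts.astype(np.int64),
        obs=metadata[["donor", "sorted_gate", "tissue", "timepoint", "cluster"]].copy(),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )

    gt = SyntheticGroundTruth(
        clones=_ground_truth_frame(config, cohort.clones),
        sharing={tuple(sorted(k)): v for k, v in config.pair_sharing().items()},
        persistence=config.persistence,
        signature_genes=sig_genes,
        signature_effect=config.signature_effect,
        config=_config_dict(config),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ctio.write_contigs(contigs, out / "filtered_contig_annotations.csv")
        metadata.to_csv(out / "cell_metadata.tsv", sep="\t", index=False)
        ctio.write_expression_mtx(adata, out / "matrix")
        gt.to_json(out / "ground_truth_sc.json")
    return ScDataset(contigs=contigs, metadata=metadata, adata=adata, ground_truth=gt)
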