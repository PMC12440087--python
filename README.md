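# clonotrack

Clonal tracking of T-cell receptor (TCR) repertoires across sorted subsets,
timepoints, tissues, and single-cell transcriptomic clusters.

Every T cell inherits its receptor from one thymic progenitor, so an
identical TCR observed in two samples identifies the same clone. This makes
the TCR a molecular barcode for asking questions that arise constantly in
autoimmunity and tumor immunology: do two sorted phenotypes (for example
CXCR5− PD-1hi "peripheral helper" and CXCR5+ PD-1hi "follicular helper" CD4
T cells) share clonal origins? Do expanded clones persist over a year of
disease? Which single-cell cluster accounts for the clonal overlap seen
between two bulk-sorted pools? `clonotrack` implements this analysis as a
tested, reusable Python library and command-line pipeline for:

* **clonotype construction** from bulk TCRβ tables (AIRR Rearrangement TSV)
  and paired-chain 10x single-cell contig tables, with productive filtering,
  technical-duplicate merging, and the standard five expansion bins
  (single / small ≤5 / medium ≤20 / large ≤100 / hyperexpanded);
* **depth-normalized clonality** — the inverse Simpson index
  `1 / Σᵢ pᵢ²` on repertoires rarefied without replacement to a common
  read depth (default 5000), averaged over replicates and iterations;
* **repertoire overlap** — Morisita–Horn
  `2 Σ pᵢqᵢ / (Σ pᵢ² + Σ qᵢ²)`, Jaccard, and shared-clone counts over any
  sample grouping;
* **longitudinal tracking** — persistence fractions of expanded clones,
  subset-transition detection, and upset-style exact intersection tables;
* **bulk ↔ single-cell linkage** — β-chain projection of paired clonotypes
  and per-cluster detection fractions / read-level pool ratios against
  bulk sorted pools;
* **signature scoring** — Wilcoxon + Benjamini–Hochberg marker derivation
  and an expression-bin-controlled module score for the activated
  B-cell-helper (TOX+ CXCL13+) state;
* **synthetic cohorts** — a generator that plants clone-size laws, subset
  sharing, temporal persistence, private CTL expansions, and an expression
  signature, emitting full ground truth for validation.

## Worked example

Simulate one donor with the default study design (three sorted subsets,
planted Tph–Tfh sharing probability 0.3, a private hyperexpanded CTL clone
set in the Tph pool) and compare the subsets at baseline:

```python
from collections import defaultdict
from clonotrack.simulate import CohortConfig, generate_cohort
from clonotrack.diversity import clonality_with_replicates, jaccard
from clonotrack.clonotypes import merge_replicates

cfg = CohortConfig(n_donors=1, seed=42)
cohort = generate_cohort(cfg, out_dir="demo")

groups = defaultdict(list)
for rep in cohort.repertoires:
    if rep.timepoint == "T0":
        groups[rep.subset].append(rep)
merged = {s: merge_replicates(*reps) for s, reps in groups.items()}

for s in cfg.subsets:
    res = clonality_with_replicates(groups[s], depth=5000, n_iter=10, seed=0)
    print(f"{s:5s} clones={merged[s].n_clones:4d}  "
          f"inverse Simpson (5000 reads) = {res.inverse_simpson_mean:6.1f}")
print(f"shared Tph-Tfh clones = {len(merged['Tph'].key_set() & merged['Tfh'].key_set())}")
print(f"Jaccard(Tph, Tfh) = {jaccard(merged['Tph'], merged['Tfh']):.3f}")
```

```
Tph   clones= 406  inverse Simpson (5000 reads) =   12.5
Tfh   clones= 400  inverse Simpson (5000 reads) =   42.2
Treg  clones= 400  inverse Simpson (5000 reads) =   95.3
shared Tph-Tfh clones = 134
Jaccard(Tph, Tfh) = 0.199
```

The Tph pool is by far the most oligoclonal (inverse Simpson ≈ 12, i.e. an
effective dozen clones carry the reads) because it carries the planted
hyperexpanded CTL clones, while 134 of its 406 clones — close to the
planted sharing probability of 0.3 — are also found in the Tfh pool.

The same stages are available from the shell:

```bash
clonotrack simulate --out-dir demo --seed 42 --n-donors 1
clonotrack validate  --manifest demo/manifest.tsv
clonotrack diversity --manifest demo/manifest.tsv --depth 5000 --out diversity.tsv
clonotrack overlap   --manifest demo/manifest.tsv --out overlap.tsv --plot overlap.png
clonotrack run       --config cohort.yaml --out-dir results
```

`clonotrack run` executes the full configured pipeline
(simulate → validate → diversity → overlap → track → link → score) and is
byte-for-byte reproducible for a fixed config and seed.

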