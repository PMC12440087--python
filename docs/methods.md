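# Methods

## Clonotype identity

A clonotype is a set of T cells carrying the same receptor under a stated
key. Two key modes are implemented and never mixed implicitly:

* **bulk_beta** — CDR3 junction + TRBV + TRBJ gene calls of the β chain.
  The default sequence level is nucleotide, the strictest clone definition;
  an amino-acid level is available for cross-platform matching. D-gene
  calls are ignored: they are frequently absent in short-read data and add
  no discriminatory power beyond the junction.
* **paired_ab** — both chains of a single cell: identical V/J genes and
  CDR3 junctions on TRA and TRB. Cells lacking a productive chain of
  either locus are removed. When a barcode carries more than one productive
  contig for a locus the highest-UMI contig is kept (ties broken
  lexicographically by CDR3 nucleotide, making the pairing deterministic
  and independent of input row order); a stricter `drop` policy discards
  such cells instead. The choice is logged per run.

Crossing modes — comparing paired single-cell clonotypes with β-only bulk
data — goes through an explicit β-chain projection. Its default level is
**amino acid** + V/J because bulk (genomic DNA) and single-cell (cDNA)
platforms can disagree at the nucleotide junction while agreeing on the
translated CDR3; nucleotide-level projection is a config option.

Non-productive rearrangements are removed before any repertoire statistic.
Clone sizes are binned as single (1), small (2–5), medium (6–20), large
(21–100), hyperexpanded (>100); sizes above the conventional printed cap of
500 remain hyperexpanded so the bins partition all positive integers.

## Clonality and overlap

Clonality is reported as the inverse Simpson index `1/Σ pᵢ²` — the
effective number of clones (1 = monoclonal; K for K equally sized clones).
Because richness and evenness estimates are depth-dependent, repertoires
are rarefied to a common depth before comparison: exactly `depth` reads
drawn **without replacement** (multivariate hypergeometric over the read
multiset), defaulting to 5000 reads with 10 independent iterations, and
averaged over iterations and technical replicates. Samples shallower than
the target are analyzed at full depth and flagged rather than excluded, so
a sparse sample degrades gracefully instead of silently disappearing.

Pairwise overlap is reported with three statistics side by side: the
abundance-weighted Morisita–Horn index
`2 Σ pᵢqᵢ / (Σ pᵢ² + Σ qᵢ²)` over the union of keys (in [0,1]; 1 iff the
relative abundance vectors coincide), the presence/absence Jaccard index,
and the raw shared-clone count. Morisita–Horn is the default because it is
nearly insensitive to sampling depth; Jaccard and shared counts answer the
complementary "how many clones" question.

## Clone tracking

Tracking reduces to set arithmetic on clonotype keys, which is exact:

* **persistence** — `|expanded(t₂) ∩ observed(t₁)| / |expanded(t₂)|`,
  where "expanded" defaults to size ≥ 2 (cells for single-cell input,
  reads for bulk) and "observed" means present in the merged-replicate
  repertoire of any analyzed subset unless a subset filter is given;
* **transitions** — clones unique to one sorted subset at baseline
  (`source \ excluded`) later detected in the other subset;
* **intersection tables** — exact-membership (upset-style) counts over
  named clone sets; the counts provably sum to the union cardinality and
  this invariant is asserted on every call.

## Bulk ↔ single-cell linkage

For each transcriptomic cluster two complementary quantities are computed
against each bulk sorted pool of the same donor. The **detection fraction**
is the share of the cluster's *distinct* projected clonotypes present in
the pool; with technical bulk replicates a clonotype counts as detected if
present in either, and per-replicate fractions are reported alongside. The
**pool ratio** is read-level: the fraction of pool X's reads carried by
cluster-matching clonotypes divided by the same fraction in pool Y (exact
reciprocal under pool exchange; an all-zero denominator is flagged infinite
rather than silently dropped). Per-cluster clonality applies the inverse
Simpson index to the cell-level clone-size spectrum within cluster × sorted
gate.

## Signature derivation and module scoring

Markers of a target cluster are derived by per-gene two-sided Wilcoxon
rank-sum (target vs all other cells) on log-normalized expression with
Benjamini–Hochberg correction; genes must pass FDR 0.05 with positive
log fold-change and are ranked by adjusted p, then by descending logFC.
The ranking rule is a declared choice; "distinctively expressed" admits
several orderings and this one favors reproducible, large-effect genes.

Cells are scored with an expression-bin-controlled module score: all genes
are placed into `n_bins = 25` equal-count bins by average expression over
all cells; each signature gene draws up to `n_ctrl = 100` control genes
(seeded, without replacement) from its bin, excluding signature genes
themselves; the score is the per-cell mean over signature genes minus the
mean over the pooled controls. Matching controls on average expression
cancels per-cell depth effects, so a constant matrix scores exactly zero
and an additive per-cell offset leaves scores unchanged. When a bin is
exhausted by signature genes (possible in small matrices), the fallback is
the nearest non-signature genes by average expression — deterministic, so
scoring stays reproducible under a fixed seed. Excluding signature genes
from the control pool is a deliberate deviation from some reference
implementations: self-contamination of controls shrinks planted effects
and complicates validation.

Droplet QC removes cells with fewer than 200 or more than 3000 expressed
genes or more than 10% mitochondrial UMIs (all thresholds configurable).

## Synthetic cohorts and what they do (not) show

The generator's defaults describe the emulated study: 3 donors; sorted
Tph / Tfh / Treg subsets; 3 timepoints; 400 clones per subset per donor;
technical duplicates produced by binomial (p = 0.5) splitting of 20 000
multinomially allocated reads per sample; 2% spiked non-productive rows.

* **Clone sizes** are drawn i.i.d. from a truncated discrete power law
  `P(s) ∝ s^−α`, s = 1..500, α = 2.5 — a heavy-tailed abundance model
  consistent with typical memory-repertoire spectra; no abundance model is
  claimed beyond that.
* **Sharing** between subset pair (i, j) is planted as a count
  `K ~ Binomial(N, S_ij)` of clones present in both pools, the remainder
  private (default S[Tph,Tfh] = 0.3, all other pairs 0; no triple-shared
  clones). The observed shared-clone fraction `|A ∩ B| / N` is then a
  clean binomial estimator of S.
* **Persistence**: each clone survives to the next timepoint with
  probability ρ = 0.7, and pools are topped up with novel clones to
  constant size, so the persister fraction of any later pool estimates ρ.
* **CTL clones**: 6 clones of uniform size 100–400, private to the Tph
  pool, persistent across all timepoints (emulating chronically expanded
  cytotoxic clones); they dominate the Tph read mass and drive its
  oligoclonality.
* **Single-cell layer** (at the last timepoint): clusters C0 (Tfh-private
  clones, CXCR5+PD-1hi gate), C1 (Tph-private, CXCR5−PD-1hi), C3 (the CTL
  clones, CXCR5−PD-1hi only), C5 (Tph/Tfh-shared clones, sorted into both
  PD-1hi gates), 80 cells each per donor, clone picks weighted by size.
  Contig β chains match the bulk clone exactly; CDR3s are random
  junctions with canonical C…F anchors back-translated through the
  standard codon table, unique within donor, with V/J names from a small
  built-in list — there is **no** germline V(D)J recombination model.
  Expression is a negative-binomial baseline (per-gene lognormal means,
  dispersion 2) with a +1.5 log2FC shift on 20 signature genes in C5
  cells.

What passing recovery tests therefore shows: the statistics are computed
correctly and the pipeline recovers planted sharing/persistence/linkage
structure at realistic sample sizes. What they do not show: robustness to
sequencing error and junction mis-assembly, cross-platform V/J call
inconsistencies, ambient-RNA or doublet contamination, batch effects, or
biologically realistic repertoire generation probabilities — none of which
the generator emulates.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng` seeded from
  explicit config values; identical config + seed reruns are byte-identical
  (pipeline tables carry a provenance header of version, config hash, and
  seed, deliberately without timestamps).
* Equal-count expression bins use average-expression ranks
  (`method="first"`), which is well-defined under ties.
* Empty inputs are reported as missing (NaN) with a logged warning rather
  than raised, except where the contract is unfulfillable (empty reference
  cluster, empty repertoire for inverse Simpson).
* Morisita–Horn on two disjoint singletons is 0 by the formula; the
  diagonal of an overlap matrix is 1 for any nonempty sample.
* Problem sizes in the validation suite are scaled to the defaults above
  (≈ 1200 clones per subset cohort-wide, ≈ 1000 paired cells), at which the
  binomial 95% half-widths are ≈ 0.026 for sharing and persistence —
  narrow enough to make parameter recovery a meaningful check.

## Known limitations

* The human single-cell clonotype rule is applied at nucleotide level with
  V/J genes for consistency with the strict definition; an amino-acid mode
  exists but which level the field's informal phrasing intends is
  genuinely ambiguous, so both are exposed rather than guessed.
* Cross-modality matching can miss clones when bulk and single-cell V-gene
  naming conventions differ; the V/J component of the projection can be
  disabled.
* The overlap statistic used in published heatmaps of this design is often
  unnamed; Morisita–Horn is this package's declared default, with Jaccard
  and shared counts always available for comparison.
* No significance testing is attached to overlap or persistence fractions;
  the package reports estimators, not inference.
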