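"""Domain types for TCR clonal tracking.

The central abstractions are the *clonotype key* — the identity under which
T cells are called "the same clone" — and the :class:`Repertoire`, a keyed
multiset of clonotype read counts for one sorted sample (donor x subset x
timepoint x tissue x replicate).

Two key modes exist and are never compared implicitly:

* ``bulk_beta`` — a single TCRbeta chain key (:class:`BetaKey`): CDR3 sequence
  (nucleotide or amino acid, per configuration) plus V and J gene calls.
  D calls are ignored: they are frequently uncalled in short-read data.
* ``paired_ab`` — a paired alpha/beta key built from both chains of a single
  cell (:func:`CellClonotype.paired_key`).

Crossing the two modes requires the explicit beta-chain projection provided
by :mod:`clonotrack.linkage`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple

from Bio.Seq import Seq

__all__ = [
    "BetaKey",
    "ChainInfo",
    "CellClonotype",
    "ClonotypeRecord",
    "ContigRecord",
    "Repertoire",
    "translate_cdr3",
]


def translate_cdr3(cdr3_nt: str) -> str:
    """Standard-table translation of a CDR3 nucleotide junction."""
    return str(Seq(cdr3_nt).translate())


class BetaKey(NamedTuple):
    """Single-chain (TCRbeta) clonotype key.

    ``cdr3`` holds either the nucleotide or the amino-acid junction depending
    on the key level chosen when the key was built; keys built at different
    levels are distinct objects and never collide in practice.
    """

    cdr3: str
    v_call: str
    j_call: str


@dataclass(frozen=True)
class ChainInfo:
    """One productive chain of a cell's receptor."""

    cdr3_nt: str
    cdr3_aa: str
    v_call: str
    j_call: str

    def key(self, level: str = "nt", use_vj: bool = True) -> BetaKey:
        cdr3 = self.cdr3_nt if level == "nt" else self.cdr3_aa
        if use_vj:
            return BetaKey(cdr3, self.v_call, self.j_call)
        return BetaKey(cdr3, "", "")


@dataclass
class ClonotypeRecord:
    """One row of a bulk clonotype table."""

    cdr3_nt: str
    cdr3_aa: str
    v_call: str
    d_call: str
    j_call: str
    read_count: int
    productive: bool

    def validate(self) -> None:
        if self.read_count < 1:
            raise ValueError(f"read_count must be >= 1, got {self.read_count}")
        if self.productive and self.cdr3_nt and len(self.cdr3_nt) % 3 != 0:
            raise ValueError(
                f"productive CDR3 nt length not divisible by 3: {self.cdr3_nt!r}"
            )
        if self.productive and self.cdr3_nt and self.cdr3_aa:
            if translate_cdr3(self.cdr3_nt) != self.cdr3_aa:
                raise ValueError(
                    f"cdr3_aa {self.cdr3_aa!r} is not the translation of {self.cdr3_nt!r}"
                )

    def key(self, level: str = "nt", use_vj: bool = True) -> BetaKey:
        cdr3 = self.cdr3_nt if level == "nt" else self.cdr3_aa
        if use_vj:
            return BetaKey(cdr3, self.v_call, self.j_call)
        return BetaKey(cdr3, "", "")


@dataclass
class ContigRecord:
    """One assembled single-cell V(D)J contig (10x dialect)."""

    barcode: str
    chain: str  # "TRA" or "TRB"
    cdr3_nt: str
    cdr3_aa: str
    v_call: str
    j_call: str
    umi_count: int
    productive: bool


@dataclass(frozen=True)
class CellClonotype:
    """A cell with exactly one productive TRA and one productive TRB."""

    barcode: str
    tra: ChainInfo
    trb: ChainInfo
    donor: str = ""
    sorted_gate: str = ""
    tissue: str = ""
    timepoint: str = ""
    cluster: str = ""

    def paired_key(self, level: str = "nt", use_vj: bool = True):
        """Paired alpha/beta clonotype key.

        The default (nucleotide CDR3 + V/J of both chains) is the strict
        clone definition: cells are clonal when both chains carry identical
        V/J genes and CDR3 nucleotide junctions. ``level='aa'`` relaxes the
        junction comparison to amino acids.
        """
        return ("paired_ab", self.tra.key(level, use_vj), self.trb.key(level, use_vj))

    def beta_key(self, level: str = "aa", use_vj: bool = True) -> BetaKey:
        """Beta-chain-only key, for matching against bulk TCRbeta data."""
        return self.trb.key(level, use_vj)


@dataclass
class Repertoire:
    """A keyed multiset of clonotype read counts for one sample.

    ``clonotypes`` maps a clonotype key to an aggregated read count (>= 1).
    ``annotations`` optionally retains per-key record details (CDR3 at the
    other sequence level, D call) so a repertoire can be written back to an
    AIRR table losslessly. ``meta`` carries processing flags (downsampling,
    rejected-row counts) and never participates in equality.
    """

    donor: str = ""
    subset: str = ""
    timepoint: str = ""
    tissue: str = ""
    replicate: str = ""
    key_level: str = "nt"
    clonotypes: Counter = field(default_factory=Counter)
    annotations: dict = field(default_factory=dict, compare=False)
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not isinstance(self.clonotypes, Counter):
            self.clonotypes = Counter(self.clonotypes)

    @property
    def total_reads(self) -> int:
        return sum(self.clonotypes.values())

    @property
    def n_clones(self) -> int:
        return len(self.clonotypes)

    @property
    def sample_id(self) -> str:
        parts = [self.donor, self.subset, self.timepoint, self.tissue, self.replicate]
        return "|".join(p for p in parts if p)

    def keys(self) -> Iterator[BetaKey]:
        return iter(self.clonotypes)

    def key_set(self) -> frozenset:
        return frozenset(self.clonotypes)

    def labels(self) -> Mapping[str, str]:
        return {
            "donor": self.donor,
            "subset": self.subset,
            "timepoint": self.timepoint,
            "tissue": self.tissue,
            "replicate": self.replicate,
        }

    def with_counts(self, counts: Mapping, **meta) -> "Repertoire":
        """Copy of this repertoire with replaced counts (labels preserved)."""
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Repertoire(
            donor=self.donor,
            subset=self.subset,
            timepoint=self.timepoint,
            tissue=self.tissue,
            replicate=self.replicate,
            key_level=self.key_level,
            clonotypes=Counter(counts),
            annotations=self.annotations,
            meta=new_meta,
        )
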