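"""shRNA library annotation: clones, target genes, and hairpin barcodes.

Every other stage of the screen analysis keys on this annotation: barcode
counting matches reads against clone sequences, and hit calling aggregates
clone-level statistics per target gene.  Control hairpins carry the reserved
gene token ``NONTARGETING``; they are counted and standardized like any other
clone but never enter the gene universe used for candidate calling or
enrichment.
"""

from __future__ import annotations

import warnings
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "NONTARGETING",
    "ShRNAClone",
    "ShRNALibrary",
    "LibrarySummary",
    "read_library",
    "write_library",
    "write_fasta",
    "library_summary",
]

#: Reserved gene token identifying nontargeting control hairpins.
NONTARGETING = "NONTARGETING"

_VALID_BASES = frozenset("ACGT")

_LIBRARY_COLUMNS = ["clone_id", "gene", "sequence"]


@dataclass(frozen=True)
class ShRNAClone:
    """A single hairpin: unique clone id, target gene symbol, barcode sequence."""

    clone_id: str
    gene: str
    sequence: str


@dataclass
class ShRNALibrary:
    """An ordered collection of clones with a fixed barcode length.

    Parameters
    ----------
    clones
        Clones in file/library order.  Order is preserved through I/O and is
        the canonical row order of count matrices.
    barcode_length
        Declared hairpin barcode length in nt; every clone sequence must have
        exactly this length.
    """

    clones: list[ShRNAClone]
    barcode_length: int
    gene_index: "OrderedDict[str, list[str]]" = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        seqs: dict[str, str] = {}
        index: OrderedDict[str, list[str]] = OrderedDict()
        for i, clone in enumerate(self.clones):
            if clone.clone_id in seen:
                raise ValueError(f"duplicate clone_id {clone.clone_id!r}")
            seen.add(clone.clone_id)
            if len(clone.sequence) != self.barcode_length:
                raise ValueError(
                    f"clone {clone.clone_id!r}: sequence length "
                    f"{len(clone.sequence)} != declared barcode length "
                    f"{self.barcode_length}"
                )
            bad = set(clone.sequence) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"clone {clone.clone_id!r} (row {i + 1}): non-ACGT "
                    f"character(s) {sorted(bad)} in sequence"
                )
            if clone.sequence in seqs:
                warnings.warn(
                    f"duplicate barcode sequence shared by clones "
                    f"{seqs[clone.sequence]!r} and {clone.clone_id!r}; reads "
                    "matching it will be tallied as ambiguous",
                    stacklevel=2,
                )
            else:
                seqs[clone.sequence] = clone.clone_id
            index.setdefault(clone.gene, []).append(clone.clone_id)
        object.__setattr__(self, "gene_index", index)

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def clone_ids(self) -> list[str]:
        return [c.clone_id for c in self.clones]

    @property
    def sequences(self) -> list[str]:
        return [c.sequence for c in self.clones]

    @property
    def genes(self) -> list[str]:
        """Target genes in first-appearance order, excluding controls."""
        return [g for g in self.gene_index if g != NONTARGETING]

    def gene_of(self) -> dict[str, str]:
        """clone_id -> gene symbol map."""
        return {c.clone_id: c.gene for c in self.clones}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clone_id": self.clone_ids,
                "gene": [c.gene for c in self.clones],
                "sequence": self.sequences,
            }
        )


@dataclass(frozen=True)
class LibrarySummary:
    n_clones: int
    n_genes: int
    n_controls: int
    clones_per_gene: "Counter[str]"

    @property
    def min_clones_per_gene(self) -> int:
        return min(self.clones_per_gene.values()) if self.clones_per_gene else 0

    @property
    def max_clones_per_gene(self) -> int:
        return max(self.clones_per_gene.values()) if self.clones_per_gene else 0


def _normalize_gene(symbol: str) -> str:
    # Upper-case, whitespace-stripped; deliberately no alias resolution so the
    # gene universe is exactly what the annotation file says.
    return symbol.strip().upper()


def read_library(path: str | Path) -> ShRNALibrary:
    """Read a library annotation TSV with columns clone_id, gene, sequence.

    Gene symbols are upper-cased and stripped; row order is preserved.
    Raises ``ValueError`` on duplicate clone ids, ragged sequence lengths, or
    non-ACGT characters (with the offending row identified).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: library file has no data rows")

    lengths = df["sequence"].str.len()
    if lengths.nunique() != 1:
        raise ValueError(
            f"{path}: ragged sequence lengths {sorted(lengths.unique())}; "
            "all barcodes must share one length"
        )
    barcode_length = int(lengths.iloc[0])

    clones = []
    for row in df.itertuples(index=True):
        seq = row.sequence.strip().upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{path}: row {row.Index + 2}: non-ACGT character(s) "
                f"{sorted(bad)} in sequence for clone {row.clone_id!r}"
            )
        clones.append(
            ShRNAClone(
                clone_id=row.clone_id.strip(),
                gene=_normalize_gene(row.gene),
                sequence=seq,
            )
        )
    return ShRNALibrary(clones=clones, barcode_length=barcode_length)


def write_library(lib: ShRNALibrary, path: str | Path) -> None:
    """Write the annotation TSV; ``read_library`` round-trips it field-for-field."""
    if len(lib.clones) == 0:
        raise ValueError("refusing to write an empty library")
    lib.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_fasta(lib: ShRNALibrary, path: str | Path) -> None:
    """Export barcodes as FASTA (id = clone_id, description = gene)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(c.sequence), id=c.clone_id, description=c.gene)
        for c in lib.clones
    ]
    seqio_write(records, str(path), "fasta")


def library_summary(lib: ShRNALibrary) -> LibrarySummary:
    """Clone/gene/control tallies; controls are excluded from the gene count."""
    per_gene: Counter[str] = Counter()
    n_controls = 0
    for clone in lib.clones:
        if clone.gene == NONTARGETING:
            n_controls += 1
        else:
            per_gene[clone.gene] += 1
    return LibrarySummary(
        n_clones=len(lib.clones),
        n_genes=len(per_gene),
        n_controls=n_controls,
        clones_per_gene=per_gene,
    )
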