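"""Extract protein-coding genes across genomes and export phylogenetic matrices.

Builds the inputs for external tree software: per-gene coding sequence
sets, and a concatenated supermatrix (nucleotide or amino acid, translated
under the invertebrate mitochondrial code) with a partition table.  Any
column in which at least one sequence carries a gap or an ambiguous symbol
is removed before concatenation, and the removals are logged so partition
bookkeeping stays auditable.  Tree inference itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .core import MitoGenome
from .kaks import strip_stop
from .names import PCGS

_NT_OK = frozenset("ACGT")
_AA_OK = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SupermatrixSpec:
    """Concatenation order and datatype of a supermatrix."""

    gene_order: tuple[str, ...] = PCGS
    datatype: str = "nucleotide"  # or "amino_acid"

    def __post_init__(self) -> None:
        if self.datatype not in ("nucleotide", "amino_acid"):
            raise ValueError(f"unknown datatype {self.datatype!r}")


@dataclass
class Supermatrix:
    """Concatenated matrix, its partitions, and the removed-column log.

    Partitions are 1-based inclusive column ranges that tile the matrix
    without overlap.
    """

    sequences: dict[str, str]
    partitions: list[tuple[str, int, int]]
    datatype: str
    removed_columns: dict[str, list[int]] = field(default_factory=dict)

    @property
    def width(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


def extract_pcgs(
    genomes: Sequence[MitoGenome],
    genes: Optional[Sequence[str]] = None,
) -> tuple[dict[str, dict[str, str]], dict[str, list[str]]]:
    """Coding-strand CDS per gene per genome, plus a report of missing genes.

    Returns ``(per_gene, missing)`` where ``per_gene[gene][identifier]`` is
    the CDS and ``missing[identifier]`` lists genes absent from that genome
    (reported, never silently dropped).
    """
    if genes is None:
        genes = list(PCGS)
    per_gene: dict[str, dict[str, str]] = {g: {} for g in genes}
    missing: dict[str, list[str]] = {}
    for genome in genomes:
        present = {f.name: f for f in genome.features if f.gene_class == "PCG"}
        for gene in genes:
            if gene in present:
                per_gene[gene][genome.identifier] = genome.coding_sequence(present[gene])
            else:
                missing.setdefault(genome.identifier, []).append(gene)
    return per_gene, missing


def _translate(cds: str) -> str:
    n = len(cds) // 3 * 3
    return str(Seq(cds[:n]).translate(table=5))


def concatenate(
    per_gene: Mapping[str, Mapping[str, str]],
    spec: Optional[SupermatrixSpec] = None,
) -> Supermatrix:
    """Concatenate aligned per-gene sets into one matrix with partitions.

    Each gene's sequences must already be equal length (aligned externally,
    or trivially equal for conspecific comparisons).  Terminal stops are
    stripped; for amino-acid matrices each gene is translated under table 5.
    Columns containing a gap or ambiguity in any sequence are removed and
    logged per gene (1-based positions within the gene block).
    """
    if spec is None:
        spec = SupermatrixSpec(gene_order=tuple(per_gene))
    taxa: list[str] = []
    for gene in spec.gene_order:
        for sp in per_gene.get(gene, {}):
            if sp not in taxa:
                taxa.append(sp)
    ok = _AA_OK if spec.datatype == "amino_acid" else _NT_OK

    parts: dict[str, list[str]] = {sp: [] for sp in taxa}
    partitions: list[tuple[str, int, int]] = []
    removed: dict[str, list[int]] = {}
    col = 1
    for gene in spec.gene_order:
        seqs = per_gene.get(gene, {})
        if set(seqs) != set(taxa):
            absent = sorted(set(taxa) - set(seqs))
            raise ValueError(f"gene {gene}: missing sequences for {absent}")
        block = {sp: strip_stop(s.upper()) for sp, s in seqs.items()}
        if spec.datatype == "amino_acid":
            block = {sp: _translate(s) for sp, s in block.items()}
        widths = {len(s) for s in block.values()}
        if len(widths) != 1:
            raise ValueError(
                f"gene {gene}: unaligned input (lengths {sorted(widths)})"
            )
        width = widths.pop()
        keep = [
            i for i in range(width)
            if all(block[sp][i] in ok for sp in taxa)
        ]
        dropped = [i + 1 for i in range(width) if i not in set(keep)]
        if dropped:
            removed[gene] = dropped
        for sp in taxa:
            parts[sp].append("".join(block[sp][i] for i in keep))
        if keep:
            partitions.append((gene, col, col + len(keep) - 1))
            col += len(keep)
    return Supermatrix(
        sequences={sp: "".join(chunks) for sp, chunks in parts.items()},
        partitions=partitions,
        datatype=spec.datatype,
        removed_columns=removed,
    )


def write_fasta_matrix(matrix: Supermatrix, path) -> None:
    with Path(path).open("w") as fh:
        for sp, seq in matrix.sequences.items():
            fh.write(f">{sp}\n{seq}\n")


def write_phylip(matrix: Supermatrix, path) -> None:
    """Relaxed PHYLIP: full names, two-space separator."""
    with Path(path).open("w") as fh:
        fh.write(f" {len(matrix.sequences)} {matrix.width}\n")
        pad = max(len(sp) for sp in matrix.sequences) + 2
        for sp, seq in matrix.sequences.items():
            fh.write(f"{sp.ljust(pad)}{seq}\n")


def write_nexus(matrix: Supermatrix, path) -> None:
    datatype = "protein" if matrix.datatype == "amino_acid" else "dna"
    with Path(path).open("w") as fh:
        fh.write("#NEXUS\nbegin data;\n")
        fh.write(f"  dimensions ntax={len(matrix.sequences)} nchar={matrix.width};\n")
        fh.write(f"  format datatype={datatype} missing=? gap=-;\n  matrix\n")
        pad = max(len(sp) for sp in matrix.sequences) + 2
        for sp, seq in matrix.sequences.items():
            fh.write(f"  {sp.ljust(pad)}{seq}\n")
        fh.write("  ;\nend;\n")
        fh.write("begin sets;\n")
        for gene, lo, hi in matrix.partitions:
            fh.write(f"  charset {gene} = {lo}-{hi};\n")
        fh.write("end;\n")


def write_partitions(matrix: Supermatrix, path) -> None:
    """RAxML-style plain-text partition file."""
    model = "LG" if matrix.datatype == "amino_acid" else "DNA"
    with Path(path).open("w") as fh:
        for gene, lo, hi in matrix.partitions:
            fh.write(f"{model}, {gene} = {lo}-{hi}\n")
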