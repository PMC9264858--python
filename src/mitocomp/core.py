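"""Domain types for circular mitogenomes and all coordinate arithmetic.

Coordinates are 1-based inclusive throughout the public surface, matching the
GenBank convention and the printed gene tables this package reproduces.
Strands are called ``J`` (majority strand, the deposited forward sequence)
and ``N`` (minority strand, the complement), the standard vocabulary for
insect mitogenomes.

The signed distance between consecutive genes on the circle is the
intergenic spacer: positive for a gap, zero for perfect adjacency, negative
for an overlap.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import names

GENE_CLASSES = frozenset({"PCG", "tRNA", "rRNA", "control_region", "other"})
STRANDS = frozenset({"J", "N"})

_SEQ_ALPHABET = frozenset("ACGTN")


class IncompleteAnnotationWarning(UserWarning):
    """A genome flagged complete does not carry the expected 37 genes + control region."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene or region on a mitogenome.

    ``start``/``end`` are 1-based inclusive and must not wrap the origin
    (origin-spanning features are rejected).  For protein-coding genes the
    stop-codon completeness must be consistent with ``length mod 3``: a
    complete TAA/TAG stop implies a length divisible by three, a truncated
    ``TA`` leaves remainder 2 and a bare ``T`` remainder 1 (the transcript is
    completed to TAA by polyadenylation).
    """

    name: str
    gene_class: str
    strand: Optional[str]
    start: int
    end: int
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if self.strand is not None and self.strand not in STRANDS:
            raise ValueError(f"strand must be 'J', 'N' or None, got {self.strand!r}")
        if self.start < 1:
            raise ValueError(f"{self.name}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"{self.name}: end < start ({self.end} < {self.start}); "
                "origin-spanning features are not supported"
            )
        for attr in ("start_codon", "stop_codon"):
            val = getattr(self, attr)
            if val is not None:
                object.__setattr__(self, attr, val.upper())
        if self.start_codon is not None and len(self.start_codon) != 3:
            raise ValueError(f"{self.name}: start codon must be 3 nt")
        if self.stop_codon is not None and not 1 <= len(self.stop_codon) <= 3:
            raise ValueError(f"{self.name}: stop codon must be 1-3 nt")
        if self.gene_class == "PCG" and self.stop_codon is not None:
            if len(self.stop_codon) % 3 != self.length % 3:
                raise ValueError(
                    f"{self.name}: stop codon {self.stop_codon!r} inconsistent "
                    f"with length {self.length} (mod 3 = {self.length % 3})"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def feature_length(f: GeneFeature) -> int:
    """Length of a feature in bp (end − start + 1)."""
    return f.length


def spacer_between(
    prev: GeneFeature,
    nxt: GeneFeature,
    genome_length: Optional[int] = None,
    *,
    wrap: bool = False,
) -> int:
    """Signed intergenic distance from ``prev`` to the following ``nxt``.

    ``next.start − prev.end − 1`` for an ordinary pair: 0 means the genes are
    perfectly adjacent, negative values measure the overlap.  For the single
    pair that spans the origin of the circle pass ``wrap=True`` together with
    the genome length.
    """
    if not wrap:
        return nxt.start - prev.end - 1
    if genome_length is None:
        raise ValueError("genome_length is required for the origin-spanning pair")
    return nxt.start + genome_length - prev.end - 1


@dataclass
class MitoGenome:
    """A circular mitochondrial genome: sequence (J-strand) plus ordered features.

    ``complete`` records whether the annotation covers the whole molecule
    (in particular whether the control region was recovered); when it is
    False the wrap-around spacer of the gene table is reported as unknown
    rather than computed from coordinates.
    """

    identifier: str
    sequence: Optional[str] = None
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    complete: bool = True
    length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            bad = set(self.sequence) - _SEQ_ALPHABET
            if bad:
                raise ValueError(f"sequence contains invalid symbols {sorted(bad)}")
            if self.length is not None and self.length != len(self.sequence):
                raise ValueError("explicit length contradicts sequence length")
            self.length = len(self.sequence)
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        if self.length is not None:
            for f in self.features:
                if f.end > self.length:
                    raise ValueError(
                        f"feature {f.name} ({f.start}-{f.end}) exceeds genome "
                        f"length {self.length}"
                    )
        if self.complete and self.features:
            n_genes = sum(1 for f in self.features if f.gene_class in ("PCG", "tRNA", "rRNA"))
            has_cr = any(f.gene_class == "control_region" for f in self.features)
            if n_genes != 37 or not has_cr:
                warnings.warn(
                    f"{self.identifier}: expected 37 genes plus a control region "
                    f"for a complete insect mitogenome, found {n_genes} genes"
                    f"{' and no control region' if not has_cr else ''}",
                    IncompleteAnnotationWarning,
                    stacklevel=2,
                )

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def coding_sequence(self, f: GeneFeature) -> str:
        """Coding-strand sequence of a feature (reverse complement for N-strand)."""
        if self.sequence is None:
            raise ValueError(f"{self.identifier} carries no sequence")
        seg = self.sequence[f.start - 1 : f.end]
        if f.strand == "N":
            seg = reverse_complement(seg)
        return seg


_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


TSV_COLUMNS = ("Gene", "Strand", "Start", "End", "Length",
               "StartCodon", "StopCodon", "Intergenic")


@dataclass
class GeneTable:
    """Ordered gene table with derived length and signed intergenic columns.

    The derived columns are pure functions of the coordinates; for a complete
    circular genome the conservation identity
    Σ lengths + Σ intergenic = genome length holds exactly.
    """

    frame: pd.DataFrame
    identifier: str = ""
    genome_length: Optional[int] = None
    circular: bool = True
    complete: bool = True

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def lengths(self) -> pd.Series:
        return self.frame["Length"]

    @property
    def intergenic(self) -> pd.Series:
        return self.frame["Intergenic"]

    def row(self, gene: str) -> pd.Series:
        hit = self.frame[self.frame["Gene"] == gene]
        if hit.empty:
            raise KeyError(gene)
        return hit.iloc[0]

    def spacer_after(self, gene: str):
        """Signed intergenic distance from ``gene`` to the next gene (None if unknown)."""
        val = self.row(gene)["Intergenic"]
        return None if pd.isna(val) else int(val)

    def conservation_sum(self) -> Optional[int]:
        """Σ lengths + Σ intergenic, or None when a spacer is unknown."""
        if self.intergenic.isna().any():
            return None
        return int(self.lengths.sum() + self.intergenic.sum())

    def features(self) -> list[GeneFeature]:
        out = []
        for _, r in self.frame.iterrows():
            out.append(
                GeneFeature(
                    name=r["Gene"],
                    gene_class=names.gene_class_of(r["Gene"]),
                    strand=None if pd.isna(r["Strand"]) or r["Strand"] == "-" else r["Strand"],
                    start=int(r["Start"]),
                    end=int(r["End"]),
                    start_codon=None if pd.isna(r["StartCodon"]) or r["StartCodon"] == "-" else r["StartCodon"],
                    stop_codon=None if pd.isna(r["StopCodon"]) or r["StopCodon"] == "-" else r["StopCodon"],
                )
            )
        return out

    def to_genome(self, sequence: Optional[str] = None) -> MitoGenome:
        return MitoGenome(
            identifier=self.identifier,
            sequence=sequence,
            features=self.features(),
            circular=self.circular,
            complete=self.complete,
            length=self.genome_length,
        )

    def to_tsv(self, path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# identifier: {self.identifier}\n")
            if self.genome_length is not None:
                fh.write(f"# genome_length: {self.genome_length}\n")
            fh.write(f"# circular: {str(self.circular).lower()}\n")
            fh.write(f"# complete: {str(self.complete).lower()}\n")
            out = self.frame.copy()
            out["Strand"] = out["Strand"].fillna("-")
            out["StartCodon"] = out["StartCodon"].fillna("-")
            out["StopCodon"] = out["StopCodon"].fillna("-")
            out["Intergenic"] = out["Intergenic"].map(
                lambda v: "NA" if pd.isna(v) else str(int(v))
            )
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneTable":
        path = Path(path)
        meta: dict[str, str] = {}
        with path.open() as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
        frame = pd.read_csv(
            path, sep="\t", comment="#",
            dtype={"Gene": str, "Strand": str, "StartCodon": str, "StopCodon": str},
            na_values=["NA"], keep_default_na=False,
        )
        missing = set(TSV_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        frame["Intergenic"] = pd.array(
            [pd.NA if v in ("", "NA") or pd.isna(v) else int(v) for v in frame["Intergenic"]],
            dtype="Int64",
        )
        for col in ("Start", "End", "Length"):
            frame[col] = frame[col].astype(int)
        return cls(
            frame=frame,
            identifier=meta.get("identifier", path.stem),
            genome_length=int(meta["genome_length"]) if "genome_length" in meta else None,
            circular=meta.get("circular", "true").lower() == "true",
            complete=meta.get("complete", "true").lower() == "true",
        )


def build_gene_table(genome: MitoGenome) -> GeneTable:
    """Derive the ordered gene table (lengths + signed intergenic spacers).

    Rows follow genome order (sorted by start).  The spacer of the last row
    wraps around the origin back to the first gene; for genomes whose
    annotation is incomplete (e.g. a missing control region) it is reported
    as unknown rather than computed.
    """
    feats = genome.features
    if not feats:
        raise ValueError(f"{genome.identifier}: no features to tabulate")
    seen_coords: set[tuple[int, int]] = set()
    for f in feats:
        if (f.start, f.end) in seen_coords:
            raise ValueError(f"duplicate coordinates {f.start}-{f.end}")
        seen_coords.add((f.start, f.end))
    for a, b in zip(feats, feats[1:]):
        if a.name == b.name and b.start <= a.end:
            raise ValueError(f"overlapping features share the name {a.name!r}")

    spacers: list[Optional[int]] = []
    for a, b in zip(feats, feats[1:]):
        spacers.append(spacer_between(a, b))
    if genome.circular and genome.complete:
        if genome.length is None:
            raise ValueError("genome length required for the wrap-around spacer")
        spacers.append(spacer_between(feats[-1], feats[0], genome.length, wrap=True))
    else:
        spacers.append(None)

    frame = pd.DataFrame(
        {
            "Gene": [f.name for f in feats],
            "Strand": [f.strand if f.strand is not None else "-" for f in feats],
            "Start": [f.start for f in feats],
            "End": [f.end for f in feats],
            "Length": [f.length for f in feats],
            "StartCodon": [f.start_codon if f.start_codon else "-" for f in feats],
            "StopCodon": [f.stop_codon if f.stop_codon else "-" for f in feats],
            "Intergenic": pd.array(spacers, dtype="Int64"),
        }
    )
    return GeneTable(
        frame=frame,
        identifier=genome.identifier,
        genome_length=genome.length,
        circular=genome.circular,
        complete=genome.complete,
    )
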