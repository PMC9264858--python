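"""Intergenic spacer extraction and motif-repeat architecture mapping.

Non-coding sequence between neighbouring mitochondrial genes (the
intergenic spacer, IGS) is rare real estate on an otherwise compact
molecule; a spacer longer than 50 bp is called *large* here.  In
*Prosopocoilus* stag beetles a large IGS sits between *trnI* and *trnQ* and
carries a short TAAAA repeat whose copy number and spacing differ between
species — a candidate synapomorphy for the genus.  A second, short spacer
between *trnS2* and *nad1* carries the beetle-wide conserved motif TACTAAA.

Motif scanning is a plain sliding window that reports every occurrence,
overlapping ones included; offsets are 1-based relative to the first base
of the spacer on the J-strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .core import GeneTable, MitoGenome, build_gene_table

LARGE_IGS_THRESHOLD = 50


@dataclass(frozen=True)
class SpacerRecord:
    """One inter-gene junction on the circle.

    ``length_bp`` is signed (negative = overlap) and None when unknown
    (origin-spanning junction of an incompletely annotated genome).
    ``sequence`` is empty unless the genome sequence is available and the
    spacer has positive length.
    """

    left_gene: str
    right_gene: str
    length_bp: Optional[int]
    sequence: str = ""
    is_large: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.length_bp is not None and self.sequence:
            if len(self.sequence) != max(self.length_bp, 0):
                raise ValueError(
                    f"{self.left_gene}-{self.right_gene}: sequence length "
                    f"{len(self.sequence)} != spacer length {self.length_bp}"
                )


@dataclass(frozen=True)
class MotifArchitecture:
    """Occurrences of one motif within one spacer.

    Satisfies count = |positions|, |gaps| = max(count − 1, 0) and
    gaps[i] = positions[i+1] − (positions[i] + |motif|).
    """

    motif: str
    positions: tuple[int, ...]
    gaps: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        expected = tuple(
            self.positions[i + 1] - (self.positions[i] + len(self.motif))
            for i in range(len(self.positions) - 1)
        )
        if self.gaps != expected:
            raise ValueError(f"gaps {self.gaps} inconsistent with positions {self.positions}")

    @property
    def count(self) -> int:
        return len(self.positions)


def extract_spacers(
    g: MitoGenome,
    large_threshold: int = LARGE_IGS_THRESHOLD,
    table: Optional[GeneTable] = None,
) -> list[SpacerRecord]:
    """One SpacerRecord per adjacent gene pair, in circular genome order.

    A spacer is flagged large when strictly longer than ``large_threshold``.
    Spacer sequences are filled in when the genome carries sequence.
    """
    if table is None:
        table = build_gene_table(g)
    feats = table.features()
    records: list[SpacerRecord] = []
    n = len(feats)
    for i, f in enumerate(feats):
        nxt = feats[(i + 1) % n]
        raw = table.frame["Intergenic"].iloc[i]
        length = None if pd.isna(raw) else int(raw)
        seq = ""
        if length is not None and length > 0 and g.sequence is not None:
            if i + 1 < n:
                seq = g.sequence[f.end : nxt.start - 1]
            else:  # wrap-around spacer
                seq = g.sequence[f.end :] + g.sequence[: nxt.start - 1]
        records.append(
            SpacerRecord(
                left_gene=f.name,
                right_gene=nxt.name,
                length_bp=length,
                sequence=seq,
                is_large=None if length is None else length > large_threshold,
            )
        )
    return records


def get_spacer(records: list[SpacerRecord], left: str, right: str) -> SpacerRecord:
    for r in records:
        if r.left_gene == left and r.right_gene == right:
            return r
    raise KeyError(f"no junction {left}-{right}")


def motif_map(igs_sequence: str, motif: str) -> MotifArchitecture:
    """All (possibly overlapping) occurrences of ``motif`` in a spacer, left to right."""
    if len(motif) < 1:
        raise ValueError("motif must be at least 1 nt")
    seq = igs_sequence.upper()
    m = motif.upper()
    positions = tuple(
        i + 1 for i in range(len(seq) - len(m) + 1) if seq[i : i + len(m)] == m
    )
    gaps = tuple(
        positions[i + 1] - (positions[i] + len(m)) for i in range(len(positions) - 1)
    )
    return MotifArchitecture(motif=m, positions=positions, gaps=gaps)


def conserved_motif_check(
    spacer: SpacerRecord, motif: str = "TACTAAA"
) -> tuple[bool, Optional[int]]:
    """Whether ``motif`` occurs in the spacer; returns (found, first 1-based offset)."""
    if not spacer.sequence:
        raise ValueError(
            f"{spacer.left_gene}-{spacer.right_gene}: spacer sequence unavailable"
        )
    idx = spacer.sequence.upper().find(motif.upper())
    return (idx >= 0, idx + 1 if idx >= 0 else None)


def compare_architectures(
    arch_by_species: Mapping[str, MotifArchitecture],
    large_igs_by_species: Optional[Mapping[str, bool]] = None,
) -> pd.DataFrame:
    """Aligned cross-species comparison of one motif's repeat architecture.

    One row per species with copy number, positions and inter-repeat gaps,
    optionally a presence/absence flag for the large trnI–trnQ IGS, and a
    flag marking architectures that differ from the first species listed.
    """
    if len(arch_by_species) < 2:
        raise ValueError("need at least two species to compare")
    species = list(arch_by_species)
    ref = arch_by_species[species[0]]
    rows = []
    for sp in species:
        arch = arch_by_species[sp]
        row = {
            "Species": sp,
            "Motif": arch.motif,
            "Count": arch.count,
            "Positions": ",".join(map(str, arch.positions)),
            "Gaps": ",".join(map(str, arch.gaps)),
            "DiffersFromFirst": arch != ref,
        }
        if large_igs_by_species is not None:
            row["LargeIGS"] = bool(large_igs_by_species.get(sp, False))
        rows.append(row)
    return pd.DataFrame(rows)
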