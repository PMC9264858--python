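"""Codon usage under the invertebrate mitochondrial genetic code.

Covers start/stop-codon classification (including the truncated T / TA stops
completed to TAA by post-transcriptional polyadenylation), codon counting
over complete codons, and relative synonymous codon usage (RSCU).

RSCU of a codon is its observed count divided by the count expected if every
codon in its synonymous family were used equally:
``RSCU(c) = count(c) * k / sum(family counts)`` with ``k`` the family size.
Under translation table 5 leucine is 6-fold and serine 8-fold degenerate
(AGA/AGG encode serine); stop codons form no family.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from Bio.Data import CodonTable

from .core import GeneFeature, MitoGenome

TABLE5 = CodonTable.unambiguous_dna_by_id[5]
STOP_CODONS = frozenset(TABLE5.stop_codons)
AA_OF: dict[str, str] = dict(TABLE5.forward_table)

#: amino acid -> tuple of synonymous codons (stops excluded)
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(AA_OF.items()):
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] += (_codon,)

FAMILY_OF: dict[str, tuple[str, ...]] = {
    c: FAMILIES[aa] for c, aa in AA_OF.items()
}


@dataclass(frozen=True)
class CodonCallRecord:
    """Start/stop codon call for one protein-coding gene."""

    gene: str
    start_codon: str
    start_class: str          # "ATN", "AAN" or "other"
    stop_codon: str           # "TAA", "TAG", "TA" or "T"
    stop_complete: bool

    def display(self) -> str:
        return f"{self.start_codon}({self.stop_codon})"


@dataclass
class CodonCounts:
    """Codon counts accumulated over protein-coding genes (complete codons only)."""

    counts: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, codon: str) -> int:
        return self.counts[codon]

    def update_from_cds(self, cds: str, include_start: bool = True) -> None:
        n_full = len(cds) // 3
        first = 0 if include_start else 1
        for i in range(first, n_full):
            codon = cds[3 * i : 3 * i + 3]
            if set(codon) <= set("ACGT"):
                self.counts[codon] += 1


def classify_codons(f: GeneFeature, g: MitoGenome) -> CodonCallRecord:
    """Read the start and stop codon of a PCG directly off the genome sequence.

    The start codon is the first three coding-strand bases.  When the gene
    length is not a multiple of three, the trailing one or two bases after
    the last full codon are the truncated stop; otherwise the final codon
    must be TAA or TAG to count as complete.
    """
    if f.gene_class != "PCG":
        raise ValueError(f"{f.name} is not a protein-coding gene")
    cds = g.coding_sequence(f)
    start = cds[:3]
    if start.startswith("AT"):
        start_class = "ATN"
    elif start.startswith("AA"):
        start_class = "AAN"
    else:
        start_class = "other"
    rem = len(cds) % 3
    if rem == 0:
        stop = cds[-3:]
        complete = stop in STOP_CODONS
    else:
        stop = cds[-rem:]
        complete = False
    return CodonCallRecord(f.name, start, start_class, stop, complete)


def codon_counts(
    g: MitoGenome,
    genes: Optional[Iterable[str]] = None,
    include_start: bool = True,
) -> CodonCounts:
    """Pool codon counts over the annotated PCGs (coding strand, complete codons).

    Truncated terminal codons are excluded; the start codon is included by
    default.  Codons containing N are dropped.
    """
    counts = CodonCounts()
    wanted = set(genes) if genes is not None else None
    for f in g.features:
        if f.gene_class != "PCG":
            continue
        if wanted is not None and f.name not in wanted:
            continue
        counts.update_from_cds(g.coding_sequence(f), include_start=include_start)
    return counts


def rscu(counts: CodonCounts | Mapping[str, int]) -> dict[str, Optional[float]]:
    """RSCU per sense codon; families with zero total map to None.

    Within any family with nonzero usage the RSCU values average to 1.
    """
    raw = counts.counts if isinstance(counts, CodonCounts) else counts
    out: dict[str, Optional[float]] = {}
    for aa, family in FAMILIES.items():
        total = sum(raw.get(c, 0) for c in family)
        k = len(family)
        for c in family:
            out[c] = None if total == 0 else raw.get(c, 0) * k / total
    return out


def rscu_table(counts: CodonCounts) -> "pd.DataFrame":  # noqa: F821
    """Tabular codon/amino-acid/count/RSCU report (the bar-chart's underlying table)."""
    import pandas as pd

    values = rscu(counts)
    rows = []
    for aa, family in sorted(FAMILIES.items()):
        for c in family:
            rows.append(
                {"Codon": c, "AminoAcid": aa, "Count": counts[c], "RSCU": values[c]}
            )
    return pd.DataFrame(rows)
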