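"""Base composition and strand-skew statistics.

AT skew = (A − T)/(A + T) and GC skew = (G − C)/(G + C), the classic
strand-asymmetry measures of mitochondrial sequences.  Skews are undefined
(None) when the denominator is zero.  Ambiguity code N is excluded from both
numerator and denominator of every statistic.

Per-class summaries pool each gene's coding-strand sequence (N-strand genes
are reverse-complemented), while the whole-genome row uses the deposited
J-strand in full.  This pooling reproduces the characteristic sign pattern
of insect mitogenomes: negative AT skew over PCGs, positive over tRNAs,
positive for the genome as a whole.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .core import MitoGenome

_CLASS_LABEL = {"PCG": "PCGs", "tRNA": "tRNAs", "rRNA": "rRNAs"}


@dataclass(frozen=True)
class CompositionSummary:
    """Counts, percentages and skews for one sequence category."""

    t: int
    c: int
    a: int
    g: int

    @property
    def total(self) -> int:
        return self.t + self.c + self.a + self.g

    def percent(self, base: str) -> float:
        return 100.0 * getattr(self, base.lower()) / self.total

    @property
    def at_percent(self) -> float:
        return 100.0 * (self.a + self.t) / self.total

    @property
    def gc_percent(self) -> float:
        return 100.0 * (self.g + self.c) / self.total

    @property
    def at_skew(self) -> Optional[float]:
        if self.a + self.t == 0:
            return None
        return (self.a - self.t) / (self.a + self.t)

    @property
    def gc_skew(self) -> Optional[float]:
        if self.g + self.c == 0:
            return None
        return (self.g - self.c) / (self.g + self.c)


def base_composition(seq: str) -> CompositionSummary:
    """Exact base counts of a sequence (N excluded)."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    summary = CompositionSummary(
        t=s.count("T"), c=s.count("C"), a=s.count("A"), g=s.count("G")
    )
    if summary.total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return summary


def skews(seq: str) -> tuple[Optional[float], Optional[float]]:
    """(AT skew, GC skew) of a sequence."""
    comp = base_composition(seq)
    return comp.at_skew, comp.gc_skew


def class_composition(g: MitoGenome) -> dict[str, CompositionSummary]:
    """Composition summaries per category: PCGs, tRNAs, rRNAs and the genome.

    Gene categories pool coding-strand sequences gene by gene (overlapping
    genes each contribute their full span); the genome row is the whole
    J-strand.  Categories absent from the annotation are omitted.
    """
    if g.sequence is None:
        raise ValueError(f"{g.identifier} carries no sequence")
    pooled: dict[str, list[str]] = {}
    for f in g.features:
        label = _CLASS_LABEL.get(f.gene_class)
        if label is None:
            continue
        pooled.setdefault(label, []).append(g.coding_sequence(f))
    out = {
        label: base_composition("".join(parts)) for label, parts in pooled.items()
    }
    out["genome"] = base_composition(g.sequence)
    return out


def composition_frame(summaries: dict[str, CompositionSummary]) -> pd.DataFrame:
    """Report table with percentages to two decimals and skews to two decimals."""
    order = [k for k in ("PCGs", "tRNAs", "rRNAs", "genome") if k in summaries]
    rows = []
    for label in order:
        s = summaries[label]
        rows.append(
            {
                "Genes": label,
                "T(U)": round(s.percent("t"), 2),
                "C": round(s.percent("c"), 2),
                "A": round(s.percent("a"), 2),
                "G": round(s.percent("g"), 2),
                "A+T%": round(s.at_percent, 2),
                "G+C%": round(s.gc_percent, 2),
                "AT-Skew": None if s.at_skew is None else round(s.at_skew, 2),
                "GC-Skew": None if s.gc_skew is None else round(s.gc_skew, 2),
            }
        )
    return pd.DataFrame(rows)
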