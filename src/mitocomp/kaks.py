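"""Pairwise Ka/Ks in the Nei–Gojobori (1986) counting framework.

For each codon every position is split into synonymous and nonsynonymous
site fractions by asking, for each of the three possible point mutations,
whether the encoded amino acid changes under the invertebrate mitochondrial
code (translation table 5).  A mutation that would create a stop codon is
counted as nonsynonymous, so each codon contributes exactly three sites and
N_sites + S_sites = 3 × (number of compared codons).

Observed differences between two codons are averaged over all minimal
mutational pathways connecting them; pathways that pass through a stop
codon are discarded whenever at least one stop-free pathway exists.
Proportions p = d/sites are corrected for multiple hits with the
Jukes–Cantor formula d = −(3/4)·ln(1 − (4/3)p), undefined (None) when
p ≥ 3/4.  Ka/Ks < 1 indicates purifying selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable, Optional, Sequence

import pandas as pd

from .codons import AA_OF, STOP_CODONS
from .core import MitoGenome

_BASES = "ACGT"


def _site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon."""
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and AA_OF[alt] == AA_OF[codon]:
                syn += 1.0
    syn /= 3.0
    return syn, 3.0 - syn


SITES: dict[str, tuple[float, float]] = {
    c: _site_fractions(c) for c in AA_OF
}


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Averages step classifications over minimal mutational pathways; paths
    through stop intermediates are excluded when avoidable.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[bool, int, int]] = []  # (stop-free, syn steps, nonsyn steps)
    for order in permutations(diff_pos):
        cur = c1
        syn = non = 0
        stop_free = True
        for i in order:
            nxt = cur[: i] + c2[i] + cur[i + 1 :]
            if nxt in STOP_CODONS:
                stop_free = False
                non += 1  # steps touching a stop count as nonsynonymous
            elif cur in STOP_CODONS:
                non += 1
            elif AA_OF[cur] == AA_OF[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        paths.append((stop_free, syn, non))
    usable = [p for p in paths if p[0]] or paths
    sd = sum(p[1] for p in usable) / len(usable)
    nd = sum(p[2] for p in usable) / len(usable)
    return sd, nd


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 multiple-hit correction; None when saturation makes it undefined."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    """Per-pair NG86 bookkeeping and corrected rates."""

    gene: Optional[str]
    pair: Optional[tuple[str, str]]
    n_codons: int
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    pN: Optional[float]
    pS: Optional[float]
    Ka: Optional[float]
    Ks: Optional[float]
    ratio: Optional[float]


def ng86_pair(
    cds_a: str,
    cds_b: str,
    gene: Optional[str] = None,
    pair: Optional[tuple[str, str]] = None,
) -> KaKsResult:
    """NG86 Ka, Ks and Ka/Ks for one codon-aligned pair of coding sequences.

    Sequences must be equal length and a multiple of three, in frame, with
    terminal stop codons already stripped.  Codon pairs containing anything
    but A/C/G/T, or an internal stop, are dropped pairwise.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError(f"unequal CDS lengths ({len(a)} vs {len(b)})")
    if len(a) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")

    N = S = nd = sd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if not (set(ca) <= set(_BASES) and set(cb) <= set(_BASES)):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        sa, na = SITES[ca]
        sb, nb = SITES[cb]
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        d_s, d_n = _pathway_differences(ca, cb)
        sd += d_s
        nd += d_n
        n_codons += 1

    pN = nd / N if N > 0 else None
    pS = sd / S if S > 0 else None
    Ka = jukes_cantor(pN) if pN is not None else None
    Ks = jukes_cantor(pS) if pS is not None else None
    ratio = Ka / Ks if (Ka is not None and Ks is not None and Ks > 0) else None
    return KaKsResult(gene, pair, n_codons, N, S, nd, sd, pN, pS, Ka, Ks, ratio)


def strip_stop(cds: str) -> str:
    """Remove the terminal stop, complete (TAA/TAG) or truncated (T/TA)."""
    rem = len(cds) % 3
    if rem:
        return cds[:-rem]
    if cds[-3:].upper() in STOP_CODONS:
        return cds[:-3]
    return cds


def _common_frame(seqs: dict[str, str]) -> dict[str, str]:
    """Right-truncate stop-stripped CDS to a common codon count.

    A convenience for near-identical mitochondrial CDS sets whose annotated
    lengths differ by a codon or two; it is not an alignment.
    """
    trimmed = {sp: strip_stop(s) for sp, s in seqs.items()}
    n = min(len(s) for s in trimmed.values()) // 3 * 3
    return {sp: s[:n] for sp, s in trimmed.items()}


def gene_matrix(
    genomes: Sequence[MitoGenome],
    genes: Optional[Iterable[str]] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Averaged per-gene Ka/Ks over all unordered genome pairs, plus a ranking.

    Per gene: arithmetic mean of pairwise Ka and of pairwise Ks (pairs with
    an undefined rate are dropped from that mean), ratio of the two means,
    and a descending ranking of genes by ratio (genes with undefined or
    zero-Ks ratios are excluded from the ranking).
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    if genes is None:
        genes = [f.name for f in genomes[0].features if f.gene_class == "PCG"]
    rows = []
    for gene in genes:
        cds = {}
        for g in genomes:
            try:
                f = g.feature(gene)
            except KeyError:
                raise ValueError(f"{g.identifier} lacks gene {gene}")
            cds[g.identifier] = g.coding_sequence(f)
        cds = _common_frame(cds)
        kas, kss = [], []
        n_pairs = 0
        for sp1, sp2 in combinations(cds, 2):
            res = ng86_pair(cds[sp1], cds[sp2], gene=gene, pair=(sp1, sp2))
            n_pairs += 1
            if res.Ka is not None:
                kas.append(res.Ka)
            if res.Ks is not None:
                kss.append(res.Ks)
        ka = sum(kas) / len(kas) if kas else None
        ks = sum(kss) / len(kss) if kss else None
        ratio = ka / ks if (ka is not None and ks is not None and ks > 0) else None
        rows.append(
            {"Gene": gene, "Ka": ka, "Ks": ks, "KaKs": ratio, "Pairs": n_pairs}
        )
    frame = pd.DataFrame(rows)
    ranked = frame.dropna(subset=["KaKs"]).sort_values("KaKs", ascending=False)
    return frame, list(ranked["Gene"])
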