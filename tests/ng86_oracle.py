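"""Independent brute-force oracle for Nei–Gojobori site and difference counting.

Everything here is computed by explicit enumeration — all nine single-base
mutations per codon for site fractions, and a recursive walk over every
substitution pathway for difference counting — deliberately sharing no code
with the package implementation it checks.

Conventions (matching the definitions the package states): mutations that
would create a stop codon count as nonsynonymous, so each codon contributes
exactly three sites; pathways through stop intermediates are dropped when a
stop-free pathway exists; proportions are Jukes–Cantor corrected.
"""

from __future__ import annotations

import math

from Bio.Data import CodonTable

_T5 = CodonTable.unambiguous_dna_by_id[5]
_STOPS = set(_T5.stop_codons)
_AA = dict(_T5.forward_table)


def site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) sites of one sense codon by enumeration."""
    syn = 0
    for pos in (0, 1, 2):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in _STOPS and _AA[alt] == _AA[codon]:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def _all_paths(cur: str, target: str) -> list[list[tuple[str, str]]]:
    if cur == target:
        return [[]]
    out = []
    for i in range(3):
        if cur[i] != target[i]:
            nxt = cur[:i] + target[i] + cur[i + 1:]
            for rest in _all_paths(nxt, target):
                out.append([(cur, nxt)] + rest)
    return out


def diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over pathways."""
    if c1 == c2:
        return 0.0, 0.0
    scored = []
    for steps in _all_paths(c1, c2):
        intermediates = [b for _, b in steps[:-1]]
        through_stop = any(c in _STOPS for c in intermediates)
        syn = sum(
            1 for a, b in steps
            if a not in _STOPS and b not in _STOPS and _AA[a] == _AA[b]
        )
        scored.append((through_stop, syn, len(steps) - syn))
    usable = [s for s in scored if not s[0]] or scored
    sd = sum(s[1] for s in usable) / len(usable)
    nd = sum(s[2] for s in usable) / len(usable)
    return sd, nd


def _jc(p: float):
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_reference(cds_a: str, cds_b: str) -> dict:
    """Full NG86 bookkeeping for one codon-aligned pair, by brute force."""
    assert len(cds_a) == len(cds_b) and len(cds_a) % 3 == 0
    N = S = nd = sd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i: i + 3], cds_b[i: i + 3]
        if not (set(ca) <= set("ACGT") and set(cb) <= set("ACGT")):
            continue
        if ca in _STOPS or cb in _STOPS:
            continue
        sa, na = site_counts(ca)
        sb, nb = site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        d_s, d_n = diff_counts(ca, cb)
        sd += d_s
        nd += d_n
    pN = nd / N if N else None
    pS = sd / S if S else None
    return {
        "N_sites": N, "S_sites": S, "Nd": nd, "Sd": sd,
        "Ka": _jc(pN) if pN is not None else None,
        "Ks": _jc(pS) if pS is not None else None,
    }
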