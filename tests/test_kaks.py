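"""NG86 Ka/Ks against a brute-force pathway-enumeration oracle."""

from __future__ import annotations

import numpy as np
import pytest

from mitocomp.core import MitoGenome
from mitocomp.kaks import gene_matrix, jukes_cantor, ng86_pair, strip_stop

from conftest import SENSE_CODONS
from ng86_oracle import ng86_reference


def random_pair(rng: np.random.Generator, n_codons: int,
                p_mut: float = 0.1) -> tuple[str, str]:
    """A random sense-codon sequence and a point-mutated copy."""
    a = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)]
    b = []
    for codon in a:
        c = list(codon)
        for pos in range(3):
            if rng.random() < p_mut:
                c[pos] = "ACGT"[rng.integers(4)]
        codon_b = "".join(c)
        if codon_b in ("TAA", "TAG"):
            codon_b = codon
        b.append(codon_b)
    return "".join(a), "".join(b)


def test_identical_sequences():
    r = ng86_pair("ATGAAATTT", "ATGAAATTT")
    assert r.Ka == 0.0 and r.Ks == 0.0
    assert r.ratio is None  # Ks = 0: ratio undefined


def test_synonymous_only_divergence():
    a = "TTTAAAGGTCATCGA" * 4
    b = "TTC" + a[3:]  # one third-position synonymous change
    r = ng86_pair(a, b)
    assert r.Ka == 0.0
    assert r.Ks is not None and r.Ks > 0.0
    assert r.Nd == 0.0 and r.Sd == 1.0


def test_symmetry():
    rng = np.random.default_rng(7)
    for _ in range(20):
        a, b = random_pair(rng, int(rng.integers(5, 30)))
        r1, r2 = ng86_pair(a, b), ng86_pair(b, a)
        assert r1.N_sites == pytest.approx(r2.N_sites)
        assert r1.Nd == pytest.approx(r2.Nd) and r1.Sd == pytest.approx(r2.Sd)


def test_site_conservation():
    """N_sites + S_sites = 3 × compared codons on random inputs."""
    rng = np.random.default_rng(8)
    for _ in range(50):
        a, b = random_pair(rng, int(rng.integers(5, 40)))
        r = ng86_pair(a, b)
        assert r.N_sites + r.S_sites == pytest.approx(3.0 * r.n_codons, abs=1e-9)


def test_oracle_equivalence_small():
    rng = np.random.default_rng(9)
    for _ in range(50):
        a, b = random_pair(rng, int(rng.integers(10, 51)))
        r = ng86_pair(a, b)
        ref = ng86_reference(a, b)
        for key in ("N_sites", "S_sites", "Nd", "Sd"):
            assert getattr(r, key) == pytest.approx(ref[key], abs=1e-9), key
        for key in ("Ka", "Ks"):
            got, want = getattr(r, key), ref[key]
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-9)


def test_monotonicity_in_synonymous_differences():
    """One more third-position synonymous difference never decreases Ks."""
    base = "TTTAAAGGTCATCGAATTCCT" * 3
    b = list(base)
    prev_ks = ng86_pair(base, base).Ks
    syn_sites = [(2, "C"), (23, "C"), (44, "C")]  # TTT->TTC in each repeat
    for pos, alt in syn_sites:
        b[pos] = alt
        ks = ng86_pair(base, "".join(b)).Ks
        assert ks >= prev_ks
        prev_ks = ks


def test_saturation_flagged_none():
    assert jukes_cantor(0.8) is None
    assert jukes_cantor(0.0) == 0.0
    with pytest.raises(ValueError):
        jukes_cantor(-0.1)


def test_alignment_preconditions():
    with pytest.raises(ValueError):
        ng86_pair("ATGAAA", "ATG")
    with pytest.raises(ValueError):
        ng86_pair("ATGA", "ATGA")


def test_ambiguous_codons_dropped_pairwise():
    r = ng86_pair("ATGNNNAAA", "ATGTTTAAA")
    assert r.n_codons == 2


def test_strip_stop():
    assert strip_stop("ATGAAATAA") == "ATGAAA"
    assert strip_stop("ATGAAAT") == "ATGAAA"
    assert strip_stop("ATGAAATA") == "ATGAAA"
    assert strip_stop("ATGAAA") == "ATGAAA"


def _mutated_copy(genome: MitoGenome, rng) -> MitoGenome:
    """Copy with synonymous-only divergence on cox1, radical changes on atp8."""
    from mitocomp.codons import FAMILY_OF, STOP_CODONS, AA_OF

    seq = list(genome.sequence)
    cox1 = genome.feature("cox1")
    n_codons = cox1.length // 3
    for j in range(5, n_codons - 5, 4):
        lo = cox1.start - 1 + 3 * j
        codon = "".join(seq[lo: lo + 3])
        # single-position synonymous alternatives only, so Nd stays zero
        alts = [
            c for c in FAMILY_OF.get(codon, ())
            if sum(x != y for x, y in zip(c, codon)) == 1
        ]
        if alts:
            seq[lo: lo + 3] = list(alts[int(rng.integers(len(alts)))])
    atp8 = genome.feature("atp8")
    for j in range(3, atp8.length // 3 - 3, 4):
        lo = atp8.start - 1 + 3 * j
        codon = "".join(seq[lo: lo + 3])
        alts = [
            c for c in AA_OF
            if c not in STOP_CODONS and AA_OF[c] != AA_OF.get(codon)
        ]
        seq[lo: lo + 3] = list(alts[int(rng.integers(len(alts)))])
    return MitoGenome(
        identifier=genome.identifier + "_derived",
        sequence="".join(seq),
        features=list(genome.features),
        circular=genome.circular,
        complete=genome.complete,
    )


def test_identical_genomes_give_null_ratios(castaneus_genome):
    twin = MitoGenome(
        "twin", sequence=castaneus_genome.sequence,
        features=list(castaneus_genome.features),
        circular=True, complete=True,
    )
    frame, ranking = gene_matrix([castaneus_genome, twin])
    assert frame["KaKs"].isna().all()
    assert ranking == []


def test_gene_matrix_ranking_reflects_selection(castaneus_genome):
    """A gene with radical divergence outranks one with synonymous-only changes."""
    rng = np.random.default_rng(12)
    derived = _mutated_copy(castaneus_genome, rng)
    frame, ranking = gene_matrix([castaneus_genome, derived])
    row = frame.set_index("Gene")
    assert row.loc["cox1", "Ka"] == 0.0
    assert row.loc["cox1", "Ks"] > 0.0
    assert row.loc["atp8", "KaKs"] > 0.0
    assert row.loc["cox1", "KaKs"] == 0.0
    assert ranking.index("atp8") < ranking.index("cox1")
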