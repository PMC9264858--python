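"""Codon classification, counting and RSCU under the invertebrate mito code."""

from __future__ import annotations

from collections import Counter

import pytest

from mitocomp.codons import (
    FAMILIES,
    CodonCounts,
    classify_codons,
    codon_counts,
    rscu,
)
from mitocomp.core import GeneFeature, MitoGenome


def _single_cds_genome(cds: str) -> MitoGenome:
    rem = len(cds) % 3
    stop = cds[-rem:] if rem else cds[-3:]
    return MitoGenome(
        "toy", sequence=cds,
        features=[GeneFeature("nad2", "PCG", "J", 1, len(cds),
                              stop_codon=stop if rem or stop in ("TAA", "TAG") else None)],
        complete=False,
    )


def test_serine_family_is_eightfold_leucine_sixfold():
    assert len(FAMILIES["S"]) == 8  # AGA/AGG encode serine in this code
    assert len(FAMILIES["L"]) == 6
    assert len(FAMILIES["M"]) == 2  # ATA is methionine


def test_classify_complete_stop():
    g = _single_cds_genome("ATGAAATAA")
    call = classify_codons(g.features[0], g)
    assert (call.start_codon, call.stop_codon) == ("ATG", "TAA")
    assert call.start_class == "ATN" and call.stop_complete


def test_classify_truncated_ta_stop():
    g = _single_cds_genome("ATGAAATA")  # 3k+2, ends in TA
    call = classify_codons(g.features[0], g)
    assert call.stop_codon == "TA" and not call.stop_complete


def test_classify_fixture_cox1(castaneus_genome):
    """cox1 starts with the noncanonical AAN and ends on a bare T."""
    call = classify_codons(castaneus_genome.feature("cox1"), castaneus_genome)
    assert call.start_codon == "AAC" and call.start_class == "AAN"
    assert call.stop_codon == "T" and not call.stop_complete


def test_classify_all_fixture_cells(castaneus_table, castaneus_genome,
                                    laterotarsus_table, laterotarsus_genome):
    """All 26 printed start/stop cells reproduce from CDS boundaries."""
    for table, genome in ((castaneus_table, castaneus_genome),
                          (laterotarsus_table, laterotarsus_genome)):
        pcgs = table.frame[table.frame["StartCodon"] != "-"]
        assert len(pcgs) == 13
        for _, row in pcgs.iterrows():
            call = classify_codons(genome.feature(row["Gene"]), genome)
            assert call.start_codon == row["StartCodon"], row["Gene"]
            assert call.stop_codon == row["StopCodon"], row["Gene"]


def test_codon_counts_simple():
    g = _single_cds_genome("ATGTTTTAA")
    counts = codon_counts(g)
    assert counts.counts == Counter({"ATG": 1, "TTT": 1, "TAA": 1})
    assert counts.total == 3


def test_codon_counts_excludes_truncated_terminal():
    g = _single_cds_genome("ATGTTTT")  # trailing T is not a codon
    counts = codon_counts(g)
    assert counts.total == 2
    no_start = codon_counts(g, include_start=False)
    assert no_start.counts == Counter({"TTT": 1})


def test_identical_cds_sets_identical_counts(castaneus_genome):
    again = codon_counts(castaneus_genome)
    assert codon_counts(castaneus_genome).counts == again.counts
    assert again.total == sum(
        f.length // 3 for f in castaneus_genome.features if f.gene_class == "PCG"
    )


def test_rscu_uniform_family():
    counts = CodonCounts(Counter({"GTA": 2, "GTC": 2, "GTG": 2, "GTT": 2}))
    vals = rscu(counts)
    assert all(vals[c] == pytest.approx(1.0) for c in FAMILIES["V"])


def test_rscu_exclusive_usage():
    vals = rscu(CodonCounts(Counter({"GCT": 2})))
    assert vals["GCT"] == pytest.approx(4.0)
    assert vals["GCC"] == 0.0


def test_rscu_toy_cds_hand_computed():
    """Counts from a 14-codon toy CDS match a hand-computed RSCU table."""
    cds = "ATG" + "TTT" * 2 + "TTC" + "GCT" * 3 + "GCC" + "AGA" * 2 + "TCT" * 2 + "AAA" + "TAA"
    g = _single_cds_genome(cds)
    vals = rscu(codon_counts(g))
    assert vals["ATG"] == pytest.approx(2.0)        # Met 2-fold, exclusive
    assert vals["TTT"] == pytest.approx(4 / 3)      # Phe 2:1
    assert vals["TTC"] == pytest.approx(2 / 3)
    assert vals["GCT"] == pytest.approx(3.0)        # Ala 3:1:0:0
    assert vals["GCC"] == pytest.approx(1.0)
    assert vals["AGA"] == pytest.approx(4.0)        # Ser 8-fold, 2 of 4 counts
    assert vals["TCT"] == pytest.approx(4.0)
    assert vals["AAA"] == pytest.approx(2.0)        # Lys exclusive
    assert "TAA" not in vals                        # stops form no family


def test_rscu_family_means_equal_one(castaneus_genome):
    counts = codon_counts(castaneus_genome)
    vals = rscu(counts)
    for aa, family in FAMILIES.items():
        total = sum(counts[c] for c in family)
        family_vals = [vals[c] for c in family]
        if total == 0:
            assert all(v is None for v in family_vals)
        else:
            assert sum(family_vals) / len(family) == pytest.approx(1.0)


def test_at_ending_codons_dominate_on_at_rich_genome():
    """Third-position A/T codons are overrepresented under AT-rich composition."""
    from mitocomp.simulate import SynthConfig, generate

    g, _ = generate(SynthConfig(seed=41, at_fraction=0.70))
    counts = codon_counts(g)
    at_end = sum(n for c, n in counts.counts.items() if c[2] in "AT")
    gc_end = sum(n for c, n in counts.counts.items() if c[2] in "GC")
    assert at_end > gc_end
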