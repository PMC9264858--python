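"""Gene-table arithmetic on the circle: lengths, signed spacers, conservation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mitocomp.core import (
    GeneFeature,
    GeneTable,
    MitoGenome,
    build_gene_table,
    feature_length,
    spacer_between,
)


def _f(name, start, end, cls="tRNA", strand="J", **kw):
    return GeneFeature(name=name, gene_class=cls, strand=strand,
                       start=start, end=end, **kw)


@pytest.mark.parametrize(
    "start,end,expected",
    [(576, 1589, 1014), (1, 1, 1), (1777, 3307, 1531)],
)
def test_feature_length(start, end, expected):
    assert feature_length(_f("x", start, end)) == expected


@pytest.mark.parametrize(
    "prev,nxt,expected",
    [
        ((1, 64), (440, 508), 375),     # large spacer
        ((1, 100), (101, 120), 0),      # perfect adjacency
        ((4194, 4349), (4346, 5014), -4),  # overlap
    ],
)
def test_spacer_between_signed(prev, nxt, expected):
    assert spacer_between(_f("a", *prev), _f("b", *nxt)) == expected


def test_spacer_wrap_needs_genome_length():
    a, b = _f("a", 900, 950), _f("b", 10, 40)
    with pytest.raises(ValueError):
        spacer_between(a, b, wrap=True)
    assert spacer_between(a, b, 1000, wrap=True) == 59


def test_single_feature_wrap_spacer():
    with pytest.warns(UserWarning, match="expected 37 genes"):
        g = MitoGenome("toy", features=[_f("only", 1, 60)], length=100,
                       circular=True, complete=True)
    table = build_gene_table(g)
    assert table.spacer_after("only") == 40


def test_origin_spanning_feature_rejected():
    with pytest.raises(ValueError, match="origin-spanning"):
        _f("bad", 100, 50)


def test_invalid_features_rejected():
    with pytest.raises(ValueError):
        _f("bad", 0, 10)
    with pytest.raises(ValueError):
        GeneFeature("bad", "nonsense", "J", 1, 10)
    # complete stop codon with length not divisible by three
    with pytest.raises(ValueError, match="inconsistent"):
        GeneFeature("pcg", "PCG", "J", 1, 10, stop_codon="TAA")


def test_build_gene_table_rejects_duplicates():
    g = MitoGenome("dup", features=[_f("a", 1, 50), _f("a", 1, 50)],
                   length=200, complete=False)
    with pytest.raises(ValueError, match="duplicate"):
        build_gene_table(g)
    g = MitoGenome("overl", features=[_f("a", 1, 50), _f("a", 40, 90)],
                   length=200, complete=False)
    with pytest.raises(ValueError, match="name"):
        build_gene_table(g)


def test_fixture_tables_reproduce_printed_cells(castaneus_table, laterotarsus_table):
    """Recomputing lengths/spacers from coordinates matches the published table."""
    for table in (castaneus_table, laterotarsus_table):
        rebuilt = build_gene_table(table.to_genome())
        assert list(rebuilt.frame["Length"]) == list(table.frame["Length"])
        got, want = rebuilt.frame["Intergenic"], table.frame["Intergenic"]
        assert ((got.isna() & want.isna()) | (got == want)).all()
    assert castaneus_table.spacer_after("trnS2") == 18
    assert laterotarsus_table.spacer_after("trnI") == 158


def test_conservation_identity(castaneus_table):
    """Σ gene lengths + Σ signed spacers equals the genome length on the circle."""
    rebuilt = build_gene_table(castaneus_table.to_genome())
    assert rebuilt.conservation_sum() == castaneus_table.genome_length == 17523


def test_incomplete_genome_wrap_spacer_unknown(laterotarsus_table):
    rebuilt = build_gene_table(laterotarsus_table.to_genome())
    assert rebuilt.spacer_after("rrnS") is None
    assert rebuilt.conservation_sum() is None


@pytest.mark.filterwarnings("ignore::UserWarning")
def test_spacers_invariant_under_rotation():
    """Adding k to all coordinates leaves every spacer unchanged."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        n = int(rng.integers(3, 12))
        starts, cursor = [], 1
        feats = []
        for i in range(n):
            length = int(rng.integers(50, 300))
            feats.append(_f(f"g{i}", cursor, cursor + length - 1))
            cursor += length + int(rng.integers(0, 40))
        L = cursor + int(rng.integers(0, 100))
        base = build_gene_table(
            MitoGenome("r", features=feats, length=L, complete=True)
        )
        k = int(rng.integers(1, L - feats[-1].end + 1))
        shifted = [_f(f.name, f.start + k, f.end + k) for f in feats]
        rot = build_gene_table(
            MitoGenome("r", features=shifted, length=L, complete=True)
        )
        assert list(base.intergenic) == list(rot.intergenic)


def test_gene_table_tsv_roundtrip(tmp_path, castaneus_table):
    out = tmp_path / "table.tsv"
    castaneus_table.to_tsv(out)
    back = GeneTable.from_tsv(out)
    assert back.identifier == castaneus_table.identifier
    assert back.genome_length == castaneus_table.genome_length
    assert back.complete == castaneus_table.complete
    pd.testing.assert_frame_equal(
        back.frame, castaneus_table.frame, check_dtype=False
    )
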