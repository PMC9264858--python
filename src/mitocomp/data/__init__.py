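"""Packaged gene-table fixtures transcribed from the published annotation.

Two *Prosopocoilus* stag-beetle mitogenomes (accessions ON401054,
*P. castaneus*, complete, 17,523 bp; ON401055, *P. laterotarsus*, nearly
complete, 17,333 bp, control region not recovered) as coordinate-only gene
tables.  :func:`fixture_genome` turns a table into a sequence-bearing
genome with a synthetic background (clearly labelled synthetic — the
deposited sequences themselves are not shipped) whose coordinates, strands
and PCG boundary codons match the table exactly.
"""

from __future__ import annotations

from importlib import resources

from ..core import GeneTable
from ..simulate import MotifSpec, genome_from_table

SPECIES = ("castaneus", "laterotarsus")

_FILES = {
    "castaneus": "prosopocoilus_castaneus.tsv",
    "laterotarsus": "prosopocoilus_laterotarsus.tsv",
}

#: Default planted repeat architectures for sequence-bearing fixtures: four
#: TAAAA copies in both large spacers (the published copy number for these
#: two species); gap sizes are scaled to each spacer's length.
FIXTURE_MOTIF_SPECS = {
    "castaneus": MotifSpec(motif="TAAAA", count=4, gaps=(40, 75, 110), lead=30),
    "laterotarsus": MotifSpec(motif="TAAAA", count=4, gaps=(20, 30, 40), lead=15),
}


def load_gene_table(species: str) -> GeneTable:
    """Packaged gene table for ``"castaneus"`` or ``"laterotarsus"``."""
    if species not in _FILES:
        raise KeyError(f"unknown fixture {species!r}; choose from {SPECIES}")
    ref = resources.files(__package__) / _FILES[species]
    with resources.as_file(ref) as path:
        return GeneTable.from_tsv(path)


def fixture_genome(species: str, seed: int = 0, plant_motifs: bool = True):
    """Synthetic sequence-bearing genome consistent with a packaged table."""
    table = load_gene_table(species)
    return genome_from_table(
        table,
        seed=seed,
        motif_spec=FIXTURE_MOTIF_SPECS[species] if plant_motifs else None,
        s2_motif="TACTAAA" if plant_motifs else None,
        s2_offset=6,
    )
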