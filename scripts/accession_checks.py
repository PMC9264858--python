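#!/usr/bin/env python
"""Optional cross-checks against downloaded GenBank accessions.

These checks need the real deposited sequences, which this package does not
ship. Download the five *Prosopocoilus* accessions yourself, e.g.:

    ON401054 (P. castaneus), ON401055 (P. laterotarsus),
    KF364622 (P. blanchardi), KU552119 (P. confucius), NC050851 (P. astacoides)

then run:

    python scripts/accession_checks.py path/to/*.gb

Reported per accession: PCG pooled AT% (expected ~67.3 for ON401054),
TAAAA copy number in the trnI-trnQ spacer (expected 4/4/5/3/3 for
castaneus/laterotarsus/blanchardi/confucius/astacoides), and — when at
least two genomes are given — per-gene averaged Ka/Ks with its ranking
(expected all < 1, cox1 minimal).
"""

from __future__ import annotations

import sys

from mitocomp.composition import class_composition
from mitocomp.io import read_genbank
from mitocomp.kaks import gene_matrix
from mitocomp.spacers import extract_spacers, get_spacer, motif_map


def main(paths: list[str]) -> None:
    if not paths:
        sys.exit(__doc__)
    genomes = []
    for path in paths:
        g = read_genbank(path)
        genomes.append(g)
        comp = class_composition(g)
        print(f"{g.identifier}: PCG AT% = {comp['PCGs'].at_percent:.2f}, "
              f"genome AT% = {comp['genome'].at_percent:.2f}")
        try:
            igs = get_spacer(extract_spacers(g), "trnI", "trnQ")
            arch = motif_map(igs.sequence, "TAAAA")
            print(f"{g.identifier}: trnI-trnQ IGS {igs.length_bp} bp, "
                  f"TAAAA x{arch.count} at {list(arch.positions)}")
        except KeyError:
            print(f"{g.identifier}: no trnI-trnQ junction found")
    if len(genomes) >= 2:
        frame, ranking = gene_matrix(genomes)
        print(frame.to_string(index=False))
        print("Ka/Ks ranking:", " > ".join(ranking))
        bad = frame[frame["KaKs"] >= 1.0]
        print("all ratios < 1.0:", bad.empty)


if __name__ == "__main__":
    main(sys.argv[1:])
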