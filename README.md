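# mitocomp

Comparative analysis of circular insect mitochondrial genomes, built around
the questions raised by *Prosopocoilus* stag-beetle mitogenomes: gene-table
construction with signed intergenic spacers on the circle, large-spacer and
motif-repeat architecture analysis, base composition and strand skews,
codon usage / RSCU under the invertebrate mitochondrial code, per-gene
Nei–Gojobori Ka/Ks, and supermatrix export for external tree software. A
seeded synthetic-mitogenome generator makes every stage testable without
downloading accessions.

Intended users: molecular systematists and mitogenome annotators who want
the standard descriptive statistics of a newly assembled insect mitogenome,
reproducibly and scriptably.

## The statistics at the core

- **Signed intergenic spacer** between consecutive genes on the circle:
  `next.start − prev.end − 1` (negative = overlap); for the origin-spanning
  pair, `next.start + L − prev.end − 1`. For a complete circular annotation
  Σ lengths + Σ spacers = L exactly. A spacer > 50 bp is a *large* IGS.
- **Strand skews**: AT skew = (A − T)/(A + T), GC skew = (G − C)/(G + C).
- **RSCU**: RSCU(c) = count(c) · k / Σ family counts, with k the synonymous
  family size under NCBI translation table 5 (serine 8-fold, leucine
  6-fold; ATA = Met; truncated T/TA stops completed by polyadenylation).
- **Ka/Ks (NG86)**: per-codon synonymous/nonsynonymous site fractions,
  pathway-averaged difference counts, Jukes–Cantor correction
  d = −(3/4)·ln(1 − 4p/3); Ka/Ks < 1 indicates purifying selection.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Two gene tables transcribed from the published annotation ship with the
package (accessions ON401054, *P. castaneus*, and ON401055,
*P. laterotarsus*). Rebuilding the table from coordinates alone:

```python
>>> from mitocomp.data import load_gene_table, fixture_genome
>>> from mitocomp.core import build_gene_table
>>> table = build_gene_table(load_gene_table("castaneus").to_genome())
>>> print(table.frame.head(4).to_string(index=False))
Gene Strand  Start  End  Length StartCodon StopCodon  Intergenic
trnI      J      1   64      64          -         -         375
trnQ      N    440  508      69          -         -          -1
trnM      J    508  575      68          -         -           0
nad2      J    576 1589    1014        ATA       TAA           2
>>> table.conservation_sum()   # Σ lengths + Σ signed spacers
17523
```

The 375-bp spacer after *trnI* is the large IGS between *trnI* and *trnQ*;
the −1 after *trnQ* is a one-base overlap with *trnM*; 17,523 bp is the
genome length, recovered exactly from the circle identity.

Spacer and motif analysis need sequence. `fixture_genome` builds a
synthetic sequence constrained to the table (coordinates, strands and PCG
boundary codons exact; background random — the deposited sequence itself
is not shipped):

```python
>>> from mitocomp.spacers import extract_spacers, get_spacer, motif_map
>>> g = fixture_genome("castaneus", seed=7)
>>> igs = get_spacer(extract_spacers(g), "trnI", "trnQ")
>>> igs.length_bp, igs.is_large
(375, True)
>>> arch = motif_map(igs.sequence, "TAAAA")
>>> arch.count, arch.positions, arch.gaps
(4, (31, 76, 156, 271), (40, 75, 110))
```

Four TAAAA copies in the large spacer, with their 1-based offsets and the
inter-repeat gap lengths — the repeat architecture that differs between
*Prosopocoilus* species.

The same objects drive composition, RSCU, Ka/Ks and supermatrix export;
from the shell:

```
mitocomp simulate --seed 3 --out-dir syn        # synthetic GenBank + truth
mitocomp report syn/SYNTH3.gb --out-dir report  # full report bundle
mitocomp kaks a.gb b.gb -o kaks.tsv             # per-gene Ka/Ks + ranking
```

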