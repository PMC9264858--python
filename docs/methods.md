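# Methods

`mitocomp` implements the standard comparative-mitogenomics workflow for
circular insect mitochondrial genomes, specialised to the questions raised
by *Prosopocoilus* stag beetles: where the intergenic spacers sit, what the
large trnI–trnQ spacer's motif-repeat architecture looks like, how biased
and skewed the base composition is, which codons the 13 protein-coding
genes prefer, and how strongly purifying selection acts on each gene.

## Coordinate model

All public coordinates are 1-based inclusive (the GenBank and printed-table
convention); internal slicing converts to 0-based half-open and round-trips
losslessly. Strands are named J (majority strand, the deposited forward
sequence) and N (minority strand). Features spanning the origin of the
circle are rejected — none occur in the genomes this package targets — so a
genome's features always sort strictly by start.

The signed spacer between consecutive genes is
`next.start − prev.end − 1`: 0 for perfect adjacency, negative for overlap
(matching printed values such as −1, −4, −8). The one origin-spanning
junction uses `next.start + L − prev.end − 1`. For a complete circular
annotation the conservation identity Σ lengths + Σ signed spacers = L holds
exactly and is enforced in tests. Completeness is an explicit annotation
flag: the *P. laterotarsus* fixture did not recover its control region, so
its wrap-around spacer is reported as unknown (NA), never as 0 — it cannot
be inferred from coordinates alone.

## Gene vocabulary

Annotation sources label genes inconsistently (COI vs cox1; tRNA-Ser(UCN)
vs trnS2). All I/O canonicalizes to one vocabulary of 13 PCGs, 22 tRNAs
(leucine and serine isoacceptors resolved by anticodon or codon-family
tag), 2 rRNAs and the control region. Unknown labels pass through with
class `other`; an unresolvable Leu/Ser tRNA is an error rather than a
guess.

## Composition and skews

AT skew = (A − T)/(A + T), GC skew = (G − C)/(G + C); N is excluded from
numerator and denominator; a zero denominator yields null, not 0. Per-class
rows pool each gene's coding-strand sequence (N-strand genes
reverse-complemented), counting overlapping genes once per gene; the genome
row uses the whole J-strand. The published tables do not state their
pooling convention; this one was chosen because it reproduces the
characteristic sign structure (negative AT skew over PCGs, positive over
tRNAs and the genome) and is documented rather than tuned — cross-checks
against deposited sequences are therefore tolerance-based.

## Codon usage

Everything uses NCBI translation table 5 (invertebrate mitochondrial):
ATA is methionine, AGA/AGG are serine — so serine is 8-fold and leucine
6-fold degenerate — and the only stops are TAA/TAG. A PCG whose length is
not a multiple of three ends in a truncated stop (T or TA, completed to TAA
by polyadenylation); completeness is required to be consistent with
length mod 3. RSCU(c) = count(c)·k / Σ family counts with k the family
size; stop codons form no family; families with zero usage report null.
Codon counts include the start codon and only complete codons (truncated
terminal bases are excluded) so family sums stay well-defined; both choices
are configurable.

## Intergenic spacers and motif repeats

A spacer is "large" when strictly longer than 50 bp (configurable). Motif
scanning is a sliding window reporting every occurrence, overlapping ones
included — deterministic and motif-agnostic; TAAAA cannot overlap itself,
so its copy numbers are unaffected. Offsets are 1-based from the spacer's
first base on the J-strand; only the J-strand is scanned. Inter-repeat gaps
are measured motif-end → next-motif-start. Architecture comparison across
species reports copy number, positions, gaps, presence of the large
trnI–trnQ spacer, and a differs-from-reference flag.

## Ka/Ks (Nei–Gojobori 1986)

Site counting splits each codon position by the fraction of the three
possible point mutations that are synonymous; a mutation creating a stop
codon counts as nonsynonymous, so each codon contributes exactly three
sites (N + S = 3 × codons, enforced as an invariant). Differences are
averaged over all minimal substitution pathways between two codons;
pathways through stop intermediates are discarded when a stop-free pathway
exists. Proportions are Jukes–Cantor corrected, d = −(3/4)·ln(1 − 4p/3),
reported null at saturation (p ≥ 3/4). Codon pairs containing N, gaps or
stops are dropped pairwise; terminal stops are stripped before analysis.

Per-gene summaries average Ka and Ks separately over all unordered genome
pairs and report the ratio of means (stable when individual pairwise Ks are
small); the ranking sorts genes by that ratio, excluding genes where it is
undefined (e.g. identical sequences, Ks = 0). When annotated CDS lengths
differ between genomes, sequences are right-truncated to a common codon
count — a convenience for near-identical conspecific CDS sets, not an
alignment, and outside the validated core; properly aligned input is the
supported path. The implementation is verified codon-by-codon against an
independent brute-force pathway-enumeration oracle (tests) to 1e-9.

## Synthetic genomes

The generator emulates the study conditions, not generic DNA. Defaults are
the *P. castaneus* layout: the ancestral gene order, the printed gene
lengths, strands, spacers and overlaps, the printed start/stop codons
(including cox1's AAN start), genome AT fraction 0.687 with AT skew 0.07
and GC skew −0.30, a 375-bp trnI–trnQ spacer carrying TAAAA × 4, and
TACTAAA at offset 6 of the 18-bp trnS2–nad1 spacer. The published figure
does not give numeric inter-repeat gaps, so the defaults (lead 30, gaps
40/75/110) are a fixed arbitrary emulation chosen once. The control-region
length absorbs whatever is needed to hit the target genome length.

Background bases realise the target composition *by construction*: base
counts are fixed by largest-remainder rounding of the target probabilities
and only their arrangement is randomised. (Pure multinomial sampling was
tried first and rejected: at ~17.5 kb its GC-skew sampling noise is ~0.015
SD — GC bases are the minority under AT-rich composition — which is the
same order as the ±0.02 recovery tolerance the generator is meant to
guarantee.) Structural plants then overwrite: motif copies are planted and
stray copies in the same spacer are scrubbed by mutating non-planted bases;
PCG boundary codons are planted on the coding strand (overlapping genes
share bases — the printed codon pairs are mutually consistent at every
overlap, and conflicting plants raise an infeasibility error); internal
in-frame stops are scrubbed in multiple passes until every PCG is a clean
ORF. These plants perturb the realised composition by well under the ±0.02
recovery tolerance. Under a randomised stop-codon policy, overlapping
PCG–PCG junctions are separated (spacer set to 0) unless pinned by the
caller, since arbitrary stop/start pairs cannot share bases; PCG lengths
are adjusted by at most 2 bp so length mod 3 matches stop completeness.

Every planted quantity is emitted in a truth record, and the generator
verifies before returning that the emitted sequence realises it exactly.
One integer seed drives all randomness; identical seeds give byte-identical
genomes.

What the generator does **not** emulate: substitution-model evolution
between species (divergent pairs for Ka/Ks tests are produced by explicit
codon-level mutation of a genome copy), tRNA secondary structure,
control-region tandem repeats, and sequencing artefacts. Passing tests
therefore demonstrate correctness of the coordinate arithmetic, counting
and recovery machinery under realistic composition and structure — not
robustness to annotation error or assembly noise in real data.

## Fixtures and problem sizes

The two packaged gene tables transcribe the published coordinate tables
(ON401054 complete at 17,523 bp; ON401055 nearly complete at 17,333 bp).
Sequence-bearing "fixture genomes" are synthetic backgrounds constrained to
those tables — the deposited sequences are not shipped — and are labelled
as such; checks that depend on the real sequences (PCG AT% ≈ 67.3, the
published TAAAA copy numbers 4/4/5/3/3 across five species, the empirical
Ka/Ks ordering) live in `scripts/accession_checks.py` and run only against
user-downloaded GenBank files.

Test problem sizes were chosen to keep the whole suite in a few seconds on
one core: 50 random generator configurations for conservation/recovery,
1,000 random strings for the motif-scan oracle, 200 random 10–50-codon
pairs for the NG86 oracle, full 17.5-kb genomes elsewhere.

## Known limitations

- Multi-contig and nuclear genomes, EMBL format, and feature-location
  operators beyond `complement(start..end)` are unsupported.
- Exact numerical parity with any particular desktop Ka/Ks program is not
  claimed; conventions (stop handling, pathway weighting, averaging) are
  stated above and tested against the package's own oracle.
- The supermatrix exporter removes any column containing a gap or ambiguity
  in any sequence; reproducing a specific published alignment's dimensions
  depends on the external aligner and is out of scope.
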