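"""Seeded generator of synthetic circular insect mitogenomes.

The generator emulates the structure a comparative mitogenome analysis
assumes: the ancestral 37-gene order plus control region, AT-rich base
composition with configurable strand skews, planted intergenic spacers and
overlaps, a large trnI–trnQ spacer carrying a short motif repeat (TAAAA by
default) with a configurable copy number and inter-repeat gaps, the
conserved TACTAAA motif in the short trnS2–nad1 spacer, and protein-coding
genes that are valid open reading frames under translation table 5 with
configurable start codons and complete (TAA/TAG) or truncated (T/TA) stops.

Every planted quantity is returned in a :class:`TruthRecord` so downstream
analyses can be tested for exact parameter recovery.  All randomness flows
from a single integer seed; the same seed yields byte-identical genomes.

Defaults reproduce the *P. castaneus* study conditions: the printed gene
lengths, strands, spacers and codons, genome AT fraction 0.687 with AT skew
0.07 and GC skew −0.30, and four TAAAA copies in a 375-bp trnI–trnQ spacer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .codons import STOP_CODONS, classify_codons
from .core import GeneFeature, GeneTable, MitoGenome
from .names import ANCESTRAL_GENE_ORDER, CONTROL_REGION, PCGS, gene_class_of
from .spacers import motif_map

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# P. castaneus reference layout: per-gene length, strand, and PCG codons.
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "trnI": 64, "trnQ": 69, "trnM": 68, "nad2": 1014, "trnW": 66, "trnC": 61,
    "trnY": 65, "cox1": 1531, "trnL2": 65, "cox2": 688, "trnK": 70, "trnD": 63,
    "atp8": 156, "atp6": 669, "cox3": 784, "trnG": 64, "nad3": 352, "trnA": 65,
    "trnR": 64, "trnN": 64, "trnS1": 67, "trnE": 64, "trnF": 65, "nad5": 1717,
    "trnH": 64, "nad4": 1336, "nad4l": 288, "trnT": 63, "trnP": 66, "nad6": 498,
    "cytb": 1141, "trnS2": 65, "nad1": 951, "trnL1": 64, "rrnL": 1268,
    "trnV": 69, "rrnS": 810, CONTROL_REGION: 2509,
}

DEFAULT_STRANDS: dict[str, Optional[str]] = {
    "trnI": "J", "trnQ": "N", "trnM": "J", "nad2": "J", "trnW": "J",
    "trnC": "N", "trnY": "N", "cox1": "J", "trnL2": "J", "cox2": "J",
    "trnK": "J", "trnD": "J", "atp8": "J", "atp6": "J", "cox3": "J",
    "trnG": "J", "nad3": "J", "trnA": "J", "trnR": "J", "trnN": "J",
    "trnS1": "J", "trnE": "J", "trnF": "N", "nad5": "N", "trnH": "N",
    "nad4": "N", "nad4l": "N", "trnT": "J", "trnP": "N", "nad6": "J",
    "cytb": "J", "trnS2": "J", "nad1": "N", "trnL1": "N", "rrnL": "N",
    "trnV": "N", "rrnS": "N", CONTROL_REGION: None,
}

#: Spacer after each gene (signed; negative = overlap), P. castaneus layout.
DEFAULT_SPACERS: dict[str, int] = {
    "trnI": 375, "trnQ": -1, "trnM": 0, "nad2": 2, "trnW": -8, "trnC": 0,
    "trnY": 1, "cox1": 0, "trnL2": 0, "cox2": 0, "trnK": 0, "trnD": 0,
    "atp8": -4, "atp6": -1, "cox3": 0, "trnG": 0, "nad3": 0, "trnA": -1,
    "trnR": -1, "trnN": 0, "trnS1": 0, "trnE": -2, "trnF": 0, "nad5": 0,
    "trnH": 0, "nad4": -7, "nad4l": 2, "trnT": 0, "trnP": 5, "nad6": -1,
    "cytb": 0, "trnS2": 18, "nad1": 0, "trnL1": 0, "rrnL": 0, "trnV": -1,
    "rrnS": 0, CONTROL_REGION: 0,
}

DEFAULT_START_CODONS: dict[str, str] = {
    "nad2": "ATA", "cox1": "AAC", "cox2": "ATA", "atp8": "ATT", "atp6": "ATA",
    "cox3": "ATG", "nad3": "ATG", "nad5": "ATA", "nad4": "ATG", "nad4l": "ATG",
    "nad6": "ATG", "cytb": "ATG", "nad1": "ATA",
}

DEFAULT_STOP_CODONS: dict[str, str] = {
    "nad2": "TAA", "cox1": "T", "cox2": "T", "atp8": "TAA", "atp6": "TAA",
    "cox3": "T", "nad3": "T", "nad5": "T", "nad4": "T", "nad4l": "TAA",
    "nad6": "TAA", "cytb": "T", "nad1": "TAG",
}


@dataclass(frozen=True)
class MotifSpec:
    """A planted motif-repeat architecture for the large trnI–trnQ spacer.

    ``lead`` is the number of spacer bases before the first copy; ``gaps``
    are the inter-repeat distances (each ≥ 1 so copies never abut).
    """

    motif: str = "TAAAA"
    count: int = 4
    gaps: tuple[int, ...] = (40, 75, 110)
    lead: int = 30

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("motif count must be >= 1")
        if len(self.gaps) != self.count - 1:
            raise ValueError("need count - 1 inter-repeat gaps")
        if any(g < 1 for g in self.gaps):
            raise ValueError("inter-repeat gaps must be >= 1")
        if self.lead < 0:
            raise ValueError("lead must be >= 0")

    @property
    def span(self) -> int:
        """Total spacer length consumed from its first base through the last copy."""
        return self.lead + self.count * len(self.motif) + sum(self.gaps)

    @property
    def positions(self) -> tuple[int, ...]:
        """Planted 1-based offsets of each copy within the spacer."""
        pos = [self.lead + 1]
        for g in self.gaps:
            pos.append(pos[-1] + len(self.motif) + g)
        return tuple(pos)


@dataclass
class SynthConfig:
    """Full parameterisation of one synthetic mitogenome."""

    seed: int = 0
    identifier: Optional[str] = None
    genome_length_target: int = 17523
    gene_order: tuple[str, ...] = ANCESTRAL_GENE_ORDER
    at_fraction: float = 0.687
    at_skew_target: float = 0.07
    gc_skew_target: float = -0.30
    gene_lengths: Optional[Mapping[str, int]] = None
    igs_spec: Optional[Mapping[str, int]] = None
    motif_spec: Optional[MotifSpec] = field(default_factory=MotifSpec)
    s2_motif: Optional[str] = "TACTAAA"
    s2_offset: int = 6
    start_codons: Optional[Mapping[str, str]] = None
    stop_codons: Optional[Mapping[str, str]] = None
    stop_codon_policy: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.at_fraction < 1.0:
            raise ValueError("at_fraction must be in (0, 1)")
        for skew in (self.at_skew_target, self.gc_skew_target):
            if not -1.0 < skew < 1.0:
                raise ValueError("skew targets must be in (-1, 1)")
        if self.stop_codon_policy is not None and not 0.0 <= self.stop_codon_policy <= 1.0:
            raise ValueError("stop_codon_policy is a fraction in [0, 1]")


@dataclass
class TruthRecord:
    """Realised values of every planted quantity, for parameter-recovery tests."""

    identifier: str
    seed: int
    genome_length: int
    spacers: dict[str, int]
    coordinates: dict[str, tuple[int, int]]
    igs_junction: tuple[str, str]
    igs_length: Optional[int]
    motif: Optional[str]
    motif_positions: tuple[int, ...]
    motif_gaps: tuple[int, ...]
    s2_motif: Optional[str]
    s2_offset: Optional[int]
    start_codons: dict[str, str]
    stop_codons: dict[str, str]
    stop_complete: dict[str, bool]
    at_fraction: float
    at_skew_target: float
    gc_skew_target: float

    @property
    def motif_count(self) -> int:
        return len(self.motif_positions)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)


def _solve_probs(at: float, at_skew: float, gc_skew: float) -> dict[str, float]:
    """Per-base sampling probabilities from (AT fraction, AT skew, GC skew)."""
    gc = 1.0 - at
    return {
        "A": at * (1.0 + at_skew) / 2.0,
        "T": at * (1.0 - at_skew) / 2.0,
        "G": gc * (1.0 + gc_skew) / 2.0,
        "C": gc * (1.0 - gc_skew) / 2.0,
    }


class _SeqBuilder:
    """Mutable genome sequence with pinned (planted) positions."""

    def __init__(self, rng: np.random.Generator, length: int, probs: dict[str, float]):
        # Fix the base counts to the target composition exactly (largest-
        # remainder rounding) and randomise only the arrangement, so the
        # realised composition and skews match their targets to ~1/length
        # rather than carrying multinomial sampling noise.
        p = np.array([probs[b] for b in "ACGT"])
        p = p / p.sum()
        counts = np.floor(p * length).astype(int)
        remainder = p * length - counts
        for i in np.argsort(-remainder)[: length - counts.sum()]:
            counts[i] += 1
        pool = np.repeat(np.array(list("ACGT")), counts)
        rng.shuffle(pool)
        self.seq = pool
        self.pinned: dict[int, str] = {}
        self.rng = rng

    def plant(self, pos0: int, base: str) -> None:
        old = self.pinned.get(pos0)
        if old is not None and old != base:
            raise ValueError(
                f"conflicting plants at position {pos0 + 1}: {old} vs {base} "
                "(infeasible configuration)"
            )
        self.seq[pos0] = base
        self.pinned[pos0] = base

    def plant_codon(self, feature_start: int, feature_end: int, strand: str,
                    coding_offset: int, codon: str) -> None:
        """Plant a codon at a 0-based coding-strand offset of a gene."""
        for t, b in enumerate(codon):
            k = coding_offset + t
            if strand == "N":
                self.plant(feature_end - 1 - k, _COMP[b])
            else:
                self.plant(feature_start - 1 + k, b)

    def text(self, lo0: int, hi0: int) -> str:
        return "".join(self.seq[lo0:hi0])


def _plant_motifs(builder: _SeqBuilder, igs_lo0: int, igs_len: int,
                  offsets_1b: Sequence[int], motif: str) -> None:
    """Plant motif copies at 1-based spacer offsets and pin their windows."""
    for off in offsets_1b:
        if off < 1 or off + len(motif) - 1 > igs_len:
            raise ValueError(
                f"motif copy at spacer offset {off} does not fit in a "
                f"{igs_len}-bp spacer (infeasible configuration)"
            )
        for t, b in enumerate(motif):
            builder.plant(igs_lo0 + off - 1 + t, b)


def _scrub_stray_motifs(builder: _SeqBuilder, igs_lo0: int, igs_len: int,
                        planted_1b: Sequence[int], motif: str,
                        max_rounds: int = 200) -> None:
    """Mutate unpinned spacer bases until only the planted copies match."""
    planted = set(planted_1b)
    m = len(motif)
    for _ in range(max_rounds):
        region = builder.text(igs_lo0, igs_lo0 + igs_len)
        stray = [
            i + 1
            for i in range(igs_len - m + 1)
            if region[i : i + m] == motif and (i + 1) not in planted
        ]
        if not stray:
            return
        for off in stray:
            candidates = [
                off - 1 + t for t in range(m)
                if (igs_lo0 + off - 1 + t) not in builder.pinned
            ]
            if not candidates:
                continue  # fully inside pinned windows; cannot be a new copy
            t = candidates[int(builder.rng.integers(len(candidates)))]
            alts = [b for b in "ACGT" if b != motif[t - (off - 1)]]
            builder.seq[igs_lo0 + t] = alts[int(builder.rng.integers(3))]
    raise RuntimeError("could not remove stray motif copies from the spacer")


def _scrub_orfs(builder: _SeqBuilder, pcg_feats: Sequence[GeneFeature],
                max_passes: int = 50) -> None:
    """Replace in-frame internal stop codons so every PCG is a valid ORF."""
    for _ in range(max_passes):
        changed = False
        for f in pcg_feats:
            length = f.end - f.start + 1
            n_full = length // 3
            last = n_full - 1 if length % 3 == 0 else n_full  # skip planted stop
            for j in range(1, last):
                if f.strand == "N":
                    idx = [f.end - 1 - (3 * j + t) for t in range(3)]
                    codon = "".join(_COMP[builder.seq[i]] for i in idx)
                else:
                    idx = [f.start - 1 + 3 * j + t for t in range(3)]
                    codon = "".join(builder.seq[i] for i in idx)
                if codon not in STOP_CODONS:
                    continue
                free = [t for t in range(3) if idx[t] not in builder.pinned]
                if not free:
                    raise ValueError(
                        f"{f.name}: internal stop codon fully pinned by "
                        "overlapping plants (infeasible configuration)"
                    )
                t = free[int(builder.rng.integers(len(free)))]
                for b in builder.rng.permutation(list("ACGT")):
                    trial = codon[:t] + b + codon[t + 1 :]
                    if trial not in STOP_CODONS and trial != codon:
                        base = trial[t] if f.strand != "N" else _COMP[trial[t]]
                        builder.seq[idx[t]] = base
                        changed = True
                        break
        if not changed:
            return
    raise RuntimeError("ORF scrubbing did not converge")


def _layout(order: Sequence[str], lengths: Mapping[str, int],
            spacers: Mapping[str, int]) -> dict[str, tuple[int, int]]:
    coords: dict[str, tuple[int, int]] = {}
    start = 1
    for i, gene in enumerate(order):
        end = start + lengths[gene] - 1
        coords[gene] = (start, end)
        if i + 1 < len(order):
            start = end + spacers[gene] + 1
    return coords


def generate(config: SynthConfig) -> tuple[MitoGenome, TruthRecord]:
    """Generate one synthetic mitogenome and the record of everything planted.

    Raises ``ValueError`` for infeasible configurations (motif architecture
    longer than its spacer, conflicting codon plants in overlap regions,
    control region squeezed below 1 bp, ...).
    """
    rng = np.random.default_rng(config.seed)
    order = tuple(config.gene_order)

    lengths = dict(DEFAULT_GENE_LENGTHS)
    if config.gene_lengths:
        lengths.update(config.gene_lengths)
    spacers = dict(DEFAULT_SPACERS)
    if config.igs_spec:
        spacers.update(config.igs_spec)
    starts = dict(DEFAULT_START_CODONS)
    if config.start_codons:
        starts.update(config.start_codons)
    stops = dict(DEFAULT_STOP_CODONS)
    if config.stop_codons:
        stops.update(config.stop_codons)

    pcgs_present = [g for g in order if g in PCGS]
    if config.stop_codon_policy is not None:
        n_inc = int(round(config.stop_codon_policy * len(pcgs_present)))
        chosen = list(rng.choice(pcgs_present, size=n_inc, replace=False)) if n_inc else []
        for gene in pcgs_present:
            if gene in chosen:
                stops[gene] = str(rng.choice(["T", "TA"]))
            else:
                stops[gene] = str(rng.choice(["TAA", "TAG"]))
    # Reconcile each PCG length with its stop-codon completeness.
    for gene in pcgs_present:
        want = len(stops[gene]) % 3
        lengths[gene] -= (lengths[gene] - want) % 3
    # Random stop assignments are generally incompatible with overlapping
    # PCG-PCG junctions (the shared bases must satisfy both the upstream
    # stop and the downstream start), so those junctions are separated
    # unless the caller pinned them explicitly.
    if config.stop_codon_policy is not None:
        pinned_junctions = set(config.igs_spec or ())
        for i, gname in enumerate(order[:-1]):
            if (gname in PCGS and order[i + 1] in PCGS
                    and spacers[gname] < 0 and gname not in pinned_junctions):
                spacers[gname] = 0

    # Size the control region so the genome hits its target length.
    if CONTROL_REGION in order:
        other = sum(lengths[g] for g in order if g != CONTROL_REGION)
        total_spacer = sum(spacers[g] for g in order)
        cr_len = config.genome_length_target - other - total_spacer
        if cr_len < 1:
            raise ValueError(
                f"genome_length_target {config.genome_length_target} leaves "
                f"{cr_len} bp for the control region (infeasible configuration)"
            )
        lengths[CONTROL_REGION] = cr_len
    coords = _layout(order, lengths, spacers)
    genome_length = coords[order[-1]][1] + spacers[order[-1]]
    if any(start < 1 for start, _ in coords.values()):
        raise ValueError("planted overlaps push a gene before position 1")

    probs = _solve_probs(config.at_fraction, config.at_skew_target, config.gc_skew_target)
    builder = _SeqBuilder(rng, genome_length, probs)

    # Plant the motif architecture in the trnI-trnQ spacer.
    igs_len = spacers.get("trnI")
    motif_positions: tuple[int, ...] = ()
    motif_gaps: tuple[int, ...] = ()
    spec = config.motif_spec
    if spec is not None:
        if igs_len is None or igs_len < spec.span:
            raise ValueError(
                f"motif architecture needs {spec.span} bp but the trnI-trnQ "
                f"spacer is {igs_len} bp (infeasible configuration)"
            )
        igs_lo0 = coords["trnI"][1]  # 0-based index of first spacer base
        _plant_motifs(builder, igs_lo0, igs_len, spec.positions, spec.motif)
        _scrub_stray_motifs(builder, igs_lo0, igs_len, spec.positions, spec.motif)
        motif_positions = spec.positions
        motif_gaps = spec.gaps

    # Plant the conserved motif in the trnS2-nad1 spacer.
    s2_off: Optional[int] = None
    if config.s2_motif is not None:
        s2_len = spacers.get("trnS2", 0)
        if config.s2_offset + len(config.s2_motif) - 1 > s2_len:
            raise ValueError(
                f"{config.s2_motif} at offset {config.s2_offset} does not fit "
                f"in the {s2_len}-bp trnS2-nad1 spacer (infeasible configuration)"
            )
        lo0 = coords["trnS2"][1]
        _plant_motifs(builder, lo0, s2_len, [config.s2_offset], config.s2_motif)
        s2_off = config.s2_offset

    # Plant PCG start and stop codons, then make every PCG a clean ORF.
    features: list[GeneFeature] = []
    for gene in order:
        start, end = coords[gene]
        cls = gene_class_of(gene)
        features.append(
            GeneFeature(
                name=gene, gene_class=cls, strand=DEFAULT_STRANDS.get(gene, "J"),
                start=start, end=end,
                start_codon=starts.get(gene) if cls == "PCG" else None,
                stop_codon=stops.get(gene) if cls == "PCG" else None,
            )
        )
    pcg_feats = [f for f in features if f.gene_class == "PCG"]
    for f in pcg_feats:
        builder.plant_codon(f.start, f.end, f.strand, 0, f.start_codon)
        stop = f.stop_codon
        builder.plant_codon(f.start, f.end, f.strand, f.length - len(stop), stop)
    _scrub_orfs(builder, pcg_feats)

    sequence = "".join(builder.seq)
    genome = MitoGenome(
        identifier=config.identifier or f"SYNTH{config.seed}",
        sequence=sequence, features=features, circular=True, complete=True,
    )

    truth = TruthRecord(
        identifier=genome.identifier,
        seed=config.seed,
        genome_length=genome_length,
        spacers={g: spacers[g] for g in order},
        coordinates=coords,
        igs_junction=("trnI", "trnQ"),
        igs_length=igs_len,
        motif=spec.motif if spec is not None else None,
        motif_positions=motif_positions,
        motif_gaps=motif_gaps,
        s2_motif=config.s2_motif,
        s2_offset=s2_off,
        start_codons={f.name: f.start_codon for f in pcg_feats},
        stop_codons={f.name: f.stop_codon for f in pcg_feats},
        stop_complete={f.name: len(f.stop_codon) == 3 for f in pcg_feats},
        at_fraction=config.at_fraction,
        at_skew_target=config.at_skew_target,
        gc_skew_target=config.gc_skew_target,
    )
    _verify(genome, truth)
    return genome, truth


def _verify(genome: MitoGenome, truth: TruthRecord) -> None:
    """Emitted sequence must realise the truth record exactly."""
    for f in genome.features:
        if f.gene_class != "PCG":
            continue
        call = classify_codons(f, genome)
        if call.start_codon != truth.start_codons[f.name] or \
                call.stop_codon != truth.stop_codons[f.name]:
            raise RuntimeError(f"planted codons not realised for {f.name}")
    if truth.motif is not None:
        trnI, trnQ = genome.feature("trnI"), genome.feature("trnQ")
        igs = genome.sequence[trnI.end : trnQ.start - 1]
        arch = motif_map(igs, truth.motif)
        if arch.positions != truth.motif_positions:
            raise RuntimeError("planted motif architecture not realised")


def genome_from_table(
    table: GeneTable,
    seed: int = 0,
    motif_spec: Optional[MotifSpec] = None,
    s2_motif: Optional[str] = None,
    s2_offset: int = 6,
    at_fraction: float = 0.687,
    at_skew: float = 0.07,
    gc_skew: float = -0.30,
) -> MitoGenome:
    """Synthetic sequence consistent with a printed gene table.

    Builds a genome whose coordinates, strands and PCG boundary codons are
    exactly those of ``table``, over a random AT-rich background — a
    sequence-bearing stand-in for an accession that is not downloaded.
    Optionally plants a motif architecture in the trnI-trnQ spacer and a
    conserved motif in the trnS2-nad1 spacer.
    """
    if table.genome_length is None:
        raise ValueError("table carries no genome length")
    rng = np.random.default_rng(seed)
    builder = _SeqBuilder(rng, table.genome_length,
                          _solve_probs(at_fraction, at_skew, gc_skew))
    feats = table.features()
    by_name = {f.name: f for f in feats}

    if motif_spec is not None:
        trnI, trnQ = by_name["trnI"], by_name["trnQ"]
        igs_len = trnQ.start - trnI.end - 1
        if igs_len < motif_spec.span:
            raise ValueError(
                f"motif architecture needs {motif_spec.span} bp but the "
                f"trnI-trnQ spacer is {igs_len} bp"
            )
        _plant_motifs(builder, trnI.end, igs_len, motif_spec.positions, motif_spec.motif)
        _scrub_stray_motifs(builder, trnI.end, igs_len, motif_spec.positions,
                            motif_spec.motif)
    if s2_motif is not None:
        trnS2, nad1 = by_name["trnS2"], by_name["nad1"]
        s2_len = nad1.start - trnS2.end - 1
        if s2_offset + len(s2_motif) - 1 > s2_len:
            raise ValueError(f"{s2_motif} does not fit in the trnS2-nad1 spacer")
        _plant_motifs(builder, trnS2.end, s2_len, [s2_offset], s2_motif)

    pcg_feats = [f for f in feats if f.gene_class == "PCG"]
    for f in pcg_feats:
        if f.start_codon:
            builder.plant_codon(f.start, f.end, f.strand, 0, f.start_codon)
        if f.stop_codon:
            builder.plant_codon(f.start, f.end, f.strand,
                                f.length - len(f.stop_codon), f.stop_codon)
    _scrub_orfs(builder, pcg_feats)

    return MitoGenome(
        identifier=table.identifier,
        sequence="".join(builder.seq),
        features=feats,
        circular=table.circular,
        complete=table.complete,
    )
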