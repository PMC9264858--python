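"""GenBank and FASTA readers/writers for annotated mitogenomes.

Only the LOCUS/FEATURES/ORIGIN blocks of the GenBank dialect are relied
upon, with the qualifiers that both MITOS exports and NCBI submissions
share (gene, product, codon_start, transl_table, note).  Gene labels are
canonicalized on read (see :mod:`mitocomp.names`), feature strands map
``complement(..)`` to the minority N strand, and start/stop codons of
protein-coding genes are read directly off the sequence.

Feature location operators beyond ``complement(start..end)`` (joins,
origin-spanning features) are rejected.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .codons import classify_codons
from .core import GeneFeature, MitoGenome
from .names import canonicalize_name

#: canonical symbol -> (feature type, product string) used on write
_TRNA_PRODUCT = {
    "trnL1": "tRNA-Leu(CUN)", "trnL2": "tRNA-Leu(UUR)",
    "trnS1": "tRNA-Ser(AGN)", "trnS2": "tRNA-Ser(UCN)",
}

_AA_NAME = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "M": "Met",
    "F": "Phe", "P": "Pro", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


def _feature_type(f: GeneFeature) -> str:
    return {
        "PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
        "control_region": "misc_feature", "other": "misc_feature",
    }[f.gene_class]


def _product_of(f: GeneFeature) -> Optional[str]:
    if f.gene_class == "tRNA":
        if f.name in _TRNA_PRODUCT:
            return _TRNA_PRODUCT[f.name]
        letter = f.name[3:4]
        return f"tRNA-{_AA_NAME.get(letter, letter)}"
    if f.gene_class == "rRNA":
        return {"rrnL": "16S ribosomal RNA", "rrnS": "12S ribosomal RNA"}.get(f.name)
    if f.gene_class == "control_region":
        return None
    return None


def write_genbank(genome: MitoGenome, path) -> None:
    """Write a genome with its annotation as a GenBank flat file."""
    if genome.sequence is None:
        raise ValueError(f"{genome.identifier}: cannot write GenBank without sequence")
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.identifier,
        name=genome.identifier[:16].replace(" ", "_"),
        description="mitochondrion" + ("" if genome.complete else ", partial"),
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "data_file_division": "INV",
        },
    )
    rec.features.append(
        SeqFeature(
            FeatureLocation(0, len(genome.sequence), strand=1),
            type="source",
            qualifiers={"organelle": ["mitochondrion"]},
        )
    )
    for f in genome.features:
        loc = FeatureLocation(f.start - 1, f.end, strand=-1 if f.strand == "N" else 1)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        product = _product_of(f)
        if product:
            quals["product"] = [product]
        if f.gene_class == "PCG":
            quals["transl_table"] = ["5"]
            quals["codon_start"] = ["1"]
        if f.gene_class == "control_region":
            quals["note"] = ["putative control region"]
        rec.features.append(SeqFeature(loc, type=_feature_type(f), qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def read_genbank(path) -> MitoGenome:
    """Read a GenBank flat file into a :class:`MitoGenome`.

    Gene names are canonicalized; strands map complement -> N; start/stop
    codons of PCGs are extracted from the sequence.  The genome is flagged
    complete when a control region is annotated.
    """
    rec = SeqIO.read(str(path), "genbank")
    sequence = str(rec.seq).upper()
    feats: list[GeneFeature] = []
    for sf in rec.features:
        if sf.type in ("source", "gene"):
            continue
        if sf.type not in ("CDS", "tRNA", "rRNA", "misc_feature", "D-loop"):
            continue
        if len(sf.location.parts) != 1:
            raise ValueError(
                f"{path}: compound feature locations are not supported "
                f"({sf.type} at {sf.location})"
            )
        label = (sf.qualifiers.get("gene") or sf.qualifiers.get("product")
                 or sf.qualifiers.get("note") or [None])[0]
        if label is None:
            warnings.warn(f"{path}: unnamed {sf.type} feature skipped", stacklevel=2)
            continue
        anticodon = (sf.qualifiers.get("anticodon") or [None])[0]
        if sf.type == "D-loop":
            name, cls = "control_region", "control_region"
        else:
            name, cls = canonicalize_name(label, anticodon=anticodon)
        strand = "N" if sf.location.strand == -1 else "J"
        feats.append(
            GeneFeature(
                name=name,
                gene_class=cls,
                strand=None if cls == "control_region" else strand,
                start=int(sf.location.start) + 1,
                end=int(sf.location.end),
            )
        )
    if not feats:
        raise ValueError(f"{path}: no usable features")
    complete = any(f.gene_class == "control_region" for f in feats)
    genome = MitoGenome(
        identifier=rec.id or rec.name,
        sequence=sequence,
        features=feats,
        circular=rec.annotations.get("topology", "circular") == "circular",
        complete=complete,
    )
    # Second pass: read PCG boundary codons off the sequence.
    enriched = []
    for f in genome.features:
        if f.gene_class == "PCG":
            call = classify_codons(f, genome)
            f = dataclasses.replace(
                f, start_codon=call.start_codon, stop_codon=call.stop_codon
            )
        enriched.append(f)
    return MitoGenome(
        identifier=genome.identifier,
        sequence=sequence,
        features=enriched,
        circular=genome.circular,
        complete=complete,
    )


def write_fasta(genome: MitoGenome, path) -> None:
    if genome.sequence is None:
        raise ValueError(f"{genome.identifier}: no sequence to write")
    rec = SeqRecord(Seq(genome.sequence), id=genome.identifier, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path) -> MitoGenome:
    """Read a single-record FASTA as an unannotated circular genome."""
    rec = SeqIO.read(str(path), "fasta")
    return MitoGenome(
        identifier=rec.id, sequence=str(rec.seq).upper(),
        features=[], circular=True, complete=False,
    )
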