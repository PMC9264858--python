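"""Canonical gene vocabulary for insect mitogenomes and annotation-label mapping.

Annotation pipelines label the same 37 mitochondrial genes very differently
("COI" vs "cox1" vs "cytochrome c oxidase subunit I"; "tRNA-Ser(UCN)" vs
"trnS2").  Everything downstream of I/O works on one canonical vocabulary:
13 protein-coding genes, 22 tRNAs (with the two leucine and two serine
isoacceptors disambiguated by anticodon or codon family), 2 rRNAs and the
control region.
"""

from __future__ import annotations

import re

PCGS: tuple[str, ...] = (
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad5", "nad4", "nad4l", "nad6", "cytb", "nad1",
)

TRNAS: tuple[str, ...] = (
    "trnI", "trnQ", "trnM", "trnW", "trnC", "trnY", "trnL2", "trnK", "trnD",
    "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF", "trnH", "trnT",
    "trnP", "trnS2", "trnL1", "trnV",
)

RRNAS: tuple[str, ...] = ("rrnL", "rrnS")

CONTROL_REGION = "control_region"

#: The ancestral insect mitogenome gene order (pancrustacean ground pattern),
#: which both newly analysed stag-beetle genomes retain.
ANCESTRAL_GENE_ORDER: tuple[str, ...] = (
    "trnI", "trnQ", "trnM", "nad2", "trnW", "trnC", "trnY", "cox1", "trnL2",
    "cox2", "trnK", "trnD", "atp8", "atp6", "cox3", "trnG", "nad3", "trnA",
    "trnR", "trnN", "trnS1", "trnE", "trnF", "nad5", "trnH", "nad4", "nad4l",
    "trnT", "trnP", "nad6", "cytb", "trnS2", "nad1", "trnL1", "rrnL", "trnV",
    "rrnS", CONTROL_REGION,
)

ALL_GENES: tuple[str, ...] = tuple(g for g in ANCESTRAL_GENE_ORDER if g != CONTROL_REGION)


def gene_class_of(symbol: str) -> str:
    """Gene class of a canonical symbol: PCG, tRNA, rRNA, control_region or other."""
    if symbol in PCGS:
        return "PCG"
    if symbol in TRNAS or (symbol.startswith("trn") and len(symbol) <= 6):
        return "tRNA"
    if symbol in RRNAS:
        return "rRNA"
    if symbol == CONTROL_REGION:
        return "control_region"
    return "other"


def _norm(label: str) -> str:
    return re.sub(r"[\s\-_.']", "", label.lower())


# Three-letter amino-acid code -> canonical tRNA letter.
_AA3 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "tyr": "Y", "val": "V",
}

# Leucine / serine isoacceptor resolution.  Keys are codon-family codes or
# anticodons (RNA or DNA spelling, U normalised to T).
_LEU = {"TTR": "trnL2", "CTN": "trnL1", "TAA": "trnL2", "TAG": "trnL1"}
_SER = {"AGN": "trnS1", "TCN": "trnS2", "TGA": "trnS2", "TCT": "trnS1", "GCT": "trnS1"}

_ALIASES: dict[str, str] = {}


def _register(symbol: str, *labels: str) -> None:
    for lab in labels:
        _ALIASES[_norm(lab)] = symbol


_register("cox1", "cox1", "coxi", "coi", "co1", "cox-1",
          "cytochrome c oxidase subunit 1", "cytochrome c oxidase subunit I",
          "cytochrome oxidase subunit 1", "cytochrome oxidase subunit I")
_register("cox2", "cox2", "coxii", "coii", "co2",
          "cytochrome c oxidase subunit 2", "cytochrome c oxidase subunit II",
          "cytochrome oxidase subunit 2")
_register("cox3", "cox3", "coxiii", "coiii", "co3",
          "cytochrome c oxidase subunit 3", "cytochrome c oxidase subunit III",
          "cytochrome oxidase subunit 3")
_register("cytb", "cytb", "cob", "cyb", "cytochrome b", "cyt b",
          "cytochrome b apoenzyme")
for _i in (1, 2, 3, 5, 6):
    _register(f"nad{_i}", f"nad{_i}", f"nd{_i}", f"nadh{_i}",
              f"NADH dehydrogenase subunit {_i}")
_register("nad4", "nad4", "nd4", "nadh4", "NADH dehydrogenase subunit 4")
_register("nad4l", "nad4l", "nd4l", "nadh4l", "NADH dehydrogenase subunit 4L")
_register("atp6", "atp6", "atpase6", "atpase 6", "atpase subunit 6",
          "ATP synthase F0 subunit 6")
_register("atp8", "atp8", "atpase8", "atpase 8", "atpase subunit 8",
          "ATP synthase F0 subunit 8")
_register("rrnL", "rrnl", "rrn l", "16s", "16s rrna", "16s ribosomal rna",
          "l-rrna", "lrrna", "lsu", "large subunit ribosomal rna", "rrn16")
_register("rrnS", "rrns", "rrn s", "12s", "12s rrna", "12s ribosomal rna",
          "s-rrna", "srrna", "ssu", "small subunit ribosomal rna", "rrn12")
_register(CONTROL_REGION, "control region", "control_region", "d-loop", "dloop",
          "at-rich region", "a+t-rich region", "putative control region",
          "cr", "misc region")

for _t in TRNAS:
    _register(_t, _t)
# Undisambiguated single-letter forms for Leu/Ser need an anticodon.
_ALIASES[_norm("trnL")] = "trnL?"
_ALIASES[_norm("trnS")] = "trnS?"


def canonicalize_name(raw: str, anticodon: str | None = None) -> tuple[str, str]:
    """Map a raw annotation label to ``(canonical_symbol, gene_class)``.

    ``anticodon`` (RNA or DNA spelling) resolves the leucine/serine
    isoacceptors when the label itself does not carry a codon-family tag like
    ``tRNA-Ser(UCN)``.  Unknown labels pass through unchanged with class
    ``"other"``; an unresolvable Leu/Ser tRNA raises ``ValueError``.
    """
    if raw is None:
        raise ValueError("gene label is required")
    hint = None
    m = re.search(r"\(([A-Za-z]{3})\)", raw)
    if m:
        hint = m.group(1)
        raw_stripped = raw[: m.start()] + raw[m.end():]
    else:
        raw_stripped = raw
    if anticodon:
        hint = anticodon
    token = _norm(raw_stripped)

    symbol = _ALIASES.get(token)
    if symbol is None:
        # "tRNA-Xxx" / "trn Xxx" forms with a three-letter amino acid.
        m = re.match(r"^trna?([a-z]{3})$", token)
        if m and m.group(1) in _AA3:
            letter = _AA3[m.group(1)]
            symbol = f"trn{letter}?" if letter in "LS" else f"trn{letter}"
    if symbol is None:
        return raw, "other"

    if symbol.endswith("?"):
        letter = symbol[3]
        table = _LEU if letter == "L" else _SER
        if hint is None:
            raise ValueError(
                f"ambiguous tRNA label {raw!r}: anticodon or codon family "
                f"needed to resolve {letter}1/{letter}2"
            )
        key = hint.upper().replace("U", "T")
        if key not in table:
            raise ValueError(f"cannot resolve {raw!r} from anticodon/family {hint!r}")
        symbol = table[key]

    return symbol, gene_class_of(symbol)
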