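"""The conserved mitochondrial gene panel.

Fungal (tremellomycete) mitochondrial genomes carry a stable complement of
41 conserved genes: 15 protein-coding genes (three ATP synthase subunits,
three cytochrome-oxidase subunits, seven NADH-dehydrogenase subunits,
apocytochrome b, and the ribosomal protein rps3), the small and large
rRNAs (rns, rnl), the RNA subunit of mitochondrial RNase P (rnpB), and
23 tRNAs covering all standard amino acids except cysteine, with two
isoacceptors each for Leu, Met, Arg and Ser.

The bundled panel carries names and types only; reference sequences are
attached at run time (typically from one annotated isolate, or from the
simulator's ancestral genome) when homology-based location is needed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


@dataclass
class PanelEntry:
    gene_name: str
    gene_type: str  # CDS | tRNA | rRNA | ncRNA
    reference: str | None = None  # nucleotide sequence (all types)
    reference_peptide: str | None = None  # CDS only


@dataclass
class ConservedPanel:
    """The gene roster shared by all isolates of a species."""

    entries: list[PanelEntry] = field(default_factory=list)

    @property
    def expected_count(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.gene_name for e in self.entries]

    def entry(self, name: str) -> PanelEntry:
        for e in self.entries:
            if e.gene_name == name:
                return e
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(e.gene_name == name for e in self.entries)

    def genes_of_type(self, gene_type: str) -> list[str]:
        return [e.gene_name for e in self.entries if e.gene_type == gene_type]

    def attach_references(self, nt: dict[str, str], pep: dict[str, str] | None = None) -> None:
        """Attach reference sequences (e.g. from an annotated isolate) in place."""
        pep = pep or {}
        for e in self.entries:
            if e.gene_name in nt:
                e.reference = nt[e.gene_name].upper()
            if e.gene_name in pep:
                e.reference_peptide = pep[e.gene_name].upper()


PROTEIN_GENES = [
    "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "rps3",
]

#: 14 proteins used for the concatenated phylogeny (rps3 excluded).
PHYLO_GENES = [g for g in PROTEIN_GENES if g != "rps3"]

RRNA_GENES = ["rns", "rnl"]
NCRNA_GENES = ["rnpB"]

# 19 amino acids (no Cys); Leu/Met/Arg/Ser doubled -> 23 tRNAs.
TRNA_GENES = [
    "trnA", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI", "trnK",
    "trnL1", "trnL2", "trnM1", "trnM2", "trnN", "trnP", "trnQ",
    "trnR1", "trnR2", "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
]


def default_panel() -> ConservedPanel:
    """The bundled 41-gene roster (names and types, no sequences)."""
    entries = [PanelEntry(g, "CDS") for g in PROTEIN_GENES]
    entries += [PanelEntry(g, "rRNA") for g in RRNA_GENES]
    entries += [PanelEntry(g, "ncRNA") for g in NCRNA_GENES]
    entries += [PanelEntry(g, "tRNA") for g in TRNA_GENES]
    panel = ConservedPanel(entries)
    assert panel.expected_count == 41
    return panel


_ROMAN = {"i": "1", "ii": "2", "iii": "3"}

_ALIASES = {
    "cytb": "cob", "cob": "cob", "atp9": "atp9", "rnpb": "rnpB",
    "nad4l": "nad4L", "rrn l": "rnl", "rrnl": "rnl", "rrns": "rns",
    "rnl": "rnl", "rns": "rns",
}


def normalize_gene_name(raw: str, panel: ConservedPanel | None = None) -> str:
    """Map an annotation label onto the panel vocabulary.

    Case-insensitive; roman-numeral subunit suffixes are arabicized, so
    cox1 == COX1 == coxI. Names outside the panel come back lower-cased
    as-is (callers treat them as "other").
    """
    name = raw.strip().replace("-", "").replace("_", "")
    low = name.lower()
    if low in _ALIASES:
        name = _ALIASES[low]
    else:
        m = re.fullmatch(r"([a-z]+)(i{1,3})", low)
        if m and m.group(1) in ("cox", "nad", "atp"):
            name = m.group(1) + _ROMAN[m.group(2)]
        else:
            name = low
    if panel is not None:
        for p in panel.names:
            if p.lower() == name.lower():
                return p
    # canonical casing for known oddballs even without a panel
    if name == "nad4l":
        return "nad4L"
    if name == "rnpb":
        return "rnpB"
    if name.startswith("trn") and len(name) > 3:
        return "trn" + name[3].upper() + name[4:]
    return name
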