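"""Circular mitochondrial genome I/O and the coordinate contract.

All coordinates are 1-based inclusive (GenBank convention). Circular
genomes admit wrap-around: an interval with ``start > end`` crosses the
origin. Minus-strand loci are stored in genome coordinates with exons
listed in transcription order (decreasing genome position).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .panel import ConservedPanel, default_panel, normalize_gene_name

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "ncRNA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneLocus:
    """One occurrence of a (usually panel) gene in a genome."""

    gene_name: str
    gene_type: str  # CDS | tRNA | rRNA | ncRNA
    strand: str  # + | -
    exons: list[tuple[int, int]]  # 1-based inclusive, transcription order
    introns: list[tuple[int, int]] = field(default_factory=list)
    translation_table: int = 4

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.gene_name}: exon list must be non-empty")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def span(self, genome_length: int) -> tuple[int, int]:
        """5'-most to 3'-most genome coordinate of the unspliced locus.

        Returned in genome orientation (start may exceed end on a wrap).
        For minus-strand loci the first element is the lower genome
        coordinate of the 3' end's... — concretely: returns the interval
        covering every exon, oriented plus-strand.
        """
        ivs = []
        for s, e in self.exons:
            ivs.append((s, e))
        if self.strand == "-":
            ivs = ivs[::-1]  # genome-ascending order
        start = ivs[0][0]
        end = ivs[-1][1]
        return start, end

    def exon_positions(self, genome_length: int) -> list[int]:
        """Genome positions of spliced bases, in transcription order."""
        pos: list[int] = []
        for s, e in self.exons:
            if s <= e:
                block = list(range(s, e + 1))
            else:  # wrap-around exon
                block = list(range(s, genome_length + 1)) + list(range(1, e + 1))
            if self.strand == "-":
                block.reverse()
            pos.extend(block)
        return pos


@dataclass
class CircularGenome:
    isolate_id: str
    sequence: str
    topology: str = "circular"
    features: list[GeneLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.isolate_id}: illegal characters {sorted(bad)}")
        if not self.sequence:
            raise ValueError(f"{self.isolate_id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    # -- coordinate contract ------------------------------------------------

    def subsequence(self, start: int, end: int, strand: str = "+") -> str:
        return subsequence(self, start, end, strand)

    def locus(self, gene_name: str) -> GeneLocus:
        for f in self.features:
            if f.gene_name == gene_name:
                return f
        raise KeyError(f"{gene_name} not annotated in {self.isolate_id}")

    def spliced(self, locus: GeneLocus) -> str:
        """Exons concatenated in transcription order, strand applied."""
        parts = [subsequence(self, s, e, "+") for s, e in locus.exons]
        if locus.strand == "-":
            parts = [revcomp(p) for p in parts]
        return "".join(parts)

    def unspliced(self, locus: GeneLocus) -> str:
        """The full genomic span of the locus, 5'->3' of the gene."""
        start, end = locus.span(self.length)
        seq = subsequence(self, start, end, "+")
        return revcomp(seq) if locus.strand == "-" else seq


@dataclass
class GenomeSet:
    genomes: list[CircularGenome]
    panel: ConservedPanel = field(default_factory=default_panel)

    def __post_init__(self) -> None:
        ids = [g.isolate_id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate isolate_id in GenomeSet")

    @property
    def isolate_ids(self) -> list[str]:
        return [g.isolate_id for g in self.genomes]

    def get(self, isolate_id: str) -> CircularGenome:
        for g in self.genomes:
            if g.isolate_id == isolate_id:
                return g
        raise KeyError(isolate_id)

    def __len__(self) -> int:
        return len(self.genomes)


# ---------------------------------------------------------------------------


def subsequence(genome: CircularGenome, start: int, end: int, strand: str = "+") -> str:
    """Slice with circular wrap-around; strand '-' returns the reverse complement."""
    n = genome.length
    if not (1 <= start <= n and 1 <= end <= n):
        raise ValueError(f"coordinates ({start},{end}) outside 1..{n}")
    if start <= end:
        seq = genome.sequence[start - 1 : end]
    else:
        if genome.topology != "circular":
            raise ValueError(f"wrap-around slice ({start},{end}) on a linear genome")
        seq = genome.sequence[start - 1 :] + genome.sequence[:end]
    return revcomp(seq) if strand == "-" else seq


def _map_position(pos: int, shift: int, n: int) -> int:
    return (pos - 1 - shift) % n + 1


def rotate(genome: CircularGenome, shift: int) -> CircularGenome:
    """Rotate a circular genome left by ``shift`` bases (origin moves to shift+1)."""
    n = genome.length
    shift %= n
    seq = genome.sequence[shift:] + genome.sequence[:shift]
    feats = []
    for f in genome.features:
        exons = [(_map_position(s, shift, n), _map_position(e, shift, n)) for s, e in f.exons]
        introns = [(_map_position(s, shift, n), _map_position(e, shift, n)) for s, e in f.introns]
        feats.append(replace(f, exons=exons, introns=introns))
    return replace(genome, sequence=seq, features=feats)


def reverse_complement_genome(genome: CircularGenome) -> CircularGenome:
    n = genome.length
    feats = []
    for f in genome.features:
        exons = [(n - e + 1, n - s + 1) if s <= e else (n - e + 1, n - s + 1) for s, e in f.exons]
        introns = [(n - e + 1, n - s + 1) for s, e in f.introns]
        strand = "-" if f.strand == "+" else "+"
        feats.append(replace(f, exons=exons, introns=introns, strand=strand))
    return replace(genome, sequence=revcomp(genome.sequence), features=feats)


def canonical_rotation(genome: CircularGenome, anchor_gene: str = "cox1") -> CircularGenome:
    """Rotate (and possibly flip) so the anchor gene's first exon starts at 1 on +.

    Length, GC content and gene order (up to rotation) are preserved.
    """
    try:
        locus = genome.locus(anchor_gene)
    except KeyError:
        avail = sorted({f.gene_name for f in genome.features})
        raise ValueError(
            f"anchor gene {anchor_gene!r} absent from {genome.isolate_id}; "
            f"available: {', '.join(avail)}"
        ) from None
    g = genome
    if locus.strand == "-":
        g = reverse_complement_genome(g)
        locus = g.locus(anchor_gene)
    start = locus.exons[0][0]
    return rotate(g, start - 1)


# -- GenBank ----------------------------------------------------------------


def _feature_name(feat) -> str | None:
    for key in ("gene", "product", "locus_tag"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return None


def read_genbank(path, panel: ConservedPanel | None = None) -> CircularGenome:
    """Read a single-record GenBank flat file into a CircularGenome.

    Gene names are normalized to the panel vocabulary; topology is taken
    from the LOCUS line, defaulting to circular with a warning.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected a single-record file, found {len(records)} records")
    rec = records[0]
    if len(rec.seq) == 0:
        raise ValueError(f"{path}: empty sequence")
    topology = rec.annotations.get("topology")
    if topology not in ("circular", "linear"):
        log.warning("%s: no topology on LOCUS line; assuming circular", path)
        topology = "circular"
    panel = panel or default_panel()
    n = len(rec.seq)
    feats: list[GeneLocus] = []
    for feat in rec.features:
        if feat.type in ("gene", "source"):
            continue
        if feat.type not in FEATURE_TYPES:
            log.warning("%s: skipping unknown feature key %r", path, feat.type)
            continue
        name = _feature_name(feat)
        if name is None:
            log.warning("%s: %s feature without a name skipped", path, feat.type)
            continue
        strand = "-" if feat.location.strand == -1 else "+"
        parts = [(int(p.start) + 1, int(p.end)) for p in feat.location.parts]
        # merge origin-wrapping split parts back into one exon
        if len(parts) >= 2 and parts[0][1] == n and parts[1][0] == 1:
            parts = [(parts[0][0], parts[1][1])] + parts[2:]
        if strand == "-":
            parts = sorted(parts, key=lambda p: p[0], reverse=True)
        introns = _gaps_between(parts, strand, n)
        table = int(feat.qualifiers.get("transl_table", [4])[0])
        feats.append(
            GeneLocus(
                gene_name=normalize_gene_name(name, panel),
                gene_type=feat.type,
                strand=strand,
                exons=parts,
                introns=introns,
                translation_table=table,
            )
        )
    return CircularGenome(
        isolate_id=rec.id if rec.id not in ("", "<unknown id>") else rec.name,
        sequence=str(rec.seq),
        topology=topology,
        features=feats,
    )


def _gaps_between(exons: list[tuple[int, int]], strand: str, n: int) -> list[tuple[int, int]]:
    """Intron intervals between consecutive exons, in transcription order."""
    gaps = []
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if strand == "+":
            gs, ge = e1 + 1, s2 - 1
        else:
            gs, ge = e2 + 1, s1 - 1
        if gs <= ge:
            gaps.append((gs, ge))
        elif (gs - 1) % n + 1 != (ge % n) + 1:  # genuine wrap gap
            gaps.append(((gs - 1) % n + 1, (ge - 1) % n + 1))
    return gaps


def _locus_to_feature(locus: GeneLocus, n: int) -> SeqFeature:
    strand = -1 if locus.strand == "-" else 1
    exons = locus.exons if locus.strand == "+" else list(reversed(locus.exons))
    parts = []
    for s, e in exons:
        if s <= e:
            parts.append(SimpleLocation(s - 1, e, strand))
        else:  # wrap-around: split at the origin
            parts.append(SimpleLocation(s - 1, n, strand))
            parts.append(SimpleLocation(0, e, strand))
    loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
    qualifiers = {"gene": [locus.gene_name]}
    if locus.gene_type == "CDS":
        qualifiers["transl_table"] = [str(locus.translation_table)]
    return SeqFeature(loc, type=locus.gene_type, qualifiers=qualifiers)


def write_genbank(genome: CircularGenome, path) -> None:
    """Emit a single-record GenBank flat file; read_genbank round-trips it."""
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.isolate_id,
        name=genome.isolate_id[:16].replace(" ", "_"),
        description=f"{genome.isolate_id} mitochondrion",
        annotations={"molecule_type": "DNA", "topology": genome.topology},
    )
    rec.features = [_locus_to_feature(f, genome.length) for f in genome.features]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        SeqIO.write([rec], str(path), "genbank")


# -- FASTA / GFF3 -----------------------------------------------------------


def read_fasta(path, topology: str = "circular") -> list[CircularGenome]:
    return [
        CircularGenome(rec.id, str(rec.seq), topology=topology)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(genomes: list[CircularGenome], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(g.sequence), id=g.isolate_id, description="") for g in genomes],
        str(path),
        "fasta",
    )


def read_gff3(genome: CircularGenome, path, panel: ConservedPanel | None = None) -> CircularGenome:
    """Attach annotations from a GFF3 file (gene= / ID= attributes) to a genome.

    Exon structure is taken from multiple lines sharing one gene label.
    """
    panel = panel or default_panel()
    df = pd.read_csv(
        str(path),
        sep="\t",
        comment="#",
        header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
    )
    df = df[df["type"].isin(FEATURE_TYPES)]

    def attr(attrs: str, key: str) -> str | None:
        for fieldv in attrs.split(";"):
            if "=" in fieldv:
                k, v = fieldv.split("=", 1)
                if k.strip() == key:
                    return v.strip()
        return None

    feats: list[GeneLocus] = []
    df = df.assign(name=[attr(a, "gene") or attr(a, "ID") for a in df["attrs"]])
    for (name, ftype, strand), grp in df.groupby(["name", "type", "strand"], sort=False):
        exons = sorted(zip(grp["start"].astype(int), grp["end"].astype(int)))
        if strand == "-":
            exons = exons[::-1]
        feats.append(
            GeneLocus(
                gene_name=normalize_gene_name(str(name), panel),
                gene_type=str(ftype),
                strand=str(strand),
                exons=[(int(s), int(e)) for s, e in exons],
                introns=_gaps_between(exons, str(strand), genome.length),
            )
        )
    return replace(genome, features=feats)
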