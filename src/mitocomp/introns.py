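"""Call introns and intergenic mobile fragments by intra-specific comparison.

The central idea: within one species, a gene's intron content varies
while its exons barely change, so aligning each isolate's unspliced
locus against the shortest (intron-free) homolog exposes every intron
as a contiguous insertion. This also finds tRNA introns that gene
prediction software misses. Group I introns carry no GT-AG-like splice
signal, so the only boundary anchor is exon conservation: within an
exact-repeat window at the junction the insertion placement is
ambiguous; we left-align and record the window size.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from . import align
from .genome_io import CircularGenome, GeneLocus, GenomeSet
from .harmonize import LocusTable

log = logging.getLogger(__name__)

MIN_INTRON_LENGTH = 50
MIN_MOBILE_LENGTH = 1000
SITE_TOLERANCE = 3
SAME_FAMILY_IDENTITY = 0.70

#: LAGLIDADG-like decapeptide block (acidic-anchored, degenerate)
LAGLIDADG_RE = re.compile(r"[LIVMF][AGS].[LIVMF][LIVMF][DE][AGSC][DENQ][GAS]")
#: GIY-(X)n-YIG N-terminal block
GIYYIG_RE = re.compile(r"G[IL]Y.{0,12}Y[IL]G")


@dataclass
class OrfHit:
    frame: int  # +1..+3 / -1..-3
    interval: tuple[int, int]  # 1-based within intron, forward coordinates
    peptide: str
    motif_label: str = "none"  # LAGLIDADG | GIY-YIG | none


@dataclass
class IntronCall:
    isolate_id: str
    host_gene: str
    insertion_site: int  # 1-based, intron follows this base of the intron-free gene
    genome_interval: tuple[int, int]
    sequence: str
    ambiguity_window: int = 0
    orfs: list[OrfHit] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class IntronFamily:
    family_id: str
    host_gene: str
    host_gene_type: str
    insertion_site: int  # consensus
    members: list[IntronCall]

    @property
    def frequency(self) -> int:
        return len({m.isolate_id for m in self.members})

    @property
    def carriers(self) -> list[str]:
        return sorted({m.isolate_id for m in self.members})


@dataclass
class MobileFragment:
    isolate_id: str
    flanking_genes: tuple[str, str]
    genome_interval: tuple[int, int]
    sequence: str

    @property
    def name(self) -> str:
        return f"{self.flanking_genes[0]}/{self.flanking_genes[1]}"

    @property
    def length(self) -> int:
        return len(self.sequence)


# -- coordinate mapping -----------------------------------------------------


def _span_offset_to_genome(locus: GeneLocus, n: int, offset: int) -> int:
    """Map a 1-based offset along the gene-oriented unspliced span to a genome position."""
    start, end = locus.span(n)
    if locus.strand == "+":
        return (start - 1 + offset - 1) % n + 1
    return (end - offset) % n + 1


def _interval_from_span(locus: GeneLocus, n: int, qs: int, qe: int) -> tuple[int, int]:
    a = _span_offset_to_genome(locus, n, qs)
    b = _span_offset_to_genome(locus, n, qe)
    return (a, b) if locus.strand == "+" else (b, a)


# -- intron calling ---------------------------------------------------------


def call_introns(
    table: LocusTable,
    gene: str,
    genomes: dict[str, CircularGenome] | None = None,
    min_intron_length: int = MIN_INTRON_LENGTH,
) -> list[IntronCall]:
    """Call introns in one gene across all isolates carrying it.

    The shortest copy serves as the intron-free reference; every
    contiguous insertion of at least ``min_intron_length`` in any other
    copy becomes a call, with the insertion site expressed in the
    reference (intron-free) gene's own coordinates.
    """
    rows = table.rows_for_gene(gene)
    if len(rows) < 2:
        return []
    lengths = {len(r.unspliced_nt) for r in rows}
    if len(lengths) == 1:
        return []
    ref_row = min(rows, key=lambda r: (len(r.unspliced_nt), r.isolate_id))
    ref = ref_row.unspliced_nt
    calls: list[IntronCall] = []
    for row in rows:
        if row.isolate_id == ref_row.isolate_id:
            continue
        qry = row.unspliced_nt
        if len(qry) < len(ref) + min_intron_length:
            continue
        for ins in align.find_insertions(ref, qry, min_intron_length):
            n = len(genomes[row.isolate_id].sequence) if genomes else 10**12
            interval = (
                _interval_from_span(row.locus, n, ins.qry_start, ins.qry_end)
                if genomes
                else (ins.qry_start, ins.qry_end)
            )
            site = max(ins.ref_site, 1)
            calls.append(
                IntronCall(
                    isolate_id=row.isolate_id,
                    host_gene=gene,
                    insertion_site=site,
                    genome_interval=interval,
                    sequence=ins.sequence,
                    ambiguity_window=align.ambiguity_window(ins, ref),
                )
            )
    return calls


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def cluster_families(
    calls: list[IntronCall],
    table: LocusTable | None = None,
    site_tolerance: int = SITE_TOLERANCE,
    same_family_identity: float = SAME_FAMILY_IDENTITY,
) -> list[IntronFamily]:
    """Single-linkage clustering of calls into intron families.

    Two calls join one family iff they share the host gene, their sites
    agree within ``site_tolerance``, and their sequence identity is at
    least ``same_family_identity``. Two families may therefore share one
    insertion site when their sequences are unrelated — distinct introns
    at one homing site. Families are named <gene>-i1..iN in site order.
    """
    families: list[IntronFamily] = []
    by_gene: dict[str, list[IntronCall]] = {}
    for c in calls:
        by_gene.setdefault(c.host_gene, []).append(c)
    for gene in sorted(by_gene):
        gcalls = sorted(by_gene[gene], key=lambda c: (c.insertion_site, c.isolate_id))
        uf = _UnionFind(len(gcalls))
        for i in range(len(gcalls)):
            for j in range(i + 1, len(gcalls)):
                a, b = gcalls[i], gcalls[j]
                if abs(a.insertion_site - b.insertion_site) > site_tolerance:
                    continue
                if align.sequence_identity(a.sequence, b.sequence) >= same_family_identity:
                    uf.union(i, j)
        groups: dict[int, list[IntronCall]] = {}
        for i, c in enumerate(gcalls):
            groups.setdefault(uf.find(i), []).append(c)
        gtype = "CDS"
        if table is not None:
            anyrow = table.rows_for_gene(gene)
            if anyrow:
                gtype = anyrow[0].locus.gene_type
        ordered = sorted(
            groups.values(),
            key=lambda ms: (
                int(pd.Series([m.insertion_site for m in ms]).median()),
                ms[0].isolate_id,
            ),
        )
        for k, members in enumerate(ordered, start=1):
            site = int(pd.Series([m.insertion_site for m in members]).median())
            families.append(
                IntronFamily(
                    family_id=f"{gene}-i{k}",
                    host_gene=gene,
                    host_gene_type=gtype,
                    insertion_site=site,
                    members=members,
                )
            )
    return families


def call_all_introns(
    table: LocusTable,
    genomes: dict[str, CircularGenome] | None = None,
    min_intron_length: int = MIN_INTRON_LENGTH,
) -> list[IntronCall]:
    """Call introns across every panel gene with length variation."""
    calls: list[IntronCall] = []
    for entry in table.panel.entries:
        calls.extend(call_introns(table, entry.gene_name, genomes, min_intron_length))
    return calls


# -- mobile fragments -------------------------------------------------------


def intergenic_spans(
    genome: CircularGenome, table: LocusTable
) -> dict[tuple[str, str], tuple[int, int, str]]:
    """Intergenic spans keyed by (left gene, right gene) in genome order.

    Values are (start, end, sequence), 1-based inclusive, possibly
    wrapping; zero-length spans get start = end + 1 and an empty string.
    """
    n = genome.length
    loci = [
        r.locus
        for (iso, _), r in sorted(table.rows.items())
        if iso == genome.isolate_id
    ]
    loci = sorted(loci, key=lambda f: f.span(n)[0])
    spans: dict[tuple[str, str], tuple[int, int, str]] = {}
    for left, right in zip(loci, loci[1:] + loci[:1]):
        ls, le = left.span(n)
        rs, re_ = right.span(n)
        start = le % n + 1
        end = (rs - 2) % n + 1
        gap = (rs - 1 - le) % n
        seq = genome.subsequence(start, end) if gap > 0 else ""
        spans[(left.gene_name, right.gene_name)] = (start, end, seq)
    return spans


def call_mobile_fragments(
    genome_set: GenomeSet,
    table: LocusTable,
    min_mobile_length: int = MIN_MOBILE_LENGTH,
) -> list[MobileFragment]:
    """Large intergenic presence/absence insertions, by homologous-span alignment.

    Only spans whose flanking gene pair is shared by every isolate are
    compared (a flank mismatch means a gene-order difference and the span
    is skipped with a warning); the shortest span is the reference.
    """
    per_genome = {
        g.isolate_id: intergenic_spans(g, table) for g in genome_set.genomes
    }
    all_keys = [set(s) for s in per_genome.values()]
    shared = set.intersection(*all_keys) if all_keys else set()
    for iso, spans in per_genome.items():
        for key in set(spans) - shared:
            log.warning("%s: intergenic span %s/%s has no homolog in all isolates; skipped",
                        iso, *key)
    frags: list[MobileFragment] = []
    for key in sorted(shared):
        seqs = {iso: per_genome[iso][key] for iso in per_genome}
        ref_iso = min(seqs, key=lambda i: (len(seqs[i][2]), i))
        ref = seqs[ref_iso][2]
        for iso, (start, end, seq) in sorted(seqs.items()):
            if iso == ref_iso or len(seq) < len(ref) + min_mobile_length:
                continue
            if not ref:
                inss = [align.Insertion(0, 1, len(seq), seq)]
            else:
                inss = align.find_insertions(ref, seq, min_mobile_length)
            n = genome_set.get(iso).length
            for ins in inss:
                if ins.length < min_mobile_length:
                    continue
                a = (start - 1 + ins.qry_start - 1) % n + 1
                b = (start - 1 + ins.qry_end - 1) % n + 1
                frags.append(
                    MobileFragment(
                        isolate_id=iso,
                        flanking_genes=key,
                        genome_interval=(a, b),
                        sequence=ins.sequence,
                    )
                )
    return frags


# -- ORFs and the landscape -------------------------------------------------


def find_orfs(
    intron: IntronCall | str, min_orf_aa: int = 50, translation_table: int = 4
) -> list[OrfHit]:
    """All ATG-initiated ORFs of at least ``min_orf_aa`` in all six frames.

    Motif labels are regex-level: a LAGLIDADG-like decapeptide block, or
    a GIY-YIG N-terminal block within the first 60 residues.
    """
    seq = intron.sequence if isinstance(intron, IntronCall) else intron
    hits: list[OrfHit] = []
    n = len(seq)
    for strand in (+1, -1):
        s = seq if strand == 1 else str(Seq(seq).reverse_complement())
        for off in range(3):
            sub = s[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            aa = str(Seq(sub).translate(table=translation_table))
            for m in re.finditer(r"M[^*]*(?:\*|$)", aa):
                pep = m.group(0).rstrip("*")
                if len(pep) < min_orf_aa:
                    continue
                nt_start = off + 3 * m.start() + 1
                nt_end = off + 3 * m.end()
                nt_end = min(nt_end, n)
                if strand == -1:
                    nt_start, nt_end = n - nt_end + 1, n - nt_start + 1
                label = "none"
                if LAGLIDADG_RE.search(pep):
                    label = "LAGLIDADG"
                elif GIYYIG_RE.search(pep[:60]) or GIYYIG_RE.search(pep):
                    label = "GIY-YIG"
                hits.append(
                    OrfHit(
                        frame=strand * (off + 1),
                        interval=(nt_start, nt_end),
                        peptide=pep,
                        motif_label=label,
                    )
                )
    return hits


def annotate_orfs(calls: list[IntronCall], min_orf_aa: int = 50) -> None:
    for c in calls:
        c.orfs = find_orfs(c, min_orf_aa)


@dataclass
class Landscape:
    matrix: pd.DataFrame  # isolates x elements, 0/1
    per_isolate_counts: pd.Series
    per_element_frequency: pd.Series
    notes: list[str]


def landscape(
    families: list[IntronFamily],
    isolates: list[str],
    mobiles: list[MobileFragment] | None = None,
) -> Landscape:
    """Presence/absence matrix of introns (and mobile fragments) per isolate."""
    cols: dict[str, set[str]] = {}
    for fam in families:
        cols[fam.family_id] = set(fam.carriers)
    for frag in mobiles or []:
        cols.setdefault(frag.name, set()).add(frag.isolate_id)
    mat = pd.DataFrame(
        {name: [int(i in carriers) for i in isolates] for name, carriers in cols.items()},
        index=pd.Index(isolates, name="isolate_id"),
    )
    counts = mat.sum(axis=1)
    freq = mat.sum(axis=0)
    notes = []
    if len(mat.columns) and (freq == len(isolates)).any():
        fixed = list(freq[freq == len(isolates)].index)
        notes.append(f"elements present in all isolates: {fixed}")
    if len(mat.columns) and (counts == 0).any():
        notes.append(f"element-free isolates: {list(counts[counts == 0].index)}")
    return Landscape(mat, counts, freq, notes)
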