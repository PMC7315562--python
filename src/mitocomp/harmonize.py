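"""Locate and harmonize the conserved gene panel across isolates.

Within one species the gene complement and gene order of the
mitochondrial genome are expected to be identical; what varies is intron
content and intergenic sequence. This module verifies that expectation:
it maps every genome's annotation onto the panel vocabulary (locating
missing loci by homology when references are available), reports the
complement per isolate, computes rotation-invariant gene-order
signatures, and exposes spliced sequences and peptides to downstream
modules. Gene boundaries taken from annotation are trusted only as far
as homology supports them — comparison across isolates is what
ultimately defines exon/intron structure (see the intron caller).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from . import align
from .genome_io import CircularGenome, GeneLocus, GenomeSet, revcomp
from .panel import ConservedPanel, PanelEntry, normalize_gene_name

log = logging.getLogger(__name__)

#: insertions below this length are treated as indel noise, not introns
MIN_INSERTION = 50


@dataclass
class LocusRow:
    isolate_id: str
    gene_name: str
    locus: GeneLocus
    unspliced_nt: str
    spliced_nt: str
    peptide: str | None = None
    has_insertion: bool = False
    flags: set[str] = field(default_factory=set)


@dataclass
class LocusTable:
    rows: dict[tuple[str, str], LocusRow]
    complement_report: pd.DataFrame  # columns: isolate_id, gene_name, status
    gene_orders: dict[str, tuple[str, ...]]
    panel: ConservedPanel

    @property
    def isolates(self) -> list[str]:
        return sorted({iso for iso, _ in self.rows})

    def genes_present(self, gene: str) -> list[str]:
        return sorted(iso for iso, g in self.rows if g == gene)

    def get(self, isolate_id: str, gene: str) -> LocusRow:
        return self.rows[(isolate_id, gene)]

    def rows_for_gene(self, gene: str) -> list[LocusRow]:
        return [self.rows[k] for k in sorted(self.rows) if k[1] == gene]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for (iso, gene), row in sorted(self.rows.items()):
            s, e = row.locus.span(10**12)
            recs.append(
                {
                    "isolate_id": iso,
                    "gene_name": gene,
                    "gene_type": row.locus.gene_type,
                    "strand": row.locus.strand,
                    "n_exons": len(row.locus.exons),
                    "span_start": s,
                    "span_end": e,
                    "unspliced_len": len(row.unspliced_nt),
                    "spliced_len": len(row.spliced_nt),
                    "has_insertion": row.has_insertion,
                    "flags": ",".join(sorted(row.flags)),
                }
            )
        return pd.DataFrame.from_records(recs)


def splice_and_translate(locus: GeneLocus, genome: CircularGenome) -> tuple[str, str, set[str]]:
    """Spliced CDS and its peptide under the locus's translation table.

    The terminal stop is removed. A spliced length not divisible by 3 is
    flagged and translation truncated to the floor; internal stops are
    flagged but not fatal (genes mid-way through intron exonization can
    legitimately look odd).
    """
    cds = genome.spliced(locus)
    flags: set[str] = set()
    usable = cds
    if len(cds) % 3 != 0:
        flags.add("len_not_multiple_of_3")
        usable = cds[: len(cds) - len(cds) % 3]
    peptide = str(Seq(usable).translate(table=locus.translation_table))
    if peptide.endswith("*"):
        peptide = peptide[:-1]
    if "*" in peptide:
        flags.add("has_internal_stop")
    return cds, peptide, flags


def _minimal_rotation(seq: tuple[str, ...]) -> tuple[str, ...]:
    n = len(seq)
    best = seq
    for i in range(1, n):
        rot = seq[i:] + seq[:i]
        if rot < best:
            best = rot
    return best


def gene_order_signature(genome: CircularGenome) -> tuple[str, ...]:
    """Rotation- and flip-invariant circular gene order signature.

    The (name, strand) sequence in genome order, reduced to its
    lexicographically minimal rotation; the reverse-complement reading is
    computed too and the smaller of the two returned, so two genomes
    share gene order iff their signatures are equal.
    """
    feats = sorted(genome.features, key=lambda f: f.span(genome.length)[0])
    fwd = tuple(f"{f.gene_name}:{f.strand}" for f in feats)
    rev = tuple(
        f"{f.gene_name}:{'-' if f.strand == '+' else '+'}" for f in reversed(feats)
    )
    if not fwd:
        return ()
    return min(_minimal_rotation(fwd), _minimal_rotation(rev))


# -- homology location ------------------------------------------------------


def _local_hit(ref: str, target: str):
    """Best local alignment of ref in target: (score, identity, coverage, t0, t1)."""
    aligner = align.nt_aligner("local")
    try:
        aln = aligner.align(ref, target)[0]
    except IndexError:
        return None
    r_blocks, t_blocks = aln.aligned
    if len(r_blocks) == 0:
        return None
    matches = sum(
        1
        for (rs, re_), (ts, te) in zip(r_blocks, t_blocks)
        for i, j in zip(range(rs, re_), range(ts, te))
        if ref[i] == target[j]
    )
    cols = sum(re_ - rs for rs, re_ in r_blocks)
    covered = r_blocks[-1][1] - r_blocks[0][0]
    return (
        aln.score,
        matches / cols if cols else 0.0,
        covered / len(ref),
        int(t_blocks[0][0]),
        int(t_blocks[-1][1]),
    )


def locate_by_homology(genome: CircularGenome, entry: PanelEntry) -> GeneLocus | None:
    """Locate a panel gene in an unannotated genome by sequence homology.

    Nucleotide search on the doubled sequence (circularity) and its
    reverse complement. Acceptance thresholds: non-coding genes require
    >=70% identity over >=70% of the reference; CDS >=60% coverage (the
    nucleotide route is used even for CDS because intra-specific
    divergence is tiny).
    """
    ref = entry.reference
    if not ref:
        return None
    doubled = genome.sequence + genome.sequence
    best = None
    for strand, target in (("+", doubled), ("-", revcomp(doubled))):
        hit = _local_hit(ref, target)
        if hit is None:
            continue
        if best is None or hit[0] > best[0][0]:
            best = (hit, strand)
    if best is None:
        return None
    (score, ident, cov, t0, t1), strand = best
    if entry.gene_type == "CDS":
        ok = cov >= 0.6 and ident >= 0.4
    else:
        ok = cov >= 0.7 and ident >= 0.7
    if not ok:
        return None
    n = genome.length
    if strand == "-":
        t0, t1 = 2 * n - t1, 2 * n - t0
    start = t0 % n + 1
    end = (t1 - 1) % n + 1
    return GeneLocus(entry.gene_name, entry.gene_type, strand, [(start, end)])


# -- harmonize --------------------------------------------------------------


def harmonize(genome_set: GenomeSet, locate_missing: bool = True) -> LocusTable:
    """Build the panel x isolate locus table.

    Annotated features are matched to the panel by normalized name (the
    highest-scoring — here: longest — candidate kept on conflict).
    Panel genes absent from the annotation are located by homology when
    the panel carries references. Missing and extra genes land in the
    complement report rather than raising.
    """
    if len(genome_set) < 2:
        raise ValueError(">=2 genomes required for any comparative operation")
    panel = genome_set.panel
    rows: dict[tuple[str, str], LocusRow] = {}
    report_recs = []
    gene_orders = {}
    for genome in genome_set.genomes:
        seen: dict[str, GeneLocus] = {}
        for feat in genome.features:
            name = normalize_gene_name(feat.gene_name, panel)
            if name not in panel:
                report_recs.append(
                    {"isolate_id": genome.isolate_id, "gene_name": name, "status": "extra"}
                )
                continue
            if name in seen:
                keep, drop = sorted(
                    (seen[name], feat), key=lambda f: -len(genome.unspliced(f))
                )
                log.warning(
                    "%s: two candidate loci for %s; keeping the longer", genome.isolate_id, name
                )
                seen[name] = keep
            else:
                seen[name] = feat
        for entry in panel.entries:
            locus = seen.get(entry.gene_name)
            if locus is None and locate_missing:
                locus = locate_by_homology(genome, entry)
            if locus is None:
                report_recs.append(
                    {
                        "isolate_id": genome.isolate_id,
                        "gene_name": entry.gene_name,
                        "status": "missing",
                    }
                )
                continue
            spliced, peptide, flags = "", None, set()
            if entry.gene_type == "CDS":
                spliced, peptide, flags = splice_and_translate(locus, genome)
            else:
                spliced = genome.spliced(locus)
            rows[(genome.isolate_id, entry.gene_name)] = LocusRow(
                isolate_id=genome.isolate_id,
                gene_name=entry.gene_name,
                locus=locus,
                unspliced_nt=genome.unspliced(locus),
                spliced_nt=spliced,
                peptide=peptide,
                flags=flags,
            )
        gene_orders[genome.isolate_id] = gene_order_signature(genome)
    # flag insertion-bearing loci: unspliced span exceeding the gene's
    # shortest copy by at least the intron-length floor
    by_gene: dict[str, list[LocusRow]] = {}
    for row in rows.values():
        by_gene.setdefault(row.gene_name, []).append(row)
    for gene_rows in by_gene.values():
        shortest = min(len(r.unspliced_nt) for r in gene_rows)
        for r in gene_rows:
            r.has_insertion = len(r.unspliced_nt) >= shortest + MIN_INSERTION
    report = pd.DataFrame.from_records(
        report_recs, columns=["isolate_id", "gene_name", "status"]
    )
    return LocusTable(rows=rows, complement_report=report, gene_orders=gene_orders, panel=panel)
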