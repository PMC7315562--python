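"""Detect introns carrying an N-terminal duplication of their host gene.

Some mitochondrial introns begin with a sequence encoding an analogue
of the N-terminal region of the exon that follows them. A host gene
carrying such an intron is called D-type; the plain form is N-type.
Because the duplicated region can take over the coding role ("exonize")
or detach downstream of the gene, repeated gain and loss of such introns
can replace a gene's N-terminus with foreign sequence.

Detection: translate the intron's 5' region (first 60% — duplications
are 5'-terminal) in the host reading frame and both alternatives, align
each candidate peptide globally (BLOSUM62) against the downstream exon's
N-terminal peptide, and call D-type when the best frame reaches the
similarity threshold over at least 30 aligned residues. Both percent
identity (exact matches) and percent similarity (positive-scoring
columns) are always reported, since either convention appears in the
literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from . import align
from .genome_io import CircularGenome, GenomeSet
from .harmonize import LocusTable
from .introns import IntronCall, IntronFamily
from .panel import ConservedPanel

log = logging.getLogger(__name__)

CALL_THRESHOLD = 50.0  # % similarity
MIN_ALIGNED_AA = 30
FIVE_PRIME_FRACTION = 0.6


@dataclass
class NdupReport:
    family_id: str
    isolate_id: str
    host_gene: str
    duplication_interval: tuple[int, int] | None  # within-intron, 1-based nt
    duplication_peptide: str
    exon_peptide: str
    aa_identity: float  # percent
    aa_similarity: float  # percent
    aligned_aa: int
    gene_type_call: str  # N-type | D-type
    structural_subtype: str = "not-ndup"
    reason: str = ""

    @property
    def positive(self) -> bool:
        return self.gene_type_call == "D-type"


def _translate(nt: str, table: int = 4) -> str:
    usable = nt[: len(nt) - len(nt) % 3]
    return str(Seq(usable).translate(table=table))


def scan_intron(
    intron: IntronCall,
    downstream_exon_nt: str,
    frame_offset: int,
    family_id: str = "",
    translation_table: int = 4,
    call_threshold: float = CALL_THRESHOLD,
    min_aligned_aa: int = MIN_ALIGNED_AA,
) -> NdupReport:
    """Scan one intron for a 5' duplication of its downstream exon.

    ``downstream_exon_nt`` is the carrier's own spliced sequence downstream
    of the intron; ``frame_offset`` the number of bases to skip so that the
    downstream exon is read in the host frame (= (3 - site % 3) % 3).
    """

    def report(call="N-type", reason="", **kw):
        base = dict(
            family_id=family_id,
            isolate_id=intron.isolate_id,
            host_gene=intron.host_gene,
            duplication_interval=None,
            duplication_peptide="",
            exon_peptide="",
            aa_identity=0.0,
            aa_similarity=0.0,
            aligned_aa=0,
            gene_type_call=call,
            reason=reason,
        )
        base.update(kw)
        return NdupReport(**base)

    exon_pep_full = _translate(downstream_exon_nt[frame_offset:], translation_table).rstrip("*")
    if len(exon_pep_full) < min_aligned_aa:
        return report(reason="exon too short")
    head_len = int(len(intron.sequence) * FIVE_PRIME_FRACTION)
    head = intron.sequence[:head_len]
    best = None
    for frame in range(3):
        # the candidate is the 5' open reading stretch: translation up to
        # the first stop — a duplication that has retained coding capacity
        cand = _translate(head[frame:], translation_table).split("*")[0]
        if len(cand) < min_aligned_aa:
            continue
        exon_pep = exon_pep_full[: len(cand)]  # matched length
        ident, sim, ncol, core = align.aligned_identity_similarity(cand, exon_pep)
        if ncol < min_aligned_aa:
            continue
        if best is None or sim > best[1]:
            best = (ident, sim, ncol, core, frame, cand, exon_pep)
    if best is None:
        return report(reason="no alignable frame")
    ident, sim, ncol, (a0, a1), frame, cand, exon_pep = best
    dup_interval = (frame + 3 * a0 + 1, min(frame + 3 * a1, len(intron.sequence)))
    positive = sim * 100 >= call_threshold and ncol >= min_aligned_aa
    # duplications are 5'-terminal: the match must start in the first half
    if positive and dup_interval[0] > len(intron.sequence) / 2:
        positive = False
    return report(
        call="D-type" if positive else "N-type",
        duplication_interval=dup_interval,
        duplication_peptide=cand[a0:a1],
        exon_peptide=exon_pep,
        aa_identity=round(ident * 100, 1),
        aa_similarity=round(sim * 100, 1),
        aligned_aa=ncol,
    )


def _has_internal_stop(pep: str) -> bool:
    return "*" in pep.rstrip("*")


def classify_structure(
    report: NdupReport,
    upstream_nt: str,
    intron_nt: str,
    downstream_nt: str,
    translation_table: int = 4,
    cdna_evidence: dict[str, str] | None = None,
) -> str:
    """Assign a structural subtype to a positive N-dup call.

    In-silico ORF-continuity proxy (cDNA splice-form evidence, when
    supplied, overrides it):

    - ``intact-intron``: reading through the intron breaks the frame or
      hits stops, while splicing it out restores an intact ORF;
    - ``exonized``: read-through from the upstream exon into the
      duplication and on into the downstream exon stays open;
    - ``downstream-TE``: the upstream portion alone already forms a
      complete ORF terminating before the predicted intron;
    - contradictions yield ``ambiguous``.
    """
    if cdna_evidence and report.family_id in cdna_evidence:
        return cdna_evidence[report.family_id]
    if not report.positive:
        return "not-ndup"
    up_pep = _translate(upstream_nt, translation_table)
    if up_pep.endswith("*") or _has_internal_stop(up_pep):
        return "downstream-TE"
    read_through = _translate(upstream_nt + intron_nt + downstream_nt, translation_table)
    spliced = _translate(upstream_nt + downstream_nt, translation_table)
    rt_open = not _has_internal_stop(read_through)
    splice_open = not _has_internal_stop(spliced)
    if rt_open:
        return "exonized"
    if splice_open:
        return "intact-intron"
    return "ambiguous"


def intron_free_sequence(span: str, calls_sorted: list[IntronCall]) -> str:
    """Remove every called intron from a gene-oriented unspliced span."""
    out = []
    pos = 0
    cum = 0
    for c in calls_sorted:
        start = c.insertion_site + cum  # span offset of the last exon base before the intron
        out.append(span[pos:start])
        pos = start + len(c.sequence)
        cum += len(c.sequence)
    out.append(span[pos:])
    return "".join(out)


def downstream_exon_of(
    call: IntronCall, table: LocusTable, all_calls: list[IntronCall]
) -> tuple[str, int]:
    """The carrier's exonic sequence downstream of a call, plus its frame offset.

    Every intron called in the same locus (including later ones) is
    removed before the downstream portion is taken.
    """
    row = table.get(call.isolate_id, call.host_gene)
    mine = sorted(
        (
            c
            for c in all_calls
            if c.isolate_id == call.isolate_id and c.host_gene == call.host_gene
        ),
        key=lambda c: c.insertion_site,
    )
    exon_seq = intron_free_sequence(row.unspliced_nt, mine)
    downstream = exon_seq[call.insertion_site :]
    frame_offset = (3 - call.insertion_site % 3) % 3
    return downstream, frame_offset


def ndup_survey(
    families: list[IntronFamily],
    table: LocusTable,
    all_calls: list[IntronCall],
    translation_table: int = 4,
    call_threshold: float = CALL_THRESHOLD,
) -> pd.DataFrame:
    """One N-dup report per (CDS family, carrier isolate), plus family calls.

    The family-level call is by majority over carriers.
    """
    recs = []
    for fam in families:
        if fam.host_gene_type != "CDS":
            continue
        for call in fam.members:
            try:
                downstream, frame_offset = downstream_exon_of(call, table, all_calls)
            except (KeyError, AssertionError):
                log.warning("%s %s: cannot derive downstream exon", fam.family_id, call.isolate_id)
                continue
            rep = scan_intron(
                call,
                downstream,
                frame_offset,
                family_id=fam.family_id,
                translation_table=translation_table,
                call_threshold=call_threshold,
            )
            recs.append(
                {
                    "family_id": fam.family_id,
                    "isolate_id": call.isolate_id,
                    "host_gene": fam.host_gene,
                    "aa_identity": rep.aa_identity,
                    "aa_similarity": rep.aa_similarity,
                    "aligned_aa": rep.aligned_aa,
                    "gene_type_call": rep.gene_type_call,
                    "reason": rep.reason,
                }
            )
    df = pd.DataFrame.from_records(
        recs,
        columns=[
            "family_id", "isolate_id", "host_gene", "aa_identity",
            "aa_similarity", "aligned_aa", "gene_type_call", "reason",
        ],
    )
    if len(df):
        fam_call = (
            df.groupby("family_id")["gene_type_call"]
            .agg(lambda s: "D-type" if (s == "D-type").mean() > 0.5 else "N-type")
            .rename("family_call")
        )
        df = df.merge(fam_call, on="family_id")
    else:
        df["family_call"] = pd.Series(dtype=str)
    return df


def detect_secondary_cargo(
    intron: IntronCall | str,
    panel: ConservedPanel,
    min_aa: int = 30,
    min_identity: float = 0.40,
    translation_table: int = 4,
) -> list[tuple[str, tuple[int, int], float]]:
    """Truncated panel-gene copies carried inside an intron.

    Translated search of every panel CDS reference peptide against all
    six frames of the intron; hits of >= ``min_aa`` aligned residues at
    >= ``min_identity`` are reported as (gene, nt interval, % identity).
    """
    seq = intron.sequence if isinstance(intron, IntronCall) else intron
    n = len(seq)
    hits = []
    aligner = align.aa_aligner("local")
    for entry in panel.entries:
        if entry.gene_type != "CDS":
            continue
        pep = entry.reference_peptide
        if not pep and entry.reference:
            pep = _translate(entry.reference, translation_table).rstrip("*")
        if not pep:
            continue
        best = None
        for strand in (+1, -1):
            s = seq if strand == 1 else str(Seq(seq).reverse_complement())
            for off in range(3):
                frame_pep = _translate(s[off:], translation_table)
                try:
                    aln = aligner.align(pep, frame_pep)[0]
                except IndexError:
                    continue
                p_blocks, f_blocks = aln.aligned
                if len(p_blocks) == 0:
                    continue
                cols = 0
                matches = 0
                for (ps, pe), (fs, fe) in zip(p_blocks, f_blocks):
                    for i, j in zip(range(ps, pe), range(fs, fe)):
                        cols += 1
                        matches += pep[i] == frame_pep[j]
                if cols < min_aa or matches / cols < min_identity:
                    continue
                a0 = off + 3 * int(f_blocks[0][0]) + 1
                a1 = min(off + 3 * int(f_blocks[-1][1]), n)
                if strand == -1:
                    a0, a1 = n - a1 + 1, n - a0 + 1
                cand = (matches / cols, (a0, a1))
                if best is None or cand[0] > best[0]:
                    best = cand
        if best:
            hits.append((entry.gene_name, best[1], round(best[0] * 100, 1)))
    return hits
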