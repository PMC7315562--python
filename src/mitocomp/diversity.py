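"""Per-region-class mutation rates (SNPs/kb) against a reference isolate.

For every gene the reference's intron-free sequence is aligned to the
query's, columns are classified by the reference codon position (or the
gene's region class), and SNPs are pooled per class before division —
one rate per class. A SNP is an aligned column where both bases are in
{A,C,G,T} and differ; gap and N columns leave both numerator and
denominator. Indels are ignored entirely. Intergenic spans are compared
with called introns and mobile fragments removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import align
from .harmonize import LocusTable
from .introns import IntronCall, MobileFragment
from .ndup import intron_free_sequence

log = logging.getLogger(__name__)

DIVERSITY_CLASSES = ["CDS_pos12", "CDS_pos3", "tRNA", "rRNA", "intergenic"]


@dataclass
class DiversityTable:
    reference_isolate_id: str
    table: pd.DataFrame  # rows (isolate, class): compared_columns, snp_count, snps_per_kb

    def rate(self, isolate: str, cls: str) -> float:
        return float(self.table.loc[(isolate, cls), "snps_per_kb"])


def _aligned_columns(ref: str, qry: str):
    """Yield (ref_index, ref_base, qry_base) for matched columns of a global alignment."""
    if ref == qry:
        for i, c in enumerate(ref):
            yield i, c, c
        return
    aln = align.align_pair(ref, qry)
    r_blocks, q_blocks = aln.aligned
    for (rs, re_), (qs, qe) in zip(r_blocks, q_blocks):
        for i, j in zip(range(rs, re_), range(qs, qe)):
            yield i, ref[i], qry[j]


def _count(ref: str, qry: str, classify) -> dict[str, list[int]]:
    """Pool compared columns and SNPs per class for one homologous pair."""
    acc: dict[str, list[int]] = {}
    for i, a, b in _aligned_columns(ref, qry):
        if a not in "ACGT" or b not in "ACGT":
            continue
        cls = classify(i)
        cols = acc.setdefault(cls, [0, 0])
        cols[0] += 1
        cols[1] += a != b
    return acc


def _exonic(table: LocusTable, iso: str, gene: str, calls: list[IntronCall]) -> str | None:
    try:
        row = table.get(iso, gene)
    except KeyError:
        return None
    mine = sorted(
        (c for c in calls if c.isolate_id == iso and c.host_gene == gene),
        key=lambda c: c.insertion_site,
    )
    return intron_free_sequence(row.unspliced_nt, mine)


def snps_per_kb(
    table: LocusTable,
    reference_isolate: str,
    intron_calls: list[IntronCall] | None = None,
    intergenic_spans: dict[str, dict] | None = None,
    mobile: list[MobileFragment] | None = None,
) -> DiversityTable:
    """SNPs/kb per isolate and region class against the reference isolate.

    ``intergenic_spans`` maps isolate -> {(left, right): (start, end, seq)}
    (see :func:`mitocomp.introns.intergenic_spans`); when supplied,
    mobile-fragment sequences are excised before comparison.
    """
    intron_calls = intron_calls or []
    isolates = table.isolates
    mobile_by_iso: dict[str, list[MobileFragment]] = {}
    for frag in mobile or []:
        mobile_by_iso.setdefault(frag.isolate_id, []).append(frag)

    acc: dict[tuple[str, str], list[int]] = {
        (iso, cls): [0, 0] for iso in isolates for cls in DIVERSITY_CLASSES
    }

    for entry in table.panel.entries:
        gene = entry.gene_name
        ref_seq = _exonic(table, reference_isolate, gene, intron_calls)
        if ref_seq is None:
            continue
        if entry.gene_type == "CDS":
            classify = lambda i: "CDS_pos12" if i % 3 < 2 else "CDS_pos3"  # noqa: E731
        elif entry.gene_type in ("tRNA", "rRNA"):
            cls_fixed = entry.gene_type
            classify = lambda i, c=cls_fixed: c  # noqa: E731
        else:
            continue  # ncRNA (rnpB) not part of the headline classes
        for iso in isolates:
            if iso == reference_isolate:
                for i, ch in enumerate(ref_seq):
                    if ch in "ACGT":
                        acc[(iso, classify(i))][0] += 1
                continue
            qry_seq = _exonic(table, iso, gene, intron_calls)
            if qry_seq is None:
                continue
            for cls, (ncol, nsnp) in _count(ref_seq, qry_seq, classify).items():
                acc[(iso, cls)][0] += ncol
                acc[(iso, cls)][1] += nsnp

    if intergenic_spans:
        ref_spans = intergenic_spans.get(reference_isolate, {})

        def cleaned(iso: str, key) -> str | None:
            span = intergenic_spans[iso].get(key)
            if span is None:
                return None
            start, end, seq = span
            for frag in mobile_by_iso.get(iso, []):
                if frag.flanking_genes == key:
                    seq = seq.replace(frag.sequence, "", 1)
            return seq

        for key in sorted(ref_spans):
            ref_seq = cleaned(reference_isolate, key)
            if not ref_seq:
                continue
            for iso in isolates:
                if iso == reference_isolate:
                    acc[(iso, "intergenic")][0] += sum(c in "ACGT" for c in ref_seq)
                    continue
                if iso not in intergenic_spans:
                    continue
                qry_seq = cleaned(iso, key)
                if not qry_seq:
                    continue
                counts = _count(ref_seq, qry_seq, lambda i: "intergenic")
                ncol, nsnp = counts.get("intergenic", (0, 0))
                acc[(iso, "intergenic")][0] += ncol
                acc[(iso, "intergenic")][1] += nsnp

    recs = []
    for (iso, cls), (ncol, nsnp) in sorted(acc.items()):
        recs.append(
            {
                "isolate_id": iso,
                "region_class": cls,
                "compared_columns": ncol,
                "snp_count": nsnp,
                "snps_per_kb": (1000.0 * nsnp / ncol) if ncol else float("nan"),
            }
        )
    df = pd.DataFrame.from_records(recs).set_index(["isolate_id", "region_class"])
    return DiversityTable(reference_isolate_id=reference_isolate, table=df)


def rank_isolates(div: DiversityTable) -> list[str]:
    """Isolates ordered by unweighted mean class rate, lowest first.

    The reference excluded; ties broken by isolate id. This ordering is
    expected to mainly correspond to the phylogeny.
    """
    means = (
        div.table["snps_per_kb"]
        .groupby(level="isolate_id")
        .mean()
        .drop(div.reference_isolate_id, errors="ignore")
    )
    return list(means.sort_index().sort_values(kind="stable").index)
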