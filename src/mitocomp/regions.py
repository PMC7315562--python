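"""Partition a genome into region classes and compute per-class GC.

Every base receives exactly one label from {CDS_pos12, CDS_pos3, tRNA,
rRNA, ncRNA, intron, mobile_fragment, intergenic}. Codon-position
classes are computed along the spliced transcript and mapped back to
genome coordinates, so the first two positions of every codon land in
CDS_pos12 and the third in CDS_pos3. Overlap precedence (highest wins):
intron > CDS > tRNA > rRNA > ncRNA > mobile_fragment > intergenic.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import CircularGenome, GeneLocus

log = logging.getLogger(__name__)

CLASSES = [
    "CDS_pos12",
    "CDS_pos3",
    "tRNA",
    "rRNA",
    "ncRNA",
    "intron",
    "mobile_fragment",
    "intergenic",
]
_CODE = {c: i for i, c in enumerate(CLASSES)}

#: classes entering the per-class GC comparison (Table-1-style)
GC_TEST_CLASSES = ["CDS_pos12", "CDS_pos3", "tRNA", "rRNA", "intron", "intergenic"]


@dataclass
class RegionMap:
    isolate_id: str
    labels: np.ndarray  # int8 codes over 0..length-1 (genome position - 1)

    def class_length(self, cls: str) -> int:
        return int(np.sum(self.labels == _CODE[cls]))

    def lengths(self) -> dict[str, int]:
        return {c: self.class_length(c) for c in CLASSES}

    def positions(self, cls: str) -> np.ndarray:
        """0-based genome positions carrying the label."""
        return np.flatnonzero(self.labels == _CODE[cls])


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T); N excluded from the denominator; strand-invariant."""
    if not sequence:
        raise ValueError("empty sequence")
    gc = sequence.count("G") + sequence.count("C")
    acgt = gc + sequence.count("A") + sequence.count("T")
    if acgt == 0:
        log.warning("all-N sequence: GC undefined")
        return math.nan
    return gc / acgt


def _paint(labels: np.ndarray, start: int, end: int, code: int, n: int) -> None:
    """Label a 1-based inclusive interval, wrapping across the origin."""
    if start <= end:
        labels[start - 1 : end] = code
    else:
        labels[start - 1 :] = code
        labels[:end] = code


def partition(
    genome: CircularGenome,
    introns: list | None = None,
    mobile: list | None = None,
    loci: list[GeneLocus] | None = None,
) -> RegionMap:
    """Assign every base to one region class.

    ``introns``/``mobile`` carry objects with a ``genome_interval``
    attribute or plain (start, end) tuples; annotated intron intervals on
    the loci themselves are honored as well. Painting goes from lowest to
    highest precedence so later classes overwrite earlier ones.
    """
    n = genome.length
    labels = np.full(n, _CODE["intergenic"], dtype=np.int8)
    loci = genome.features if loci is None else loci

    def interval(obj) -> tuple[int, int]:
        return obj.genome_interval if hasattr(obj, "genome_interval") else tuple(obj)

    for frag in mobile or []:
        s, e = interval(frag)
        _paint(labels, s, e, _CODE["mobile_fragment"], n)
    for gtype in ("ncRNA", "rRNA", "tRNA"):
        for locus in loci:
            if locus.gene_type != gtype:
                continue
            for s, e in locus.exons:
                _paint(labels, s, e, _CODE[gtype], n)
    for locus in loci:
        if locus.gene_type != "CDS":
            continue
        pos = locus.exon_positions(n)
        arr = np.asarray(pos, dtype=np.int64) - 1
        phase = np.arange(arr.size) % 3
        labels[arr[phase < 2]] = _CODE["CDS_pos12"]
        labels[arr[phase == 2]] = _CODE["CDS_pos3"]
    for locus in loci:
        for s, e in locus.introns:
            _paint(labels, s, e, _CODE["intron"], n)
    for call in introns or []:
        s, e = interval(call)
        _paint(labels, s, e, _CODE["intron"], n)
    rmap = RegionMap(genome.isolate_id, labels)
    assert sum(rmap.lengths().values()) == n, "region classes must tile the genome"
    return rmap


def class_sequences(rmap: RegionMap, genome: CircularGenome) -> dict[str, str]:
    """Concatenated bases per class, in genome order."""
    seq = np.frombuffer(genome.sequence.encode(), dtype="S1")
    out = {}
    for cls in CLASSES:
        idx = rmap.positions(cls)
        out[cls] = seq[idx].tobytes().decode()
    return out


def gc_by_class(rmap: RegionMap, genome: CircularGenome) -> pd.Series:
    """GC fraction per class, over the concatenation of the class's bases."""
    seqs = class_sequences(rmap, genome)
    return pd.Series(
        {cls: (gc_content(s) if s else math.nan) for cls, s in seqs.items()},
        name=genome.isolate_id,
    )


@dataclass
class GcTestReport:
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # class_a, class_b, u_statistic, p_raw, p_holm

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairwise[self.pairwise["p_holm"] < 0.05]
        return list(zip(sig["class_a"], sig["class_b"]))


def class_gc_difference_test(gc_table: pd.DataFrame) -> GcTestReport:
    """Do region classes differ in GC across isolates?

    ``gc_table``: isolates x classes GC fractions. Omnibus
    Kruskal-Wallis across classes, then pairwise Mann-Whitney U with
    Holm correction — nonparametric because the per-isolate values are
    few and not independent draws from a normal model.
    """
    cols = [c for c in gc_table.columns if gc_table[c].notna().any()]
    if len(cols) < 2:
        raise ValueError(">=2 classes required")
    if len(gc_table) < 3:
        raise ValueError(">=3 isolates required")
    groups = [gc_table[c].dropna().to_numpy() for c in cols]
    if np.ptp(np.concatenate(groups)) == 0:
        log.warning("constant GC across all classes; test degenerate")
        empty = pd.DataFrame(columns=["class_a", "class_b", "u_statistic", "p_raw", "p_holm"])
        return GcTestReport(statistic=0.0, p_value=1.0, pairwise=empty)
    stat, p = stats.kruskal(*groups)
    recs = []
    for (ca, ga), (cb, gb) in itertools.combinations(zip(cols, groups), 2):
        if np.ptp(np.concatenate([ga, gb])) == 0:
            u, pr = float(len(ga) * len(gb) / 2), 1.0
        else:
            u, pr = stats.mannwhitneyu(ga, gb, alternative="two-sided")
        recs.append({"class_a": ca, "class_b": cb, "u_statistic": float(u), "p_raw": float(pr)})
    pw = pd.DataFrame.from_records(recs)
    pw["p_holm"] = multipletests(pw["p_raw"], method="holm")[1]
    return GcTestReport(statistic=float(stat), p_value=float(p), pairwise=pw)


def region_table(
    rmaps: dict[str, RegionMap], genomes: dict[str, CircularGenome]
) -> pd.DataFrame:
    """Per-isolate per-class length and GC summary (one row per isolate)."""
    recs = []
    for iso, rmap in rmaps.items():
        g = genomes[iso]
        gcs = gc_by_class(rmap, g)
        rec = {"isolate_id": iso, "genome_size": g.length, "gc_overall": gc_content(g.sequence)}
        for cls in CLASSES:
            rec[f"len_{cls}"] = rmap.class_length(cls)
            rec[f"gc_{cls}"] = gcs[cls]
        recs.append(rec)
    return pd.DataFrame.from_records(recs).set_index("isolate_id").sort_index()
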