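"""Synthetic isolate sets with ground truth.

Generates a set of circular mitochondrial genomes that share a conserved
gene backbone with identical gene order, evolves them along a supplied
phylogeny with per-region-class substitution rates (Jukes-Cantor per
class; codon positions 1+2 far slower than position 3; tRNA/rRNA slow;
intergenic fast), and applies scripted structural events: intron gains
(optionally carrying homing-endonuclease-like ORFs and/or a 5'
N-terminal duplication of the downstream exon at a configurable
amino-acid similarity) and large intergenic mobile-fragment insertions.

The four-stage gain / exonization / detachment / loss cycle of
N-dup introns is modeled both as a state machine
(:func:`fig4_transition`) and structurally (:func:`ndup_cycle` and the
per-event ``stage`` field), so the "partial foreign replacement of a
host gene's N-terminus" signature can be produced and verified.

Everything is deterministic: the same seed and config yield
byte-identical genomes and truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .genome_io import CircularGenome, GeneLocus, GenomeSet, revcomp
from .panel import default_panel

_TABLE4 = CodonTable.unambiguous_dna_by_id[4]
STOP_CODONS = set(_TABLE4.stop_codons)  # TAA, TAG
_CODONS_FOR_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE4.forward_table.items()):
    _CODONS_FOR_AA.setdefault(aa, []).append(codon)

#: rate multipliers relative to codon position 3
DEFAULT_MULTIPLIERS = {
    "CDS_pos12": 0.12,
    "CDS_pos3": 1.0,
    "tRNA": 0.10,
    "rRNA": 0.10,
    "ncRNA": 0.10,
    "intergenic": 1.0,
}

BASES = np.frombuffer(b"ACGT", dtype="S1")


# -- configuration ----------------------------------------------------------


@dataclass
class PlanGene:
    name: str
    gene_type: str
    strand: str
    length: int


@dataclass
class GenomePlan:
    genes: list[PlanGene]
    spacer_length: int = 120
    gc_genic: float = 0.40
    gc_intergenic: float = 0.30

    def gene(self, name: str) -> PlanGene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)


@dataclass
class IntronEvent:
    host_gene: str
    site: int  # 1-based, intron follows this base of the intron-free gene
    length: int  # approximate length of the generated intron
    carriers: list[str]  # distinct isolate ids
    orf_motif: str | None = None  # LAGLIDADG | GIY-YIG | None
    ndup_similarity: float | None = None
    stage: int = 1  # 1 intact intron, 2 exonized (event >=3 not placed in genomes)

    def name(self, index_within_gene: int) -> str:
        return f"{self.host_gene}-e{index_within_gene}"


@dataclass
class MobileEvent:
    left_gene: str
    right_gene: str
    length: int
    carriers: list[str]

    @property
    def name(self) -> str:
        return f"{self.left_gene}/{self.right_gene}"


@dataclass
class SimConfig:
    seed: int
    tree: str  # newick over the distinct isolates, branch lengths = pos3 subs/site
    plan: GenomePlan
    multipliers: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MULTIPLIERS))
    intron_events: list[IntronEvent] = field(default_factory=list)
    mobile_events: list[MobileEvent] = field(default_factory=list)
    duplicate_isolates: dict[str, str] = field(default_factory=dict)  # alias -> source


@dataclass
class SimTruth:
    events: pd.DataFrame  # one row per (event, carrier): name, host, site, length, interval
    presence: pd.DataFrame  # isolates x event names (aliases expanded)
    region_lengths: pd.DataFrame  # isolates x class lengths
    diversity: pd.DataFrame  # (isolate, class) realized columns/snps vs reference tip
    reference_isolate: str
    event_names: dict[int, str]  # intron event index -> name


# -- low-level sequence generation -----------------------------------------


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p).tobytes().decode()


def _random_cds(rng: np.random.Generator, length: int, gc: float) -> str:
    """ATG + internal non-stop codons + TAA; length must be a multiple of 3."""
    assert length % 3 == 0 and length >= 9
    n_internal = length // 3 - 2
    codons = []
    while len(codons) < n_internal:
        c = _random_seq(rng, 3, gc)
        if c not in STOP_CODONS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def _jc_p(d: float) -> float:
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def _evolve(
    seq: str, d: float, rng: np.random.Generator, frozen: np.ndarray | None = None
) -> str:
    if d <= 0:
        # still consume one draw so traversal stays deterministic per shape
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    p = np.full(arr.size, _jc_p(d))
    if frozen is not None:
        p[frozen] = 0.0
    hit = rng.random(arr.size) < p
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _evolve_cds(
    seq: str,
    d12: float,
    d3: float,
    rng: np.random.Generator,
    frozen: np.ndarray | None = None,
) -> str:
    """Codon-aware evolution: stop-creating changes are reverted (purifying)."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n = arr.size
    phase = np.arange(n) % 3
    p = np.where(phase < 2, _jc_p(d12), _jc_p(d3))
    # first and last codon (start/stop) are frozen
    p[:3] = 0.0
    p[-3:] = 0.0
    if frozen is not None:
        p[frozen] = 0.0
    hit = rng.random(n) < p
    for i in np.flatnonzero(hit):
        old = arr[i]
        arr[i] = rng.choice(BASES[BASES != old])
        c0 = i - i % 3
        if arr[c0 : c0 + 3].tobytes().decode() in STOP_CODONS:
            arr[i] = old
    return arr.tobytes().decode()


def aa_analog(
    nt_segment: str,
    target_similarity: float,
    rng: np.random.Generator,
) -> str:
    """A codon-preserving analog of a coding segment at a target aa similarity.

    The peptide is mutated greedily — random positions are substituted
    with residues scoring <= 0 in BLOSUM62 against the original — until
    the fraction of positive-scoring columns reaches the target, then
    back-translated with random synonymous codons. The construction is
    checked against the same metric the classifier uses, so the realized
    similarity is exact up to 1/length rounding.
    """
    assert len(nt_segment) % 3 == 0
    from Bio.Seq import Seq

    pep = list(str(Seq(nt_segment).translate(table=4)))
    assert "*" not in pep, "segment must be stop-free"
    n = len(pep)
    n_sub = int(round((1.0 - target_similarity) * n))
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    aas = "ARNDCQEGHILKMFPSTWYV"
    positions = rng.permutation(n)[:n_sub]
    for i in positions:
        orig = pep[i]
        neg = [a for a in aas if a != orig and blosum[orig, a] <= 0]
        pep[i] = neg[rng.integers(len(neg))]
    out = []
    for aa in pep:
        codons = _CODONS_FOR_AA[aa]
        out.append(codons[rng.integers(len(codons))])
    return "".join(out)


def _orf_block(rng: np.random.Generator, motif: str, n_codons: int = 110) -> str:
    """An ATG-initiated ORF carrying a regex-detectable endonuclease motif."""
    if motif == "LAGLIDADG":
        motif_aa = "LAGLIDADG"
        insert_at = (20, 70)
    else:
        motif_aa = "GIYRSGYIG"
        insert_at = (5, None)
    body = []
    while len(body) < n_codons:
        c = _random_seq(rng, 3, 0.38)
        if c not in STOP_CODONS:
            body.append(c)
    def backtrans(aa_seq: str) -> str:
        return "".join(_CODONS_FOR_AA[a][rng.integers(len(_CODONS_FOR_AA[a]))] for a in aa_seq)
    body[insert_at[0] : insert_at[0] + len(motif_aa)] = [
        backtrans(a) for a in motif_aa
    ]
    if insert_at[1] is not None:
        body[insert_at[1] : insert_at[1] + len(motif_aa)] = [backtrans(a) for a in motif_aa]
    return "ATG" + "".join(body) + "TAA"


# -- the Fig.-4-style N-dup cycle ------------------------------------------

FIG4_TRANSITIONS = {
    ("N", "gain"): "D-intact",
    ("D-intact", "exonize"): "D-exonized",
    ("D-intact", "detach"): "D-downstream",
    ("D-exonized", "detach"): "D-downstream",
    ("D-downstream", "lose"): "N",
}


def fig4_transition(state: str, event: str) -> str:
    """The legal state machine of the N-dup intron gain/loss cycle."""
    try:
        return FIG4_TRANSITIONS[(state, event)]
    except KeyError:
        raise ValueError(f"illegal transition ({state!r}, {event!r})") from None


@dataclass
class HostGeneState:
    """A host CDS with an optional N-dup element, tracked through the cycle."""

    state: str
    cds: str  # the full annotated coding span (insertion included while present)
    site: int  # insertion point (multiple of 3), measured on the intron-free gene
    dup_nt: int  # length of the duplicated/analog segment
    ins_len: int = 0  # current length of the inserted element within cds
    downstream_element: str = ""


def ndup_gain(
    cds: str,
    site: int,
    dup_codons: int,
    similarity: float,
    rng: np.random.Generator,
    filler: int = 150,
) -> HostGeneState:
    """N + gain -> D-intact: insert a TE whose 5' end duplicates the downstream exon."""
    assert site % 3 == 0 and site > 0
    dup_len = 3 * dup_codons
    segment = cds[site : site + dup_len]
    dup = aa_analog(segment, similarity, rng)
    spacer = _random_seq(rng, filler, 0.35)
    intron = dup + "TAATAG" + spacer
    return HostGeneState(
        state="D-intact",
        cds=cds[:site] + intron + cds[site:],
        site=site,
        dup_nt=dup_len,
        ins_len=len(intron),
    )


def ndup_apply(hg: HostGeneState, event: str, rng: np.random.Generator) -> HostGeneState:
    """Apply one cycle event structurally; the state machine gates legality."""
    new_state = fig4_transition(hg.state, event)
    site, dup_nt, ins_len = hg.site, hg.dup_nt, hg.ins_len
    if event == "exonize":
        # remove the frame breaks: the post-duplication part of the insertion
        # becomes in-frame, stop-free coding sequence
        tail_len = ins_len - dup_nt
        n_codons = max(1, tail_len // 3)
        tail = []
        while len(tail) < n_codons:
            c = _random_seq(rng, 3, 0.35)
            if c not in STOP_CODONS:
                tail.append(c)
        new_cds = hg.cds[: site + dup_nt] + "".join(tail) + hg.cds[site + ins_len :]
        return replace(hg, state=new_state, cds=new_cds, ins_len=dup_nt + 3 * n_codons)
    if event == "detach":
        # the analog takes over the coding role; the original N-terminal
        # segment plus TE remnant moves downstream of the gene
        dup = hg.cds[site : site + dup_nt]
        ins_end = site + ins_len
        original_segment = hg.cds[ins_end : ins_end + dup_nt]
        rest = hg.cds[ins_end + dup_nt :]
        remnant = hg.cds[site + dup_nt : ins_end]
        return replace(
            hg,
            state=new_state,
            cds=hg.cds[:site] + dup + rest,
            ins_len=0,
            downstream_element=remnant + original_segment,
        )
    if event == "lose":
        return replace(hg, state=new_state, downstream_element="")
    raise AssertionError


def ndup_cycle(
    cds: str,
    site: int,
    dup_codons: int,
    similarity: float,
    rng: np.random.Generator,
) -> tuple[str, HostGeneState]:
    """Run a full gain -> exonize -> detach -> lose cycle on a CDS.

    Returns (final_cds, final_state). The final gene stays translatable
    and differs from the original only by the substituted N-terminal
    segment — the partial-foreign-replacement signature.
    """
    hg = ndup_gain(cds, site, dup_codons, similarity, rng)
    hg = ndup_apply(hg, "exonize", rng)
    hg = ndup_apply(hg, "detach", rng)
    hg = ndup_apply(hg, "lose", rng)
    return hg.cds, hg


# -- simulation -------------------------------------------------------------


def _validate(config: SimConfig, tips: list[str]) -> None:
    gene_names = {g.name for g in config.plan.genes}
    order = [g.name for g in config.plan.genes]
    taken: dict[tuple[str, int], set[str]] = {}
    for ev in config.intron_events:
        if ev.host_gene not in gene_names:
            raise ValueError(f"intron event host {ev.host_gene!r} not in plan")
        g = config.plan.gene(ev.host_gene)
        if not (1 <= ev.site <= g.length - 1):
            raise ValueError(f"{ev.host_gene}: site {ev.site} outside 1..{g.length - 1}")
        for iso in ev.carriers:
            if iso not in tips:
                raise ValueError(f"carrier {iso} not a tree tip")
        key = (ev.host_gene, ev.site)
        clash = taken.setdefault(key, set()) & set(ev.carriers)
        if clash:
            raise ValueError(f"colliding intron events at {key} in {sorted(clash)}")
        taken[key] |= set(ev.carriers)
        if ev.stage == 2 and ev.site % 3 != 0:
            raise ValueError("stage-2 (exonized) events need a site that is a multiple of 3")
    for mv in config.mobile_events:
        i = order.index(mv.left_gene)
        if order[(i + 1) % len(order)] != mv.right_gene:
            raise ValueError(f"mobile event flanks {mv.name} are not adjacent in the plan")
        for iso in mv.carriers:
            if iso not in tips:
                raise ValueError(f"carrier {iso} not a tree tip")
    for alias, src in config.duplicate_isolates.items():
        if src not in tips:
            raise ValueError(f"duplicate source {src} not a tree tip")
        if alias in tips:
            raise ValueError(f"alias {alias} collides with a tree tip")


def _class_of(gene_type: str) -> str:
    return {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "ncRNA": "ncRNA"}[gene_type]


def _build_intron(
    ev: IntronEvent,
    host_tipseq: str,
    rng: np.random.Generator,
) -> str:
    """Generate an event's intron sequence (shared by all carriers)."""
    pieces = []
    length = ev.length
    if ev.ndup_similarity is not None:
        dup_codons = min(100, max(35, (length // 2) // 3))
        # read the downstream exon in the host frame so the duplication
        # encodes the same peptide the classifier will compare against
        frame_offset = (3 - ev.site % 3) % 3
        start = ev.site + frame_offset
        max_codons = (len(host_tipseq) - start - 3) // 3  # keep clear of the stop
        dup_codons = min(dup_codons, max_codons)
        seg = host_tipseq[start : start + 3 * dup_codons]
        # the copied segment must be stop-free for aa-level mutation
        seg_codons = [seg[i : i + 3] for i in range(0, len(seg), 3)]
        seg = "".join(c if c not in STOP_CODONS else "TGG" for c in seg_codons)
        pieces.append(aa_analog(seg, ev.ndup_similarity, rng))
        pieces.append("TAATAG")
    if ev.orf_motif:
        pieces.append(_orf_block(rng, ev.orf_motif))
    fixed = sum(len(p) for p in pieces)
    pad = max(30, length - fixed)
    pieces.append(_random_seq(rng, pad, 0.35))
    return "".join(pieces)


def _fix_junctions(intron: str, flank_before: set[str], flank_after: set[str],
                   is_ndup: bool) -> str:
    """Make insertion boundaries slide-free against every carrier's flanks."""
    first, last = intron[0], intron[-1]
    if first in flank_after:
        for b in "GCAT":
            cand = b + intron[1:3]
            if b not in flank_after and not (is_ndup and cand in STOP_CODONS):
                first = b
                break
    if last in flank_before:
        for b in "GCAT":
            if b not in flank_before:
                last = b
                break
    return first + intron[1:-1] + last


def simulate(config: SimConfig) -> tuple[GenomeSet, SimTruth]:
    """Generate the genome set and its ground truth."""
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    tips = sorted(t.taxon.label for t in tree.leaf_node_iter())
    _validate(config, tips)
    rng = np.random.default_rng([config.seed, 2024])
    plan = config.plan
    mult = config.multipliers

    # ancestral parts: one spacer after each gene
    anc: dict[str, str] = {}
    for g in plan.genes:
        if g.gene_type == "CDS":
            anc[g.name] = _random_cds(rng, g.length, plan.gc_genic)
        else:
            anc[g.name] = _random_seq(rng, g.length, plan.gc_genic)
        anc[f"spacer:{g.name}"] = _random_seq(rng, plan.spacer_length, plan.gc_intergenic)

    # homing target sites are conserved exonic context: the two bases on
    # either side of every scripted insertion site never substitute, so
    # scripted boundaries stay alignment-identifiable
    frozen_at: dict[str, np.ndarray] = {}
    for ev in config.intron_events:
        g = plan.gene(ev.host_gene)
        mask = frozen_at.setdefault(ev.host_gene, np.zeros(g.length, dtype=bool))
        lo = max(0, ev.site - 2)
        hi = min(g.length, ev.site + 2)
        mask[lo:hi] = True

    # evolve parts down the tree (preorder; deterministic traversal)
    seqs_at: dict[int, dict[str, str]] = {id(tree.seed_node): anc}
    tip_parts: dict[str, dict[str, str]] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            parent_seqs = anc
        else:
            parent_seqs = seqs_at[id(node.parent_node)]
        if node is not tree.seed_node:
            bl = node.edge.length or 0.0
            evolved = {}
            for g in plan.genes:
                cls = _class_of(g.gene_type)
                frozen = frozen_at.get(g.name)
                if cls == "CDS":
                    evolved[g.name] = _evolve_cds(
                        parent_seqs[g.name], bl * mult["CDS_pos12"], bl * mult["CDS_pos3"],
                        rng, frozen
                    )
                else:
                    evolved[g.name] = _evolve(parent_seqs[g.name], bl * mult[cls], rng, frozen)
                sp = f"spacer:{g.name}"
                evolved[sp] = _evolve(parent_seqs[sp], bl * mult["intergenic"], rng)
            seqs_at[id(node)] = evolved
        if node.is_leaf():
            tip_parts[node.taxon.label] = seqs_at[id(node)]

    # event sequences (one per event, shared across carriers)
    intron_seqs: list[str] = []
    for k, ev in enumerate(config.intron_events):
        ev_rng = np.random.default_rng([config.seed, 7, k])
        host_seq = tip_parts[sorted(ev.carriers)[0]][ev.host_gene]
        seq = _build_intron(ev, host_seq, ev_rng)
        if ev.stage == 2:
            # exonized: in-frame, stop-free, length a multiple of 3
            codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
            seq = "".join(c if c not in STOP_CODONS else "TGG" for c in codons)
        flank_before = {tip_parts[t][ev.host_gene][ev.site - 1] for t in tips}
        flank_after = {tip_parts[t][ev.host_gene][ev.site] for t in tips}
        seq = _fix_junctions(seq, flank_before, flank_after, ev.ndup_similarity is not None)
        if ev.stage == 2:
            codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
            seq = "".join(c if c not in STOP_CODONS else "TGG" for c in codons)
        intron_seqs.append(seq)

    mobile_seqs = [
        _random_seq(np.random.default_rng([config.seed, 11, k]), mv.length, 0.33)
        for k, mv in enumerate(config.mobile_events)
    ]

    # name events the way the caller will: <gene>-i<k> by site order,
    # ties broken by the first (lowest-id) carrier, aliases included
    def _first_carrier(ev: IntronEvent) -> str:
        ids = set(ev.carriers)
        for alias, src in config.duplicate_isolates.items():
            if src in ids:
                ids.add(alias)
        return min(ids)

    event_names: dict[int, str] = {}
    by_gene: dict[str, list[int]] = {}
    for k, ev in enumerate(config.intron_events):
        by_gene.setdefault(ev.host_gene, []).append(k)
    for gene, idxs in by_gene.items():
        for j, k in enumerate(
            sorted(
                idxs,
                key=lambda k: (
                    config.intron_events[k].site,
                    _first_carrier(config.intron_events[k]),
                ),
            ),
            start=1,
        ):
            event_names[k] = f"{gene}-i{j}"

    genomes: list[CircularGenome] = []
    event_recs = []
    region_recs = []
    for tip in tips:
        parts = tip_parts[tip]
        seq_chunks: list[str] = []
        feats: list[GeneLocus] = []
        pos = 0  # 0-based genome offset of the next chunk
        cls_len: dict[str, int] = {
            c: 0
            for c in [
                "CDS_pos12", "CDS_pos3", "tRNA", "rRNA", "ncRNA",
                "intron", "mobile_fragment", "intergenic",
            ]
        }
        for g in plan.genes:
            base = parts[g.name]
            my_events = [
                (k, ev)
                for k, ev in enumerate(config.intron_events)
                if ev.host_gene == g.name and tip in ev.carriers
            ]
            my_events.sort(key=lambda t: t[1].site)
            # build gene-oriented sequence with insertions, tracking exons
            gene_seq = []
            exon_bounds: list[tuple[int, int]] = []  # local 1-based
            intron_bounds: list[tuple[int, int, int]] = []  # (start, end, event idx)
            cursor = 0
            local = 0
            for k, ev in my_events:
                seg = base[cursor : ev.site]
                gene_seq.append(seg)
                exon_bounds.append((local + 1, local + len(seg)))
                local += len(seg)
                ins = intron_seqs[k]
                gene_seq.append(ins)
                if ev.stage == 2:
                    # exonized: the insertion is coding now — merge into the exon
                    s, e = exon_bounds.pop()
                    exon_bounds.append((s, e + len(ins)))
                else:
                    intron_bounds.append((local + 1, local + len(ins), k))
                local += len(ins)
                cursor = ev.site
            seg = base[cursor:]
            gene_seq.append(seg)
            exon_bounds.append((local + 1, local + len(seg)))
            local += len(seg)
            full = "".join(gene_seq)
            # merge adjacent exon bounds created around stage-2 merges
            merged: list[tuple[int, int]] = []
            for s, e in exon_bounds:
                if s > e:
                    continue
                if merged and merged[-1][1] + 1 == s:
                    merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            m = len(full)
            if g.strand == "+":
                exons = [(pos + s, pos + e) for s, e in merged]
            else:
                # transcription order = local order; on '-' that is
                # decreasing genome position
                exons = [(pos + m - e + 1, pos + m - s + 1) for s, e in merged]
            intr = []
            for s, e, k in intron_bounds:
                if g.strand == "+":
                    iv = (pos + s, pos + e)
                else:
                    iv = (pos + m - e + 1, pos + m - s + 1)
                intr.append(iv)
                event_recs.append(
                    {
                        "event": event_names[k],
                        "host_gene": g.name,
                        "isolate_id": tip,
                        "site": config.intron_events[k].site,
                        "length": e - s + 1,
                        "genome_start": iv[0],
                        "genome_end": iv[1],
                    }
                )
            feats.append(
                GeneLocus(
                    gene_name=g.name,
                    gene_type=g.gene_type,
                    strand=g.strand,
                    exons=exons,
                    introns=intr,
                )
            )
            seq_chunks.append(full if g.strand == "+" else revcomp(full))
            # region truth
            exonic = sum(e - s + 1 for s, e in merged)
            intron_total = sum(e - s + 1 for s, e, _ in intron_bounds)
            if g.gene_type == "CDS":
                cls_len["CDS_pos12"] += exonic // 3 * 2
                cls_len["CDS_pos3"] += exonic // 3
            else:
                cls_len[_class_of(g.gene_type)] += exonic
            cls_len["intron"] += intron_total
            pos += m
            # spacer after the gene (with mobile insertions)
            spacer = parts[f"spacer:{g.name}"]
            for k, mv in enumerate(config.mobile_events):
                if mv.left_gene == g.name and tip in mv.carriers:
                    mid = len(spacer) // 2
                    frag = mobile_seqs[k]
                    event_recs.append(
                        {
                            "event": mv.name,
                            "host_gene": "",
                            "isolate_id": tip,
                            "site": 0,
                            "length": len(frag),
                            "genome_start": pos + mid + 1,
                            "genome_end": pos + mid + len(frag),
                        }
                    )
                    spacer = spacer[:mid] + frag + spacer[mid:]
                    cls_len["mobile_fragment"] += len(frag)
            cls_len["intergenic"] += len(spacer) - sum(
                len(mobile_seqs[k])
                for k, mv in enumerate(config.mobile_events)
                if mv.left_gene == g.name and tip in mv.carriers
            )
            seq_chunks.append(spacer)
            pos += len(spacer)
        genome = CircularGenome(
            isolate_id=tip, sequence="".join(seq_chunks), topology="circular", features=feats
        )
        genomes.append(genome)
        region_recs.append({"isolate_id": tip, **cls_len, "genome_size": genome.length})

    # expand duplicate isolates
    all_ids = list(tips)
    for alias, src in sorted(config.duplicate_isolates.items()):
        srcg = next(g for g in genomes if g.isolate_id == src)
        genomes.append(replace(srcg, isolate_id=alias))
        all_ids.append(alias)
    genomes.sort(key=lambda g: g.isolate_id)
    all_ids.sort()

    # presence matrix (aliases expanded)
    alias_of: dict[str, list[str]] = {t: [t] for t in tips}
    for alias, src in config.duplicate_isolates.items():
        alias_of[src].append(alias)
    cols: dict[str, set[str]] = {}
    for k, ev in enumerate(config.intron_events):
        cols[event_names[k]] = {a for c in ev.carriers for a in alias_of[c]}
    for mv in config.mobile_events:
        cols[mv.name] = {a for c in mv.carriers for a in alias_of[c]}
    presence = pd.DataFrame(
        {name: [int(i in s) for i in all_ids] for name, s in cols.items()},
        index=pd.Index(all_ids, name="isolate_id"),
    )

    # realized diversity truth vs the reference tip (the TF04-series
    # representative when present, matching the analysis default)
    ref_tip = "TF04" if "TF04" in tips else tips[0]
    div_recs = []
    for tip in tips:
        counts = {c: [0, 0] for c in ["CDS_pos12", "CDS_pos3", "tRNA", "rRNA", "intergenic"]}
        for g in plan.genes:
            a, b = tip_parts[ref_tip][g.name], tip_parts[tip][g.name]
            if g.gene_type == "CDS":
                for i, (x, y) in enumerate(zip(a, b)):
                    cls = "CDS_pos12" if i % 3 < 2 else "CDS_pos3"
                    counts[cls][0] += 1
                    counts[cls][1] += x != y
            elif g.gene_type in ("tRNA", "rRNA"):
                counts[g.gene_type][0] += len(a)
                counts[g.gene_type][1] += sum(x != y for x, y in zip(a, b))
            sa, sb = tip_parts[ref_tip][f"spacer:{g.name}"], tip_parts[tip][f"spacer:{g.name}"]
            counts["intergenic"][0] += len(sa)
            counts["intergenic"][1] += sum(x != y for x, y in zip(sa, sb))
        for cls, (ncol, nsnp) in counts.items():
            div_recs.append(
                {
                    "isolate_id": tip,
                    "region_class": cls,
                    "compared_columns": ncol,
                    "snp_count": nsnp,
                    "snps_per_kb": 1000.0 * nsnp / ncol if ncol else float("nan"),
                }
            )

    truth = SimTruth(
        events=pd.DataFrame.from_records(event_recs),
        presence=presence,
        region_lengths=pd.DataFrame.from_records(region_recs).set_index("isolate_id"),
        diversity=pd.DataFrame.from_records(div_recs).set_index(["isolate_id", "region_class"]),
        reference_isolate=ref_tip,
        event_names=event_names,
    )
    return GenomeSet(genomes=genomes, panel=default_panel()), truth


# -- the default genome plan and the headline scenario ----------------------

_CDS_LENGTHS = {
    "atp6": 750, "atp8": 150, "atp9": 225, "cob": 1140, "cox1": 1500,
    "cox2": 750, "cox3": 810, "nad1": 960, "nad2": 1500, "nad3": 360,
    "nad4": 1440, "nad4L": 270, "nad5": 1980, "nad6": 600, "rps3": 1200,
}
_MINUS_STRAND = {"cox3", "trnR1", "rps3", "rnpB", "trnM1", "atp9"}

#: gene order of the default plan: tRNA clusters between nad6/cox3 and
#: nad4/cob, trnG immediately after trnR1 and atp9 after nad3 so the two
#: canonical mobile-fragment sites exist.
_DEFAULT_ORDER = [
    "cox1", "trnY", "cox2", "trnL1", "nad1", "trnQ", "nad2", "trnW", "nad6",
    # nine tRNAs between nad6 and cox3
    "trnA", "trnD", "trnE", "trnF", "trnH", "trnI", "trnK", "trnL2", "trnM2",
    "cox3", "rns", "trnR1", "trnG", "rnl", "rps3", "rnpB", "nad3", "atp9",
    "nad4L", "nad4",
    # four tRNAs between nad4 and cob
    "trnM1", "trnN", "trnP", "trnR2",
    "cob", "trnS1", "nad5", "trnS2", "trnT", "atp6", "trnV", "atp8",
]


def default_plan(spacer_length: int = 120) -> GenomePlan:
    genes = []
    for name in _DEFAULT_ORDER:
        if name in _CDS_LENGTHS:
            genes.append(PlanGene(name, "CDS", "-" if name in _MINUS_STRAND else "+",
                                  _CDS_LENGTHS[name]))
        elif name == "rnl":
            genes.append(PlanGene(name, "rRNA", "+", 2500))
        elif name == "rns":
            genes.append(PlanGene(name, "rRNA", "+", 1200))
        elif name == "rnpB":
            genes.append(PlanGene(name, "ncRNA", "-", 300))
        else:
            genes.append(PlanGene(name, "tRNA", "-" if name in _MINUS_STRAND else "+", 72))
    assert len(genes) == 41
    return GenomePlan(genes=genes, spacer_length=spacer_length)


#: the ten distinct mtDNA sequences among the sixteen isolates
DISTINCT_ISOLATES = [
    "TF01", "TF04", "TF05", "TF06", "TF07", "TF08", "TF09", "TF11", "TF12", "TF15",
]
DUPLICATE_ISOLATES = {
    "TF02": "TF04", "TF03": "TF04", "TF10": "TF04", "TF13": "TF04", "TF16": "TF04",
    "TF14": "TF11",
}

DEFAULT_TREE = (
    "((((TF04:0.004,TF12:0.004):0.004,TF05:0.008):0.003,"
    "(TF09:0.008,(TF06:0.006,TF07:0.006):0.004):0.003):0.004,"
    "((TF11:0.008,TF15:0.008):0.004,(TF01:0.009,TF08:0.012):0.004):0.004);"
)


def sim_config_from_yaml(text: str, seed: int | None = None) -> SimConfig:
    """Build a SimConfig from a YAML document.

    Recognized keys: seed, tree (newick), spacer_length, multipliers,
    intron_events, mobile_events, duplicate_isolates; the gene plan is
    the default 41-gene backbone (a custom plan is library-level API).
    """
    import yaml

    doc = yaml.safe_load(text) or {}
    plan = default_plan(spacer_length=int(doc.get("spacer_length", 120)))
    events = [IntronEvent(**e) for e in doc.get("intron_events", [])]
    mobiles = [MobileEvent(**m) for m in doc.get("mobile_events", [])]
    mult = dict(DEFAULT_MULTIPLIERS)
    mult.update(doc.get("multipliers", {}))
    return SimConfig(
        seed=int(seed if seed is not None else doc.get("seed", 0)),
        tree=doc.get("tree", DEFAULT_TREE),
        plan=plan,
        multipliers=mult,
        intron_events=events,
        mobile_events=mobiles,
        duplicate_isolates=dict(doc.get("duplicate_isolates", {})),
    )


def headline_scenario(seed: int = 1, divergence_scale: float = 1.0) -> SimConfig:
    """A 16-isolate scenario scripted to the headline structure of the study:

    24 intron events (11 in protein-coding genes, 3 in tRNAs, 10 in
    rRNAs — nine of them in rnl over six sites, three of which host two
    unrelated introns), two intergenic mobile fragments, six N-dup
    introns, and six duplicate isolates. Per-isolate element counts span
    1..15 and no element is universal.
    """
    tree = DEFAULT_TREE
    if divergence_scale != 1.0:
        import re as _re

        tree = _re.sub(
            r":([0-9.]+)", lambda m: f":{float(m.group(1)) * divergence_scale:.6f}", tree
        )
    A = ["TF04", "TF12", "TF05"]
    B = ["TF06", "TF07", "TF09"]
    C = ["TF11", "TF15"]
    D = ["TF01", "TF08"]
    ev = [
        # 11 CDS introns; six carry N-terminal duplications
        IntronEvent("cox1", 390, 900, B + ["TF08"]),
        IntronEvent("cox1", 702, 1100, C + ["TF05"], ndup_similarity=0.80),
        IntronEvent("cox2", 300, 700, A + ["TF08"]),
        IntronEvent("cox2", 511, 800, D, orf_motif="LAGLIDADG"),
        IntronEvent("cob", 240, 850, B),
        IntronEvent("cob", 600, 1200, C + ["TF08"], ndup_similarity=0.80),
        IntronEvent("nad4", 450, 2100, ["TF11", "TF15"], ndup_similarity=0.725),
        IntronEvent("nad4", 900, 2200, ["TF05", "TF07"], ndup_similarity=0.81,
                    orf_motif="LAGLIDADG"),
        IntronEvent("nad3", 180, 1000, ["TF08"], ndup_similarity=0.80),
        IntronEvent("nad5", 750, 1300, ["TF05", "TF06", "TF08"], ndup_similarity=0.80),
        IntronEvent("cox3", 405, 700, A + B + ["TF08"]),
        # 3 tRNA introns
        IntronEvent("trnL1", 35, 350, B),
        IntronEvent("trnI", 38, 400, ["TF11", "TF15"]),
        IntronEvent("trnP", 30, 600, ["TF05", "TF06", "TF08"], orf_motif="GIY-YIG"),
        # 10 rRNA introns: nine in rnl over six sites, one in rns
        IntronEvent("rnl", 547, 500, A + ["TF08"]),
        IntronEvent("rnl", 772, 450, B),
        IntronEvent("rnl", 1753, 288, ["TF04", "TF12"]),
        IntronEvent("rnl", 1753, 803, C, orf_motif="LAGLIDADG"),
        IntronEvent("rnl", 2239, 420, ["TF05", "TF08"]),
        IntronEvent("rnl", 2239, 700, ["TF06", "TF07"], orf_motif="LAGLIDADG"),
        IntronEvent("rnl", 2301, 260, ["TF08", "TF11", "TF15"]),
        IntronEvent("rnl", 2397, 240, ["TF08"]),
        IntronEvent("rnl", 2397, 550, ["TF05", "TF09"]),
        IntronEvent("rns", 600, 800, ["TF08", "TF07"]),
    ]
    mobiles = [
        MobileEvent("trnR1", "trnG", 1864, A + B + ["TF11", "TF15", "TF08"]),
        MobileEvent("nad3", "atp9", 2684, A + C + ["TF09", "TF08"]),
    ]
    return SimConfig(
        seed=seed,
        tree=tree,
        plan=default_plan(),
        intron_events=ev,
        mobile_events=mobiles,
        duplicate_isolates=dict(DUPLICATE_ISOLATES),
    )
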