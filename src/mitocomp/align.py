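"""Shared pairwise/multiple alignment helpers.

Nucleotide alignments use EDNAFULL-like affine scoring (match +5,
mismatch -4, gap open 10, gap extend 0.5); peptide alignments use
BLOSUM62 with BLAST-like gap costs. Multiple peptide alignment shells
out to mafft when available, with a reference-anchored fallback that is
adequate for the near-identical intra-specific sequences this package
targets.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def nt_aligner(mode: str = "global") -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.match_score = 5
    a.mismatch_score = -4
    a.open_gap_score = -10
    a.extend_gap_score = -0.5
    return a


def aa_aligner(mode: str = "global") -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.substitution_matrix = _BLOSUM62
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def align_pair(ref: str, qry: str, aligner: Align.PairwiseAligner | None = None):
    aligner = aligner or nt_aligner()
    return aligner.align(ref, qry)[0]


@dataclass
class Insertion:
    """A contiguous block present in the query but absent from the reference."""

    ref_site: int  # 1-based ref position after which the block sits (0 = before ref)
    qry_start: int  # 1-based, inclusive, in query coordinates
    qry_end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.qry_end - self.qry_start + 1


def find_insertions(ref: str, qry: str, min_length: int = 1) -> list[Insertion]:
    """Insertions in ``qry`` relative to ``ref`` from one global affine alignment.

    Within an exact-repeat ambiguity window each insertion is left-aligned.
    """
    aln = align_pair(ref, qry)
    ref_blocks, qry_blocks = aln.aligned
    out: list[Insertion] = []
    prev_r_end = 0
    prev_q_end = 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, qry_blocks):
        if qs > prev_q_end and rs == prev_r_end:
            seq = qry[prev_q_end:qs]
            if len(seq) >= min_length:
                out.append(Insertion(prev_r_end, prev_q_end + 1, qs, seq))
        elif qs > prev_q_end and rs > prev_r_end:
            # substitution-adjacent indel: treat the unaligned query run as
            # an insertion after the last aligned ref base
            seq = qry[prev_q_end:qs]
            if len(seq) >= min_length:
                out.append(Insertion(rs, prev_q_end + 1, qs, seq))
        prev_r_end, prev_q_end = re_, qe
    if len(qry) > prev_q_end:
        seq = qry[prev_q_end:]
        if len(seq) >= min_length:
            out.append(Insertion(prev_r_end, prev_q_end + 1, len(qry), seq))
    return [left_align(ins, ref, qry) for ins in out]


def left_align(ins: Insertion, ref: str, qry: str) -> Insertion:
    """Slide an insertion as far left as sequence identity permits.

    The total slide range (left + right) is the ambiguity window; callers
    that need it can recompute it with :func:`ambiguity_window`.
    """
    site, qs, qe = ins.ref_site, ins.qry_start, ins.qry_end
    seq = list(ins.sequence)
    while site > 0 and seq[-1] == ref[site - 1]:
        seq = [seq[-1]] + seq[:-1]
        site -= 1
        qs -= 1
        qe -= 1
    return Insertion(site, qs, qe, "".join(seq))


def ambiguity_window(ins: Insertion, ref: str) -> int:
    """Number of alternative placements of a (left-aligned) insertion."""
    w = 0
    site = ins.ref_site
    seq = list(ins.sequence)
    while site < len(ref) and seq[0] == ref[site]:
        seq = seq[1:] + [seq[0]]
        site += 1
        w += 1
    return w


def sequence_identity(a: str, b: str) -> float:
    """Global edit-distance identity: 1 - d / max(len).

    Fast (edlib) and adequate for thresholding family membership.
    """
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def aligned_identity_similarity(pep_a: str, pep_b: str) -> tuple[float, float, int, tuple[int, int]]:
    """Global BLOSUM62 alignment of two peptides.

    Returns (identity, similarity, aligned_columns, (a_start, a_end)) where
    identity is exact matches / aligned columns, similarity the fraction of
    columns with a positive BLOSUM62 score, terminal gaps excluded from the
    denominator, and (a_start, a_end) the 0-based half-open span of pep_a
    covered by the alignment core.
    """
    if not pep_a or not pep_b:
        return 0.0, 0.0, 0, (0, 0)
    aln = aa_aligner().align(pep_a, pep_b)[0]
    a_blocks, b_blocks = aln.aligned
    if len(a_blocks) == 0:
        return 0.0, 0.0, 0, (0, 0)
    ncol = 0
    matches = 0
    positives = 0
    # columns strictly inside the aligned core (terminal gaps excluded);
    # internal gaps count as columns with no match/positive credit
    core_a = (a_blocks[0][0], a_blocks[-1][1])
    prev_a = prev_b = None
    for (as_, ae), (bs, be) in zip(a_blocks, b_blocks):
        if prev_a is not None:
            ncol += (as_ - prev_a) + (bs - prev_b)
        for i, j in zip(range(as_, ae), range(bs, be)):
            ncol += 1
            ca, cb = pep_a[i], pep_b[j]
            if ca == cb:
                matches += 1
            try:
                score = _BLOSUM62[ca, cb]
            except (KeyError, IndexError):
                score = -4
            if score > 0:
                positives += 1
        prev_a, prev_b = ae, be
    if ncol == 0:
        return 0.0, 0.0, 0, (0, 0)
    return matches / ncol, positives / ncol, ncol, core_a


def _mafft_available() -> bool:
    return shutil.which("mafft") is not None


def multiple_align(seqs: dict[str, str], protein: bool = True) -> dict[str, str]:
    """Multiple sequence alignment preserving input order.

    Uses mafft when present; otherwise anchors every sequence to the first
    by pairwise alignment and merges gap columns (sufficient for the
    nearly identical sequences of an intra-specific panel).
    """
    ids = list(seqs)
    if len(ids) == 1:
        return dict(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) == 1:
        # equal lengths: near-identical intra-specific case, align as-is
        return dict(seqs)
    if _mafft_available():
        return _mafft(seqs)
    return _reference_anchored_msa(seqs, protein)


def _mafft(seqs: dict[str, str]) -> dict[str, str]:
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fa"
        with open(fin, "w") as fh:
            for k, v in seqs.items():
                fh.write(f">{k}\n{v}\n")
        res = subprocess.run(
            ["mafft", "--auto", "--quiet", "--anysymbol", str(fin)],
            capture_output=True,
            text=True,
            check=True,
        )
        out = {}
        with tempfile.NamedTemporaryFile("w+", suffix=".fa", dir=tmp, delete=False) as fo:
            fo.write(res.stdout)
            fo.flush()
            for rec in SeqIO.parse(fo.name, "fasta"):
                out[rec.id] = str(rec.seq).upper()
    return {k: out[k] for k in seqs}


def _reference_anchored_msa(seqs: dict[str, str], protein: bool) -> dict[str, str]:
    ids = list(seqs)
    ref = seqs[ids[0]]
    aligner = aa_aligner() if protein else nt_aligner()
    # per-sequence: map ref positions -> (gaps before ref column, residue)
    pads = np.zeros(len(ref) + 1, dtype=int)  # max insertion length before each ref col
    rows = {}
    for k in ids[1:]:
        aln = aligner.align(ref, seqs[k])[0]
        r_blocks, q_blocks = aln.aligned
        cells: list[tuple[int, str]] = []  # (ref column 0-based or -1 for pre, char)
        prev_r = prev_q = 0
        ins_at: dict[int, str] = {}
        for (rs, re_), (qs, qe) in zip(r_blocks, q_blocks):
            if qs > prev_q:
                ins_at[rs] = seqs[k][prev_q:qs]
            prev_q = qe
            prev_r = re_
            for i, j in zip(range(rs, re_), range(qs, qe)):
                cells.append((i, seqs[k][j]))
        if len(seqs[k]) > prev_q:
            ins_at[len(ref)] = seqs[k][prev_q:]
        rows[k] = (dict(cells), ins_at)
        for col, s in ins_at.items():
            pads[col] = max(pads[col], len(s))
    out = {}
    # build ref row
    ref_row = []
    for col in range(len(ref) + 1):
        ref_row.append("-" * pads[col])
        if col < len(ref):
            ref_row.append(ref[col])
    out[ids[0]] = "".join(ref_row)
    for k in ids[1:]:
        cells, ins_at = rows[k]
        row = []
        for col in range(len(ref) + 1):
            ins = ins_at.get(col, "")
            row.append(ins + "-" * (pads[col] - len(ins)))
            if col < len(ref):
                row.append(cells.get(col, "-"))
        out[k] = "".join(row)
    return {k: out[k] for k in seqs}
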