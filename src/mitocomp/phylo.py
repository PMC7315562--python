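"""Concatenated protein alignment and a plumbing NJ tree.

The tree orders the presence/absence landscape; it is deliberately a
simple neighbor-joining tree on p-distances. The concatenated alignment
is exported in FASTA and relaxed-PHYLIP for external maximum-likelihood
tools, which remain out of scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .align import multiple_align
from .harmonize import LocusTable
from .panel import PHYLO_GENES

log = logging.getLogger(__name__)


@dataclass
class ConcatAlignment:
    isolates: list[str]
    blocks: dict[str, dict[str, str]]  # gene -> isolate -> aligned peptide
    matrix: dict[str, str]  # isolate -> concatenated row

    @property
    def total_columns(self) -> int:
        return len(next(iter(self.matrix.values()))) if self.matrix else 0

    def block_widths(self) -> dict[str, int]:
        return {g: len(next(iter(b.values()))) for g, b in self.blocks.items()}

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for iso in self.isolates:
                fh.write(f">{iso}\n{self.matrix[iso]}\n")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f" {len(self.isolates)} {self.total_columns}\n")
            for iso in self.isolates:
                fh.write(f"{iso}  {self.matrix[iso]}\n")


def concat_align(table: LocusTable, genes: list[str] | None = None) -> ConcatAlignment:
    """Per-gene multiple peptide alignments, concatenated in fixed gene order.

    An isolate missing a gene receives an all-gap block (with a warning).
    """
    genes = list(genes) if genes is not None else list(PHYLO_GENES)
    isolates = table.isolates
    blocks: dict[str, dict[str, str]] = {}
    for gene in genes:
        peps = {}
        for iso in isolates:
            try:
                row = table.get(iso, gene)
                if row.peptide:
                    peps[iso] = row.peptide
            except KeyError:
                pass
        if not peps:
            log.warning("gene %s has no peptides in any isolate; block skipped", gene)
            continue
        aligned = multiple_align(peps, protein=True)
        width = len(next(iter(aligned.values())))
        block = {}
        for iso in isolates:
            if iso in aligned:
                block[iso] = aligned[iso]
            else:
                log.warning("%s missing %s: all-gap block", iso, gene)
                block[iso] = "-" * width
        blocks[gene] = block
    matrix = {iso: "".join(blocks[g][iso] for g in blocks) for iso in isolates}
    return ConcatAlignment(isolates=isolates, blocks=blocks, matrix=matrix)


def p_distance_matrix(aln: ConcatAlignment) -> DistanceMatrix:
    """Pairwise p-distances; gap columns are excluded pairwise."""
    ids = sorted(aln.isolates)
    k = len(ids)
    rows = [np.frombuffer(aln.matrix[i].encode(), dtype="S1") for i in ids]
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = rows[i], rows[j]
            ok = (a != b"-") & (b != b"-") & (a != b"X") & (b != b"X")
            n = int(ok.sum())
            d = float((a[ok] != b[ok]).mean()) if n else 0.0
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids)


def nj_tree(aln: ConcatAlignment, outgroup: str | None = None) -> str:
    """Neighbor-joining newick string; deterministic given the isolate set."""
    if len(aln.isolates) < 3:
        raise ValueError(">=3 isolates required for a tree")
    dm = p_distance_matrix(aln)
    tree = _skbio_nj(dm)
    if outgroup is not None:
        tip = tree.find(outgroup)
        tree = tree.root_at(tip.parent)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0  # NJ can emit tiny negative branches
    return str(tree).strip()


def tree_leaf_order(newick: str) -> list[str]:
    """Leaf names in tree traversal order (for ordering landscape rows)."""
    from skbio import TreeNode
    import io

    tree = TreeNode.read(io.StringIO(newick))
    return [t.name for t in tree.tips()]
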