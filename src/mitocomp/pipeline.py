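"""End-to-end orchestration: harmonize -> partition -> introns/mobile ->
families -> N-dup survey -> diversity -> landscape -> tree.

The report bundle mirrors the study's result sections: a complement
report, region/GC tables, intron calls and families, mobile fragments,
the N-dup survey, the per-class diversity table, the presence/absence
landscape ordered by a plumbing NJ tree, and a summary with the headline
counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diversity as diversity_mod
from . import introns as introns_mod
from . import ndup as ndup_mod
from . import phylo as phylo_mod
from . import regions as regions_mod
from .genome_io import CircularGenome, GenomeSet, read_genbank
from .harmonize import LocusTable, harmonize

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    inputs: list[str] = field(default_factory=list)  # GenBank paths
    reference_isolate: str | None = None  # default: TF04-series, else first id
    anchor_gene: str = "cox1"
    translation_table: int = 4
    min_intron_length: int = introns_mod.MIN_INTRON_LENGTH
    min_mobile_length: int = introns_mod.MIN_MOBILE_LENGTH
    site_tolerance: int = introns_mod.SITE_TOLERANCE
    family_identity: float = introns_mod.SAME_FAMILY_IDENTITY
    ndup_threshold: float = ndup_mod.CALL_THRESHOLD
    min_orf_aa: int = 50
    outgroup: str | None = None
    seed: int = 0
    outdir: str | None = None


@dataclass
class PipelineReport:
    locus_table: LocusTable
    region_table: pd.DataFrame
    gc_test: regions_mod.GcTestReport | None
    intron_calls: list[introns_mod.IntronCall]
    families: list[introns_mod.IntronFamily]
    mobile_fragments: list[introns_mod.MobileFragment]
    landscape: introns_mod.Landscape
    ndup_table: pd.DataFrame
    diversity: diversity_mod.DiversityTable
    isolate_ranking: list[str]
    tree_newick: str | None
    alignment: phylo_mod.ConcatAlignment | None
    summary: dict
    warnings: list[str]


def _default_reference(isolates: list[str]) -> str:
    for iso in isolates:
        if iso.upper() == "TF04":
            return iso
    return sorted(isolates)[0]


def run_pipeline(config: RunConfig, genome_set: GenomeSet | None = None) -> PipelineReport:
    """Run every stage on a genome set (loaded from config.inputs if not given)."""
    warnings_acc: list[str] = []
    if genome_set is None:
        genomes = [read_genbank(p) for p in config.inputs]
        genome_set = GenomeSet(genomes=genomes)
    if len(genome_set) < 2:
        raise ValueError(">=2 genomes required")
    genomes_by_id: dict[str, CircularGenome] = {
        g.isolate_id: g for g in genome_set.genomes
    }

    table = harmonize(genome_set)
    if len(table.complement_report):
        warnings_acc.append(
            f"complement deviations: {len(table.complement_report)} (see report)"
        )

    calls = introns_mod.call_all_introns(
        table, genomes_by_id, min_intron_length=config.min_intron_length
    )
    introns_mod.annotate_orfs(calls, config.min_orf_aa)
    families = introns_mod.cluster_families(
        calls,
        table,
        site_tolerance=config.site_tolerance,
        same_family_identity=config.family_identity,
    )
    mobiles = introns_mod.call_mobile_fragments(
        genome_set, table, min_mobile_length=config.min_mobile_length
    )

    rmaps = {}
    for g in genome_set.genomes:
        own_calls = [c for c in calls if c.isolate_id == g.isolate_id]
        own_mob = [m for m in mobiles if m.isolate_id == g.isolate_id]
        loci = [r.locus for (iso, _), r in table.rows.items() if iso == g.isolate_id]
        rmaps[g.isolate_id] = regions_mod.partition(g, own_calls, own_mob, loci=loci)
    region_tbl = regions_mod.region_table(rmaps, genomes_by_id)

    gc_test = None
    gc_cols = [f"gc_{c}" for c in regions_mod.GC_TEST_CLASSES]
    gc_table = region_tbl[gc_cols].rename(columns=lambda c: c[3:])
    if len(gc_table) >= 3:
        try:
            gc_test = regions_mod.class_gc_difference_test(gc_table)
        except ValueError as exc:
            warnings_acc.append(f"GC class test skipped: {exc}")

    ndup_table = ndup_mod.ndup_survey(
        families, table, calls,
        translation_table=config.translation_table,
        call_threshold=config.ndup_threshold,
    )

    reference = config.reference_isolate or _default_reference(table.isolates)
    spans = {
        g.isolate_id: introns_mod.intergenic_spans(g, table) for g in genome_set.genomes
    }
    div = diversity_mod.snps_per_kb(
        table, reference, intron_calls=calls, intergenic_spans=spans, mobile=mobiles
    )
    ranking = diversity_mod.rank_isolates(div)

    tree_newick = None
    alignment = None
    isolates = table.isolates
    if len(isolates) >= 3:
        alignment = phylo_mod.concat_align(table)
        tree_newick = phylo_mod.nj_tree(alignment, outgroup=config.outgroup)
        leaf_order = [x for x in phylo_mod.tree_leaf_order(tree_newick) if x in isolates]
    else:
        leaf_order = isolates
    scape = introns_mod.landscape(families, leaf_order, mobiles)

    cds_fams = [f for f in families if f.host_gene_type == "CDS"]
    trna_fams = [f for f in families if f.host_gene_type == "tRNA"]
    rrna_fams = [f for f in families if f.host_gene_type == "rRNA"]
    ndup_pos = (
        ndup_table.drop_duplicates("family_id")
        if len(ndup_table)
        else ndup_table
    )
    n_ndup = int((ndup_pos["family_call"] == "D-type").sum()) if len(ndup_pos) else 0
    summary = {
        "n_isolates": len(isolates),
        "n_intron_families": len(families),
        "n_cds_intron_families": len(cds_fams),
        "n_trna_intron_families": len(trna_fams),
        "n_rrna_intron_families": len(rrna_fams),
        "n_mobile_fragment_sites": len({m.name for m in mobiles}),
        "n_ndup_positive_families": n_ndup,
        "per_isolate_element_counts": scape.per_isolate_counts.to_dict(),
        "element_count_min": int(scape.per_isolate_counts.min()) if len(scape.matrix.columns) else 0,
        "element_count_max": int(scape.per_isolate_counts.max()) if len(scape.matrix.columns) else 0,
        "mean_gc_overall": float(region_tbl["gc_overall"].mean()),
        "reference_isolate": reference,
        "isolate_ranking_low_to_high": ranking,
    }
    report = PipelineReport(
        locus_table=table,
        region_table=region_tbl,
        gc_test=gc_test,
        intron_calls=calls,
        families=families,
        mobile_fragments=mobiles,
        landscape=scape,
        ndup_table=ndup_table,
        diversity=div,
        isolate_ranking=ranking,
        tree_newick=tree_newick,
        alignment=alignment,
        summary=summary,
        warnings=warnings_acc,
    )
    if config.outdir:
        write_report(report, config, Path(config.outdir))
    return report


def calls_frame(calls: list[introns_mod.IntronCall]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "isolate_id": c.isolate_id,
                "host_gene": c.host_gene,
                "insertion_site": c.insertion_site,
                "genome_start": c.genome_interval[0],
                "genome_end": c.genome_interval[1],
                "length": c.length,
                "ambiguity_window": c.ambiguity_window,
                "orf_motifs": ",".join(sorted({o.motif_label for o in c.orfs} - {"none"})),
                "n_orfs": len(c.orfs),
            }
            for c in sorted(calls, key=lambda c: (c.host_gene, c.insertion_site, c.isolate_id))
        ],
        columns=[
            "isolate_id", "host_gene", "insertion_site", "genome_start",
            "genome_end", "length", "ambiguity_window", "orf_motifs", "n_orfs",
        ],
    )


def families_frame(families: list[introns_mod.IntronFamily]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "family_id": f.family_id,
                "host_gene": f.host_gene,
                "host_gene_type": f.host_gene_type,
                "insertion_site": f.insertion_site,
                "frequency": f.frequency,
                "carriers": ",".join(f.carriers),
                "median_length": int(pd.Series([m.length for m in f.members]).median()),
            }
            for f in families
        ],
        columns=[
            "family_id", "host_gene", "host_gene_type", "insertion_site",
            "frequency", "carriers", "median_length",
        ],
    )


def mobiles_frame(mobiles: list[introns_mod.MobileFragment]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "name": m.name,
                "isolate_id": m.isolate_id,
                "genome_start": m.genome_interval[0],
                "genome_end": m.genome_interval[1],
                "length": m.length,
            }
            for m in sorted(mobiles, key=lambda m: (m.name, m.isolate_id))
        ],
        columns=["name", "isolate_id", "genome_start", "genome_end", "length"],
    )


_TSV_HEADER = "# mitocomp v0.1 table\n"


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        df.to_csv(fh, sep="\t", index=index)


def write_report(report: PipelineReport, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(report.locus_table.to_frame(), outdir / "locus_table.tsv")
    _write_tsv(report.locus_table.complement_report, outdir / "complement_report.tsv")
    _write_tsv(report.region_table, outdir / "region_table.tsv", index=True)
    if report.gc_test is not None:
        _write_tsv(report.gc_test.pairwise, outdir / "gc_class_test.tsv")
    _write_tsv(calls_frame(report.intron_calls), outdir / "intron_calls.tsv")
    _write_tsv(families_frame(report.families), outdir / "intron_families.tsv")
    _write_tsv(mobiles_frame(report.mobile_fragments), outdir / "mobile_fragments.tsv")
    _write_tsv(report.ndup_table, outdir / "ndup_survey.tsv")
    _write_tsv(report.diversity.table.reset_index(), outdir / "diversity.tsv")
    _write_tsv(report.landscape.matrix, outdir / "presence_matrix.tsv", index=True)
    if report.tree_newick:
        (outdir / "tree.nwk").write_text(report.tree_newick + "\n")
    if report.alignment is not None:
        report.alignment.to_fasta(outdir / "concat_alignment.fasta")
        report.alignment.to_phylip(outdir / "concat_alignment.phy")
    (outdir / "summary.json").write_text(json.dumps(report.summary, indent=2, sort_keys=True) + "\n")
    (outdir / "run_config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))
    if len(report.landscape.matrix.columns):
        plot_landscape(report.landscape, outdir / "presence_matrix.png")


def plot_landscape(scape: introns_mod.Landscape, path: Path) -> None:
    """Presence/absence matrix figure: isolates x elements, stars for presence."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = scape.matrix
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.35 * len(mat.columns) + 2), max(3.0, 0.3 * len(mat) + 1.5))
    )
    ys, xs = (mat.values == 1).nonzero()
    ax.scatter(xs, ys, marker="*", s=80, color="tab:blue")
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(mat)), mat.index, fontsize=7)
    ax.invert_yaxis()
    ax.set_xlim(-0.5, len(mat.columns) - 0.5)
    ax.set_title("Intron / mobile-fragment landscape")
    for x, freq in enumerate(scape.per_element_frequency):
        ax.annotate(str(freq), (x, len(mat) - 0.3), ha="center", fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_region_bed(rmap: regions_mod.RegionMap, path: Path) -> None:
    """BED export of a region map (0-based half-open at the boundary only)."""
    import numpy as np

    labels = rmap.labels
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                cls = regions_mod.CLASSES[labels[start]]
                fh.write(f"{rmap.isolate_id}\t{start}\t{i}\t{cls}\n")
                start = i
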