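# Methods

## The comparison model

The package assumes a set of circular mitochondrial genomes from one
species that share a conserved gene complement and gene order, so that
every inter-isolate length difference inside a gene is an insertion or
deletion of mobile content rather than a rearrangement. All coordinates
are 1-based inclusive; circular genomes admit wrap-around intervals
(`start > end`); minus-strand loci are stored in genome coordinates with
exons in transcription order. Translation uses the mold-mitochondrial
code (table 4, stops TAA/TAG) by default, overridable per run — the
standard assumption for fungal mtDNA. The canonical rotation anchor is
`cox1` (arbitrary but fixed). `N` bases are tolerated but excluded from
every GC and SNP denominator.

## Locating and harmonizing the panel

The bundled panel is the 41-gene roster (15 CDS, *rns*, *rnl*, *rnpB*,
23 tRNAs: every standard amino acid except Cys, with Leu/Met/Arg/Ser
doubled). Annotated features are mapped onto it by normalized name
(case-insensitive, Roman subunit numerals arabicized). Panel genes
missing from an annotation are located by local nucleotide alignment of
a reference sequence against the doubled genome (circularity) and its
reverse complement; acceptance thresholds are deliberately loose
(CDS ≥ 60 % coverage at ≥ 40 % identity, non-coding ≥ 70 %/≥ 70 %)
because intra-specific divergence is tiny. The panel ships names and
types only; references are attached at run time from an annotated
isolate or from simulator output. Missing/extra genes are reported, not
fatal. Gene-order signatures are the lexicographically minimal rotation
of the (name, strand) circle, compared also after full reverse
complement, so they are rotation- and flip-invariant.

## Intron calling

For each gene the shortest intra-specific copy is the intron-free
reference (shorter homologs, not predictions, define "intron-free" —
the same logic that exposes tRNA introns invisible to annotation
software). Each longer copy is globally aligned to it with affine
scoring (match +5, mismatch −4, gap open 10, gap extend 0.5 —
EDNAFULL-like defaults); contiguous insertions ≥ `min_intron_length`
(50 bp, separating introns from indel noise) become calls. Group I
introns carry no GT–AG signal, so boundary placement relies entirely on
exon conservation: within an exact-repeat window at the junction the
placement is ambiguous; insertions are left-aligned (VCF-style) and the
window size recorded as `ambiguity_window`. When an exon substitution
sits immediately adjacent to the junction the placement is ambiguous at
equal alignment score and no pairwise method can resolve it; in
practice homing-endonuclease target sites are conserved sequence
context, and the simulator encodes exactly that (below).

Families are single-linkage clusters over calls of one gene: same site
within ±3 nt *and* edit-distance identity ≥ 0.70 (1 − d/max-length).
The identity threshold is the package's choice for "same intron";
unrelated co-resident introns at one site fall well below it. Families
are named `<gene>-i1..iN` by consensus site, ties broken by lowest
carrier id. Frequencies count isolates, with duplicate mtDNAs counted
once per isolate. A warning is emitted when no intron-free reference
can exist (a family carried by all non-reference isolates); genuinely
universal insertions are undetectable without external references, a
stated limit of the intra-specific design.

Mobile fragments use the same insertion logic on intergenic spans
keyed by flanking-gene pairs shared across all isolates, with
`min_mobile_length` = 1000 bp. ORFs inside introns are ATG-initiated,
≥ 50 aa, in all six frames; motif labels are regex-level — a degenerate
acidic-anchored LAGLIDADG decapeptide block and a GIY-…-YIG block —
not profile HMMs, which matches the label-only granularity the analysis
needs.

## N-terminal-duplication introns

The 5′ open reading stretch of the intron (translation up to the first
stop, within the 5′ 60 % of the intron — known duplications are
5′-terminal, and the restriction curbs false positives) is translated
in three frames and globally aligned (BLOSUM62, −11/−1 gaps) to the
downstream exon peptide of matched length read in the host frame.
Identity = exact matches / aligned columns; similarity = columns with
positive BLOSUM62 score / aligned columns; terminal gaps excluded.
Both are always reported because the field uses either convention.
A call is positive (host gene D-type) at ≥ 50 % similarity over ≥ 30
aligned residues — far below the weakest published case (≈ 72 %) yet
far above random expectation (~30–40 %), and the first-stop truncation
means random introns rarely even reach 30 readable residues.

Structural subtyping is an in-silico proxy for splice-form (cDNA)
evidence, which overrides it when supplied: a terminated upstream ORF ⇒
downstream-TE; an open read-through from upstream exon through the
insertion into the downstream exon ⇒ exonized; a frame-broken
read-through with a clean splice ⇒ intact-intron; contradictions ⇒
ambiguous. A translated local-alignment search of all panel CDS
references against the intron (≥ 30 aa at ≥ 40 % identity) reports
truncated-gene cargo.

## Diversity statistics

SNPs/kb per region class against a reference isolate (the TF04-series
representative when present, else the first id): per gene, called
introns are excised, the intron-free sequences aligned, and each
reference column classified (codon position for CDS; class label
otherwise); intergenic spans are compared with mobile fragments
removed. A SNP is an aligned column with two differing ACGT bases; gap
and N columns leave numerator and denominator; indels are ignored.
Counts are pooled per class before division (one rate per class, the
simplest consistent convention), and isolates are ranked by the
unweighted mean of their class rates.

The per-class GC comparison uses Kruskal–Wallis across classes plus
Holm-adjusted pairwise Mann–Whitney: with ~16 non-independent values
per class a nonparametric, assumption-light test is the conservative
choice. Per-class GC is computed over the concatenated bases of each
class (a mean of per-feature GCs is the obvious alternative; the
concatenation is the default).

## Phylogeny

The tree is deliberately plumbing: per-gene multiple peptide alignment
(mafft when available; a reference-anchored merge otherwise) of the 14
conserved proteins (rps3 excluded), concatenated; neighbor-joining on
p-distances with pairwise gap deletion; deterministic tie-breaks on
sorted isolate ids; tiny negative NJ branches clamped to zero. The
concatenated matrix is exported in FASTA and relaxed PHYLIP so users
can build a bootstrapped ML tree externally; alignment width depends on
alignment parameters and is reported, never asserted.

## The simulator

The generator *is* the study conditions. Defaults: the 41-gene backbone
with realistic fungal-mtDNA gene lengths (CDS 150–1980 bp, rnl 2500,
rns 1200, rnpB 300, tRNAs 72 bp), six genes on the minus strand
(cox3, trnR1, rps3, rnpB, trnM1, atp9), 120-bp spacers, genic GC 0.40
and intergenic GC 0.30. Sequences evolve down a user tree under
per-class Jukes–Cantor with branch lengths in pos3 substitutions/site
and multipliers pos12 0.12, tRNA/rRNA/ncRNA 0.10, intergenic 1.0 —
reproducing the qualitative contrast of slow first/second codon
positions and non-coding genes versus fast third positions and
intergenic DNA. CDS evolution is codon-aware: changes creating stops
are reverted (purifying selection keeps genes translatable), and start/
stop codons are frozen.

Scripted events place introns (per host gene, site, length, carrier
set, optional ORF motif, optional N-dup target similarity) and mobile
fragments (per adjacent flank pair). Event sequences are generated once
and shared by carriers; flank divergence then comes from the tree. Two
design points matter for ground truth:

- **Junction identifiability.** Intron boundary bases are chosen to
  differ from every isolate's flanking bases (no exact-repeat slide),
  and the two bases on each side of a scripted insertion site are
  exempt from substitution. This encodes homing-target conservation and
  makes scripted boundaries exactly recoverable; without it, a
  substitution landing on the junction base creates a placement tie no
  pairwise aligner can break.
- **N-dup construction is checked against the classifier's own
  metric.** The duplicated segment is copied from the downstream exon
  read in the host frame, mutated at the amino-acid level (random
  positions replaced by residues with non-positive BLOSUM62 score)
  until the positive-column fraction hits the target, then
  back-translated with random synonymous codons — so the realized
  similarity equals the target up to 1/length rounding, independently
  of alignment heuristics.

Duplicate-isolate aliases map several ids onto one genome, emulating
clonal series within a sample. The four-stage N-dup cycle is modeled as
a state machine (N → D-intact → D-exonized → D-downstream → N, with
detach legal from both D states) and structurally: exonization
replaces the frame-breaking part of the insertion with in-frame
stop-free codons; detachment swaps the analog into the coding role and
moves the original N-terminal segment plus TE remnant downstream; loss
deletes the element. A full cycle leaves the gene translatable and
altered only in the N-terminal segment — partial foreign replacement.

The bundled `headline_scenario` scripts 16 isolates (10 distinct
sequences), 24 intron events (11 CDS / 3 tRNA / 10 rRNA, with nine rnl
introns on six sites, three of which host two unrelated introns), two
mobile fragments (1864 and 2684 bp), six N-dup introns (targets
0.725–0.81), and per-isolate element counts spanning 1–15 with no
universal element. Genomes come out at 26–37 kb; the full pipeline on
the scenario runs in well under a minute on one CPU, which sets the
problem sizes used throughout the tests and the acceptance script.

## What the simulator does not emulate

Real data contain sequencing and assembly artifacts (homopolymer
indels), unscripted micro-indels, intron degradation and twintrons,
recombination, annotation errors, and base-composition heterogeneity
along the genome. Passing the simulator-based suite therefore shows the
machinery is correct under the stated model — exact insertions on a
conserved backbone with class-structured substitution — not that every
real junction will be recovered to the base. The boundary ambiguity
window and the always-reported identity/similarity pair are the
honest-uncertainty outlets on real data.

## Numerical and degenerate-input choices

Identity for family clustering is edit-distance based (1 − d/max
length) for speed; alignment-based identity is used where residue
detail matters. Alignment ties are broken deterministically by
Biopython's first-path rule plus left-alignment. All-N sequences yield
missing GC with a warning; constant data yield p = 1 in the GC test;
fewer than three isolates skip the tree and the GC test; a single
genome is a hard error for any comparative operation. Every random
draw flows from `numpy.random.default_rng` seeded from the run seed, so
equal seed and config reproduce genomes, truth tables and report
bundles byte-identically (PNG figures aside).
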