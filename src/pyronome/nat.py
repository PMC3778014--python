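"""Natural antisense transcript (NAT) detection from spliced-read junctions.

Spliced reads reveal transcript strand even in non-strand-specific RNA-seq:
the intron consensus is 5' GT (or GC) ... AG 3'. A junction whose motifs
read canonically only on the strand opposite an overlapping gene evidences
an antisense transcript. Calls are filtered on absolute spliced-read support
(>= 5 reads) and support relative to the sense transcript's mean exon depth
(> 10%), and annotated with QC flags (near assembly gaps, inside repeats,
near scaffold ends) standing in for the manual curation such calls receive;
flags never alter the pass/fail verdict.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io import GeneModel, GenomeSequence, revcomp

logger = logging.getLogger(__name__)

DONOR_MOTIFS = {"GT", "GC"}
ACCEPTOR_MOTIF = "AG"


@dataclass
class SpliceJunction:
    scaffold: str
    start: int  # intron start, 0-based
    end: int    # intron end, half-open
    read_support: int
    donor_motif: str = ""
    acceptor_motif: str = ""
    inferred_strand: str = "ambiguous"

    def __post_init__(self) -> None:
        if self.end - self.start < 4:
            raise ValueError("intron too short to carry both splice motifs")
        if self.read_support < 0:
            raise ValueError("read support must be >= 0")


@dataclass
class NatCall:
    gene_id: str
    junction: SpliceJunction
    sense_depth: float
    relative_coverage: float
    passes: bool
    flags: set[str] = field(default_factory=set)


def infer_strand(
    genome: Mapping[str, str], scaffold: str, intron: tuple[int, int]
) -> tuple[str, str, str]:
    """Infer junction strand from the intron boundary motifs.

    Returns (strand, donor_motif, acceptor_motif) where strand is '+', '-'
    or 'ambiguous' (motifs read canonically in both or neither direction).
    Motifs are reported in the reading direction of the inferred strand;
    for ambiguous junctions the forward-strand 2-mers are reported.
    """
    seq = genome[scaffold]
    start, end = intron
    if start < 0 or end > len(seq) or end - start < 4:
        raise ValueError(f"intron {intron} out of bounds for scaffold {scaffold!r}")
    left = seq[start : start + 2]
    right = seq[end - 2 : end]
    fwd = left in DONOR_MOTIFS and right == ACCEPTOR_MOTIF
    rc_donor = revcomp(right)
    rc_acceptor = revcomp(left)
    rev = rc_donor in DONOR_MOTIFS and rc_acceptor == ACCEPTOR_MOTIF
    if fwd and not rev:
        return "+", left, right
    if rev and not fwd:
        return "-", rc_donor, rc_acceptor
    return "ambiguous", left, right


def annotate_junctions(
    genome: Sequence[GenomeSequence] | Mapping[str, str],
    raw_junctions: Sequence[tuple[str, int, int, int]],
) -> list[SpliceJunction]:
    """Build SpliceJunction objects with motif-inferred strand."""
    seqs = (
        genome
        if isinstance(genome, Mapping)
        else {r.id: r.seq for r in genome}
    )
    out = []
    for scaffold, start, end, support in raw_junctions:
        strand, donor, acceptor = infer_strand(seqs, scaffold, (start, end))
        out.append(
            SpliceJunction(scaffold, start, end, support, donor, acceptor, strand)
        )
    return out


def assign_orientation(
    junction: SpliceJunction, genes: Sequence[GeneModel]
) -> list[tuple[str, str]]:
    """(gene_id, 'sense'|'antisense') for every gene whose span overlaps the
    intron by >= 1 bp on the same scaffold. Ambiguous junctions get none."""
    if junction.inferred_strand not in {"+", "-"}:
        return []
    out = []
    for g in genes:
        if g.scaffold != junction.scaffold:
            continue
        lo, hi = g.span
        if junction.start < hi and junction.end > lo:
            out.append(
                (g.gene_id, "sense" if g.strand == junction.inferred_strand else "antisense")
            )
    return out


def filter_nats(
    antisense: Sequence[tuple[str, SpliceJunction]],
    coverage: Mapping[str, float],
    min_reads: int = 5,
    min_rel: float = 0.10,
) -> tuple[list[NatCall], dict]:
    """Apply the support filters to antisense (gene, junction) records.

    A call passes iff read_support >= min_reads (inclusive, "at least five")
    AND read_support > min_rel * mean sense exon depth (strict, "more than
    10%"). Genes with zero sense depth pass the relative test whenever the
    absolute test holds. The summary counts distinct passing junctions and
    distinct genes with >= 1 passing junction.
    """
    calls: list[NatCall] = []
    for gene_id, j in antisense:
        if gene_id not in coverage:
            raise KeyError(f"no sense-coverage entry for gene {gene_id}")
        depth = float(coverage[gene_id])
        rel = j.read_support / depth if depth > 0 else float("inf")
        passes = j.read_support >= min_reads and j.read_support > min_rel * depth
        calls.append(NatCall(gene_id, j, depth, rel, passes))
    passing = [c for c in calls if c.passes]
    summary = {
        "n_sites": len({(c.junction.scaffold, c.junction.start, c.junction.end) for c in passing}),
        "n_genes": len({c.gene_id for c in passing}),
    }
    return calls, summary


def qc_flags(
    calls: Sequence[NatCall],
    genome: Sequence[GenomeSequence] | Mapping[str, str],
    repeats: Sequence[tuple[str, int, int]] | None = None,
    gap_dist: int = 500,
    min_gap_run: int = 10,
) -> None:
    """Populate curation flags in place; flags never change ``passes``.

    near_gap: an N-run of >= ``min_gap_run`` bases within ``gap_dist`` of the
    intron. in_repeat: intron overlaps a repeat interval. near_scaffold_end:
    intron within ``gap_dist`` of a scaffold boundary.
    """
    seqs = genome if isinstance(genome, Mapping) else {r.id: r.seq for r in genome}
    gap_runs: dict[str, list[tuple[int, int]]] = {}
    for sid, seq in seqs.items():
        gap_runs[sid] = [
            (m.start(), m.end()) for m in re.finditer("N{%d,}" % min_gap_run, seq)
        ]
    for c in calls:
        j = c.junction
        seq = seqs[j.scaffold]
        if j.start < gap_dist or len(seq) - j.end < gap_dist:
            c.flags.add("near_scaffold_end")
        for gs, ge in gap_runs[j.scaffold]:
            if gs < j.end + gap_dist and ge > j.start - gap_dist:
                c.flags.add("near_gap")
                break
        if repeats:
            for rs_scaf, rs, re_ in repeats:
                if rs_scaf == j.scaffold and rs < j.end and re_ > j.start:
                    c.flags.add("in_repeat")
                    break


def detect_nats(
    genome: Sequence[GenomeSequence],
    genes: Sequence[GeneModel],
    raw_junctions: Sequence[tuple[str, int, int, int]],
    coverage: Mapping[str, float],
    repeats: Sequence[tuple[str, int, int]] | None = None,
    min_reads: int = 5,
    min_rel: float = 0.10,
) -> tuple[list[NatCall], dict]:
    """End-to-end NAT detection: strand inference, orientation assignment
    against stranded gene models, support filtering, and QC flagging."""
    junctions = annotate_junctions(genome, raw_junctions)
    antisense = []
    for j in junctions:
        for gene_id, orient in assign_orientation(j, genes):
            if orient == "antisense":
                antisense.append((gene_id, j))
    calls, summary = filter_nats(antisense, coverage, min_reads, min_rel)
    qc_flags(calls, genome, repeats)
    return calls, summary


def write_nat_tsv(calls: Sequence[NatCall], summary: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene\tscaffold\tintron_start\tintron_end\tstrand\tsupport"
            "\tsense_depth\trelative_coverage\tpasses\tflags\n"
        )
        for c in calls:
            j = c.junction
            rel = "inf" if c.relative_coverage == float("inf") else f"{c.relative_coverage:.4f}"
            fh.write(
                f"{c.gene_id}\t{j.scaffold}\t{j.start}\t{j.end}\t{j.inferred_strand}"
                f"\t{j.read_support}\t{c.sense_depth:.2f}\t{rel}"
                f"\t{int(c.passes)}\t{','.join(sorted(c.flags)) or '.'}\n"
            )
        fh.write(
            f"# summary: {summary['n_sites']} passing antisense splice sites in "
            f"{summary['n_genes']} genes\n"
        )
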