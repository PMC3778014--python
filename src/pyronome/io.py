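"""Readers/writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted at the boundary. DNA is normalised to uppercase over {A,C,G,T,N}:
U maps to T and any other IUPAC ambiguity code collapses to N, so downstream
dinucleotide and k-mer counting can simply skip N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """One scaffold: a named uppercase DNA string over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("scaffold id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"scaffold {self.id!r} has empty sequence")


@dataclass
class GeneModel:
    """A stranded gene with exon intervals on a named scaffold.

    ``exons`` are 0-based half-open intervals, sorted and disjoint. ``span``
    is [min exon/gene start, max exon/gene end) and includes annotated UTRs.
    """

    gene_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]
    span: tuple[int, int] = None  # type: ignore[assignment]
    peptide_length: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"gene {self.gene_id}: overlapping exons {(s0, e0)} and {(s1, e1)}")
        if self.span is None:
            self.span = (self.exons[0][0], self.exons[-1][1])
        lo, hi = self.span
        if self.exons and (self.exons[0][0] < lo or self.exons[-1][1] > hi):
            raise ValueError(f"gene {self.gene_id}: exon outside gene span {self.span}")

    @property
    def exon_union_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class CountMatrix:
    """Per-gene read counts for an ordered set of samples.

    ``samples`` are "<condition>_<replicate>" labels; ``counts`` is a
    genes x samples integer array; ``gene_lengths`` holds mRNA lengths in nt.
    """

    genes: list[str]
    samples: list[str]
    counts: np.ndarray
    gene_lengths: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_lengths = np.asarray(self.gene_lengths)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample labels must be unique")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.gene_lengths < 1).any():
            raise ValueError("every gene needs a length >= 1")
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape does not match genes x samples")

    def condition_columns(self, condition: str) -> list[int]:
        cols = [i for i, s in enumerate(self.samples) if s.rsplit("_", 1)[0] == condition]
        if not cols:
            raise KeyError(f"no samples for condition {condition!r}")
        return cols


@dataclass
class SimilarityHit:
    """One row of a 12-column BLAST tabular (-outfmt 6) file."""

    query: str
    subject: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.bitscore < 0 or self.evalue < 0:
            raise ValueError("bitscore and e-value must be non-negative")


def normalize_dna(seq: str, context: str = "") -> str:
    """Uppercase, U->T, and collapse anything outside {A,C,G,T,N} to N."""
    s = seq.upper().replace("U", "T")
    if not set(s) <= _VALID:
        bad = sorted(set(s) - _VALID)
        logger.warning("sequence %s: non-ACGTN characters %s mapped to N", context or "?", bad)
        s = "".join(c if c in _VALID else "N" for c in s)
    return s


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, normalize_dna(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon features from a GFF3 file.

    Coordinates are converted to 0-based half-open. For genes with multiple
    mRNAs the exon set is the merged union of all isoform exons. Genes with
    strand '.' are skipped with a warning; exons outside their gene span are
    a hard error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        if g.strand not in {"+", "-"}:
            logger.warning("gene %s: strand %r, skipped", g.id, g.strand)
            continue
        span = (g.start - 1, g.end)
        exons: list[tuple[int, int]] = []
        for ex in db.children(g, featuretype="exon"):
            iv = (ex.start - 1, ex.end)
            if iv[0] < span[0] or iv[1] > span[1]:
                raise ValueError(
                    f"gene {g.id}: exon {ex.start}..{ex.end} outside gene span "
                    f"{g.start}..{g.end}"
                )
            exons.append(iv)
        if not exons:
            exons = [span]
        merged = merge_intervals(exons)
        genes.append(GeneModel(g.id, g.seqid, g.strand, merged, span=span))
    return genes


def write_gff3_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon features (inverse of :func:`read_gff3_genes`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.scaffold}\tpyronome\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.scaffold}\tpyronome\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.scaffold}\tpyronome\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.e{i};Parent={mrna}\n"
                )


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, merging overlapping or adjacent ones."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def read_junctions(
    path: str | Path, dialect: str = "bed12"
) -> list[tuple[str, int, int, int]]:
    """Read splice junctions as (scaffold, intron_start, intron_end, support).

    ``bed12``: Tophat junctions.bed dialect -- the two blocks are the exonic
    anchors, the intron is the gap between them:
    intron = [chromStart + blockSizes[0], chromStart + blockStarts[1]).
    ``intron_bed6``: chrom, intron start, intron end, name, score=read count,
    optional strand (ignored; strand is inferred from intron motifs).
    """
    if dialect not in {"bed12", "intron_bed6"}:
        raise ValueError(f"unknown junction dialect {dialect!r}")
    out: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            f = line.split("\t")
            if dialect == "intron_bed6":
                chrom, start, end, _name, score = f[0], int(f[1]), int(f[2]), f[3], int(f[4])
                if score < 0:
                    raise ValueError(f"{path}:{ln}: negative score {score}")
                out.append((chrom, start, end, score))
            else:
                chrom, chrom_start, score = f[0], int(f[1]), int(f[4])
                if score < 0:
                    raise ValueError(f"{path}:{ln}: negative score {score}")
                n_blocks = int(f[9])
                if n_blocks != 2:
                    logger.warning("%s:%d: blockCount=%d != 2, record skipped", path, ln, n_blocks)
                    continue
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                out.append((chrom, chrom_start + sizes[0], chrom_start + starts[1], score))
    return out


def genome_stats(genome: Sequence[GenomeSequence]) -> dict:
    """Assembly summary: total length, scaffold count, N50, GC fraction.

    GC = (G+C)/(A+C+G+T) with N excluded from the denominator. N50 is the
    length of the scaffold at which the cumulative length (descending order)
    first reaches half of the total.
    """
    if not genome:
        raise ValueError("empty genome")
    lengths = sorted((len(r.seq) for r in genome), reverse=True)
    total = sum(lengths)
    gc = acgt = 0
    for r in genome:
        gc += r.seq.count("G") + r.seq.count("C")
        acgt += len(r.seq) - r.seq.count("N")
    cum = 0
    n50 = lengths[0]
    for L in lengths:
        cum += L
        if cum * 2 >= total:
            n50 = L
            break
    return {
        "total_length": total,
        "n_scaffolds": len(genome),
        "n50": n50,
        "gc_fraction": gc / acgt if acgt else 0.0,
    }


# ---------------------------------------------------------------------------
# tabular round trips

def write_gene_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene": g.gene_id,
                "scaffold": g.scaffold,
                "strand": g.strand,
                "span_start": g.span[0],
                "span_end": g.span[1],
                "exons": ";".join(f"{s}-{e}" for s, e in g.exons),
                "peptide_length": "" if g.peptide_length is None else g.peptide_length,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_tsv(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"peptide_length": "Int64"})
    genes = []
    for row in df.itertuples(index=False):
        exons = [tuple(map(int, p.split("-"))) for p in row.exons.split(";")]
        pep = None if pd.isna(row.peptide_length) else int(row.peptide_length)
        genes.append(
            GeneModel(
                row.gene, row.scaffold, row.strand, exons,
                span=(int(row.span_start), int(row.span_end)), peptide_length=pep,
            )
        )
    return genes


def read_counts_tsv(path: str | Path, lengths_path: str | Path | None = None) -> CountMatrix:
    """Count table with header ``gene<TAB>sample1<TAB>...``; lengths either
    from a two-column TSV (gene, length) or a ``length`` column in the table."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene":
        raise ValueError("count table must start with a 'gene' column")
    df = df.set_index("gene")
    if lengths_path is not None:
        ldf = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = ldf.iloc[:, 0].reindex(df.index).to_numpy()
    elif "length" in df.columns:
        lengths = df.pop("length").to_numpy()
    else:
        raise ValueError("gene lengths required (length column or lengths file)")
    return CountMatrix(
        genes=list(df.index),
        samples=list(df.columns),
        counts=df.to_numpy(dtype=np.int64),
        gene_lengths=np.asarray(lengths, dtype=np.int64),
    )


def write_counts_tsv(cm: CountMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cm.counts, index=pd.Index(cm.genes, name="gene"), columns=cm.samples)
    df.insert(0, "length", cm.gene_lengths)
    df.to_csv(path, sep="\t")


def read_blast_tab(path: str | Path) -> list[SimilarityHit]:
    """12-column BLAST tabular (-outfmt 6 layout)."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            hits.append(
                SimilarityHit(
                    query=f[0],
                    subject=f[1],
                    percent_identity=float(f[2]),
                    alignment_length=int(f[3]),
                    evalue=float(f[10]),
                    bitscore=float(f[11]),
                )
            )
    return hits


def write_blast_tab(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.percent_identity:.2f}\t{h.alignment_length}"
                f"\t0\t0\t1\t{h.alignment_length}\t1\t{h.alignment_length}"
                f"\t{h.evalue:.2e}\t{h.bitscore:.1f}\n"
            )
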