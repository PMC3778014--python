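"""Seeded generators for every pipeline stage.

Each generator is a pure function of a :class:`SimConfig`: the same seed
produces byte-identical outputs. Defaults mirror the study design the
pipeline targets: a ~50%-GC haploid fungal genome, one planted duplication
carrying RIP-style C:G->T:A mutations in CpA/TpG context, uniform-coverage
error-bearing short reads, spliced gene models with planted antisense
introns at controlled read support, negative-binomial count tables for
three conditions (sex, DD, vegmix) x two biological replicates with fold
changes planted in the sex condition, and ortholog position tables with
planted syntenic blocks. Every generator returns a truth table alongside
its data so downstream detectors can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .io import CountMatrix, GeneModel, GenomeSequence
from .synteny import GenePosition, OrthologMap, SimilarityHit

CONDITIONS = ("sex", "DD", "vegmix")


@dataclass
class SimConfig:
    """Shared knobs for all generators; see docs/methods.md for rationale."""

    seed: int = 0
    genome_length: int = 500_000
    gc_content: float = 0.478
    rip_duplication_length: int = 2_000
    rip_mutation_rate: float = 0.5
    n_genes: int = 100
    antisense_fraction: float = 0.3
    read_length: int = 100
    coverage: float = 50.0
    error_rate: float = 0.0
    nb_dispersion: float = 0.05
    planted_log2fc: float = 3.0
    planted_fraction: float = 0.05
    replicates: int = 2

    def __post_init__(self) -> None:
        for name in ("gc_content", "antisense_fraction", "rip_mutation_rate", "error_rate",
                     "planted_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("genome_length", "rip_duplication_length", "n_genes", "read_length",
                     "replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator per stage so stages stay reproducible
        regardless of how much randomness other stages consume."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.int8)


_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def simulate_genome(config: SimConfig) -> tuple[list[GenomeSequence], dict]:
    """Random genome with one planted duplication, RIP-mutated in one copy.

    The duplicated segment (> 400 bp, the minimum substrate length for RIP)
    is copied to a disjoint location; in the copy, each C of a CpA
    dinucleotide mutates to T and each G of a TpG mutates to A (the two
    strand-symmetric RIP products), each with probability
    ``rip_mutation_rate``, decided on the pre-mutation sequence. The truth
    table records the donor and mutated intervals.
    """
    L, D = config.genome_length, config.rip_duplication_length
    if D <= 400:
        raise ValueError("rip_duplication_length must exceed 400 bp (RIP substrate minimum)")
    if L < 2 * D:
        raise ValueError("genome shorter than twice the duplication length")
    rng = config.rng(1)
    codes = _random_bases(rng, L, config.gc_content)
    # donor in the first half, RIPped copy in the second half, both away
    # from the genome ends so windows cover them fully
    donor_start = int(rng.integers(0, L // 2 - D))
    copy_start = int(rng.integers(L // 2, L - D))
    segment = codes[donor_start : donor_start + D].copy()
    mutated = segment.copy()
    r = rng.random(D)
    for i in range(D - 1):
        if segment[i] == 1 and segment[i + 1] == 0 and r[i] < config.rip_mutation_rate:
            mutated[i] = 3  # CpA -> TpA
        elif segment[i] == 3 and segment[i + 1] == 2 and r[i] < config.rip_mutation_rate:
            mutated[i + 1] = 0  # TpG -> TpA
    codes[copy_start : copy_start + D] = mutated
    truth = {
        "donor": (donor_start, donor_start + D),
        "mutated": (copy_start, copy_start + D),
        "n_mutations": int((segment != mutated).sum()),
        "seed": config.seed,
    }
    return [GenomeSequence("sim_scaffold_1", _to_str(codes))], truth


def simulate_reads(
    genome: list[GenomeSequence], config: SimConfig
) -> list[str]:
    """Uniform shotgun reads from both strands with substitution errors.

    Total read bases ~ coverage x genome length (+-1 read).
    """
    if config.coverage < 1:
        raise ValueError("coverage must be >= 1")
    rng = config.rng(2)
    out: list[str] = []
    for rec in genome:
        codes = np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8)
        codes = np.select([codes == c for c in b"ACGT"], [0, 1, 2, 3], default=-1).astype(np.int8)
        G = len(codes)
        if config.read_length > G:
            raise ValueError("read_length exceeds scaffold length")
        n_reads = int(round(config.coverage * G / config.read_length))
        starts = rng.integers(0, G - config.read_length + 1, size=n_reads)
        strands = rng.random(n_reads) < 0.5
        for s, rev in zip(starts, strands):
            read = codes[s : s + config.read_length].copy()
            if config.error_rate > 0:
                errs = np.nonzero(rng.random(config.read_length) < config.error_rate)[0]
                if errs.size:
                    read[errs] = (read[errs] + rng.integers(1, 4, size=errs.size)) % 4
            if rev:
                read = 3 - read[::-1]
            out.append(_to_str(read.astype(np.int8)))
    return out


# ---------------------------------------------------------------------------
# transcriptome with planted antisense junctions

#: deterministic (support, sense depth) probes for the first planted
#: antisense junctions, exercising the filter's strict boundaries:
#: 5 > 0.1*49 passes, 5 = 0.1*50 fails, 4 fails the absolute test.
BOUNDARY_PROBES = [(5, 49.0), (5, 50.0), (4, 10.0), (30, 100.0)]


def simulate_transcriptome(
    genome: list[GenomeSequence], config: SimConfig, max_retries: int = 50
) -> tuple[list[GenomeSequence], list[GeneModel], list[tuple[str, int, int, int]], dict[str, float], list[dict]]:
    """Plant spliced gene models and antisense introns into a genome copy.

    Each gene gets one sense intron with a canonical GT..AG motif written
    into the genome sequence; a configured fraction of genes additionally
    get an antisense intron (canonical on the opposite strand) with a
    controlled spliced-read support against a controlled sense mean exon
    depth. Returns (edited genome, gene models, raw junction tuples,
    per-gene mean exon depth, NAT truth table). The truth table marks which
    antisense junctions must pass the support filters
    (support >= 5 and support > 10% of sense depth).
    """
    rng = config.rng(3)
    rec = genome[0]
    codes = bytearray(rec.seq, "ascii")
    L = len(codes)
    gene_len, intron_len, margin = 1200, 90, 300
    spacing = L // config.n_genes
    if spacing < gene_len + 2 * margin:
        raise ValueError("genes do not fit in the genome without overlap")
    genes: list[GeneModel] = []
    junctions: list[tuple[str, int, int, int]] = []
    coverage: dict[str, float] = {}
    truth: list[dict] = []
    n_anti = int(round(config.antisense_fraction * config.n_genes))
    anti_idx = set(rng.choice(config.n_genes, size=n_anti, replace=False).tolist())
    probe_queue = list(BOUNDARY_PROBES)

    def write_motif(start: int, end: int, strand: str) -> None:
        if strand == "+":
            codes[start : start + 2] = b"GT"
            codes[end - 2 : end] = b"AG"
        else:  # reverse-strand canonical motif reads CT..AC on the forward text
            codes[start : start + 2] = b"CT"
            codes[end - 2 : end] = b"AC"

    for gi in range(config.n_genes):
        gene_id = f"SIMG_{gi + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        g_start = gi * spacing + margin
        g_end = g_start + gene_len
        # sense intron in the middle of the gene
        i_start = g_start + gene_len // 2
        i_end = i_start + intron_len
        write_motif(i_start, i_end, strand)
        exons = [(g_start, i_start), (i_end, g_end)]
        genes.append(GeneModel(gene_id, rec.id, strand, exons, span=(g_start, g_end)))
        depth = float(rng.integers(50, 300))
        sense_support = max(5, int(round(depth * 0.7)))
        junctions.append((rec.id, i_start, i_end, sense_support))
        if gi in anti_idx:
            if probe_queue:
                support, depth = probe_queue.pop(0)
            else:
                support = int(rng.integers(1, 60))
                depth = float(rng.integers(20, 300))
            anti_strand = "-" if strand == "+" else "+"
            # antisense intron in the first exon, clear of the sense motif
            a_start = g_start + 60
            a_end = a_start + intron_len
            placed = False
            for _ in range(max_retries):
                probe_iv = (a_start, a_end)
                if probe_iv[1] < i_start - 4:
                    placed = True
                    break
                a_start += 10
                a_end += 10
            if not placed:
                raise RuntimeError(f"could not place antisense intron for {gene_id}")
            write_motif(a_start, a_end, anti_strand)
            junctions.append((rec.id, a_start, a_end, support))
            expect_pass = support >= 5 and support > 0.10 * depth
            truth.append(
                {
                    "gene": gene_id,
                    "intron": (a_start, a_end),
                    "strand": anti_strand,
                    "support": support,
                    "sense_depth": depth,
                    "expect_pass": expect_pass,
                }
            )
        coverage[gene_id] = depth
    edited = [GenomeSequence(rec.id, codes.decode("ascii"))] + [
        GenomeSequence(r.id, r.seq) for r in genome[1:]
    ]
    return edited, genes, junctions, coverage, truth


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, dict]:
    """Negative-binomial count table for sex/DD/vegmix x replicates.

    Gene means are log-uniform in [100, 2000]; a ``planted_fraction`` of
    genes have their mean multiplied by 2**planted_log2fc in the sex
    condition only. Counts are NB with variance mu + dispersion * mu^2.
    The truth table records planted gene ids and direction.
    """
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    rng = config.rng(4)
    n = config.n_genes
    genes = [f"SIMG_{i + 1:05d}" for i in range(n)]
    means = np.exp(rng.uniform(np.log(100), np.log(2000), size=n))
    n_planted = int(round(config.planted_fraction * n))
    planted = np.sort(rng.choice(n, size=n_planted, replace=False))
    fold = 2.0 ** config.planted_log2fc
    samples = [f"{c}_{r + 1}" for c in CONDITIONS for r in range(config.replicates)]
    counts = np.zeros((n, len(samples)), dtype=np.int64)
    r_nb = 1.0 / config.nb_dispersion
    for si, sample in enumerate(samples):
        cond = sample.rsplit("_", 1)[0]
        mu = means.copy()
        if cond == "sex":
            mu[planted] *= fold
        p = r_nb / (r_nb + mu)
        counts[:, si] = rng.negative_binomial(r_nb, p)
    lengths = rng.integers(500, 3000, size=n)
    cm = CountMatrix(genes=genes, samples=samples, counts=counts, gene_lengths=lengths)
    truth = {
        "planted_genes": [genes[i] for i in planted],
        "direction": "up_in_sex" if config.planted_log2fc > 0 else
                     ("down_in_sex" if config.planted_log2fc < 0 else "none"),
        "log2fc": config.planted_log2fc,
        "seed": config.seed,
    }
    return cm, truth


def simulate_external_table(cm: CountMatrix) -> dict[tuple[str, str], tuple[float, float]]:
    """Emulated Bayesian differential-expression table for consensus calling.

    For each gene and comparison, the external ratio is the pooled
    library-normalised ratio and the probability of differential expression
    is 1 - p of a two-sided binomial test of the pooled condition-A count
    against the expected library share -- an independent route from the
    replicate-ratio classification it is combined with.
    """
    from .expression import COMPARISONS

    totals = cm.counts.sum(axis=0).astype(float)
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for cond_a, cond_b in COMPARISONS:
        ia = cm.condition_columns(cond_a)
        ib = cm.condition_columns(cond_b)
        lib_a, lib_b = totals[ia].sum(), totals[ib].sum()
        share = lib_a / (lib_a + lib_b)
        comparison = f"{cond_a}/{cond_b}"
        ka = cm.counts[:, ia].sum(axis=1)
        kb = cm.counts[:, ib].sum(axis=1)
        for gi, gene in enumerate(cm.genes):
            a, b = int(ka[gi]), int(kb[gi])
            if b == 0 or a + b == 0:
                continue
            ratio = (a / lib_a) / (b / lib_b)
            pval = stats.binomtest(a, a + b, share).pvalue
            out[(gene, comparison)] = (ratio, 1.0 - pval)
    return out


# ---------------------------------------------------------------------------
# orthologs and synteny

def simulate_orthologs(
    config: SimConfig,
    n_scaffolds: int = 4,
    spacing: int = 5_000,
    shuffle_fraction: float = 0.0,
) -> tuple[dict[str, GenePosition], dict[str, GenePosition], list[SimilarityHit], list[SimilarityHit], dict]:
    """Two gene-position tables plus reciprocal similarity tables.

    Genome B reproduces genome A's gene order and spacing; a
    ``shuffle_fraction`` of B genes is relocated to uniformly random
    positions on random scaffolds, breaking their neighbourhoods. Hit
    tables are built so RBH recovers the true ortholog map (true pair
    bitscore 200, decoy cross-hits at 120). Truth synteny counts are
    derived by brute force in the test suite, not here.
    """
    if config.n_genes < 2:
        raise ValueError("need at least 2 genes")
    rng = config.rng(5)
    per_scaf = -(-config.n_genes // n_scaffolds)
    pos_a: dict[str, GenePosition] = {}
    pos_b: dict[str, GenePosition] = {}
    for i in range(config.n_genes):
        ga, gb = f"A_{i + 1:05d}", f"B_{i + 1:05d}"
        scaf = i // per_scaf + 1
        offset = (i % per_scaf) * spacing
        pos_a[ga] = GenePosition(ga, f"scafA_{scaf}", offset)
        pos_b[gb] = GenePosition(gb, f"scafB_{scaf}", offset)
    n_shuffled = int(round(shuffle_fraction * config.n_genes))
    shuffled = rng.choice(config.n_genes, size=n_shuffled, replace=False)
    span = per_scaf * spacing * 50  # relocations land far from any block
    for i in shuffled:
        gb = f"B_{i + 1:05d}"
        pos_b[gb] = GenePosition(
            gb,
            f"scafB_shuf_{int(rng.integers(1, n_scaffolds * 10))}",
            int(rng.integers(0, span)),
        )
    hits_ab, hits_ba = [], []
    for i in range(config.n_genes):
        ga, gb = f"A_{i + 1:05d}", f"B_{i + 1:05d}"
        hits_ab.append(SimilarityHit(ga, gb, 90.0, 300, 1e-80, 200.0))
        hits_ba.append(SimilarityHit(gb, ga, 90.0, 300, 1e-80, 200.0))
        decoy = f"B_{(i + 1) % config.n_genes + 1:05d}"
        hits_ab.append(SimilarityHit(ga, decoy, 40.0, 150, 1e-10, 120.0))
    truth = {
        "pairs": {(f"A_{i + 1:05d}", f"B_{i + 1:05d}") for i in range(config.n_genes)},
        "shuffled_b": {f"B_{i + 1:05d}" for i in shuffled},
        "seed": config.seed,
    }
    return pos_a, pos_b, hits_ab, hits_ba, truth
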