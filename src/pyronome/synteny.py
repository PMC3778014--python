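"""Reciprocal-best-hit orthology, lineage-specificity grouping, and
microsynteny (conserved local gene neighbourhood) counting.

Orthologs between two proteomes are called as reciprocal best hits (RBH) in
pairwise similarity tables; genes with unresolvable within-species paralogy
(tied top bitscores) are excluded. Genes are then binned into nested
lineage-specificity groups (orphan genes outward to genes conserved in all
compared genomes) from their ortholog presence pattern, and microsynteny is
quantified as the number of unordered pairs (triplets) of ortholog pairs
whose members lie within a bounded window -- default 20 kb for pairs, 40 kb
for triplets -- on one scaffold in *both* species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ks_compare
from .io import SimilarityHit

logger = logging.getLogger(__name__)


@dataclass
class OrthologMap:
    pairs: set[tuple[str, str]] = field(default_factory=set)
    excluded: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        a_genes = [a for a, _ in self.pairs]
        b_genes = [b for _, b in self.pairs]
        if len(set(a_genes)) != len(a_genes) or len(set(b_genes)) != len(b_genes):
            raise ValueError("ortholog map must be one-to-one")


@dataclass
class GenePosition:
    gene_id: str
    scaffold: str
    start: int


def _best_hits(hits: Sequence[SimilarityHit], max_evalue: float) -> tuple[dict, set]:
    """Per-query best subject and the queries with tied top bitscores."""
    by_query: dict[str, list[SimilarityHit]] = {}
    for h in hits:
        if h.evalue <= max_evalue:
            by_query.setdefault(h.query, []).append(h)
    best: dict[str, str] = {}
    tied: set[str] = set()
    for q, hs in by_query.items():
        hs.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject))
        if len(hs) > 1 and hs[0].bitscore == hs[1].bitscore:
            tied.add(q)
        best[q] = hs[0].subject
    return best, tied


def reciprocal_best_hits(
    hits_ab: Sequence[SimilarityHit],
    hits_ba: Sequence[SimilarityHit],
    max_evalue: float = 1e-3,
) -> OrthologMap:
    """RBH orthology between species A and B.

    Best hit per query = highest bitscore (ties resolved by lower e-value,
    then lexicographic subject id). A pair (a, b) is kept iff best(a->b)=b
    and best(b->a)=a. A gene whose top two bitscores are exactly equal in
    either direction is unresolvable paralogy and goes to ``excluded``.
    """
    best_ab, tied_a = _best_hits(hits_ab, max_evalue)
    best_ba, tied_b = _best_hits(hits_ba, max_evalue)
    pairs = set()
    for a, b in best_ab.items():
        if a in tied_a or b in tied_b:
            continue
        if best_ba.get(b) == a:
            pairs.add((a, b))
    return OrthologMap(pairs=pairs, excluded=tied_a | tied_b)


def assign_lineage(
    presence: Mapping[str, set[str]],
    hierarchy: Sequence[tuple[str, set[str]]],
    excluded: set[str] | None = None,
) -> dict[str, str]:
    """Lineage-specificity group per gene from ortholog presence patterns.

    ``hierarchy`` is an ordered list of (label, species set) with each clade
    a superset of the previous; the first label is the orphan group (its
    species set should be empty). A gene is assigned the innermost clade
    whose species set covers every species it has an ortholog in. Genes in
    ``excluded`` (ambiguous paralogy) are dropped before assignment.
    """
    prev: set[str] = set()
    for label, spp in hierarchy:
        if not prev <= set(spp):
            raise ValueError(f"hierarchy not nested at group {label!r}")
        prev = set(spp)
    excluded = excluded or set()
    out: dict[str, str] = {}
    for gene, spp in presence.items():
        if gene in excluded:
            continue
        for label, clade in hierarchy:
            if spp <= set(clade):
                out[gene] = label
                break
        else:
            raise ValueError(
                f"gene {gene}: species {sorted(spp)} not covered by the outermost clade"
            )
    return out


def group_summaries(
    assignments: Mapping[str, str],
    group_order: Sequence[str],
    peptide_lengths: Mapping[str, int] | None = None,
    dev_calls: Mapping[str, str] | None = None,
    rpkm_by_condition: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Per-group table: n, median peptide length, % differentially expressed
    up/down during sexual development, and KS tests of the sex RPKM
    distribution against DD and vegmix within each group."""
    rows = []
    for label in group_order:
        genes = [g for g, grp in assignments.items() if grp == label]
        row: dict = {"group": label, "n": len(genes)}
        if peptide_lengths is not None:
            pls = [peptide_lengths[g] for g in genes if g in peptide_lengths]
            row["median_peptide_length"] = float(np.median(pls)) if pls else np.nan
        if dev_calls is not None:
            calls = [dev_calls[g] for g in genes if g in dev_calls]
            n = len(calls)
            row["pct_up_in_sex"] = 100 * sum(c == "up_in_sex" for c in calls) / n if n else np.nan
            row["pct_down_in_sex"] = (
                100 * sum(c == "down_in_sex" for c in calls) / n if n else np.nan
            )
        if rpkm_by_condition is not None:
            vals = {
                cond: np.array([v[g] for g in genes if g in v])
                for cond, v in rpkm_by_condition.items()
            }
            sex = vals.get("sex", np.array([]))
            for other in ("DD", "vegmix"):
                key = f"ks_p_sex_vs_{other}"
                if sex.size and vals.get(other) is not None and vals[other].size:
                    _, row[key] = ks_compare(sex, vals[other])
                else:
                    row[key] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _positions_by_scaffold(
    positions: Mapping[str, GenePosition], genes: Sequence[str]
) -> dict[str, list[tuple[int, str]]]:
    by_scaf: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        p = positions[g]
        by_scaf.setdefault(p.scaffold, []).append((p.start, g))
    for lst in by_scaf.values():
        lst.sort()
    return by_scaf


def syntenic_pairs_triplets(
    pos_a: Mapping[str, GenePosition],
    pos_b: Mapping[str, GenePosition],
    orthologs: OrthologMap,
    pair_window: int = 20_000,
    triplet_window: int = 40_000,
) -> tuple[int, int]:
    """Count syntenic ortholog pairs and triplets.

    A pair is two distinct ortholog pairs whose A genes share a scaffold
    within ``pair_window`` (start-coordinate distance) AND whose B genes
    share a scaffold within ``pair_window``; a triplet requires all three
    pairwise distances <= ``triplet_window`` in both species. Each unordered
    set is counted once. Scans per-scaffold sorted gene lists with a sliding
    coordinate window; validated in the test suite against brute-force
    subset enumeration.
    """
    a_to_b = dict(orthologs.pairs)
    for g in a_to_b:
        if g not in pos_a:
            raise KeyError(f"no position for gene {g} in species A")
    for g in a_to_b.values():
        if g not in pos_b:
            raise KeyError(f"no position for gene {g} in species B")
    by_scaf = _positions_by_scaffold(pos_a, list(a_to_b))

    def b_ok(g1: str, g2: str, window: int) -> bool:
        p1, p2 = pos_b[a_to_b[g1]], pos_b[a_to_b[g2]]
        return p1.scaffold == p2.scaffold and abs(p1.start - p2.start) <= window

    window = max(pair_window, triplet_window)
    n_pairs = n_triplets = 0
    for _, lst in sorted(by_scaf.items()):
        n = len(lst)
        for i in range(n):
            si, gi = lst[i]
            js = []
            for j in range(i + 1, n):
                sj, gj = lst[j]
                if sj - si > window:
                    break
                if sj - si <= pair_window and b_ok(gi, gj, pair_window):
                    n_pairs += 1
                if sj - si <= triplet_window:
                    js.append(j)
            for x in range(len(js)):
                jx = js[x]
                sx, gx = lst[jx]
                for y in range(x + 1, len(js)):
                    jy = js[y]
                    sy, gy = lst[jy]
                    if sy - si > triplet_window:
                        break
                    if (
                        sy - sx <= triplet_window
                        and b_ok(gi, gx, triplet_window)
                        and b_ok(gi, gy, triplet_window)
                        and b_ok(gx, gy, triplet_window)
                    ):
                        n_triplets += 1
    return n_pairs, n_triplets


def syntenic_counts_bruteforce(
    pos_a: Mapping[str, GenePosition],
    pos_b: Mapping[str, GenePosition],
    orthologs: OrthologMap,
    pair_window: int = 20_000,
    triplet_window: int = 40_000,
) -> tuple[int, int]:
    """O(n^2)/O(n^3) all-subsets oracle for :func:`syntenic_pairs_triplets`.

    Enumerates every unordered pair and triple of ortholog pairs via dense
    pairwise closeness matrices; deliberately independent of the
    sliding-window implementation it validates.
    """
    a_to_b = dict(orthologs.pairs)
    genes = sorted(a_to_b)
    n = len(genes)

    def close_matrix(p: Mapping[str, GenePosition], ids: Sequence[str], w: int) -> np.ndarray:
        scafs = np.array([p[g].scaffold for g in ids])
        starts = np.array([p[g].start for g in ids])
        same = scafs[:, None] == scafs[None, :]
        near = np.abs(starts[:, None] - starts[None, :]) <= w
        return same & near

    b_ids = [a_to_b[g] for g in genes]
    pair_ok = close_matrix(pos_a, genes, pair_window) & close_matrix(pos_b, b_ids, pair_window)
    iu = np.triu_indices(n, 1)
    n_pairs = int(pair_ok[iu].sum())
    trip_ok = close_matrix(pos_a, genes, triplet_window) & close_matrix(
        pos_b, b_ids, triplet_window
    )
    n_triplets = 0
    for i, j in zip(*np.triu_indices(n, 1)):
        if trip_ok[i, j]:
            ks = np.nonzero(trip_ok[i] & trip_ok[j])[0]
            n_triplets += int((ks > j).sum())
    return n_pairs, n_triplets


def read_positions_tsv(path) -> dict[str, GenePosition]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        if row.gene in out:
            raise ValueError(f"duplicate position for gene {row.gene}")
        out[row.gene] = GenePosition(row.gene, str(row.scaffold), int(row.start))
    return out


def write_positions_tsv(positions: Mapping[str, GenePosition], path) -> None:
    pd.DataFrame(
        [{"gene": p.gene_id, "scaffold": p.scaffold, "start": p.start} for p in positions.values()]
    ).to_csv(path, sep="\t", index=False)
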