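"""Sliding-window RIP (repeat-induced point mutation) index scanning.

RIP converts C:G pairs to T:A in duplicated sequence during the sexual
cycle, preferentially at CpA (and, on the other strand, TpG) sites. The
scanner computes in each window:

* product index   = TpA / ApT          (elevated by RIP: CpA -> TpA)
* substrate index = (CpA+TpG) / (ApC+GpT)  (depleted by RIP)
* composite index = product - substrate

A window is called ``ripped`` under the threshold rule (product >= 1.1 and
substrate < 0.9) or, in composite mode, when the composite index is > 0;
``non_ripped`` under the converse thresholds (product < 0.8 and substrate
>= 1.1). Windows with a zero denominator have undefined indices and never
contribute to regions.

Compositionally unbiased DNA has both indices near 1.0, i.e. right at the
calling thresholds, so isolated ripped windows are expected by chance.
Reported RIPped *regions* therefore require a sustained run of supporting
windows (``min_windows``, default 12 at the default 500/100 window/step,
i.e. ~1.6 kb of continuous evidence); see docs/methods.md for the null
calibration behind the default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import GenomeSequence

logger = logging.getLogger(__name__)

BASES = "ACGT"
DINUCS = [a + b for a in BASES for b in BASES]
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

#: calling thresholds for sequence that has been subjected to RIP
RIPPED_PRODUCT_MIN = 1.1
RIPPED_SUBSTRATE_MAX = 0.9
#: calling thresholds for sequence that has not been subjected to RIP
NONRIPPED_PRODUCT_MAX = 0.8
NONRIPPED_SUBSTRATE_MIN = 1.1


@dataclass
class DinucCounts:
    """Counts of the 16 overlapping dinucleotides of a window (N skipped)."""

    counts: dict[str, int]

    def __getitem__(self, dinuc: str) -> int:
        return self.counts.get(dinuc, 0)


@dataclass
class RipWindowScore:
    scaffold: str
    start: int
    end: int
    product_index: float | None
    substrate_index: float | None
    composite_index: float | None
    call: str  # ripped | non_ripped | indeterminate | undefined


@dataclass
class RipRegion:
    scaffold: str
    start: int
    end: int
    n_windows: int


def dinucleotide_counts(window: str) -> DinucCounts:
    """Count all overlapping dinucleotides on the given strand; any
    dinucleotide containing N is skipped."""
    if len(window) < 2:
        raise ValueError("window must be at least 2 bases")
    counts: dict[str, int] = {}
    for i in range(len(window) - 1):
        d = window[i : i + 2]
        if "N" in d:
            continue
        counts[d] = counts.get(d, 0) + 1
    return DinucCounts(counts)


def rip_indices(counts: DinucCounts) -> tuple[float | None, float | None, float | None]:
    """(product, substrate, composite); None where a denominator is zero."""
    product = counts["TA"] / counts["AT"] if counts["AT"] else None
    sub_den = counts["AC"] + counts["GT"]
    substrate = (counts["CA"] + counts["TG"]) / sub_den if sub_den else None
    composite = product - substrate if product is not None and substrate is not None else None
    return product, substrate, composite


def classify_window(
    product: float | None, substrate: float | None, mode: str = "thresholds"
) -> str:
    if mode not in {"thresholds", "composite"}:
        raise ValueError(f"unknown RIP classification mode {mode!r}")
    if product is None or substrate is None:
        return "undefined"
    if mode == "composite":
        return "ripped" if product - substrate > 0 else "non_ripped"
    if product >= RIPPED_PRODUCT_MIN and substrate < RIPPED_SUBSTRATE_MAX:
        return "ripped"
    if product < NONRIPPED_PRODUCT_MAX and substrate >= NONRIPPED_SUBSTRATE_MIN:
        return "non_ripped"
    return "indeterminate"


def window_count(L: int, window: int, step: int) -> int:
    """Number of fixed-size windows: floor((L - window)/step) + 1 for L >= window."""
    if L < window:
        return 0
    return (L - window) // step + 1


def _scan_scaffold(seq: str, window: int, step: int) -> np.ndarray:
    """Per-window counts of the six RIP-relevant dinucleotides.

    Returns an (n_windows, 6) array ordered TA, AT, CA, TG, AC, GT.
    """
    c = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = window_count(len(seq), window, step)
    starts = np.arange(n) * step
    valid = (c[:-1] >= 0) & (c[1:] >= 0)
    d = np.where(valid, c[:-1] * 4 + c[1:], -1)
    out = np.empty((n, 6), dtype=np.int64)
    for j, dinuc in enumerate(("TA", "AT", "CA", "TG", "AC", "GT")):
        code = BASES.index(dinuc[0]) * 4 + BASES.index(dinuc[1])
        cum = np.concatenate([[0], np.cumsum(d == code)])
        # dinucleotides starting in [start, start+window-2]
        out[:, j] = cum[starts + window - 1] - cum[starts]
    return out


def scan_genome(
    genome: Sequence[GenomeSequence],
    window: int = 500,
    step: int = 100,
    mode: str = "thresholds",
    min_windows: int = 12,
) -> tuple[list[RipWindowScore], list[RipRegion], float]:
    """Scan a genome; return per-window scores, merged RIPped regions, and
    the RIPped genome fraction (merged region length / total genome length).

    Overlapping or adjacent ripped windows merge into maximal regions; a
    region is reported only when supported by >= ``min_windows`` windows.
    """
    if not genome:
        raise ValueError("empty genome")
    if window < 2 or step < 1:
        raise ValueError("window must be >= 2 and step >= 1")
    classify_window(1.0, 1.0, mode)  # validate mode up front
    scores: list[RipWindowScore] = []
    regions: list[RipRegion] = []
    total_len = sum(len(r.seq) for r in genome)
    for rec in genome:
        n = window_count(len(rec.seq), window, step)
        if n == 0:
            logger.warning("scaffold %s shorter than window (%d bp), skipped", rec.id, window)
            continue
        counts = _scan_scaffold(rec.seq, window, step)
        run_start = run_n = 0
        run_end = -1
        for i in range(n):
            start = i * step
            ta, at, ca, tg, ac, gt = counts[i]
            product = ta / at if at else None
            den = ac + gt
            substrate = (ca + tg) / den if den else None
            composite = (
                product - substrate if product is not None and substrate is not None else None
            )
            call = classify_window(product, substrate, mode)
            scores.append(
                RipWindowScore(rec.id, start, start + window, product, substrate, composite, call)
            )
            if call == "ripped" and run_n > 0 and start <= run_end:
                run_n += 1
                run_end = start + window
            elif call == "ripped":
                if run_n >= min_windows:
                    regions.append(RipRegion(rec.id, run_start, run_end, run_n))
                run_start, run_end, run_n = start, start + window, 1
            else:
                if run_n >= min_windows:
                    regions.append(RipRegion(rec.id, run_start, run_end, run_n))
                run_n = 0
        if run_n >= min_windows:
            regions.append(RipRegion(rec.id, run_start, run_end, run_n))
    ripped_len = sum(r.end - r.start for r in regions)
    return scores, regions, ripped_len / total_len


def write_regions_bed(regions: Sequence[RipRegion], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions, 1):
            fh.write(f"{r.scaffold}\t{r.start}\t{r.end}\trip_region_{i}\t{r.n_windows}\n")


def write_windows_tsv(scores: Sequence[RipWindowScore], path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tstart\tend\tproduct\tsubstrate\tcomposite\tcall\n")
        for s in scores:
            def fmt(x):
                return "NA" if x is None else f"{x:.4f}"
            fh.write(
                f"{s.scaffold}\t{s.start}\t{s.end}\t{fmt(s.product_index)}"
                f"\t{fmt(s.substrate_index)}\t{fmt(s.composite_index)}\t{s.call}\n"
            )
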