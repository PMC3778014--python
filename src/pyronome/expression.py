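"""Ratio-based ("classical") RNA-seq differential-expression analysis.

Counts are normalised to each sample's library size; per-replicate
expression ratios between two conditions feed a five-tier classification
(groups 0-4) built from ratio thresholds and the coefficient of variation,
and a consensus verdict (-1/0/+1) combines the classical ratios with an
external Bayesian ratio/probability table. RPKM values, a univariate
Gaussian-mixture decomposition of log2 expression levels, and two-sample
Kolmogorov-Smirnov comparisons support the downstream expression-level
analyses.

Group rules (evaluated 4 > 3 > 2 > 1, first satisfied wins):

* group 4: ratios <= 0.25 or >= 4 in all replicates (same side)
* group 3: mean ratio <= 0.25 or >= 4 and CV < 0.5
* group 2: ratios <= 0.5 or >= 2 in all replicates (same side)
* group 1: mean ratio <= 0.5 or >= 2 and CV < 0.5
* group 0: everything else

CV is the sample standard deviation (n-1) over the mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import CountMatrix

logger = logging.getLogger(__name__)

COMPARISONS = (("sex", "DD"), ("sex", "vegmix"), ("DD", "vegmix"))

#: consensus ratio thresholds (up, down) per mode
CONSENSUS_THRESHOLDS = {"normal": (2.0, 0.5), "stringent": (4.0, 0.25)}
DEFAULT_PROB_THRESHOLD = 1.0 - 1e-6


@dataclass
class RatioRecord:
    gene_id: str
    comparison: str
    replicate_ratios: list[float]
    defined: bool
    mean_ratio: float = float("nan")
    sd: float = float("nan")
    cv: float = float("nan")

    def __post_init__(self) -> None:
        if self.defined:
            r = np.asarray(self.replicate_ratios, dtype=float)
            self.mean_ratio = float(r.mean())
            self.sd = float(r.std(ddof=1)) if r.size > 1 else 0.0
            self.cv = self.sd / self.mean_ratio if self.mean_ratio > 0 else float("inf")


@dataclass
class ConsensusCall:
    gene_id: str
    comparison: str
    call: int  # -1, 0, +1
    mode: str


def normalized_counts(cm: CountMatrix, scale: float = 1e6) -> np.ndarray:
    """Counts normalised to the total read count of each sample (x scale)."""
    totals = cm.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ValueError("sample with zero total counts")
    return cm.counts / totals * scale


def normalize_and_ratio(
    cm: CountMatrix, cond_a: str, cond_b: str, pairing: str = "index"
) -> list[RatioRecord]:
    """Per-gene replicate-paired expression ratios A/B on normalised counts.

    Replicate i of A is paired with replicate i of B (``pairing='index'``),
    or every A replicate with every B replicate (``pairing='all'``). A record
    is undefined (gene excluded downstream) when any paired denominator is 0.
    """
    norm = normalized_counts(cm)
    ia = cm.condition_columns(cond_a)
    ib = cm.condition_columns(cond_b)
    if pairing == "index":
        if len(ia) != len(ib):
            raise ValueError(
                f"conditions {cond_a}/{cond_b} have {len(ia)} vs {len(ib)} replicates"
            )
        pairs = list(zip(ia, ib))
    elif pairing == "all":
        pairs = [(a, b) for a in ia for b in ib]
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    comparison = f"{cond_a}/{cond_b}"
    out = []
    for gi, gene in enumerate(cm.genes):
        dens = [norm[gi, b] for _, b in pairs]
        if any(d == 0 for d in dens):
            out.append(RatioRecord(gene, comparison, [], defined=False))
        else:
            ratios = [float(norm[gi, a] / norm[gi, b]) for a, b in pairs]
            out.append(RatioRecord(gene, comparison, ratios, defined=True))
    return out


def classify_group(record: RatioRecord) -> int | None:
    """Group 0-4 for a defined ratio record; None when undefined (excluded)."""
    if not record.defined:
        return None
    r = record.replicate_ratios
    mean, cv = record.mean_ratio, record.cv
    if all(x >= 4 for x in r) or all(x <= 0.25 for x in r):
        return 4
    if (mean >= 4 or mean <= 0.25) and cv < 0.5:
        return 3
    if all(x >= 2 for x in r) or all(x <= 0.5 for x in r):
        return 2
    if (mean >= 2 or mean <= 0.5) and cv < 0.5:
        return 1
    return 0


def consensus_call(
    gene_id: str,
    comparison: str,
    group: int | None,
    classical_ratio: float,
    external_ratio: float | None,
    external_probability: float | None,
    mode: str = "normal",
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
) -> ConsensusCall:
    """Combine the classical classification with an external Bayesian table.

    +1 iff both ratios exceed the mode's upper threshold, the external
    probability of differential expression is at threshold, and the gene is
    in groups 1-4; -1 analogously below the lower threshold; else 0.
    Missing external entries yield 0 with a warning.
    """
    if mode not in CONSENSUS_THRESHOLDS:
        raise ValueError(f"unknown consensus mode {mode!r}")
    hi, lo = CONSENSUS_THRESHOLDS[mode]
    if external_ratio is None or external_probability is None:
        logger.warning("gene %s %s: no external entry, consensus 0", gene_id, comparison)
        return ConsensusCall(gene_id, comparison, 0, mode)
    call = 0
    if group is not None and group >= 1 and external_probability >= prob_threshold:
        if classical_ratio > hi and external_ratio > hi:
            call = 1
        elif classical_ratio < lo and external_ratio < lo:
            call = -1
    return ConsensusCall(gene_id, comparison, call, mode)


def dev_specific(calls: Mapping[str, int]) -> str:
    """Development-specific verdict from the three comparison calls.

    ``up_in_sex`` iff sex/DD = +1, sex/vegmix = +1 and DD/vegmix = 0;
    ``down_in_sex`` analogously with -1; else ``none``.
    """
    trio = (calls["sex/DD"], calls["sex/vegmix"], calls["DD/vegmix"])
    if trio == (1, 1, 0):
        return "up_in_sex"
    if trio == (-1, -1, 0):
        return "down_in_sex"
    return "none"


def rpkm(cm: CountMatrix) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Reads per kilobase per million counted reads.

    Returns (per-sample RPKM matrix, per-condition means over replicates).
    """
    if (cm.gene_lengths <= 0).any():
        raise ValueError("zero-length gene")
    totals = cm.counts.sum(axis=0).astype(float)
    mat = cm.counts * 1e9 / (cm.gene_lengths[:, None] * totals[None, :])
    conditions = dict.fromkeys(s.rsplit("_", 1)[0] for s in cm.samples)
    cond_means = {
        c: mat[:, cm.condition_columns(c)].mean(axis=1) for c in conditions
    }
    return mat, cond_means


@dataclass
class MixtureFit:
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    responsibilities: np.ndarray
    log_likelihoods: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def labels(self) -> np.ndarray:
        return self.responsibilities.argmax(axis=1)


def mixture_fit(
    values: Sequence[float],
    k: int = 2,
    tol: float = 1e-8,
    max_iter: int = 500,
    var_floor: float = 1e-6,
) -> MixtureFit:
    """K-component univariate normal mixture by expectation-maximisation.

    Initialisation is deterministic: component means at the (i+0.5)/K
    quantiles of the data, equal weights, and the pooled sample variance.
    Converged when the log-likelihood improves by less than ``tol``.
    Callers should exclude the zero-coverage sentinel (-11) beforehand.
    """
    x = np.asarray(values, dtype=float)
    if x.size < k:
        raise ValueError(f"need at least k={k} observations, got {x.size}")
    means = np.quantile(x, (np.arange(k) + 0.5) / k)
    variances = np.full(k, max(x.var(), var_floor))
    weights = np.full(k, 1.0 / k)
    lls: list[float] = []
    resp = np.full((x.size, k), 1.0 / k)
    for _ in range(max_iter):
        # E step
        log_pdf = stats.norm.logpdf(x[:, None], means[None, :], np.sqrt(variances)[None, :])
        log_w = np.log(weights)[None, :] + log_pdf
        log_norm = np.logaddexp.reduce(log_w, axis=1)
        resp = np.exp(log_w - log_norm[:, None])
        ll = float(log_norm.sum())
        if lls and ll - lls[-1] < tol:
            lls.append(ll)
            return MixtureFit(means, variances, weights, resp, lls, converged=True)
        lls.append(ll)
        # M step
        nk = resp.sum(axis=0)
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = np.maximum(
            (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk, var_floor
        )
    return MixtureFit(means, variances, weights, resp, lls, converged=False)


def ks_compare(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test (asymptotic p-value)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if min(a.size, b.size) < 25:
        logger.warning(
            "KS asymptotic p-value with min(n, m)=%d < 25 is approximate",
            min(a.size, b.size),
        )
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def classify_all(
    cm: CountMatrix,
    external: Mapping[tuple[str, str], tuple[float, float]] | None = None,
    mode: str = "normal",
    pairing: str = "index",
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
) -> dict[str, dict]:
    """Full classical pipeline over the three study comparisons.

    ``external`` maps (gene, comparison) to (ratio, probability). Returns a
    per-gene dict with ratio records, groups, consensus calls and the
    development-specific verdict ('NA' when any comparison is undefined).
    """
    per_gene: dict[str, dict] = {
        g: {"ratios": {}, "groups": {}, "calls": {}} for g in cm.genes
    }
    if external is None:
        logger.warning("no external ratio/probability table: all consensus calls will be 0")
        external = {}
    n_missing = 0
    for cond_a, cond_b in COMPARISONS:
        comparison = f"{cond_a}/{cond_b}"
        for rec in normalize_and_ratio(cm, cond_a, cond_b, pairing=pairing):
            group = classify_group(rec)
            entry = per_gene[rec.gene_id]
            entry["ratios"][comparison] = rec
            entry["groups"][comparison] = group
            if not rec.defined:
                entry["calls"][comparison] = None
                continue
            ext = external.get((rec.gene_id, comparison))
            if ext is None:
                n_missing += 1
                entry["calls"][comparison] = 0
                continue
            cc = consensus_call(
                rec.gene_id,
                comparison,
                group,
                rec.mean_ratio,
                ext[0],
                ext[1],
                mode=mode,
                prob_threshold=prob_threshold,
            )
            entry["calls"][comparison] = cc.call
    if n_missing:
        logger.warning(
            "%d gene/comparison entries missing from the external table: consensus 0",
            n_missing,
        )
    for gene, entry in per_gene.items():
        calls = entry["calls"]
        if any(v is None for v in calls.values()):
            entry["dev_specific"] = "NA"
        else:
            entry["dev_specific"] = dev_specific(calls)
    return per_gene
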