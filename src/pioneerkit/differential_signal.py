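"""Region quantification and a simplified negative-binomial differential test.

The test is a deliberately simple NB Wald test (no dispersion-trend fitting,
no fold-change shrinkage, no outlier filtering): per-region log2 fold change
on median-of-ratios-normalized means with a pseudocount, a method-of-moments
dispersion estimate shrunk toward the across-region median, and a two-sided
normal tail on the Wald statistic. Multiple testing is corrected with
Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_intervals import GenomicInterval, as_reads_frame

logger = logging.getLogger(__name__)

LOG2 = np.log(2.0)


@dataclass
class RegionCountMatrix:
    """Regions x samples read counts with per-sample condition labels."""

    regions: list[GenomicInterval]
    samples: list[str]
    conditions: list[str]  # per sample, "treated" or "control"
    counts: np.ndarray  # shape (n_regions, n_samples), nonnegative ints
    strandness: str = "none"  # {"none", "reverse"}

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.regions)} regions x {len(self.samples)} samples"
            )
        if len(self.conditions) != len(self.samples):
            raise ValueError("one condition label required per sample")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "strand": [r.strand for r in self.regions],
            }
        )
        for j, s in enumerate(self.samples):
            df[s] = self.counts[:, j]
        return df


def _count_chrom(
    reads: pd.DataFrame, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Overlap counts per region via sorted-boundary inclusion-exclusion.

    A read [s, e) overlaps region [S, E) iff s < E and e > S. The two
    failure sets {s >= E} and {e <= S} are disjoint for S < E, so
    count = n - #{s >= E} - #{e <= S}.
    """
    rs = np.sort(reads["start"].to_numpy(dtype=np.int64))
    re_ = np.sort(reads["end"].to_numpy(dtype=np.int64))
    n = len(rs)
    start_ge_E = n - np.searchsorted(rs, ends, side="left")
    end_le_S = np.searchsorted(re_, starts, side="right")
    return n - start_ge_E - end_le_S


def _count_sample(
    frame: pd.DataFrame,
    regions: list[GenomicInterval],
    strandness: str,
    mode: str,
) -> np.ndarray:
    counts = np.zeros(len(regions), dtype=np.int64)
    region_idx: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(regions):
        region_idx.setdefault((r.chrom, r.strand), []).append(i)

    if mode == "five_prime":
        if strandness == "reverse" and len(frame) and (frame["strand"] == ".").any():
            raise ValueError("reverse strandness requires stranded reads")
        pos = np.where(
            frame["strand"].to_numpy() == "+",
            frame["start"].to_numpy(dtype=np.int64),
            frame["end"].to_numpy(dtype=np.int64) - 1,
        )
        frame = frame.assign(start=pos, end=pos + 1)

    for (chrom, rstrand), idxs in region_idx.items():
        sub = frame[frame["chrom"] == chrom]
        if mode == "five_prime" and strandness != "none" and rstrand != ".":
            # reverse-stranded library: a read is assigned to features on the
            # opposite strand (featureCounts -s 2 convention); forward: same
            if strandness == "reverse":
                want = "-" if rstrand == "+" else "+"
            else:
                want = rstrand
            sub = sub[sub["strand"] == want]
        if len(sub) == 0:
            continue
        starts = np.asarray([regions[i].start for i in idxs], dtype=np.int64)
        ends = np.asarray([regions[i].end for i in idxs], dtype=np.int64)
        counts[np.asarray(idxs)] = _count_chrom(sub, starts, ends)
    return counts


def count_regions(
    sample_reads: dict,
    conditions: dict,
    regions: list[GenomicInterval],
    strandness: str = "none",
    mode: str = "fragment",
) -> RegionCountMatrix:
    """Count reads/fragments per region per sample.

    ``sample_reads`` maps sample label -> read set (DataFrame or interval
    sequence); ``conditions`` maps sample label -> "treated"/"control".
    A read is assigned to *every* region it overlaps (multi-assignment).
    ``mode="fragment"`` counts any-overlap of the full fragment, ignoring
    strand; ``mode="five_prime"`` counts single-base 5' positions, and with
    ``strandness="reverse"`` assigns reads to opposite-strand features only.
    """
    if strandness not in ("none", "reverse", "forward"):
        raise ValueError(f"unknown strandness {strandness!r}")
    if mode not in ("fragment", "five_prime"):
        raise ValueError(f"unknown mode {mode!r}")
    samples = list(sample_reads)
    counts = np.zeros((len(regions), len(samples)), dtype=np.int64)
    for j, label in enumerate(samples):
        frame = as_reads_frame(sample_reads[label])
        counts[:, j] = _count_sample(frame, regions, strandness, mode)
    return RegionCountMatrix(
        regions=list(regions),
        samples=samples,
        conditions=[conditions[s] for s in samples],
        counts=counts,
        strandness=strandness,
    )


def libsize_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library-size factors, rescaled to geometric mean 1.

    Regions with a zero count in any sample are excluded from the reference;
    if none survive, total-count scaling is used instead (logged).
    All-zero matrices are rejected.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or counts.sum() == 0:
        raise ValueError("cannot compute size factors for an all-zero matrix")
    allpos = (counts > 0).all(axis=1)
    if allpos.any():
        logref = np.log(counts[allpos]).mean(axis=1)  # log geometric mean per region
        factors = np.exp(
            np.median(np.log(counts[allpos]) - logref[:, None], axis=0)
        )
    else:
        logger.warning(
            "no region with all-positive counts; falling back to total-count scaling"
        )
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total count")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_differential(
    log2fc: np.ndarray, fdr: np.ndarray, fc_cut: float = 1.0, fdr_cut: float = 0.1
) -> np.ndarray:
    """Label regions increased / decreased / unchanged (strict inequalities)."""
    log2fc = np.asarray(log2fc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    labels = np.full(log2fc.shape, "unchanged", dtype=object)
    sig = fdr < fdr_cut
    labels[(log2fc > fc_cut) & sig] = "increased"
    labels[(log2fc < -fc_cut) & sig] = "decreased"
    return labels


def nb_test(
    matrix: RegionCountMatrix,
    factors: np.ndarray | None = None,
    pseudocount: float = 0.5,
    shrink_weight: float = 0.5,
    fc_cut: float = 1.0,
    fdr_cut: float = 0.1,
) -> pd.DataFrame:
    """Per-region NB Wald test of treated vs control.

    log2FC = log2((mean normalized treated + c) / (mean normalized control + c))
    with pseudocount c. The Wald variance uses NB variance mu + alpha*mu^2
    with a per-region method-of-moments dispersion, floored at 0 and shrunk
    toward the across-region median with weight ``shrink_weight``. P-values
    are two-sided tails of a t reference whose effective degrees of freedom
    account for the dispersion shrinkage; q-values are BH-adjusted.

    Returns a DataFrame with columns log2FC, pvalue, padj, baseMean,
    dispersion and class.
    """
    cond = np.asarray(matrix.conditions)
    t_idx = np.flatnonzero(cond == "treated")
    c_idx = np.flatnonzero(cond == "control")
    if len(t_idx) < 2 or len(c_idx) < 2:
        raise ValueError(
            "nb_test requires >=2 replicates per condition; "
            "use descriptive summaries for unreplicated designs"
        )
    counts = matrix.counts.astype(float)
    if factors is None:
        factors = libsize_factors(counts)
    factors = np.asarray(factors, dtype=float)
    norm = counts / factors

    m_t = norm[:, t_idx].mean(axis=1)
    m_c = norm[:, c_idx].mean(axis=1)
    log2fc = np.log2((m_t + pseudocount) / (m_c + pseudocount))
    base_mean = norm.mean(axis=1)

    # method-of-moments dispersion from pooled within-condition variance:
    # Var(normalized count) = mu/f + alpha*mu^2  (NB with mean mu*f per sample)
    n_t, n_c = len(t_idx), len(c_idx)
    var_t = norm[:, t_idx].var(axis=1, ddof=1)
    var_c = norm[:, c_idx].var(axis=1, ddof=1)
    s2 = ((n_t - 1) * var_t + (n_c - 1) * var_c) / (n_t + n_c - 2)
    inv_f = 1.0 / factors
    h = inv_f.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = (s2 - base_mean * h) / np.square(base_mean)
    alpha_raw = np.where(base_mean > 0, alpha_raw, 0.0)
    alpha_raw = np.maximum(alpha_raw, 0.0)
    alpha_med = float(np.median(alpha_raw[base_mean > 0])) if (base_mean > 0).any() else 0.0
    alpha = shrink_weight * alpha_raw + (1.0 - shrink_weight) * alpha_med

    # Wald variance of log2(mean + c) per condition, delta method
    def _var_log2_mean(mean: np.ndarray, idx: np.ndarray) -> np.ndarray:
        # Var(sample mean of normalized counts); q = normalized mean
        q = np.maximum(mean, 0.0)
        var_mean = (q * inv_f[idx].sum() / len(idx) ** 2) + alpha * q**2 / len(idx)
        return var_mean / np.square((mean + pseudocount) * LOG2)

    var_log = _var_log2_mean(m_t, t_idx) + _var_log2_mean(m_c, c_idx)
    se = np.sqrt(var_log)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    # t reference with Satterthwaite-style effective df: shrinking the
    # dispersion with weight w toward the across-region median scales the
    # variance-estimator noise by w^2, so df_eff = (n_t + n_c - 2) / w^2
    df_eff = (n_t + n_c - 2) / max(shrink_weight, 1e-3) ** 2
    pvalue = 2.0 * stats.t.sf(np.abs(wald), df_eff)
    pvalue = np.clip(pvalue, 0.0, 1.0)
    # regions with no signal at all are uninformative
    pvalue = np.where((m_t == 0) & (m_c == 0), 1.0, pvalue)
    padj = bh_adjust(pvalue)

    result = pd.DataFrame(
        {
            "log2FC": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "baseMean": base_mean,
            "dispersion": alpha,
        }
    )
    result["class"] = classify_differential(log2fc, padj, fc_cut, fdr_cut)
    return result
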