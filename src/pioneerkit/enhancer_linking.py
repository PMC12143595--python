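"""Enhancer-to-gene linking with distance and significance filters.

Chromatin-interaction pairs (given as input, not computed) connect
transcription-initiation peaks at enhancers to genes. Proximal pairs are
removed with a minimum-distance filter (default 2.5 kb between the peak
summit and the annotated gene TSS), and candidate target genes are those
reachable through a factor-bound, significantly induced enhancer TSS whose
linked gene is itself significantly upregulated.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LINK_COLUMNS = [
    "peak_id", "gene_id", "distance", "tss_log2fc", "tss_fdr",
    "gene_log2fc", "gene_fdr", "p53_bound",
]


def build_links(
    ctss_peaks: pd.DataFrame,
    pairs: pd.DataFrame,
    gene_table: pd.DataFrame,
    min_distance: int = 2500,
) -> pd.DataFrame:
    """Join peaks to genes through interaction pairs and drop proximal links.

    ``ctss_peaks`` needs columns peak_id, chrom, summit, log2FC, FDR and
    p53_bound; ``pairs`` needs peak_id and gene_id; ``gene_table`` needs
    gene_id, chrom, tss_pos, log2FC and FDR. Distance is measured from the
    peak summit to the annotated gene TSS; links with distance <
    ``min_distance`` are removed (promoter-proximal). Cross-chromosome
    pairs are kept as distal. Pairs referencing unknown peaks or genes are
    dropped with a warning.
    """
    peaks = ctss_peaks.set_index("peak_id")
    genes = gene_table.set_index("gene_id")
    rows = []
    for _, pair in pairs.iterrows():
        pid, gid = pair["peak_id"], pair["gene_id"]
        if pid not in peaks.index:
            logger.warning("pair references unknown peak %r; dropped", pid)
            continue
        if gid not in genes.index:
            logger.warning("pair references unknown gene %r; dropped", gid)
            continue
        pk, gn = peaks.loc[pid], genes.loc[gid]
        if pk["chrom"] == gn["chrom"]:
            distance = abs(int(pk["summit"]) - int(gn["tss_pos"]))
            if distance < min_distance:
                continue
        else:
            distance = -1  # trans pair: unquestionably distal
        rows.append(
            {
                "peak_id": pid,
                "gene_id": gid,
                "distance": distance,
                "tss_log2fc": float(pk["log2FC"]),
                "tss_fdr": float(pk["FDR"]),
                "gene_log2fc": float(gn["log2FC"]),
                "gene_fdr": float(gn["FDR"]),
                "p53_bound": bool(pk["p53_bound"]),
            }
        )
    return pd.DataFrame(rows, columns=LINK_COLUMNS)


def candidate_genes(
    links: pd.DataFrame,
    tss_fc: float = 1.0,
    tss_fdr: float = 0.1,
    gene_fc: float = 0.5,
    gene_fdr: float = 0.05,
) -> list[str]:
    """Deduplicated genes with >= 1 qualifying factor-bound enhancer link.

    A link qualifies iff the peak is factor-bound AND the enhancer TSS is
    significantly induced (log2FC > tss_fc, FDR < tss_fdr) AND the gene is
    significantly upregulated (log2FC > gene_fc, FDR < gene_fdr); all
    inequalities strict. Output is sorted; loosening any threshold never
    removes a candidate.
    """
    if len(links) == 0:
        return []
    ok = (
        links["p53_bound"]
        & (links["tss_log2fc"] > tss_fc)
        & (links["tss_fdr"] < tss_fdr)
        & (links["gene_log2fc"] > gene_fc)
        & (links["gene_fdr"] < gene_fdr)
    )
    return sorted(links.loc[ok, "gene_id"].unique())


def change_correlation(
    tss_log2fc,
    gene_log2fc,
    p53_bound=None,
    subset: str = "all",
) -> tuple[float, float]:
    """Spearman rank correlation (average-rank ties, two-sided p).

    ``subset="p53_bound"`` restricts to links whose peak is factor-bound.
    Constant inputs make the correlation undefined: (nan, nan) is returned.
    """
    x = np.asarray(tss_log2fc, dtype=float)
    y = np.asarray(gene_log2fc, dtype=float)
    if subset == "p53_bound":
        if p53_bound is None:
            raise ValueError("subset='p53_bound' requires the p53_bound flags")
        mask = np.asarray(p53_bound, dtype=bool)
        x, y = x[mask], y[mask]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    if len(x) < 3:
        raise ValueError("need >= 3 pairs for a rank correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
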