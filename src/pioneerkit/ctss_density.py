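"""Transcription-initiation (CTSS) positional density around RE centers.

Each canonical response element contributes a per-region-normalized vector
of 5'-end read counts over a fixed offset window (default center +-200 bp);
regions with too few reads are dropped, and the mean of the normalized
vectors is the density profile. A coarse offset histogram (enrichment over
the uniform expectation) and a smoothed mode finder complete the picture:
on treated data the density is expected to show modes at the RE itself and
at ~+50 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_intervals import SignalTrack

logger = logging.getLogger(__name__)


@dataclass
class DensityProfile:
    """Mean normalized CTSS density over offsets around RE centers."""

    offsets: np.ndarray       # -flank..+flank inclusive
    density: np.ndarray       # mean of per-region normalized vectors
    n_regions: int
    stratum: str = "all"
    condition: str = ""

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets)
        self.density = np.asarray(self.density, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "density": self.density,
                "n_regions": self.n_regions,
                "stratum": self.stratum,
                "condition": self.condition,
            }
        )


def density_profile(
    ctss_track: SignalTrack,
    re_centers,
    min_reads: int = 5,
    flank: int = 200,
    stratum: str = "all",
    condition: str = "",
    strand: str | None = None,
) -> DensityProfile:
    """Mean per-region-normalized 5'-end density around RE centers.

    ``re_centers`` is a sequence of (chrom, center) pairs — canonical REs
    only, by the caller's selection. Each region's window is center
    ``+-flank`` (2*flank+1 positions); regions with a total read count
    below ``min_reads`` are dropped. Each surviving region's count vector
    is divided by its own total, so the mean density sums to 1. Strands are
    pooled unless ``strand`` is given (diagnostic mode).
    """
    centers = list(re_centers)
    width = 2 * flank + 1
    acc = np.zeros(width)
    n_used = 0
    for chrom, center in centers:
        window = ctss_track.window_array(
            chrom, int(center) - flank, int(center) + flank + 1, strand=strand
        )
        total = window.sum()
        if total < min_reads:
            continue
        acc += window / total
        n_used += 1
    if n_used == 0:
        logger.info("density_profile[%s/%s]: no region passed min_reads=%d",
                    stratum, condition, min_reads)
        return DensityProfile(
            offsets=np.arange(-flank, flank + 1), density=acc,
            n_regions=0, stratum=stratum, condition=condition,
        )
    return DensityProfile(
        offsets=np.arange(-flank, flank + 1), density=acc / n_used,
        n_regions=n_used, stratum=stratum, condition=condition,
    )


def density_profiles_by_stratum(
    ctss_track: SignalTrack,
    re_centers,
    strata,
    min_reads: int = 5,
    flank: int = 200,
    condition: str = "",
) -> dict[str, DensityProfile]:
    """Per-stratum profiles plus the pooled "all" profile.

    ``strata`` is a parallel sequence of stratum labels for ``re_centers``.
    Mass-weighting the stratified profiles by their region counts recovers
    the unstratified profile exactly.
    """
    centers = list(re_centers)
    labels = list(strata)
    if len(centers) != len(labels):
        raise ValueError("re_centers and strata must be parallel")
    out: dict[str, DensityProfile] = {}
    for lab in sorted(set(labels)):
        subset = [c for c, l in zip(centers, labels) if l == lab]
        out[lab] = density_profile(
            ctss_track, subset, min_reads, flank, stratum=lab, condition=condition
        )
    out["all"] = density_profile(
        ctss_track, centers, min_reads, flank, stratum="all", condition=condition
    )
    return out


def offset_histogram(
    offsets, span: int = 401, n_windows: int = 19
) -> pd.DataFrame:
    """Coarse positional-enrichment histogram of RE-center-to-CTSS offsets.

    Offsets (within +-span//2) are binned into contiguous windows of width
    ceil(span / n_windows) starting at -span//2; the last window is
    truncated at +span//2. Enrichment is the observed bin fraction over the
    uniform expectation (bin width / span), so the width-weighted mean
    enrichment is 1. Returns a frame with bin_start, bin_end (inclusive),
    count, fraction and enrichment.
    """
    offsets = np.asarray(list(offsets), dtype=np.int64)
    if offsets.size == 0:
        raise ValueError("offset_histogram requires at least one offset")
    half = span // 2
    keep = (offsets >= -half) & (offsets <= half)
    offsets = offsets[keep]
    if offsets.size == 0:
        raise ValueError(f"no offsets within +-{half}")
    width = int(np.ceil(span / n_windows))
    edges = np.arange(-half, half + 1, width)
    if edges[-1] <= half:
        edges = np.append(edges, half + 1)  # truncated final bin
    counts, _ = np.histogram(offsets, bins=edges)
    widths = np.diff(edges)
    fraction = counts / counts.sum()
    enrichment = fraction / (widths / span)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:] - 1,
            "count": counts,
            "fraction": fraction,
            "enrichment": enrichment,
        }
    )


def peak_offsets(
    profile: DensityProfile,
    n_modes: int = 2,
    smooth_bw: int = 5,
    min_separation: int = 20,
) -> list[int]:
    """Mode offsets of a density profile (sorted by height, tallest first).

    The profile is smoothed with a centered moving average of width
    ``smooth_bw``; local maxima at least ``min_separation`` bp apart are
    ranked by smoothed height and the top ``n_modes`` returned. If fewer
    maxima exist, the available ones are returned (logged). Results are
    invariant under rescaling of the profile.
    """
    from scipy.signal import find_peaks

    if profile.density.sum() <= 0:
        raise ValueError("cannot find modes of an empty profile")
    kernel = np.ones(smooth_bw) / smooth_bw
    smooth = np.convolve(profile.density, kernel, mode="same")
    idx, _ = find_peaks(smooth, distance=min_separation)
    if len(idx) == 0:
        # monotone or single-spike profiles: fall back to the global argmax
        idx = np.array([int(np.argmax(smooth))])
    order = np.argsort(smooth[idx])[::-1]
    top = idx[order[:n_modes]]
    if len(top) < n_modes:
        logger.info("peak_offsets: only %d mode(s) found (wanted %d)",
                    len(top), n_modes)
    return [int(profile.offsets[i]) for i in top]
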