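"""Layered classification of binding sites and its summary statistics.

A binding site is labeled along four independent axes:

* accessibility transition (constitutively_open / opened /
  constitutively_closed / putatively_closed), from peak presence in the
  control and treated conditions;
* collapsed chromatin state (promoter / enhancer / transcription /
  quiescent / n/a), from an 18-state segmentation;
* TSS status (induced / uninduced / none), from overlap with
  differential transcription-initiation peaks;
* response-element status (canonical / noncanonical / none), from the
  attached RE annotation.

The module also fits the occupancy-to-transcription sigmoid, whose
midpoint estimates the local binding-signal threshold above which a site
induces transcription initiation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_intervals import GenomicInterval, IntervalIndex, extend_interval

logger = logging.getLogger(__name__)

TRANSITIONS = (
    "constitutively_open",
    "opened",
    "constitutively_closed",
    "putatively_closed",
)

# 18-state -> 4-state chromatin collapse
COLLAPSE_MAP: dict[str, str] = {}
for _s in ("TssA", "TssBiv", "TssFlnk", "TssFlnkD", "TssFlnkU"):
    COLLAPSE_MAP[_s] = "promoter"
for _s in ("EnhA1", "EnhA2", "EnhBiv", "EnhG1", "EnhG2", "EnhWk"):
    COLLAPSE_MAP[_s] = "enhancer"
for _s in ("Tx", "TxWk"):
    COLLAPSE_MAP[_s] = "transcription"
for _s in ("Het", "Quies", "ReprPC", "ReprPCWk", "ZNF/Rpts"):
    COLLAPSE_MAP[_s] = "quiescent"

RE_SUBTYPES = {
    "two_half_sites_no_spacer": "canonical",
    "three_quarter_sites": "noncanonical",
    "spacer1_half_sites": "noncanonical",
    "single_half_site": "noncanonical",
    "none": "none",
}


@dataclass(frozen=True)
class BindingSite:
    """A binding site with occupancy (CPM) and RE annotation."""

    interval: GenomicInterval
    occupancy: float = 0.0
    re_subtype: str = "none"
    re_center: int | None = None

    def __post_init__(self) -> None:
        if self.re_subtype not in RE_SUBTYPES:
            raise ValueError(f"unknown RE subtype {self.re_subtype!r}")
        if self.re_subtype != "none" and self.re_center is not None:
            if not (self.interval.start <= self.re_center < self.interval.end):
                raise ValueError("re_center must lie inside the site interval")


def accessibility_transition(
    site: GenomicInterval | BindingSite,
    peaks_control: IntervalIndex,
    peaks_treated: IntervalIndex,
) -> str:
    """Open/closed transition label from peak presence in both conditions.

    Presence means >= 1 bp overlap with a peak. Sites open in control but
    not treated are labeled putatively_closed — retained but interpreted
    with caution, as such calls tend to be false positives.
    """
    iv = site.interval if isinstance(site, BindingSite) else site
    open_c = peaks_control.any_overlap(iv.chrom, iv.start, iv.end)
    open_t = peaks_treated.any_overlap(iv.chrom, iv.start, iv.end)
    if open_c:
        return "constitutively_open" if open_t else "putatively_closed"
    return "opened" if open_t else "constitutively_closed"


def collapse_state(state18: str) -> str:
    """Reduce an 18-state chromatin label to the four collapsed classes.

    Unlisted labels map to "n/a" (unannotated region).
    """
    return COLLAPSE_MAP.get(state18, "n/a")


def re_status(site: BindingSite) -> tuple[str, str]:
    """(canonical/noncanonical/none, subtype) from the RE annotation."""
    return RE_SUBTYPES[site.re_subtype], site.re_subtype


def tss_status(
    site: GenomicInterval | BindingSite,
    ctss_peaks: list,
    peak_log2fc: dict | None = None,
    extension: int = 200,
    induced_cut: float = 0.5,
    induced_dominates: bool = True,
) -> str:
    """TSS status of a site: induced / uninduced / none.

    ``ctss_peaks`` is a list of (interval, log2fc) pairs, or CTSSPeak
    objects with ``peak_log2fc`` mapping summit-keyed ids; each peak is
    extended ``extension`` bp upstream (strand-aware) before overlap.
    A site overlapping any TSS with log2fc > ``induced_cut`` is induced
    (strict inequality); overlapping only weaker TSSs -> uninduced;
    no overlap -> none.
    """
    iv = site.interval if isinstance(site, BindingSite) else site
    fcs: list[float] = []
    for item in ctss_peaks:
        if isinstance(item, tuple):
            peak_iv, fc = item
        else:  # CTSSPeak
            peak_iv = item.interval
            fc = peak_log2fc[id(item)] if peak_log2fc else 0.0
        ext = extend_interval(peak_iv, upstream=extension, strand_aware=True)
        if ext.chrom == iv.chrom and ext.start < iv.end and iv.start < ext.end:
            fcs.append(float(fc))
    if not fcs:
        return "none"
    if induced_dominates:
        return "induced" if max(fcs) > induced_cut else "uninduced"
    return "induced" if fcs[0] > induced_cut else "uninduced"


@dataclass
class LayerSummary:
    """Counts, percentages and pairwise contingency tables over layer axes."""

    total: int
    counts: dict = field(default_factory=dict)       # axis -> {label: count}
    fractions: dict = field(default_factory=dict)    # axis -> {label: fraction}
    crosstabs: dict = field(default_factory=dict)    # "a|b" -> nested counts

    def percent(self, axis: str, label: str, digits: int | None = 0) -> float:
        """Percentage of sites with ``label`` on ``axis`` (whole-percent
        rounding by default; ``digits=None`` returns the raw value)."""
        frac = self.fractions[axis].get(label, 0.0)
        pct = 100.0 * frac
        return pct if digits is None else round(pct, digits)

    def to_json(self) -> str:
        payload = {
            "total": self.total,
            "counts": self.counts,
            "fractions": self.fractions,
            "crosstabs": self.crosstabs,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def summarize_layers(
    site_table: pd.DataFrame, axes: list[str] | None = None
) -> LayerSummary:
    """Contingency summary of a per-site layer table.

    ``site_table`` has one row per site and one column per layer axis.
    Counts per axis sum to the total; percentages per axis sum to 100
    (up to rounding). Results are invariant to row order.
    """
    if axes is None:
        axes = [
            c for c in ("transition", "state", "tss_status", "re_status")
            if c in site_table.columns
        ]
    total = int(len(site_table))
    summary = LayerSummary(total=total)
    if total == 0:
        summary.counts = {a: {} for a in axes}
        summary.fractions = {a: {} for a in axes}
        return summary
    for axis in axes:
        vc = site_table[axis].value_counts()
        summary.counts[axis] = {str(k): int(v) for k, v in sorted(vc.items())}
        summary.fractions[axis] = {
            str(k): float(v) / total for k, v in sorted(vc.items())
        }
    for i, a in enumerate(axes):
        for b in axes[i + 1:]:
            ct = pd.crosstab(site_table[a], site_table[b])
            summary.crosstabs[f"{a}|{b}"] = {
                str(r): {str(c): int(ct.loc[r, c]) for c in ct.columns}
                for r in ct.index
            }
    return summary


# ---------------------------------------------------------------------------
# Occupancy -> transcription sigmoid
# ---------------------------------------------------------------------------

@dataclass
class SigmoidFit:
    """Four-parameter logistic fit of transcription change on log10 occupancy.

    ``x0`` (in log10 CPM) is the occupancy-threshold estimate; ``a`` and
    ``b`` are the lower and upper asymptotes and ``k`` the slope scale.
    """

    a: float
    b: float
    x0: float
    k: float
    r2: float
    rho: float
    rho_p: float
    converged: bool = True
    degenerate: bool = False
    linear_fallback: bool = False

    @property
    def occupancy_threshold(self) -> float:
        """Midpoint on the original CPM scale."""
        return 10.0**self.x0


def _sigmoid(logx: np.ndarray, a: float, b: float, x0: float, k: float) -> np.ndarray:
    z = np.clip(-(logx - x0) / k, -500.0, 500.0)
    return a + (b - a) / (1.0 + np.exp(z))


def fit_occupancy_response(
    occupancy: np.ndarray,
    delta_tss: np.ndarray,
    k_grid: tuple[float, ...] = (0.1, 0.3, 1.0),
    x0_quantiles: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9),
) -> SigmoidFit:
    """Least-squares sigmoid fit of local transcription change on occupancy.

    The fit is on log10 occupancy with multi-start initialization (x0 over
    data quantiles, k over ``k_grid``). Reports r^2 and the two-sided
    Spearman correlation. Constant responses are flagged degenerate; if no
    start converges a straight-line fallback is reported and flagged.
    """
    x = np.asarray(occupancy, dtype=float)
    y = np.asarray(delta_tss, dtype=float)
    if len(x) != len(y) or len(x) < 10:
        raise ValueError("need >= 10 paired observations")
    if (x <= 0).any():
        raise ValueError("occupancy must be positive (fit is on log10 scale)")
    logx = np.log10(x)

    if np.ptp(y) == 0 or np.ptp(logx) == 0:
        return SigmoidFit(
            a=float(y[0]), b=float(y[0]), x0=float(np.median(logx)), k=1.0,
            r2=0.0, rho=float("nan"), rho_p=float("nan"),
            converged=True, degenerate=True,
        )

    rho, rho_p = stats.spearmanr(x, y)
    sst = float(np.sum((y - y.mean()) ** 2))

    best: tuple[float, np.ndarray] | None = None
    for q in x0_quantiles:
        for k0 in k_grid:
            p0 = [float(y.min()), float(y.max()), float(np.quantile(logx, q)), k0]
            try:
                popt, _ = optimize.curve_fit(
                    _sigmoid, logx, y, p0=p0, maxfev=20_000
                )
            except (RuntimeError, optimize.OptimizeWarning):
                continue
            sse = float(np.sum((y - _sigmoid(logx, *popt)) ** 2))
            if np.isfinite(sse) and (best is None or sse < best[0]):
                best = (sse, popt)

    if best is None:
        logger.warning("sigmoid fit failed to converge; reporting linear fallback")
        slope, intercept = np.polyfit(logx, y, 1)
        resid = y - (slope * logx + intercept)
        r2 = 1.0 - float(np.sum(resid**2)) / sst
        return SigmoidFit(
            a=float(intercept), b=float(slope), x0=float(np.median(logx)), k=1.0,
            r2=r2, rho=float(rho), rho_p=float(rho_p),
            converged=False, linear_fallback=True,
        )

    sse, (a, b, x0, k) = best
    # normalize orientation: keep k > 0 by swapping asymptotes
    if k < 0:
        a, b, k = b, a, -k
    r2 = 1.0 - sse / sst
    return SigmoidFit(
        a=float(a), b=float(b), x0=float(x0), k=float(k),
        r2=float(r2), rho=float(rho), rho_p=float(rho_p),
    )
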