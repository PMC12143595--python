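"""Ground-truthed multi-omics simulator for pioneer-factor binding sites.

The generator emulates the signal structure the downstream analysis assumes:

* binding sites with graded occupancy (log-normal, in CPM-like units) and a
  response-element (RE) class (canonical / noncanonical / none);
* a collapsed chromatin state per site (promoter / enhancer / transcription /
  quiescent), emitted as an 18-state segmentation so state collapsing is
  exercised downstream;
* accessibility fragments in two size classes — sub-nucleosomal (< 120 bp)
  over nucleosome-depleted regions at open sites, and mono-nucleosome
  (180-240 bp) fragments placed around positioned nucleosome dyads;
* stranded CAGE 5'-end reads whose positions are RE center plus an offset
  drawn from a two-component Gaussian mixture (default centers 0 and +50 bp);
* negative-binomial replicate noise (variance mu + alpha*mu^2) around
  condition means, with treatment effects that depend on site occupancy;
* enhancer-gene pairs wiring a known set of genes to induced enhancer sites,
  plus a directly simulated gene-level differential table.

Open/closed ground truth is defined by the simulated nucleosome layout
(eviction), not by the downstream classifier's rule, so classifier recovery
is a genuine test. All randomness flows from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_intervals import GenomicInterval, write_bed

SUBNUC_MAX = 120        # sub-nucleosomal fragments: length < 120 bp
MONO_RANGE = (180, 240)  # mono-nucleosome fragments: 180-240 bp inclusive

COLLAPSED_STATES = ("promoter", "enhancer", "transcription", "quiescent")

# 18-state labels per collapsed class, used to emit a segmentation that the
# state-collapsing stage has to reduce again
STATE18_BY_CLASS = {
    "promoter": ["TssA", "TssBiv", "TssFlnk", "TssFlnkD", "TssFlnkU"],
    "enhancer": ["EnhA1", "EnhA2", "EnhBiv", "EnhG1", "EnhG2", "EnhWk"],
    "transcription": ["Tx", "TxWk"],
    "quiescent": ["Het", "Quies", "ReprPC", "ReprPCWk", "ZNF/Rpts"],
}

NONCANONICAL_SUBTYPES = (
    "three_quarter_sites",
    "spacer1_half_sites",
    "single_half_site",
)


@dataclass
class SimulationConfig:
    """Study conditions for the simulator. Defaults are the package's
    reference conditions; see docs for rationale."""

    n_chroms: int = 2
    chrom_length: int = 300_000
    n_sites: int = 500
    # RE class probabilities (canonical, noncanonical, none)
    re_class_probs: tuple[float, float, float] = (0.70, 0.18, 0.12)
    # marginal collapsed-state probabilities (promoter, enhancer,
    # transcription, quiescent)
    state_probs: tuple[float, float, float, float] = (0.15, 0.25, 0.25, 0.35)
    # occupancy (CPM-like): log-normal on natural log scale
    occupancy_mu: float = float(np.log(10.0))
    occupancy_sigma: float = 1.2
    open_fraction_baseline: float = 0.27
    # constitutive openness is state dependent: baseline * multiplier
    open_state_multipliers: dict = field(
        default_factory=lambda: {
            "promoter": 2.0, "enhancer": 1.6, "transcription": 0.5, "quiescent": 0.35,
        }
    )
    # eviction (opening) of closed sites upon treatment: logistic in log10
    # occupancy, midpoint x0 and slope k
    evict_x0_log10: float = 1.6
    evict_k: float = 0.3
    # transcription induction: max CAGE log2FC times the same logistic form
    cage_max_log2fc: float = 4.0
    cage_x0_log10: float = 1.48
    cage_k: float = 0.25
    # TSS offset mixture relative to RE center (bp)
    tss_offset_centers: tuple[float, float] = (0.0, 50.0)
    tss_offset_weights: tuple[float, float] = (0.5, 0.5)
    tss_offset_sd: float = 5.0
    # per-site mean event counts per library before depth scaling
    atac_open_mean: float = 60.0
    atac_closed_mean: float = 2.0
    atac_open_boost: float = 1.4    # further opening of constitutively open sites
    mono_per_nucleosome: float = 15.0
    hist_base_mean: float = 20.0
    hist_state_multipliers: dict = field(
        default_factory=lambda: {
            "promoter": 2.0, "enhancer": 1.5, "transcription": 0.8, "quiescent": 0.3,
        }
    )
    cage_promoter_mean: float = 30.0
    cage_open_mean: float = 2.0
    cage_closed_mean: float = 0.3
    # background fragment rain (uniform), events per base per library
    background_rate: float = 2e-4
    nb_dispersion: float = 0.05
    n_replicates: dict = field(
        default_factory=lambda: {"atac": 4, "cage": 4, "h3k4me1": 2, "h3k27ac": 2}
    )
    depth: float = 100_000.0  # expected events per library (per assay)
    n_linked_genes: int = 12
    n_decoy_genes: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name, probs in (
            ("re_class_probs", self.re_class_probs),
            ("state_probs", self.state_probs),
            ("tss_offset_weights", self.tss_offset_weights),
        ):
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        if self.depth < 1 or any(r < 1 for r in self.n_replicates.values()):
            raise ValueError("depth and replicate counts must be >= 1")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Per-site and per-gene truth tables behind a simulated dataset."""

    sites: pd.DataFrame
    genes: pd.DataFrame


@dataclass
class SimulatedData:
    """Simulated read sets plus the static annotations the pipeline consumes.

    ``fragments[assay][condition]`` is a list of per-replicate DataFrames
    (chrom/start/end/strand); ``cage[condition]`` likewise (stranded).
    """

    fragments: dict
    cage: dict
    states_bed: list[GenomicInterval]
    pairs: pd.DataFrame
    gene_table: pd.DataFrame
    config: SimulationConfig


def _nb_sample(rng: np.random.Generator, mean, alpha: float, size=None) -> np.ndarray:
    """NB draw with variance mu + alpha*mu^2 (Poisson when alpha == 0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _frag_frame(chrom, start, end, strand=None) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
            "strand": strand if strand is not None else ".",
        }
    )


def _empty_reads() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=object),
        }
    )


def _place_sites(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Jittered-grid site placement, >= ~1 kb apart, away from chrom edges."""
    chroms = cfg.chrom_names()
    margin = 2_000
    per_chrom = [cfg.n_sites // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_sites % cfg.n_chroms):
        per_chrom[i] += 1
    rows = []
    sid = 0
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        usable = cfg.chrom_length - 2 * margin
        spacing = usable / n
        jitter = rng.integers(-int(min(200, spacing / 4)), int(min(200, spacing / 4)) + 1, n)
        centers = (margin + spacing * (np.arange(n) + 0.5)).astype(np.int64) + jitter
        for c in centers:
            rows.append({"site_id": f"site_{sid:04d}", "chrom": chrom, "center": int(c)})
            sid += 1
    df = pd.DataFrame(rows, columns=["site_id", "chrom", "center"])
    df["start"] = df["center"] - 100
    df["end"] = df["center"] + 100
    return df


def _simulate_sites(
    cfg: SimulationConfig, rng: np.random.Generator, null: bool
) -> pd.DataFrame:
    sites = _place_sites(cfg, rng)
    n = len(sites)
    if n == 0:
        return sites

    re_class = rng.choice(
        ["canonical", "noncanonical", "none"], size=n, p=list(cfg.re_class_probs)
    )
    subtype = np.where(
        re_class == "canonical",
        "two_half_sites_no_spacer",
        np.where(
            re_class == "noncanonical",
            rng.choice(NONCANONICAL_SUBTYPES, size=n),
            "none",
        ),
    )
    state = rng.choice(COLLAPSED_STATES, size=n, p=list(cfg.state_probs))
    state18 = np.array(
        [rng.choice(STATE18_BY_CLASS[s]) for s in state], dtype=object
    )
    occupancy = rng.lognormal(cfg.occupancy_mu, cfg.occupancy_sigma, n)
    p_open = np.clip(
        cfg.open_fraction_baseline
        * np.array([cfg.open_state_multipliers[s] for s in state]),
        0.0,
        1.0,
    )
    open_control = rng.random(n) < p_open
    # constitutively open sites carry somewhat higher occupancy
    occupancy = occupancy * np.where(open_control, 1.8, 1.0)

    log10_occ = np.log10(occupancy)
    p_evict = _logistic((log10_occ - cfg.evict_x0_log10) / cfg.evict_k)
    evicted = (~open_control) & (rng.random(n) < p_evict)
    if null:
        evicted[:] = False
    open_treated = open_control | evicted

    cage_lfc = cfg.cage_max_log2fc * _logistic(
        (log10_occ - cfg.cage_x0_log10) / cfg.cage_k
    )
    if null:
        cage_lfc[:] = 0.0

    sites["re_class"] = re_class
    sites["re_subtype"] = subtype
    sites["re_center"] = sites["center"]
    sites["state"] = state
    sites["state18"] = state18
    sites["occupancy"] = occupancy
    sites["open_control"] = open_control
    sites["open_treated"] = open_treated
    sites["transition"] = np.select(
        [open_control & open_treated, ~open_control & open_treated],
        ["constitutively_open", "opened"],
        default="constitutively_closed",
    )
    sites["true_cage_log2fc"] = cage_lfc
    return sites


def _condition_means(cfg: SimulationConfig, sites: pd.DataFrame, null: bool) -> pd.DataFrame:
    """Expected per-site event counts per library, per assay and condition."""
    means = pd.DataFrame(index=sites.index)
    if len(sites) == 0:
        for assay in ("atac", "h3k4me1", "h3k27ac", "cage"):
            means[f"{assay}_control"] = pd.Series(dtype=float)
            means[f"{assay}_treated"] = pd.Series(dtype=float)
        return means
    open_c = sites["open_control"].to_numpy()
    open_t = sites["open_treated"].to_numpy()

    means["atac_control"] = np.where(open_c, cfg.atac_open_mean, cfg.atac_closed_mean)
    means["atac_treated"] = np.where(
        open_t,
        np.where(open_c, cfg.atac_open_mean * cfg.atac_open_boost, cfg.atac_open_mean),
        cfg.atac_closed_mean,
    )

    hist_mult = sites["state"].map(cfg.hist_state_multipliers).to_numpy(dtype=float)
    hist_ctrl = cfg.hist_base_mean * hist_mult
    remodel_gain = np.select(
        [~open_c & open_t, ~open_c & ~open_t], [3.0, 1.7], default=1.3
    )
    for assay in ("h3k4me1", "h3k27ac"):
        means[f"{assay}_control"] = hist_ctrl
        means[f"{assay}_treated"] = hist_ctrl * remodel_gain

    is_prom = (sites["state"] == "promoter").to_numpy()
    cage_ctrl = np.where(
        is_prom,
        cfg.cage_promoter_mean,
        np.where(open_c, cfg.cage_open_mean, cfg.cage_closed_mean),
    )
    means["cage_control"] = cage_ctrl
    means["cage_treated"] = cage_ctrl * 2.0 ** sites["true_cage_log2fc"].to_numpy()

    if null:
        for assay in ("atac", "h3k4me1", "h3k27ac", "cage"):
            means[f"{assay}_treated"] = means[f"{assay}_control"]
    return means


def _depth_scale(cfg: SimulationConfig, means: pd.DataFrame, assay: str) -> float:
    """Scale factor so expected events per library ~= cfg.depth."""
    bg = cfg.background_rate * cfg.chrom_length * cfg.n_chroms
    site_mean = 0.0
    if len(means):
        site_mean = float(
            np.maximum(means[f"{assay}_control"], means[f"{assay}_treated"]).mean()
            * len(means)
        )
        if assay == "atac":
            # ATAC libraries carry both sub-nucleosomal and mono fragments
            site_mean += len(means) * 4 * cfg.mono_per_nucleosome
    total = site_mean + bg
    return cfg.depth / total if total > 0 else 1.0


def _background_fragments(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    length_sampler,
    rate_scale: float,
    stranded: bool,
) -> pd.DataFrame:
    frames = []
    for chrom in cfg.chrom_names():
        n_bg = rng.poisson(cfg.background_rate * rate_scale * cfg.chrom_length)
        if n_bg == 0:
            continue
        lengths = length_sampler(rng, n_bg)
        starts = rng.integers(0, cfg.chrom_length - np.max(lengths) - 1, n_bg)
        strand = rng.choice(["+", "-"], n_bg) if stranded else "."
        frames.append(_frag_frame(chrom, starts, starts + lengths, strand))
    if not frames:
        return _empty_reads()
    return pd.concat(frames, ignore_index=True)


def _subnuc_lengths(rng, n):
    return rng.integers(50, SUBNUC_MAX, n)  # < 120 strictly


def _mono_lengths(rng, n):
    return rng.integers(MONO_RANGE[0], MONO_RANGE[1] + 1, n)  # 180-240 inclusive


def _hist_lengths(rng, n):
    return rng.integers(150, 301, n)


def _atac_library(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sites: pd.DataFrame,
    site_means: np.ndarray,
    open_flags: np.ndarray,
    scale: float,
) -> pd.DataFrame:
    """One ATAC replicate: sub-nucleosomal + mono-nucleosome + background."""
    frames = [_background_fragments(cfg, rng, _subnuc_lengths, scale * 0.6, False),
              _background_fragments(cfg, rng, _mono_lengths, scale * 0.4, False)]
    if len(sites):
        chroms = sites["chrom"].to_numpy()
        centers = sites["center"].to_numpy()
        counts = _nb_sample(rng, site_means * scale, cfg.nb_dispersion)
        for i in range(len(sites)):
            k = int(counts[i])
            if k > 0:
                # sub-nucleosomal fragments over the NDR (only meaningful at
                # open sites, where the mean is high)
                lengths = _subnuc_lengths(rng, k)
                mid = centers[i] + rng.normal(0, 40, k).astype(np.int64)
                starts = np.maximum(mid - lengths // 2, 0)
                frames.append(_frag_frame(chroms[i], starts, starts + lengths))
            # mono-nucleosome fragments around positioned dyads; open sites
            # have a depleted center with flanking nucleosomes, closed sites
            # a nucleosome over the RE
            if open_flags[i]:
                dyads = centers[i] + np.array([-340, -160, 160, 340])
            else:
                dyads = centers[i] + np.array([-340, -170, 0, 170, 340])
            nmono = _nb_sample(
                rng, np.full(len(dyads), cfg.mono_per_nucleosome * scale),
                cfg.nb_dispersion,
            )
            for dyad, m in zip(dyads, nmono):
                if m == 0:
                    continue
                lengths = _mono_lengths(rng, m)
                mid = dyad + rng.normal(0, 15, m).astype(np.int64)
                starts = np.maximum(mid - lengths // 2, 0)
                frames.append(_frag_frame(chroms[i], starts, starts + lengths))
    return pd.concat(frames, ignore_index=True)


def _hist_library(
    cfg, rng, sites, site_means: np.ndarray, scale: float
) -> pd.DataFrame:
    frames = [_background_fragments(cfg, rng, _hist_lengths, scale, False)]
    if len(sites):
        counts = _nb_sample(rng, site_means * scale, cfg.nb_dispersion)
        chroms = sites["chrom"].to_numpy()
        centers = sites["center"].to_numpy()
        for i in range(len(sites)):
            k = int(counts[i])
            if k == 0:
                continue
            lengths = _hist_lengths(rng, k)
            mid = centers[i] + rng.normal(0, 300, k).astype(np.int64)
            starts = np.maximum(mid - lengths // 2, 0)
            frames.append(_frag_frame(chroms[i], starts, starts + lengths))
    return pd.concat(frames, ignore_index=True)


def _cage_library(
    cfg, rng, sites, site_means: np.ndarray, scale: float
) -> pd.DataFrame:
    """One CAGE replicate: stranded 30-bp reads with 5' ends at RE-center +
    mixture offset, plus uniform background."""
    frames = [_background_fragments(cfg, rng, lambda r, n: np.full(n, 30), scale, True)]
    if len(sites):
        counts = _nb_sample(rng, site_means * scale, cfg.nb_dispersion)
        chroms = sites["chrom"].to_numpy()
        anchors = sites["re_center"].to_numpy()
        centers = np.asarray(cfg.tss_offset_centers, dtype=float)
        weights = np.asarray(cfg.tss_offset_weights, dtype=float)
        for i in range(len(sites)):
            k = int(counts[i])
            if k == 0:
                continue
            comp = rng.choice(len(centers), size=k, p=weights)
            offsets = rng.normal(centers[comp], cfg.tss_offset_sd).round().astype(np.int64)
            pos = anchors[i] + offsets
            strand = rng.choice(["+", "-"], k)
            starts = np.where(strand == "+", pos, pos - 29)
            starts = np.maximum(starts, 0)
            frames.append(_frag_frame(chroms[i], starts, starts + 30, strand))
    return pd.concat(frames, ignore_index=True)


def _states_bed(cfg: SimulationConfig, sites: pd.DataFrame) -> list[GenomicInterval]:
    """18-state segmentation: site neighborhoods get their state, rest Quies."""
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[tuple[int, int, str]]] = {
        c: [] for c in cfg.chrom_names()
    }
    for _, s in sites.iterrows():
        by_chrom[s["chrom"]].append(
            (int(s["center"]) - 500, int(s["center"]) + 500, s["state18"])
        )
    for chrom in cfg.chrom_names():
        segs = sorted(by_chrom[chrom])
        cursor = 0
        for start, end, label in segs:
            start = max(start, cursor)
            if start > cursor:
                out.append(GenomicInterval(chrom, cursor, start, name="Quies"))
            if end > start:
                out.append(GenomicInterval(chrom, start, end, name=label))
            cursor = max(cursor, end)
        if cursor < cfg.chrom_length:
            out.append(GenomicInterval(chrom, cursor, cfg.chrom_length, name="Quies"))
    return out


def _genes_and_pairs(
    cfg: SimulationConfig, rng: np.random.Generator, sites: pd.DataFrame, null: bool
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulated gene differential table, enhancer-gene pairs, and gene truth.

    Linked genes are wired to strongly induced non-promoter sites and given
    differential stats that clear the candidate filters; decoys are either
    unlinked or fail a filter.
    """
    gene_rows, pair_rows, truth_rows = [], [], []
    gid = 0
    if len(sites) and not null:
        eligible = sites[
            (sites["state"] != "promoter") & (sites["true_cage_log2fc"] > 1.0)
        ]
        chosen = eligible.head(cfg.n_linked_genes)
        for _, s in chosen.iterrows():
            gene_id = f"gene_{gid:03d}"
            tss = min(int(s["center"]) + 50_000, cfg.chrom_length - 1_000)
            # gene induction tracks enhancer induction (attenuated + noise),
            # staying above the candidate thresholds for wired genes
            lfc = 0.6 + 0.35 * (float(s["true_cage_log2fc"]) - 1.0)
            lfc += 0.2 * float(rng.random())
            gene_rows.append(
                {
                    "gene_id": gene_id, "chrom": s["chrom"], "tss_pos": tss,
                    "strand": "+", "log2FC": lfc, "FDR": 0.01,
                }
            )
            pair_rows.append(
                {
                    "pair_id": f"pair_{gid:03d}",
                    "enhancer_chrom": s["chrom"],
                    "enhancer_pos": int(s["re_center"]),
                    "gene_id": gene_id,
                }
            )
            truth_rows.append(
                {"gene_id": gene_id, "linked_site": s["site_id"], "true_target": True}
            )
            gid += 1
    for _ in range(cfg.n_decoy_genes):
        gene_id = f"gene_{gid:03d}"
        chrom = cfg.chrom_names()[int(rng.integers(0, cfg.n_chroms))]
        gene_rows.append(
            {
                "gene_id": gene_id, "chrom": chrom,
                "tss_pos": int(rng.integers(10_000, cfg.chrom_length - 10_000)),
                "strand": rng.choice(["+", "-"]),
                "log2FC": float(rng.normal(0, 0.2)),
                "FDR": float(rng.uniform(0.2, 1.0)),
            }
        )
        truth_rows.append({"gene_id": gene_id, "linked_site": "", "true_target": False})
        gid += 1
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "tss_pos", "strand", "log2FC", "FDR"]
    )
    pairs = pd.DataFrame(
        pair_rows, columns=["pair_id", "enhancer_chrom", "enhancer_pos", "gene_id"]
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "linked_site", "true_target"])
    return genes, pairs, truth


def simulate(
    config: SimulationConfig, null: bool = False
) -> tuple[GroundTruth, SimulatedData]:
    """Generate a full ground-truthed dataset under ``config``.

    Deterministic for a fixed config (including its seed). With ``null``
    all treatment effects are forced to zero (condition means identical,
    only replicate noise differs).
    """
    rng = np.random.default_rng(config.seed)
    sites = _simulate_sites(config, rng, null)
    means = _condition_means(config, sites, null)

    fragments: dict = {}
    for assay in ("atac", "h3k4me1", "h3k27ac"):
        scale = _depth_scale(config, means, assay)
        fragments[assay] = {}
        for condition in ("control", "treated"):
            site_means = means[f"{assay}_{condition}"].to_numpy() if len(means) else np.empty(0)
            libs = []
            for _rep in range(config.n_replicates[assay]):
                if assay == "atac":
                    flags = sites[f"open_{condition}"].to_numpy() if len(sites) else np.empty(0, bool)
                    libs.append(
                        _atac_library(config, rng, sites, site_means, flags, scale)
                    )
                else:
                    libs.append(_hist_library(config, rng, sites, site_means, scale))
            fragments[assay][condition] = libs

    cage: dict = {}
    scale = _depth_scale(config, means, "cage")
    for condition in ("control", "treated"):
        site_means = means[f"cage_{condition}"].to_numpy() if len(means) else np.empty(0)
        cage[condition] = [
            _cage_library(config, rng, sites, site_means, scale)
            for _rep in range(config.n_replicates["cage"])
        ]

    genes, pairs, gene_truth = _genes_and_pairs(config, rng, sites, null)

    truth_sites = sites.copy()
    if len(truth_sites):
        for assay in ("atac", "h3k4me1", "h3k27ac", "cage"):
            with np.errstate(divide="ignore"):
                truth_sites[f"true_{assay}_log2fc"] = np.log2(
                    means[f"{assay}_treated"] / means[f"{assay}_control"]
                )
    truth = GroundTruth(sites=truth_sites, genes=gene_truth)
    data = SimulatedData(
        fragments=fragments,
        cage=cage,
        states_bed=_states_bed(config, sites),
        pairs=pairs,
        gene_table=genes,
        config=config,
    )
    return truth, data


def simulate_null(config: SimulationConfig) -> tuple[GroundTruth, SimulatedData]:
    """Full dataset with every treatment effect forced to zero."""
    return simulate(config, null=True)


# ---------------------------------------------------------------------------
# Direct region-count simulation (for differential-test calibration/recovery)
# ---------------------------------------------------------------------------

def simulate_counts(
    n_regions: int,
    n_per_condition: int = 4,
    depth: float = 1e6,
    dispersion: float = 0.05,
    log2fc=0.0,
    base_mu: float = float(np.log(50.0)),
    base_sigma: float = 1.0,
    seed: int = 0,
):
    """Simulate a regions x samples NB count matrix directly.

    Region base means are log-normal; treated means are base * 2**log2fc.
    Per-sample expected counts are scaled so each library sums to ``depth``
    in expectation. Returns (RegionCountMatrix, true log2fc array).
    """
    from .differential_signal import RegionCountMatrix

    rng = np.random.default_rng(seed)
    base = rng.lognormal(base_mu, base_sigma, n_regions)
    lfc = np.broadcast_to(np.asarray(log2fc, dtype=float), (n_regions,)).copy()
    mean_c = base * depth / base.sum()
    mean_t = mean_c * 2.0**lfc
    mean_t = mean_t * depth / mean_t.sum()

    cols, samples, conditions = [], [], []
    for i in range(n_per_condition):
        cols.append(_nb_sample(rng, mean_c, dispersion))
        samples.append(f"control_{i + 1}")
        conditions.append("control")
    for i in range(n_per_condition):
        cols.append(_nb_sample(rng, mean_t, dispersion))
        samples.append(f"treated_{i + 1}")
        conditions.append("treated")
    regions = [
        GenomicInterval("chrS", 1000 * i + 100, 1000 * i + 600, name=f"r{i}")
        for i in range(n_regions)
    ]
    matrix = RegionCountMatrix(
        regions=regions,
        samples=samples,
        conditions=conditions,
        counts=np.column_stack(cols),
    )
    return matrix, lfc


def simulate_null_counts(
    n_regions: int, n_per_condition: int = 4, depth: float = 1e6,
    dispersion: float = 0.05, seed: int = 0,
):
    """Null count matrix: identical condition means, replicate noise only."""
    return simulate_counts(
        n_regions, n_per_condition, depth, dispersion, log2fc=0.0, seed=seed
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_dataset(truth: GroundTruth, data: SimulatedData, outdir) -> None:
    """Write the dataset in the same plain-text dialects the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.config.to_yaml(outdir / "config.yaml")
    truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    write_bed(data.states_bed, outdir / "states18.bed")
    data.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    data.gene_table.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    for assay, by_cond in data.fragments.items():
        for condition, libs in by_cond.items():
            for rep, frame in enumerate(libs, start=1):
                path = outdir / f"{assay}_{condition}_rep{rep}.bed"
                frame.to_csv(
                    path, sep="\t", index=False, header=False,
                    columns=["chrom", "start", "end"],
                )
    for condition, libs in data.cage.items():
        for rep, frame in enumerate(libs, start=1):
            path = outdir / f"cage_{condition}_rep{rep}.bed"
            out = frame.assign(name=".", score=0)
            out.to_csv(
                path, sep="\t", index=False, header=False,
                columns=["chrom", "start", "end", "name", "score", "strand"],
            )
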