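"""Configuration-driven end-to-end orchestration.

Stages run in dependency order: peak calling and accessibility transitions,
chromatin-state collapsing, per-assay differential signal, CTSS peak calling
and TSS status, the occupancy-transcription sigmoid, nucleosome profiles,
initiation-density profiles, and enhancer-gene linking. Outputs are plain
text (TSV/JSON) plus a run manifest; identical config and seed reproduce
identical outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_intervals import (
    GenomicInterval,
    IntervalIndex,
    SignalTrack,
    as_reads_frame,
    five_prime_coverage,
    call_ctss,
    merge_within,
    read_bed,
)
from .ctss_density import density_profiles_by_stratum, offset_histogram, peak_offsets
from .differential_signal import count_regions, nb_test
from .enhancer_linking import build_links, candidate_genes, change_correlation
from .nucleosome_profile import anchored_profile, eviction_and_shift, mono_occupancy, profile_table
from .site_layers import (
    accessibility_transition,
    collapse_state,
    fit_occupancy_response,
    re_status,
    summarize_layers,
    tss_status,
    BindingSite,
)
from .synthetic_data import SimulationConfig, simulate, write_dataset, SUBNUC_MAX

logger = logging.getLogger(__name__)

ASSAYS = ("atac", "h3k4me1", "h3k27ac")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds.

    Either ``simulate`` (generator settings) or ``inputs`` (paths to BED/TSV
    files) must be provided. Thresholds default to the analysis' standard
    values; see docs/methods.md.
    """

    outdir: str = "pipeline_out"
    seed: int = 0
    simulate: SimulationConfig | None = None
    inputs: dict | None = None
    # differential thresholds
    fc_cut: float = 1.0
    fdr_cut: float = 0.1
    # TSS status
    tss_induced_cut: float = 0.5
    tss_extension: int = 200
    # initiation density
    density_min_reads: int = 5
    density_flank: int = 200
    # enhancer linking
    link_min_distance: int = 2500
    pair_match_tolerance: int = 300
    # nucleosome profiling
    nuc_half_width: int = 500
    center_window: int = 73
    # peak calling (accessibility)
    atac_peak_min_height: float = 20.0
    atac_peak_min_length: int = 50
    atac_peak_max_gap: int = 100
    # peak calling (CTSS, per strand) then merging within cage_merge_gap
    cage_peak_min_height: float = 3.0
    cage_peak_min_length: int = 1
    cage_peak_max_gap: int = 10
    cage_merge_gap: int = 50
    # CAGE counting orientation; the simulator emits reads on the transcript
    # strand, hence "forward"; set "reverse" for reverse-stranded libraries
    cage_strandness: str = "forward"
    # sigmoid fit: sites need this many pooled local CAGE reads to enter
    sigmoid_min_reads: int = 5

    def __post_init__(self) -> None:
        if isinstance(self.simulate, dict):
            self.simulate = SimulationConfig(**self.simulate)
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either 'simulate' or 'inputs'")
        if not (0 < self.fdr_cut <= 1):
            raise ValueError("fdr_cut must be in (0, 1]")
        if self.inputs is not None:
            missing = [
                str(p)
                for p in _iter_paths(self.inputs)
                if not Path(p).exists()
            ]
            if missing:
                raise FileNotFoundError(
                    "missing input path(s): " + ", ".join(missing)
                )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"] = asdict(self.simulate)
        return d


def _iter_paths(inputs: dict):
    for v in inputs.values():
        if isinstance(v, (list, tuple)):
            yield from v
        elif isinstance(v, dict):
            yield from _iter_paths(v)
        else:
            yield v


# ---------------------------------------------------------------------------
# Simple threshold peak caller (synthetic-track stand-in)
# ---------------------------------------------------------------------------

def simple_peak_caller(
    track: SignalTrack,
    min_height: float,
    min_length: int = 50,
    max_gap: int = 100,
    strand: str | None = None,
) -> list[GenomicInterval]:
    """Threshold peak calling on a coverage track.

    Positions with coverage >= ``min_height`` are grouped into runs, runs
    separated by <= ``max_gap`` uncovered bases are bridged, and runs
    shorter than ``min_length`` are dropped. Default min-length/max-gap
    match the accessibility peak-calling settings used throughout.
    """
    if min_height <= 0:
        raise ValueError("min_height must be > 0")
    peaks: list[GenomicInterval] = []
    strands = [strand] if strand is not None else [None]
    for chrom in track.chroms():
        for st in strands:
            pieces = []
            for s in (track.strands() if st is None else [st]):
                pos, vals = track.positions(chrom, s)
                pieces.append((pos, vals))
            if st is None and len(pieces) > 1:
                allpos = np.concatenate([p for p, _ in pieces])
                allval = np.concatenate([v for _, v in pieces])
                upos, inv = np.unique(allpos, return_inverse=True)
                uval = np.zeros(len(upos))
                np.add.at(uval, inv, allval)
                pos, vals = upos, uval
            else:
                pos, vals = pieces[0]
            qual = pos[vals >= min_height]
            if len(qual) == 0:
                continue
            gaps = np.flatnonzero(np.diff(qual) - 1 > max_gap)
            starts = np.concatenate([[0], gaps + 1])
            ends = np.concatenate([gaps, [len(qual) - 1]])
            for i, j in zip(starts, ends):
                run_start, run_end = int(qual[i]), int(qual[j]) + 1
                if run_end - run_start >= min_length:
                    peaks.append(
                        GenomicInterval(chrom, run_start, run_end, st or ".")
                    )
    peaks.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return peaks


def fragment_coverage(frames: list[pd.DataFrame]) -> SignalTrack:
    """Per-base full-span coverage of pooled fragment sets (unstranded)."""
    track = SignalTrack()
    pooled = pd.concat([as_reads_frame(f) for f in frames], ignore_index=True)
    for chrom, grp in pooled.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        hi = int(ends.max())
        delta = np.zeros(hi + 1)
        np.add.at(delta, starts, 1.0)
        np.add.at(delta, ends, -1.0)
        cov = np.cumsum(delta)[:-1]
        pos = np.flatnonzero(cov > 0)
        track.add_events(chrom, pos, cov[pos], strand=".")
    return track


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------

def _load_inputs(cfg: PipelineConfig):
    inp = cfg.inputs
    sites = pd.read_csv(inp["sites"], sep="\t")
    states = read_bed(inp["states"])
    pairs = pd.read_csv(inp["pairs"], sep="\t")
    genes = pd.read_csv(inp["genes"], sep="\t")
    fragments = {}
    for assay in ASSAYS:
        fragments[assay] = {}
        for condition in ("control", "treated"):
            fragments[assay][condition] = [
                pd.read_csv(
                    p, sep="\t", header=None, names=["chrom", "start", "end"]
                ).assign(strand=".")
                for p in inp[f"{assay}_{condition}"]
            ]
    cage = {}
    for condition in ("control", "treated"):
        cage[condition] = [
            pd.read_csv(
                p, sep="\t", header=None,
                names=["chrom", "start", "end", "name", "score", "strand"],
            )[["chrom", "start", "end", "strand"]]
            for p in inp[f"cage_{condition}"]
        ]
    return sites, states, pairs, genes, fragments, cage


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def _stage(name: str):
    """Decorator-free stage timer used inline."""
    return time.perf_counter(), name


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages; write the report bundle to ``config.outdir``.

    Returns a dict with the site-layer table, summary, profiles, candidate
    genes and output paths. Deterministic for fixed config and seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_all = time.perf_counter()

    # ---- stage: inputs -----------------------------------------------------
    t0 = time.perf_counter()
    if config.simulate is not None:
        sim_cfg = config.simulate
        if sim_cfg.seed != config.seed:
            sim_cfg = SimulationConfig(**{**asdict(sim_cfg), "seed": config.seed})
        truth, data = simulate(sim_cfg)
        sites = truth.sites.copy()
        states = data.states_bed
        pairs_raw, gene_table = data.pairs, data.gene_table
        fragments, cage = data.fragments, data.cage
        write_dataset(truth, data, outdir / "data")
    else:
        sites, states, pairs_raw, gene_table, fragments, cage = _load_inputs(config)
    n_sites = len(sites)
    logger.info("stage=inputs wall=%.2fs sites=%d", time.perf_counter() - t0, n_sites)

    site_ivs = [
        GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]), name=r["site_id"])
        for _, r in sites.iterrows()
    ]

    # ---- stage: accessibility peaks & transitions --------------------------
    t0 = time.perf_counter()
    peaks = {}
    for condition in ("control", "treated"):
        subnuc = []
        for frame in fragments["atac"][condition]:
            lengths = frame["end"] - frame["start"]
            subnuc.append(frame[lengths < SUBNUC_MAX])
        cov = fragment_coverage(subnuc)
        peaks[condition] = simple_peak_caller(
            cov,
            config.atac_peak_min_height,
            config.atac_peak_min_length,
            config.atac_peak_max_gap,
        )
    idx_c, idx_t = IntervalIndex(peaks["control"]), IntervalIndex(peaks["treated"])
    transitions = [accessibility_transition(iv, idx_c, idx_t) for iv in site_ivs]
    logger.info(
        "stage=atac_peaks wall=%.2fs peaks_control=%d peaks_treated=%d",
        time.perf_counter() - t0, len(peaks["control"]), len(peaks["treated"]),
    )

    # ---- stage: chromatin state --------------------------------------------
    t0 = time.perf_counter()
    state_idx: dict[str, list[GenomicInterval]] = {}
    for seg in states:
        state_idx.setdefault(seg.chrom, []).append(seg)
    for segs in state_idx.values():
        segs.sort(key=lambda iv: iv.start)
    state_labels = []
    for _, r in sites.iterrows():
        center = int((int(r["start"]) + int(r["end"])) // 2)
        label18 = "n/a"
        segs = state_idx.get(r["chrom"], [])
        starts = np.array([s.start for s in segs])
        k = int(np.searchsorted(starts, center, side="right")) - 1
        if 0 <= k < len(segs) and segs[k].start <= center < segs[k].end:
            label18 = segs[k].name or "n/a"
        state_labels.append(collapse_state(label18))
    logger.info("stage=states wall=%.2fs", time.perf_counter() - t0)

    # ---- stage: per-assay differential -------------------------------------
    t0 = time.perf_counter()
    assay_results: dict[str, pd.DataFrame] = {}
    for assay in ASSAYS:
        half = 0 if assay == "atac" else 400
        regions = [
            GenomicInterval(iv.chrom, max(0, iv.start - half), iv.end + half, name=iv.name)
            for iv in site_ivs
        ]
        sample_reads, conditions = {}, {}
        for condition in ("control", "treated"):
            for rep, frame in enumerate(fragments[assay][condition], start=1):
                label = f"{assay}_{condition}_{rep}"
                sample_reads[label] = frame
                conditions[label] = condition
        matrix = count_regions(sample_reads, conditions, regions, mode="fragment")
        assay_results[assay] = nb_test(
            matrix, fc_cut=config.fc_cut, fdr_cut=config.fdr_cut
        )
    logger.info("stage=differential wall=%.2fs assays=%d",
                time.perf_counter() - t0, len(assay_results))

    # ---- stage: CTSS peaks & differential ----------------------------------
    t0 = time.perf_counter()
    pooled_cage = pd.concat(
        cage["control"] + cage["treated"], ignore_index=True
    )
    ctss_track = five_prime_coverage(pooled_cage)
    raw_peaks: list[GenomicInterval] = []
    for st in ("+", "-"):
        raw_peaks.extend(
            simple_peak_caller(
                ctss_track,
                config.cage_peak_min_height,
                config.cage_peak_min_length,
                config.cage_peak_max_gap,
                strand=st,
            )
        )
    merged_peaks = merge_within(raw_peaks, config.cage_merge_gap, stranded=True)
    ctss_peaks = call_ctss(ctss_track, merged_peaks)

    cage_samples, cage_conditions = {}, {}
    for condition in ("control", "treated"):
        for rep, frame in enumerate(cage[condition], start=1):
            label = f"cage_{condition}_{rep}"
            cage_samples[label] = frame
            cage_conditions[label] = condition
    strandness = "none" if config.cage_strandness == "none" else config.cage_strandness
    peak_regions = [p.interval for p in ctss_peaks]
    if peak_regions:
        peak_matrix = count_regions(
            cage_samples, cage_conditions, peak_regions,
            strandness=strandness, mode="five_prime",
        )
        peak_diff = nb_test(peak_matrix, fc_cut=config.fc_cut, fdr_cut=config.fdr_cut)
    else:
        peak_diff = pd.DataFrame(
            columns=["log2FC", "pvalue", "padj", "baseMean", "dispersion", "class"]
        )
    tss_pairs = [
        (p.interval, float(peak_diff["log2FC"].iloc[i]))
        for i, p in enumerate(ctss_peaks)
    ]
    tss_labels = [
        tss_status(
            iv, tss_pairs,
            extension=config.tss_extension, induced_cut=config.tss_induced_cut,
        )
        for iv in site_ivs
    ]
    logger.info("stage=ctss wall=%.2fs peaks=%d",
                time.perf_counter() - t0, len(ctss_peaks))

    # ---- stage: local delta-TSS & sigmoid ----------------------------------
    t0 = time.perf_counter()
    flank = config.density_flank
    local_regions = [
        GenomicInterval(
            iv.chrom, max(0, iv.center - flank), iv.center + flank + 1, name=iv.name
        )
        for iv in site_ivs
    ]
    sigmoid_summary: dict = {"fitted": False}
    local_diff = None
    if n_sites:
        local_matrix = count_regions(
            cage_samples, cage_conditions, local_regions, mode="five_prime",
            strandness="none",
        )
        local_diff = nb_test(local_matrix, fc_cut=config.fc_cut, fdr_cut=config.fdr_cut)
        total_reads = local_matrix.counts.sum(axis=1)
        occ = sites["occupancy"].to_numpy(dtype=float)
        fit_mask = (total_reads >= config.sigmoid_min_reads) & (occ > 0)
        if fit_mask.sum() >= 10:
            fit = fit_occupancy_response(
                occ[fit_mask], local_diff["log2FC"].to_numpy()[fit_mask]
            )
            sigmoid_summary = {
                "fitted": True,
                "a": fit.a, "b": fit.b, "x0": fit.x0, "k": fit.k,
                "occupancy_threshold_cpm": fit.occupancy_threshold,
                "r2": fit.r2, "spearman_rho": fit.rho, "spearman_p": fit.rho_p,
                "n_sites": int(fit_mask.sum()),
                "degenerate": fit.degenerate,
                "linear_fallback": fit.linear_fallback,
            }
    logger.info("stage=sigmoid wall=%.2fs", time.perf_counter() - t0)

    # ---- stage: nucleosome profiles ----------------------------------------
    t0 = time.perf_counter()
    nuc_tracks = {
        condition: mono_occupancy(
            pd.concat(fragments["atac"][condition], ignore_index=True)
        )
        for condition in ("control", "treated")
    }
    has_re = sites["re_subtype"] != "none" if n_sites else pd.Series(dtype=bool)
    nuc_summary: dict = {}
    profile_frames: dict[str, pd.DataFrame] = {}
    for group in ("constitutively_open", "opened", "constitutively_closed"):
        mask = has_re & (pd.Series(transitions, index=sites.index) == group)
        anchors = [
            (r["chrom"], int(r["re_center"]), ".")
            for _, r in sites[mask].iterrows()
        ]
        if not anchors:
            continue
        prof_c = anchored_profile(nuc_tracks["control"], anchors, config.nuc_half_width)
        prof_t = anchored_profile(nuc_tracks["treated"], anchors, config.nuc_half_width)
        eviction, shift = eviction_and_shift(
            prof_c, prof_t, config.center_window
        )
        nuc_summary[group] = {
            "n_anchors": len(anchors),
            "eviction_score": eviction,
            "shift_lag_bp": shift,
        }
        profile_frames[group] = profile_table(prof_c, prof_t)
    logger.info("stage=nucleosome wall=%.2fs groups=%d",
                time.perf_counter() - t0, len(nuc_summary))

    # ---- stage: initiation density -----------------------------------------
    t0 = time.perf_counter()
    density_summary: dict = {}
    density_frames: list[pd.DataFrame] = []
    if n_sites:
        canonical = sites["re_subtype"] == "two_half_sites_no_spacer"
        centers = [
            (r["chrom"], int(r["re_center"])) for _, r in sites[canonical].iterrows()
        ]
        strata = [state_labels[i] for i in np.flatnonzero(canonical.to_numpy())]
        if centers:
            for condition in ("control", "treated"):
                track = five_prime_coverage(
                    pd.concat(cage[condition], ignore_index=True)
                )
                profs = density_profiles_by_stratum(
                    track, centers, strata,
                    min_reads=config.density_min_reads, flank=flank,
                    condition=condition,
                )
                for prof in profs.values():
                    density_frames.append(prof.to_frame())
                all_prof = profs["all"]
                entry: dict = {"n_regions": all_prof.n_regions}
                if all_prof.n_regions > 0:
                    entry["modes_bp"] = peak_offsets(all_prof)
                    off = all_prof.offsets
                    entry["mass_within_60bp"] = float(
                        all_prof.density[np.abs(off) <= 60].sum()
                    )
                density_summary[condition] = entry
            # offset histogram on the treated condition
            treated_track = five_prime_coverage(
                pd.concat(cage["treated"], ignore_index=True)
            )
            offsets: list[int] = []
            for chrom, center in centers:
                window = treated_track.window_array(
                    chrom, center - flank, center + flank + 1
                )
                nz = np.flatnonzero(window)
                offsets.extend(
                    np.repeat(nz - flank, window[nz].astype(int)).tolist()
                )
            if offsets:
                hist = offset_histogram(offsets, span=2 * flank + 1)
                hist.to_csv(outdir / "offset_histogram.tsv", sep="\t", index=False)
    logger.info("stage=density wall=%.2fs", time.perf_counter() - t0)

    # ---- stage: enhancer linking -------------------------------------------
    t0 = time.perf_counter()
    link_summary: dict = {"n_links": 0, "candidates": []}
    links = pd.DataFrame()
    if len(ctss_peaks) and len(pairs_raw):
        site_index = IntervalIndex(iv for iv in site_ivs)
        peak_table = pd.DataFrame(
            {
                "peak_id": [f"peak_{i:05d}" for i in range(len(ctss_peaks))],
                "chrom": [p.interval.chrom for p in ctss_peaks],
                "summit": [p.summit for p in ctss_peaks],
                "log2FC": peak_diff["log2FC"].to_numpy(),
                "FDR": peak_diff["padj"].to_numpy(),
                "p53_bound": [
                    site_index.any_overlap(
                        p.interval.chrom, p.interval.start, p.interval.end
                    )
                    for p in ctss_peaks
                ],
            }
        )
        # map position-keyed pairs to called peaks (nearest summit in range)
        mapped = []
        for _, pr in pairs_raw.iterrows():
            same = peak_table[peak_table["chrom"] == pr["enhancer_chrom"]]
            if len(same) == 0:
                continue
            d = (same["summit"] - int(pr["enhancer_pos"])).abs()
            j = d.idxmin()
            if d.loc[j] <= config.pair_match_tolerance:
                mapped.append({"peak_id": peak_table.loc[j, "peak_id"],
                               "gene_id": pr["gene_id"]})
            else:
                logger.warning(
                    "pair %s: no CTSS peak within %d bp; dropped",
                    pr.get("pair_id", "?"), config.pair_match_tolerance,
                )
        if mapped:
            links = build_links(
                peak_table, pd.DataFrame(mapped), gene_table,
                min_distance=config.link_min_distance,
            )
            cands = candidate_genes(
                links, tss_fc=config.fc_cut, tss_fdr=config.fdr_cut,
            )
            link_summary = {"n_links": int(len(links)), "candidates": cands,
                            "n_candidates": len(cands)}
            if len(links) >= 3 and links["tss_log2fc"].nunique() > 1:
                rho, p = change_correlation(
                    links["tss_log2fc"], links["gene_log2fc"]
                )
                link_summary["spearman_rho_all"] = rho
                if links["p53_bound"].sum() >= 3:
                    rho_b, _ = change_correlation(
                        links["tss_log2fc"], links["gene_log2fc"],
                        links["p53_bound"], subset="p53_bound",
                    )
                    link_summary["spearman_rho_p53_bound"] = rho_b
    logger.info("stage=links wall=%.2fs links=%d",
                time.perf_counter() - t0, link_summary["n_links"])

    # ---- stage: layer table & summary --------------------------------------
    t0 = time.perf_counter()
    layer_table = sites[["site_id", "chrom", "start", "end"]].copy() if n_sites else pd.DataFrame(
        columns=["site_id", "chrom", "start", "end"]
    )
    if n_sites:
        layer_table["occupancy"] = sites["occupancy"].to_numpy()
        layer_table["transition"] = transitions
        layer_table["state"] = state_labels
        layer_table["tss_status"] = tss_labels
        layer_table["re_status"] = [
            re_status(
                BindingSite(
                    interval=iv,
                    occupancy=float(sites["occupancy"].iloc[i]),
                    re_subtype=str(sites["re_subtype"].iloc[i]),
                    re_center=int(sites["re_center"].iloc[i])
                    if sites["re_subtype"].iloc[i] != "none" else None,
                )
            )[0]
            for i, iv in enumerate(site_ivs)
        ]
        for assay in ASSAYS:
            layer_table[f"{assay}_log2fc"] = assay_results[assay]["log2FC"].to_numpy()
            layer_table[f"{assay}_fdr"] = assay_results[assay]["padj"].to_numpy()
            layer_table[f"{assay}_class"] = assay_results[assay]["class"].to_numpy()
        if local_diff is not None:
            layer_table["local_tss_log2fc"] = local_diff["log2FC"].to_numpy()
    summary = summarize_layers(layer_table) if n_sites else summarize_layers(
        pd.DataFrame(columns=["transition", "state", "tss_status", "re_status"])
    )

    bundle = {
        "total_sites": int(n_sites),
        "layers": json.loads(summary.to_json()),
        "sigmoid": sigmoid_summary,
        "nucleosome": nuc_summary,
        "density": density_summary,
        "links": link_summary,
        "n_ctss_peaks": int(len(ctss_peaks)),
        "n_atac_peaks": {c: len(peaks[c]) for c in peaks},
    }

    # ---- outputs ------------------------------------------------------------
    layer_table.to_csv(outdir / "site_layers.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=float)
    for group, frame in profile_frames.items():
        frame.to_csv(outdir / f"nucleosome_profile_{group}.tsv", sep="\t", index=False)
    if density_frames:
        pd.concat(density_frames, ignore_index=True).to_csv(
            outdir / "ctss_density.tsv", sep="\t", index=False
        )
    if len(links):
        links.to_csv(outdir / "links.tsv", sep="\t", index=False)
        pd.DataFrame({"gene_id": link_summary["candidates"]}).to_csv(
            outdir / "candidate_genes.tsv", sep="\t", index=False
        )

    cfg_dict = config.to_dict()
    cfg_yaml = yaml.safe_dump(cfg_dict, sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "pioneerkit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("stage=report wall=%.2fs total=%.2fs",
                time.perf_counter() - t0, time.perf_counter() - t_all)

    return {
        "layer_table": layer_table,
        "summary": bundle,
        "links": links,
        "ctss_peaks": ctss_peaks,
        "outdir": str(outdir),
    }
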