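"""Seeded synthetic-data generators with planted ground truth.

The generators emulate the statistical structure of the study inputs: a
small genome with non-overlapping gene models; an ATAC peak set carrying
implanted TF motif matches; an H3K27ac landscape (promoters of active
genes plus enhancer elements around ATAC peaks) shared between two
conditions; BRD4 tracks whose enrichment is multiplied at the designated
driver TF's binding sites in one condition; expression coupled to
promoter-proximal BRD4; a PPI graph with planted TF cliques; a TF ChIP
(engineered vs parental) peak/read layer for the driver; and a pooled
screen with planted depleting/enriching genes.

Every generator is a pure function of (config, seed): the same seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomeAssembly, GenomicInterval, RegionSet, Transcript, window_around
from .motifs import MotifModel, reverse_complement
from .screen import ScreenTable
from .signal import FragmentTrack

__all__ = [
    "SynthConfig",
    "ScreenConfig",
    "GroundTruth",
    "SynthDataset",
    "generate_regulatory_genome",
    "simulate_tracks",
    "simulate_expression",
    "simulate_ppi",
    "simulate_screen",
    "simulate_dataset",
    "write_dataset",
]

CONDITIONS = ("hscp", "lscp")  # high / low stem-cell-potential conditions
BASES = "ACGT"


@dataclass(frozen=True)
class ScreenConfig:
    """Pooled-screen simulation parameters."""

    n_genes: int = 500
    reagents_per_gene: int = 5
    planted_down: int = 25
    planted_up: int = 10
    effect_log2fc: float = 1.5  # magnitude; sign set by direction
    mean_reads: float = 500.0
    dispersion: float = 0.15
    n_timepoints: int = 2


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic regulatory genome.

    Defaults are the desk-scale conditions every stage is tested under:
    one 5 Mb chromosome, 200 genes, a 20-TF panel whose designated driver
    carries a 2x BRD4 gain at its 200 binding sites in the "lscp"
    condition only, and 1e6 reads per track.
    """

    seed: int = 0
    genome_length: int = 5_000_000
    chrom: str = "chr1"
    n_genes: int = 200
    n_inactive_genes: int = 30
    n_tfs: int = 20
    # widths sized so a consensus site's exact p (4^-w) clears the BH
    # q < 1e-5 cutoff over the default scan universe (~4e5 offsets)
    motif_width_min: int = 16
    motif_width_max: int = 18
    consensus_prob: float = 0.97
    n_atac_peaks: int = 1000
    atac_peak_width: int = 200
    enhancer_pad: int = 400
    driver_tf_index: int = 0
    driver_edge_count: int = 200
    nondriver_edge_count: int = 30
    driver_brd4_gain: float = 2.0
    read_depth: int = 1_000_000
    # uniform-background share of reads; strong marks are high signal-to-noise,
    # and background overlapping a region dilutes its planted fold change. The
    # background also absorbs planted extra signal so depth stays constant.
    background_fraction: float = 0.15
    n_reps_h3k27ac: int = 3
    n_reps_brd4: int = 2
    n_reps_tfchip: int = 2
    expression_noise_sd: float = 0.25  # log2 scale
    n_expression_reps: int = 3
    clique_intra_p: float = 0.9
    clique_inter_p: float = 0.05
    n_spurious_tfchip_peaks: int = 30
    screen: ScreenConfig = field(default_factory=ScreenConfig)

    def __post_init__(self) -> None:
        if self.driver_tf_index >= self.n_tfs:
            raise ValueError("driver_tf_index must be < n_tfs")
        need = (self.driver_edge_count
                + (self.n_tfs - 1) * self.nondriver_edge_count)
        if need > self.n_atac_peaks:
            raise ValueError(
                f"not enough ATAC peaks ({self.n_atac_peaks}) for the requested "
                f"implants ({need})")
        if self.screen.planted_down + self.screen.planted_up > self.screen.n_genes:
            raise ValueError("planted screen genes exceed screen gene count")


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline on the synthetic dataset."""

    driver_tf: str
    driver_peak_indices: List[int]
    driver_target_genes: List[str]
    active_transcripts: List[str]
    ppi_clusters: Dict[str, int]
    screen_down_genes: List[str]
    screen_up_genes: List[str]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


@dataclass
class SynthLayout:
    """Genome layout produced by :func:`generate_regulatory_genome`."""

    config: SynthConfig
    assembly: GenomeAssembly
    transcripts: List[Transcript]
    tf_names: List[str]
    active_gene_names: List[str]
    atac: RegionSet
    landscape_elements: RegionSet  # promoters + enhancer regions, merged
    enhancer_regions: RegionSet  # one per ATAC peak (peak +/- pad)
    h3k27ac_peak_sets: Dict[str, RegionSet]  # sample id -> peaks
    pwms: List[MotifModel]
    implant_map: Dict[str, List[int]]  # tf -> ATAC peak indices
    driver_tf: str
    promoter_strength: Dict[str, float]  # per active gene, BRD4 weight

    @property
    def tf_transcripts(self) -> Dict[str, List[Transcript]]:
        out: Dict[str, List[Transcript]] = {tf: [] for tf in self.tf_names}
        for t in self.transcripts:
            if t.gene_name in out:
                out[t.gene_name].append(t)
        return out


def _rngs(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _gene_name(i: int, tf_ids: Mapping[int, str]) -> str:
    return tf_ids.get(i, f"GENE{i + 1:03d}")


def generate_regulatory_genome(config: SynthConfig) -> SynthLayout:
    """Build the genome, gene models, ATAC peaks, motifs and implants.

    Gene bodies are placed in non-overlapping slots; TF genes are a random
    subset. ATAC peaks land within +/-45 kb of active TSSs (outside the
    +/-1.5 kb promoter core so they are distal elements); each TF's motif
    consensus is implanted in its designated peaks, the driver TF getting
    ``driver_edge_count`` of them. H3K27ac peak sets cover active-gene
    promoters and all enhancer regions in every sample, with small
    coordinate jitter per sample.
    """
    cfg = config
    (rng_seq, rng_genes, rng_atac, rng_motif, rng_implant,
     rng_peaks, rng_strength) = _rngs(cfg.seed, 7)

    # -- gene models in non-overlapping slots
    slot = cfg.genome_length // cfg.n_genes
    if slot < 12_000:
        raise ValueError("genome too short for the requested gene count")
    tf_slots = rng_genes.choice(cfg.n_genes, size=cfg.n_tfs, replace=False)
    tf_ids = {int(s): f"TF{j + 1:02d}" for j, s in enumerate(sorted(tf_slots))}
    driver_tf = tf_ids[int(sorted(tf_slots)[cfg.driver_tf_index])]
    non_tf_slots = [i for i in range(cfg.n_genes) if i not in tf_ids]
    inactive = set(rng_genes.choice(non_tf_slots,
                                    size=min(cfg.n_inactive_genes, len(non_tf_slots)),
                                    replace=False).tolist())
    transcripts = []
    active_gene_names = []
    for i in range(cfg.n_genes):
        name = _gene_name(i, tf_ids)
        length = int(rng_genes.integers(2000, min(10_000, slot - 4000)))
        start = int(i * slot + rng_genes.integers(2000, slot - length - 2000))
        strand = "+" if rng_genes.random() < 0.5 else "-"
        span = GenomicInterval(cfg.chrom, start, start + length, strand=strand)
        transcripts.append(Transcript(f"TX{i + 1:03d}", name, span))
        if i not in inactive:
            active_gene_names.append(name)
    active_set = set(active_gene_names)

    # -- ATAC peaks: first one distal peak near each TF, then the rest
    active_tss = [(t.gene_name, t.tss) for t in transcripts
                  if t.gene_name in active_set]
    taken: List[Tuple[int, int]] = []
    peak_gene: List[str] = []  # gene each peak was placed near

    def _place_near(tss: int, rng) -> Optional[GenomicInterval]:
        for _ in range(200):
            off = int(rng.integers(2000, 45_000)) * (1 if rng.random() < 0.5 else -1)
            start = tss + off
            end = start + cfg.atac_peak_width
            if start < cfg.enhancer_pad or end > cfg.genome_length - cfg.enhancer_pad:
                continue
            pad_lo = start - cfg.enhancer_pad - 10
            pad_hi = end + cfg.enhancer_pad + 10
            if any(pad_lo < e and s < pad_hi for s, e in taken):
                continue
            taken.append((pad_lo, pad_hi))
            return GenomicInterval(cfg.chrom, start, end)
        return None

    peaks: List[GenomicInterval] = []
    tf_own_peak: Dict[str, int] = {}
    if cfg.n_atac_peaks > 0:
        for t in transcripts:
            if t.gene_name in tf_ids.values():
                iv = _place_near(t.tss, rng_atac)
                if iv is None:
                    raise ValueError("could not place a distal peak near every TF")
                tf_own_peak[t.gene_name] = len(peaks)
                peaks.append(iv)
                peak_gene.append(t.gene_name)
        while len(peaks) < cfg.n_atac_peaks:
            gene, tss = active_tss[int(rng_atac.integers(len(active_tss)))]
            iv = _place_near(tss, rng_atac)
            if iv is not None:
                peaks.append(iv)
                peak_gene.append(gene)
    order = np.argsort([p.start for p in peaks])
    remap = {int(old): new for new, old in enumerate(order)}
    peaks = [peaks[i] for i in order]
    peak_gene = [peak_gene[i] for i in order]
    tf_own_peak = {tf: remap[i] for tf, i in tf_own_peak.items()}
    atac = RegionSet(peaks, merged=True)

    # -- motifs (high-information consensus PWMs)
    tf_names = sorted(tf_ids.values())
    pwms = []
    for tf in tf_names:
        w = int(rng_motif.integers(cfg.motif_width_min, cfg.motif_width_max + 1))
        consensus = rng_motif.integers(0, 4, size=w)
        probs = np.full((4, w), (1 - cfg.consensus_prob) / 3)
        probs[consensus, np.arange(w)] = cfg.consensus_prob
        pwms.append(MotifModel(tf, probs))

    # -- implant assignment: disjoint peak sets per TF. The driver's peaks
    # are drawn from a contiguous block of genes so its planted target-gene
    # set stays a proper subset of the active genes (+/-50 kb windows span
    # several gene slots, so a scattered assignment would hit every gene).
    n_peaks = len(peaks)
    own = set(tf_own_peak.values())
    implant_map: Dict[str, List[int]] = {tf: [] for tf in tf_names}
    if n_peaks > 0:
        gene_order = [t.gene_name for t in transcripts
                      if t.gene_name in active_set]
        peaks_by_gene: Dict[str, List[int]] = {g: [] for g in gene_order}
        for i, g in enumerate(peak_gene):
            if i not in own:
                peaks_by_gene[g].append(i)
        start_gene = int(rng_implant.integers(len(gene_order)))
        driver_pool: List[int] = []
        gi = start_gene
        while len(driver_pool) < cfg.driver_edge_count - 1 and gi < start_gene + len(gene_order):
            driver_pool.extend(peaks_by_gene[gene_order[gi % len(gene_order)]])
            gi += 1
        driver_pool = driver_pool[:cfg.driver_edge_count - 1]
        if len(driver_pool) < cfg.driver_edge_count - 1:
            raise ValueError("not enough ATAC peaks for the driver edge count")
        used = own | set(driver_pool)
        pool = [i for i in range(n_peaks) if i not in used]
        pool = list(np.array(pool)[rng_implant.permutation(len(pool))])
        cursor = 0
        for tf in tf_names:
            if tf == driver_tf:
                implant_map[tf] = sorted([tf_own_peak[tf]] + driver_pool)
                continue
            want = cfg.nondriver_edge_count
            mine = [tf_own_peak[tf]] + [int(p) for p in pool[cursor:cursor + want - 1]]
            cursor += want - 1
            if len(mine) < want:
                raise ValueError("not enough ATAC peaks for the requested implants")
            implant_map[tf] = sorted(mine)

    # -- genome sequence with implanted consensus sites
    seq_codes = rng_seq.integers(0, 4, size=cfg.genome_length, dtype=np.int8)
    seq = np.frombuffer("ACGT".encode(), dtype=np.uint8)[seq_codes]
    seq = seq.tobytes().decode("ascii")
    seq_list = list(seq)
    model_by_tf = {m.name: m for m in pwms}
    for tf in tf_names:
        m = model_by_tf[tf]
        site = m.consensus
        for pidx in implant_map[tf]:
            peak = peaks[pidx]
            off = int(rng_implant.integers(0, len(peak) - m.width + 1))
            s = site if rng_implant.random() < 0.5 else reverse_complement(site)
            start = peak.start + off
            seq_list[start:start + m.width] = list(s)
    assembly = GenomeAssembly.from_sequences({cfg.chrom: "".join(seq_list)})

    # -- landscape: promoters of active genes + enhancer regions
    promoters = [window_around(t.tss, 1000, t.chrom, assembly, name=t.gene_name)
                 for t in transcripts if t.gene_name in active_set]
    enhancers = [GenomicInterval(cfg.chrom, p.start - cfg.enhancer_pad,
                                 p.end + cfg.enhancer_pad, name=f"enh_{i}")
                 for i, p in enumerate(peaks)]
    enhancer_set = RegionSet(enhancers, merged=True)
    from .intervals import merge_union
    landscape = merge_union([RegionSet(promoters), enhancer_set])

    # -- per-sample H3K27ac peak calls (shared landscape, jittered)
    h3k27ac_sets: Dict[str, RegionSet] = {}
    for cond in CONDITIONS:
        for rep in range(1, cfg.n_reps_h3k27ac + 1):
            jit = rng_peaks.integers(-20, 21, size=(len(landscape), 2))
            ivs = []
            for (j0, j1), iv in zip(jit, landscape):
                start = max(0, iv.start + int(j0))
                end = min(cfg.genome_length, iv.end + int(j1))
                if start < end:
                    ivs.append(GenomicInterval(cfg.chrom, start, end))
            h3k27ac_sets[f"{cond}_rep{rep}"] = RegionSet(ivs)

    strength = {g: float(rng_strength.gamma(3.0, 1.0) + 0.5)
                for g in active_gene_names}
    return SynthLayout(cfg, assembly, transcripts, tf_names, active_gene_names,
                       atac, landscape, enhancer_set, h3k27ac_sets, pwms,
                       implant_map, driver_tf, strength)


# ---------------------------------------------------------------------------
# Read tracks
# ---------------------------------------------------------------------------

def _sample_track(rng: np.random.Generator, cfg: SynthConfig,
                  region_starts: np.ndarray, region_lens: np.ndarray,
                  weights: np.ndarray,
                  norm: Optional[float] = None) -> Tuple[np.ndarray, np.ndarray, int]:
    """Poisson region counts plus uniform background -> read 5' placements.

    ``norm`` fixes the weight normalization (pass the ungained weight sum so
    a planted enrichment gain stays multiplicative across conditions); the
    background absorbs the remainder so total depth is constant.
    """
    depth = cfg.read_depth
    if weights.sum() <= 0:  # background-only track (input / parental)
        n_bg = depth
        counts = np.zeros(weights.size, dtype=np.int64)
    else:
        # the uniform background absorbs any planted extra signal so total
        # depth (hence rpm normalization) is identical across conditions
        budget = depth * (1.0 - cfg.background_fraction)
        counts = rng.poisson(budget * weights / (norm or weights.sum()))
        n_bg = max(0, depth - int(counts.sum()))
    mids = (np.repeat(region_starts, counts)
            + rng.random(int(counts.sum())) * np.repeat(region_lens, counts))
    bg_mids = rng.random(n_bg) * cfg.genome_length
    mids = np.concatenate([mids, bg_mids])
    minus = rng.random(mids.size) < 0.5
    half = 100  # half the 200 bp fragment: 5' end sits half a fragment out
    pos = np.where(minus, mids + half, mids - half).astype(np.int64)
    pos = np.clip(pos, 0, cfg.genome_length - 1)
    order = np.argsort(pos, kind="stable")
    return pos[order], minus[order], int(mids.size)


def _track_from_arrays(cfg: SynthConfig, pos: np.ndarray, minus: np.ndarray,
                       total: int, name: str) -> FragmentTrack:
    return FragmentTrack.from_arrays(
        {cfg.chrom: (pos, minus)}, total_mapped=total, extension=200,
        chrom_sizes={cfg.chrom: cfg.genome_length}, name=name)


def simulate_tracks(layout: SynthLayout) -> Dict[Tuple[str, str, int], FragmentTrack]:
    """Simulate H3K27ac / BRD4 / input / TF-ChIP fragment tracks.

    Keys are ``(mark, condition, replicate)``. BRD4 enrichment at the
    driver TF's enhancer regions is multiplied by ``driver_brd4_gain`` in
    the "lscp" condition only; H3K27ac is shared between conditions; the
    input track is uniform background; the TF ChIP ("tfchip") is enriched
    at the driver's peaks in the engineered condition and is
    background-only in the parental condition.
    """
    cfg = layout.config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(8)[7])
    landscape = layout.landscape_elements
    starts = np.array([iv.start for iv in landscape])
    lens = np.array([len(iv) for iv in landscape], dtype=float)

    promoter_gene = {}
    for t in layout.transcripts:
        if t.gene_name in layout.promoter_strength:
            promoter_gene[t.gene_name] = window_around(t.tss, 1000, t.chrom)
    promoter_weight = np.zeros(len(landscape))
    for gene, win in promoter_gene.items():
        for ridx in landscape.overlapping_indices(win):
            promoter_weight[ridx] += layout.promoter_strength[gene]

    enhancer_weight = np.zeros(len(landscape))
    for iv in layout.enhancer_regions:
        for ridx in landscape.overlapping_indices(iv):
            enhancer_weight[ridx] += 1.0

    driver_weight = np.zeros(len(landscape))
    driver_peaks = layout.implant_map[layout.driver_tf]
    for pidx in driver_peaks:
        peak = layout.atac[pidx]
        for ridx in landscape.overlapping_indices(peak):
            driver_weight[ridx] = 1.0

    tracks: Dict[Tuple[str, str, int], FragmentTrack] = {}
    for cond in CONDITIONS:
        h3_w = 2.0 * promoter_weight / max(layout.promoter_strength.values()) \
            + enhancer_weight
        for rep in range(1, cfg.n_reps_h3k27ac + 1):
            pos, minus, total = _sample_track(rng, cfg, starts, lens, h3_w)
            tracks[("h3k27ac", cond, rep)] = _track_from_arrays(
                cfg, pos, minus, total, f"h3k27ac_{cond}_{rep}")
        gain = cfg.driver_brd4_gain if cond == "lscp" else 1.0
        base_w = promoter_weight + enhancer_weight
        # multiplicative gain at driver regions, normalized to the ungained
        # sum so the planted per-edge fold change is exactly the gain
        brd4_w = base_w * (1.0 + (gain - 1.0) * driver_weight)
        for rep in range(1, cfg.n_reps_brd4 + 1):
            pos, minus, total = _sample_track(rng, cfg, starts, lens, brd4_w,
                                              norm=float(base_w.sum()))
            tracks[("brd4", cond, rep)] = _track_from_arrays(
                cfg, pos, minus, total, f"brd4_{cond}_{rep}")
        pos, minus, total = _sample_track(rng, cfg, starts, lens,
                                          np.zeros(len(landscape)))
        tracks[("input", cond, 1)] = _track_from_arrays(
            cfg, pos, minus, total, f"input_{cond}")

    # TF ChIP for the driver: engineered (enriched) vs parental (background)
    for rep in range(1, cfg.n_reps_tfchip + 1):
        pos, minus, total = _sample_track(rng, cfg, starts, lens,
                                          driver_weight * enhancer_weight)
        tracks[("tfchip", "engineered", rep)] = _track_from_arrays(
            cfg, pos, minus, total, f"tfchip_engineered_{rep}")
        pos, minus, total = _sample_track(rng, cfg, starts, lens,
                                          np.zeros(len(landscape)))
        tracks[("tfchip", "parental", rep)] = _track_from_arrays(
            cfg, pos, minus, total, f"tfchip_parental_{rep}")
    return tracks


def tfchip_peak_sets(layout: SynthLayout) -> Dict[str, List[RegionSet]]:
    """Per-replicate TF-ChIP peak calls for the driver TF.

    Engineered replicates contain the driver's true peaks (jittered) plus a
    shared set of spurious peaks; parental replicates contain only the
    spurious peaks, so differencing recovers the truth.
    """
    cfg = layout.config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(9)[8])
    driver_peaks = [layout.atac[i] for i in layout.implant_map[layout.driver_tf]]
    spurious = []
    for _ in range(cfg.n_spurious_tfchip_peaks):
        start = int(rng.integers(0, cfg.genome_length - 300))
        spurious.append(GenomicInterval(cfg.chrom, start, start + 250))

    def jitter(ivs: Sequence[GenomicInterval]) -> RegionSet:
        out = []
        for iv in ivs:
            j0, j1 = rng.integers(-10, 11, size=2)
            start = max(0, iv.start + int(j0))
            end = min(cfg.genome_length, iv.end + int(j1))
            out.append(GenomicInterval(cfg.chrom, start, end))
        return RegionSet(out)

    engineered = [jitter(driver_peaks + spurious)
                  for _ in range(cfg.n_reps_tfchip)]
    parental = [jitter(spurious)]
    return {"engineered": engineered, "parental": parental}


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(layout: SynthLayout,
                        tracks: Mapping[Tuple[str, str, int], FragmentTrack]
                        ) -> pd.DataFrame:
    """FPKM table coupled to promoter-proximal BRD4 occupancy.

    ``log2 FPKM = a * log2(brd4_rpm + 1) + noise`` per condition, with
    ``a`` chosen so every active gene stays >= 10 FPKM even at -4 sd of
    noise; inactive genes get background expression below 10 FPKM.
    Indexed by transcript id with 3 replicate columns per condition.
    """
    from .signal import gene_signal_table

    cfg = layout.config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(10)[9])
    brd4 = {cond: [tr for key, tr in tracks.items()
                   if key[0] == "brd4" and key[1] == cond]
            for cond in CONDITIONS}
    table = gene_signal_table(layout.transcripts, layout.landscape_elements,
                              brd4, assembly=layout.assembly)
    active = set(layout.active_gene_names)
    is_active = table["gene_name"].isin(active).to_numpy()
    rpm = table[list(CONDITIONS)].to_numpy(float)
    log_rpm = np.log2(rpm + 1.0)
    min_active = log_rpm[is_active].min()
    sd = cfg.expression_noise_sd
    a = max(1.0, (np.log2(10.0) + 4.0 * sd + 0.5) / max(min_active, 0.1))
    cols = {}
    for c, cond in enumerate(CONDITIONS):
        for rep in range(1, cfg.n_expression_reps + 1):
            noise = rng.normal(0.0, sd, size=len(table))
            log_fpkm = a * log_rpm[:, c] + noise
            fpkm = np.where(is_active, 2.0 ** log_fpkm,
                            rng.uniform(0.2, 5.0, size=len(table)))
            cols[f"{cond}_rep{rep}"] = fpkm
    out = pd.DataFrame(cols, index=table["transcript_id"])
    out.index.name = "transcript_id"
    out.insert(0, "gene_name", table["gene_name"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# PPI graph and screen
# ---------------------------------------------------------------------------

def simulate_ppi(tf_names: Sequence[str], seed: int,
                 intra_p: float = 0.9, inter_p: float = 0.05,
                 intra_score: float = 0.7, inter_score: float = 0.45
                 ) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """PPI edge list with two planted cliques over the TF panel.

    The panel is split in half into two clusters; within-cluster edges
    appear with probability ``intra_p`` (score ``intra_score``) and
    between-cluster edges with probability ``inter_p``. Every TF is
    guaranteed at least one within-cluster edge. Returns the edge table
    (STRING-like columns) and the planted cluster assignment.
    """
    rng = np.random.default_rng(seed)
    tfs = sorted(tf_names)
    half = len(tfs) // 2
    cluster = {tf: (0 if i < half else 1) for i, tf in enumerate(tfs)}
    rows = []
    connected = set()
    for i, a in enumerate(tfs):
        for b in tfs[i + 1:]:
            same = cluster[a] == cluster[b]
            p = intra_p if same else inter_p
            if rng.random() < p:
                score = intra_score if same else inter_score
                ev = "experimental" if rng.random() < 0.7 else "predicted"
                rows.append((a, b, score, ev))
                if same:
                    connected.update((a, b))
    for tf in tfs:
        if tf not in connected:
            mates = [t for t in tfs if t != tf and cluster[t] == cluster[tf]]
            mate = mates[int(rng.integers(len(mates)))]
            rows.append((tf, mate, intra_score, "experimental"))
            connected.update((tf, mate))
    df = pd.DataFrame(rows, columns=["protein1", "protein2",
                                     "combined_score", "evidence"])
    return df, cluster


def simulate_screen(cfg: ScreenConfig, seed: int) -> Tuple[ScreenTable, List[str], List[str]]:
    """Pooled-screen counts with planted depleting / enriching genes.

    Reference counts are negative-binomial (mean ``mean_reads``); later
    timepoints scale a planted gene's reagent means by
    ``2^(t * effect_log2fc)`` (negative exponent for the depleting set).
    Returns the table plus the planted down and up gene lists.
    """
    rng = np.random.default_rng(seed)
    genes = [f"SG{i + 1:04d}" for i in range(cfg.n_genes)]
    planted = rng.choice(cfg.n_genes, size=cfg.planted_down + cfg.planted_up,
                         replace=False)
    down = sorted(genes[i] for i in planted[:cfg.planted_down])
    up = sorted(genes[i] for i in planted[cfg.planted_down:])
    sgrnas, mapping = [], {}
    for g in genes:
        for r in range(1, cfg.reagents_per_gene + 1):
            sg = f"{g}_sg{r}"
            sgrnas.append(sg)
            mapping[sg] = g
    n_sg = len(sgrnas)
    nb_n = 1.0 / cfg.dispersion

    def nb(mean: np.ndarray) -> np.ndarray:
        p = nb_n / (nb_n + mean)
        return rng.negative_binomial(nb_n, p)

    base = np.full(n_sg, cfg.mean_reads)
    cols = {"reference": nb(base)}
    effect = np.zeros(n_sg)
    gene_arr = np.array([mapping[s] for s in sgrnas])
    effect[np.isin(gene_arr, down)] = -cfg.effect_log2fc
    effect[np.isin(gene_arr, up)] = cfg.effect_log2fc
    timepoints = []
    for t in range(1, cfg.n_timepoints + 1):
        name = f"t{t}"
        timepoints.append(name)
        cols[name] = nb(base * 2.0 ** (t * effect))
    counts = pd.DataFrame(cols, index=pd.Index(sgrnas, name="sgrna"))
    return ScreenTable(counts, mapping, "reference", timepoints), down, up


# ---------------------------------------------------------------------------
# Bundled dataset
# ---------------------------------------------------------------------------

@dataclass
class SynthDataset:
    layout: SynthLayout
    tracks: Dict[Tuple[str, str, int], FragmentTrack]
    tfchip_peaks: Dict[str, List[RegionSet]]
    expression: pd.DataFrame
    ppi: pd.DataFrame
    screen: ScreenTable
    truth: GroundTruth


def simulate_dataset(config: SynthConfig) -> SynthDataset:
    """Run every generator and assemble the ground truth."""
    layout = generate_regulatory_genome(config)
    tracks = simulate_tracks(layout)
    chip_peaks = tfchip_peak_sets(layout)
    expression = simulate_expression(layout, tracks)
    seeds = np.random.SeedSequence(config.seed).spawn(13)
    ppi, clusters = simulate_ppi(layout.tf_names,
                                 seeds[10].generate_state(1)[0] % (2 ** 31),
                                 intra_p=config.clique_intra_p,
                                 inter_p=config.clique_inter_p)
    screen, down, up = simulate_screen(config.screen,
                                       seeds[11].generate_state(1)[0] % (2 ** 31))
    driver_peaks = layout.implant_map[layout.driver_tf]
    targets = set()
    for t in layout.transcripts:
        if t.gene_name not in set(layout.active_gene_names):
            continue
        win = window_around(t.tss, 50_000, t.chrom, layout.assembly)
        for pidx in driver_peaks:
            peak = layout.atac[pidx]
            if peak.start < win.end and win.start < peak.end:
                targets.add(t.gene_name)
                break
    active_tx = [t.transcript_id for t in layout.transcripts
                 if t.gene_name in set(layout.active_gene_names)]
    truth = GroundTruth(layout.driver_tf, list(map(int, driver_peaks)),
                        sorted(targets), active_tx, clusters, down, up)
    return SynthDataset(layout, tracks, chip_peaks, expression, ppi, screen, truth)


def write_dataset(ds: SynthDataset, outdir) -> None:
    """Emit the dataset as the plain-text files the readers consume."""
    from . import io as cio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    layout = ds.layout
    cio.write_fasta(layout.assembly, out / "genome.fa")
    cio.write_chrom_sizes(layout.assembly.chrom_sizes, out / "chrom.sizes")
    cio.write_transcripts_tsv(layout.transcripts, out / "genes.tsv")
    cio.write_narrowpeak(layout.atac, out / "atac.narrowPeak")
    for sample, rs in layout.h3k27ac_peak_sets.items():
        cio.write_narrowpeak(rs, out / f"h3k27ac_{sample}.narrowPeak")
    for cls, reps in ds.tfchip_peaks.items():
        for i, rs in enumerate(reps, 1):
            cio.write_narrowpeak(rs, out / f"tfchip_{cls}_rep{i}.narrowPeak")
    cio.write_meme([(m.name, m.probs) for m in layout.pwms], out / "pwms.meme")
    for (mark, cond, rep), track in ds.tracks.items():
        path = out / f"reads_{mark}_{cond}_{rep}.bed"
        track.write_bed(path)
    ds.expression.to_csv(out / "expression.tsv", sep="\t")
    cio.write_ppi_tsv(ds.ppi, out / "ppi.tsv")
    counts = ds.screen.counts.copy()
    counts.insert(0, "gene", [ds.screen.sgrna_to_gene[s] for s in counts.index])
    counts.to_csv(out / "screen_counts.tsv", sep="\t")
    ds.truth.to_json(out / "ground_truth.json")
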