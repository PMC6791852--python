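"""Read-density quantification and the gene-level occupancy ranking.

Fragment tracks hold read 5'-end placements; each read is extended to a
fixed fragment length (200 bp by default) and region occupancy is reported
as AUC in reads-per-million (rpm): the number of extended reads overlapping
the region divided by millions of mapped reads. A read counts once per
region regardless of how many bases it covers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .intervals import (
    GenomeAssembly,
    GenomicInterval,
    RegionSet,
    Transcript,
    window_around,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentTrack",
    "SignalValue",
    "BinnedProfile",
    "extend_read",
    "region_auc",
    "sample_similarity",
    "call_active_genes",
    "gene_window_signal",
    "gene_signal_table",
    "rank_genes_by_delta",
    "binned_profile",
    "DegenerateTrackError",
]

DEFAULT_EXTENSION = 200


class DegenerateTrackError(ValueError):
    """A track cannot be normalized (zero depth or zero median signal)."""


def extend_read(chrom: str, pos: int, strand: str, extension: int = DEFAULT_EXTENSION,
                chrom_len: Optional[int] = None) -> GenomicInterval:
    """Extend a read 5' placement to ``extension`` bp in its direction.

    Plus-strand reads cover ``[pos, pos + ext)``; minus-strand reads cover
    ``[pos - ext + 1, pos + 1)``. Unstranded placements are treated as plus.
    Coordinates are clamped to the chromosome.
    """
    if extension <= 0:
        raise ValueError("extension must be positive")
    if strand == "-":
        start, end = pos - extension + 1, pos + 1
    else:
        start, end = pos, pos + extension
    start = max(0, start)
    if chrom_len is not None:
        end = min(end, chrom_len)
    return GenomicInterval(chrom, start, end)


@dataclass(frozen=True)
class SignalValue:
    """Region occupancy: AUC in rpm and mean per-base density in rpm/bp."""

    auc_rpm: float
    density_rpm_per_bp: float


class FragmentTrack:
    """Aligned-read placements with depth normalization.

    Parameters
    ----------
    placements
        Iterable of ``(chrom, five_prime_pos, strand)``.
    total_mapped
        Total mapped reads for rpm normalization; defaults to the number of
        placements.
    extension
        Fragment extension in bp applied to every read.
    """

    def __init__(self, placements: Iterable[Tuple[str, int, str]],
                 total_mapped: Optional[int] = None,
                 extension: int = DEFAULT_EXTENSION,
                 assembly: Optional[GenomeAssembly] = None,
                 name: str = "track"):
        raw: Dict[str, List[Tuple[int, bool]]] = {}
        warned_unstranded = False
        for chrom, pos, strand in placements:
            if strand == ".":
                if not warned_unstranded:
                    logger.warning("track %s: unstranded placements treated as '+'", name)
                    warned_unstranded = True
                strand = "+"
            raw.setdefault(chrom, []).append((pos, strand == "-"))
        by_chrom = {
            chrom: (np.array([p for p, _ in items], dtype=np.int64),
                    np.array([m for _, m in items], dtype=bool))
            for chrom, items in raw.items()
        }
        chrom_sizes = assembly.chrom_sizes if assembly is not None else None
        self._init_from_arrays(by_chrom, total_mapped, extension, chrom_sizes, name)

    @classmethod
    def from_arrays(cls, by_chrom: Mapping[str, Tuple[np.ndarray, np.ndarray]],
                    total_mapped: Optional[int] = None,
                    extension: int = DEFAULT_EXTENSION,
                    chrom_sizes: Optional[Mapping[str, int]] = None,
                    name: str = "track") -> "FragmentTrack":
        """Vectorized constructor: ``{chrom: (positions, is_minus)}`` arrays."""
        self = cls.__new__(cls)
        self._init_from_arrays(dict(by_chrom), total_mapped, extension,
                               chrom_sizes, name)
        return self

    def _init_from_arrays(self, by_chrom, total_mapped, extension,
                          chrom_sizes, name) -> None:
        self.extension = int(extension)
        if self.extension <= 0:
            raise ValueError("extension must be positive")
        self.name = name
        self._raw: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        self._by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        n = 0
        for chrom, (pos, minus) in by_chrom.items():
            pos = np.asarray(pos, dtype=np.int64)
            minus = np.asarray(minus, dtype=bool)
            n += pos.size
            starts = np.where(minus, pos - self.extension + 1, pos)
            ends = np.where(minus, pos + 1, pos + self.extension)
            starts = np.maximum(starts, 0)
            if chrom_sizes is not None and chrom in chrom_sizes:
                ends = np.minimum(ends, chrom_sizes[chrom])
            self._raw[chrom] = (pos, minus)
            self._by_chrom[chrom] = (np.sort(starts), np.sort(ends))
        self.n_placements = n
        self.total_mapped = int(total_mapped) if total_mapped is not None else n
        if n > 0 and self.total_mapped < n:
            raise ValueError("total_mapped cannot be smaller than the placement count")

    def write_bed(self, path) -> None:
        """Write placements as BED6 plus a ``.totals`` sidecar."""
        from pathlib import Path

        frames = []
        for chrom, (pos, minus) in sorted(self._raw.items()):
            frames.append(pd.DataFrame({
                "chrom": chrom, "start": pos, "end": pos + 1,
                "name": ".", "score": 0,
                "strand": np.where(minus, "-", "+"),
            }))
        df = pd.concat(frames) if frames else pd.DataFrame(
            columns=["chrom", "start", "end", "name", "score", "strand"])
        df.to_csv(path, sep="\t", header=False, index=False)
        Path(str(path) + ".totals").write_text(f"{self.total_mapped}\n")

    @property
    def millions(self) -> float:
        return self.total_mapped / 1e6

    def count_overlapping(self, region: GenomicInterval) -> int:
        """Number of extended reads sharing >= 1 base with ``region``."""
        entry = self._by_chrom.get(region.chrom)
        if entry is None:
            return 0
        starts, ends = entry
        n = starts.size
        n_right = n - int(np.searchsorted(starts, region.end, side="left"))
        n_left = int(np.searchsorted(ends, region.start, side="right"))
        return n - n_left - n_right

    def base_coverage(self, region: GenomicInterval) -> np.ndarray:
        """Per-base overlapping-read count across ``region``."""
        entry = self._by_chrom.get(region.chrom)
        if entry is None:
            return np.zeros(len(region), dtype=np.int64)
        starts, ends = entry
        pos = np.arange(region.start, region.end) + 1
        return (np.searchsorted(starts, pos, side="left")
                - np.searchsorted(ends, pos - 1, side="right"))

    def reads_on_chrom(self, chrom: str) -> int:
        entry = self._by_chrom.get(chrom)
        return 0 if entry is None else int(entry[0].size)


def region_auc(track: FragmentTrack, region: GenomicInterval) -> SignalValue:
    """AUC of read occupancy in ``region``: overlapping reads / millions mapped."""
    if track.total_mapped == 0:
        raise DegenerateTrackError(
            f"track {track.name}: total_mapped is 0, rpm normalization undefined")
    count = track.count_overlapping(region)
    auc = count / track.millions
    return SignalValue(auc_rpm=auc, density_rpm_per_bp=auc / len(region))


def _region_auc_vector(track: FragmentTrack, regions: RegionSet) -> np.ndarray:
    return np.array([region_auc(track, iv).auc_rpm for iv in regions], dtype=float)


def sample_similarity(landscape: RegionSet, tracks: Mapping[str, FragmentTrack]
                      ) -> Tuple[pd.DataFrame, List[str]]:
    """Pairwise sample similarity over the active landscape.

    Per sample, the vector of region AUCs is normalized to its median, then
    pairwise Pearson correlation is computed and samples are clustered
    (average linkage) on the distance ``1 - r``.

    Returns the correlation matrix (DataFrame) and the leaf order of the
    dendrogram.
    """
    if not landscape.merged:
        raise ValueError("landscape must be a merged RegionSet")
    names = list(tracks)
    if len(names) < 2:
        raise ValueError("need at least two tracks")
    mat = []
    for name in names:
        v = _region_auc_vector(tracks[name], landscape)
        med = np.median(v)
        if med == 0:
            raise DegenerateTrackError(f"track {name}: median region AUC is 0")
        mat.append(v / med)
    mat = np.asarray(mat)
    corr = np.corrcoef(mat)
    corr_df = pd.DataFrame(corr, index=names, columns=names)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    order = [names[i] for i in leaves_list(z)]
    return corr_df, order


def call_active_genes(transcripts: Sequence[Transcript],
                      h3k27ac_peak_sets: Sequence[RegionSet],
                      expression: pd.DataFrame,
                      fpkm_min: float = 10.0,
                      promoter_half_width: int = 1000,
                      assembly: Optional[GenomeAssembly] = None
                      ) -> List[Transcript]:
    """Transcripts with a promoter H3K27ac peak and expression >= ``fpkm_min``.

    A transcript is active if any sample's H3K27ac peak set has a peak
    overlapping the +/-1 kb TSS window AND its expression reaches
    ``fpkm_min`` (inclusive) in at least one sample. Expression is looked up
    by transcript id first, then by gene name; missing entries count as 0.
    """
    max_expr: Dict[str, float] = expression.max(axis=1).to_dict()
    missing_logged = False
    out = []
    for t in transcripts:
        expr = max_expr.get(t.transcript_id)
        if expr is None:
            expr = max_expr.get(t.gene_name)
        if expr is None:
            if not missing_logged:
                logger.warning("some transcripts missing from expression table; "
                               "treated as 0 FPKM (first: %s)", t.transcript_id)
                missing_logged = True
            expr = 0.0
        if expr < fpkm_min:
            continue
        promoter = window_around(t.tss, promoter_half_width, t.chrom, assembly)
        if any(s.overlaps_any(promoter) for s in h3k27ac_peak_sets):
            out.append(t)
    return out


def gene_window_signal(gene: Transcript, landscape: RegionSet,
                       track: FragmentTrack, half_width: int = 50_000,
                       assembly: Optional[GenomeAssembly] = None) -> float:
    """Summed AUC (rpm) over landscape regions within +/-``half_width`` of the TSS.

    Regions overlapping the window by >= 1 base contribute their full-extent
    AUC (not clipped to the window).
    """
    if not landscape.merged:
        raise ValueError("landscape must be a merged RegionSet")
    window = window_around(gene.tss, half_width, gene.chrom, assembly)
    return float(sum(region_auc(track, iv).auc_rpm
                     for iv in landscape.overlapping(window)))


def gene_signal_table(genes: Sequence[Transcript], landscape: RegionSet,
                      tracks_by_condition: Mapping[str, Sequence[FragmentTrack]],
                      half_width: int = 50_000,
                      assembly: Optional[GenomeAssembly] = None) -> pd.DataFrame:
    """Per-gene mean AUC per condition (replicates averaged arithmetically)."""
    window_idx = [
        landscape.overlapping_indices(window_around(g.tss, half_width, g.chrom, assembly))
        for g in genes
    ]
    rows = {}
    for cond, tracks in tracks_by_condition.items():
        # cache region AUC per track, then sum per gene window
        auc = np.array([_region_auc_vector(tr, landscape) for tr in tracks])
        mean_auc = auc.mean(axis=0)
        rows[cond] = [float(mean_auc[idx].sum()) for idx in window_idx]
    df = pd.DataFrame(rows)
    df.insert(0, "transcript_id", [g.transcript_id for g in genes])
    df.insert(1, "gene_name", [g.gene_name for g in genes])
    return df


def rank_genes_by_delta(table: pd.DataFrame, cond_a: str, cond_b: str,
                        pseudo: float = 1.0,
                        column: str = "log2fc") -> pd.DataFrame:
    """Rank genes by log2((A + c) / (B + c)), descending.

    Ties are broken by gene name so the ordering is deterministic.
    """
    df = table.copy()
    df[column] = np.log2((df[cond_a] + pseudo) / (df[cond_b] + pseudo))
    df = df.sort_values([column, "gene_name"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass(frozen=True)
class BinnedProfile:
    """Mean of one rank-ordered bin with a bootstrap CI of the mean."""

    bin_index: int
    mean: float
    ci_low: float
    ci_high: float
    n: int


def binned_profile(values: Sequence[float], bin_size: int = 100,
                   n_boot: int = 1000, seed: int = 0,
                   ci: float = 95.0) -> List[BinnedProfile]:
    """Binned averages over rank-ordered values with bootstrap CIs.

    Values are split into consecutive bins of ``bin_size`` (the last bin may
    be short). The CI is the 2.5/97.5 percentile (for ``ci=95``) of
    ``n_boot`` bootstrap means obtained by resampling the bin's values with
    replacement. Deterministic given ``seed``.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    out = []
    for b, start in enumerate(range(0, values.size, bin_size)):
        chunk = values[start:start + bin_size]
        idx = rng.integers(0, chunk.size, size=(n_boot, chunk.size))
        boot_means = chunk[idx].mean(axis=1)
        lo, hi = np.percentile(boot_means, [lo_q, hi_q])
        m = float(chunk.mean())
        out.append(BinnedProfile(b, m, float(min(lo, m)), float(max(hi, m)),
                                 int(chunk.size)))
    return out
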