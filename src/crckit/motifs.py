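"""PWM motif scanning with exact p-values and the binary occupancy matrix.

Scanning follows the FIMO approach: log-odds scores in bits against a
0-order background, an exact null score distribution computed by dynamic
programming over discretized per-column scores, Benjamini-Hochberg
q-values over every scanned offset on both strands, and a q-value cutoff
(1e-5 by default) for reported occurrences.

Column scores are discretized to a fixed granularity (1e-3 bits by
default); the scanner and the p-value table share the same discretized
scores, so the survival function is exact for every score the scanner can
produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .intervals import GenomeAssembly, GenomicInterval, RegionSet, merge_union

logger = logging.getLogger(__name__)

__all__ = [
    "MotifModel",
    "MotifHit",
    "scan_regions",
    "occupancy_matrix",
    "estimate_background",
    "reverse_complement",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGTN", "TGCAN")
# complement permutation of the ACGT axis
_COMP_IDX = np.array([3, 2, 1, 0])


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to codes A=0 C=1 G=2 T=3, anything else=4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


class MotifModel:
    """A position weight matrix with smoothed log-odds scoring.

    Parameters
    ----------
    name : str
        TF / motif name.
    probs : (4, w) array
        Per-column base probabilities in ACGT order; columns must sum to 1.
    background : (4,) array, optional
        0-order background; uniform by default.
    pseudocount : float
        Background-weighted pseudocount mixed into the frequencies before
        log-odds: ``p' = (p + c * bg) / (1 + c)``.
    granularity : float
        Score discretization step in bits for the exact p-value table.
    """

    def __init__(self, name: str, probs: np.ndarray,
                 background: Optional[np.ndarray] = None,
                 pseudocount: float = 0.1,
                 granularity: float = 1e-3):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError("probs must be a (4, w) array")
        colsums = probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError(f"motif {name}: columns do not sum to 1")
        self.name = name
        self.probs = probs / colsums
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        if not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        self.background = bg / bg.sum()
        self.pseudocount = float(pseudocount)
        self.granularity = float(granularity)
        smoothed = (self.probs + self.pseudocount * self.background[:, None]) / (
            1.0 + self.pseudocount)
        bits = np.log2(smoothed / self.background[:, None])
        # integer column scores shared by the scanner and the p-value DP
        self.int_scores = np.rint(bits / self.granularity).astype(np.int64)
        self._survival: Optional[np.ndarray] = None
        self._min_total: Optional[int] = None

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=0))

    def information_content(self) -> float:
        """Mean information content per column (bits), vs the background."""
        p = np.clip(self.probs, 1e-12, None)
        ic = (p * np.log2(p / self.background[:, None])).sum(axis=0)
        return float(ic.mean())

    def with_background(self, background: np.ndarray) -> "MotifModel":
        return MotifModel(self.name, self.probs, background,
                          self.pseudocount, self.granularity)

    def log_odds_score(self, window: str) -> float:
        """Log-odds score of a single w-mer in bits; N positions contribute 0."""
        if len(window) != self.width:
            raise ValueError(f"window length {len(window)} != motif width {self.width}")
        codes = _encode(window)
        units = 0
        for j, c in enumerate(codes):
            if c < 4:
                units += self.int_scores[c, j]
        return units * self.granularity

    # -- exact null distribution ------------------------------------------

    def _ensure_distribution(self) -> None:
        if self._survival is not None:
            return
        cur = np.array([1.0])
        cur_min = 0
        for j in range(self.width):
            col = self.int_scores[:, j]
            lo, hi = int(col.min()), int(col.max())
            new = np.zeros(cur.size + hi - lo, dtype=float)
            for b in range(4):
                shift = int(col[b]) - lo
                new[shift:shift + cur.size] += cur * self.background[b]
            cur = new
            cur_min += lo
        # survival[i] = P(total_units >= cur_min + i)
        self._survival = np.cumsum(cur[::-1])[::-1]
        self._min_total = cur_min

    def score_pvalue(self, score_bits: float) -> float:
        """Exact p-value: probability a background w-mer scores >= ``score_bits``."""
        self._ensure_distribution()
        units = int(np.rint(score_bits / self.granularity))
        idx = units - self._min_total
        if idx <= 0:
            return 1.0
        if idx >= self._survival.size:
            return float(self._survival[-1])  # above the max attainable score
        return float(self._survival[idx])

    def max_score(self) -> float:
        return float(self.int_scores.max(axis=0).sum() * self.granularity)

    def _pvalues_for_units(self, units: np.ndarray) -> np.ndarray:
        self._ensure_distribution()
        idx = np.clip(units - self._min_total, 0, self._survival.size - 1)
        p = self._survival[idx]
        return np.where(units - self._min_total <= 0, 1.0, p)

    def _scan_units(self, codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
        """Total integer scores at every offset; offsets touching N get -inf-like."""
        w = self.width
        if codes.size < w:
            return np.zeros(0, dtype=np.int64)
        ext = np.vstack([matrix, np.zeros(w, dtype=np.int64)])  # row 4 = N
        windows = sliding_window_view(codes, w)
        units = ext[windows, np.arange(w)].sum(axis=1)
        has_n = (windows == 4).any(axis=1)
        units = units.astype(np.int64)
        units[has_n] = np.iinfo(np.int64).min // 2  # N-containing offsets never pass
        return units


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence passing the q-value cutoff."""

    tf: str
    region: GenomicInterval  # width-w interval of the match
    strand: str
    score_bits: float
    p: float
    q: float


def estimate_background(regions: RegionSet, assembly: GenomeAssembly) -> np.ndarray:
    """0-order base frequencies of the scanned sequence, strand-symmetrized.

    Symmetrizing (averaging with the complement) makes one null score
    distribution valid for both scanned strands. Falls back to uniform when
    no ACGT bases are present.
    """
    counts = np.zeros(4)
    for iv in regions:
        codes = _encode(assembly.fetch(iv))
        counts += np.bincount(codes[codes < 4], minlength=4)[:4]
    if counts.sum() == 0:
        return np.full(4, 0.25)
    bg = counts / counts.sum()
    return (bg + bg[_COMP_IDX]) / 2.0


def scan_regions(motif_models: Sequence[MotifModel] | MotifModel,
                 regions: RegionSet,
                 assembly: GenomeAssembly,
                 q_max: float = 1e-5,
                 background: Optional[np.ndarray] = None,
                 ) -> Dict[str, List[MotifHit]]:
    """Scan regions on both strands; return q-passing hits per motif.

    For each motif the BH correction is applied over every scanned offset on
    both strands, and occurrences with ``q < q_max`` are returned sorted by
    coordinate.
    """
    single = isinstance(motif_models, MotifModel)
    models = [motif_models] if single else list(motif_models)
    if background is None:
        background = estimate_background(regions, assembly)
    models = [m.with_background(background) for m in models]

    encoded = []
    for iv in regions:
        if assembly.sequence is None or iv.chrom not in assembly.sequence:
            raise KeyError(f"no sequence available for chromosome {iv.chrom!r}")
        encoded.append((iv, _encode(assembly.fetch(iv))))

    out: Dict[str, List[MotifHit]] = {}
    for m in models:
        fwd = m.int_scores
        # scanning the forward strand with the reverse-complemented matrix
        # reports minus-strand matches at the same coordinates
        rev = fwd[_COMP_IDX][:, ::-1]
        segments: List[Tuple[GenomicInterval, str, int, int]] = []  # (iv, strand, lo, hi)
        unit_list: List[np.ndarray] = []
        offset = 0
        for iv, codes in encoded:
            for strand, matrix in (("+", fwd), ("-", rev)):
                units = m._scan_units(codes, matrix)
                unit_list.append(units)
                segments.append((iv, strand, offset, offset + units.size))
                offset += units.size
        if offset == 0:
            out[m.name] = []
            continue
        all_units = np.concatenate(unit_list)
        pvals = m._pvalues_for_units(all_units)
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        passing = np.nonzero(qvals < q_max)[0]
        hits = []
        for idx in passing:
            for iv, strand, lo, hi in segments:
                if lo <= idx < hi:
                    off = int(idx - lo)
                    hit_iv = GenomicInterval(iv.chrom, iv.start + off,
                                             iv.start + off + m.width, strand=strand)
                    hits.append(MotifHit(m.name, hit_iv, strand,
                                         float(all_units[idx] * m.granularity),
                                         float(pvals[idx]), float(qvals[idx])))
                    break
        hits.sort(key=lambda h: (h.region.chrom, h.region.start, h.strand))
        out[m.name] = hits
    return out


def occupancy_matrix(hits_by_tf: Mapping[str, Sequence[MotifHit]],
                     extension: int = 50,
                     assembly: Optional[GenomeAssembly] = None,
                     ) -> Tuple[pd.DataFrame, pd.DataFrame, List[str]]:
    """Binary occupancy matrix of atomic regions x TFs, with TF clustering.

    Hits are extended by ``extension`` bp on both sides, merged across all
    TFs into atomic regions, and cell (r, t) is 1 iff TF t has an extended
    hit overlapping region r. Returns (matrix, TF correlation matrix, TF
    order from average-linkage clustering on 1 - r). TFs with zero hits are
    dropped with a warning.
    """
    ext_sets: Dict[str, RegionSet] = {}
    for tf, hits in hits_by_tf.items():
        if not hits:
            logger.warning("occupancy_matrix: TF %s has no hits; dropped", tf)
            continue
        ivs = []
        for h in hits:
            start = max(0, h.region.start - extension)
            end = h.region.end + extension
            if assembly is not None:
                end = min(end, assembly.chrom_sizes[h.region.chrom])
            ivs.append(GenomicInterval(h.region.chrom, start, end))
        ext_sets[tf] = RegionSet(ivs)
    if not ext_sets:
        raise ValueError("no TF has any hits")
    atomic = merge_union(list(ext_sets.values()))
    tfs = sorted(ext_sets)
    mat = np.zeros((len(atomic), len(tfs)), dtype=np.int8)
    for t, tf in enumerate(tfs):
        for iv in ext_sets[tf]:
            for r in atomic.overlapping_indices(iv):
                mat[r, t] = 1
    index = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in atomic]
    matrix = pd.DataFrame(mat, index=index, columns=tfs)
    if len(tfs) >= 2:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(mat.T.astype(float))
        # zero-variance columns make Pearson undefined: identical columns are
        # treated as perfectly concordant, otherwise uncorrelated
        if np.isnan(corr).any():
            for i in range(len(tfs)):
                for j in range(len(tfs)):
                    if np.isnan(corr[i, j]):
                        corr[i, j] = 1.0 if (mat[:, i] == mat[:, j]).all() else 0.0
        np.fill_diagonal(corr, 1.0)
        dist = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="average")
        order = [tfs[i] for i in leaves_list(z)]
    else:
        corr = np.ones((len(tfs), len(tfs)))
        order = list(tfs)
    corr_df = pd.DataFrame(corr, index=tfs, columns=tfs)
    return matrix, corr_df, order
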