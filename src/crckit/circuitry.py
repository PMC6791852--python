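"""Core regulatory circuitry: TF prioritization, Markov clustering of the
PPI graph, regulatory IN/OUT connectivity, and BRD4 IN/OUT degrees.

A regulatory interaction is a TF binding (a q-passing motif occurrence)
inside a nucleosome-free region (ATAC peak) that lies within an active
cis-regulatory element (H3K27ac landscape region). The BRD4 OUT degree of
a TF is the total BRD4 occupancy at the landscape regions it is predicted
to bind; the IN degree is BRD4 occupancy at its own proximal elements.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomeAssembly, GenomicInterval, RegionSet, Transcript, window_around
from .motifs import MotifHit
from .signal import FragmentTrack, region_auc

logger = logging.getLogger(__name__)

__all__ = [
    "MclConvergenceError",
    "prioritize_tfs",
    "mcl_cluster",
    "nucleosome_free_regions",
    "CircuitEdge",
    "enumerate_edges",
    "regulatory_connectivity",
    "DegreeRecord",
    "brd4_degree",
    "rank_delta_out",
    "compare_connectivity",
]

PROXIMAL_HALF_WIDTH = 50_000
PROMOTER_HALF_WIDTH = 1_000
PPI_MIN_SCORE = 0.400


class MclConvergenceError(RuntimeError):
    """Markov clustering failed to converge within the iteration budget."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(f"MCL did not converge in {max_iter} iterations "
                         f"(residual {residual:.3g})")
        self.residual = residual


# ---------------------------------------------------------------------------
# TF prioritization (active + motif + enhancer-regulated + PPI evidence)
# ---------------------------------------------------------------------------

def _tss_by_gene(transcripts: Sequence[Transcript]) -> Dict[str, List[Transcript]]:
    out: Dict[str, List[Transcript]] = {}
    for t in transcripts:
        out.setdefault(t.gene_name, []).append(t)
    return out


def _has_distal_element(txs: Sequence[Transcript], landscape: RegionSet,
                        assembly: Optional[GenomeAssembly],
                        half_width: int = PROXIMAL_HALF_WIDTH,
                        promoter_half_width: int = PROMOTER_HALF_WIDTH) -> bool:
    for t in txs:
        window = window_around(t.tss, half_width, t.chrom, assembly)
        promoter = window_around(t.tss, promoter_half_width, t.chrom, assembly)
        for iv in landscape.overlapping(window):
            if not (iv.start < promoter.end and promoter.start < iv.end):
                return True
    return False


def prioritize_tfs(active_transcripts: Sequence[Transcript],
                   all_transcripts: Sequence[Transcript],
                   tf_catalog: Sequence[str],
                   motif_names: Set[str],
                   landscape: RegionSet,
                   ppi_edges: pd.DataFrame,
                   assembly: Optional[GenomeAssembly] = None,
                   min_ppi_score: float = PPI_MIN_SCORE) -> pd.DataFrame:
    """Filter candidate CRC TFs.

    A TF (gene name in ``tf_catalog``) is retained if it is actively
    expressed, has a known binding motif, is regulated by a distal
    (non-promoter-overlapping) landscape element within +/-50 kb of a TSS,
    and has at least one PPI edge above ``min_ppi_score`` to another
    catalog TF. Returns one row per catalog TF with the individual filter
    flags and a ``retained`` column.
    """
    active_genes = {t.gene_name for t in active_transcripts}
    by_gene = _tss_by_gene(all_transcripts)
    catalog = sorted(set(tf_catalog))
    edges = ppi_edges[ppi_edges["combined_score"] > min_ppi_score]
    ppi_partners: Dict[str, Set[str]] = {tf: set() for tf in catalog}
    cat = set(catalog)
    for r in edges.itertuples(index=False):
        a, b = r.protein1, r.protein2
        if a in cat and b in cat and a != b:
            ppi_partners[a].add(b)
            ppi_partners[b].add(a)
    rows = []
    for tf in catalog:
        txs = by_gene.get(tf, [])
        active = tf in active_genes
        has_motif = tf in motif_names
        enhancer = bool(txs) and _has_distal_element(txs, landscape, assembly)
        has_ppi = len(ppi_partners[tf]) > 0
        rows.append({"tf": tf, "active": active, "has_motif": has_motif,
                     "enhancer_regulated": enhancer, "has_ppi": has_ppi,
                     "retained": active and has_motif and enhancer and has_ppi})
    df = pd.DataFrame(rows).set_index("tf")
    dropped = df.index[~df["has_motif"]].tolist()
    if dropped:
        logger.info("TFs without a motif in the database: %s", ", ".join(dropped))
    return df


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def mcl_cluster(graph: nx.Graph, inflation: float = 2.0, expansion: int = 2,
                tol: float = 1e-6, max_iter: int = 200,
                prune: float = 1e-12) -> Dict[str, int]:
    """Markov clustering of an undirected weighted graph.

    Alternates expansion (matrix power) and inflation (entrywise power plus
    column renormalization) of the column-stochastic adjacency matrix with
    self-loops until the matrix is stable, then reads clusters off the
    attractor structure. Deterministic: nodes are processed in sorted order
    and cluster ids are assigned by the smallest member name.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    np.fill_diagonal(m, np.maximum(m.diagonal(), 1.0))  # self-loops
    m = m / m.sum(axis=0, keepdims=True)
    residual = np.inf
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        residual = float(np.abs(m - prev).max())
        if residual < tol:
            break
    else:
        raise MclConvergenceError(residual, max_iter)
    # attractor interpretation: connected components of the support
    support = (m > 1e-5) | (m.T > 1e-5)
    np.fill_diagonal(support, True)
    comp_graph = nx.from_numpy_array(support.astype(int))
    clusters: Dict[str, int] = {}
    comps = sorted((sorted(c) for c in nx.connected_components(comp_graph)),
                   key=lambda c: nodes[c[0]])
    for cid, comp in enumerate(comps):
        for i in comp:
            clusters[nodes[i]] = cid
    return clusters


# ---------------------------------------------------------------------------
# Circuit edges and connectivity
# ---------------------------------------------------------------------------

def nucleosome_free_regions(atac: RegionSet, landscape: RegionSet) -> RegionSet:
    """ATAC peaks overlapping an active landscape region."""
    return atac.filter(lambda iv: landscape.overlaps_any(iv))


@dataclass(frozen=True)
class CircuitEdge:
    """A predicted TF -> region regulatory interaction.

    One edge per (TF, landscape region): the TF has at least one q-passing
    motif hit inside a nucleosome-free (ATAC) peak lying in the region.
    """

    tf: str
    region_index: int
    region: GenomicInterval
    via: GenomicInterval
    brd4_auc: Mapping[str, float] = field(default_factory=dict)


def enumerate_edges(tf: str, hits: Sequence[MotifHit], landscape: RegionSet,
                    nfr: RegionSet,
                    brd4_by_condition: Optional[Mapping[str, Sequence[FragmentTrack]]] = None,
                    ) -> List[CircuitEdge]:
    """Edges of ``tf``: landscape regions bound via a hit inside an ATAC peak.

    When ``brd4_by_condition`` is given, each edge carries the
    replicate-averaged BRD4 AUC of its landscape region per condition.
    """
    seen: Dict[int, Tuple[GenomicInterval, GenomicInterval]] = {}
    for h in hits:
        for peak in nfr.overlapping(h.region):
            if not peak.contains(h.region):
                continue
            for ridx in landscape.overlapping_indices(peak):
                if ridx not in seen:
                    seen[ridx] = (landscape[ridx], peak)
    edges = []
    for ridx in sorted(seen):
        region, peak = seen[ridx]
        auc: Dict[str, float] = {}
        if brd4_by_condition is not None:
            for cond, tracks in brd4_by_condition.items():
                auc[cond] = float(np.mean([region_auc(t, region).auc_rpm
                                           for t in tracks]))
        edges.append(CircuitEdge(tf, ridx, region, peak, auc))
    return edges


def regulatory_connectivity(tf_transcripts: Mapping[str, Sequence[Transcript]],
                            hits_by_tf: Mapping[str, Sequence[MotifHit]],
                            landscape: RegionSet, nfr: RegionSet,
                            assembly: Optional[GenomeAssembly] = None,
                            half_width: int = PROXIMAL_HALF_WIDTH) -> pd.DataFrame:
    """Per-TF inward/outward regulatory connectivity.

    ``out_count(t)`` is the number of unique panel TFs u (including t
    itself) with a t-motif hit inside a nucleosome-free peak within u's
    proximal elements (landscape regions within +/-50 kb of a TSS of u);
    ``in_count`` is the transpose. The two columns therefore have equal
    sums and each is bounded by the panel size.
    """
    tfs = sorted(tf_transcripts)
    bound_regions: Dict[str, Set[int]] = {}
    for tf in tfs:
        edges = enumerate_edges(tf, hits_by_tf.get(tf, ()), landscape, nfr)
        bound_regions[tf] = {e.region_index for e in edges}
    proximal: Dict[str, Set[int]] = {}
    for tf in tfs:
        regions: Set[int] = set()
        for t in tf_transcripts[tf]:
            window = window_around(t.tss, half_width, t.chrom, assembly)
            regions.update(landscape.overlapping_indices(window))
        proximal[tf] = regions
    out_count = {tf: 0 for tf in tfs}
    in_count = {tf: 0 for tf in tfs}
    for t in tfs:
        for u in tfs:
            if bound_regions[t] & proximal[u]:
                out_count[t] += 1
                in_count[u] += 1
    return pd.DataFrame({"in_count": [in_count[tf] for tf in tfs],
                         "out_count": [out_count[tf] for tf in tfs]},
                        index=pd.Index(tfs, name="tf"))


# ---------------------------------------------------------------------------
# BRD4 degrees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DegreeRecord:
    """BRD4 IN/OUT degree of one TF with the edge-level fold-change summary."""

    tf: str
    in_degree_rpm: Mapping[str, float]
    out_degree_rpm: Mapping[str, float]
    mean_edge_log2fc: float
    ratio_of_sums_log2fc: float
    ci_low: float
    ci_high: float
    n_edges: int

    @property
    def has_edges(self) -> bool:
        return self.n_edges > 0


def brd4_degree(tf: str, edges: Sequence[CircuitEdge],
                cond_a: str, cond_b: str,
                proximal_auc: Optional[Mapping[str, float]] = None,
                pseudo: float = 1.0, n_boot: int = 1000,
                seed: int = 0) -> DegreeRecord:
    """BRD4 OUT degree (sum over edges) and the edge-level log2 fold change.

    ``mean_edge_log2fc`` is the mean over edges of
    ``log2((auc_a + pseudo) / (auc_b + pseudo))`` with a bootstrap CI
    (resampling edges with replacement, ``n_boot`` draws, seeded).
    ``proximal_auc`` supplies the IN degree per condition.
    """
    conds = (cond_a, cond_b)
    if not edges:
        return DegreeRecord(tf, dict(proximal_auc or {}),
                            {c: 0.0 for c in conds}, float("nan"), float("nan"),
                            float("nan"), float("nan"), 0)
    a = np.array([e.brd4_auc[cond_a] for e in edges], dtype=float)
    b = np.array([e.brd4_auc[cond_b] for e in edges], dtype=float)
    per_edge = np.log2((a + pseudo) / (b + pseudo))
    mean_fc = float(per_edge.mean())
    ratio_fc = float(np.log2((a.sum() + pseudo) / (b.sum() + pseudo)))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, per_edge.size, size=(n_boot, per_edge.size))
    boot = per_edge[idx].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return DegreeRecord(
        tf,
        dict(proximal_auc or {}),
        {cond_a: float(a.sum()), cond_b: float(b.sum())},
        mean_fc, ratio_fc,
        float(min(lo, mean_fc)), float(max(hi, mean_fc)),
        int(per_edge.size),
    )


def rank_delta_out(records: Sequence[DegreeRecord]) -> List[DegreeRecord]:
    """Rank TFs by mean edge-level BRD4 OUT-degree log2 fold change.

    Descending; ties broken by edge count then name. TFs without edges are
    excluded (their fold change is undefined) and logged.
    """
    with_edges = [r for r in records if r.has_edges]
    skipped = [r.tf for r in records if not r.has_edges]
    if skipped:
        logger.warning("rank_delta_out: excluded TFs with no edges: %s",
                       ", ".join(skipped))
    return sorted(with_edges,
                  key=lambda r: (-r.mean_edge_log2fc, -r.n_edges, r.tf))


def brd4_degrees_for_panel(pwms, atac: RegionSet, landscape: RegionSet,
                           assembly: GenomeAssembly,
                           brd4_by_condition: Mapping[str, Sequence[FragmentTrack]],
                           cond_a: str, cond_b: str,
                           q_max: float = 1e-5, pseudo: float = 1.0,
                           n_boot: int = 1000, seed: int = 0
                           ) -> List[DegreeRecord]:
    """Scan the TF panel and compute every TF's BRD4 OUT-degree record.

    Convenience wrapper chaining motif scanning over the nucleosome-free
    regions, edge enumeration, and :func:`brd4_degree` per TF.
    """
    from .motifs import scan_regions

    nfr = nucleosome_free_regions(atac, landscape)
    hits = scan_regions(pwms, nfr, assembly, q_max=q_max)
    records = []
    for m in pwms:
        edges = enumerate_edges(m.name, hits.get(m.name, ()), landscape, nfr,
                                brd4_by_condition)
        records.append(brd4_degree(m.name, edges, cond_a, cond_b,
                                   pseudo=pseudo, n_boot=n_boot, seed=seed))
    return records


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def compare_connectivity(group_a: Sequence[float], group_b: Sequence[float],
                         alternative: str = "greater",
                         exact_max_n: int = 16) -> Tuple[float, float]:
    """One-sided Wilcoxon rank-sum test between two groups of counts.

    ``alternative`` refers to group_a relative to group_b ("greater" or
    "less"). Midranks handle ties; the null is enumerated exactly over all
    C(n+m, n) group assignments when ``n + m <= exact_max_n``, otherwise
    the tie-corrected normal approximation (scipy) is used. Returns
    ``(W, p)`` with W the rank sum of group_a.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    w_obs = float(ranks[:a.size].sum())
    n, m = a.size, b.size
    if n + m <= exact_max_n:
        count = 0
        total = 0
        for comb in itertools.combinations(range(n + m), n):
            w = ranks[list(comb)].sum()
            total += 1
            if alternative == "greater":
                count += w >= w_obs - 1e-9
            else:
                count += w <= w_obs + 1e-9
        return w_obs, count / total
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return w_obs, float(res.pvalue)
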