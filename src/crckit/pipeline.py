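"""Configuration-driven orchestration of the analysis stages.

Stages consume a dataset directory (as emitted by the synthetic generator
or assembled from real processed data with the same file names) and write
their outputs plus a provenance manifest (parameter hash, input/output
checksums) into the output directory. Reruns with the same config and
inputs are byte-identical.

Stage order: landscape -> circuitry -> targets; screen is independent.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .circuitry import (
    brd4_degree,
    enumerate_edges,
    mcl_cluster,
    nucleosome_free_regions,
    prioritize_tfs,
    rank_delta_out,
    regulatory_connectivity,
)
from .intervals import GenomeAssembly, RegionSet, Transcript, merge_union
from .motifs import MotifModel, scan_regions
from .screen import ScreenTable, gene_stats_table
from .signal import (
    FragmentTrack,
    binned_profile,
    call_active_genes,
    gene_signal_table,
    rank_genes_by_delta,
)
from .targets import (
    gene_proximal_signal,
    high_confidence_peaks,
    preranked_enrichment,
    split_by_atac,
    target_expression_contrast,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ValidationError", "DependencyError", "run"]

CONDITIONS = ("hscp", "lscp")
STAGES = ("landscape", "circuitry", "targets", "screen")


class ValidationError(ValueError):
    """The run configuration is invalid."""


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream output."""


@dataclass
class RunConfig:
    """Flat parameter block for a pipeline run."""

    indir: str
    outdir: str
    seed: int = 0
    pseudo: float = 1.0
    fpkm_min: float = 10.0
    q_max: float = 1e-5
    inflation: float = 2.0
    n_boot: int = 1000
    bin_size: int = 100
    promoter_half_width: int = 1000
    proximal_half_width: int = 50_000
    min_ppi_score: float = 0.400
    top_n_targets: int = 100
    n_perm: int = 1000
    gene_set_file: Optional[str] = None

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        flat = {}
        for key, val in data.items():
            if isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        flat.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**flat)
        except TypeError as exc:
            raise ValidationError(str(exc)) from None

    def validate(self) -> None:
        if not Path(self.indir).is_dir():
            raise ValidationError(f"input directory not found: {self.indir}")
        for name in ("genes.tsv", "chrom.sizes"):
            if not (Path(self.indir) / name).exists():
                raise ValidationError(f"missing required input: {name}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _fmt(x: float) -> float:
    """Round floats to 6 significant digits for reproducible diffs."""
    return float(f"{x:.6g}")


class _Dataset:
    """Lazy readers over the dataset directory."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.indir = Path(cfg.indir)
        self.read_files: List[str] = []
        sizes = cio.read_chrom_sizes(self._p("chrom.sizes"))
        self.assembly = GenomeAssembly(sizes)
        self._seq_loaded = False

    def _p(self, name: str) -> Path:
        path = self.indir / name
        if path.exists() and str(path) not in self.read_files:
            self.read_files.append(str(path))
        return path

    def with_sequence(self) -> GenomeAssembly:
        if not self._seq_loaded:
            fa = self._p("genome.fa")
            if not fa.exists():
                raise ValidationError("genome.fa required for motif scanning")
            self.assembly = cio.read_fasta(fa)
            self._seq_loaded = True
        return self.assembly

    def transcripts(self) -> List[Transcript]:
        return cio.read_transcripts_tsv(self._p("genes.tsv"), self.assembly)

    def h3k27ac_sets(self) -> Dict[str, RegionSet]:
        out = {}
        for path in sorted(self.indir.glob("h3k27ac_*.narrowPeak")):
            sample = path.stem.replace("h3k27ac_", "")
            out[sample] = cio.read_narrowpeak(self._p(path.name), self.assembly)
        if not out:
            raise ValidationError("no h3k27ac_*.narrowPeak files found")
        return out

    def atac(self) -> RegionSet:
        return cio.read_narrowpeak(self._p("atac.narrowPeak"), self.assembly)

    def expression(self) -> pd.DataFrame:
        return cio.read_table(self._p("expression.tsv"), index_col="transcript_id")

    def tracks(self, mark: str, cond: str) -> List[FragmentTrack]:
        paths = sorted(self.indir.glob(f"reads_{mark}_{cond}_*.bed"))
        out = []
        for path in paths:
            placements, total = cio.read_fragments_bed(self._p(path.name),
                                                       assembly=self.assembly)
            out.append(FragmentTrack(placements, total, assembly=self.assembly,
                                     name=path.stem))
        if not out:
            raise ValidationError(f"no read tracks for {mark}/{cond}")
        return out

    def pwms(self) -> List[MotifModel]:
        entries = cio.read_meme(self._p("pwms.meme"))
        return [MotifModel(name, probs, bg) for name, probs, bg in entries]

    def ppi(self) -> pd.DataFrame:
        return cio.read_ppi_tsv(self._p("ppi.tsv"))

    def tfchip_sets(self, cls: str) -> List[RegionSet]:
        paths = sorted(self.indir.glob(f"tfchip_{cls}_rep*.narrowPeak"))
        return [cio.read_narrowpeak(self._p(p.name), self.assembly) for p in paths]

    def screen(self) -> ScreenTable:
        return ScreenTable.from_tsv(self._p("screen_counts.tsv"), "reference")


def _expression_fc(expr: pd.DataFrame, pseudo: float) -> pd.Series:
    """Gene-level log2(hscp/lscp) fold change from replicate FPKM columns."""
    num = expr.drop(columns=[c for c in ("gene_name",) if c in expr.columns])
    means = {}
    for cond in CONDITIONS:
        cols = [c for c in num.columns if c.startswith(cond)]
        means[cond] = num[cols].astype(float).mean(axis=1)
    fc = np.log2((means["hscp"] + pseudo) / (means["lscp"] + pseudo))
    if "gene_name" in expr.columns:
        fc = fc.groupby(expr["gene_name"]).max()
    return fc


def _stage_landscape(ds: _Dataset, cfg: RunConfig, outdir: Path) -> Dict[str, object]:
    transcripts = ds.transcripts()
    peak_sets = ds.h3k27ac_sets()
    landscape = merge_union(list(peak_sets.values()), ds.assembly)
    expr = ds.expression()
    num = expr.drop(columns=[c for c in ("gene_name",) if c in expr.columns])
    active = call_active_genes(transcripts, list(peak_sets.values()), num,
                               fpkm_min=cfg.fpkm_min,
                               promoter_half_width=cfg.promoter_half_width,
                               assembly=ds.assembly)
    brd4 = {c: ds.tracks("brd4", c) for c in CONDITIONS}
    h3 = {c: ds.tracks("h3k27ac", c) for c in CONDITIONS}
    table = gene_signal_table(active, landscape, brd4,
                              half_width=cfg.proximal_half_width,
                              assembly=ds.assembly)
    ranked = rank_genes_by_delta(table, "hscp", "lscp", pseudo=cfg.pseudo,
                                 column="log2fc_brd4")
    h3_table = gene_signal_table(active, landscape, h3,
                                 half_width=cfg.proximal_half_width,
                                 assembly=ds.assembly)
    h3_fc = dict(zip(h3_table["transcript_id"],
                     np.log2((h3_table["hscp"] + cfg.pseudo)
                             / (h3_table["lscp"] + cfg.pseudo))))
    ranked["log2fc_h3k27ac"] = ranked["transcript_id"].map(h3_fc)
    mrna = {}
    for cond in CONDITIONS:
        cols = [c for c in num.columns if c.startswith(cond)]
        mrna[cond] = num[cols].astype(float).mean(axis=1)
    mrna_fc = np.log2((mrna["hscp"] + cfg.pseudo) / (mrna["lscp"] + cfg.pseudo))
    ranked["log2fc_mrna"] = ranked["transcript_id"].map(mrna_fc.to_dict())
    for col in ("hscp", "lscp", "log2fc_brd4", "log2fc_h3k27ac", "log2fc_mrna"):
        ranked[col] = ranked[col].map(_fmt)
    cio.write_bed(landscape, outdir / "landscape.bed")
    pd.DataFrame({"transcript_id": [t.transcript_id for t in active],
                  "gene_name": [t.gene_name for t in active]}).to_csv(
        outdir / "active_transcripts.tsv", sep="\t", index=False)
    ranked.to_csv(outdir / "gene_signal.tsv", sep="\t", index=False)
    for col, fname in (("log2fc_h3k27ac", "binned_h3k27ac.tsv"),
                       ("log2fc_mrna", "binned_mrna.tsv")):
        prof = binned_profile(ranked[col].to_numpy(float), cfg.bin_size,
                              cfg.n_boot, seed=cfg.seed)
        pd.DataFrame([{"bin": p.bin_index, "mean": _fmt(p.mean),
                       "ci_low": _fmt(p.ci_low), "ci_high": _fmt(p.ci_high),
                       "n": p.n} for p in prof]).to_csv(
            outdir / fname, sep="\t", index=False)
    return {"n_landscape_regions": len(landscape),
            "n_active_transcripts": len(active)}


def _stage_circuitry(ds: _Dataset, cfg: RunConfig, outdir: Path) -> Dict[str, object]:
    active_path = outdir / "active_transcripts.tsv"
    if not active_path.exists():
        raise DependencyError("circuitry requires the landscape stage outputs")
    active_ids = set(pd.read_csv(active_path, sep="\t")["transcript_id"])
    transcripts = ds.transcripts()
    active = [t for t in transcripts if t.transcript_id in active_ids]
    landscape = merge_union(list(ds.h3k27ac_sets().values()), ds.assembly)
    atac = ds.atac()
    assembly = ds.with_sequence()
    pwms = ds.pwms()
    ppi = ds.ppi()
    nfr = nucleosome_free_regions(atac, landscape)
    hits = scan_regions(pwms, nfr, assembly, q_max=cfg.q_max)
    filters = prioritize_tfs(active, transcripts, [m.name for m in pwms],
                             {m.name for m in pwms}, landscape, ppi,
                             assembly=assembly, min_ppi_score=cfg.min_ppi_score)
    retained = sorted(filters.index[filters["retained"]])
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(retained)
    for r in ppi.itertuples(index=False):
        if (r.combined_score > cfg.min_ppi_score
                and r.protein1 in retained and r.protein2 in retained):
            g.add_edge(r.protein1, r.protein2, weight=r.combined_score)
    clusters = mcl_cluster(g, inflation=cfg.inflation)
    tf_tx = {tf: [t for t in transcripts if t.gene_name == tf] for tf in retained}
    conn = regulatory_connectivity(tf_tx, hits, landscape, nfr, assembly,
                                   half_width=cfg.proximal_half_width)
    brd4 = {c: ds.tracks("brd4", c) for c in CONDITIONS}
    records = []
    edge_rows = []
    for tf in retained:
        edges = enumerate_edges(tf, hits.get(tf, ()), landscape, nfr, brd4)
        from .intervals import window_around
        from .signal import region_auc

        prox_auc = {}
        prox_idx = set()
        for t in tf_tx[tf]:
            win = window_around(t.tss, cfg.proximal_half_width, t.chrom, assembly)
            prox_idx.update(landscape.overlapping_indices(win))
        for cond, tracks in brd4.items():
            prox_auc[cond] = float(sum(
                np.mean([region_auc(tr, landscape[i]).auc_rpm for tr in tracks])
                for i in prox_idx))
        rec = brd4_degree(tf, edges, "hscp", "lscp", prox_auc,
                          pseudo=cfg.pseudo, n_boot=cfg.n_boot, seed=cfg.seed)
        records.append(rec)
        for e in edges:
            edge_rows.append({"tf": tf, "chrom": e.region.chrom,
                              "start": e.region.start, "end": e.region.end,
                              "atac_start": e.via.start, "atac_end": e.via.end,
                              **{f"brd4_{c}": _fmt(v) for c, v in e.brd4_auc.items()}})
    ranked = rank_delta_out(records)
    filters.to_csv(outdir / "tf_filters.tsv", sep="\t")
    pd.Series(clusters, name="cluster").rename_axis("tf").to_csv(
        outdir / "clusters.tsv", sep="\t")
    conn.to_csv(outdir / "connectivity.tsv", sep="\t")
    pd.DataFrame(edge_rows).to_csv(outdir / "edges.tsv", sep="\t", index=False)
    deg = pd.DataFrame([{
        "tf": r.tf, "n_edges": r.n_edges,
        "out_hscp": _fmt(r.out_degree_rpm.get("hscp", 0.0)),
        "out_lscp": _fmt(r.out_degree_rpm.get("lscp", 0.0)),
        "in_hscp": _fmt(r.in_degree_rpm.get("hscp", 0.0)),
        "in_lscp": _fmt(r.in_degree_rpm.get("lscp", 0.0)),
        "mean_edge_log2fc": _fmt(r.mean_edge_log2fc),
        "ratio_of_sums_log2fc": _fmt(r.ratio_of_sums_log2fc),
        "ci_low": _fmt(r.ci_low), "ci_high": _fmt(r.ci_high),
    } for r in ranked])
    deg.to_csv(outdir / "degrees.tsv", sep="\t", index=False)
    top_abs = max(ranked, key=lambda r: abs(r.mean_edge_log2fc)) if ranked else None
    return {"n_retained_tfs": len(retained),
            "n_clusters": len(set(clusters.values())),
            "top_tf_by_abs_delta_out": top_abs.tf if top_abs else None}


def _pool_tracks(tracks: Sequence[FragmentTrack]) -> FragmentTrack:
    by_chrom: Dict[str, List[Tuple[np.ndarray, np.ndarray]]] = {}
    total = 0
    for tr in tracks:
        total += tr.total_mapped
        for chrom, (pos, minus) in tr._raw.items():
            by_chrom.setdefault(chrom, []).append((pos, minus))
    merged = {chrom: (np.concatenate([p for p, _ in items]),
                      np.concatenate([m for _, m in items]))
              for chrom, items in by_chrom.items()}
    return FragmentTrack.from_arrays(merged, total, tracks[0].extension,
                                     name="pooled")


def _stage_targets(ds: _Dataset, cfg: RunConfig, outdir: Path) -> Dict[str, object]:
    active_path = outdir / "active_transcripts.tsv"
    if not active_path.exists():
        raise DependencyError("targets requires the landscape stage outputs")
    engineered = ds.tfchip_sets("engineered")
    parental = ds.tfchip_sets("parental")
    if len(engineered) < 2:
        raise ValidationError("need >= 2 engineered TF-ChIP replicates")
    peaks = high_confidence_peaks(engineered, parental)
    with_atac, without_atac = split_by_atac(peaks, [ds.atac()])
    chip = _pool_tracks(ds.tracks("tfchip", "engineered"))
    try:
        input_track = _pool_tracks(ds.tracks("input", "lscp"))
    except ValidationError:
        input_track = None
    transcripts = ds.transcripts()
    active_ids = set(pd.read_csv(active_path, sep="\t")["transcript_id"])
    active = [t for t in transcripts if t.transcript_id in active_ids]
    scores = gene_proximal_signal(with_atac, chip, input_track, active,
                                  assembly=ds.assembly,
                                  promoter_half_width=cfg.promoter_half_width,
                                  distal_half_width=cfg.proximal_half_width)
    cio.write_bed(peaks, outdir / "high_confidence_peaks.bed")
    pd.DataFrame([{"gene_name": s.gene_name, "rank": s.rank,
                   "promoter_auc": _fmt(s.promoter_auc),
                   "distal_auc": _fmt(s.distal_auc),
                   "total_auc": _fmt(s.total)} for s in scores]).to_csv(
        outdir / "gene_targets.tsv", sep="\t", index=False)
    summary: Dict[str, object] = {
        "n_high_confidence_peaks": len(peaks),
        "n_peaks_with_atac": len(with_atac),
        "n_peaks_without_atac": len(without_atac),
        "n_target_genes": len(scores),
    }
    if cfg.gene_set_file:
        gene_set = [line.strip() for line in
                    Path(cfg.gene_set_file).read_text().splitlines()
                    if line.strip()]
        enr = preranked_enrichment([s.gene_name for s in scores], gene_set,
                                   n_perm=cfg.n_perm, seed=cfg.seed)
        (outdir / "enrichment.json").write_text(json.dumps({
            "es": _fmt(enr.es), "p_perm": _fmt(enr.p_perm),
            "n_perm": enr.n_perm, "leading_edge": list(enr.leading_edge)},
            indent=1))
        summary["enrichment_es"] = _fmt(enr.es)
    top = [s.gene_name for s in scores[:cfg.top_n_targets]]
    bound = {s.gene_name for s in scores}
    others = sorted({t.gene_name for t in active} - bound)
    fc = _expression_fc(ds.expression(), cfg.pseudo).to_dict()
    contrast = target_expression_contrast(top, others, fc)
    (outdir / "targets_contrast.json").write_text(
        json.dumps(contrast, indent=1, default=_fmt))
    summary["contrast_t"] = _fmt(contrast["t"])
    return summary


def _stage_screen(ds: _Dataset, cfg: RunConfig, outdir: Path) -> Dict[str, object]:
    table = ds.screen()
    stats = gene_stats_table(table, pseudo=cfg.pseudo)
    stats.round(6).to_csv(outdir / "screen_stats.tsv", sep="\t")
    return {"n_screen_genes": int(stats.shape[0]),
            "timepoints": list(table.timepoints)}


_STAGE_FNS = {
    "landscape": _stage_landscape,
    "circuitry": _stage_circuitry,
    "targets": _stage_targets,
    "screen": _stage_screen,
}


def run(cfg: RunConfig, stages: Optional[Sequence[str]] = None) -> Dict[str, object]:
    """Execute the requested stages in dependency order; write a manifest."""
    cfg.validate()
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = _Dataset(cfg)
    summaries: Dict[str, object] = {}
    for stage in ordered:
        logger.info("running stage %s", stage)
        summaries[stage] = _STAGE_FNS[stage](ds, cfg, outdir)
    manifest = {
        "config": dataclasses.asdict(cfg),
        "stages": ordered,
        "summaries": summaries,
        "inputs": {os.path.basename(p): _sha256(Path(p)) for p in ds.read_files},
        "outputs": {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
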