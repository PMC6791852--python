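"""Readers and writers for the external formats the pipeline touches.

Tabular formats go through pandas; FASTA reading goes through pyfaidx;
MEME-minimal motif files are parsed with Bio.motifs. GTF/refFlat 1-based
starts are converted to the internal 0-based half-open convention here.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .intervals import (
    GenomeAssembly,
    GenomicInterval,
    RegionSet,
    Transcript,
)

__all__ = [
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_fasta",
    "write_fasta",
    "read_transcripts_tsv",
    "write_transcripts_tsv",
    "read_gtf_transcripts",
    "read_table",
    "read_meme",
    "write_meme",
    "read_fragments_bed",
    "write_fragments_bed",
    "read_ppi_tsv",
    "write_ppi_tsv",
]

_BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def _norm(chrom: str, assembly: Optional[GenomeAssembly]) -> str:
    return assembly.normalize_chrom(chrom) if assembly is not None else chrom


def read_bed(path, assembly: Optional[GenomeAssembly] = None,
             merged: bool = False) -> RegionSet:
    """Read BED3/BED6 into a :class:`RegionSet`."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    ivs = []
    for row in df.itertuples(index=False):
        row = tuple(row)
        chrom = _norm(row[0], assembly)
        name = row[3] if len(row) > 3 and not pd.isna(row[3]) else None
        score = float(row[4]) if len(row) > 4 and not pd.isna(row[4]) else None
        strand = row[5] if len(row) > 5 and row[5] in ("+", "-") else "."
        ivs.append(GenomicInterval(chrom, int(row[1]), int(row[2]),
                                   strand=strand, name=name, score=score))
    rs = RegionSet(ivs, merged=merged)
    if assembly is not None:
        rs.check_bounds(assembly)
    return rs


def write_bed(regions: RegionSet | Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in regions:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields += [iv.name or ".",
                           "0" if iv.score is None else f"{iv.score:g}",
                           iv.strand]
            fh.write("\t".join(fields) + "\n")


def read_narrowpeak(path, assembly: Optional[GenomeAssembly] = None) -> RegionSet:
    """Read ENCODE narrowPeak (10-column). The summit column is ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    ivs = []
    for row in df.itertuples(index=False):
        row = tuple(row)
        chrom = _norm(row[0], assembly)
        strand = row[5] if len(row) > 5 and row[5] in ("+", "-") else "."
        score = float(row[6]) if len(row) > 6 and not pd.isna(row[6]) else None
        ivs.append(GenomicInterval(chrom, int(row[1]), int(row[2]),
                                   strand=strand,
                                   name=None if pd.isna(row[3]) else row[3],
                                   score=score))
    rs = RegionSet(ivs)
    if assembly is not None:
        rs.check_bounds(assembly)
    return rs


def write_narrowpeak(regions: RegionSet | Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(regions):
            fh.write("\t".join([
                iv.chrom, str(iv.start), str(iv.end),
                iv.name or f"peak_{i + 1}", "0", iv.strand,
                "0" if iv.score is None else f"{iv.score:g}",
                "-1", "-1", "-1",
            ]) + "\n")


def read_chrom_sizes(path) -> Dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype=str)
    return {r.chrom: int(r.size) for r in df.itertuples(index=False)}


def write_chrom_sizes(sizes: Dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_fasta(path) -> GenomeAssembly:
    """Load an (uncompressed) FASTA into memory as a GenomeAssembly."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return GenomeAssembly.from_sequences(seqs)


def write_fasta(assembly: GenomeAssembly, path, width: int = 80) -> None:
    if assembly.sequence is None:
        raise ValueError("assembly has no sequence to write")
    with open(path, "w") as fh:
        for chrom, seq in assembly.sequence.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


_TX_COLS = ["transcript_id", "gene_name", "chrom", "strand", "tx_start", "tx_end"]


def read_transcripts_tsv(path, assembly: Optional[GenomeAssembly] = None,
                         one_based: bool = False) -> List[Transcript]:
    """Read a refFlat-style transcript table.

    Expects a header with at least the columns ``transcript_id, gene_name,
    chrom, strand, tx_start, tx_end``. Set ``one_based=True`` for tables
    exported with 1-based starts (converted with start - 1 on read).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TX_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"transcript table missing columns: {missing}")
    off = 1 if one_based else 0
    out = []
    for r in df.itertuples(index=False):
        chrom = _norm(r.chrom, assembly)
        span = GenomicInterval(chrom, int(r.tx_start) - off, int(r.tx_end),
                               strand=r.strand)
        out.append(Transcript(r.transcript_id, r.gene_name, span))
    return out


def write_transcripts_tsv(transcripts: Sequence[Transcript], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TX_COLS) + "\n")
        for t in transcripts:
            fh.write("\t".join([t.transcript_id, t.gene_name, t.chrom, t.strand,
                                str(t.span.start), str(t.span.end)]) + "\n")


def read_gtf_transcripts(path, assembly: Optional[GenomeAssembly] = None) -> List[Transcript]:
    """Extract transcript models from a minimal GTF (exon structure ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "transcript":
                continue
            attrs = {}
            for item in f[8].strip().rstrip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attrs[key] = val.strip().strip('"')
            chrom = _norm(f[0], assembly)
            span = GenomicInterval(chrom, int(f[3]) - 1, int(f[4]), strand=f[6])
            out.append(Transcript(attrs.get("transcript_id", f"{chrom}:{f[3]}"),
                                  attrs.get("gene_name", attrs.get("gene_id", "NA")),
                                  span))
    return out


def read_table(path, index_col: Optional[str] = None) -> pd.DataFrame:
    """Plain TSV with header (expression / count tables)."""
    df = pd.read_csv(path, sep="\t")
    if index_col is not None:
        df = df.set_index(index_col)
    return df


def read_meme(path) -> List[Tuple[str, np.ndarray, np.ndarray]]:
    """Parse a MEME minimal motif file.

    Returns ``(name, probs, background)`` per motif, with ``probs`` as a
    ``(4, w)`` array in ACGT order and ``background`` as 4 probabilities.
    """
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        probs = np.array([m.pwm[b] for b in "ACGT"], dtype=float)
        bg = np.array([m.background[b] for b in "ACGT"], dtype=float)
        out.append((m.name, probs, bg))
    return out


def write_meme(entries: Sequence[Tuple[str, np.ndarray]], path,
               background: Optional[np.ndarray] = None) -> None:
    """Write motifs in MEME minimal format (probs are (4, w), ACGT order)."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {0:.5f} C {1:.5f} G {2:.5f} T {3:.5f}\n\n".format(*bg))
        for name, probs in entries:
            probs = np.asarray(probs, float)
            w = probs.shape[1]
            fh.write(f"MOTIF {name}\n")
            # large nsites so count-based parsers do not quantize the probs
            fh.write(f"letter-probability matrix: alength= 4 w= {w} "
                     "nsites= 1000000 E= 0\n")
            for j in range(w):
                fh.write(" ".join(f"{probs[i, j]:.6f}" for i in range(4)) + "\n")
            fh.write("\n")


def read_fragments_bed(path, totals_path=None,
                       assembly: Optional[GenomeAssembly] = None):
    """Read a BED6 of read 5'-end placements plus a sidecar total count.

    Returns ``(placements, total_mapped)`` where placements is a list of
    ``(chrom, pos, strand)``. The sidecar (``<path>.totals`` by default)
    holds the total mapped-read count as a single integer; without it the
    number of placements is used.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    placements = []
    for row in df.itertuples(index=False):
        row = tuple(row)
        chrom = _norm(row[0], assembly)
        strand = row[5] if len(row) > 5 and row[5] in ("+", "-") else "."
        placements.append((chrom, int(row[1]), strand))
    if totals_path is None:
        totals_path = Path(str(path) + ".totals")
    total = len(placements)
    if Path(totals_path).exists():
        total = int(Path(totals_path).read_text().split()[0])
    return placements, total


def write_fragments_bed(placements, path, total_mapped: Optional[int] = None) -> None:
    with open(path, "w") as fh:
        for i, (chrom, pos, strand) in enumerate(placements):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\tread_{i}\t0\t{strand}\n")
    if total_mapped is not None:
        Path(str(path) + ".totals").write_text(f"{total_mapped}\n")


def read_fragments_bam(path, assembly: Optional[GenomeAssembly] = None):
    """Optional BAM/SAM adapter: aligned reads -> 5' placements.

    Returns ``(placements, total_mapped)`` in the same shape as
    :func:`read_fragments_bed`. Requires pysam (the ``bam`` extra).
    """
    import pysam

    placements = []
    total = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            total += 1
            chrom = read.reference_name
            if assembly is not None:
                chrom = assembly.normalize_chrom(chrom)
            if read.is_reverse:
                placements.append((chrom, read.reference_end - 1, "-"))
            else:
                placements.append((chrom, read.reference_start, "+"))
    return placements, total


def read_ppi_tsv(path) -> pd.DataFrame:
    """STRING-export-like edge list.

    Columns ``protein1, protein2, combined_score[, evidence]``; scores on the
    0-1000 STRING export scale are divided by 1000.
    """
    df = pd.read_csv(path, sep="\t")
    need = {"protein1", "protein2", "combined_score"}
    if not need <= set(df.columns):
        raise ValueError(f"PPI table needs columns {sorted(need)}")
    score = df["combined_score"].astype(float)
    if score.max() > 1.0:
        score = score / 1000.0
    out = df.copy()
    out["combined_score"] = score
    if "evidence" not in out.columns:
        out["evidence"] = "experimental"
    return out


def write_ppi_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)
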