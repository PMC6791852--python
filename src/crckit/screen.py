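"""Pooled CRISPR screen gene-level statistics.

Counts are depth-normalized to counts-per-million, reagent (sgRNA) log2
fold changes are taken against the reference/input library, standardized
to z-scores across the whole library, summarized per gene as quartiles
(Q1/Q3), and aggregated with the RSA (redundant siRNA activity) rank-based
hypergeometric statistic in both directions (Down for dropout, Up for
enrichment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenTable",
    "normalize_and_fc",
    "reagent_zscores",
    "gene_quartiles",
    "rsa",
    "rsa_empirical_pvalues",
    "gene_stats_table",
]


@dataclass
class ScreenTable:
    """sgRNA count matrix with the sgRNA -> gene map and sample roles.

    ``counts`` is indexed by sgRNA id with one column per sample;
    ``reference`` names the input-library column and ``timepoints`` the
    ordered later samples.
    """

    counts: pd.DataFrame
    sgrna_to_gene: Mapping[str, str]
    reference: str
    timepoints: Sequence[str]

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.index if s not in self.sgrna_to_gene]
        if missing:
            raise ValueError(f"sgRNAs without a gene mapping: {missing[:5]} ...")
        if self.reference not in self.counts.columns:
            raise ValueError(f"reference sample {self.reference!r} not in counts")
        if (self.counts[self.reference].sum()) <= 0:
            raise ValueError("reference column total must be positive")

    @property
    def genes(self) -> pd.Series:
        return pd.Series([self.sgrna_to_gene[s] for s in self.counts.index],
                         index=self.counts.index, name="gene")

    @classmethod
    def from_tsv(cls, path, reference: str,
                 timepoints: Optional[Sequence[str]] = None) -> "ScreenTable":
        """Read a counts TSV with columns ``sgrna, gene, <sample>...``."""
        df = pd.read_csv(path, sep="\t")
        mapping = dict(zip(df["sgrna"], df["gene"]))
        counts = df.drop(columns=["gene"]).set_index("sgrna")
        if timepoints is None:
            timepoints = [c for c in counts.columns if c != reference]
        return cls(counts, mapping, reference, list(timepoints))


def normalize_and_fc(table: ScreenTable, sample: str,
                     pseudo: float = 1.0) -> pd.Series:
    """Per-sgRNA log2 fold change of ``sample`` vs the reference library.

    Both columns are scaled to counts-per-million first:
    ``log2((cpm_sample + pseudo) / (cpm_ref + pseudo))``.
    """
    if sample == table.reference:
        raise ValueError("sample must differ from the reference")
    counts = table.counts
    for col in (sample, table.reference):
        if counts[col].sum() <= 0:
            raise ValueError(f"column {col!r} has zero total count")
    cpm_s = counts[sample] * 1e6 / counts[sample].sum()
    cpm_r = counts[table.reference] * 1e6 / counts[table.reference].sum()
    return np.log2((cpm_s + pseudo) / (cpm_r + pseudo)).rename(f"log2fc_{sample}")


def reagent_zscores(log2fc: pd.Series) -> pd.Series:
    """Standardize reagent fold changes over the whole library.

    ``z = (x - mean) / sd`` with the population standard deviation taken
    over ALL reagents; zero variance is an error.
    """
    x = log2fc.astype(float)
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise ValueError("need >= 2 finite reagent values")
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance across reagents; z-scores undefined")
    return ((x - x.mean()) / sd).rename(str(x.name).replace("log2fc", "z")
                                        if x.name else "z")


def gene_quartiles(z: pd.Series, sgrna_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Per-gene 25th/75th percentiles of reagent z-scores (linear interpolation)."""
    genes = pd.Series([sgrna_to_gene[s] for s in z.index], index=z.index)
    rows = {}
    for gene, vals in z.groupby(genes):
        q1, q3 = np.percentile(vals.to_numpy(float), [25, 75])
        rows[gene] = (float(q1), float(q3), int(vals.size))
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["q1_z", "q3_z", "n_reagents"])
    df.index.name = "gene"
    return df.sort_index()


def _direction_ranks(log2fc: pd.Series, direction: str) -> np.ndarray:
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    x = log2fc.to_numpy(float)
    x = x if direction == "down" else -x
    return stats.rankdata(x, method="average")  # rank 1 = most extreme


def rsa(log2fc: pd.Series, sgrna_to_gene: Mapping[str, str],
        direction: str = "down") -> pd.Series:
    """RSA log10 p per gene: min-over-j rank-based hypergeometric tail.

    Reagents are ranked over the whole library in the direction of interest
    (ascending fold change for "down", descending for "up"; ties get
    midranks). For a gene with reagents at ranks ``r_1 < ... < r_k`` out of
    N, the statistic is ``log10(min_j P[X >= j])`` with
    ``X ~ Hypergeometric(N, k, r_j)`` — the chance that j or more of the
    gene's k reagents land in the top r_j by luck. Note the minimum over j
    is not corrected for multiplicity, so it is an aggressive score for
    ranking rather than a calibrated p-value; use
    :func:`rsa_empirical_pvalues` for a calibrated version.
    """
    ranks = _direction_ranks(log2fc, direction)
    genes = np.array([sgrna_to_gene[s] for s in log2fc.index])
    n_total = ranks.size
    out = {}
    for gene in np.unique(genes):
        r = np.sort(ranks[genes == gene])
        k = r.size
        draws = np.rint(r).astype(int)
        tails = stats.hypergeom.sf(np.arange(1, k + 1) - 1, n_total, k, draws)
        out[gene] = float(np.log10(max(tails.min(), 1e-300)))
    s = pd.Series(out, name=f"rsa_{direction}_logp")
    s.index.name = "gene"
    return s.sort_index()


def rsa_empirical_pvalues(log2fc: pd.Series, sgrna_to_gene: Mapping[str, str],
                          direction: str = "down", n_perm: int = 2000,
                          seed: int = 0) -> pd.Series:
    """Permutation-calibrated RSA p-values.

    The sgRNA -> gene labels are shuffled ``n_perm`` times; each gene's
    empirical p is the fraction of permuted RSA statistics (for the same
    reagent-set size) at least as extreme as the observed one, with the +1
    correction. Under a null screen these are uniform by construction.
    """
    rng = np.random.default_rng(seed)
    observed = rsa(log2fc, sgrna_to_gene, direction)
    genes = pd.Series({s: sgrna_to_gene[s] for s in log2fc.index})
    sizes = genes.groupby(genes).size()
    ranks = _direction_ranks(log2fc, direction)
    n_total = ranks.size
    # permutation null of the RSA statistic, per reagent-set size
    null_by_k: Dict[int, np.ndarray] = {}
    for k in sorted(sizes.unique()):
        vals = np.empty(n_perm)
        for i in range(n_perm):
            r = np.sort(rng.choice(n_total, size=k, replace=False) + 1)
            tails = stats.hypergeom.sf(np.arange(1, k + 1) - 1, n_total, k, r)
            vals[i] = np.log10(max(tails.min(), 1e-300))
        null_by_k[k] = np.sort(vals)
    out = {}
    for gene, logp in observed.items():
        null = null_by_k[int(sizes[gene])]
        count = int(np.searchsorted(null, logp, side="right"))
        out[gene] = (1 + count) / (n_perm + 1)
    s = pd.Series(out, name=f"rsa_{direction}_emp_p")
    s.index.name = "gene"
    return s.sort_index()


def gene_stats_table(table: ScreenTable, pseudo: float = 1.0) -> pd.DataFrame:
    """Per-gene screen summary across all timepoints.

    For every timepoint sample: reagent log2 fold changes vs the reference,
    z-scores, gene Q1/Q3, and RSA Down/Up log10 p. Columns are suffixed
    with the sample name.
    """
    pieces = []
    for sample in table.timepoints:
        fc = normalize_and_fc(table, sample, pseudo=pseudo)
        z = reagent_zscores(fc)
        q = gene_quartiles(z, table.sgrna_to_gene)
        down = rsa(fc, table.sgrna_to_gene, "down")
        up = rsa(fc, table.sgrna_to_gene, "up")
        df = q.join(down).join(up)
        df.columns = [f"{c}_{sample}" if c != "n_reagents" else c
                      for c in df.columns]
        pieces.append(df)
    out = pieces[0]
    for df in pieces[1:]:
        out = out.join(df.drop(columns="n_reagents"))
    return out
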