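"""Cross-dataset concordance, ECDF comparison and composition clustering.

Spearman rank correlations (average ranks on ties) compare CSC tables from
different half-life datasets or against external per-codon metrics such as
tAI; two-sample Kolmogorov-Smirnov tests compare ECDFs of gene scores
(e.g. original vs shuffled CSCg, stress-induced vs background genes); and
agglomerative clustering on Euclidean distances groups genes by their
(optimal, neutral, non-optimal) codon-class composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .csc import CSCTable, CSCgTable
from .codons import SENSE_CODONS


@dataclass
class ConcordanceMatrix:
    """Pairwise Spearman rho / p / support between per-codon score tables."""

    labels: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.rho.to_csv(path, sep="\t", float_format="%.6g")

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.labels:
            for b in self.labels:
                rows.append(
                    {"a": a, "b": b, "rho": self.rho.loc[a, b],
                     "p": self.p.loc[a, b], "n": self.n.loc[a, b]}
                )
        return pd.DataFrame(rows)


@dataclass
class EcdfComparison:
    """Two-sample KS comparison with the step curves for plotting."""

    statistic: float
    pvalue: float
    curve_a: pd.DataFrame  # columns x, ecdf
    curve_b: pd.DataFrame


@dataclass
class ClusterResult:
    """Hierarchical clustering of genes on codon-class composition triples."""

    labels: dict[str, int]
    distance_matrix: pd.DataFrame
    linkage_matrix: np.ndarray

    def summary(self, reads: Mapping[str, float] | None = None) -> pd.DataFrame:
        """Per-cluster gene counts/shares and, if given, read shares."""
        genes = list(self.labels)
        lab = pd.Series(self.labels)
        rows = []
        total_reads = sum(reads.get(g, 0.0) for g in genes) if reads else None
        for k in sorted(set(lab)):
            members = [g for g in genes if self.labels[g] == k]
            row = {"cluster": k, "n_genes": len(members),
                   "gene_share": len(members) / len(genes)}
            if reads is not None:
                r = sum(reads.get(g, 0.0) for g in members)
                row["read_share"] = r / total_reads if total_reads else np.nan
            rows.append(row)
        return pd.DataFrame(rows)


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def csc_concordance(tables: Sequence[CSCTable]) -> ConcordanceMatrix:
    """Pairwise Spearman rho over the 61 per-codon CSC values.

    Undefined (NaN) entries trigger pairwise deletion; the support ``n``
    matrix reports how many codons entered each comparison.
    """
    if len(tables) < 2:
        raise ValueError("need at least two CSC tables")
    labels = [t.dataset_label or f"table{i}" for i, t in enumerate(tables)]
    mat = np.array([[t.values.get(c, np.nan) for c in SENSE_CODONS] for t in tables])
    k = len(tables)
    rho = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), mat.shape[1])
    for i in range(k):
        n[i, i] = int(np.isfinite(mat[i]).sum())
        for j in range(i + 1, k):
            mask = np.isfinite(mat[i]) & np.isfinite(mat[j])
            n[i, j] = n[j, i] = int(mask.sum())
            if mask.sum() < 3:
                rho[i, j] = rho[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            r, pv = _spearman(mat[i, mask], mat[j, mask])
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
    return ConcordanceMatrix(
        labels,
        pd.DataFrame(rho, index=labels, columns=labels),
        pd.DataFrame(p, index=labels, columns=labels),
        pd.DataFrame(n, index=labels, columns=labels),
    )


def metric_correlation(
    csc: CSCTable, external: Mapping[str, float]
) -> tuple[float, float, int]:
    """Spearman rho between CSC and an external per-codon metric.

    Computed over the codon intersection with pairwise deletion of
    undefined values; for inverse-residence-time style comparisons the
    caller supplies the already-inverted metric.  Returns (rho, p, n);
    rho is NaN when either side is constant.
    """
    shared = [
        c for c in SENSE_CODONS
        if c in external and c in csc.values
        and np.isfinite(csc.values[c]) and np.isfinite(external[c])
    ]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared codons; need >= 3")
    x = np.array([csc.values[c] for c in shared])
    y = np.array([external[c] for c in shared])
    r, pv = _spearman(x, y)
    return r, pv, len(shared)


def _ecdf_curve(sample: np.ndarray) -> pd.DataFrame:
    xs = np.sort(sample)
    return pd.DataFrame({"x": xs, "ecdf": np.arange(1, len(xs) + 1) / len(xs)})


def ecdf_compare(
    sample_a: Sequence[float], sample_b: Sequence[float], exact_max_n: int = 25
) -> EcdfComparison:
    """Two-sample KS statistic D = sup |ECDF_a - ECDF_b| with p-value.

    The asymptotic two-sample p-value is used, switching to the exact
    distribution when both samples have at most ``exact_max_n`` points.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if max(a.size, b.size) <= exact_max_n else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return EcdfComparison(float(res.statistic), float(res.pvalue), _ecdf_curve(a), _ecdf_curve(b))


def cluster_compositions(
    compositions: Mapping[str, tuple[float, float, float]],
    k: int = 3,
    method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of genes on their 3-proportion vectors.

    Euclidean distances, ``method`` linkage (average by default), cut at
    ``k`` clusters.  Genes are sorted by id before linkage so the result is
    deterministic regardless of input order.
    """
    genes = sorted(compositions)
    if len(genes) < k:
        raise ValueError(f"cannot form {k} clusters from {len(genes)} genes")
    x = np.array([compositions[g] for g in genes], dtype=float)
    condensed = pdist(x, metric="euclidean")
    z = linkage(condensed, method=method)
    labels = fcluster(z, t=k, criterion="maxclust")
    dist = pd.DataFrame(squareform(condensed), index=genes, columns=genes)
    return ClusterResult(dict(zip(genes, map(int, labels))), dist, z)


def stress_subset_cscg_shift(
    cscg: CSCgTable, induced_ids: Sequence[str], background_ids: Sequence[str] | None = None
) -> EcdfComparison:
    """Compare the CSCg ECDF of an induced gene set against a background.

    The induced set (e.g. genes induced >= 1.5-fold under a stress; the
    fold filter is applied by the caller) is deduplicated and intersected
    with the CSCg table; the background defaults to all scored genes.
    """
    induced = sorted({g for g in induced_ids if g in cscg.values})
    if not induced:
        raise ValueError("no induced ids present in the CSCg table")
    if background_ids is None:
        background = sorted(cscg.values)
    else:
        background = sorted({g for g in background_ids if g in cscg.values})
        if not background:
            raise ValueError("no background ids present in the CSCg table")
    return ecdf_compare([cscg[g] for g in induced], [cscg[g] for g in background])


def kruskal_wallis(*samples: Sequence[float]) -> tuple[float, float]:
    """Pass-through Kruskal-Wallis H test over two or more samples."""
    res = stats.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


def normality_test(sample: Sequence[float]) -> tuple[float, float]:
    """Pass-through D'Agostino-Pearson omnibus normality test."""
    res = stats.normaltest(np.asarray(sample, dtype=float))
    return float(res.statistic), float(res.pvalue)
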