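"""Positional CSC profiles and window-normalized ribosome metagenes.

Two families of positional summaries:

* **codon-level**: the mean CSC at each of the first / last K codon
  positions across genes (is optimality structured along the ORF?), and a
  ranking of genes by the mean CSC of their first ``n_first`` codons into
  deciles plus extreme alpha/beta groups.

* **nucleotide-level**: per-gene footprint coverage is normalized by the
  summed reads in a fixed window (so long genes are comparable with short
  ones), anchored at a common position (the ATG or a stretch start), and
  averaged per offset across genes; two metagene groups are compared per
  offset with Welch t-tests under Holm-Sidak family-wise adjustment.

The metagene span ``(-L, +L)`` covers offsets ``-L .. L-1``: L nucleotides
before the anchor and L from the anchor on, the anchor itself at offset 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .csc import CSCTable
from .sequence_io import CoverageTrack, GeneSequence


@dataclass
class PositionalCSCProfile:
    """Mean CSC by codon position from the start (head) and end (tail)."""

    head_means: np.ndarray
    tail_means: np.ndarray
    head_n: np.ndarray
    tail_n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        k = np.arange(1, len(self.head_means) + 1)
        return pd.DataFrame(
            {
                "position": k,
                "head_mean": self.head_means,
                "head_n": self.head_n,
                "tail_mean": self.tail_means,
                "tail_n": self.tail_n,
            }
        )


@dataclass
class MetageneProfile:
    """Anchored average of window-normalized coverage.

    ``offsets`` are contiguous nucleotide offsets relative to the anchor
    (anchor = 0); ``adjusted_p`` is filled by :func:`compare_metagenes`.
    """

    offsets: np.ndarray
    mean_normalized: np.ndarray
    n_genes: int
    adjusted_p: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"offset": self.offsets, "mean": self.mean_normalized, "n": self.n_genes}
        )
        if self.adjusted_p is not None:
            df["adjusted_p"] = self.adjusted_p
        return df


def positional_csc_profile(
    genes: Iterable[GeneSequence],
    csc: CSCTable,
    K: int = 20,
    include_start: bool = True,
) -> PositionalCSCProfile:
    """Average CSC at head positions 1..K and the last K positions.

    Genes contribute wherever the position is defined (a gene of length
    ``l`` contributes to head position k iff l >= k, analogously for the
    tail), so ``head_n`` is non-increasing.  ``include_start=False`` drops
    the invariant ATG at position 1 from the head averages.
    """
    head_sum = np.zeros(K)
    head_n = np.zeros(K, dtype=int)
    tail_sum = np.zeros(K)
    tail_n = np.zeros(K, dtype=int)
    n_genes = 0
    for gene in genes:
        n_genes += 1
        vals = np.array([csc[c] for c in gene.sense_codons])
        kh = min(K, len(vals))
        start = 1 if not include_start else 0
        head_sum[start:kh] += vals[start:kh]
        head_n[start:kh] += 1
        kt = min(K, len(vals))
        tail_sum[:kt] += vals[::-1][:kt]
        tail_n[:kt] += 1
    if n_genes == 0:
        raise ValueError("empty gene set")
    with np.errstate(invalid="ignore"):
        head = np.where(head_n > 0, head_sum / np.maximum(head_n, 1), np.nan)
        tail = np.where(tail_n > 0, tail_sum / np.maximum(tail_n, 1), np.nan)
    return PositionalCSCProfile(head, tail, head_n, tail_n)


def group_by_initial_csc(
    genes: Iterable[GeneSequence],
    csc: CSCTable,
    n_first: int = 10,
    n_groups: int = 10,
    alpha_size: int = 50,
) -> pd.DataFrame:
    """Rank genes by mean CSC of their first ``n_first`` codons.

    Returns a frame sorted ascending by that mean (ties broken by gene_id)
    with columns ``gene_id``, ``initial_mean_csc``, ``rank`` (1 = lowest),
    ``group`` (1..n_groups, near-equal sizes, remainder spread over the
    last groups), ``alpha`` (ranks 1..alpha_size) and ``beta`` (the next
    alpha_size ranks).  Genes shorter than ``n_first`` sense codons are
    excluded.
    """
    rows = []
    for gene in genes:
        sense = gene.sense_codons
        if len(sense) < n_first:
            continue
        rows.append((gene.gene_id, float(np.mean([csc[c] for c in sense[:n_first]]))))
    if len(rows) < 2 * alpha_size:
        raise ValueError(f"need >= {2 * alpha_size} rankable genes, got {len(rows)}")
    df = pd.DataFrame(rows, columns=["gene_id", "initial_mean_csc"])
    df = df.sort_values(["initial_mean_csc", "gene_id"], kind="mergesort").reset_index(drop=True)
    n = len(df)
    df["rank"] = np.arange(1, n + 1)
    base, extra = divmod(n, n_groups)
    sizes = [base + (1 if g >= n_groups - extra else 0) for g in range(n_groups)]
    df["group"] = np.repeat(np.arange(1, n_groups + 1), sizes)
    df["alpha"] = df["rank"] <= alpha_size
    df["beta"] = (df["rank"] > alpha_size) & (df["rank"] <= 2 * alpha_size)
    return df


class ZeroWindowError(ValueError):
    """The normalization window contains no reads."""


def normalize_track(track: CoverageTrack, window: tuple[int, int]) -> CoverageTrack:
    """Divide every position by the summed reads in ``window`` (1-based, closed).

    The normalized values sum to 1 over the window; a zero window sum
    raises :class:`ZeroWindowError` so callers can exclude (and count) the
    gene instead of propagating NaN.
    """
    start, end = window
    if start < 1 or end > len(track) or start > end:
        raise ValueError(
            f"window {window} outside track {track.gene_id!r} of length {len(track)}"
        )
    total = float(track.counts[start - 1 : end].sum())
    if total == 0:
        raise ZeroWindowError(f"zero reads in window {window} of {track.gene_id!r}")
    return CoverageTrack(track.gene_id, track.counts / total)


def metagene_matrix(
    tracks: Mapping[str, CoverageTrack],
    anchors: Mapping[str, int],
    span: int = 500,
    normalize_window: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene normalized coverage re-aligned at each gene's anchor.

    ``anchors`` maps gene_id to a 1-based anchor nucleotide; offsets run
    from -span to span-1.  By default each gene is normalized over its own
    anchored span; ``normalize_window`` (1-based, closed, in CDS
    coordinates) overrides this, e.g. ``(1, 500)`` for ATG-anchored
    profiles.  Genes whose track does not cover the full span, have no
    anchor/track, or have zero reads in the normalization window are
    excluded; exclusion counts are returned alongside the matrix.
    """
    offsets = np.arange(-span, span)
    rows: dict[str, np.ndarray] = {}
    excluded = {"no_track": 0, "truncated_span": 0, "zero_window": 0}
    for gid in sorted(anchors):
        anchor = anchors[gid]
        track = tracks.get(gid)
        if track is None:
            excluded["no_track"] += 1
            continue
        lo, hi = anchor - span, anchor + span - 1
        if lo < 1 or hi > len(track):
            excluded["truncated_span"] += 1
            continue
        window = normalize_window if normalize_window is not None else (lo, hi)
        try:
            norm = normalize_track(track, window)
        except ZeroWindowError:
            excluded["zero_window"] += 1
            continue
        rows[gid] = norm.counts[lo - 1 : hi]
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=offsets)
    return matrix, excluded


def metagene(
    tracks: Mapping[str, CoverageTrack],
    anchors: Mapping[str, int],
    span: int = 500,
    normalize_window: tuple[int, int] | None = None,
) -> MetageneProfile:
    """Mean window-normalized coverage per offset across contributing genes."""
    matrix, _ = metagene_matrix(tracks, anchors, span, normalize_window)
    if matrix.empty:
        raise ValueError("no genes contribute to the metagene (all excluded)")
    return MetageneProfile(
        offsets=matrix.columns.to_numpy(dtype=int),
        mean_normalized=matrix.to_numpy().mean(axis=0),
        n_genes=len(matrix),
    )


def holm_sidak(pvalues: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjustment of a family of p-values.

    Sorted ascending, adjusted p_(i) = max_{k<=i} [1 - (1 - p_(k))^(m-k+1)]
    (1-based k), clipped to 1; returned in the original order.  Adjusted
    values are monotone along the sorted order and never below the raw p.
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def compare_metagenes(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame) -> pd.DataFrame:
    """Per-offset Welch t-test between two metagene groups, Holm-Sidak adjusted.

    Input matrices come from :func:`metagene_matrix` (genes x offsets, same
    offsets).  Offsets where both groups are degenerate (zero variance and
    equal means make the statistic undefined) get p = 1 and are flagged.
    Returns a frame with offset, group means, t, raw and adjusted p, flag.
    """
    if not np.array_equal(matrix_a.columns, matrix_b.columns):
        raise ValueError("metagene matrices must share the same offsets")
    if len(matrix_a) < 2 or len(matrix_b) < 2:
        raise ValueError("need >= 2 genes per group at every offset")
    a = matrix_a.to_numpy()
    b = matrix_b.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)
    t = np.where(np.isfinite(t), t, 0.0)
    return pd.DataFrame(
        {
            "offset": matrix_a.columns.to_numpy(dtype=int),
            "mean_a": a.mean(axis=0),
            "mean_b": b.mean(axis=0),
            "t": t,
            "p_raw": p,
            "p_adjusted": holm_sidak(p),
            "degenerate": degenerate,
        }
    )
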