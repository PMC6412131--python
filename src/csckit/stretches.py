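"""Locating stretches of extreme codon optimality along ORFs.

A *stretch* is a run of ``w`` consecutive codons (default 10) whose summed
CSC crosses a threshold: <= ``lo`` (default -1.28) for a non-optimal
stretch, >= ``hi`` (default +1.28) for an optimal one.  The +-1.28 default
is the summed-CSC level previously associated with mRNA destabilization.
Window sums are computed over sense codons only, codon 1 being the ATG;
overlapping or abutting qualifying windows of the same polarity are merged
into a single stretch anchored at the leftmost qualifying start (a
``merge=False`` mode reports every raw qualifying window instead).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .csc import CSCTable
from .sequence_io import GeneSequence, HalfLifeTable


@dataclass(frozen=True)
class StretchHit:
    """One located extreme-CSC codon stretch.

    ``start_codon`` is 1-based (codon 1 = ATG) and ``relative_position`` is
    ``start_codon / l_i`` with ``l_i`` the gene length in sense codons.
    """

    gene_id: str
    start_codon: int
    end_codon: int          # last codon of the merged run's final window
    window_codons: int
    sum_csc: float
    polarity: str           # "non_optimal" | "optimal"
    relative_position: float

    @property
    def anchor_nt(self) -> int:
        """First nucleotide of the stretch, 1-based (for metagene anchoring)."""
        return 3 * (self.start_codon - 1) + 1


def window_sums(gene: GeneSequence, csc: CSCTable, w: int = 10) -> np.ndarray:
    """Summed CSC of every w-codon window; entry k covers codons k+1..k+w.

    Returns an empty vector when the gene has fewer than ``w`` sense
    codons.  Uses a prefix-sum rolling evaluation; the terminal stop is
    never scored.
    """
    if w < 1:
        raise ValueError("window must be >= 1 codon")
    sense = gene.sense_codons
    if len(sense) < w:
        return np.empty(0)
    vals = np.fromiter((csc[c] for c in sense), dtype=float, count=len(sense))
    if not np.all(np.isfinite(vals)):
        bad = sorted({c for c in sense if not np.isfinite(csc[c])})
        raise ValueError(f"gene {gene.gene_id!r} uses codons with undefined CSC: {bad}")
    prefix = np.concatenate(([0.0], np.cumsum(vals)))
    return prefix[w:] - prefix[:-w]


def _merge_runs(starts: np.ndarray, w: int) -> list[tuple[int, int, list[int]]]:
    """Group qualifying window starts whose spans overlap or abut."""
    runs: list[list[int]] = [[int(starts[0])]]
    for s in starts[1:]:
        # previous window covers [prev, prev+w-1]; abutting means s <= prev+w
        if s <= runs[-1][-1] + w:
            runs[-1].append(int(s))
        else:
            runs.append([int(s)])
    return [(r[0], r[-1] + w - 1, r) for r in runs]


def find_stretches(
    genes: Iterable[GeneSequence],
    csc: CSCTable,
    w: int = 10,
    lo: float = -1.28,
    hi: float = 1.28,
    merge: bool = True,
) -> list[StretchHit]:
    """Scan every gene for windows with summed CSC <= lo or >= hi.

    With ``merge=True`` (default) overlapping/abutting qualifying windows of
    one polarity collapse into a single hit anchored at the leftmost
    qualifying start, carrying the most extreme window sum of the run.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got lo={lo}, hi={hi}")
    hits: list[StretchHit] = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        sums = window_sums(gene, csc, w)
        if sums.size == 0:
            continue
        li = gene.n_sense
        for polarity, mask, pick in (
            ("non_optimal", sums <= lo, np.min),
            ("optimal", sums >= hi, np.max),
        ):
            starts = np.nonzero(mask)[0] + 1  # 1-based codon index
            if starts.size == 0:
                continue
            if merge:
                for first, last_end, members in _merge_runs(starts, w):
                    extreme = float(pick(sums[np.asarray(members) - 1]))
                    hits.append(
                        StretchHit(gene.gene_id, first, last_end, w, extreme, polarity, first / li)
                    )
            else:
                for s in starts:
                    hits.append(
                        StretchHit(
                            gene.gene_id, int(s), int(s) + w - 1, w,
                            float(sums[s - 1]), polarity, float(s) / li,
                        )
                    )
    return hits


def stretch_counts(hits: Iterable[StretchHit]) -> pd.DataFrame:
    """Genome-wide stretch and gene counts per polarity."""
    rows = []
    by_pol: dict[str, list[StretchHit]] = {}
    for h in hits:
        by_pol.setdefault(h.polarity, []).append(h)
    for pol in ("non_optimal", "optimal"):
        sub = by_pol.get(pol, [])
        rows.append({"polarity": pol, "n_stretches": len(sub), "n_genes": len({h.gene_id for h in sub})})
    return pd.DataFrame(rows)


def filter_for_metagene(
    hits: Sequence[StretchHit],
    half_lives: HalfLifeTable | None = None,
    max_start_codon: int = 200,
    single_stretch_only: bool = True,
) -> tuple[list[StretchHit], dict[str, int]]:
    """Reduce hits to the set usable for anchored metagene averaging.

    Filtering order (each step's removal count reported): genes with more
    than one stretch of the polarity are dropped, then stretches starting at
    or beyond ``max_start_codon``, then genes without a measured half-life.
    """
    removed = {"multi_stretch": 0, "position": 0, "no_half_life": 0}
    kept = list(hits)
    if single_stretch_only:
        tally = Counter((h.gene_id, h.polarity) for h in kept)
        before = len(kept)
        kept = [h for h in kept if tally[(h.gene_id, h.polarity)] == 1]
        removed["multi_stretch"] = before - len(kept)
    before = len(kept)
    kept = [h for h in kept if h.start_codon < max_start_codon]
    removed["position"] = before - len(kept)
    if half_lives is not None:
        before = len(kept)
        kept = [h for h in kept if h.gene_id in half_lives]
        removed["no_half_life"] = before - len(kept)
    return kept, removed


def stretch_position_histogram(
    hits: Sequence[StretchHit], mode: str = "relative", bins: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency of stretch start positions, absolute (codons) or relative.

    Returns ``(frequencies, bin_edges)``; frequencies sum to 1.
    """
    if not hits:
        raise ValueError("no hits to histogram")
    if mode == "relative":
        values = [h.relative_position for h in hits]
        counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    elif mode == "absolute":
        values = [h.start_codon for h in hits]
        counts, edges = np.histogram(values, bins=bins)
    else:
        raise ValueError(f"mode must be 'relative' or 'absolute', got {mode!r}")
    return counts / counts.sum(), edges


def position_halflife_association(
    hits: Sequence[StretchHit], half_lives: HalfLifeTable
) -> tuple[float, float, int]:
    """Spearman rank correlation between stretch start codon and half-life.

    Average ranks are used for ties.  A constant input on either side makes
    the correlation undefined; (nan, nan, n) is returned in that case.
    """
    pairs = [(h.start_codon, half_lives[h.gene_id]) for h in hits if h.gene_id in half_lives]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 hits with half-lives, got {len(pairs)}")
    x, y = zip(*pairs)
    if len(set(x)) == 1 or len(set(y)) == 1:
        return float("nan"), float("nan"), len(pairs)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue), len(pairs)


def hits_to_frame(hits: Iterable[StretchHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "start_codon": h.start_codon,
                "end_codon": h.end_codon,
                "sum_csc": h.sum_csc,
                "polarity": h.polarity,
                "relative_position": h.relative_position,
            }
            for h in hits
        ]
    )


def write_hits_tsv(hits: Iterable[StretchHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_hits_bed(hits: Iterable[StretchHit], path: str | Path) -> None:
    """Nucleotide-interval BED (0-based half-open) on CDS coordinates."""
    lines = []
    for h in hits:
        start0 = 3 * (h.start_codon - 1)
        end0 = 3 * h.end_codon
        lines.append(f"{h.gene_id}\t{start0}\t{end0}\t{h.polarity}\t{h.sum_csc:.6g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
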