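"""Synonymous-shuffle null genomes.

A shuffled genome keeps every protein sequence and the genome-wide count of
every codon, but randomizes which synonymous codon each position uses.  It
is the null model for asking whether observed codon arrangements (and the
CSCg distribution they produce) could arise from the genomic codon bias
alone.

The shuffle is an exact permutation: all occurrences of each amino acid's
synonymous codons are pooled over the bias-source genes, each pool is
shuffled (seeded Fisher-Yates via numpy), and codons are dealt back in gene
order.  This guarantees exact conservation of the per-codon copy numbers,
which independent proportional draws would satisfy only in expectation.
Met, Trp (one-fold degenerate) and stop codons pass through unchanged.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codons import AA_OF
from .csc import CSCTable, CSCgTable, cscg_table
from .sequence_io import GeneSequence


class PoolExhaustionError(ValueError):
    """The bias source does not cover the amino-acid demand of the targets."""


def _build_pools(genes: Iterable[GeneSequence], rng: np.random.Generator) -> dict[str, list[str]]:
    pools: dict[str, list[str]] = {}
    for gene in genes:
        for codon in gene.sense_codons:
            pools.setdefault(AA_OF[codon], []).append(codon)
    for aa in sorted(pools):
        pool = pools[aa]
        pools[aa] = [pool[i] for i in rng.permutation(len(pool))]
    return pools


def shuffle_genome(
    genes: Sequence[GeneSequence],
    seed: int,
    bias_source: Sequence[GeneSequence] | None = None,
) -> list[GeneSequence]:
    """Deal synonymous codons from a pooled, shuffled bias source.

    With ``bias_source is None`` (self-sourced, the default) the genome-wide
    multiset of codons is exactly preserved.  Passing a subset — e.g. only
    the genes with CSCg below zero — shuffles ``genes`` under that subset's
    codon bias instead.  Output is a deterministic function of the inputs
    and the seed, and preserves the input record order.
    """
    if bias_source is None:
        bias_source = genes
    rng = np.random.default_rng(seed)
    pools = _build_pools(bias_source, rng)

    demand = Counter(AA_OF[c] for g in genes for c in g.sense_codons)
    for aa, needed in sorted(demand.items()):
        if len(pools.get(aa, [])) < needed:
            raise PoolExhaustionError(
                f"bias source supplies {len(pools.get(aa, []))} codons for amino acid "
                f"{aa!r} but the target genes need {needed}"
            )

    cursors = dict.fromkeys(pools, 0)
    shuffled: list[GeneSequence] = []
    for gene in genes:
        new_codons: list[str] = []
        for codon in gene.sense_codons:
            aa = AA_OF[codon]
            new_codons.append(pools[aa][cursors[aa]])
            cursors[aa] += 1
        if gene.has_terminal_stop:
            new_codons.append(gene.codons[-1])  # stops never exchange
        shuffled.append(GeneSequence(gene.gene_id, tuple(new_codons), gene.has_terminal_stop))
    return shuffled


def codon_count_vector(genes: Iterable[GeneSequence]) -> Counter:
    """Genome-wide multiset of all codons (stops included)."""
    counts: Counter = Counter()
    for gene in genes:
        counts.update(gene.codons)
    return counts


def shuffled_cscg_distribution(
    genes: Sequence[GeneSequence],
    csc: CSCTable,
    seed: int,
    bias_source: Sequence[GeneSequence] | None = None,
) -> pd.DataFrame:
    """Paired original vs shuffled CSCg, one row per gene.

    Columns ``gene_id``, ``original``, ``shuffled``; the shuffled column is
    CSCg recomputed on the shuffled genome.
    """
    original: CSCgTable = cscg_table(genes, csc)
    shuffled_genes = shuffle_genome(genes, seed, bias_source=bias_source)
    shuffled: CSCgTable = cscg_table(shuffled_genes, csc)
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "original": [original[g.gene_id] for g in genes],
            "shuffled": [shuffled[g.gene_id] for g in genes],
        }
    )
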