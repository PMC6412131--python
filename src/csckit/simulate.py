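"""Seeded synthetic data: genomes, half-lives with planted codon effects,
and footprint coverage with planted pauses.

The half-life generator is linear in codon proportions,

    half_life_i = intercept + sum_j beta_j * N_ij + eps_i,

with Gaussian noise and a small positive floor — exactly the generative
family the Pearson-based CSC statistic is matched to, so recovery of the
planted per-codon effects beta_j has a known ideal.  Coverage is Poisson
per nucleotide with an optional localized multiplicative pause, emulating
ribosome accumulation at a non-optimal stretch.

All generators are pure functions of their parameters and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .codons import SENSE_CODONS
from .sequence_io import CoverageTrack, GeneSequence, HalfLifeTable

#: floor (minutes) keeping generated half-lives strictly positive at high noise
HALF_LIFE_FLOOR = 0.1


@dataclass
class PlantedEffectSpec:
    """Parameters of the linear codon-effect half-life model.

    ``beta`` maps codons to their effect (minutes per unit proportion);
    codons absent from the mapping have zero effect.  ``noise_sd`` is the
    standard deviation of the additive Gaussian noise in minutes.
    """

    beta: Mapping[str, float]
    intercept: float = 20.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.beta) - set(SENSE_CODONS)
        if unknown:
            raise ValueError(f"beta refers to non-sense codons: {sorted(unknown)}")


def make_genome(
    n_genes: int,
    length_distribution: tuple[int, int] = (100, 600),
    codon_usage: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[GeneSequence]:
    """Generate ``n_genes`` CDS with controlled codon usage.

    Each gene starts with ATG, ends with TAA, and has a body drawn i.i.d.
    from ``codon_usage`` restricted to sense codons (uniform over the 61
    sense codons by default).  ``length_distribution`` bounds the number of
    sense codons per gene (closed interval, uniform); lengths must be >= 2.
    """
    lo, hi = length_distribution
    if lo < 2 or hi < lo:
        raise ValueError(f"invalid length distribution {length_distribution}")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if codon_usage is None:
        codons = list(SENSE_CODONS)
        weights = np.ones(len(codons))
    else:
        codons = [c for c in SENSE_CODONS if codon_usage.get(c, 0) > 0]
        if any(w < 0 for w in codon_usage.values()):
            raise ValueError("codon usage weights must be non-negative")
        if not codons:
            raise ValueError("codon usage has no positive sense-codon weight")
        weights = np.array([codon_usage[c] for c in codons], dtype=float)
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = []
    for i in range(n_genes):
        n_sense = int(rng.integers(lo, hi + 1))
        body = rng.choice(len(codons), size=n_sense - 1, p=probs)
        seq = ("ATG", *(codons[j] for j in body), "TAA")
        genes.append(GeneSequence(f"g{i + 1:0{width}d}", seq, True))
    return genes


def make_half_lives(
    genes: Sequence[GeneSequence], spec: PlantedEffectSpec, dataset_label: str = "synthetic"
) -> HalfLifeTable:
    """Half-lives linear in codon proportions plus noise, floored at 0.1 min."""
    rng = np.random.default_rng(spec.seed)
    values = {}
    for gene in genes:
        sense = gene.sense_codons
        signal = sum(spec.beta.get(c, 0.0) for c in sense) / len(sense)
        hl = spec.intercept + signal + rng.normal(0.0, spec.noise_sd)
        values[gene.gene_id] = max(hl, HALF_LIFE_FLOOR)
    return HalfLifeTable(values, dataset_label)


def planted_halflife_experiment(
    n_genes: int = 2000,
    seed: int = 0,
    noise_ratio: float = 0.5,
    length_distribution: tuple[int, int] = (100, 600),
    beta_sd: float = 10.0,
    intercept: float = 20.0,
) -> tuple[list[GeneSequence], HalfLifeTable, dict[str, float]]:
    """The package's standard parameter-recovery setup.

    Draws per-codon effects beta_j ~ Normal(0, beta_sd), builds a uniform-
    usage genome, then sets the noise standard deviation to ``noise_ratio``
    times the standard deviation of the noiseless signal across genes.
    Returns (genes, half_lives, beta).
    """
    rng = np.random.default_rng(seed)
    beta = {c: float(rng.normal(0.0, beta_sd)) for c in SENSE_CODONS}
    genes = make_genome(n_genes, length_distribution, seed=seed + 1)
    signals = []
    for gene in genes:
        sense = gene.sense_codons
        signals.append(sum(beta[c] for c in sense) / len(sense))
    noise_sd = noise_ratio * float(np.std(signals))
    spec = PlantedEffectSpec(beta, intercept=intercept, noise_sd=noise_sd, seed=seed + 2)
    return genes, make_half_lives(genes, spec), beta


def make_coverage(
    genes: Sequence[GeneSequence],
    base_rate: float = 5.0,
    pause: tuple[int, int, float] | None = None,
    seed: int = 0,
) -> dict[str, CoverageTrack]:
    """Poisson(base_rate) coverage per CDS nucleotide, optional pause.

    ``pause = (anchor_nt, width_nt, fold)`` multiplies the rate by ``fold``
    over nucleotides ``[anchor, anchor + width)`` (1-based) in every gene;
    the window must lie inside every gene.  Track length is 3x the codon
    count including a terminal stop.
    """
    if base_rate <= 0:
        raise ValueError("base_rate must be > 0")
    rng = np.random.default_rng(seed)
    tracks = {}
    for gene in genes:
        n_nt = gene.n_nt
        rate = np.full(n_nt, float(base_rate))
        if pause is not None:
            anchor, width, fold = pause
            if fold < 1:
                raise ValueError("pause fold must be >= 1")
            if anchor < 1 or anchor + width - 1 > n_nt:
                raise ValueError(
                    f"pause window [{anchor}, {anchor + width}) outside gene "
                    f"{gene.gene_id!r} of {n_nt} nt"
                )
            rate[anchor - 1 : anchor - 1 + width] *= fold
        tracks[gene.gene_id] = CoverageTrack(gene.gene_id, rng.poisson(rate).astype(float))
    return tracks
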