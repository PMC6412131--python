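"""Codon stabilization coefficients (CSC) and gene-level means (CSCg).

The CSC of codon *j* is the Pearson correlation coefficient, across genes,
between the proportion ``N_ij = C_ij / l_i`` of codon *j* in gene *i* (the
count divided by the gene length in sense codons) and the mRNA half-life of
gene *i*.  The gene-level score is the proportion-weighted mean

    CSCg_i = sum_j CSC_j * C_ij / l_i = sum_j CSC_j * N_ij,

so CSCg always lies between the smallest and largest CSC in the table.
Only the 61 amino-acid coding codons are scored: the terminal stop codon is
excluded from both the counts and the length, while the initiator ATG is an
ordinary Met codon.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .codons import SENSE_CODONS
from .sequence_io import GeneSequence, HalfLifeTable


@dataclass(frozen=True)
class CodonFrequencyVector:
    """Per-gene codon proportions over the 61 sense codons."""

    gene_id: str
    counts: Mapping[str, int]       # C_ij, sense codons only
    length_codons: int              # l_i = sum_j C_ij

    @property
    def proportions(self) -> dict[str, float]:
        """N_ij = C_ij / l_i for all 61 sense codons (absent codons -> 0)."""
        li = self.length_codons
        return {c: self.counts.get(c, 0) / li for c in SENSE_CODONS}


@dataclass
class CSCTable:
    """61 per-codon stabilization coefficients with their support size.

    A codon whose proportion has zero variance across the shared gene set
    has no defined correlation; such codons are stored as NaN and listed in
    ``undefined`` rather than silently zeroed.
    """

    values: dict[str, float]
    n_genes: int
    dataset_label: str = ""
    undefined: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("a Pearson r over fewer than 3 gene pairs is refused")
        for codon, v in self.values.items():
            if codon in self.undefined:
                continue
            if not np.isfinite(v) or abs(v) > 1 + 1e-12:
                raise ValueError(f"CSC for {codon} out of [-1, 1]: {v}")

    def __getitem__(self, codon: str) -> float:
        return self.values[codon]

    def defined_values(self) -> dict[str, float]:
        return {c: v for c, v in self.values.items() if c not in self.undefined}

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "codon": list(SENSE_CODONS),
                "csc": [self.values.get(c, np.nan) for c in SENSE_CODONS],
                "n": self.n_genes,
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, dataset_label: str = "") -> "CSCTable":
        df = pd.read_csv(path, sep="\t")
        values = dict(zip(df["codon"].astype(str), df["csc"].astype(float)))
        undefined = frozenset(c for c, v in values.items() if not np.isfinite(v))
        n = int(df["n"].iloc[0]) if "n" in df.columns else 3
        return cls(values, n, dataset_label or Path(path).stem, undefined)


@dataclass
class CSCgTable:
    """gene_id -> mean codon stabilization coefficient."""

    values: dict[str, float]
    dataset_label: str = ""

    def __getitem__(self, gene_id: str) -> float:
        return self.values[gene_id]

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"gene_id": list(self.values), "cscg": list(self.values.values())}
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, dataset_label: str = "") -> "CSCgTable":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["gene_id"].astype(str), df["cscg"].astype(float))), dataset_label)


@dataclass
class CodonClassMap:
    """Partition of the 61 sense codons into optimal / neutral / non-optimal.

    A codon is optimal iff CSC > hi and non-optimal iff CSC < lo (strict
    inequalities, so boundary values are neutral).
    """

    classes: dict[str, str]
    hi: float
    lo: float

    def __getitem__(self, codon: str) -> str:
        return self.classes[codon]


def codon_frequencies(gene: GeneSequence) -> CodonFrequencyVector:
    """Count sense codons and normalize by gene length in codons (N_ij)."""
    sense = gene.sense_codons
    if not sense:
        raise ValueError(f"gene {gene.gene_id!r} has zero sense codons")
    return CodonFrequencyVector(gene.gene_id, Counter(sense), len(sense))


def frequency_matrix(freqs: Iterable[CodonFrequencyVector]) -> pd.DataFrame:
    """Genes x 61 proportion matrix, rows indexed by gene_id."""
    rows = {f.gene_id: f.proportions for f in freqs}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(SENSE_CODONS))


def compute_csc(
    freqs: Iterable[CodonFrequencyVector],
    half_lives: HalfLifeTable,
    log_transform: bool = False,
) -> CSCTable:
    """Correlate each codon's proportion with mRNA half-life across genes.

    One global gene set — the genes present in both inputs — is used for
    all 61 correlations, so CSC values are comparable across codons.  Genes
    missing a half-life are dropped once, globally.  ``log_transform``
    correlates against log half-lives instead (off by default; the metric
    is defined on the raw minutes scale).
    """
    mat = frequency_matrix(freqs)
    shared = [g for g in mat.index if g in half_lives]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} genes shared with the half-life table; need >= 3")
    mat = mat.loc[shared]
    hl = np.array([half_lives[g] for g in shared], dtype=float)
    if log_transform:
        hl = np.log(hl)
    if np.ptp(hl) == 0:
        raise ValueError("half-lives have zero variance across the shared gene set")

    x = mat.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    yc = hl - hl.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    values: dict[str, float] = {}
    undefined: set[str] = set()
    for k, codon in enumerate(SENSE_CODONS):
        if sx[k] == 0:
            values[codon] = np.nan
            undefined.add(codon)
        else:
            values[codon] = float((xc[:, k] @ yc) / (sx[k] * sy))
    return CSCTable(values, len(shared), half_lives.dataset_label, frozenset(undefined))


def compute_cscg(freq: CodonFrequencyVector, csc: CSCTable) -> float:
    """CSCg_i = sum_j CSC_j * N_ij over the gene's sense codons."""
    total = 0.0
    for codon, count in freq.counts.items():
        if codon in csc.undefined:
            raise ValueError(
                f"gene {freq.gene_id!r} uses codon {codon} whose CSC is undefined"
            )
        total += csc[codon] * count
    return total / freq.length_codons


def cscg_table(
    genes: Iterable[GeneSequence], csc: CSCTable, dataset_label: str = ""
) -> CSCgTable:
    return CSCgTable(
        {g.gene_id: compute_cscg(codon_frequencies(g), csc) for g in genes},
        dataset_label or csc.dataset_label,
    )


def classify_codons(csc: CSCTable, hi: float = 0.1, lo: float = -0.1) -> CodonClassMap:
    """Three-way partition: optimal (CSC > hi), non-optimal (CSC < lo), else neutral."""
    if not hi > lo:
        raise ValueError(f"need hi > lo, got hi={hi}, lo={lo}")
    if csc.undefined:
        raise ValueError(f"cannot classify codons with undefined CSC: {sorted(csc.undefined)}")
    classes = {}
    for codon, v in csc.values.items():
        if v > hi:
            classes[codon] = "optimal"
        elif v < lo:
            classes[codon] = "non_optimal"
        else:
            classes[codon] = "neutral"
    return CodonClassMap(classes, hi, lo)


def gene_class_composition(
    freq: CodonFrequencyVector, classes: CodonClassMap
) -> tuple[float, float, float]:
    """Proportion of the gene's sense codons in each optimality class."""
    tallies = {"optimal": 0, "neutral": 0, "non_optimal": 0}
    for codon, count in freq.counts.items():
        tallies[classes[codon]] += count
    li = freq.length_codons
    return (tallies["optimal"] / li, tallies["neutral"] / li, tallies["non_optimal"] / li)
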