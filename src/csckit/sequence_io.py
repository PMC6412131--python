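"""Reading, validating and writing CDS collections, tables and coverage tracks.

Conventions used throughout the package:

* codon index 1 is the ATG; nucleotide position 1 is the first base of the
  ATG; all intervals are closed on both ends unless a writer says otherwise.
* the terminal stop codon is kept on the sequence (``has_terminal_stop``)
  but excluded from every scoring operation downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import STOP_CODONS, translate

_VALID_BASES = frozenset("ACGT")


class EmptyCollectionError(ValueError):
    """Raised when an input yields zero valid records."""


class SchemaError(ValueError):
    """Raised when a delimited file lacks a declared column."""


@dataclass(frozen=True)
class GeneSequence:
    """An in-frame coding sequence as an ordered codon list.

    Invariants (enforced by :func:`validate_cds`): every codon is a
    trinucleotide over {A,C,G,T}; stop codons occur only at the last
    position; at least two codons are present.
    """

    gene_id: str
    codons: tuple[str, ...]
    has_terminal_stop: bool

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """Codons scored downstream: everything except a terminal stop."""
        return self.codons[:-1] if self.has_terminal_stop else self.codons

    @property
    def n_sense(self) -> int:
        return len(self.sense_codons)

    @property
    def n_nt(self) -> int:
        return 3 * len(self.codons)

    def protein(self) -> str:
        """One-letter translation of the sense codons (no trailing ``*``)."""
        return translate(list(self.sense_codons))

    def sequence(self) -> str:
        return "".join(self.codons)


@dataclass
class RejectionReport:
    """Machine-readable record of why input records were excluded."""

    rejected: list[tuple[str, str]] = field(default_factory=list)

    def add(self, gene_id: str, reason: str) -> None:
        self.rejected.append((gene_id, reason))

    def __len__(self) -> int:
        return len(self.rejected)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rejected, columns=["gene_id", "reason"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class HalfLifeTable:
    """gene_id -> mRNA half-life in minutes; all values finite and > 0."""

    values: dict[str, float]
    dataset_label: str = ""

    def __post_init__(self) -> None:
        for gid, hl in self.values.items():
            if not np.isfinite(hl) or hl <= 0:
                raise ValueError(f"half-life for {gid!r} must be finite and > 0, got {hl}")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values

    def __getitem__(self, gene_id: str) -> float:
        return self.values[gene_id]

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        key_column: str = "gene",
        value_column: str = "half_life",
        dataset_label: str = "",
    ) -> "HalfLifeTable":
        mapping, _ = read_table(path, key_column, value_column, value_domain="positive_real")
        return cls(mapping, dataset_label or Path(path).stem)


@dataclass
class CoverageTrack:
    """Per-nucleotide ribosome footprint counts on CDS coordinates.

    ``counts[0]`` is nucleotide position 1, the first base of the ATG.
    """

    gene_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError(f"negative coverage in track {self.gene_id!r}")

    def __len__(self) -> int:
        return len(self.counts)


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T (common FASTA dialects)."""
    return seq.upper().replace("U", "T")


def validate_cds(gene_id: str, seq: str) -> tuple[GeneSequence | None, str | None]:
    """Validate one raw CDS string; return (record, None) or (None, reason)."""
    seq = normalize_sequence(seq)
    if len(seq) % 3 != 0:
        return None, "length_not_multiple_of_3"
    codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
    if len(codons) < 2:
        return None, "too_short"
    if any(set(c) - _VALID_BASES for c in codons):
        return None, "ambiguous_base"
    if any(c in STOP_CODONS for c in codons[:-1]):
        return None, "internal_stop"
    return GeneSequence(gene_id, codons, codons[-1] in STOP_CODONS), None


def read_cds_fasta(
    path: str | Path,
    exclude_ids: Iterable[str] | None = None,
) -> tuple[list[GeneSequence], RejectionReport]:
    """Read a CDS FASTA, keeping only records that pass in-frame validation.

    Records failing validation are excluded and listed in the rejection
    report with a machine-readable reason; ids in ``exclude_ids`` (e.g. a
    user-supplied list of dubious ORFs or mitochondrial genes) are excluded
    with reason ``excluded_by_list``.
    """
    exclude = set(exclude_ids or ())
    genes: list[GeneSequence] = []
    report = RejectionReport()
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        gid = record.id
        if gid in exclude:
            report.add(gid, "excluded_by_list")
            continue
        if gid in seen:
            report.add(gid, "duplicate_id")
            continue
        gene, reason = validate_cds(gid, str(record.seq))
        if gene is None:
            report.add(gid, reason or "invalid")
        else:
            genes.append(gene)
            seen.add(gid)
    if not genes:
        raise EmptyCollectionError(f"no valid CDS records in {path}")
    return genes, report


def write_cds_fasta(genes: Iterable[GeneSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.sequence()), id=g.gene_id, description="") for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")


_DOMAINS = {
    "real": lambda v: np.isfinite(v),
    "positive_real": lambda v: np.isfinite(v) and v > 0,
    "nonnegative_real": lambda v: np.isfinite(v) and v >= 0,
}


def read_table(
    path: str | Path,
    key_column: str,
    value_column: str,
    value_domain: str = "real",
) -> tuple[dict[str, float], int]:
    """Read a keyed value column from a delimited file (TSV/CSV sniffed).

    Rows whose value does not parse into ``value_domain`` are dropped and
    counted; returns ``(mapping, n_dropped)``.
    """
    if value_domain not in _DOMAINS:
        raise ValueError(f"unknown value domain {value_domain!r}")
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in (key_column, value_column) if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    ok = _DOMAINS[value_domain]
    mapping: dict[str, float] = {}
    dropped = 0
    for key, raw in zip(df[key_column], df[value_column]):
        try:
            value = float(raw)
        except (TypeError, ValueError):
            dropped += 1
            continue
        if not ok(value):
            dropped += 1
            continue
        mapping[str(key)] = value
    return mapping, dropped


def read_coverage(path: str | Path) -> dict[str, CoverageTrack]:
    """Read long-form coverage (gene_id, position, count) into tracks.

    Positions are 1-based on the CDS; unlisted positions are filled with 0
    up to the maximum listed position for that gene.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return {}
    missing = [c for c in ("gene_id", "position", "count") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if (df["position"] < 1).any():
        bad = df[df["position"] < 1].iloc[0]
        raise ValueError(
            f"coverage position must be >= 1; got {bad['position']} for {bad['gene_id']}"
        )
    dup = df.duplicated(subset=["gene_id", "position"])
    if dup.any():
        bad = df[dup].iloc[0]
        raise ValueError(
            f"duplicate coverage row for ({bad['gene_id']}, position {bad['position']})"
        )
    tracks: dict[str, CoverageTrack] = {}
    for gid, sub in df.groupby("gene_id", sort=False):
        length = int(sub["position"].max())
        counts = np.zeros(length, dtype=float)
        counts[sub["position"].to_numpy(dtype=int) - 1] = sub["count"].to_numpy(dtype=float)
        tracks[str(gid)] = CoverageTrack(str(gid), counts)
    return tracks


def write_coverage(tracks: Mapping[str, CoverageTrack], path: str | Path) -> None:
    """Write tracks back to the long-form TSV dialect (zero rows elided)."""
    buf = io.StringIO()
    buf.write("gene_id\tposition\tcount\n")
    for gid in tracks:
        counts = tracks[gid].counts
        for pos in np.nonzero(counts)[0]:
            buf.write(f"{gid}\t{pos + 1}\t{counts[pos]:g}\n")
    Path(path).write_text(buf.getvalue())
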