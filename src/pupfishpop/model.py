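"""Core data model shared by every pipeline stage.

Conventions used throughout the package:

* All internal coordinates are **0-based, half-open** ``[start, end)``.
  VCF (1-based) and GFF3 (1-based, closed) are converted at the I/O
  boundary and nowhere else.
* Diploid genotypes are small integer codes (:data:`HOM_REF`,
  :data:`HET`, :data:`HOM_ALT`, :data:`MISSING`).  Missingness is a
  first-class code: every downstream denominator counts non-missing
  calls explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Genotype codes. Polarized genotypes reuse the same integers with the
# reading HOM_ANC / HET / HOM_DER (the reference allele stands in for the
# ancestral state).
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

GT_NAMES = {HOM_REF: "HOM_REF", HET: "HET", HOM_ALT: "HOM_ALT", MISSING: "MISSING"}
POLARIZED_NAMES = {HOM_REF: "HOM_ANC", HET: "HET", HOM_ALT: "HOM_DER", MISSING: "MISSING"}

# Mutation-effect classes. LOF is strictly "stop gained": a SNP whose
# alternate codon is a stop while the reference codon is not.
SYN = "SYN"
NSYN = "NSYN"
LOF = "LOF"
NONCODING = "NONCODING"
MUTATION_CLASSES = (SYN, NSYN, LOF)


class PupfishPopError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PupfishPopError):
    pass


class ParseError(PupfishPopError):
    pass


@dataclass(frozen=True)
class GenomeDescriptor:
    """Ordered contig table: names, lengths, and the total genome size.

    The total size is the denominator of F_ROH (the fraction of the
    genome lying in runs of homozygosity above the length threshold).
    """

    contigs: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ConfigurationError("contig names must be unique")
        for name, length in self.contigs:
            if length <= 0:
                raise ConfigurationError(f"contig {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.contigs]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.contigs)

    @property
    def total_size(self) -> int:
        return sum(l for _, l in self.contigs)

    def contig_order(self) -> dict[str, int]:
        return {n: i for i, (n, _) in enumerate(self.contigs)}


@dataclass
class SampleTable:
    """Maps sample id to group label (species/population) and optional year."""

    groups: dict[str, str]
    years: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ConfigurationError("sample table is empty")

    @property
    def samples(self) -> list[str]:
        return list(self.groups)

    def members(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups.values():
            if g not in seen:
                seen.append(g)
        return seen


@dataclass
class GeneAnnotation:
    """A single gene reduced to one CDS chain (its longest transcript).

    ``cds`` holds 0-based half-open ``(start, end, phase)`` intervals in
    **transcription order**: ascending genomic coordinates on the plus
    strand, descending on the minus strand. ``usable`` is False when the
    phase-adjusted CDS length is not a multiple of 3, in which case the
    gene is excluded from effect classification.
    """

    gene_id: str
    contig: str
    strand: str
    cds: tuple[tuple[int, int, int], ...]
    usable: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ConfigurationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        ivs = sorted((s, e) for s, e, _ in self.cds)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ConfigurationError(f"gene {self.gene_id}: overlapping CDS intervals")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint (min CDS start, max CDS end)."""
        return min(s for s, _, _ in self.cds), max(e for _, e, _ in self.cds)

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds)


@dataclass
class CensusSeries:
    """Seasonal census counts: (year, season, count) records."""

    records: tuple[tuple[int, str, int], ...]

    def __post_init__(self) -> None:
        keys = [(y, s) for y, s, _ in self.records]
        if len(set(keys)) != len(keys):
            raise ConfigurationError("duplicate (year, season) census record")
        for year, season, count in self.records:
            if season not in ("spring", "autumn"):
                raise ConfigurationError(f"unknown season {season!r}")
            if count < 1:
                raise ConfigurationError(f"census count must be >= 1, got {count} ({year} {season})")

    def counts(self, season: str) -> np.ndarray:
        return np.array([c for _, s, c in self.records if s == season], dtype=float)


class GenotypeMatrix:
    """Biallelic-SNP genotype matrix: sites x samples integer codes.

    ``sites`` is a DataFrame with columns ``contig, pos, ref, alt``
    (``pos`` 0-based) and ``codes`` is an int8 array of shape
    ``(n_sites, n_samples)`` holding the genotype codes above.
    """

    def __init__(self, sites: pd.DataFrame, codes: np.ndarray, samples: Sequence[str]):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.shape != (len(sites), len(samples)):
            raise ConfigurationError(
                f"codes shape {codes.shape} does not match {len(sites)} sites x {len(samples)} samples"
            )
        self.sites = sites.reset_index(drop=True)
        self.codes = codes
        self.samples = list(samples)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise ConfigurationError(f"unknown sample {sample!r}") from None

    def column(self, sample: str) -> np.ndarray:
        return self.codes[:, self.sample_index(sample)]

    def segregating_mask(self) -> np.ndarray:
        """Sites polymorphic across all samples (both alleles observed)."""
        has_alt = ((self.codes == HET) | (self.codes == HOM_ALT)).any(axis=1)
        has_ref = ((self.codes == HET) | (self.codes == HOM_REF)).any(axis=1)
        return has_alt & has_ref

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(self.sites.loc[mask], self.codes[mask], self.samples)


@dataclass(frozen=True)
class ROHSegment:
    """A run of homozygosity for one sample (0-based half-open bp)."""

    sample: str
    contig: str
    start: int
    end: int
    n_sites: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigurationError(f"ROH segment has end <= start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DeletionCall:
    """A structural-variant deletion with its carrier samples."""

    call_id: str
    contig: str
    start: int
    end: int
    carriers: frozenset[str]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigurationError(f"deletion has end <= start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a sorted disjoint set."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def interval_total(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bp covered after merging overlaps."""
    return sum(e - s for s, e in merge_intervals(intervals))
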