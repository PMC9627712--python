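"""Runs-of-homozygosity inference, F_ROH summaries, and tract dating.

The detector is a two-state hidden Markov model over the ordered variant
sites of one sample on one contig.  The hidden state is *autozygous*
(both haplotypes descend from a recent common ancestor) versus
*non-autozygous*; the observation at each site is simply HET or HOM
(either homozygote), missing calls being skipped.

Emissions
    autozygous:      P(HET) = eps            (genotyping error)
    non-autozygous:  P(HET) = 2p(1-p)        (Hardy-Weinberg at allele
                     frequency p when frequencies are supplied, else the
                     constant complement of ``hom_emission_outside``)

Transitions between adjacent sites separated by d bp follow the
symmetric two-state continuous-time chain,

    P(switch) = (1 - exp(-2 r d)) / 2,

with r the expected state changes per bp; this equals r*d for small r*d
and saturates at 1/2 for distant sites, so unlinked sites carry no state
information.  The most probable state path is recovered with the Viterbi
algorithm, and maximal autozygous runs become segments trimmed to their
first/last supporting (non-missing) site.

Tract age: a run of homozygosity of genetic length L centimorgans is
broken up by recombination at rate L/100 per meiosis on each of the two
lineages joining the sample to the common ancestor, so the expected
number of generations back to that ancestor is g = 100 / (2 L).  Longer
tracts mean more recent shared ancestry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import groupby

import numpy as np
import pandas as pd

from .model import (
    HET,
    MISSING,
    ConfigurationError,
    GenomeDescriptor,
    GenotypeMatrix,
    PupfishPopError,
    ROHSegment,
    merge_intervals,
)

# Length classes in Mb: short ROHs reflect background/historic inbreeding,
# long ones recent close-kin mating. Bins are lower-closed, upper-open.
LENGTH_CLASSES: tuple[tuple[float, float], ...] = ((0.1, 1.0), (1.0, 10.0), (10.0, math.inf))
CLASS_LABELS = ("0.1-1Mb", "1-10Mb", ">=10Mb")

DEFAULT_MIN_ROH_LENGTH = 100_000  # bp; F_ROH counts tracts at least this long


@dataclass(frozen=True)
class ROHParams:
    """Tunable knobs of the autozygosity HMM.

    het_emission_in_autozygous
        Probability a truly autozygous site is called HET (error), default 0.005.
    hom_emission_outside
        P(HOM) at a non-autozygous site when no allele frequencies are
        supplied; 0.7 suits cohort-segregating SNP panels.
    transition_rate
        Expected state switches per bp (0.1 per Mb by default).
    min_sites_per_tract
        Minimum supporting SNPs for a reported segment.
    min_report_length
        Length threshold used by F_ROH and the class summary (bp).
    """

    het_emission_in_autozygous: float = 0.005
    hom_emission_outside: float = 0.7
    transition_rate: float = 0.1e-6
    min_sites_per_tract: int = 10
    min_report_length: int = DEFAULT_MIN_ROH_LENGTH

    def __post_init__(self) -> None:
        for name in ("het_emission_in_autozygous", "hom_emission_outside"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0,1), got {v}")
        if self.transition_rate <= 0:
            raise ConfigurationError("transition_rate must be positive")
        if self.min_report_length <= 0:
            raise ConfigurationError("min_report_length must be positive")


def switch_probability(distance_bp: np.ndarray | float, rate_per_bp: float) -> np.ndarray | float:
    """Symmetric two-state chain switch probability over ``distance_bp``."""
    return 0.5 * (1.0 - np.exp(-2.0 * rate_per_bp * np.asarray(distance_bp, dtype=float)))


def _emission_logs(is_het: np.ndarray, params: ROHParams,
                   freqs: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Per-site log emission for (autozygous, non-autozygous) states."""
    eps = params.het_emission_in_autozygous
    log_auto = np.where(is_het, math.log(eps), math.log1p(-eps))
    if freqs is None:
        p_het_out = np.full(is_het.shape, 1.0 - params.hom_emission_outside)
    else:
        p = np.clip(np.asarray(freqs, dtype=float), 0.0, 1.0)
        p_het_out = np.clip(2.0 * p * (1.0 - p), 1e-6, 1.0 - 1e-6)
    log_out = np.where(is_het, np.log(p_het_out), np.log1p(-p_het_out))
    return log_auto, log_out


def viterbi_states(is_het: np.ndarray, positions: np.ndarray, params: ROHParams,
                   freqs: np.ndarray | None = None) -> np.ndarray:
    """Decode the most probable autozygous/non-autozygous path.

    Returns a boolean array (True = autozygous) over the supplied sites.
    Initial state distribution is the chain's stationary (1/2, 1/2).
    """
    T = len(is_het)
    log_auto, log_out = _emission_logs(np.asarray(is_het, bool), params, freqs)
    d = np.diff(np.asarray(positions, dtype=float))
    p_sw = np.clip(switch_probability(d, params.transition_rate), 1e-300, 0.5)
    log_sw = np.log(p_sw)
    log_st = np.log1p(-p_sw)

    # delta[t, k]: best log prob of a path ending in state k at site t
    delta = np.empty((T, 2))
    back = np.zeros((T, 2), dtype=np.int8)
    delta[0, 0] = math.log(0.5) + log_auto[0]
    delta[0, 1] = math.log(0.5) + log_out[0]
    for t in range(1, T):
        for k, em in ((0, log_auto[t]), (1, log_out[t])):
            stay = delta[t - 1, k] + log_st[t - 1]
            move = delta[t - 1, 1 - k] + log_sw[t - 1]
            if stay >= move:
                delta[t, k] = stay + em
                back[t, k] = k
            else:
                delta[t, k] = move + em
                back[t, k] = 1 - k
    states = np.empty(T, dtype=np.int8)
    states[-1] = 0 if delta[-1, 0] >= delta[-1, 1] else 1
    for t in range(T - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states == 0


def detect_roh(genotypes: np.ndarray, positions: np.ndarray, params: ROHParams | None = None,
               freqs: np.ndarray | None = None, *, sample: str = "sample",
               contig: str = "contig") -> list[ROHSegment]:
    """Detect ROH segments for one sample on one contig.

    ``genotypes`` are integer codes; MISSING sites are skipped but physical
    distance still accumulates across them.  Segments are maximal Viterbi
    autozygous runs trimmed to their first/last supporting SNP and filtered
    by ``min_sites_per_tract``; no length filter is applied here (length
    thresholds belong to the summary stage).
    """
    params = params or ROHParams()
    genotypes = np.asarray(genotypes)
    positions = np.asarray(positions)
    if len(genotypes) != len(positions):
        raise ConfigurationError("genotypes and positions differ in length")
    if np.any(np.diff(positions) <= 0):
        raise PupfishPopError("site positions must be strictly increasing")
    keep = genotypes != MISSING
    if not keep.any():
        return []
    gt = genotypes[keep]
    pos = positions[keep]
    f = np.asarray(freqs)[keep] if freqs is not None else None
    auto = viterbi_states(gt == HET, pos, params, f)

    segments: list[ROHSegment] = []
    i = 0
    idx = np.arange(len(auto))
    for state, grp in groupby(zip(auto, idx), key=lambda t: t[0]):
        members = [t[1] for t in grp]
        if state:
            first, last = members[0], members[-1]
            n = len(members)
            if n >= params.min_sites_per_tract and pos[last] + 1 > pos[first]:
                segments.append(ROHSegment(sample, contig, int(pos[first]), int(pos[last]) + 1, n))
    return segments


def detect_roh_cohort(gm: GenotypeMatrix, params: ROHParams | None = None,
                      freqs: np.ndarray | None = None) -> list[ROHSegment]:
    """Run :func:`detect_roh` for every sample on every contig of a matrix."""
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    contigs = gm.sites["contig"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    for contig in pd.unique(contigs):
        mask = contigs == contig
        cpos = pos[mask]
        cfreqs = freqs[mask] if freqs is not None else None
        for j, sample in enumerate(gm.samples):
            col = gm.codes[mask, j]
            if (col != MISSING).any():
                segments.extend(detect_roh(col, cpos, params, cfreqs, sample=sample, contig=contig))
    return segments


def _merged_lengths(segments: list[ROHSegment]) -> list[int]:
    """Per-sample, per-contig merged tract lengths."""
    out: list[int] = []
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for s in segments:
        by_key.setdefault((s.sample, s.contig), []).append((s.start, s.end))
    for ivs in by_key.values():
        out.extend(e - s for s, e in merge_intervals(ivs))
    return out


def compute_froh(segments: list[ROHSegment], genome: GenomeDescriptor,
                 min_length: int = DEFAULT_MIN_ROH_LENGTH) -> float:
    """F_ROH: summed length of merged tracts >= ``min_length``, over genome size."""
    lengths = genome.lengths
    for s in segments:
        if s.contig not in lengths or s.end > lengths[s.contig] or s.start < 0:
            raise ConfigurationError(f"segment outside contig bounds: {s}")
    total = sum(l for l in _merged_lengths(segments) if l >= min_length)
    return total / genome.total_size


def bin_roh_lengths(segments: list[ROHSegment], genome: GenomeDescriptor,
                    min_length: int = DEFAULT_MIN_ROH_LENGTH) -> dict[str, float]:
    """Genome fraction in each tract-length class; fractions sum to F_ROH."""
    fractions = dict.fromkeys(CLASS_LABELS, 0.0)
    for l in _merged_lengths(segments):
        if l < min_length:
            continue
        mb = l / 1e6
        for (lo, hi), label in zip(LENGTH_CLASSES, CLASS_LABELS):
            if lo <= mb < hi:
                fractions[label] += l / genome.total_size
                break
    return fractions


def inbreeding_summary(segments: list[ROHSegment], genome: GenomeDescriptor,
                       samples: list[str], min_length: int = DEFAULT_MIN_ROH_LENGTH) -> pd.DataFrame:
    """Per-sample F_ROH and length-class fractions as a tidy table."""
    rows = []
    by_sample: dict[str, list[ROHSegment]] = {s: [] for s in samples}
    for seg in segments:
        by_sample.setdefault(seg.sample, []).append(seg)
    for sample in samples:
        segs = by_sample[sample]
        froh = compute_froh(segs, genome, min_length)
        fr = bin_roh_lengths(segs, genome, min_length)
        rows.append({"sample": sample, "F_ROH": froh, "n_segments": len(segs), **fr})
    return pd.DataFrame(rows)


def recombination_rate(map_length_cM: float, genome_bp: float) -> float:
    """Average recombination rate in cM/Mb from total map length and genome size."""
    if map_length_cM <= 0 or genome_bp <= 0:
        raise ConfigurationError("map length and genome size must be positive")
    return map_length_cM / (genome_bp / 1e6)


def date_roh(length_bp: float, rate_cM_per_Mb: float) -> float:
    """Generations to the common ancestor of a tract: g = 100 / (2 L_cM)."""
    if length_bp <= 0 or rate_cM_per_Mb <= 0:
        raise ConfigurationError("length and rate must be positive")
    length_cM = length_bp * rate_cM_per_Mb / 1e6
    return 100.0 / (2.0 * length_cM)


def round_half_up(x: float) -> int:
    """Display rounding for tract ages (nearest integer, halves up)."""
    return int(math.floor(x + 0.5))


def roh_age_table(segments: list[ROHSegment], rate_cM_per_Mb: float,
                  min_length: int = DEFAULT_MIN_ROH_LENGTH) -> pd.DataFrame:
    """Length and estimated age per reported segment."""
    rows = []
    for s in segments:
        if s.length < min_length:
            continue
        g = date_roh(s.length, rate_cM_per_Mb)
        rows.append({
            "sample": s.sample, "contig": s.contig, "start": s.start, "end": s.end,
            "length_bp": s.length, "length_cM": s.length * rate_cM_per_Mb / 1e6,
            "g": g, "g_rounded": round_half_up(g),
        })
    return pd.DataFrame(rows, columns=["sample", "contig", "start", "end", "length_bp",
                                       "length_cM", "g", "g_rounded"])
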