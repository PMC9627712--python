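"""Synthetic inbred-cohort generator with exact truth tables.

The generator emulates the statistical structure of short-read genotype
data from small, inbred desert-pupfish populations, so that every
downstream stage (ROH inference, effect classification, load statistics,
uniqueness filters) can be validated against known truth:

* **Autozygosity mosaics** — each sample receives homozygous-by-descent
  tracts laid down with exponential lengths of mean 100/(2g) cM (g =
  generations to the tract's common ancestor), converted to bp with a
  uniform recombination rate, until a target genome fraction is covered.
  Inside tracts the two haplotypes are identical (a single population
  allele drawn at each site), corrupted to HET at a small error rate;
  outside tracts genotypes are Hardy–Weinberg draws at Beta-distributed
  alternate-allele frequencies.
* **Coding genes** — random non-overlapping gene models (1–2 exons, both
  strands, premature-stop-free reference ORFs) written into the
  reference sequence, with SYN/NSYN/stop-gain variants planted so their
  class is guaranteed by construction against the standard codon table.
  Background SNPs are placed outside CDS so planted classes are the only
  coding variation.
* **Privacy patterns** — planted variants and deletions can be shared
  across groups, private-and-segregating in a focal group, or fixed
  homozygous-derived in the focal group and absent elsewhere.

All randomness flows from one seed; identical config + seed gives
byte-identical output files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import io as pio
from .model import (
    HET,
    HOM_ALT,
    HOM_REF,
    LOF,
    MISSING,
    MUTATION_CLASSES,
    NSYN,
    SYN,
    ConfigurationError,
    DeletionCall,
    GeneAnnotation,
    GenomeDescriptor,
    GenotypeMatrix,
    SampleTable,
    interval_total,
    merge_intervals,
)

PATTERNS = ("shared", "group_private", "fixed_in_group")
DELETION_PATTERNS = ("group_private", "shared", "partial_focal")

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_NONSTOP_CODONS = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in _STOPS
)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    group: str
    target_F: float
    tract_age_g: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_F < 1.0:
            raise ConfigurationError(f"{self.sample_id}: target_F must be in [0,1)")
        if self.tract_age_g < 1:
            raise ConfigurationError(f"{self.sample_id}: tract_age_g must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    seed: int = 0
    contigs: tuple[tuple[str, int], ...] = (("chr1", 5_000_000), ("chr2", 3_000_000))
    snp_density: float = 400.0  # background SNPs per Mb
    samples: tuple[SampleSpec, ...] = ()
    allele_freq_beta: tuple[float, float] = (0.5, 0.5)
    het_error_inside_roh: float = 0.001
    missing_rate: float = 0.02
    recomb_rate_cM_per_Mb: float = 4.6
    n_genes: int = 30
    codons_range: tuple[int, int] = (60, 180)  # codons per gene, excl. stop
    two_exon_fraction: float = 0.5
    focal_group: str = "diabolis"
    # class -> pattern -> count
    planted_variants: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    # pattern -> count
    planted_deletions: Mapping[str, int] = field(default_factory=dict)
    deletion_length_range: tuple[int, int] = (500, 5_000)
    mispolarized_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("het_error_inside_roh", "missing_rate", "mispolarized_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {v}")
        if self.snp_density <= 0:
            raise ConfigurationError("snp_density must be positive")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate sample ids")
        for cls in self.planted_variants:
            if cls not in MUTATION_CLASSES:
                raise ConfigurationError(f"unknown planted class {cls!r}")
        for pat in self.planted_deletions:
            if pat not in DELETION_PATTERNS:
                raise ConfigurationError(f"unknown deletion pattern {pat!r}")


@dataclass
class TruthTables:
    """Exact bookkeeping of everything the generator planted."""

    roh: pd.DataFrame        # sample, contig, start, end
    variants: pd.DataFrame   # contig, pos, ref, alt, gene_id, cls, pattern
    deletions: pd.DataFrame  # call_id, contig, start, end, pattern, carriers
    samples: pd.DataFrame    # sample, group, target_F, realized_F, n_tracts


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    genome: GenomeDescriptor
    sequences: dict[str, str]
    genes: list[GeneAnnotation]
    gm: GenotypeMatrix
    site_freqs: np.ndarray
    deletions: list[DeletionCall]
    truth: TruthTables

    @property
    def sample_table(self) -> SampleTable:
        return SampleTable({s.sample_id: s.group for s in self.config.samples})

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit VCF/FASTA/GFF3/BED plus truth TSVs; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "fasta": outdir / "reference.fa",
            "gff3": outdir / "genes.gff3",
            "deletions": outdir / "deletions.bed",
            "samples": outdir / "sample_table.tsv",
            "freqs": outdir / "site_freqs.tsv",
            "truth_roh": outdir / "truth_roh.tsv",
            "truth_variants": outdir / "truth_variants.tsv",
            "truth_deletions": outdir / "truth_deletions.tsv",
            "truth_samples": outdir / "truth_samples.tsv",
        }
        pio.write_vcf(self.gm, paths["vcf"], self.genome)
        pio.write_fasta(self.sequences, paths["fasta"])
        pio.write_gff3(self.genes, paths["gff3"])
        pio.write_deletions_bed(self.deletions, paths["deletions"])
        st = pd.DataFrame({"sample": [s.sample_id for s in self.config.samples],
                           "group": [s.group for s in self.config.samples]})
        pio.write_tsv(st, paths["samples"])
        freqs = self.gm.sites[["contig", "pos"]].copy()
        freqs["alt_freq"] = self.site_freqs
        pio.write_tsv(freqs, paths["freqs"])
        pio.write_tsv(self.truth.roh, paths["truth_roh"])
        pio.write_tsv(self.truth.variants, paths["truth_variants"])
        pio.write_tsv(self.truth.deletions, paths["truth_deletions"])
        pio.write_tsv(self.truth.samples, paths["truth_samples"])
        return paths


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _seq_to_str(arr: np.ndarray) -> str:
    return "".join(_BASES[i] for i in arr)


def _place_genes(rng: np.random.Generator, cfg: SimulationConfig,
                 seq_arrays: dict[str, np.ndarray]) -> list[GeneAnnotation]:
    """Lay non-overlapping gene models and write their ORFs into the sequence."""
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in cfg.contigs}
    contig_names = [c for c, _ in cfg.contigs]
    lengths = dict(cfg.contigs)
    weights = np.array([lengths[c] for c in contig_names], dtype=float)
    weights /= weights.sum()
    genes: list[GeneAnnotation] = []
    margin = 3_000
    for gi in range(cfg.n_genes):
        placed = False
        for _ in range(200):
            contig = contig_names[rng.choice(len(contig_names), p=weights)]
            n_codons = int(rng.integers(cfg.codons_range[0], cfg.codons_range[1] + 1))
            coding_len = 3 * (n_codons + 1)  # + stop codon
            two_exon = rng.random() < cfg.two_exon_fraction
            intron = int(rng.integers(200, 1001)) if two_exon else 0
            span = coding_len + intron
            clen = lengths[contig]
            if span + 2 * margin >= clen:
                continue
            start = int(rng.integers(margin, clen - span - margin))
            iv = (start - margin, start + span + margin)
            if any(s < iv[1] and iv[0] < e for s, e in occupied[contig]):
                continue
            occupied[contig].append(iv)
            strand = "+" if rng.random() < 0.5 else "-"
            coding = "".join(_NONSTOP_CODONS[int(i)]
                             for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons))
            coding += _STOPS[int(rng.integers(0, 3))]
            if two_exon:
                # split at an arbitrary coding base so codons straddle the junction
                split = int(rng.integers(1, coding_len - 1))
            else:
                split = coding_len
            exon_lens = [split, coding_len - split] if two_exon else [coding_len]
            # genomic intervals in ascending order
            ivs_genomic: list[tuple[int, int]] = []
            cur = start
            for k, el in enumerate(exon_lens):
                ivs_genomic.append((cur, cur + el))
                cur += el + (intron if k == 0 and two_exon else 0)
            # write coding bases into the sequence
            genomic_coding = coding if strand == "+" else coding.translate(_COMPLEMENT)[::-1]
            arr = seq_arrays[contig]
            offset = 0
            for s, e in ivs_genomic:
                piece = genomic_coding[offset:offset + (e - s)]
                arr[s:e] = [_BASES.index(b) for b in piece]
                offset += e - s
            # CDS in transcription order with GFF3 phases
            order = ivs_genomic if strand == "+" else ivs_genomic[::-1]
            cds = []
            done = 0
            for s, e in order:
                phase = (3 - done % 3) % 3
                cds.append((s, e, phase))
                done += e - s
            genes.append(GeneAnnotation(f"gene{gi:03d}", contig, strand, tuple(cds)))
            placed = True
            break
        if not placed:
            raise ConfigurationError("could not place gene; genome too small for config")
    return genes


def _coding_to_genomic(gene: GeneAnnotation, idx: int) -> int:
    """Genomic position of in-frame coding index ``idx`` (phase-0 genes)."""
    offset = 0
    for s, e, _ in gene.cds:
        if idx < offset + (e - s):
            within = idx - offset
            return s + within if gene.strand == "+" else e - 1 - within
        offset += e - s
    raise IndexError(idx)


def _substitution_class(coding: str, idx: int, new_base: str) -> str:
    codon_i, within = divmod(idx, 3)
    codon = coding[codon_i * 3: codon_i * 3 + 3]
    alt_codon = codon[:within] + new_base + codon[within + 1:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return SYN
    if alt_aa == "*" and ref_aa != "*":
        return LOF
    return NSYN


def _draw_hwe(rng: np.random.Generator, p: float, n: int) -> np.ndarray:
    u = rng.random(n)
    gt = np.full(n, HOM_REF, dtype=np.int8)
    gt[u < p * p + 2 * p * (1 - p)] = HET
    gt[u < p * p] = HOM_ALT
    return gt


def _plant_variant_genotypes(rng: np.random.Generator, pattern: str,
                             focal_idx: np.ndarray, groups: np.ndarray,
                             autozygous: np.ndarray) -> np.ndarray:
    """Genotypes for one planted variant, respecting each sample's tract
    state at the site: autozygous samples carry a single drawn allele
    (never HET), non-autozygous samples are Hardy–Weinberg draws."""
    n = len(groups)

    def draw_one(j: int, p: float) -> int:
        if autozygous[j]:
            return HOM_ALT if rng.random() < p else HOM_REF
        u = rng.random()
        if u < p * p:
            return HOM_ALT
        if u < p * p + 2 * p * (1 - p):
            return HET
        return HOM_REF

    gt = np.full(n, HOM_REF, dtype=np.int8)
    if pattern == "fixed_in_group":
        gt[focal_idx] = HOM_ALT
        return gt
    if pattern == "group_private":
        for _ in range(1000):
            draw = np.array([draw_one(j, 0.5) for j in focal_idx], dtype=np.int8)
            if np.any(draw != HOM_REF) and np.any(draw != HOM_ALT):
                gt[focal_idx] = draw
                return gt
        raise ConfigurationError("failed to draw a segregating private genotype vector")
    if pattern == "shared":
        group_labels = np.unique(groups)
        for _ in range(1000):
            p = rng.uniform(0.2, 0.6)
            draw = np.array([draw_one(j, p) for j in range(n)], dtype=np.int8)
            carriers = draw != HOM_REF
            groups_with = {g for g, c in zip(groups, carriers) if c}
            if len(groups_with) >= min(2, len(group_labels)) and np.any(draw == HOM_REF):
                return draw
        raise ConfigurationError("failed to draw a shared genotype vector")
    raise ConfigurationError(f"unknown pattern {pattern!r}")


def mean_tract_length_bp(tract_age_g: float, rate_cM_per_Mb: float) -> float:
    """Expected autozygous-tract length for ancestry g generations back:
    100/(2g) cM, converted to bp at the given recombination rate."""
    return (100.0 / (2.0 * tract_age_g)) / rate_cM_per_Mb * 1e6


def sample_tract_lengths(rng: np.random.Generator, tract_age_g: float,
                         rate_cM_per_Mb: float, n: int) -> np.ndarray:
    """Draw n exponential tract lengths (bp) for a given tract age."""
    return rng.exponential(mean_tract_length_bp(tract_age_g, rate_cM_per_Mb), size=n)


def _lay_tracts(rng: np.random.Generator, cfg: SimulationConfig, spec: SampleSpec,
                lengths: dict[str, int]) -> dict[str, list[tuple[int, int]]]:
    """Autozygosity mosaic for one sample: merged tracts covering target_F exactly."""
    total = sum(lengths.values())
    goal = int(round(spec.target_F * total))
    tracts: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
    if goal == 0:
        return tracts
    mean_bp = mean_tract_length_bp(spec.tract_age_g, cfg.recomb_rate_cM_per_Mb)
    names = list(lengths)
    weights = np.array([lengths[c] for c in names], dtype=float)
    weights /= weights.sum()

    def covered() -> int:
        return sum(interval_total(v) for v in tracts.values() if v)

    for _ in range(100_000):
        contig = names[int(rng.choice(len(names), p=weights))]
        clen = lengths[contig]
        start = int(rng.integers(0, clen))
        length = max(1, int(round(rng.exponential(mean_bp))))
        end = min(start + length, clen)
        if end <= start:
            continue
        before = covered()
        tracts[contig].append((start, end))
        tracts[contig] = merge_intervals(tracts[contig])
        now = covered()
        if now >= goal:
            if now > goal:
                # shrink the final tract until coverage hits the goal exactly
                lo, hi = start + 1, end
                other_cov = sum(interval_total(v) for c2, v in tracts.items() if c2 != contig)
                prev_on_contig = _remove_last(tracts[contig], (start, end))
                while lo < hi:
                    mid = (lo + hi) // 2
                    trial_cov = other_cov + interval_total(prev_on_contig + [(start, mid)])
                    if trial_cov >= goal:
                        hi = mid
                    else:
                        lo = mid + 1
                tracts[contig] = merge_intervals(prev_on_contig + [(start, lo)])
            return tracts
    raise ConfigurationError(
        f"{spec.sample_id}: could not reach target_F={spec.target_F}; config infeasible")


def _remove_last(merged: list[tuple[int, int]], raw: tuple[int, int]) -> list[tuple[int, int]]:
    """Subtract the raw interval from a merged set (used while trimming)."""
    s0, e0 = raw
    out = []
    for s, e in merged:
        if e <= s0 or s >= e0:
            out.append((s, e))
            continue
        if s < s0:
            out.append((s, s0))
        if e > e0:
            out.append((e0, e))
    return out


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort with truth tables (deterministic in seed)."""
    if not config.samples:
        raise ConfigurationError("config declares no samples")
    rng = np.random.default_rng(config.seed)
    lengths = dict(config.contigs)
    genome = GenomeDescriptor(config.contigs)
    seq_arrays = {c: _random_sequence(rng, l) for c, l in config.contigs}
    genes = _place_genes(rng, config, seq_arrays)
    seqs = {c: _seq_to_str(a) for c, a in seq_arrays.items()}

    samples = [s.sample_id for s in config.samples]
    groups = np.array([s.group for s in config.samples])
    focal_idx = np.flatnonzero(groups == config.focal_group)
    if config.planted_variants and len(focal_idx) == 0:
        raise ConfigurationError(f"no samples in focal group {config.focal_group!r}")

    # --- autozygosity mosaics (needed before planting: planted genotypes
    #     respect tract state) ----------------------------------------------
    tract_map = {s.sample_id: _lay_tracts(rng, config, s, lengths) for s in config.samples}

    def _autozygous_at(contig: str, pos: int) -> np.ndarray:
        flags = np.zeros(len(samples), dtype=bool)
        for j, spec in enumerate(config.samples):
            for s, e in tract_map[spec.sample_id][contig]:
                if s <= pos < e:
                    flags[j] = True
                    break
        return flags

    # --- planted coding variants -------------------------------------------
    planted_rows = []
    planted_codes = []
    used_positions: set[tuple[str, int]] = set()
    gene_cycle = 0
    for cls in MUTATION_CLASSES:
        per_pattern = config.planted_variants.get(cls, {})
        for pattern in PATTERNS:
            for _ in range(int(per_pattern.get(pattern, 0))):
                ok = False
                for _attempt in range(500):
                    gene = genes[gene_cycle % len(genes)]
                    gene_cycle += 1
                    coding = _gene_coding(gene, seqs)
                    n_codable = len(coding) - 3  # exclude the terminal stop codon
                    idx = int(rng.integers(0, n_codable))
                    ref_cbase = coding[idx]
                    alts = [b for b in _BASES if b != ref_cbase]
                    rng.shuffle(alts)
                    for alt_cbase in alts:
                        if _substitution_class(coding, idx, alt_cbase) != cls:
                            continue
                        pos = _coding_to_genomic(gene, idx)
                        if (gene.contig, pos) in used_positions:
                            continue
                        ref = seqs[gene.contig][pos]
                        alt = alt_cbase if gene.strand == "+" else alt_cbase.translate(_COMPLEMENT)
                        codes = _plant_variant_genotypes(
                            rng, pattern, focal_idx, groups, _autozygous_at(gene.contig, pos))
                        planted_rows.append({
                            "contig": gene.contig, "pos": pos, "ref": ref, "alt": alt,
                            "gene_id": gene.gene_id, "cls": cls, "pattern": pattern,
                        })
                        planted_codes.append(codes)
                        used_positions.add((gene.contig, pos))
                        ok = True
                        break
                    if ok:
                        break
                if not ok:
                    raise ConfigurationError(f"could not plant a {cls}/{pattern} variant")

    # --- background SNPs (outside CDS) -------------------------------------
    cds_ivs: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in config.contigs}
    for g in genes:
        for s, e, _ in g.cds:
            cds_ivs[g.contig].append((s, e))
    bg_rows = []
    for contig, clen in config.contigs:
        n_sites = int(round(config.snp_density * clen / 1e6))
        forbidden = merge_intervals(cds_ivs[contig])
        pos = np.unique(rng.integers(0, clen, size=n_sites * 2))
        keep = np.ones(len(pos), dtype=bool)
        for s, e in forbidden:
            keep &= ~((pos >= s) & (pos < e))
        pos = pos[keep]
        planted_here = {c["pos"] for c in planted_rows if c["contig"] == contig}
        if planted_here:
            pos = pos[~np.isin(pos, sorted(planted_here))]
        if len(pos) > n_sites:
            sel = np.sort(rng.choice(len(pos), size=n_sites, replace=False))
            pos = pos[sel]
        for p0 in pos:
            ref = seqs[contig][int(p0)]
            alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            bg_rows.append({"contig": contig, "pos": int(p0), "ref": ref, "alt": alt})

    a, b = config.allele_freq_beta
    bg_freqs = rng.beta(a, b, size=len(bg_rows))

    # --- background genotypes ----------------------------------------------
    bg_df = pd.DataFrame(bg_rows, columns=["contig", "pos", "ref", "alt"])
    n_bg = len(bg_df)
    bg_codes = np.full((n_bg, len(samples)), HOM_REF, dtype=np.int8)
    contig_arr = bg_df["contig"].to_numpy()
    pos_arr = bg_df["pos"].to_numpy()
    for j, spec in enumerate(config.samples):
        inside = np.zeros(n_bg, dtype=bool)
        for contig, ivs in tract_map[spec.sample_id].items():
            if not ivs:
                continue
            mask = contig_arr == contig
            starts = np.array([s for s, _ in ivs])
            ends = np.array([e for _, e in ivs])
            k = np.searchsorted(starts, pos_arr[mask], side="right") - 1
            ok = (k >= 0) & (pos_arr[mask] < ends[np.clip(k, 0, None)])
            inside[np.flatnonzero(mask)[ok]] = True
        # inside tracts: one drawn population allele, duplicated
        u = rng.random(n_bg)
        hom = np.where(u < bg_freqs, HOM_ALT, HOM_REF).astype(np.int8)
        flip = rng.random(n_bg) < config.het_error_inside_roh
        hom[flip] = HET
        # outside: Hardy-Weinberg at the site frequency
        u2 = rng.random(n_bg)
        out = np.full(n_bg, HOM_REF, dtype=np.int8)
        out[u2 < bg_freqs ** 2 + 2 * bg_freqs * (1 - bg_freqs)] = HET
        out[u2 < bg_freqs ** 2] = HOM_ALT
        col = np.where(inside, hom, out)
        miss = rng.random(n_bg) < config.missing_rate
        col[miss] = MISSING
        bg_codes[:, j] = col

    # --- mispolarization (optional) ----------------------------------------
    mispolarized = np.zeros(n_bg, dtype=bool)
    if config.mispolarized_fraction > 0 and n_bg:
        flip_sites = rng.random(n_bg) < config.mispolarized_fraction
        mispolarized = flip_sites
        for i in np.flatnonzero(flip_sites):
            contig, p0 = bg_df.at[i, "contig"], int(bg_df.at[i, "pos"])
            ref, alt = bg_df.at[i, "ref"], bg_df.at[i, "alt"]
            bg_df.at[i, "ref"], bg_df.at[i, "alt"] = alt, ref
            seq_arrays[contig][p0] = _BASES.index(alt)
            row = bg_codes[i]
            was_ref = row == HOM_REF
            was_alt = row == HOM_ALT
            row[was_ref] = HOM_ALT
            row[was_alt] = HOM_REF
        seqs = {c: _seq_to_str(arr) for c, arr in seq_arrays.items()}
        bg_freqs = np.where(mispolarized, 1 - bg_freqs, bg_freqs)

    # --- assemble site table ------------------------------------------------
    planted_df = pd.DataFrame(planted_rows, columns=["contig", "pos", "ref", "alt",
                                                     "gene_id", "cls", "pattern"])
    planted_freqs = (np.array([
        (2 * np.sum(c == HOM_ALT) + np.sum(c == HET)) / (2 * len(c)) for c in planted_codes
    ]) if planted_codes else np.empty(0))
    sites = pd.concat([bg_df, planted_df[["contig", "pos", "ref", "alt"]]], ignore_index=True)
    codes = np.vstack([bg_codes] + ([np.array(planted_codes, dtype=np.int8)]
                                    if planted_codes else []))
    freqs = np.concatenate([bg_freqs, planted_freqs])
    order = genome.contig_order()
    sort_idx = np.lexsort((sites["pos"].to_numpy(), sites["contig"].map(order).to_numpy()))
    sites = sites.iloc[sort_idx].reset_index(drop=True)
    codes = codes[sort_idx]
    freqs = freqs[sort_idx]
    gm = GenotypeMatrix(sites, codes, samples)

    # --- deletions ----------------------------------------------------------
    deletions: list[DeletionCall] = []
    del_rows = []
    placement_modes = ("overlap_gene", "near_gene", "far")
    mode_i = 0
    background_idx = np.flatnonzero(groups != config.focal_group)
    for pattern in DELETION_PATTERNS:
        for k in range(int(config.planted_deletions.get(pattern, 0))):
            length = int(rng.integers(config.deletion_length_range[0],
                                      config.deletion_length_range[1] + 1))
            mode = placement_modes[mode_i % 3]
            mode_i += 1
            contig, start = _place_deletion(rng, mode, genes, lengths, length)
            if pattern == "group_private":
                carriers = frozenset(samples[i] for i in focal_idx)
            elif pattern == "partial_focal":
                subset = focal_idx[: max(1, len(focal_idx) - 1)]
                carriers = frozenset(samples[i] for i in subset)
            else:  # shared
                extra = rng.choice(background_idx, size=max(1, len(background_idx) // 2),
                                   replace=False)
                carriers = frozenset(samples[i] for i in np.concatenate([focal_idx, extra]))
            call_id = f"del_{pattern}_{k}"
            deletions.append(DeletionCall(call_id, contig, start, start + length, carriers))
            del_rows.append({"call_id": call_id, "contig": contig, "start": start,
                             "end": start + length, "pattern": pattern,
                             "carriers": ",".join(sorted(carriers))})

    # --- truth tables -------------------------------------------------------
    roh_rows = []
    sample_rows = []
    total_bp = genome.total_size
    for spec in config.samples:
        tr = tract_map[spec.sample_id]
        covered = 0
        n_tracts = 0
        for contig in lengths:
            for s, e in tr[contig]:
                roh_rows.append({"sample": spec.sample_id, "contig": contig,
                                 "start": s, "end": e})
                covered += e - s
                n_tracts += 1
        sample_rows.append({"sample": spec.sample_id, "group": spec.group,
                            "target_F": spec.target_F,
                            "realized_F": covered / total_bp, "n_tracts": n_tracts})
    truth_variants = planted_df.copy()
    truth_variants["mispolarized"] = False
    truth = TruthTables(
        roh=pd.DataFrame(roh_rows, columns=["sample", "contig", "start", "end"]),
        variants=truth_variants,
        deletions=pd.DataFrame(del_rows, columns=["call_id", "contig", "start", "end",
                                                  "pattern", "carriers"]),
        samples=pd.DataFrame(sample_rows),
    )
    return SimulatedCohort(config, genome, seqs, genes, gm, freqs, deletions, truth)


def _gene_coding(gene: GeneAnnotation, seqs: Mapping[str, str]) -> str:
    parts = []
    for s, e, _ in gene.cds:
        piece = seqs[gene.contig][s:e]
        if gene.strand == "-":
            piece = piece.translate(_COMPLEMENT)[::-1]
        parts.append(piece)
    return "".join(parts)


def _place_deletion(rng: np.random.Generator, mode: str, genes: list[GeneAnnotation],
                    lengths: dict[str, int], length: int) -> tuple[str, int]:
    for _ in range(500):
        if mode in ("overlap_gene", "near_gene") and genes:
            gene = genes[int(rng.integers(0, len(genes)))]
            lo, hi = gene.span
            if mode == "overlap_gene":
                start = max(0, lo + int(rng.integers(0, max(1, hi - lo))))
            else:
                start = hi + int(rng.integers(100, 1_900))
            contig = gene.contig
        else:
            names = list(lengths)
            contig = names[int(rng.integers(0, len(names)))]
            start = int(rng.integers(0, lengths[contig]))
        if start + length <= lengths[contig]:
            if mode == "far" and genes:
                near = any(g.contig == contig and g.span[0] - 10_000 < start + length
                           and start < g.span[1] + 10_000 for g in genes)
                if near:
                    continue
            return contig, start
    raise ConfigurationError("could not place deletion")


def realized_truth_summary(truth: TruthTables, genome: GenomeDescriptor,
                           gm: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Exact per-sample bookkeeping: realized F, tract count and (when the
    genotype matrix is supplied) planted-variant derived-carrier counts per class."""
    total = genome.total_size
    rows = []
    for rec in truth.samples.itertuples():
        sub = truth.roh[truth.roh["sample"] == rec.sample]
        true_f = float((sub["end"] - sub["start"]).sum()) / total
        row = {"sample": rec.sample, "group": rec.group, "true_F": true_f,
               "n_tracts": len(sub)}
        if gm is not None and len(truth.variants):
            key = gm.sites.set_index(["contig", "pos"]).index
            for cls in MUTATION_CLASSES:
                v = truth.variants[truth.variants["cls"] == cls]
                idx = [key.get_loc((c, p)) for c, p in zip(v["contig"], v["pos"])]
                col = gm.codes[idx, gm.sample_index(rec.sample)]
                row[f"n_{cls}_carried"] = int(np.sum((col == HET) | (col == HOM_ALT)))
        rows.append(row)
    return pd.DataFrame(rows)


def fixture_config(seed: int = 20_220_907) -> SimulationConfig:
    """The repo's standard tiny cohort: 2 contigs, 6 samples, 3 species groups.

    Emulates the study design in miniature — a severely inbred focal
    species (high F, recent tract ages) plus two less-inbred relatives —
    with planted coding variants and deletions in every privacy pattern.
    """
    samples = (
        SampleSpec("DHP1", "diabolis", 0.60, 4),
        SampleSpec("DHP2", "diabolis", 0.50, 4),
        SampleSpec("NEV1", "nevadensis", 0.15, 8),
        SampleSpec("NEV2", "nevadensis", 0.10, 8),
        SampleSpec("SAL1", "salinus", 0.10, 8),
        SampleSpec("SAL2", "salinus", 0.05, 8),
    )
    return SimulationConfig(
        seed=seed,
        contigs=(("chr1", 5_000_000), ("chr2", 3_000_000)),
        samples=samples,
        planted_variants={
            SYN: {"shared": 6, "group_private": 2, "fixed_in_group": 2},
            NSYN: {"shared": 6, "group_private": 2, "fixed_in_group": 2},
            LOF: {"shared": 8, "group_private": 3, "fixed_in_group": 3},
        },
        planted_deletions={"group_private": 3, "shared": 2, "partial_focal": 1},
    )


def cohort_digest(cohort: SimulatedCohort) -> str:
    """Stable digest of all emitted arrays/tables (determinism checks)."""
    h = hashlib.sha256()
    h.update(cohort.gm.codes.tobytes())
    h.update(cohort.gm.sites.to_csv(index=False).encode())
    for name in sorted(cohort.sequences):
        h.update(cohort.sequences[name].encode())
    h.update(cohort.truth.roh.to_csv(index=False).encode())
    h.update(cohort.truth.variants.to_csv(index=False).encode())
    h.update(cohort.truth.deletions.to_csv(index=False).encode())
    for d in cohort.deletions:
        h.update(repr((d.call_id, d.contig, d.start, d.end, sorted(d.carriers))).encode())
    return h.hexdigest()
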