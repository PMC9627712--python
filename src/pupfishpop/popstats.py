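"""Population-level summaries: private fixed LOF variants, private
deletions with gene proximity, harmonic-mean effective population size,
and Weir–Cockerham F_st.

The harmonic mean of census counts approximates the variance effective
population size over a period of fluctuating abundance; it is dominated
by the bottleneck minima, which is why it sits at or below the
arithmetic mean.

F_st uses the Weir & Cockerham (1984) variance-components estimator
(theta-hat).  Per site, the variation in allele frequency is decomposed
into among-population (a), among-individual-within-population (b) and
within-individual (c) components computed from genotype counts and
observed heterozygosity; the genome-wide estimate is the ratio of sums
sum(a) / sum(a+b+c) — the "weighted" convention — with the per-site mean
ratio also reported.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    HET,
    HOM_ALT,
    HOM_REF,
    LOF,
    MISSING,
    CensusSeries,
    ConfigurationError,
    DeletionCall,
    GeneAnnotation,
    GenotypeMatrix,
)

log = logging.getLogger(__name__)


def unique_fixed_lof(gm: GenotypeMatrix, effects: pd.DataFrame,
                     focal_samples: list[str], background_samples: list[str]) -> pd.DataFrame:
    """LOF sites fixed homozygous-derived in the focal group, absent elsewhere.

    A site is retained when (i) at least one focal sample is genotyped,
    (ii) every non-missing focal genotype is homozygous-derived, and
    (iii) every non-missing background genotype carries zero derived
    alleles.  Missing focal calls are ignored, honoring "samples for
    which genotypic information was available".
    """
    if not focal_samples or not background_samples:
        raise ConfigurationError("focal and background sample sets must be non-empty")
    if set(focal_samples) & set(background_samples):
        raise ConfigurationError("focal and background sample sets overlap")
    fi = [gm.sample_index(s) for s in focal_samples]
    bi = [gm.sample_index(s) for s in background_samples]
    lof_idx = np.flatnonzero(effects["effect"].to_numpy() == LOF)
    rows = []
    n_all_missing = 0
    for i in lof_idx:
        focal = gm.codes[i, fi]
        back = gm.codes[i, bi]
        focal_nm = focal[focal != MISSING]
        back_nm = back[back != MISSING]
        if len(focal_nm) == 0:
            n_all_missing += 1
            continue
        if np.all(focal_nm == HOM_ALT) and np.all(back_nm == HOM_REF):
            rows.append({
                "contig": gm.sites.at[i, "contig"], "pos": int(gm.sites.at[i, "pos"]),
                "ref": gm.sites.at[i, "ref"], "alt": gm.sites.at[i, "alt"],
                "gene_id": effects["gene_id"].iloc[i] if "gene_id" in effects else "",
                "n_focal_genotyped": int(len(focal_nm)),
                "n_background_genotyped": int(len(back_nm)),
            })
    if n_all_missing:
        log.info("unique_fixed_lof: %d LOF sites had no genotyped focal sample", n_all_missing)
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "gene_id",
                                       "n_focal_genotyped", "n_background_genotyped"])


def _gene_distance(deletion: DeletionCall, genes: list[GeneAnnotation]) -> tuple[float, str]:
    best = np.inf
    best_gene = ""
    for g in genes:
        if g.contig != deletion.contig:
            continue
        lo, hi = g.span
        if deletion.start < hi and lo < deletion.end:
            return 0.0, g.gene_id
        d = lo - deletion.end if lo >= deletion.end else deletion.start - hi
        if d < best:
            best, best_gene = d, g.gene_id
    return best, best_gene


def unique_deletions(deletions: list[DeletionCall], focal_samples: list[str],
                     background_samples: list[str], genes: list[GeneAnnotation],
                     window: int = 2_000, max_length: int = 1_000_000) -> pd.DataFrame:
    """Deletions carried by ALL focal samples and no background sample,
    annotated with distance to the nearest gene.

    ``near_gene`` flags calls within ``window`` bp of (or overlapping) a
    gene.  Calls longer than ``max_length`` are flagged ``size_outlier``
    (likely artefacts) but reported rather than dropped.
    """
    if not focal_samples:
        raise ConfigurationError("focal sample list must be explicit and non-empty")
    focal = set(focal_samples)
    background = set(background_samples)
    rows = []
    for d in deletions:
        if not focal <= d.carriers:
            continue
        if d.carriers & background:
            continue
        dist, gene_id = _gene_distance(d, genes)
        rows.append({
            "call_id": d.call_id, "contig": d.contig, "start": d.start, "end": d.end,
            "length": d.length, "nearest_gene": gene_id,
            "gene_distance": dist if np.isfinite(dist) else np.nan,
            "near_gene": bool(np.isfinite(dist) and dist <= window),
            "size_outlier": d.length > max_length,
        })
    out = pd.DataFrame(rows, columns=["call_id", "contig", "start", "end", "length",
                                      "nearest_gene", "gene_distance", "near_gene",
                                      "size_outlier"])
    return out.sort_values(["contig", "start"]).reset_index(drop=True)


def harmonic_mean_ne(census: CensusSeries) -> pd.DataFrame:
    """Per-season harmonic-mean effective size: Ne = n / sum(1/N_i)."""
    rows = []
    for season in ("spring", "autumn"):
        counts = census.counts(season)
        if len(counts) == 0:
            continue
        if np.any(counts <= 0):
            raise ConfigurationError("harmonic mean undefined for non-positive counts")
        ne = stats.hmean(counts)
        rows.append({"season": season, "Ne": float(ne), "Ne_rounded": int(round(ne)),
                     "n_years": int(len(counts)), "arithmetic_mean": float(np.mean(counts))})
    return pd.DataFrame(rows)


def weir_cockerham_components(gm: GenotypeMatrix, group1: list[str],
                              group2: list[str]) -> pd.DataFrame:
    """Per-site Weir & Cockerham (1984) variance components for two groups.

    Sites that are monomorphic across both groups, or genotyped in fewer
    than two individuals in either group, yield NaN components and are
    excluded from the genome-wide ratio.
    """
    i1 = [gm.sample_index(s) for s in group1]
    i2 = [gm.sample_index(s) for s in group2]
    g1 = gm.codes[:, i1].astype(float)
    g2 = gm.codes[:, i2].astype(float)
    r = 2.0

    def pop_stats(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nm = g != MISSING
        n = nm.sum(axis=1).astype(float)                       # individuals genotyped
        alt = np.where(nm, g, 0.0)
        # derived-allele count: HET contributes 1, HOM_ALT 2
        ac = np.where(nm, (g == HET) * 1.0 + (g == HOM_ALT) * 2.0, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = ac / (2 * n)
            h = np.where(nm, g == HET, 0.0).sum(axis=1) / n    # observed het freq
        return n, p, h

    n1, p1, h1 = pop_stats(g1)
    n2, p2, h2 = pop_stats(g2)
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                   - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2
    mono = (pbar <= 0) | (pbar >= 1)
    valid &= ~mono & (nbar > 1)
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    out = gm.sites[["contig", "pos"]].copy()
    out["a"], out["b"], out["c"] = a, b, c
    n_skipped = int((~valid).sum())
    if n_skipped:
        log.info("weir_cockerham: %d sites skipped (monomorphic or under-genotyped)", n_skipped)
    return out


def weir_cockerham_fst(gm: GenotypeMatrix, group1: list[str],
                       group2: list[str]) -> dict[str, float]:
    """Genome-wide F_st: ratio of sums (headline) and mean of per-site ratios."""
    comp = weir_cockerham_components(gm, group1, group2)
    ok = comp[["a", "b", "c"]].notna().all(axis=1)
    a = comp.loc[ok, "a"].to_numpy()
    abc = comp.loc[ok, ["a", "b", "c"]].sum(axis=1).to_numpy()
    nonzero = abc != 0
    if not nonzero.any():
        raise ConfigurationError("no usable sites for F_st")
    weighted = float(a[nonzero].sum() / abc[nonzero].sum())
    per_site = a[nonzero] / abc[nonzero]
    return {"fst_weighted": weighted, "fst_mean": float(np.mean(per_site)),
            "n_sites": int(nonzero.sum())}
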