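"""Coding-effect classification and ancestral/derived polarization.

SNPs falling in a CDS are classified against the standard nuclear codon
table by locating the codon containing the site in transcription
direction (strand-aware, phase-aware across exon junctions) and
translating the reference and alternate codons:

* same amino acid                      -> SYN  (stop-retained included)
* different amino acid, alt not stop   -> NSYN (stop-loss lands here too)
* alt codon is a stop, ref is not      -> LOF  ("stop gained" only)

This deliberately conservative LOF definition — premature stop codons
only — excludes splice, frameshift and stop-loss effects, which are more
prone to misannotation.

Polarization uses the reference genome allele as the ancestral proxy (an
outgroup reference), so HOM_REF reads as homozygous-ancestral and
HOM_ALT as homozygous-derived.  An optional ancestral-allele table can
override the proxy per site.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .model import (
    LOF,
    NONCODING,
    NSYN,
    SYN,
    GeneAnnotation,
    PupfishPopError,
)

log = logging.getLogger(__name__)

_SEVERITY = {LOF: 3, NSYN: 2, SYN: 1, NONCODING: 0}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def transcript_sequence(gene: GeneAnnotation, seqs: Mapping[str, str]) -> str:
    """Spliced coding sequence in translation frame (leading phase bases dropped)."""
    contig_seq = seqs[gene.contig]
    parts = []
    for s, e, _ in gene.cds:
        piece = contig_seq[s:e]
        if gene.strand == "-":
            piece = piece.translate(_COMPLEMENT)[::-1]
        parts.append(piece)
    cds = "".join(parts)
    phase = gene.cds[0][2]
    return cds[phase:]


def coding_index(gene: GeneAnnotation, pos: int) -> int | None:
    """0-based index of genomic position ``pos`` within the in-frame coding
    sequence, or None when the position is outside every CDS interval (or in
    the leading phase bases)."""
    offset = 0
    for s, e, _ in gene.cds:
        if s <= pos < e:
            idx = offset + (pos - s if gene.strand == "+" else e - 1 - pos)
            idx -= gene.cds[0][2]
            return idx if idx >= 0 else None
        offset += e - s
    return None


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def classify_snp_effect(contig: str, pos: int, ref: str, alt: str,
                        gene: GeneAnnotation, seqs: Mapping[str, str]) -> str:
    """Classify one SNP against one gene; NONCODING when outside its CDS."""
    if not gene.usable:
        log.warning("gene %s flagged unusable; site %s:%d treated as NONCODING",
                    gene.gene_id, contig, pos + 1)
        return NONCODING
    if gene.contig != contig:
        return NONCODING
    if seqs[contig][pos] != ref:
        raise PupfishPopError(
            f"reference mismatch at {contig}:{pos + 1}: sequence has "
            f"{seqs[contig][pos]!r}, VCF says {ref!r}")
    idx = coding_index(gene, pos)
    if idx is None:
        return NONCODING
    ref_base, alt_base = ref, alt
    if gene.strand == "-":
        ref_base = ref_base.translate(_COMPLEMENT)
        alt_base = alt_base.translate(_COMPLEMENT)
    cds = transcript_sequence(gene, seqs)
    codon_i, within = divmod(idx, 3)
    codon = cds[codon_i * 3: codon_i * 3 + 3]
    if len(codon) < 3:
        return NONCODING  # trailing partial codon of an unusual model
    if codon[within] != ref_base:
        raise PupfishPopError(
            f"internal frame error at {contig}:{pos + 1} in gene {gene.gene_id}")
    alt_codon = codon[:within] + alt_base + codon[within + 1:]
    ref_aa = _translate(codon)
    alt_aa = _translate(alt_codon)
    if ref_aa == alt_aa:
        return SYN
    if alt_aa == "*" and ref_aa != "*":
        return LOF
    return NSYN


def classify_variants(sites: pd.DataFrame, genes: Sequence[GeneAnnotation],
                      seqs: Mapping[str, str]) -> pd.DataFrame:
    """Classify every site against all genes; overlapping genes resolved by
    severity (LOF > NSYN > SYN).  Returns columns ``effect`` and ``gene_id``.
    """
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    effects, gene_ids = [], []
    for row in sites.itertuples():
        best, best_gene = NONCODING, ""
        for g in by_contig.get(row.contig, []):
            lo, hi = g.span
            if not (lo <= row.pos < hi):
                continue
            eff = classify_snp_effect(row.contig, int(row.pos), row.ref, row.alt, g, seqs)
            if _SEVERITY[eff] > _SEVERITY[best]:
                best, best_gene = eff, g.gene_id
        effects.append(best)
        gene_ids.append(best_gene)
    out = sites[["contig", "pos", "ref", "alt"]].copy()
    out["effect"] = effects
    out["gene_id"] = gene_ids
    return out


_ANN_TERM_MAP = {"stop_gained": LOF, "missense_variant": NSYN, "synonymous_variant": SYN}


def parse_snpeff_ann(ann_field: str | None) -> str:
    """Map a SnpEff 4.x ``ANN`` field to a mutation class.

    Only the three terms the analysis uses are mapped; everything else
    (intron, UTR, splice, stop_lost, ...) is NONCODING for load purposes.
    Multiple annotations: the most severe mapped term wins.
    """
    if not ann_field:
        return NONCODING
    best = NONCODING
    try:
        for annotation in str(ann_field).split(","):
            fields = annotation.split("|")
            if len(fields) < 2:
                raise ValueError("too few '|' fields")
            for term in fields[1].split("&"):
                eff = _ANN_TERM_MAP.get(term.strip(), NONCODING)
                if _SEVERITY[eff] > _SEVERITY[best]:
                    best = eff
    except ValueError as exc:
        log.warning("malformed ANN field %r (%s); site skipped", ann_field, exc)
        return NONCODING
    return best


def polarize(codes: np.ndarray, ancestral_is_ref: np.ndarray | None = None) -> np.ndarray:
    """Polarize genotype codes into ancestral/derived orientation.

    With the reference-as-ancestral proxy this is the identity mapping
    (HOM_REF -> HOM_ANC, HOM_ALT -> HOM_DER).  ``ancestral_is_ref`` is a
    per-site boolean hook for an external ancestral-allele table: where
    False, homozygote codes are swapped (HET and MISSING unchanged).
    """
    codes = np.asarray(codes)
    if ancestral_is_ref is None:
        return codes.copy()
    flip = ~np.asarray(ancestral_is_ref, dtype=bool)
    out = codes.copy()
    if codes.ndim == 1:
        flip_rows = flip
    else:
        flip_rows = flip[:, None] & np.ones(codes.shape, dtype=bool)
    hom_ref = (out == 0) & flip_rows
    hom_alt = (out == 2) & flip_rows
    out[hom_ref] = 2
    out[hom_alt] = 0
    return out
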