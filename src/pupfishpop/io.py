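"""Readers and writers for the standard formats the pipeline consumes.

VCF is read with cyvcf2 and written as plain VCF 4.2 text (sites + GT
only — the only fields the analysis uses).  GFF3 is parsed with gffutils;
FASTA with Biopython.  BED output is BED4 with 0-based half-open
coordinates.  All conversions between 1-based file conventions and the
package's 0-based half-open internal convention happen here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .model import (
    HOM_ALT,
    HOM_REF,
    HET,
    MISSING,
    CensusSeries,
    ConfigurationError,
    DeletionCall,
    GeneAnnotation,
    GenomeDescriptor,
    GenotypeMatrix,
    ParseError,
    ROHSegment,
    SampleTable,
)

log = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")

# cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_CYVCF2_MAP = {0: HOM_REF, 1: HET, 2: MISSING, 3: HOM_ALT}


def read_vcf(path: str | Path, sample_table: SampleTable | None = None) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records and non-SNP records (indels, symbolic alleles)
    are skipped; the skip count is logged.  Phased and unphased genotypes
    are treated identically.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if sample_table is not None:
        unknown = [s for s in samples if s not in sample_table.groups]
        if unknown:
            raise ConfigurationError(f"VCF samples absent from sample table: {unknown}")
    contigs, positions, refs, alts, rows = [], [], [], [], []
    n_skipped = 0
    for rec in vcf:
        ref = rec.REF
        alt = rec.ALT
        if len(alt) != 1 or len(ref) != 1 or len(alt[0]) != 1 \
                or ref not in _NUCLEOTIDES or alt[0] not in _NUCLEOTIDES:
            n_skipped += 1
            continue
        contigs.append(rec.CHROM)
        positions.append(rec.POS - 1)  # to 0-based
        refs.append(ref)
        alts.append(alt[0])
        rows.append([_CYVCF2_MAP[g] for g in rec.gt_types])
    if n_skipped:
        log.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    sites = pd.DataFrame({"contig": contigs, "pos": positions, "ref": refs, "alt": alts})
    codes = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return GenotypeMatrix(sites, codes, samples)


_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path, genome: GenomeDescriptor | None = None) -> None:
    """Write a sites+GT VCF (4.2).  Sites are sorted by contig order then position."""
    order = genome.contig_order() if genome is not None else None
    sites = gm.sites.copy()
    sites["_row"] = np.arange(len(sites))
    if order is not None:
        missing = set(sites["contig"]) - set(order)
        if missing:
            raise ConfigurationError(f"sites on contigs absent from genome: {sorted(missing)}")
        sites["_corder"] = sites["contig"].map(order)
    else:
        sites["_corder"] = sites["contig"]
    sites = sites.sort_values(["_corder", "pos"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if genome is not None:
            for name, length in genome.contigs:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        for _, row in sites.iterrows():
            gts = "\t".join(_GT_STRING[int(c)] for c in gm.codes[int(row["_row"])])
            fh.write(f"{row['contig']}\t{int(row['pos']) + 1}\t.\t{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def genome_from_sequences(seqs: Mapping[str, str]) -> GenomeDescriptor:
    return GenomeDescriptor(tuple((n, len(s)) for n, s in seqs.items()))


def read_contig_table(path: str | Path) -> GenomeDescriptor:
    """Read a two-column TSV (contig, length) into a GenomeDescriptor."""
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "length"], comment="#")
    return GenomeDescriptor(tuple(zip(df["contig"], df["length"].astype(int))))


def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    """Parse gene models from GFF3 into :class:`GeneAnnotation` objects.

    One CDS chain is kept per gene: the longest transcript's.  CDS
    intervals arrive 1-based closed and leave 0-based half-open, ordered
    in transcription direction (reverse genomic order on the minus
    strand).  Genes whose phase-adjusted CDS length is not a multiple of
    3 are flagged unusable for effect classification (with a warning)
    rather than dropped.
    """
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique", sort_attribute_values=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    genes: list[GeneAnnotation] = []
    for gene in db.features_of_type("gene"):
        best: list | None = None
        transcripts = list(db.children(gene, featuretype="mRNA"))
        parents = transcripts if transcripts else [gene]
        for parent in parents:
            cds = list(db.children(parent, featuretype="CDS", order_by="start"))
            if not cds:
                continue
            if best is None or sum(len(c) for c in cds) > sum(len(c) for c in best):
                best = cds
        if best is None:
            continue
        strand = gene.strand if gene.strand in "+-" else "+"
        # gffutils keeps GFF3 1-based closed coords; convert here.
        ivs = [(c.start - 1, c.end, 0 if c.frame in (".", None) else int(c.frame)) for c in best]
        ivs.sort(key=lambda t: t[0])
        if strand == "-":
            ivs = ivs[::-1]
        first_phase = ivs[0][2]
        total = sum(e - s for s, e, _ in ivs) - first_phase
        usable = total % 3 == 0
        if not usable:
            log.warning("gene %s: CDS length %d not divisible by 3; flagged unusable", gene.id, total)
        genes.append(GeneAnnotation(gene.id, gene.seqid, strand, tuple(ivs), usable=usable))
    return genes


def write_gff3(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    """Emit gene/mRNA/CDS features; internal 0-based half-open back to 1-based closed."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo, hi = g.span
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.contig}\tpupfishpop\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t{attrs}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{g.contig}\tpupfishpop\tmRNA\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n")
            for i, (s, e, phase) in enumerate(g.cds):
                fh.write(
                    f"{g.contig}\tpupfishpop\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


def write_bed(segments: Iterable[ROHSegment], path: str | Path, genome: GenomeDescriptor | None = None) -> None:
    """Write ROH segments as BED4 (name column = sample), sorted by contig order then start."""
    segs = list(segments)
    if genome is not None:
        order = genome.contig_order()
        lengths = genome.lengths
        for s in segs:
            if s.contig not in lengths:
                raise ConfigurationError(f"segment on unknown contig: {s}")
            if s.end > lengths[s.contig] or s.start < 0:
                raise ConfigurationError(f"segment outside contig bounds: {s}")
        segs.sort(key=lambda s: (order[s.contig], s.start, s.sample))
    else:
        segs.sort(key=lambda s: (s.contig, s.start, s.sample))
    with open(path, "w") as fh:
        for s in segs:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.sample}\n")


def read_bed_segments(path: str | Path) -> list[ROHSegment]:
    segs = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{i}: expected BED4, got {len(parts)} columns")
            segs.append(ROHSegment(parts[3], parts[0], int(parts[1]), int(parts[2])))
    return segs


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_census_tsv(path: str | Path) -> CensusSeries:
    """Census TSV with header ``year season count``."""
    df = pd.read_csv(path, sep="\t")
    expected = {"year", "season", "count"}
    if not expected.issubset(df.columns):
        raise ParseError(f"census table must have columns {sorted(expected)}, got {list(df.columns)}")
    return CensusSeries(tuple(
        (int(r.year), str(r.season), int(r.count)) for r in df.itertuples()
    ))


def read_sample_table(path: str | Path) -> SampleTable:
    """Sample metadata TSV with columns ``sample`` and ``group`` (optional ``year``)."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "group"}.issubset(df.columns):
        raise ParseError("sample table must have columns 'sample' and 'group'")
    if df["sample"].duplicated().any():
        raise ConfigurationError("duplicate sample ids in sample table")
    years = {}
    if "year" in df.columns:
        years = {r.sample: int(r.year) for r in df.itertuples() if not pd.isna(r.year)}
    return SampleTable(dict(zip(df["sample"], df["group"])), years)


def write_deletions_bed(deletions: Iterable[DeletionCall], path: str | Path) -> None:
    """BED4+1: contig, start, end, id, comma-joined carrier samples."""
    dels = sorted(deletions, key=lambda d: (d.contig, d.start))
    with open(path, "w") as fh:
        for d in dels:
            carriers = ",".join(sorted(d.carriers))
            fh.write(f"{d.contig}\t{d.start}\t{d.end}\t{d.call_id}\t{carriers}\n")


def read_deletions_bed(path: str | Path) -> list[DeletionCall]:
    dels = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}:{i}: expected 5 columns (contig start end id carriers)")
            carriers = frozenset(c for c in parts[4].split(",") if c)
            dels.append(DeletionCall(parts[3], parts[0], int(parts[1]), int(parts[2]), carriers))
    return dels


def read_deletions_sv_vcf(path: str | Path) -> list[DeletionCall]:
    """Read DEL records from an SV VCF; any non-reference GT counts as presence."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dels = []
    for rec in vcf:
        svtype = rec.INFO.get("SVTYPE")
        if svtype != "DEL":
            continue
        end = rec.INFO.get("END")
        if end is None:
            end = rec.POS + abs(int(rec.INFO.get("SVLEN", 0)))
        carriers = frozenset(
            s for s, g in zip(samples, rec.gt_types) if g in (1, 3)  # HET or HOM_ALT
        )
        call_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
        dels.append(DeletionCall(call_id, rec.CHROM, rec.POS - 1, int(end), carriers))
    return dels
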