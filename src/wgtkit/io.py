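"""Readers and writers for the standard formats the pipeline consumes.

Coordinate conventions are converted at this boundary: VCF and GFF3 are
1-based on disk and become 0-based half-open in memory; BED is written
0-based half-open, as the format requires.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError


@dataclasses.dataclass(frozen=True)
class GeneFeature:
    """A gene span in internal coordinates (0-based, half-open)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."


@dataclasses.dataclass(frozen=True)
class VariantSite:
    """One called variant: position is 1-based as in the VCF."""

    chrom: str
    pos: int
    is_het: bool
    dp: float
    qual: float


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    """Write sequences as FASTA, wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_gff_genes(
    path: str | Path, feature_types: tuple[str, ...] = ("gene",)
) -> list[GeneFeature]:
    """Extract gene features from a GFF3 file.

    GFF3 is 1-based closed; the returned intervals are 0-based half-open.
    Malformed lines raise :class:`InputError` naming the file and line.
    """
    genes: list[GeneFeature] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise InputError(
                    f"{path}:{lineno}: expected 9 tab-separated GFF3 columns, "
                    f"got {len(fields)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if ftype not in feature_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise InputError(f"{path}:{lineno}: invalid interval [{start}, {end}]")
            gene_id = _gff_attribute(attrs, "ID")
            if gene_id is None:
                raise InputError(f"{path}:{lineno}: gene feature lacks an ID attribute")
            genes.append(GeneFeature(gene_id, chrom, start - 1, end, strand))
    return genes


def _gff_attribute(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def read_vcf_sites(
    path: str | Path, lengths_path: str | Path | None = None
) -> tuple[list[VariantSite], dict[str, int]]:
    """Read variant sites and contig lengths from a VCF.

    Contig lengths come from ``##contig`` header lines; when the header
    carries none, a two-column (name, length) TSV must be supplied.
    DP is taken from the first sample's FORMAT field when present, else
    from INFO. A missing QUAL or DP is recorded as NaN and will fail any
    finite filter threshold.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lengths: dict[str, int] = {}
    try:
        if vcf.seqlens and vcf.seqnames:
            lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except AttributeError:  # cyvcf2 raises when the header has no lengths
        lengths = {}
    if not lengths:
        if lengths_path is None:
            raise InputError(
                f"{path}: no ##contig lengths in header and no lengths file given"
            )
        lengths = read_lengths_tsv(lengths_path)

    sites: list[VariantSite] = []
    for var in vcf:
        dp = float("nan")
        try:
            fmt_dp = var.format("DP")
        except KeyError:
            fmt_dp = None
        if fmt_dp is not None and len(fmt_dp):
            dp = float(fmt_dp[0][0])
        elif var.INFO.get("DP") is not None:
            dp = float(var.INFO.get("DP"))
        qual = float("nan") if var.QUAL is None else float(var.QUAL)
        is_het = False
        if var.genotypes:
            alleles = [a for a in var.genotypes[0][:-1] if a >= 0]
            is_het = len(alleles) == 2 and alleles[0] != alleles[1]
        sites.append(VariantSite(var.CHROM, var.POS, is_het, dp, qual))
    return sites, lengths


def read_lengths_tsv(path: str | Path) -> dict[str, int]:
    """Read a fai-like two-column (chromosome, length) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def read_similarity_table(path: str | Path) -> pd.DataFrame:
    """Read an outfmt-6-like similarity table.

    Expects at least four tab-separated columns: query id, subject id,
    bitscore, e-value. Extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise InputError(f"{path}: similarity table needs >= 4 columns")
    df = df.iloc[:, :4]
    df.columns = ["query", "subject", "bitscore", "evalue"]
    if df["query"].isna().any() or df["subject"].isna().any():
        raise InputError(f"{path}: empty ids in similarity table")
    return df


def read_id_list(path: str | Path) -> list[str]:
    """Read gene ids from a one-per-line file or the first column of a TSV."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids.append(line.split("\t")[0])
    return ids


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    """Write (chrom, start, end) intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_dating_table(path: str | Path) -> pd.DataFrame:
    """Read a (species, ks_peak, time_mya) divergence-event table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"species", "ks_peak", "time_mya"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: dating table needs columns {sorted(required)}")
    return df
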