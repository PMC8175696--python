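"""Heterozygosity ("hybridization") hotspot scanning.

Diploid variant calls are filtered on depth and quality, heterozygous
sites are counted in fixed-width windows along each chromosome (200 kb
by default, tumbling), and windows exceeding a count cutoff (>1000
sites, equivalently >0.5% heterozygosity) are called hotspots. Genes
overlapping hotspots form a gene set that is tested for term enrichment
against the genome background with Fisher's exact test and
Benjamini–Hochberg correction.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .io import GeneFeature, VariantSite, read_vcf_sites

DEFAULT_WINDOW = 200_000
DEFAULT_COUNT_CUTOFF = 1000
DEFAULT_RATE_CUTOFF = 0.005


@dataclasses.dataclass(frozen=True)
class FilterPolicy:
    """Depth/quality band for retaining variant calls.

    ``qual_field`` selects whether the quality threshold applies to the
    site QUAL column (default) or to the genotype quality (GQ); the
    upstream description of the filter ("minQ") does not distinguish the
    two, so both are supported.
    """

    dp_min: float = 2
    dp_max: float = 20
    qual_min: float = 20
    qual_field: str = "QUAL"

    def __post_init__(self) -> None:
        if self.dp_min > self.dp_max:
            raise InputError("dp_min must be <= dp_max")


@dataclasses.dataclass
class GenomeWindow:
    """A window in 0-based half-open coordinates with its het-site count."""

    chrom: str
    start: int
    end: int
    het_count: int = 0
    is_hotspot: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def het_rate(self) -> float:
        return self.het_count / self.width


@dataclasses.dataclass(frozen=True)
class HotspotSet:
    """Hotspot calls plus the summary statistics reported alongside."""

    windows: tuple[GenomeWindow, ...]
    n_hotspots: int
    fraction_het_in_hotspots: float
    per_chromosome: pd.DataFrame  # chrom, n_hotspots, mean_sites_per_hotspot
    count_cutoff: float
    rate_cutoff: float

    @property
    def hotspots(self) -> tuple[GenomeWindow, ...]:
        return tuple(w for w in self.windows if w.is_hotspot)


def filter_variants(
    vcf: str | Path | Sequence[VariantSite],
    policy: FilterPolicy = FilterPolicy(),
    lengths: Mapping[str, int] | str | Path | None = None,
) -> tuple[list[VariantSite], dict[str, int]]:
    """Retain heterozygous sites inside the depth/quality band.

    ``vcf`` may be a path (parsed with contig lengths from the header or
    a lengths file) or an already-parsed site list (then ``lengths`` must
    be a mapping). Sites with missing DP or QUAL fail the band.
    """
    if isinstance(vcf, (str, Path)):
        lengths_path = None if isinstance(lengths, Mapping) else lengths
        sites, header_lengths = read_vcf_sites(vcf, lengths_path)
        chrom_lengths = dict(lengths) if isinstance(lengths, Mapping) else header_lengths
    else:
        if not isinstance(lengths, Mapping):
            raise InputError("chromosome lengths are required with pre-parsed sites")
        sites, chrom_lengths = list(vcf), dict(lengths)
    kept = [
        s
        for s in sites
        if s.is_het
        and policy.dp_min <= s.dp <= policy.dp_max
        and s.qual >= policy.qual_min
    ]
    return kept, chrom_lengths


def window_counts(
    sites: Sequence[VariantSite],
    chrom_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    step: int | None = None,
) -> list[GenomeWindow]:
    """Count sites in windows tiling each chromosome from 0.

    Windows advance by ``step`` (defaults to the window width, i.e.
    non-overlapping, in which case counts partition the site set); the
    trailing partial window is kept with its true width.
    """
    if step is None:
        step = window
    if window <= 0 or step <= 0:
        raise InputError("window and step must be positive")
    by_chrom: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    for site in sites:
        if site.chrom not in chrom_lengths:
            raise InputError(f"site {site.chrom}:{site.pos} on unknown chromosome")
        if site.pos > chrom_lengths[site.chrom]:
            raise InputError(
                f"site {site.chrom}:{site.pos} beyond chromosome length "
                f"{chrom_lengths[site.chrom]}"
            )
        by_chrom[site.chrom].append(site.pos - 1)  # to 0-based
    windows: list[GenomeWindow] = []
    for chrom, length in chrom_lengths.items():
        pos = np.sort(np.asarray(by_chrom[chrom], dtype=int))
        start = 0
        while start < length:
            end = min(start + window, length)
            count = int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
            windows.append(GenomeWindow(chrom, start, end, count))
            start += step
    return windows


def call_hotspots(
    windows: Sequence[GenomeWindow],
    count_cutoff: float = DEFAULT_COUNT_CUTOFF,
    rate_cutoff: float = DEFAULT_RATE_CUTOFF,
    mode: str = "fixed",
    quantile: float = 0.95,
) -> HotspotSet:
    """Flag hotspot windows and summarise.

    Full-width windows are flagged iff their count strictly exceeds
    ``count_cutoff``; partial (trailing) windows iff their rate strictly
    exceeds ``rate_cutoff``, since a count cutoff is width-dependent.
    ``mode="quantile"`` instead takes the right tail of the per-window
    count density: the cutoff becomes the ``quantile`` of full-window
    counts (the exploratory route to the same call).
    """
    if mode not in ("fixed", "quantile"):
        raise InputError(f"unknown hotspot mode {mode!r}")
    windows = [dataclasses.replace(w) for w in windows]
    full_width = max((w.width for w in windows), default=0)
    if mode == "quantile":
        full_counts = [w.het_count for w in windows if w.width == full_width]
        count_cutoff = float(np.quantile(full_counts, quantile)) if full_counts else 0.0
        rate_cutoff = count_cutoff / full_width if full_width else 0.0
    for w in windows:
        if w.width == full_width:
            w.is_hotspot = w.het_count > count_cutoff
        else:
            w.is_hotspot = w.het_rate > rate_cutoff
    total = sum(w.het_count for w in windows)
    in_hot = sum(w.het_count for w in windows if w.is_hotspot)
    fraction = in_hot / total if total else 0.0
    rows = []
    for chrom in sorted({w.chrom for w in windows}):
        hs = [w for w in windows if w.chrom == chrom and w.is_hotspot]
        rows.append(
            {
                "chrom": chrom,
                "n_hotspots": len(hs),
                "mean_sites_per_hotspot": float(np.mean([w.het_count for w in hs])) if hs else 0.0,
            }
        )
    per_chrom = pd.DataFrame(rows, columns=["chrom", "n_hotspots", "mean_sites_per_hotspot"])
    return HotspotSet(
        windows=tuple(windows),
        n_hotspots=sum(w.is_hotspot for w in windows),
        fraction_het_in_hotspots=fraction,
        per_chromosome=per_chrom,
        count_cutoff=float(count_cutoff),
        rate_cutoff=float(rate_cutoff),
    )


def genes_in_hotspots(
    hotspots: HotspotSet | Iterable[GenomeWindow],
    genes: Sequence[GeneFeature],
) -> set[str]:
    """Gene ids whose span overlaps at least one hotspot window by >= 1 bp."""
    flagged = hotspots.hotspots if isinstance(hotspots, HotspotSet) else tuple(hotspots)
    trees: dict[str, IntervalTree] = {}
    for w in flagged:
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end)
    hits = set()
    for gene in genes:
        tree = trees.get(gene.chrom)
        if tree is not None and tree.overlap(gene.start, gene.end):
            hits.add(gene.id)
    return hits


def enrichment(
    gene_set: set[str],
    background: set[str],
    term_map: Mapping[str, Iterable[str]] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-term 2x2 Fisher exact enrichment of a gene set vs background.

    ``term_map`` maps gene id -> terms (or a two-column DataFrame of
    gene, term rows). For each term the table is (in-set with term,
    in-set without, out-of-set with, out-of-set without); p-values are
    two-sided and Benjamini–Hochberg adjusted across terms.
    """
    if not background:
        raise InputError("background gene set is empty")
    if not gene_set <= background:
        raise InputError("gene_set must be a subset of background")
    if isinstance(term_map, pd.DataFrame):
        pairs = term_map.iloc[:, :2].itertuples(index=False)
        mapping: dict[str, set[str]] = {}
        for gene, term in pairs:
            mapping.setdefault(str(gene), set()).add(str(term))
        term_map = mapping
    term_genes: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene not in background:
            continue
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)
    out_set = background - gene_set
    rows = []
    for term in sorted(term_genes):
        with_term = term_genes[term]
        a = len(gene_set & with_term)
        b = len(gene_set) - a
        c = len(out_set & with_term)
        d = len(out_set) - c
        odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"term": term, "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p": p})
    table = pd.DataFrame(rows, columns=["term", "a", "b", "c", "d", "odds_ratio", "p"])
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["p_adj"] = []
    return table
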