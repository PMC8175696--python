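"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators cover the four input classes the analysis consumes:

* :func:`gen_ks_sample` — Ks age distributions as mixtures of lognormal
  duplication components over a uniform background, the shape empirical
  paranome/anchor distributions take when whole-genome duplications sit
  on top of continuous small-scale duplication.
* :func:`gen_cds_pair` — codon-aligned sequence pairs evolved to a target
  synonymous (and nonsynonymous) divergence, for estimator recovery.
* :func:`gen_het_vcf` — diploid variant calls with background versus
  elevated-heterozygosity intervals, for the hotspot scan.
* :func:`gen_protein_set` — protein sets with planted six-residue motif
  occurrences and controlled basic/acidic composition, for the S-RNase
  classifier.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, SaturationError, SpecificationError
from .ks import (
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    KsDistribution,
    ng86_site_counts,
)

_BASES = "ACGT"
# codon families whose third position is fourfold degenerate
_FOURFOLD_PREFIXES = frozenset(
    p for p in {c[:2] for c in SENSE_CODONS}
    if all(p + b in CODON_TO_AA for b in _BASES)
    and len({CODON_TO_AA[p + b] for b in _BASES}) == 1
)


# ---------------------------------------------------------------------------
# Ks mixtures


@dataclasses.dataclass(frozen=True)
class KsMixtureSpec:
    """Mixture of lognormal duplication components over a uniform background.

    Each component is (location, spread, weight) with the location the
    *median* of the lognormal (the Ks position of the peak on a log-scale
    density) and the spread its log-scale standard deviation.
    """

    components: tuple[tuple[float, float, float], ...] = ()
    background_weight: float = 0.0
    background_range: tuple[float, float] = (0.0, 3.0)

    def __post_init__(self) -> None:
        total = self.background_weight + sum(w for _, _, w in self.components)
        if self.background_weight < 0 or any(w < 0 for _, _, w in self.components):
            raise SpecificationError("mixture weights must be nonnegative")
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise SpecificationError(f"mixture weights sum to {total}, expected 1")
        if any(loc <= 0 for loc, _, _ in self.components):
            raise SpecificationError("component locations must be positive")
        if any(sd <= 0 for _, sd, _ in self.components):
            raise SpecificationError("component spreads must be positive")
        lo, hi = self.background_range
        if not lo < hi:
            raise SpecificationError("background_range must be ordered (lo < hi)")


def gen_ks_sample(spec: KsMixtureSpec, n: int, seed: int, kind: str = "paranome") -> KsDistribution:
    """Draw n Ks values from the mixture.

    Component draws are lognormal with the stated location as median;
    background draws are uniform on ``background_range``.
    """
    if n < 0:
        raise SpecificationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    weights = [w for _, _, w in spec.components] + [spec.background_weight]
    choices = rng.choice(len(weights), size=n, p=weights)
    values = np.empty(n)
    for i, (loc, sd, _w) in enumerate(spec.components):
        mask = choices == i
        values[mask] = rng.lognormal(mean=math.log(loc), sigma=sd, size=int(mask.sum()))
    bg = choices == len(spec.components)
    values[bg] = rng.uniform(*spec.background_range, size=int(bg.sum()))
    labels = [f"sim{i}" for i in range(n)]
    return KsDistribution(values, labels, kind=kind)


# ---------------------------------------------------------------------------
# Codon pairs at a target divergence


def _p_from_d(d: float) -> float:
    """Invert the Jukes-Cantor correction: expected raw proportion of
    differing sites for a corrected distance d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _random_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    return [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)]


def _synonymous_alternatives(codon: str) -> list[str]:
    """Sense codons one base away encoding the same amino acid."""
    out = []
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in CODON_TO_AA and CODON_TO_AA[alt] == CODON_TO_AA[codon]:
                out.append(alt)
    return out


def _nonsynonymous_alternatives(codon: str) -> list[str]:
    out = []
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in CODON_TO_AA and CODON_TO_AA[alt] != CODON_TO_AA[codon]:
                out.append(alt)
    return out


def gen_cds_pair(
    target_ks: float,
    target_ka: float,
    n_codons: int,
    seed: int,
    base_seq: str | None = None,
) -> tuple[str, str, dict]:
    """Evolve a codon-aligned pair to a target NG86 divergence.

    A stop-free ancestor is drawn uniformly over sense codons (or taken
    from ``base_seq``); substitutions are then placed as single-base
    changes at distinct codons — synonymous changes at codons with a
    synonymous one-step neighbour, nonsynonymous changes elsewhere — with
    per-codon substitution probabilities chosen so that the *expected*
    NG86 estimate equals the target. At most one change per codon keeps
    pathway averaging trivial and the construction exact in expectation.

    Returns (seq_a, seq_b, truth) where truth records the placed counts.

    Raises :class:`SaturationError` when the implied proportion of
    synonymous differences reaches Jukes-Cantor saturation (p >= 3/4) or
    the sequence offers too few substitutable sites to realise it.
    """
    if target_ks < 0 or target_ka < 0:
        raise SpecificationError("divergence targets must be >= 0")
    if n_codons < 1:
        raise SpecificationError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    if base_seq is not None:
        if len(base_seq) != 3 * n_codons:
            raise SpecificationError("base_seq length must equal 3 * n_codons")
        codons_a = [base_seq[i : i + 3].upper() for i in range(0, len(base_seq), 3)]
        if any(c in STOP_CODONS or c not in CODON_TO_AA for c in codons_a):
            raise SpecificationError("base_seq must consist of sense codons")
    else:
        codons_a = _random_cds(n_codons, rng)

    S_total = sum(ng86_site_counts(c)[0] for c in codons_a)
    N_total = 3.0 * n_codons - S_total

    p_s = _p_from_d(target_ks)
    p_n = _p_from_d(target_ka)
    if p_s >= 0.75 - 1e-12 or p_n >= 0.75 - 1e-12:
        raise SaturationError("target divergence is at or beyond Jukes-Cantor saturation")

    syn_capable = [i for i, c in enumerate(codons_a) if _synonymous_alternatives(c)]
    expected_sd = p_s * S_total
    if target_ks > 0:
        if not syn_capable or expected_sd > len(syn_capable):
            raise SaturationError(
                f"too few synonymous sites: need expected {expected_sd:.2f} "
                f"substitutions over {len(syn_capable)} substitutable codons"
            )
    q_s = expected_sd / len(syn_capable) if syn_capable and target_ks > 0 else 0.0

    codons_b = list(codons_a)
    sd_placed = 0
    syn_hit: set[int] = set()
    for i in syn_capable:
        if rng.random() < q_s:
            alts = _synonymous_alternatives(codons_a[i])
            # prefer fourfold third-position changes: they leave the codon's
            # site counts unchanged, keeping S identical in both sequences
            ff = [a for a in alts if a[:2] == codons_a[i][:2] and codons_a[i][:2] in _FOURFOLD_PREFIXES]
            pool = ff if ff else alts
            codons_b[i] = pool[rng.integers(0, len(pool))]
            sd_placed += 1
            syn_hit.add(i)

    nd_placed = 0
    if target_ka > 0:
        non_capable = [
            i for i in range(n_codons)
            if i not in syn_hit and _nonsynonymous_alternatives(codons_a[i])
        ]
        expected_nd = p_n * N_total
        if not non_capable or expected_nd > len(non_capable):
            raise SaturationError(
                f"too few nonsynonymous sites: need expected {expected_nd:.2f} "
                f"substitutions over {len(non_capable)} substitutable codons"
            )
        q_n = expected_nd / len(non_capable)
        for i in non_capable:
            if rng.random() < q_n:
                alts = _nonsynonymous_alternatives(codons_a[i])
                codons_b[i] = alts[rng.integers(0, len(alts))]
                nd_placed += 1

    truth = {
        "S": S_total,
        "N": N_total,
        "Sd": sd_placed,
        "Nd": nd_placed,
        "target_ks": target_ks,
        "target_ka": target_ka,
    }
    return "".join(codons_a), "".join(codons_b), truth


# ---------------------------------------------------------------------------
# Heterozygosity VCFs


@dataclasses.dataclass(frozen=True)
class HetGenomeSpec:
    """Background heterozygosity with planted elevated-rate intervals.

    ``hotspot_intervals`` are (chrom, start, end, rate) with 0-based
    half-open coordinates; inside an interval the local rate *replaces*
    the background rate.
    """

    chromosome_lengths: dict[str, int]
    background_rate: float
    hotspot_intervals: tuple[tuple[str, int, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate < 0:
            raise SpecificationError("background_rate must be >= 0")
        for chrom, start, end, rate in self.hotspot_intervals:
            if chrom not in self.chromosome_lengths:
                raise SpecificationError(f"interval on unknown chromosome {chrom!r}")
            if not 0 <= start < end <= self.chromosome_lengths[chrom]:
                raise SpecificationError(
                    f"interval [{start}, {end}) outside {chrom} "
                    f"(length {self.chromosome_lengths[chrom]})"
                )
            if rate < 0:
                raise SpecificationError("interval rates must be >= 0")


def _piecewise_segments(spec: HetGenomeSpec, chrom: str) -> list[tuple[int, int, float]]:
    """Non-overlapping (start, end, rate) segments covering the chromosome."""
    length = spec.chromosome_lengths[chrom]
    marks = {0, length}
    intervals = [(s, e, r) for c, s, e, r in spec.hotspot_intervals if c == chrom]
    for s, e, _ in intervals:
        marks.update((s, e))
    edges = sorted(marks)
    segments = []
    for s, e in zip(edges[:-1], edges[1:]):
        rate = spec.background_rate
        for hs, he, hr in intervals:
            if hs <= s and e <= he:
                rate = hr
                break
        segments.append((s, e, rate))
    return segments


def gen_het_vcf(
    spec: HetGenomeSpec, out_path: str | Path | None = None
) -> tuple[str, list[tuple[str, int, int, float]]]:
    """Generate a diploid VCF whose heterozygous sites follow a Poisson
    process at the local rate.

    Every record is heterozygous (GT 0/1) with DP=10 and QUAL=50, inside
    the default filter band. Records are sorted, positions 1-based, and
    contig lengths are written as ``##contig`` header lines. Returns the
    VCF text (also written to ``out_path`` when given) and the planted
    truth intervals.
    """
    rng = np.random.default_rng(spec.seed)
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in spec.chromosome_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample1")
    for chrom in spec.chromosome_lengths:
        positions: list[int] = []
        for s, e, rate in _piecewise_segments(spec, chrom):
            lam = rate * (e - s)
            count = rng.poisson(lam) if lam > 0 else 0
            if count:
                positions.extend(rng.integers(s, e, size=count).tolist())
        positions = sorted(set(positions))
        for pos0 in positions:
            ref = _BASES[rng.integers(0, 4)]
            alt = _BASES[(  _BASES.index(ref) + 1 + rng.integers(0, 3)) % 4]
            lines.append(
                f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t50\tPASS\t.\tGT:DP\t0/1:10"
            )
    text = "\n".join(lines) + "\n"
    if out_path is not None:
        Path(out_path).write_text(text)
    return text, list(spec.hotspot_intervals)


# ---------------------------------------------------------------------------
# Protein sets


PATTERN4_CLASSES: tuple[str, ...] = (
    "CG", "P", "QLRSTIK", "DGIKNPSTVY", "ADEIMNPSTV", "DGKNQST",
)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclasses.dataclass(frozen=True)
class ProteinSetSpec:
    """Counts of motif-bearing, basic and acidic proteins to generate."""

    n_with_pattern4: int = 0
    n_basic_no_pattern4: int = 0
    n_acidic_no_pattern4: int = 0
    length: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_with_pattern4, self.n_basic_no_pattern4, self.n_acidic_no_pattern4) < 0:
            raise SpecificationError("counts must be >= 0")
        if self.length < 6:
            raise SpecificationError("length must be >= 6 (motif width)")


def _weighted_seq(length: int, enriched: str, frac: float, excluded: str, rng) -> str:
    pool = [a for a in _AA20 if a not in excluded and a not in enriched]
    out = []
    for _ in range(length):
        if rng.random() < frac:
            out.append(enriched[rng.integers(0, len(enriched))])
        else:
            out.append(pool[rng.integers(0, len(pool))])
    return "".join(out)


def _has_pattern4(seq: str) -> bool:
    from .si import match_pattern4

    return bool(match_pattern4(seq))


def gen_protein_set(spec: ProteinSetSpec) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate proteins with planted motif and charge structure.

    Motif-bearing sequences carry >= 1 six-residue occurrence of the
    pattern-4 classes; "basic" sequences are Lys/Arg-enriched and free of
    both the motif and acidic residues; "acidic" sequences are Asp/Glu-
    enriched and Lys/Arg-free. The truth table records the intended class
    and the isoelectric point of each sequence as generated.
    """
    from .si import compute_pi

    rng = np.random.default_rng(spec.seed)
    records: dict[str, str] = {}
    rows = []

    def _add(name: str, seq: str, intended: str) -> None:
        records[name] = seq
        rows.append(
            {
                "id": name,
                "intended_class": intended,
                "has_pattern4": _has_pattern4(seq),
                "pI": compute_pi(seq),
            }
        )

    for i in range(spec.n_with_pattern4):
        while True:
            seq = _weighted_seq(spec.length, "", 0.0, "", rng)
            motif = "".join(
                cls[rng.integers(0, len(cls))] for cls in PATTERN4_CLASSES
            )
            start = int(rng.integers(0, spec.length - 5))
            seq = seq[:start] + motif + seq[start + 6 :]
            if _has_pattern4(seq):
                break
        _add(f"p4_{i}", seq, "with_pattern4")

    for i in range(spec.n_basic_no_pattern4):
        while True:
            seq = _weighted_seq(spec.length, "KR", 0.35, "DE", rng)
            if not _has_pattern4(seq):
                break
        _add(f"basic_{i}", seq, "basic")

    for i in range(spec.n_acidic_no_pattern4):
        while True:
            seq = _weighted_seq(spec.length, "DE", 0.35, "KR", rng)
            if not _has_pattern4(seq):
                break
        _add(f"acidic_{i}", seq, "acidic")

    truth = pd.DataFrame(rows, columns=["id", "intended_class", "has_pattern4", "pI"])
    return records, truth
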