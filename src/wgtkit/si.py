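"""S-RNase candidate classification and S-locus detection.

In Solanaceae, gametophytic self-incompatibility is mediated by pistil
S-RNases (members of the RNase-T2 family) together with pollen S-locus
F-box proteins linked to the S-RNase gene. Within the RNase-T2 family,
S-RNases are distinguished by two sequence characteristics: they lack
the six-position amino-acid class motif known as pattern 4,

    [CG] P [QLRSTIK] [DGIKNPSTVY] [ADEIMNPSTV] [DGKNQST]

and their isoelectric point falls between pH 8 and 10 (they are basic
proteins). A genomic S-locus candidate is an S-RNase gene with F-box
genes in its flanking region on the same chromosome.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Mapping, Sequence

from .errors import InputError
from .io import GeneFeature

PATTERN4_REGEX = re.compile(r"(?=([CG]P[QLRSTIK][DGIKNPSTVY][ADEIMNPSTV][DGKNQST]))")

# Bjellqvist pKa values as used by the ExPASy/ProtParam convention.
BJELLQVIST_PKA: dict[str, float] = {
    "Nterm": 7.5,
    "K": 10.0,
    "R": 12.0,
    "H": 5.98,
    "Cterm": 3.55,
    "D": 4.05,
    "E": 4.45,
    "C": 9.0,
    "Y": 10.0,
}

# EMBOSS iep defaults, swappable alternative.
EMBOSS_PKA: dict[str, float] = {
    "Nterm": 8.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "Cterm": 3.6,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}

SI_PI_BAND = (8.0, 10.0)


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.strip().upper()
        if not seq:
            raise InputError(f"protein {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", seq)


@dataclasses.dataclass(frozen=True)
class SiClassification:
    """Verdict for one RNase-T2 family member."""

    id: str
    has_pattern4: bool
    pattern4_positions: tuple[int, ...]
    pI: float
    is_srnase_candidate: bool


@dataclasses.dataclass(frozen=True)
class SLocusCandidate:
    """An S-RNase gene with the F-box genes found in its flanking region."""

    srnase_id: str
    chrom: str
    start: int
    end: int
    flank_bp: int
    fbox_genes: tuple[tuple[str, int], ...]  # (gene id, distance in bp; 0 = overlap)


def match_pattern4(seq: str) -> list[int]:
    """0-based start positions of all (possibly overlapping) pattern-4
    matches. X and other non-standard letters match no class."""
    seq = seq.strip().upper()
    return [m.start() for m in PATTERN4_REGEX.finditer(seq)]


def net_charge(seq: str, ph: float, pka: Mapping[str, float] = BJELLQVIST_PKA) -> float:
    """Net protein charge Q(pH): positive groups (N-terminus, K, R, H)
    minus negative groups (C-terminus, D, E, C, Y), each with
    Henderson–Hasselbalch occupancy. Strictly decreasing in pH."""
    seq = seq.strip().upper()
    pos = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    for aa in "KRH":
        n = seq.count(aa)
        if n:
            pos += n / (1.0 + 10 ** (ph - pka[aa]))
    neg = 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa in "DECY":
        n = seq.count(aa)
        if n:
            neg += n / (1.0 + 10 ** (pka[aa] - ph))
    return pos - neg


def compute_pi(
    seq: str,
    pka: Mapping[str, float] = BJELLQVIST_PKA,
    tol: float = 1e-3,
) -> float:
    """Isoelectric point: the unique root of the net-charge function on
    [0, 14], found by bisection to |Q| < tol.

    The termini always contribute one positive and one negative group,
    so Q(0) > 0 > Q(14) and a root exists for every sequence.
    """
    seq = seq.strip().upper()
    if not seq:
        raise InputError("empty sequence")
    lo, hi = 0.0, 14.0
    q_mid = net_charge(seq, (lo + hi) / 2, pka)
    for _ in range(200):
        mid = (lo + hi) / 2
        q_mid = net_charge(seq, mid, pka)
        if abs(q_mid) < tol:
            return mid
        if q_mid > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def classify(
    proteins: Mapping[str, str] | Sequence[ProteinRecord],
    membership: Iterable[str],
    pi_band: tuple[float, float] = SI_PI_BAND,
    pka: Mapping[str, float] = BJELLQVIST_PKA,
) -> list[SiClassification]:
    """Classify RNase-T2 family members into S-RNase candidates.

    A member is a candidate iff its sequence has no pattern-4 match
    anywhere and its isoelectric point lies in ``pi_band`` (closed at
    both ends). ``membership`` lists the family member ids (from
    upstream domain annotation); every member must be present in the
    proteome.
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.id: p.sequence for p in proteins}
    members = list(membership)
    missing = [m for m in members if m not in proteins]
    if missing:
        raise InputError(f"family members absent from proteome: {missing}")
    lo, hi = pi_band
    out = []
    for member in members:
        seq = proteins[member].strip().upper()
        positions = match_pattern4(seq)
        pi = compute_pi(seq, pka)
        out.append(
            SiClassification(
                id=member,
                has_pattern4=bool(positions),
                pattern4_positions=tuple(positions),
                pI=pi,
                is_srnase_candidate=(not positions) and lo <= pi <= hi,
            )
        )
    return out


def find_slocus(
    candidate_ids: Iterable[str],
    genes: Sequence[GeneFeature],
    fbox_ids: Iterable[str],
    flank_bp: int = 1_000_000,
) -> list[SLocusCandidate]:
    """Locate S-locus candidates: F-box genes flanking each S-RNase gene.

    For every candidate S-RNase gene, reports the F-box genes on the
    same chromosome whose span intersects the candidate span extended by
    ``flank_bp`` on both sides, with the gap distance in bp (0 when the
    spans overlap). Unresolvable ids raise an error.
    """
    by_id = {g.id: g for g in genes}
    candidates = list(candidate_ids)
    fboxes = list(fbox_ids)
    missing = [i for i in candidates + fboxes if i not in by_id]
    if missing:
        raise InputError(f"gene ids absent from annotation: {missing}")
    out = []
    for cand in candidates:
        gene = by_id[cand]
        lo = max(0, gene.start - flank_bp)
        hi = gene.end + flank_bp
        linked = []
        for fb in fboxes:
            f = by_id[fb]
            if f.chrom != gene.chrom or f.id == gene.id:
                continue
            if f.start < hi and f.end > lo:
                if f.end <= gene.start:
                    dist = gene.start - f.end
                elif f.start >= gene.end:
                    dist = f.start - gene.end
                else:
                    dist = 0
                linked.append((f.id, dist))
        linked.sort(key=lambda x: (x[1], x[0]))
        out.append(
            SLocusCandidate(
                srnase_id=cand,
                chrom=gene.chrom,
                start=gene.start,
                end=gene.end,
                flank_bp=flank_bp,
                fbox_genes=tuple(linked),
            )
        )
    return out
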