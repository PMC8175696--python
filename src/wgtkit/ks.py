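"""Nei–Gojobori (1986) counting estimation of synonymous and nonsynonymous
divergence between codon-aligned coding sequences.

The estimator counts, for each codon, the fractional number of synonymous
(S) and nonsynonymous (N) sites — per position, the fraction of single-base
changes that preserve the encoded amino acid, renormalised over changes
that do not create a stop codon, so that S + N = 3 per codon exactly.
Differences between two aligned codons that differ at k positions are
averaged with equal weight over all k! mutational pathways, skipping
pathways that pass through a stop codon. The raw proportions p_s = Sd/S
and p_n = Nd/N are corrected for multiple hits with the Jukes–Cantor
formula d = -(3/4) ln(1 - (4/3) p), which is undefined (saturated) at
p >= 3/4.

Ks serves as a proxy for the age of a duplication or speciation event;
collections of per-pair Ks values ("age distributions") are the input to
whole-genome-duplication peak detection in :mod:`wgtkit.wgd`.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .errors import InputError, SaturationError

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
_BASES = "ACGT"


@dataclasses.dataclass(frozen=True)
class CodonPair:
    """Two aligned, in-frame, stop-free coding sequences."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise InputError(f"aligned sequences differ in length ({len(a)} vs {len(b)})")
        if len(a) % 3 != 0:
            raise InputError(f"sequence length {len(a)} is not a multiple of 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclasses.dataclass(frozen=True)
class KsEstimate:
    """Per-pair site and difference counts with corrected distances.

    ``ks``/``ka`` are NaN when the corresponding proportion is saturated
    (p >= 3/4) or when the site count is zero; ``saturated`` reports
    synonymous saturation, the condition under which a pair is dropped
    from age distributions.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    p_s: float
    p_n: float
    ks: float
    ka: float
    saturated: bool
    n_codons: int
    n_skipped: int = 0


@dataclasses.dataclass
class KsDistribution:
    """A sample of Ks values of one kind (paranome, anchors or orthologs)."""

    values: np.ndarray
    labels: list[str]
    kind: str = "paranome"
    saturated_count: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values < 0).any():
            raise InputError("Ks values must be nonnegative")

    def __len__(self) -> int:
        return int(self.values.size)


def _validate_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise InputError(f"{codon!r} is not an unambiguous DNA codon")
    if codon in STOP_CODONS:
        raise InputError(f"{codon!r} is a stop codon")
    return codon


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Fractional synonymous and nonsynonymous site counts of one codon.

    At each of the three positions the fraction of single-base changes
    that are synonymous is computed over the changes that yield a sense
    codon (changes to stop codons are excluded and the position is
    renormalised over what remains), then summed. The two fractions add
    to exactly 3.
    """
    codon = _validate_codon(codon)
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_sense = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            n_sense += 1
            if CODON_TO_AA[alt] == aa:
                n_syn += 1
        if n_sense:
            syn += n_syn / n_sense
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two sense codons,
    averaged with equal weight over stop-free mutational pathways."""
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0
    pathways: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(positions):
        current = codon_a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
                sd = nd = math.nan
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        (blocked if through_stop else pathways).append((sd, nd))
    if not pathways:
        # All orderings pass through a stop; fall back to counting every
        # step of every ordering, treating stop intermediates as
        # nonsynonymous steps (vanishingly rare in real alignments).
        pathways = []
        for order in itertools.permutations(positions):
            current = codon_a
            sd = nd = 0.0
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                if nxt in STOP_CODONS or CODON_TO_AA.get(nxt) != CODON_TO_AA.get(current):
                    nd += 1
                else:
                    sd += 1
                current = nxt
            pathways.append((sd, nd))
    sd = sum(p[0] for p in pathways) / len(pathways)
    nd = sum(p[1] for p in pathways) / len(pathways)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - (4/3) p).

    Returns NaN at or beyond saturation (p >= 3/4); strictly increasing
    in p on [0, 3/4).
    """
    if p < 0:
        raise InputError(f"proportion {p} < 0")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p) + 0.0


def ng86_pairwise(pair: CodonPair | tuple[str, str]) -> KsEstimate:
    """Estimate Ks and Ka for one codon-aligned pair.

    Codons containing a base outside {A,C,G,T} in either sequence are
    skipped entirely (sites and differences). An internal stop codon is
    an input error.
    """
    if not isinstance(pair, CodonPair):
        pair = CodonPair(*pair)
    s_a = s_b = 0.0
    sd = nd = 0.0
    n_skipped = 0
    for codon_a, codon_b in pair.codons():
        if any(b not in _BASES for b in codon_a + codon_b):
            n_skipped += 1
            continue
        if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
            raise InputError(f"internal stop codon in pair ({codon_a}/{codon_b})")
        s_a += ng86_site_counts(codon_a)[0]
        s_b += ng86_site_counts(codon_b)[0]
        d = _codon_diffs(codon_a, codon_b)
        sd += d[0]
        nd += d[1]
    n_counted = pair.n_codons - n_skipped
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_counted - S
    p_s = sd / S if S > 0 else math.nan
    p_n = nd / N if N > 0 else math.nan
    ks = jukes_cantor(p_s) if S > 0 else math.nan
    ka = jukes_cantor(p_n) if N > 0 else math.nan
    saturated = bool(S > 0 and p_s >= 0.75)
    return KsEstimate(S, N, sd, nd, p_s, p_n, ks, ka, saturated, pair.n_codons, n_skipped)


def build_distribution(
    pairs: Sequence[CodonPair | tuple[str, str]],
    kind: str = "paranome",
    labels: Sequence[str] | None = None,
) -> KsDistribution:
    """Assemble a Ks age distribution from codon-aligned pairs.

    One value per non-saturated pair; saturated pairs are excluded and
    counted in ``saturated_count``. No range filtering happens here —
    that belongs to peak detection.
    """
    if labels is None:
        labels = [f"pair{i}" for i in range(len(pairs))]
    values: list[float] = []
    kept: list[str] = []
    n_sat = 0
    for label, pair in zip(labels, pairs):
        est = ng86_pairwise(pair)
        if est.saturated or math.isnan(est.ks):
            n_sat += 1
            continue
        values.append(est.ks)
        kept.append(label)
    if not values:
        warnings.warn(f"all {len(pairs)} pairs saturated or undefined; empty {kind} distribution")
    return KsDistribution(np.asarray(values), kept, kind, n_sat)


def distribution_to_frame(
    pairs: Sequence[CodonPair | tuple[str, str]],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-pair estimates as a (pair_id, ks, ka, saturated) table."""
    if labels is None:
        labels = [f"pair{i}" for i in range(len(pairs))]
    rows = []
    for label, pair in zip(labels, pairs):
        est = ng86_pairwise(pair)
        rows.append({"pair_id": label, "ks": est.ks, "ka": est.ka, "saturated": est.saturated})
    return pd.DataFrame(rows, columns=["pair_id", "ks", "ka", "saturated"])


def _best_hits(table: pd.DataFrame) -> dict[str, str]:
    """Best subject per query: highest bitscore, ties broken by lower
    e-value then lexicographic subject id. Row order never matters."""
    ranked = table.sort_values(
        ["bitscore", "evalue", "subject"], ascending=[False, True, True], kind="mergesort"
    )
    return ranked.drop_duplicates("query", keep="first").set_index("query")["subject"].to_dict()


def rbh_orthologs(ab: pd.DataFrame, ba: pd.DataFrame) -> list[tuple[str, str]]:
    """One-to-one orthologs by reciprocal best hit.

    A pair (a, b) is returned iff b is a's best subject in the a->b table
    and a is b's best subject in the b->a table. The result is sorted by
    the first id and is invariant to input row order.
    """
    if ab.empty or ba.empty:
        return []
    best_ab = _best_hits(ab)
    best_ba = _best_hits(ba)
    pairs = [
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    ]
    return sorted(pairs)
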