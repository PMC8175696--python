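"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOPS = set(_TABLE.stop_codons)
SENSE = sorted(_TABLE.forward_table)


def translate(codon: str) -> str:
    return "*" if codon in STOPS else _TABLE.forward_table[codon]


def oracle_site_counts(codon: str) -> tuple[float, float]:
    """Brute-force NG86 site counts: per position, enumerate the three
    alternative bases, drop changes to stops, renormalise."""
    syn = 0.0
    aa = translate(codon)
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1 :] for b in "ACGT" if b != codon[pos]]
        sense = [c for c in alts if c not in STOPS]
        if sense:
            syn += sum(translate(c) == aa for c in sense) / len(sense)
    return syn, 3.0 - syn


def oracle_codon_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Brute-force pathway enumeration between two sense codons: walk every
    ordering of the differing positions, drop orderings through stops,
    average syn/nonsyn step counts over what remains."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = codon_a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                ok = False
                break
            if translate(nxt) == translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        return float("nan"), float("nan")
    return (sum(p[0] for p in paths) / len(paths), sum(p[1] for p in paths) / len(paths))


def oracle_ng86(seq_a: str, seq_b: str) -> dict:
    """Brute-force NG86 estimate for a codon-aligned pair."""
    import math

    s_a = s_b = sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        s_a += oracle_site_counts(ca)[0]
        s_b += oracle_site_counts(cb)[0]
        d = oracle_codon_diffs(ca, cb)
        sd += d[0]
        nd += d[1]
    S = (s_a + s_b) / 2
    N = 3 * (len(seq_a) // 3) - S
    p_s = sd / S if S else float("nan")
    ks = float("nan") if p_s >= 0.75 else -0.75 * math.log(1 - 4 * p_s / 3)
    return {"S": S, "N": N, "Sd": sd, "Nd": nd, "p_s": p_s, "ks": ks}


def oracle_pi(seq: str, pka: dict) -> float:
    """Charge-bisection oracle on a fine pH grid (independent of the
    package's bisection): smallest grid pH where net charge turns negative."""
    grid = np.linspace(0, 14, 140001)
    charges = 1.0 / (1.0 + 10 ** (grid - pka["Nterm"]))
    for aa in "KRH":
        charges += seq.count(aa) / (1.0 + 10 ** (grid - pka[aa]))
    charges -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - grid))
    for aa in "DECY":
        charges -= seq.count(aa) / (1.0 + 10 ** (pka[aa] - grid))
    idx = np.argmax(charges < 0)
    return float(grid[idx])


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_sense_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(SENSE[i] for i in rng.integers(0, len(SENSE), size=n))
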