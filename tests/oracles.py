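"""Independent reference implementations used only as test oracles.

Each is written straight from first principles (scalar loops, exact
rational arithmetic, table lookups) and shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

# --- Weir & Cockerham (1984) variance components, general-r formulas ----

def wc_components_oracle(groups: list[list[int]]) -> tuple[float, float, float]:
    """(a, b, c) for one biallelic locus from per-group genotype code lists
    (0/1/2 alt-allele dosage, -1 missing).  Written from the published
    general-r formulas with explicit loops."""
    r = len(groups)
    n, p, h = [], [], []
    for grp in groups:
        called = [g for g in grp if g != -1]
        ni = len(called)
        n.append(ni)
        p.append(sum(called) / (2.0 * ni))
        h.append(sum(1 for g in called if g == 1) / ni)
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (s2 - (1.0 / (nbar - 1))
                       * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def wc_multilocus_oracle(loci: list[list[list[int]]]) -> float:
    """Ratio-of-sums over loci of per-locus (a, b, c)."""
    num = den = 0.0
    for groups in loci:
        a, b, c = wc_components_oracle(groups)
        num += a
        den += a + b + c
    return num / den


# --- standard genetic code, independent table ---------------------------

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_oracle(cds: str) -> str:
    return "".join(CODON_TABLE[cds[i:i + 3]]
                   for i in range(0, len(cds) - len(cds) % 3, 3))


# --- two-tailed Fisher exact test by full enumeration --------------------

def fisher_oracle(table: list[list[int]], tie_rel_tol: float = 1e-7) -> float:
    """Exact-rational enumeration of all tables with the observed margins;
    p sums point probabilities <= observed * (1 + tol)."""
    (x11, x12), (x21, x22) = table
    r1, c1 = x11 + x12, x11 + x21
    n = x11 + x12 + x21 + x22
    if 0 in (r1, n - r1, c1, n - c1):
        return 1.0

    def point(k: int) -> Fraction:
        return Fraction(math.comb(c1, k) * math.comb(n - c1, r1 - k),
                        math.comb(n, r1))

    obs = point(x11)
    cut = obs * (Fraction(10 ** 7 + 1, 10 ** 7))  # exact 1 + 1e-7
    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    p = sum((pk for k in range(lo, hi + 1)
             if (pk := point(k)) <= cut), Fraction(0))
    return float(min(p, Fraction(1)))


# --- brute-force minimal sample size --------------------------------------

def min_n_oracle(p: float, alpha: float) -> int:
    n = 1
    while (1.0 - p) ** (2 * n) > alpha:
        n += 1
    return n
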