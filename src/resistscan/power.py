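"""Analytic detection power for a resistance allele in a resequencing
sample of N diploids.

With 2N alleles sampled independently (binomial sampling: no inbreeding,
no pooling), an allele at population frequency p is missed entirely with
probability (1 - p)^(2N).  Evaluated in log space so tiny p and large N
stay accurate.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def miss_probability(p: float, n_diploids: int) -> float:
    """(1 - p)^(2N): probability that a sample of ``n_diploids`` diploid
    individuals contains no copy of an allele at frequency ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency {p} outside [0, 1]")
    if n_diploids < 0:
        raise ValueError("negative sample size")
    if n_diploids == 0:
        return 1.0
    if p == 1.0:
        return 0.0
    return math.exp(2 * n_diploids * math.log1p(-p))


def detection_probability(p: float, n_diploids: int) -> float:
    return 1.0 - miss_probability(p, n_diploids)


def min_sample_size(p: float, alpha: float) -> int:
    """Smallest N with (1 - p)^(2N) <= alpha.

    Closed form ceil(ln(alpha) / (2 ln(1 - p))), nudged against floating
    error so the boundary inequalities hold exactly.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(
            "allele frequency must be in (0, 1): p = 0 admits no finite "
            "sample size, p = 1 needs none")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n = max(1, math.ceil(math.log(alpha) / (2 * math.log1p(-p))))
    while miss_probability(p, n) > alpha:
        n += 1
    while n > 1 and miss_probability(p, n - 1) <= alpha:
        n -= 1
    return n


def power_curve(freqs, n_diploids: int) -> pd.DataFrame:
    """Miss/detection probabilities over a frequency grid (TSV-ready)."""
    freqs = np.asarray(freqs, dtype=float)
    miss = np.array([miss_probability(f, n_diploids) for f in freqs])
    return pd.DataFrame({"allele_frequency": freqs, "n_diploids": n_diploids,
                         "miss_probability": miss,
                         "detection_probability": 1.0 - miss})
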