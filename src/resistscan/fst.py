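"""Weir & Cockerham (1984) F_ST between two groups of diploids, the
ratio-of-sums multi-locus combination, a genome-resampling empirical null
for a candidate interval, and the complete-differentiation scan.

Estimator
---------
For a biallelic locus scored in r = 2 groups with sample sizes n_i, alt
allele frequencies p_i and observed heterozygote frequencies h_i, the
variance components are

    n_bar = mean n_i,  n_T = n_1 + n_2,
    n_c   = n_T - (n_1^2 + n_2^2) / n_T,
    p_bar = (n_1 p_1 + n_2 p_2) / n_T,
    s^2   = [n_1 (p_1 - p_bar)^2 + n_2 (p_2 - p_bar)^2] / n_bar,
    h_bar = (n_1 h_1 + n_2 h_2) / n_T,

    a = (n_bar / n_c) * (s^2 - (p_bar q_bar - s^2/2 - h_bar/4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar q_bar - s^2/2 - (2 n_bar - 1)/(4 n_bar) h_bar)
    c = h_bar / 2

and theta = a / (a + b + c).  Per-locus theta is deliberately left
untruncated (the estimator is unbiased, not non-negative); the multi-locus
estimate is the ratio of sums sum(a) / sum(a+b+c) over informative loci,
the "weighted" convention of the usual command-line implementation.

Empirical null
--------------
The observed multi-locus theta over a candidate interval of length L is
compared with theta over windows of the same length drawn uniformly from
the genome: a chromosome is chosen with probability proportional to its
number of valid start positions (length - L + 1), then a start uniformly;
windows containing no informative SNP are redrawn and counted.  Draws use
a counter-based Philox generator so the replicate stream is independent of
any batching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import GeneModel, GenotypeMatrix, HET, MISSING, ValidationError

THETA_ONE_TOL = 1e-12


class UninformativeLocusError(ValidationError):
    pass


@dataclass(frozen=True)
class FstComponents:
    """Variance components of one locus (a: among-group, b: among
    individuals within groups, c: within individuals)."""
    a: float
    b: float
    c: float
    n1: int
    n2: int
    p1: float
    p2: float
    h1: float
    h2: float
    informative: bool

    @property
    def theta(self) -> Optional[float]:
        denom = self.a + self.b + self.c
        if not self.informative or denom == 0.0:
            return None
        return self.a / denom


def _group_arrays(calls: np.ndarray, labels: np.ndarray
                  ) -> tuple[np.ndarray, ...]:
    """Per-site n, p, h for the two groups encoded in boolean ``labels``
    (True = group 1).  ``calls`` is (L, n) int8."""
    out = []
    for mask in (labels, ~labels):
        sub = calls[:, mask]
        called = sub != MISSING
        n = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            alt = np.where(called, sub, 0).sum(axis=1)
            p = alt / (2 * n)
            h = np.where(called, sub == HET, False).sum(axis=1) / n
        out += [n, p, h]
    return tuple(out)


def fst_components_array(calls: np.ndarray, labels: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                    np.ndarray]:
    """Vectorized (a, b, c, informative) over all sites.

    A site is informative when both groups have >= 2 called genotypes and
    the pooled frequency is polymorphic (monomorphic sites carry no
    information about differentiation and are excluded from sums, matching
    the behaviour of the standard tooling).
    """
    n1, p1, h1, n2, p2, h2 = _group_arrays(calls, labels)
    nT = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = nT / 2.0
        nc = nT - (n1.astype(float) ** 2 + n2.astype(float) ** 2) / nT
        pbar = (n1 * p1 + n2 * p2) / nT
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / nT
        pq = pbar * (1.0 - pbar)
        a = (nbar / nc) * (s2 - (pq - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pq - s2 / 2.0
                                     - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    informative = (n1 >= 2) & (n2 >= 2) & (pbar > 0) & (pbar < 1)
    a = np.where(informative, a, 0.0)
    b = np.where(informative, b, 0.0)
    c = np.where(informative, c, 0.0)
    return a, b, c, informative


def fst_per_locus(calls: np.ndarray, labels: np.ndarray) -> FstComponents:
    """Weir-Cockerham components of a single locus.

    ``calls``: (n_samples,) int8 genotype codes; ``labels``: boolean,
    True for group 1.
    """
    calls = np.asarray(calls, dtype=np.int8).reshape(1, -1)
    labels = np.asarray(labels, dtype=bool)
    a, b, c, inf = fst_components_array(calls, labels)
    n1, p1, h1, n2, p2, h2 = (x[0] for x in _group_arrays(calls, labels))
    return FstComponents(float(a[0]), float(b[0]), float(c[0]),
                         int(n1), int(n2), float(p1), float(p2),
                         float(h1), float(h2), bool(inf[0]))


def fst_multilocus(components: Sequence[FstComponents] | tuple[np.ndarray, ...]
                   ) -> float:
    """Ratio-of-sums multi-locus theta over informative loci.

    Accepts either a list of :class:`FstComponents` or the array tuple
    returned by :func:`fst_components_array`.  Raises when no informative
    locus remains (an undefined estimate is never silently reported as 0).
    """
    if isinstance(components, tuple):
        a, b, c, inf = components
        num = float(a[inf].sum())
        den = float((a[inf] + b[inf] + c[inf]).sum())
        n_inf = int(inf.sum())
    else:
        inf_list = [f for f in components if f.informative]
        num = sum(f.a for f in inf_list)
        den = sum(f.a + f.b + f.c for f in inf_list)
        n_inf = len(inf_list)
    if n_inf == 0 or den == 0.0:
        raise UninformativeLocusError(
            "multi-locus F_ST undefined: no informative polymorphic locus")
    return num / den


def mean_of_ratios(components: Sequence[FstComponents]) -> float:
    """Unweighted mean of per-locus theta (non-default alternative)."""
    thetas = [f.theta for f in components
              if f.informative and f.theta is not None]
    if not thetas:
        raise UninformativeLocusError("no informative locus")
    return float(np.mean(thetas))


# ---------------------------------------------------------------------------
# Genome-resampling empirical null
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    observed_theta: float
    replicate_thetas: np.ndarray
    n_requested: int
    n_valid: int
    n_redrawn: int
    locus_length: int
    seed: int

    @property
    def p_plain(self) -> float:
        """#(replicate >= observed) / n_valid, ties counted (tol 1e-12)."""
        k = int((self.replicate_thetas >= self.observed_theta
                 - THETA_ONE_TOL).sum())
        return k / self.n_valid

    @property
    def p_conservative(self) -> float:
        k = int((self.replicate_thetas >= self.observed_theta
                 - THETA_ONE_TOL).sum())
        return (k + 1) / (self.n_valid + 1)

    def summary(self) -> dict:
        return {"observed_theta": self.observed_theta,
                "n_requested": self.n_requested, "n_valid": self.n_valid,
                "n_redrawn": self.n_redrawn,
                "locus_length": self.locus_length, "seed": self.seed,
                "p_plain": self.p_plain,
                "p_conservative": self.p_conservative,
                "replicate_mean": float(self.replicate_thetas.mean()),
                "replicate_q95": float(np.quantile(self.replicate_thetas,
                                                   0.95))}


def resampling_null(gm: GenotypeMatrix, labels: np.ndarray,
                    target_interval: tuple[str, int, int],
                    genome_extent: dict[str, int], n_reps: int,
                    seed: int, exclude_target: bool = False,
                    redraw_budget_factor: int = 10) -> NullDistribution:
    """Empirical null for multi-locus theta over a candidate interval.

    ``target_interval`` is (chrom, start0, end0) half-open; its length L
    defines the resampled window size.  Windows with zero informative SNPs
    are redrawn (scoring them 0 would deflate the null); the total redraw
    budget is ``redraw_budget_factor * n_reps`` extra draws.
    """
    chrom_t, start_t, end_t = target_interval
    L = end_t - start_t
    if L <= 0 or n_reps < 1:
        raise ValidationError("empty target interval or n_reps < 1")
    if chrom_t not in genome_extent or end_t > genome_extent[chrom_t]:
        raise ValidationError("target interval outside genome extent")
    labels = np.asarray(labels, dtype=bool)

    a, b, c, inf = fst_components_array(gm.calls, labels)
    target_mask = gm.in_region(chrom_t, start_t, end_t)
    obs = fst_multilocus((a[target_mask], b[target_mask], c[target_mask],
                          inf[target_mask]))

    # per-chromosome sorted informative-site positions with component prefix sums
    chrom_data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    pos0_all = gm.sites["pos"].to_numpy() - 1
    chroms_all = gm.sites["chrom"].to_numpy()
    for chrom in genome_extent:
        m = (chroms_all == chrom) & inf
        pos = pos0_all[m]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        cum_a = np.concatenate([[0.0], np.cumsum(a[m][order])])
        cum_abc = np.concatenate([[0.0], np.cumsum((a + b + c)[m][order])])
        chrom_data[chrom] = (pos, cum_a, cum_abc)

    chrom_names = list(genome_extent)
    placeable = np.array([max(genome_extent[ch] - L + 1, 0)
                          for ch in chrom_names], dtype=float)
    if placeable.sum() <= 0:
        raise ValidationError(
            f"no chromosome can host a window of length {L}")
    probs = placeable / placeable.sum()

    rng = np.random.Generator(np.random.Philox(key=seed))
    thetas = np.empty(n_reps)
    n_valid = n_redrawn = 0
    budget = redraw_budget_factor * n_reps
    batch = max(1024, n_reps // 4)
    while n_valid < n_reps:
        ci = rng.choice(len(chrom_names), size=batch, p=probs)
        starts = np.floor(rng.random(batch)
                          * placeable[ci]).astype(np.int64)
        for k in range(batch):
            if n_valid >= n_reps:
                break
            chrom = chrom_names[ci[k]]
            s = int(starts[k])
            if (exclude_target and chrom == chrom_t
                    and s < end_t and s + L > start_t):
                n_redrawn += 1
            else:
                pos, cum_a, cum_abc = chrom_data[chrom]
                lo = np.searchsorted(pos, s, side="left")
                hi = np.searchsorted(pos, s + L, side="left")
                den = cum_abc[hi] - cum_abc[lo]
                if hi > lo and den != 0.0:
                    thetas[n_valid] = (cum_a[hi] - cum_a[lo]) / den
                    n_valid += 1
                    continue
                n_redrawn += 1
            if n_redrawn > budget:
                raise ValidationError(
                    f"redraw budget exhausted ({n_redrawn} empty windows for "
                    f"{n_valid} valid replicates); use longer windows or "
                    f"denser data")
    return NullDistribution(observed_theta=obs, replicate_thetas=thetas,
                            n_requested=n_reps, n_valid=n_valid,
                            n_redrawn=n_redrawn, locus_length=L, seed=seed)


# ---------------------------------------------------------------------------
# Complete-differentiation scan
# ---------------------------------------------------------------------------

def complete_differentiation_scan(gm: GenotypeMatrix, labels: np.ndarray,
                                  region: tuple[str, int, int],
                                  gene_models: dict[str, GeneModel]
                                  ) -> pd.DataFrame:
    """All SNPs in a region with theta = 1 (within 1e-12), labeled by
    coding context (exonic / intronic / intergenic).

    theta = 1 requires the two groups fixed for different alleles with no
    heterozygote; columns: chrom, pos, ref, alt, theta, coding_context.
    """
    chrom, start0, end0 = region
    if end0 <= start0:
        raise ValidationError("empty region")
    mask = gm.in_region(chrom, start0, end0)
    sub = gm.subset_sites(mask)
    labels = np.asarray(labels, dtype=bool)
    a, b, c, inf = fst_components_array(sub.calls, labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(inf & ((a + b + c) != 0), a / (a + b + c), np.nan)
    rows = []
    for i in np.flatnonzero(inf & (theta >= 1.0 - THETA_ONE_TOL)):
        ch, pos, ref, alt = sub.site_key(int(i))
        context = "intergenic"
        for gmdl in gene_models.values():
            cls = gmdl.classify_position(ch, pos - 1)
            if cls == "exonic":
                context = "exonic"
                break
            if cls == "intronic":
                context = "intronic"
        rows.append((ch, pos, ref, alt, float(theta[i]), context))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "theta", "coding_context"])


def labels_from_popmap(gm: GenotypeMatrix, popmap, level: str,
                       group1: str, group2: str) -> np.ndarray:
    """Boolean labels (True = group1) from a population map column,
    restricted check that every sample belongs to one of the two groups."""
    col = popmap.table[level]
    vals = [col.get(s, None) for s in gm.samples]
    bad = sorted({v for v in vals if v not in (group1, group2)})
    if bad:
        raise ValidationError(
            f"samples outside groups {group1}/{group2}: levels {bad}")
    return np.array([v == group1 for v in vals])
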