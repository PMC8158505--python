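"""Gene-family CNV burden per cohort and the two-tailed exact test.

The burden summary pools gene-level duplication/deletion events across the
individuals of each cohort, per P450 clan, and also reports per-individual
means (pooled events are not independent observations, so both views are
emitted).  The two-tailed Fisher test sums, over all 2x2 tables with the
observed margins, the hypergeometric point probabilities not exceeding the
observed table's (with a 1e-7 relative tie tolerance, the convention of
the usual statistical environment); probabilities are evaluated in log
space so large totals remain exact to double precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from scipy.stats.contingency import odds_ratio as _conditional_or

from .model import CnvStateTable, PopulationMap, ValidationError

TIE_REL_TOL = 1e-7


def fisher_exact_two_tailed(table) -> tuple[float, float]:
    """Two-tailed Fisher exact test on a 2x2 table.

    Returns (conditional-MLE odds ratio, p).  A zero row or column margin
    makes the test degenerate: p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("need a 2x2 table of non-negative counts")
    r1, r2 = t.sum(axis=1)
    c1, c2 = t.sum(axis=0)
    n = t.sum()
    if n == 0:
        raise ValidationError("empty table")
    if 0 in (r1, r2, c1, c2):
        return np.nan, 1.0
    lo = max(0, r1 - c2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = hypergeom.logpmf(support, n, c1, r1)
    log_obs = hypergeom.logpmf(t[0, 0], n, c1, r1)
    keep = logp <= log_obs + np.log1p(TIE_REL_TOL)
    p = float(np.exp(logsumexp(logp[keep])))
    p = min(p, 1.0)
    orr = _conditional_or(t, kind="conditional")
    return float(orr.statistic), p


@dataclass
class BurdenSummary:
    """Per (cohort, clan) duplication/deletion event totals and means.

    ``table`` columns: cohort, clan, n_individuals, duplicated_total,
    deleted_total, duplicated_mean, deleted_mean.
    """

    table: pd.DataFrame

    def row(self, cohort: str, clan: str) -> pd.Series:
        df = self.table
        sel = df[(df["cohort"] == cohort) & (df["clan"] == clan)]
        if not len(sel):
            raise ValidationError(f"no burden row for ({cohort}, {clan})")
        return sel.iloc[0]

    @property
    def clans(self) -> list[str]:
        return sorted(self.table["clan"].unique())

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.table["cohort"].unique())


def burden(cnv: CnvStateTable, popmap: PopulationMap) -> BurdenSummary:
    """Count duplicated and deleted genes per individual, pooled by
    cohort and clan.  A gene counts once per individual regardless of the
    magnitude of its copy-number change."""
    missing = sorted(set(popmap.samples) - set(cnv.samples))
    if missing:
        raise ValidationError(f"samples missing from CNV table: {missing}")
    states = cnv.states.loc[popmap.samples]
    clans = pd.Series({g: cnv.clan_of_gene[g] for g in states.columns})
    cohorts = pd.Series({s: popmap.cohort(s) for s in states.index})

    rows = []
    for cohort in sorted(cohorts.unique()):
        samp = cohorts.index[cohorts == cohort]
        block = states.loc[samp]
        for clan in sorted(clans.unique()):
            genes = clans.index[clans == clan]
            sub = block[genes]
            dup = int((sub == "duplicated").to_numpy().sum())
            dele = int((sub == "deleted").to_numpy().sum())
            n = len(samp)
            rows.append((cohort, clan, n, dup, dele, dup / n, dele / n))
    return BurdenSummary(pd.DataFrame(
        rows, columns=["cohort", "clan", "n_individuals", "duplicated_total",
                       "deleted_total", "duplicated_mean", "deleted_mean"]))


def burden_contrast(summary: BurdenSummary, clan: str,
                    cohort_order: Optional[list[str]] = None
                    ) -> tuple[np.ndarray, float]:
    """2x2 contrast of pooled duplication vs deletion events between the
    two cohorts of one clan: rows = cohorts, columns = (duplicated,
    deleted); p from the two-tailed exact test."""
    cohorts = cohort_order or summary.cohorts
    if len(cohorts) != 2:
        raise ValidationError(f"need exactly two cohorts, have {cohorts}")
    if clan not in summary.clans:
        raise ValidationError(f"clan {clan!r} absent; have {summary.clans}")
    table = np.array([[int(summary.row(co, clan)["duplicated_total"]),
                       int(summary.row(co, clan)["deleted_total"])]
                      for co in cohorts])
    _, p = fisher_exact_two_tailed(table)
    return table, p
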