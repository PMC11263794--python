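"""Exact binomial tests of nuclear localization category counts.

Microscopy scoring yields, per genotype, the number of nuclei falling into a
category (chromocenter accumulation vs diffuse signal; presence vs absence
of intranucleolar foci). Mutant counts are tested against the WT observed
frequency taken as a fixed null probability, with the exact two-sided
binomial test (minimum-likelihood method): the p-value sums the null
probabilities of every outcome no more likely than the observed one.

Using the WT sample to fix p0 is a convention, not a two-proportion test;
output tables carry a note saying so.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .compstats import TestResult
from .errors import DegenerateNullError, InvalidDataError

logger = logging.getLogger(__name__)

#: Relative slack when comparing point probabilities, so ties produced by
#: floating-point noise count as "no more likely".
_RELATIVE_GAMMA = 1e-7


def counts_from_percent(percent: float, n_total: int) -> int:
    """Reconstruct an integer count from a printed percentage and n."""
    if not (0.0 <= percent <= 100.0):
        raise InvalidDataError(f"percent {percent} outside [0, 100]")
    if n_total < 1:
        raise InvalidDataError("n_total must be >= 1")
    count = int(round(percent / 100.0 * n_total))
    if abs(count / n_total - percent / 100.0) > 0.5 / n_total:
        logger.warning(
            "percent %.1f%% of n=%d is not consistent with any integer count",
            percent,
            n_total,
        )
    return count


def binomial_vs_reference(k: int, n: int, p0: float) -> TestResult:
    """Exact two-sided binomial test of k successes out of n against p0.

    Minimum-likelihood method: p = sum over outcomes j of Pr(j | n, p0)
    for every j with Pr(j) <= Pr(k), capped at 1.
    """
    if not (0 <= k <= n):
        raise InvalidDataError(f"k={k} outside [0, n={n}]")
    if not (0.0 < p0 < 1.0):
        raise DegenerateNullError("p0 must lie strictly between 0 and 1")
    j = np.arange(n + 1)
    pmf = stats.binom.pmf(j, n, p0)
    p_obs = pmf[k]
    p = float(min(1.0, pmf[pmf <= p_obs * (1 + _RELATIVE_GAMMA)].sum()))
    return TestResult(
        quantity=f"{k}/{n} vs p0={p0:.6g}",
        comparison="exact two-sided binomial (minimum-likelihood)",
        statistic=float(k),
        df=n,
        p=p,
    )


def localization_tests(
    counts: pd.DataFrame, reference: str = "WT"
) -> pd.DataFrame:
    """Run the binomial tests for every genotype x category against the
    reference genotype's observed frequency.

    ``counts`` columns: genotype, category, n_total and either count or
    percent (count preferred; percent reconstructed via
    :func:`counts_from_percent`).
    """
    df = counts.copy()
    if "count" not in df.columns:
        if "percent" not in df.columns:
            raise InvalidDataError("counts table needs a count or percent column")
        df["count"] = [
            counts_from_percent(p, n) for p, n in zip(df["percent"], df["n_total"])
        ]
    else:
        df["count"] = df["count"].astype(int)

    ref = df[df["genotype"] == reference].set_index("category")
    if ref.empty:
        raise InvalidDataError(f"reference genotype {reference!r} absent from table")
    rows = []
    for _, rec in df[df["genotype"] != reference].iterrows():
        cat = rec["category"]
        if cat not in ref.index:
            raise InvalidDataError(f"category {cat!r} missing for reference")
        p0 = ref.loc[cat, "count"] / ref.loc[cat, "n_total"]
        res = binomial_vs_reference(int(rec["count"]), int(rec["n_total"]), p0)
        rows.append(
            {
                "genotype": rec["genotype"],
                "category": cat,
                "count": int(rec["count"]),
                "n_total": int(rec["n_total"]),
                "p0": p0,
                "p": res.p,
                "significant_0.05": res.p < 0.05,
                "note": f"null p0 = {reference} observed frequency (convention)",
            }
        )
    return pd.DataFrame(rows)
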