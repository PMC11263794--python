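"""Compositional statistics for modified-form abundances.

Peak-area-derived percentages are compositions in the Aitchison sense: only
relative information, constant-sum constraint, spurious negative correlation
between raw parts. All tests therefore run on log-ratio coordinates:

* ilr for multivariate comparisons (Hotelling's T2 on amalgamated
  acetylation/methylation levels),
* the two-part alr on a log2 scale (one form against the sum of all others)
  for univariate t tests and one-way ANOVA with Tukey HSD letters.

Zeros and missing values are imputed first by deterministic multiplicative
replacement (a fraction of the smallest observed abundance of that part
within the sample's group), after which every row is re-closed to 100%.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigError,
    InvalidDataError,
    MustImputeFirstError,
    SingularCovarianceError,
)

logger = logging.getLogger(__name__)

MARK_CLASSES = {
    "acetylation": ("ac",),
    "methylation": ("me1", "me2", "me3"),
}


@dataclass
class TestResult:
    """Outcome of one statistical comparison."""

    quantity: str
    comparison: str
    statistic: float
    df: object
    p: float
    adjusted_p: Optional[float] = None


def close_rows(matrix: np.ndarray, total: float = 100.0) -> np.ndarray:
    """Rescale each row to the given constant sum."""
    matrix = np.asarray(matrix, dtype=float)
    sums = matrix.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise InvalidDataError("row with non-positive sum cannot be closed")
    return total * matrix / sums


def impute_missing(
    matrix: pd.DataFrame,
    groups: pd.Series,
    delta_factor: float = 0.65,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace missing/zero parts by delta_factor x the smallest observed
    positive abundance of that part within the same group, then re-close
    rows to 100.

    Returns (imputed matrix, boolean flags of imputed cells). A part with
    no positive observation in any group is dropped with a warning.
    """
    mat = matrix.copy().astype(float)
    groups = groups.reindex(mat.index)
    dead = [c for c in mat.columns if not (mat[c].fillna(0) > 0).any()]
    if dead:
        logger.warning("dropping part(s) never observed: %s", dead)
        mat = mat.drop(columns=dead)

    flags = mat.isna() | (mat <= 0)
    for grp, idx in mat.groupby(groups.loc[mat.index]).groups.items():
        block = mat.loc[idx]
        for col in mat.columns:
            col_vals = block[col]
            needs = col_vals.isna() | (col_vals <= 0)
            if not needs.any():
                continue
            observed = col_vals[col_vals > 0]
            if observed.empty:
                # fall back to the global minimum of the part
                observed = mat[col][mat[col] > 0]
            mat.loc[col_vals.index[needs], col] = delta_factor * observed.min()
    closed = pd.DataFrame(
        close_rows(mat.values), index=mat.index, columns=mat.columns
    )
    return closed, flags


def amalgamate(
    matrix: pd.DataFrame,
    form_mods: Mapping[str, Sequence[str]],
    mark_class: str,
) -> pd.DataFrame:
    """Sum forms into (modified, nonmodified) parts for one mark class.

    ``form_mods`` maps each column (form) to the modification kinds it
    carries; a form counts as modified when it carries at least one
    modification of the class.
    """
    if mark_class not in MARK_CLASSES:
        raise ConfigError(
            f"unknown mark class {mark_class!r}; expected one of {sorted(MARK_CLASSES)}"
        )
    kinds = set(MARK_CLASSES[mark_class])
    modified_cols = [
        c for c in matrix.columns if kinds & set(form_mods.get(c, ()))
    ]
    other_cols = [c for c in matrix.columns if c not in modified_cols]
    out = pd.DataFrame(index=matrix.index)
    out["modified"] = matrix[modified_cols].sum(axis=1) if modified_cols else 0.0
    out["nonmodified"] = matrix[other_cols].sum(axis=1) if other_cols else 0.0
    return out


def _ilr_basis(d: int) -> np.ndarray:
    """Orthonormal sequential binary partition basis: balance i contrasts
    part i against parts i+1..D."""
    basis = np.zeros((d - 1, d))
    for i in range(d - 1):
        r = d - i - 1  # parts remaining after part i
        basis[i, i] = np.sqrt(r / (r + 1))
        basis[i, i + 1 :] = -np.sqrt(r / (r + 1)) / r
    return basis


def ilr_transform(rows: np.ndarray) -> np.ndarray:
    """Isometric log-ratio coordinates (D parts -> D-1 reals per row)."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if np.any(rows <= 0):
        raise MustImputeFirstError("ilr requires strictly positive parts")
    logs = np.log(rows)
    coords = logs @ _ilr_basis(rows.shape[1]).T
    return coords if coords.shape[0] > 1 else coords[0]


def ilr_inverse(coords: np.ndarray, total: float = 100.0) -> np.ndarray:
    """Invert ilr coordinates back to a closed composition."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    basis = _ilr_basis(coords.shape[1] + 1)
    comp = np.exp(coords @ basis)
    comp = close_rows(comp, total)
    return comp if comp.shape[0] > 1 else comp[0]


def alr2_log2(part: float | np.ndarray) -> float | np.ndarray:
    """log2 of one part against the rest of a two-part composition (%)."""
    part = np.asarray(part, dtype=float)
    if np.any(part <= 0) or np.any(part >= 100):
        raise MustImputeFirstError("alr2 requires 0 < part < 100; impute first")
    out = np.log2(part / (100.0 - part))
    return float(out) if out.ndim == 0 else out


def hotelling_t2(group_a: np.ndarray, group_b: np.ndarray) -> TestResult:
    """Two-sample Hotelling T2 with the exact F reference distribution.

    Inputs are ilr coordinates (n x p). Requires n_a + n_b - 2 > p and an
    invertible pooled covariance.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise InvalidDataError("dimension mismatch between groups")
    na, nb, p = a.shape[0], b.shape[0], a.shape[1]
    if na + nb - 2 <= p - 1 or na < 2 or nb < 2:
        raise InvalidDataError("too few samples for the dimension")
    diff = a.mean(axis=0) - b.mean(axis=0)
    pooled = ((na - 1) * np.cov(a, rowvar=False, ddof=1).reshape(p, p)
              + (nb - 1) * np.cov(b, rowvar=False, ddof=1).reshape(p, p)) / (na + nb - 2)
    try:
        solve = np.linalg.solve(pooled, diff)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "pooled covariance singular; reduce the number of parts"
        ) from exc
    if np.linalg.cond(pooled) > 1e12:
        raise SingularCovarianceError(
            "pooled covariance near-singular; reduce the number of parts"
        )
    t2 = (na * nb) / (na + nb) * float(diff @ solve)
    df1, df2 = p, na + nb - 1 - p
    f_stat = t2 * df2 / ((na + nb - 2) * p)
    pval = float(stats.f.sf(f_stat, df1, df2))
    return TestResult(
        quantity="ilr coordinates",
        comparison="two-sample Hotelling T2",
        statistic=t2,
        df=(df1, df2),
        p=pval,
    )


def two_condition_ttest(
    values_a: Sequence[float], values_b: Sequence[float], quantity: str = ""
) -> TestResult:
    """Two-sided pooled-variance (Student) t test on log-ratio values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidDataError("t test requires at least two values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] != b[0]:
        logger.warning("degenerate zero variance with unequal means; p set to 0")
        return TestResult(quantity, "t test", np.inf, a.size + b.size - 2, 0.0)
    stat, p = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(
        quantity=quantity,
        comparison="two-sided Student t",
        statistic=float(stat),
        df=a.size + b.size - 2,
        p=float(p),
    )


def compact_letter_display(
    labels: Sequence[str], nonsig_pairs: set[frozenset[str]]
) -> dict[str, str]:
    """Assign letters so two groups share a letter iff their pairwise
    comparison is non-significant.

    Letters correspond to maximal cliques of the non-significance graph
    (groups not significantly different from each other), the standard
    construction behind compact letter displays.
    """
    g = nx.Graph()
    g.add_nodes_from(labels)
    for pair in nonsig_pairs:
        x, y = tuple(pair)
        g.add_edge(x, y)
    cliques = sorted(
        (sorted(c, key=list(labels).index) for c in nx.find_cliques(g)),
        key=lambda c: list(labels).index(c[0]),
    )
    letters = {lab: "" for lab in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, clique in enumerate(cliques):
        for lab in clique:
            letters[lab] += alphabet[i]
    return letters


def anova_tukey(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05, quantity: str = ""
) -> tuple[TestResult, list[TestResult], dict[str, str]]:
    """One-way ANOVA, Tukey HSD pairwise comparisons, and letter groupings."""
    if len(groups) < 2:
        raise InvalidDataError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise InvalidDataError(f"group {name!r} has fewer than two values")
    labels = list(groups)
    k = len(labels)
    f_stat, f_p = stats.f_oneway(*[np.asarray(groups[g], float) for g in labels])
    n = sum(len(v) for v in groups.values())
    df_err = n - k
    omnibus = TestResult(
        quantity=quantity,
        comparison="one-way ANOVA",
        statistic=float(f_stat),
        df=(k - 1, df_err),
        p=float(f_p),
    )
    mse = sum(
        np.sum((np.asarray(v, float) - np.mean(v)) ** 2) for v in groups.values()
    ) / df_err
    means = {g: float(np.mean(groups[g])) for g in labels}
    pairwise = []
    nonsig: set[frozenset[str]] = set()
    for g1, g2 in itertools.combinations(labels, 2):
        diff = means[g2] - means[g1]
        n1, n2 = len(groups[g1]), len(groups[g2])
        # Tukey-Kramer: studentized range of the pairwise mean difference
        se_q = np.sqrt(mse / 2.0 * (1.0 / n1 + 1.0 / n2))
        if se_q > 0:
            q_stat = abs(diff) / se_q
            adj_p = float(np.clip(stats.studentized_range.sf(q_stat, k, df_err), 0, 1))
            # unadjusted reference: Fisher-LSD t with the same pooled MSE
            p_unadj = float(2 * stats.t.sf(q_stat / np.sqrt(2.0), df_err))
        else:
            adj_p = 0.0 if diff != 0 else 1.0
            p_unadj = adj_p
        res = TestResult(
            quantity=quantity,
            comparison=f"{g1} vs {g2} (Tukey HSD)",
            statistic=diff,  # mean difference
            df=float(df_err),
            p=p_unadj,
            adjusted_p=adj_p,
        )
        pairwise.append(res)
        if adj_p >= alpha:
            nonsig.add(frozenset((g1, g2)))
    letters = compact_letter_display(labels, nonsig)
    return omnibus, pairwise, letters
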