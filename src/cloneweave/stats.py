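"""Exact cohort-level association statistics for 2x2 tables.

The two-sided Fisher exact p-value uses the probability-mass ordering: the
sum of hypergeometric probabilities of all tables with the observed margins
that are at most as probable as the observed table (with a small relative
tolerance for floating-point ties). The phi coefficient is the Pearson
correlation of two binary indicators, computable directly from the table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

_TIE_RTOL = 1e-7


@dataclass
class ContingencyTable2x2:
    """Cell counts; rows = factor 1 yes/no, columns = factor 2 yes/no."""

    a: int
    b: int
    c: int
    d: int
    row_label: str = "factor1"
    col_label: str = "factor2"

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("cells must be non-negative integers")
        if self.n == 0:
            raise ValueError("table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class AssociationResult:
    table: ContingencyTable2x2
    p_fisher_two_sided: float
    phi: float | None
    odds_ratio: float


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by hypergeometric enumeration.

    Enumerates every table with the observed margins; sums the probability
    of those no more probable than the observed one (relative tie tolerance
    1e-7). A zero margin makes every permissible table identical, so p = 1
    is returned with a warning.
    """
    r1, r2, c1, _ = table.margins
    n = table.n
    if 0 in table.margins:
        warnings.warn("zero margin: Fisher test degenerate, p = 1", stacklevel=2)
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[table.a - lo]
    p = float(pmf[pmf <= p_obs * (1 + _TIE_RTOL)].sum())
    return min(p, 1.0)


def phi_coefficient(table: ContingencyTable2x2) -> float:
    """phi = (ad - bc) / sqrt(row and column margin product).

    Equals the Pearson correlation of the two 0/1 indicator vectors;
    undefined (error) when any margin is zero.
    """
    r1, r2, c1, c2 = table.margins
    if 0 in (r1, r2, c1, c2):
        raise ValueError("phi undefined: a table margin is zero")
    return (table.a * table.d - table.b * table.c) / float(
        np.sqrt(r1) * np.sqrt(r2) * np.sqrt(c1) * np.sqrt(c2)
    )


def odds_ratio(table: ContingencyTable2x2) -> float:
    if table.b * table.c == 0:
        return float("inf") if table.a * table.d > 0 else float("nan")
    return (table.a * table.d) / (table.b * table.c)


def associate(table: ContingencyTable2x2) -> AssociationResult:
    """Fisher p, phi (when defined) and odds ratio for one table."""
    try:
        phi = phi_coefficient(table)
    except ValueError:
        phi = None
    return AssociationResult(
        table=table,
        p_fisher_two_sided=fisher_exact_two_sided(table),
        phi=phi,
        odds_ratio=odds_ratio(table),
    )


def build_contingency(
    cohort: pd.DataFrame, factor1: str, factor2: str
) -> ContingencyTable2x2:
    """Joint yes/no counts of two binary cohort columns.

    Rows with a missing value in either column are excluded pairwise
    (counts logged).
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    for col in (factor1, factor2):
        if col not in cohort.columns:
            raise KeyError(f"cohort column missing: {col!r}")
    sub = cohort[[factor1, factor2]].dropna()
    n_dropped = len(cohort) - len(sub)
    if n_dropped:
        logger.info("build_contingency: excluded %d rows with missing values", n_dropped)
    if sub.empty:
        raise ValueError("no complete observations for the factor pair")
    f1 = sub[factor1].astype(bool)
    f2 = sub[factor2].astype(bool)
    return ContingencyTable2x2(
        a=int((f1 & f2).sum()),
        b=int((f1 & ~f2).sum()),
        c=int((~f1 & f2).sum()),
        d=int((~f1 & ~f2).sum()),
        row_label=factor1,
        col_label=factor2,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_correlation(x, y) -> tuple[float, float]:
    """Continuous-variable Pearson r and two-sided p (general helper)."""
    r, p = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def two_proportion_power(
    p1: float,
    p2: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    method: str = "normal",
    n_sim: int = 100_000,
    seed: int = 0,
) -> dict:
    """Power to detect a difference between two independent proportions.

    Methods: ``normal`` (pooled two-sample z approximation), ``arcsine``
    (variance-stabilised approximation), ``fisher_exact_sim`` (Monte-Carlo
    over binomial draws, each replicate tested with the two-sided Fisher
    exact test; returns the standard error of the estimate).
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    out: dict = {"method": method, "alpha": alpha}
    if p1 == p2:
        out["note"] = "p1 == p2: power equals the attained type-I error rate"
    z_a = sps.norm.ppf(1 - alpha / 2)
    if method == "normal":
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        se0 = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
        se1 = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
        if se1 == 0:
            se1 = 1e-12
        delta = abs(p1 - p2)
        power = sps.norm.sf((z_a * se0 - delta) / se1) + sps.norm.cdf(
            (-z_a * se0 - delta) / se1
        )
        out["power"] = float(power)
    elif method == "arcsine":
        h = 2 * np.arcsin(np.sqrt(p1)) - 2 * np.arcsin(np.sqrt(p2))
        se = np.sqrt(1 / n1 + 1 / n2)
        power = sps.norm.sf(z_a - abs(h) / se) + sps.norm.cdf(-z_a - abs(h) / se)
        out["power"] = float(power)
    elif method == "fisher_exact_sim":
        rng = np.random.default_rng(seed)
        x1 = rng.binomial(n1, p1, size=n_sim)
        x2 = rng.binomial(n2, p2, size=n_sim)
        # cache p-values over the (x1, x2) grid actually drawn
        cache: dict[tuple[int, int], float] = {}
        hits = 0
        for k1, k2 in zip(x1, x2):
            key = (int(k1), int(k2))
            if key not in cache:
                t = ContingencyTable2x2(key[0], n1 - key[0], key[1], n2 - key[1])
                cache[key] = fisher_exact_two_sided(t)
            if cache[key] < alpha:
                hits += 1
        power = hits / n_sim
        out["power"] = power
        out["se"] = float(np.sqrt(power * (1 - power) / n_sim))
    else:
        raise ValueError(f"unknown method: {method!r}")
    return out
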