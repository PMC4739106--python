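"""Exact tests for independence of migration direction and genetic origin.

The philopatry hypothesis predicts that directionally migrating fish head
toward the population they genetically belong to.  The 2×2 table crosses
genetic assignment (rows: Kattegat, North Sea/W Skagerrak) with migration
direction (columns: towards Kattegat, towards the North Sea).  The two
direction groups are treated as fixed-size binomial samples and
independence is tested with Boschloo's unconditional exact test: the test
statistic is Fisher's exact p, and the p-value is the supremum over the
common success probability π of the probability of drawing a table at
least as extreme, located by a fine grid plus golden-section refinement.
Boschloo's p never exceeds Fisher's p on the same table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .behaviour import DIRECTION_OF, BehaviourCategory

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-12


@dataclass
class ContingencyTable2x2:
    """Rows: assignment pool; columns: migration direction."""

    a: int  # row1/col1
    b: int  # row1/col2
    c: int  # row2/col1
    d: int  # row2/col2
    row_labels: tuple[str, str] = ("Kattegat", "NorthSea_WSkagerrak")
    col_labels: tuple[str, str] = ("towardsKattegat", "towardsNorthSea")

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total < 1:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class ExactTestResult:
    method: str  # "fisher" | "boschloo"
    sided: str  # "one" | "two"
    p: float
    fisher_p: float | None = None  # observed Fisher statistic (boschloo)
    pi_argmax: float | None = None  # nuisance argmax (boschloo)


def build_contingency(records: list[tuple[BehaviourCategory, str]]) -> ContingencyTable2x2:
    """Count (assigned pool × migration direction) over classified, assigned
    fish.  Nonmigratory and excluded fish are dropped; both North-Sea-bound
    groups collapse into the towards-North-Sea column."""
    cells = {("Kattegat", "towardsKattegat"): 0, ("Kattegat", "towardsNorthSea"): 0,
             ("NorthSea_WSkagerrak", "towardsKattegat"): 0, ("NorthSea_WSkagerrak", "towardsNorthSea"): 0}
    for category, pool in records:
        direction = DIRECTION_OF.get(category)
        if direction is None or pool is None:
            continue
        if pool not in ("Kattegat", "NorthSea_WSkagerrak"):
            raise ValueError(f"unknown assignment pool {pool!r}")
        cells[(pool, direction)] += 1
    if sum(cells.values()) == 0:
        raise ValueError("no directionally migrating fish: contingency table is empty")
    return ContingencyTable2x2(
        cells[("Kattegat", "towardsKattegat")],
        cells[("Kattegat", "towardsNorthSea")],
        cells[("NorthSea_WSkagerrak", "towardsKattegat")],
        cells[("NorthSea_WSkagerrak", "towardsNorthSea")],
    )


# ---------------------------------------------------------------------------
# Fisher's exact test (hypergeometric enumeration)


def _fisher_p(x1: int, n1: int, x2: int, n2: int, sided: str, alternative: str = "greater") -> float:
    """Fisher p for the table (x1, n1−x1; x2, n2−x2), margins fixed.

    Columns are the two samples; ``x`` counts successes (row 1).  One-sided
    'greater' is the tail where sample 1 is enriched in successes.
    """
    total, succ = n1 + n2, x1 + x2
    if sided == "one":
        if alternative == "greater":
            return float(stats.hypergeom.sf(x1 - 1, total, succ, n1))
        return float(stats.hypergeom.cdf(x1, total, succ, n1))
    lo, hi = max(0, succ - n2), min(succ, n1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, total, succ, n1)
    p_obs = stats.hypergeom.pmf(x1, total, succ, n1)
    return float(pmf[pmf <= p_obs * (1 + _TIE_TOL)].sum())


def fisher_exact(table: ContingencyTable2x2, sided: str = "one",
                 alternative: str | None = None) -> ExactTestResult:
    """Fisher's exact test, conditioning on both margins.

    With ``sided="one"`` and no explicit ``alternative``, the tail is taken
    in the direction of the observed association.  Degenerate margins give
    p = 1 by convention (logged).
    """
    n1, n2 = table.a + table.c, table.b + table.d
    if n1 == 0 or n2 == 0 or (table.a + table.b) == 0 or (table.c + table.d) == 0:
        logger.warning("degenerate margins in %s: Fisher p = 1 by convention", table.as_array().tolist())
        return ExactTestResult("fisher", sided, 1.0)
    if alternative is None and sided == "one":
        alternative = "greater" if table.a / n1 >= table.b / n2 else "less"
    p = _fisher_p(table.a, n1, table.b, n2, sided, alternative or "greater")
    return ExactTestResult("fisher", sided, min(p, 1.0))


# ---------------------------------------------------------------------------
# Boschloo's unconditional exact test


def _statistic_table(n1: int, n2: int, sided: str) -> np.ndarray:
    """Fisher p for every table (x1, x2), x1 ≤ n1, x2 ≤ n2 (vectorised for
    the one-sided case; direct enumeration otherwise)."""
    x1 = np.arange(n1 + 1)[:, None]
    x2 = np.arange(n2 + 1)[None, :]
    if sided == "one":
        return stats.hypergeom.sf(x1 - 1, n1 + n2, x1 + x2, n1)
    t = np.empty((n1 + 1, n2 + 1))
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            t[i, j] = _fisher_p(i, n1, j, n2, "two")
    return t


def boschloo_test(
    table: ContingencyTable2x2,
    sided: str = "one",
    grid_size: int = 1001,
    refine: bool = True,
    orientation: str = "columns",
) -> ExactTestResult:
    """Boschloo's unconditional exact test of independence.

    ``orientation="columns"`` (default) treats the two migration-direction
    groups as fixed binomial samples, successes being row-1 (Kattegat)
    assignments; ``"rows"`` transposes.  One-sided tests the philopatric
    alternative: success probability higher in the towards-Kattegat group.
    The nuisance success probability π is maximised on a uniform grid of
    ``grid_size`` points in (0.001, 0.999) with optional golden-section
    refinement around the argmax.
    """
    if grid_size < 101:
        raise ValueError("grid_size must be ≥ 101")
    if orientation == "columns":
        x1, x2 = table.a, table.b
        n1, n2 = table.a + table.c, table.b + table.d
    elif orientation == "rows":
        x1, x2 = table.a, table.c
        n1, n2 = table.a + table.b, table.c + table.d
    else:
        raise ValueError("orientation must be 'columns' or 'rows'")
    if n1 == 0 or n2 == 0:
        raise ValueError("a binomial sample size is zero: Boschloo undefined")

    t = _statistic_table(n1, n2, sided)
    t_obs = float(t[x1, x2])
    mask = t <= t_obs + _TIE_TOL
    i1 = np.arange(n1 + 1)
    i2 = np.arange(n2 + 1)
    rej = np.argwhere(mask)

    def reject_prob(pi: float) -> float:
        p1 = stats.binom.pmf(i1, n1, pi)[:, None]
        p2 = stats.binom.pmf(i2, n2, pi)[None, :]
        return float((p1 * p2)[mask].sum())

    grid = np.linspace(0.001, 0.999, grid_size)
    # all grid points at once: P(reject | pi) = Σ_{(i,j) in R} Bin(i;n1,pi) Bin(j;n2,pi)
    pm1 = stats.binom.pmf(rej[:, 0][:, None], n1, grid[None, :])
    pm2 = stats.binom.pmf(rej[:, 1][:, None], n2, grid[None, :])
    values = (pm1 * pm2).sum(axis=0)
    best = int(np.argmax(values))
    p, pi_star = float(values[best]), float(grid[best])
    if refine:
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, grid_size - 1)]
        res = optimize.minimize_scalar(
            lambda pi: -reject_prob(pi), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        if -res.fun > p:
            p, pi_star = float(-res.fun), float(res.x)
    return ExactTestResult("boschloo", sided, min(p, 1.0), fisher_p=t_obs, pi_argmax=pi_star)
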