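"""Cohort comparison statistics.

Two-sided Mann-Whitney (Wilcoxon rank-sum) for continuous comparisons
(e.g. age at onset, POLE-signature TMB across cohorts) and the two-sided
Fisher exact test for 2x2 histotype tables, both implemented directly so
their conventions are explicit:

* Mann-Whitney uses midranks for ties; the p-value is exact (full
  enumeration of rank assignments) when the pooled sample size is at
  most 12 and there are no ties, otherwise a normal approximation with
  tie-corrected variance and a 0.5 continuity correction.
* Fisher's two-sided p sums the hypergeometric probabilities of all
  margin-preserving tables whose point probability does not exceed the
  observed one (point-probability rule, with a 1e-7 relative slack
  against rounding), matching the convention of standard statistical
  environments.
"""

from __future__ import annotations

import dataclasses
import math
from itertools import combinations
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import InsufficientDataError

_EXACT_MAX_N = 12


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties sharing their average rank."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1  # average of ranks i+1..j+1
        i = j + 1
    return ranks


def _exact_u_pvalue(u: float, nx: int, ny: int) -> float:
    """Two-sided exact p by enumerating all C(n, nx) rank assignments."""
    n = nx + ny
    base = nx * (nx + 1) / 2
    us = [sum(c) - base for c in combinations(range(1, n + 1), nx)]
    total = len(us)
    le = sum(1 for v in us if v <= u + 1e-9)
    ge = sum(1 for v in us if v >= u - 1e-9)
    return min(1.0, 2.0 * min(le, ge) / total)


def mann_whitney_two_sided(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney test. Returns (U of the first group, p).

    U is computed from rank sums with midranks for ties and satisfies
    U_x + U_y = n_x * n_y. p is always in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    has_ties = len(np.unique(pooled)) < pooled.size
    if nx + ny <= _EXACT_MAX_N and not has_ties:
        return u, _exact_u_pvalue(u, nx, ny)
    # normal approximation with tie correction and continuity correction
    n = nx + ny
    mu = nx * ny / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = nx * ny / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u, 1.0  # all pooled values identical
    z = max(0.0, abs(u - mu) - 0.5) / math.sqrt(var)
    p = math.erfc(z / math.sqrt(2))
    return u, min(1.0, max(p, 1e-300))


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]], e.g. rows = POLE status, cols = histotype."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("table entries must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table total must be >= 1")


def fisher_exact_two_sided(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table (point-probability rule)."""
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    dist = hypergeom(n, r1, c1)
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    probs = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = float(probs[probs <= p_obs * (1 + 1e-7)].sum())
    return min(1.0, max(p, 1e-300))


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    mean: float
    median: float
    q1: float
    q3: float


def summarize_group(values: Sequence[float] | np.ndarray) -> GroupSummary:
    """Mean, median and quartiles (linear-interpolation convention)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InsufficientDataError("cannot summarize an empty group")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return GroupSummary(mean=float(values.mean()), median=float(med), q1=float(q1), q3=float(q3))


def compare_cohort(
    calls: pd.DataFrame,
    annotations: pd.DataFrame,
    histotype: str = "endometrioid",
) -> dict:
    """The cohort-level comparisons around a POLE call table.

    Merges per-sample calls (``sample_id``, ``pole_tmb``, ``outlier``)
    with clinical annotations (``sample_id``, ``age_years``,
    ``histology``) and computes: Mann-Whitney of POLE-signature TMB and
    of age between called and uncalled samples, the Fisher exact test of
    POLE status against histotype, and the POLE frequency within the
    histotype of interest. Returns a JSON-ready dict.
    """
    df = calls.merge(annotations, on="sample_id", how="inner")
    pole = df[df["outlier"]]
    rest = df[~df["outlier"]]
    out: dict = {
        "n_samples": int(len(df)),
        "n_pole": int(len(pole)),
    }
    if len(pole) and len(rest):
        u_tmb, p_tmb = mann_whitney_two_sided(pole["pole_tmb"], rest["pole_tmb"])
        out["tmb_mann_whitney"] = {"U": u_tmb, "p": p_tmb}
        if "age_years" in df.columns:
            u_age, p_age = mann_whitney_two_sided(pole["age_years"], rest["age_years"])
            out["age_mann_whitney"] = {
                "U": u_age,
                "p": p_age,
                "mean_age_pole": float(pole["age_years"].mean()),
                "mean_age_rest": float(rest["age_years"].mean()),
            }
    if "histology" in df.columns:
        is_h = df["histology"].str.lower() == histotype.lower()
        tab = ContingencyTable2x2(
            a=int((df["outlier"] & is_h).sum()),
            b=int((df["outlier"] & ~is_h).sum()),
            c=int((~df["outlier"] & is_h).sum()),
            d=int((~df["outlier"] & ~is_h).sum()),
        )
        out["histotype_fisher"] = {
            "table": [[tab.a, tab.b], [tab.c, tab.d]],
            "p": fisher_exact_two_sided(tab),
        }
        n_h = int(is_h.sum())
        if n_h:
            out["pole_frequency_in_histotype_pct"] = 100.0 * tab.a / n_h
    if len(pole):
        s = summarize_group(pole["pole_tmb"])
        out["pole_tmb_summary"] = dataclasses.asdict(s)
    return out
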