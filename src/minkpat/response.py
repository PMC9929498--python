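"""Receiver-response statistics for egg-rejection experiments.

An egg-manipulation trial replaces one host egg with an experimental egg
under one of three treatments — scribbles painted on, area-matched blotches
painted on, or a water-only handling control — and records whether the host
rejects it within the observation window.  This module reconstructs trial
counts from published rejection frequencies, fits the binomial logistic
regression of rejection on treatment with Wald inference, and provides the
matched-pairs t-test used for before/after painting comparisons of pattern
statistics.

For a saturated one-factor design the logistic MLE has a closed form:
each coefficient is a difference of cell log-odds, and its Wald standard
error is sqrt(1/r_t + 1/(n_t−r_t) + 1/r_ref + 1/(n_ref−r_ref)) over the
rejected/accepted counts of the two cells.  The IRLS fit must (and does)
reproduce this, which the test suite checks to 1e-6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TREATMENTS",
    "GlmResult",
    "reconstruct_counts",
    "records_from_counts",
    "fit_logistic",
    "paired_t_test",
]

TREATMENTS = ("blotches", "scribbles", "water")


@dataclass
class GlmResult:
    """Wald summary of a logistic regression of rejection on treatment.

    ``table`` has one row per model term (intercept plus one dummy per
    non-reference treatment) with columns estimate (log-odds), se, z, p.
    """

    table: pd.DataFrame
    reference: str
    n: int
    df_resid: int
    converged: bool
    separation: bool

    def coef(self, term: str) -> pd.Series:
        return self.table.loc[term]


def reconstruct_counts(
    freqs: Mapping[str, float] | Sequence[float],
    ns: Mapping[str, int] | Sequence[int],
) -> dict[str, int]:
    """Rejection counts from published frequencies: round-half-up(freq x n).

    Accepts dicts keyed by treatment or plain sequences in a matching
    order.  Half-up rounding reverses the rounding applied when a
    frequency like 11/17 is printed as 65%.
    """
    if not isinstance(freqs, Mapping):
        freqs = dict(zip(_default_keys(len(freqs)), freqs))
    if not isinstance(ns, Mapping):
        ns = dict(zip(freqs.keys(), ns))
    counts = {}
    for k, f in freqs.items():
        n = int(ns[k])
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"frequency for {k!r} outside [0, 1]")
        if n <= 0:
            raise ValueError(f"sample size for {k!r} must be positive")
        counts[k] = int(math.floor(f * n + 0.5))
    return counts


def _default_keys(k: int) -> list[str]:
    # unnamed sequences follow the reporting order: test treatment first,
    # then the paint control, then the handling control
    order = ("scribbles", "blotches", "water")
    if k > len(order):
        raise ValueError("provide named frequencies for more than three groups")
    return list(order[:k])


def records_from_counts(
    counts: Mapping[str, int], ns: Mapping[str, int] | Sequence[int]
) -> pd.DataFrame:
    """Expand per-treatment (rejections, n) into one Bernoulli row per trial."""
    if not isinstance(ns, Mapping):
        ns = dict(zip(counts.keys(), ns))
    rows = []
    for t, r in counts.items():
        n = int(ns[t])
        if not 0 <= r <= n:
            raise ValueError(f"count {r} outside [0, {n}] for {t!r}")
        rows += [{"treatment": t, "rejected": 1}] * r
        rows += [{"treatment": t, "rejected": 0}] * (n - r)
    return pd.DataFrame(rows)


def fit_logistic(records: pd.DataFrame, reference: str = "blotches") -> GlmResult:
    """Binomial logistic regression ``rejected ~ treatment`` with Wald inference.

    ``records`` needs columns ``treatment`` and ``rejected`` (0/1).  The
    ``reference`` level absorbs the intercept; each remaining level gets a
    dummy coefficient equal to its log-odds difference from the reference.
    Complete separation (a cell with 0 or 100% rejection) is flagged rather
    than silently reported with divergent estimates.
    """
    if not {"treatment", "rejected"} <= set(records.columns):
        raise ValueError("records need 'treatment' and 'rejected' columns")
    levels = sorted(records["treatment"].unique())
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among treatments {levels}")
    missing = [t for t in levels if (records["treatment"] == t).sum() == 0]
    if missing:
        raise ValueError(f"no records for treatments {missing}")

    order = [reference] + [t for t in levels if t != reference]
    cat = pd.Categorical(records["treatment"], categories=order)
    dummies = pd.get_dummies(cat, drop_first=True, dtype=float)
    Xd = sm.add_constant(dummies)
    Xd.columns = ["intercept"] + [f"treatment[{t}]" for t in order[1:]]
    yv = records["rejected"].astype(float).to_numpy()

    # separation check: any all-0 or all-1 cell makes the MLE infinite
    cell = records.groupby("treatment")["rejected"].agg(["sum", "count"])
    separation = bool(((cell["sum"] == 0) | (cell["sum"] == cell["count"])).any())

    fit = sm.GLM(yv, Xd, family=sm.families.Binomial()).fit(maxiter=500, tol=1e-14)
    table = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "z": fit.params / fit.bse,
            "p": 2 * stats.norm.sf(np.abs(fit.params / fit.bse)),
        }
    )
    return GlmResult(
        table=table,
        reference=reference,
        n=len(records),
        df_resid=int(len(records) - Xd.shape[1]),
        converged=bool(fit.converged) and not separation,
        separation=separation,
    )


def paired_t_test(before: Sequence[float], after: Sequence[float]) -> tuple[float, int, float]:
    """Matched-pairs t-test on after − before differences.

    Returns ``(t, df, p)`` with df = n − 1 and a two-sided p-value; a
    positive t means the quantity increased after the manipulation.
    Zero-variance differences (including identical vectors) are degenerate:
    t is 0 for identical vectors, otherwise an error is raised.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape or b.ndim != 1:
        raise ValueError("before and after must be equal-length 1-D sequences")
    n = len(b)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, n - 1, 1.0
        raise ValueError("zero-variance nonzero differences: t is undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), n - 1, float(res.pvalue)
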