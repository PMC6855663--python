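"""Per-day group comparisons with Holm multiplicity correction.

One-way fixed-effects ANOVA across all arms, pairwise two-sided Student's
t-tests (pooled variance by default, Welch behind a flag), and the
Bonferroni-Holm step-down adjustment — all implemented from first
principles; scipy supplies only the F and t tail probabilities.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _dist

FAMILY_PER_DAY = "per-day"
FAMILY_ALL_DAYS = "all-days"


@dataclass
class PvalueFamily:
    """A family of comparisons with raw and Holm-adjusted p-values."""

    labels: list[str]
    raw_p: np.ndarray
    adjusted_p: np.ndarray


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA: F = MS_between / MS_within.

    Returns (F, p) with p from the F(k-1, N-k) distribution. All
    observations identical gives (0, 1) by convention.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 1 for a in arrs):
        raise ValueError("need >= 2 groups, each non-empty")
    n_total = sum(len(a) for a in arrs)
    k = len(arrs)
    df_between, df_within = k - 1, n_total - k
    if df_within < 1:
        raise ValueError("insufficient within-group degrees of freedom")
    grand = np.concatenate(arrs).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    if ss_within == 0 and ss_between == 0:
        return 0.0, 1.0
    if ss_within == 0:
        return math.inf, 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(_dist.f.sf(f, df_between, df_within))
    return float(f), p


def two_sample_t(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled-variance Student's t by default.

    ``equal_var=False`` gives the Welch variant (Welch-Satterthwaite df).
    Degenerate zero-variance samples: equal means -> (0, 1); unequal means
    -> signed infinity with p = 0 (flagged via warning).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if equal_var:
        df = na + nb - 2
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(pooled * (1 / na + 1 / nb))
    else:
        se = math.sqrt(va / na + vb / nb)
        if se > 0:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            df = na + nb - 2
    if se == 0:
        if diff == 0:
            return 0.0, 1.0
        warnings.warn("zero variance with unequal means: |t| infinite",
                      stacklevel=2)
        return math.copysign(math.inf, diff), 0.0
    t = diff / se
    p = 2.0 * float(_dist.t.sf(abs(t), df))
    return float(t), p


def holm_adjust(raw_p: Sequence[float]) -> list[float]:
    """Bonferroni-Holm step-down adjustment, returned in the input order.

    Sort ascending; adj_(i) = min(1, max_{j<=i} (m-j+1)*p_(j)). Uniformly no
    more conservative than plain Bonferroni.
    """
    p = np.asarray(raw_p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj_sorted[i] = min(1.0, running)
    out = np.empty(m)
    out[order] = adj_sorted
    return out.tolist()


def per_day_comparisons(
    per_animal: pd.DataFrame,
    equal_var: bool = True,
    family: str = FAMILY_PER_DAY,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Omnibus ANOVA and Holm-corrected pairwise t-tests at each day.

    ``per_animal`` is the tidy per-animal table (columns group, day, rtv).
    Only days with >= 2 groups having >= 2 animals each enter the pairwise
    analysis. The correction family is all pairwise comparisons at one day
    (default) or, with ``family="all-days"``, all pairs across all days;
    ANOVA omnibus p-values are reported unadjusted in either case.
    """
    if family not in (FAMILY_PER_DAY, FAMILY_ALL_DAYS):
        raise ValueError(f"unknown family {family!r}")
    rows = []
    for day, sub in per_animal[per_animal["day"] > 0].groupby("day"):
        samples = {g: s["rtv"].to_numpy() for g, s in sub.groupby("group")}
        usable = {g: v for g, v in samples.items() if len(v) >= 2}
        if len(usable) >= 2:
            f, p = one_way_anova(list(usable.values()))
            rows.append(
                {"day": day, "comparison": "ANOVA:" + "|".join(sorted(usable)),
                 "statistic": f, "raw_p": p, "kind": "anova"}
            )
            for g1, g2 in itertools.combinations(sorted(usable), 2):
                t, p = two_sample_t(usable[g1], usable[g2], equal_var=equal_var)
                rows.append(
                    {"day": day, "comparison": f"{g1} vs {g2}",
                     "statistic": t, "raw_p": p, "kind": "pairwise"}
                )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["adjusted_p"] = df["raw_p"]
    pair = df["kind"] == "pairwise"
    if family == FAMILY_PER_DAY:
        for day in df.loc[pair, "day"].unique():
            sel = pair & (df["day"] == day)
            df.loc[sel, "adjusted_p"] = holm_adjust(df.loc[sel, "raw_p"].tolist())
    else:
        df.loc[pair, "adjusted_p"] = holm_adjust(df.loc[pair, "raw_p"].tolist())
    df["significant"] = df["adjusted_p"] < alpha
    return df.drop(columns="kind").rename(columns={"statistic": "t_or_F"})
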