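"""Inference layer: 2x2 repeated-measures ANOVA, Friedman, Dunn, paired t.

The design under study is a fully crossed within-subject 2x2: Condition
(without music / with music) x Time (pre / post exercise).  Graph-metric
aggregates are analyzed with a repeated-measures ANOVA whose error stratum
is the subject-by-effect interaction, reported with partial eta squared
(SS_effect / (SS_effect + SS_error)).  Rank-scale strength measures are
analyzed nonparametrically: the Friedman omnibus test over the four
conditions followed by Dunn's pairwise mean-rank comparisons with Bonferroni
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EffectResult",
    "AnovaResult",
    "rm_anova_2x2",
    "friedman_test",
    "dunn_posthoc",
    "paired_t",
]


@dataclass(frozen=True)
class EffectResult:
    F: float
    df: tuple[int, int]
    p: float
    partial_eta2: float


@dataclass(frozen=True)
class AnovaResult:
    condition: EffectResult
    time: EffectResult
    interaction: EffectResult

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("condition", "time", "interaction"):
            e: EffectResult = getattr(self, name)
            rows.append((name, e.F, e.df[0], e.df[1], e.p, e.partial_eta2))
        return pd.DataFrame(
            rows, columns=["effect", "F", "df1", "df2", "p", "partial_eta2"]
        )


def rm_anova_2x2(
    table: pd.DataFrame,
    subject: str = "subject",
    condition: str = "condition",
    time: str = "time",
    value: str = "value",
) -> AnovaResult:
    """Two-way fully within-subject ANOVA for a 2x2 complete crossed design.

    Sums of squares are decomposed with subject-by-effect error strata:
    F_effect = MS_effect / MS_(effect x subject), df = (1, n - 1).  Partial
    eta squared is SS_effect / (SS_effect + SS_error_effect).  Sphericity is
    moot for 1-df within-subject effects, so no correction is applied.
    """
    df = table[[subject, condition, time, value]].copy()
    conds = sorted(df[condition].unique())
    times = sorted(df[time].unique())
    subs = sorted(df[subject].unique())
    if len(conds) != 2 or len(times) != 2:
        raise ValueError("both factors must have exactly 2 levels")
    n = len(subs)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    cells = df.set_index([subject, condition, time])[value]
    missing = [
        (s, a, b)
        for s in subs
        for a in conds
        for b in times
        if (s, a, b) not in cells.index
    ]
    if missing:
        raise ValueError(f"incomplete design; missing cells: {missing}")
    if cells.index.duplicated().any():
        raise ValueError("duplicate observations for at least one cell")

    y = np.empty((n, 2, 2))
    for i, s in enumerate(subs):
        for a, cond in enumerate(conds):
            for b, tim in enumerate(times):
                y[i, a, b] = cells.loc[(s, cond, tim)]

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))  # subject means
    m_a = y.mean(axis=(0, 2))  # condition means
    m_b = y.mean(axis=(0, 1))  # time means
    m_sa = y.mean(axis=2)  # subject x condition
    m_sb = y.mean(axis=1)  # subject x time
    m_ab = y.mean(axis=0)  # condition x time

    ss_a = 2 * n * ((m_a - grand) ** 2).sum()
    ss_b = 2 * n * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = 2 * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_bs = 2 * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_abs = (resid**2).sum()

    def effect(ss_eff: float, ss_err: float) -> EffectResult:
        df_err = n - 1
        ms_eff = ss_eff / 1.0
        ms_err = ss_err / df_err
        if ms_err == 0:
            f = 0.0 if ms_eff == 0 else np.inf
        else:
            f = ms_eff / ms_err
        p = float(sps.f.sf(f, 1, df_err)) if np.isfinite(f) else 0.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        return EffectResult(float(f), (1, df_err), p, float(eta))

    return AnovaResult(
        condition=effect(ss_a, ss_as),
        time=effect(ss_b, ss_bs),
        interaction=effect(ss_ab, ss_abs),
    )


def _midranks(blocks: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, blocks)


def _exact_friedman_p(ranks: np.ndarray, observed: float) -> float:
    """Exact permutation p for the Friedman statistic (tie-free blocks).

    Dynamic program over subjects on the joint distribution of column rank
    sums; each subject's rank row is permuted uniformly over the k!
    orderings.  Feasible for small n and k <= 4.
    """
    from itertools import permutations

    n, k = ranks.shape
    base = tuple(range(1, k + 1))
    perms = [np.array(p, dtype=int) for p in permutations(base)]
    dist: dict[tuple[int, ...], float] = {tuple([0] * k): 1.0}
    w = 1.0 / len(perms)
    for _ in range(n):
        nxt: dict[tuple[int, ...], float] = {}
        for state, prob in dist.items():
            for p in perms:
                new = tuple(int(s + r) for s, r in zip(state, p))
                nxt[new] = nxt.get(new, 0.0) + prob * w
        dist = nxt
    scale = 12.0 / (n * k * (k + 1))
    shift = 3.0 * n * (k + 1)
    p_val = 0.0
    for state, prob in dist.items():
        chi2 = scale * sum(r * r for r in state) - shift
        if chi2 >= observed - 1e-9:
            p_val += prob
    return p_val


def friedman_test(
    blocks: np.ndarray, exact: bool | None = None
) -> tuple[float, int, float]:
    """Friedman rank test for k related samples.

    ``blocks`` is (n subjects x k conditions).  The statistic is the
    tie-corrected chi-square from within-subject midranks; the p-value comes
    from the chi-square reference distribution with k-1 df, or from exact
    permutation enumeration when requested (or by default for n <= 8,
    k <= 4, tie-free data).

    Returns (chi2, df, p).
    """
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2:
        raise ValueError("blocks must be 2-D (subjects x conditions)")
    n, k = blocks.shape
    if k < 3:
        raise ValueError("Friedman test requires k >= 3 conditions")
    if n < 2:
        raise ValueError("Friedman test requires n >= 2 subjects")
    if all(np.unique(row).size == 1 for row in blocks):
        raise ValueError("degenerate input: every subject's row is constant")
    chi2, _ = sps.friedmanchisquare(*[blocks[:, j] for j in range(k)])
    chi2 = float(chi2)
    df = k - 1
    ranks = _midranks(blocks)
    has_ties = any(np.unique(row).size < k for row in blocks)
    if exact is None:
        exact = n <= 8 and k <= 4 and not has_ties
    if exact and not has_ties:
        p = _exact_friedman_p(ranks, chi2)
    else:
        p = float(sps.chi2.sf(chi2, df))
    return chi2, df, p


def dunn_posthoc(blocks: np.ndarray, correction: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise mean-rank comparisons after a Friedman test.

    For each of the k(k-1)/2 condition pairs: z = (Rbar_u - Rbar_v) /
    sqrt(k(k+1)/(6n)); raw two-sided p from the normal reference; adjusted
    p = min(1, raw * number of pairs) under Bonferroni.
    """
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is implemented")
    blocks = np.asarray(blocks, dtype=float)
    n, k = blocks.shape
    ranks = _midranks(blocks)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pairs = list(combinations(range(k), 2))
    m = len(pairs)
    rows = []
    for u, v in pairs:
        z = (mean_ranks[u] - mean_ranks[v]) / se
        raw = 2.0 * sps.norm.sf(abs(z))
        rows.append((u, v, z, raw, min(1.0, raw * m)))
    return pd.DataFrame(rows, columns=["i", "j", "z", "p_raw", "p_adjusted"])


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Paired t-test on a - b differences: (t, df, two-sided p).

    Identical samples return (0, n-1, 1).  A nonzero constant difference has
    zero variance, leaving t undefined, and raises instead.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("samples must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, a.size - 1, 1.0
        raise ValueError("zero difference variance: paired t undefined")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), a.size - 1, float(res.pvalue)
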