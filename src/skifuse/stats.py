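"""Statistical comparisons: normality-gated paired tests and two-way
repeated-measures ANOVA with Tukey post-hoc pairwise comparisons.

Paired condition comparisons test the differences for normality
(Shapiro-Wilk); normal differences use a paired t-test, non-normal ones the
Wilcoxon signed-rank test (zero differences dropped, exact null
distribution for small samples).  Lap x segment effects use the univariate
two-way repeated-measures ANOVA with the subject as the repeated factor:
each within factor is tested against its own factor-by-subject interaction
mean square.  Tukey pairwise comparisons use the studentized range on the
same error term, so adjusted p-values are never smaller than the
corresponding unadjusted paired comparisons.  No sphericity correction is
applied by default; Greenhouse-Geisser is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "PairedSample",
    "TestResult",
    "paired_compare",
    "rm_anova2",
    "tukey_pairs",
]

ALPHA = 0.05


class DesignError(ValueError):
    """Unbalanced or incomplete repeated-measures design."""


@dataclass(frozen=True)
class PairedSample:
    """Matched condition-A / condition-B values for a set of subjects."""

    subjects: tuple
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b) or len(self.subjects) != len(self.a):
            raise ValueError("paired sample lengths must match")
        if len(self.a) < 3:
            raise ValueError("paired comparison needs n >= 3")

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.b, dtype=float) - np.asarray(self.a, dtype=float)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one paired comparison."""

    statistic: float
    pvalue: float
    test: str  # "paired-t" | "wilcoxon-signed-rank"
    normality_p: float
    alpha: float = ALPHA
    degenerate: bool = False


def paired_compare(
    sample: PairedSample | tuple,
    force_test: str | None = None,
    alpha: float = ALPHA,
) -> TestResult:
    """Compare two matched conditions, gating the test on normality.

    The paired differences are tested with Shapiro-Wilk; if the normality
    p-value is >= ``alpha`` a paired t-test is used, otherwise the Wilcoxon
    signed-rank test (zero differences dropped; exact distribution for
    n <= 25 without ties).  ``force_test`` (``"paired-t"`` or
    ``"wilcoxon-signed-rank"``) overrides the gate.  All-zero differences
    under Wilcoxon are a degenerate sample, flagged with p = 1.
    """
    if not isinstance(sample, PairedSample):
        a, b = np.asarray(sample[0], float), np.asarray(sample[1], float)
        sample = PairedSample(tuple(range(len(a))), a, b)
    d = sample.differences
    if np.any(~np.isfinite(d)):
        raise ValueError("missing pairs are not allowed")
    if np.allclose(d, d[0]):
        # Shapiro is undefined for constant input; treat as normal
        normality_p = 1.0
    else:
        normality_p = float(sps.shapiro(d).pvalue)
    if force_test is not None:
        test = force_test
        if test not in ("paired-t", "wilcoxon-signed-rank"):
            raise ValueError(f"unknown test {test!r}")
    else:
        test = "paired-t" if normality_p >= alpha else "wilcoxon-signed-rank"

    if test == "paired-t":
        if np.allclose(d, 0.0):
            return TestResult(0.0, 1.0, test, normality_p, alpha, degenerate=True)
        res = sps.ttest_rel(sample.b, sample.a)
        return TestResult(float(res.statistic), float(res.pvalue), test, normality_p, alpha)
    nonzero = d[d != 0.0]
    if len(nonzero) == 0:
        return TestResult(0.0, 1.0, test, normality_p, alpha, degenerate=True)
    method = "exact" if len(nonzero) <= 25 and len(np.unique(np.abs(nonzero))) == len(nonzero) else "auto"
    res = sps.wilcoxon(d, zero_method="wilcox", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), test, normality_p, alpha)


def _check_balanced(data: pd.DataFrame, subject: str, a: str, b: str) -> None:
    counts = data.groupby([subject, a, b], observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1]
        raise DesignError(
            f"design must have exactly one observation per subject x {a} x {b} "
            f"cell; offending cells: {list(bad.index[:10])}"
        )
    subjects = data[subject].unique()
    cells = {(x, y) for x in data[a].unique() for y in data[b].unique()}
    missing = []
    for s in subjects:
        have = set(map(tuple, data.loc[data[subject] == s, [a, b]].itertuples(index=False)))
        missing.extend((s, *c) for c in cells - have)
    if missing:
        raise DesignError(f"missing cells: {missing[:10]}")


def _ss_decomposition(data: pd.DataFrame, dv: str, subject: str, a: str, b: str):
    """Explicit sums-of-squares decomposition of the two-way RM design."""
    y = data[dv].to_numpy(dtype=float)
    grand = y.mean()
    n_s = data[subject].nunique()
    n_a = data[a].nunique()
    n_b = data[b].nunique()

    m_s = data.groupby(subject, observed=True)[dv].mean()
    m_a = data.groupby(a, observed=True)[dv].mean()
    m_b = data.groupby(b, observed=True)[dv].mean()
    m_sa = data.groupby([subject, a], observed=True)[dv].mean()
    m_sb = data.groupby([subject, b], observed=True)[dv].mean()
    m_ab = data.groupby([a, b], observed=True)[dv].mean()

    ss_a = n_s * n_b * float(((m_a - grand) ** 2).sum())
    ss_b = n_s * n_a * float(((m_b - grand) ** 2).sum())
    ss_ab = n_s * float(
        ((m_ab - m_a.reindex(m_ab.index.get_level_values(0)).to_numpy()
          - m_b.reindex(m_ab.index.get_level_values(1)).to_numpy() + grand) ** 2).sum()
    )
    ss_as = n_b * float(
        ((m_sa - m_s.reindex(m_sa.index.get_level_values(0)).to_numpy()
          - m_a.reindex(m_sa.index.get_level_values(1)).to_numpy() + grand) ** 2).sum()
    )
    ss_bs = n_a * float(
        ((m_sb - m_s.reindex(m_sb.index.get_level_values(0)).to_numpy()
          - m_b.reindex(m_sb.index.get_level_values(1)).to_numpy() + grand) ** 2).sum()
    )
    resid = (
        y
        - m_sa.loc[list(zip(data[subject], data[a]))].to_numpy()
        - m_sb.loc[list(zip(data[subject], data[b]))].to_numpy()
        - m_ab.loc[list(zip(data[a], data[b]))].to_numpy()
        + m_s.loc[data[subject]].to_numpy()
        + m_a.loc[data[a]].to_numpy()
        + m_b.loc[data[b]].to_numpy()
        - grand
    )
    ss_abs = float((resid**2).sum())
    return {
        "n_s": n_s, "n_a": n_a, "n_b": n_b,
        "ss_a": ss_a, "ss_b": ss_b, "ss_ab": ss_ab,
        "ss_as": ss_as, "ss_bs": ss_bs, "ss_abs": ss_abs,
    }


def rm_anova2(
    data: pd.DataFrame,
    dv: str,
    subject: str = "subject",
    a: str = "lap",
    b: str = "segment",
    gg_correction: bool = False,
) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA (both factors within subjects).

    Requires a complete balanced design with one observation per subject x
    A x B cell.  Each effect is tested against its interaction with the
    subject factor; the A x B interaction against the three-way residual.
    With ``gg_correction`` the degrees of freedom of each effect are scaled
    by its Greenhouse-Geisser epsilon.

    Returns a table with columns effect, F, num_df, den_df, p.
    """
    _check_balanced(data, subject, a, b)
    d = _ss_decomposition(data, dv, subject, a, b)
    n_s, n_a, n_b = d["n_s"], d["n_a"], d["n_b"]
    rows = []
    specs = [
        (a, d["ss_a"], n_a - 1, d["ss_as"], (n_a - 1) * (n_s - 1)),
        (b, d["ss_b"], n_b - 1, d["ss_bs"], (n_b - 1) * (n_s - 1)),
        (f"{a}:{b}", d["ss_ab"], (n_a - 1) * (n_b - 1), d["ss_abs"],
         (n_a - 1) * (n_b - 1) * (n_s - 1)),
    ]
    eps_by_effect = _gg_epsilons(data, dv, subject, a, b) if gg_correction else {}
    for name, ss_eff, df_eff, ss_err, df_err in specs:
        ms_err = ss_err / df_err
        f = (ss_eff / df_eff) / ms_err if ms_err > 0 else (0.0 if ss_eff == 0 else np.inf)
        eps = eps_by_effect.get(name, 1.0)
        p = float(sps.f.sf(f, eps * df_eff, eps * df_err)) if np.isfinite(f) else 0.0
        rows.append((name, f, eps * df_eff, eps * df_err, p))
    return pd.DataFrame(rows, columns=["effect", "F", "num_df", "den_df", "p"])


def _gg_epsilons(data, dv, subject, a, b) -> dict[str, float]:
    """Greenhouse-Geisser epsilon per within factor (main effects only)."""
    out: dict[str, float] = {}
    for factor, other in ((a, b), (b, a)):
        wide = (
            data.groupby([subject, factor], observed=True)[dv].mean().unstack(factor)
        )
        cov = np.cov(wide.to_numpy(), rowvar=False, ddof=1)
        k = cov.shape[0]
        mean_diag = np.trace(cov) / k
        grand = cov.mean()
        row_means = cov.mean(axis=1)
        num = (k * (mean_diag - grand)) ** 2
        den = (k - 1) * (np.sum(cov**2) - 2 * k * np.sum(row_means**2) + k**2 * grand**2)
        out[factor] = float(num / den) if den > 0 else 1.0
    return out


def tukey_pairs(
    data: pd.DataFrame,
    dv: str,
    effect: str,
    subject: str = "subject",
    a: str = "lap",
    b: str = "segment",
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons for one main effect of the RM ANOVA.

    Marginal level means are compared with the studentized-range
    distribution using the effect's own factor-by-subject error mean square,
    so each adjusted p-value is >= the unadjusted p-value of the matching
    pooled-error t-test (also returned).
    """
    if effect not in (a, b):
        raise ValueError(f"effect must be {a!r} or {b!r}, got {effect!r}")
    _check_balanced(data, subject, a, b)
    d = _ss_decomposition(data, dv, subject, a, b)
    n_s = d["n_s"]
    if effect == a:
        ss_err, df_err = d["ss_as"], (d["n_a"] - 1) * (n_s - 1)
        n_per_level = n_s * d["n_b"]
    else:
        ss_err, df_err = d["ss_bs"], (d["n_b"] - 1) * (n_s - 1)
        n_per_level = n_s * d["n_a"]
    ms_err = ss_err / df_err
    means = data.groupby(effect, observed=True)[dv].mean()
    k = len(means)
    se = np.sqrt(ms_err / n_per_level)
    rows = []
    for lv1, lv2 in combinations(means.index, 2):
        diff = float(means[lv2] - means[lv1])
        if se > 0:
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_err))
            t = abs(diff) / (se * np.sqrt(2.0))
            p_unadj = float(2 * sps.t.sf(t, df_err))
        else:
            q, p_adj, p_unadj = 0.0, 1.0, 1.0
        rows.append((lv1, lv2, diff, q, p_adj, p_unadj))
    return pd.DataFrame(
        rows, columns=["level_1", "level_2", "mean_diff", "q", "p_adj", "p_unadj"]
    )
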