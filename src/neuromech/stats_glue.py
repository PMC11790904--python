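"""Statistical decision tree and Spearman correlation used by all modules.

Test selection mirrors the study's menu: normality is assessed with the
D'Agostino-Pearson test for more than 7 data points and Shapiro-Wilk for
3-7; two normal independent groups are compared with Student's t or
Welch's t depending on an F test of variance equality, non-normal groups
with Mann-Whitney U; dependent groups use the paired t-test or the
Wilcoxon signed-rank test (normality judged on the differences); three or
more groups use one-way ANOVA with Tukey's post hoc test or
Kruskal-Wallis with Dunn's test (Bonferroni-adjusted).  All tests are
two-tailed; the normality and variance gates use alpha = 0.05.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientSampleError, UndefinedCorrelationError

GATE_ALPHA = 0.05


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_two_tailed: float
    n_per_group: tuple[int, ...]
    notes: list[str] = field(default_factory=list)
    pairwise_p: dict[tuple[int, int], float] | None = None


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman(
    x: np.ndarray,
    y: np.ndarray,
    seed: int | None = None,
    n_mc: int = 20_000,
) -> tuple[float, float]:
    """Average-rank Spearman correlation with a two-tailed p value.

    For n <= 7 the p value is computed by exhaustive permutation of one
    rank vector; for 8 <= n <= 10 by seeded Monte-Carlo permutation;
    asymptotically otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise InsufficientSampleError("paired samples required")
    if n < 5:
        raise InsufficientSampleError("need at least 5 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rho_of_ranks(rx, ry)

    if n <= 7:
        total = 0
        extreme = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rho_of_ranks(rx, np.asarray(perm))) >= abs(rho) - 1e-12:
                extreme += 1
        return rho, extreme / total
    if n <= 10:
        rng = np.random.default_rng(seed)
        count = 0
        ry_perm = ry.copy()
        for _ in range(n_mc):
            rng.shuffle(ry_perm)
            if abs(_rho_of_ranks(rx, ry_perm)) >= abs(rho) - 1e-12:
                count += 1
        return rho, (count + 1) / (n_mc + 1)
    res = stats.spearmanr(x, y)
    return rho, float(res.pvalue)


def is_normal(sample: np.ndarray, alpha: float = GATE_ALPHA) -> tuple[bool, str]:
    """Normality gate: D'Agostino-Pearson for n > 7, Shapiro-Wilk for 3-7."""
    sample = np.asarray(sample, dtype=float)
    n = sample.size
    if n < 3:
        raise InsufficientSampleError("need at least 3 data points")
    if np.ptp(sample) == 0:
        # a constant sample carries no evidence against normality here;
        # the downstream location tests handle it explicitly
        return True, "constant-sample"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if n > 7:
            p = float(stats.normaltest(sample).pvalue)
            name = "dagostino-pearson"
        else:
            p = float(stats.shapiro(sample).pvalue)
            name = "shapiro-wilk"
    return p >= alpha, f"{name} p={p:.3g}"


def f_test_equal_variance(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed F test of variance equality for two normal groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p = 2.0 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    return float(min(p, 1.0))


def compare_two(a: np.ndarray, b: np.ndarray, paired: bool = False) -> TestResult:
    """Two-group comparison following the normality/variance decision tree."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientSampleError("each group needs at least 3 data points")
    notes: list[str] = []

    if paired:
        if a.size != b.size:
            raise InsufficientSampleError("paired groups must have equal size")
        diffs = a - b
        normal, note = is_normal(diffs)
        notes.append(f"normality(differences): {note}")
        if np.all(diffs == 0):
            return TestResult("paired-t", 0.0, 1.0, (a.size, b.size), notes)
        if normal:
            res = stats.ttest_rel(a, b)
            return TestResult(
                "paired-t", float(res.statistic), float(res.pvalue), (a.size, b.size), notes
            )
        res = stats.wilcoxon(a, b)
        return TestResult(
            "wilcoxon-signed-rank",
            float(res.statistic),
            float(res.pvalue),
            (a.size, b.size),
            notes,
        )

    norm_a, note_a = is_normal(a)
    norm_b, note_b = is_normal(b)
    notes += [f"normality(a): {note_a}", f"normality(b): {note_b}"]
    if norm_a and norm_b:
        p_var = f_test_equal_variance(a, b)
        equal_var = p_var >= GATE_ALPHA
        notes.append(f"f-test p={p_var:.3g}")
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            return TestResult("student-t", 0.0, 1.0, (a.size, b.size), notes)
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        name = "student-t" if equal_var else "welch-t"
        return TestResult(
            name, float(res.statistic), float(res.pvalue), (a.size, b.size), notes
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(
        "mann-whitney-u", float(res.statistic), float(res.pvalue), (a.size, b.size), notes
    )


def _dunn_pairwise(groups: list[np.ndarray]) -> dict[tuple[int, int], float]:
    """Dunn's post hoc z tests on rank means with tie correction and
    Bonferroni adjustment."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(float(np.mean(ranks[start : start + g.size])))
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(groups) * (len(groups) - 1) // 2
    out: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(var_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = abs(mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * stats.norm.sf(z) * m)
        out[(i, j)] = float(p)
    return out


def compare_multi(groups: list[np.ndarray]) -> TestResult:
    """Three-or-more-group comparison: ANOVA + Tukey when every group
    passes the normality gate, otherwise Kruskal-Wallis + Dunn."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise InsufficientSampleError("need at least 3 groups")
    if any(g.size < 3 for g in groups):
        raise InsufficientSampleError("each group needs at least 3 data points")
    notes = []
    all_normal = True
    for k, g in enumerate(groups):
        ok, note = is_normal(g)
        notes.append(f"normality(group {k}): {note}")
        all_normal &= ok
    ns = tuple(g.size for g in groups)

    if all_normal:
        if all(np.ptp(g) == 0 for g in groups) and len({float(g[0]) for g in groups}) == 1:
            pairwise = {
                (i, j): 1.0 for i, j in itertools.combinations(range(len(groups)), 2)
            }
            return TestResult("anova-tukey", 0.0, 1.0, ns, notes, pairwise)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = stats.f_oneway(*groups)
        values = np.concatenate(groups)
        labels = np.concatenate([np.full(g.size, k) for k, g in enumerate(groups)])
        tukey = pairwise_tukeyhsd(values, labels, alpha=0.05)
        pairs = list(itertools.combinations(range(len(groups)), 2))
        pairwise = {
            pair: float(p) for pair, p in zip(pairs, np.asarray(tukey.pvalues))
        }
        return TestResult(
            "anova-tukey", float(res.statistic), float(res.pvalue), ns, notes, pairwise
        )
    res = stats.kruskal(*groups)
    pairwise = _dunn_pairwise(groups)
    return TestResult(
        "kruskal-dunn", float(res.statistic), float(res.pvalue), ns, notes, pairwise
    )
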