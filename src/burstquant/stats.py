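"""Case-vs-control inference battery.

Four tests, matching the comparison procedures used for stage- and
track-level burst metrics between a perturbed enhancer and its control:

* Mann-Whitney U (rank test; exact null for small tie-free samples,
  otherwise normal approximation with tie and continuity corrections);
* a mean-difference permutation test whose alternative direction is chosen
  by the sign of the observed difference — as specified for the original
  procedure — with the complementary two-sided p always reported alongside,
  because the data-dependent one-sided rule alone is anti-conservative;
* unpaired t-test that switches from the pooled (Student) form to Welch's
  form when an F-test finds the group variances significantly unequal;
* a variance comparison (F ratio or Brown-Forsythe/Levene on absolute
  deviations from the median).

Exact permutation p-values use the include-observed convention, so p >= 1/N
always.  The embryo (movie) is the intended statistical unit for headline
comparisons; per-track comparisons are exploratory.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    sidedness: str                     # two_sided | greater | less
    n_case: int
    n_control: int
    n_permutations: int | str | None = None   # integer or "exact"
    observed_difference: float | None = None
    p_two_sided: float | None = None   # permutation test: always-reported 2-sided p
    seed: int | None = None
    detail: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value out of range: {self.p_value}")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Conventional star coding; anything above 0.05 is 'ns'."""
    if np.isnan(p):
        return "na"
    for cut, sym in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p <= cut:
            return sym
    return "ns"


_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


def mann_whitney_u(case, control, sidedness: str = "two_sided") -> TestResult:
    """Mann-Whitney U test of whether one group tends to exceed the other.

    U is the rank-sum statistic of the case group (midranks for ties).  The
    null distribution is enumerated exactly when n_case + n_control <= 12 and
    there are no ties; otherwise the normal approximation with tie correction
    and continuity correction is used.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(case) == 0 or len(control) == 0:
        raise ValueError("both samples must be nonempty")
    if sidedness not in _ALTERNATIVES:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    pooled = np.concatenate([case, control])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical in both groups; MWU p set to 1",
                      RuntimeWarning, stacklevel=2)
        u = len(case) * len(control) / 2.0
        return TestResult("mann_whitney_u", u, 1.0, sidedness,
                          len(case), len(control), detail="degenerate: all ties")
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(case, control, alternative=_ALTERNATIVES[sidedness],
                           method=method, use_continuity=True)
    return TestResult("mann_whitney_u", float(res.statistic), float(res.pvalue),
                      sidedness, len(case), len(control), detail=method)


def permutation_test(case, control, n_permutations: int = 10_000,
                     seed: int | None = None,
                     exact_cutoff: int = 20_000) -> TestResult:
    """Mean-difference permutation test with data-dependent direction.

    The statistic is mean(case) - mean(control).  If the observed difference
    is positive the alternative is "case greater"; if negative, "control
    greater"; the one-sided p is the proportion of group relabelings whose
    difference is at least as extreme in that direction, counting the
    observed arrangement.  A two-sided p (|difference| at least as large) is
    reported alongside.  All C(n, n_case) relabelings are enumerated when
    there are at most ``exact_cutoff`` of them; otherwise Monte Carlo with
    ``n_permutations`` draws and a mandatory seed.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(case) == 0 or len(control) == 0:
        raise ValueError("both samples must be nonempty")
    n_case, n = len(case), len(case) + len(control)
    pooled = np.concatenate([case, control])
    total = pooled.sum()
    obs = case.mean() - control.mean()

    def diff_from_case_sum(s):
        return s / n_case - (total - s) / (n - n_case)

    n_exact = math.comb(n, n_case)
    if n_exact <= exact_cutoff:
        idx = np.fromiter(itertools.chain.from_iterable(
            itertools.combinations(range(n), n_case)),
            dtype=np.intp).reshape(n_exact, n_case)
        diffs = diff_from_case_sum(pooled[idx].sum(axis=1))
        n_perm = "exact"
        denom = n_exact
        used_seed = None
    else:
        if seed is None:
            raise ValueError("seed is required for Monte Carlo permutation testing")
        rng = np.random.default_rng(seed)
        sums = np.empty(n_permutations)
        for i in range(n_permutations):
            sums[i] = pooled[rng.permutation(n)[:n_case]].sum()
        diffs = diff_from_case_sum(sums)
        diffs = np.append(diffs, obs)   # include-observed convention
        n_perm = n_permutations
        denom = n_permutations + 1
        used_seed = seed

    tol = 1e-9 * max(1.0, float(np.abs(pooled).max()))  # float-safe tie handling
    if obs > 0:
        sided, extreme = "greater", diffs >= obs - tol
    elif obs < 0:
        sided, extreme = "less", diffs <= obs + tol
    else:
        sided, extreme = "two_sided", np.abs(diffs) >= abs(obs) - tol
    p_one = float(extreme.sum()) / denom
    p_two = float((np.abs(diffs) >= abs(obs) - tol).sum()) / denom
    if obs == 0:
        p_one = 1.0
        detail = "degenerate: zero observed difference"
    else:
        detail = None
    return TestResult("permutation", obs, min(p_one, 1.0), sided,
                      n_case, n - n_case, n_permutations=n_perm,
                      observed_difference=obs, p_two_sided=min(p_two, 1.0),
                      seed=used_seed, detail=detail)


def t_test_auto(case, control, alpha: float = 0.05) -> TestResult:
    """Unpaired t-test, switching to Welch when variances differ significantly.

    A two-sided F-test of variance equality at ``alpha`` decides between the
    pooled (Student) and Welch (Satterthwaite df) forms; the chosen branch is
    recorded in ``detail``.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need at least two values per group")
    v1, v2 = case.var(ddof=1), control.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if case.mean() == control.mean():
            return TestResult("t_test", 0.0, 1.0, "two_sided",
                              len(case), len(control),
                              detail="degenerate: zero variance, equal means")
        raise ValueError("zero variance in both groups with unequal means")
    f_p = _variance_f_p(case, control)
    welch = f_p < alpha
    res = sps.ttest_ind(case, control, equal_var=not welch)
    return TestResult("t_test", float(res.statistic), float(res.pvalue),
                      "two_sided", len(case), len(control),
                      detail=f"{'welch' if welch else 'pooled'} (F-test p={f_p:.4g})")


def _variance_f_p(case, control) -> float:
    v1, v2 = case.var(ddof=1), control.var(ddof=1)
    if v1 == 0 or v2 == 0:
        return 0.0
    if v1 >= v2:
        f, d1, d2 = v1 / v2, len(case) - 1, len(control) - 1
    else:
        f, d1, d2 = v2 / v1, len(control) - 1, len(case) - 1
    return min(1.0, 2.0 * sps.f.sf(f, d1, d2))


def variance_compare(case, control, method: str = "F") -> TestResult:
    """Compare group variances by F ratio or Brown-Forsythe (median) Levene.

    The F statistic uses the larger/smaller-variance convention with a
    two-sided p (doubled upper tail, capped at 1).
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need at least two values per group")
    if method == "F":
        v1, v2 = case.var(ddof=1), control.var(ddof=1)
        if v1 == 0 and v2 == 0:
            raise ValueError("zero variance in both groups")
        if v1 == v2:
            return TestResult("variance_F", 1.0, 1.0, "two_sided",
                              len(case), len(control))
        hi, lo = max(v1, v2), min(v1, v2)
        if lo == 0:
            return TestResult("variance_F", float("inf"), 0.0, "two_sided",
                              len(case), len(control),
                              detail="degenerate: one group has zero variance")
        p = _variance_f_p(case, control)
        return TestResult("variance_F", hi / lo, p, "two_sided",
                          len(case), len(control))
    if method == "levene":
        stat, p = sps.levene(case, control, center="median")
        return TestResult("variance_levene", float(stat), float(p), "two_sided",
                          len(case), len(control))
    raise ValueError(f"unknown variance comparison method {method!r}")
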