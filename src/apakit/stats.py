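"""Exact small-sample nonparametric tests and the cross-task validation
battery.

With cohorts of 8–14 subjects, large-sample approximations are unreliable,
so the signed-rank and rank-sum tests here compute exact permutation
p-values: Wilcoxon by the full sign-assignment distribution of the positive
rank sum (a polynomial-convolution enumeration, exact under midranks) and
Mann-Whitney by enumerating group assignments (falling back to seeded
permutation sampling when the assignment count is too large).  Spearman
correlations use midranks, with an exact permutation p for n ≤ 8 and the
t approximation above that.  Two-sided p-values double the smaller tail,
capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional

import numpy as np
from scipy import stats as sps

from .types import ValidationError

_EPS = 1e-9


@dataclass
class DescriptiveStats:
    n: int
    mean: float
    sd: float       # ddof=1
    se: float
    min: float
    max: float


def descriptives(values) -> DescriptiveStats:
    """Mean, SD (n−1), SE and range; errors on n < 2 (SD undefined)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValidationError("descriptives of an empty sample")
    if v.size == 1:
        raise ValidationError("sd undefined for a single observation")
    sd = float(np.std(v, ddof=1))
    return DescriptiveStats(n=int(v.size), mean=float(np.mean(v)), sd=sd,
                            se=sd / float(np.sqrt(v.size)),
                            min=float(v.min()), max=float(v.max()))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank, exact

@dataclass
class WilcoxonResult:
    w: float            # positive-rank sum W+
    z: float            # normal approximation (tie-corrected)
    p_exact: float      # two-sided, full sign-assignment enumeration
    p_normal: float     # two-sided, normal approximation
    n_used: int         # pairs after dropping zero differences
    n_dropped: int
    p_exact_greater: float = 1.0   # one-sided P(W+ >= w)
    p_exact_less: float = 1.0      # one-sided P(W+ <= w)


def _signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact pmf of W+ over all 2^m equally likely sign assignments.

    Midranks are half-integers, so doubling makes every rank integral and
    the distribution is a polynomial product of (1 + x^r) terms.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    poly = np.zeros(total + 1)
    poly[0] = 1.0
    for r in r2:
        nxt = poly.copy()
        nxt[r:] += poly[:total + 1 - r]
        poly = nxt
    poly /= poly.sum()
    support = np.arange(total + 1) / 2.0
    return support, poly


def wilcoxon_exact(a, b=None) -> WilcoxonResult:
    """Exact Wilcoxon signed-rank test on paired samples (or on differences
    directly if ``b`` is None).  Zero differences are dropped (Wilcoxon's
    original rule); if all differences are zero the test degenerates to
    p = 1."""
    a = np.asarray(a, dtype=float)
    d = a if b is None else a - np.asarray(b, dtype=float)
    if not np.isfinite(d).all():
        raise ValidationError("non-finite differences")
    nz = d[np.abs(d) > _EPS]
    n_dropped = d.size - nz.size
    m = nz.size
    if m == 0:
        return WilcoxonResult(w=0.0, z=0.0, p_exact=1.0, p_normal=1.0,
                              n_used=0, n_dropped=n_dropped)
    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())

    support, pmf = _signed_rank_distribution(ranks)
    p_lo = float(pmf[support <= w_plus + _EPS].sum())
    p_hi = float(pmf[support >= w_plus - _EPS].sum())
    p_exact = min(1.0, 2.0 * min(p_lo, p_hi))
    mu = m * (m + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    var = m * (m + 1) * (2 * m + 1) / 24.0 - (counts ** 3 - counts).sum() / 48.0
    z = 0.0 if var <= 0 else (w_plus - mu) / np.sqrt(var)
    p_normal = min(1.0, 2.0 * sps.norm.sf(abs(z))) if var > 0 else 1.0
    return WilcoxonResult(w=w_plus, z=float(z), p_exact=p_exact,
                          p_normal=float(p_normal), n_used=m,
                          n_dropped=n_dropped, p_exact_greater=p_hi,
                          p_exact_less=p_lo)


# ---------------------------------------------------------------------------
# Mann-Whitney U, exact

@dataclass
class MannWhitneyResult:
    u: float            # min(U_A, U_B), the conventionally reported statistic
    u_a: float
    u_b: float
    p_exact: float      # two-sided; exact enumeration or seeded permutation
    method: str         # "enumeration" | "permutation"
    p_exact_less: float = 1.0      # one-sided P(U_A <= u_a)
    p_exact_greater: float = 1.0   # one-sided P(U_A >= u_a)


def mannwhitney_exact(group_a, group_b, max_enumeration: int = 400_000,
                      n_permutations: int = 20_000,
                      seed: int = 0) -> MannWhitneyResult:
    """Rank-sum test with tie-aware midranks and an exact two-sided p.

    All C(n_a+n_b, n_a) group assignments are enumerated when feasible;
    above ``max_enumeration`` (or always reproducibly seedable) a random
    permutation p is computed instead.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("empty group")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na, nb = a.size, b.size
    r_a = float(ranks[:na].sum())
    u_a = r_a - na * (na + 1) / 2.0
    u_b = na * nb - u_a

    n_total = comb(na + nb, na)
    if n_total <= max_enumeration:
        sums = np.fromiter(
            (sum(ranks[list(idx)]) for idx in
             combinations(range(na + nb), na)),
            dtype=float, count=n_total)
        u_all = sums - na * (na + 1) / 2.0
        p_lo = float(np.mean(u_all <= u_a + _EPS))
        p_hi = float(np.mean(u_all >= u_a - _EPS))
        method = "enumeration"
    else:
        rng = np.random.default_rng(seed)
        u_all = np.empty(n_permutations)
        for i in range(n_permutations):
            perm = rng.permutation(ranks)
            u_all[i] = perm[:na].sum() - na * (na + 1) / 2.0
        p_lo = float(np.mean(u_all <= u_a + _EPS))
        p_hi = float(np.mean(u_all >= u_a - _EPS))
        method = "permutation"
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    return MannWhitneyResult(u=float(min(u_a, u_b)), u_a=float(u_a),
                             u_b=float(u_b), p_exact=p, method=method,
                             p_exact_less=p_lo, p_exact_greater=p_hi)


# ---------------------------------------------------------------------------
# Spearman correlation

@dataclass
class SpearmanResult:
    r_s: float
    p: float
    n: int
    method: str     # "exact" | "t"


def spearman(x, y, method: str = "auto",
             exact_limit: int = 8) -> SpearmanResult:
    """Spearman rank correlation with midranks for ties.

    Exact permutation p (all n! rank orderings) for n ≤ ``exact_limit``
    under ``auto``; the t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValidationError("spearman needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    rx, ry = sps.rankdata(x), sps.rankdata(y)

    def _corr(u, v):
        u = u - u.mean()
        v = v - v.mean()
        return float(u @ v / np.sqrt((u @ u) * (v @ v)))

    r = _corr(rx, ry)
    if method == "auto":
        method = "exact" if n <= exact_limit else "t"
    if method == "exact":
        from itertools import permutations
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        num = pc @ rxc
        den = np.sqrt((rxc @ rxc) * (pc * pc).sum(axis=1))
        r_all = num / den
        p = float(np.mean(np.abs(r_all) >= abs(r) - _EPS))
    elif method == "t":
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1 - r * r))
            p = float(2 * sps.t.sf(abs(t), n - 2))
    else:
        raise ValidationError(f"unknown method {method!r}")
    return SpearmanResult(r_s=r, p=p, n=n, method=method)


# ---------------------------------------------------------------------------
# cross-task validation battery

@dataclass
class ValidationReport:
    """Statistics linking the upright step task to the in-scanner task."""

    n_subjects: int
    step_wilcoxon: WilcoxonResult           # supported vs unsupported, N/cm
    scanner_wilcoxon: WilcoxonResult        # supported vs unsupported, %
    cross_task: SpearmanResult              # step diff vs scanner diff
    step_diff: np.ndarray                   # unsupported − supported
    scanner_diff: np.ndarray
    updrs_vs_step: Optional[SpearmanResult] = None
    updrs_vs_scanner: Optional[SpearmanResult] = None

    def format_text(self) -> str:
        lines = [
            f"n = {self.n_subjects} matched subjects",
            (f"step task supported vs unsupported: W = "
             f"{self.step_wilcoxon.w:.1f}, Z = {self.step_wilcoxon.z:.2f}, "
             f"exact p = {self.step_wilcoxon.p_exact:.4f}"),
            (f"scanner task supported vs unsupported: W = "
             f"{self.scanner_wilcoxon.w:.1f}, Z = "
             f"{self.scanner_wilcoxon.z:.2f}, exact p = "
             f"{self.scanner_wilcoxon.p_exact:.4f}"),
            (f"cross-task correlation (difference scores): r_s = "
             f"{self.cross_task.r_s:.2f}, p = {self.cross_task.p:.3f} "
             f"[{self.cross_task.method}]"),
        ]
        for label, res in (("UPDRS vs step", self.updrs_vs_step),
                           ("UPDRS vs scanner", self.updrs_vs_scanner)):
            if res is not None:
                lines.append(f"{label}: r_s = {res.r_s:.2f}, p = {res.p:.3f}")
        return "\n".join(lines)


def validation_analysis(step_results, scanner_results,
                        clinical=None) -> ValidationReport:
    """The full cross-task validation battery on matched per-subject data.

    ``step_results`` and ``scanner_results`` are DataFrames with columns
    ``subject, supported, unsupported`` (step: F_ml amplitude in N/cm;
    scanner: force magnitude in %).  ``clinical``, if given, has columns
    ``subject, updrs_motor``.  Difference scores are unsupported −
    supported; correlations are Spearman; condition contrasts are exact
    Wilcoxon tests.
    """
    step = step_results.set_index("subject").sort_index()
    scan = scanner_results.set_index("subject").sort_index()
    if list(step.index) != list(scan.index):
        raise ValidationError("subject sets differ between tasks")
    step_diff = (step["unsupported"] - step["supported"]).to_numpy(float)
    scan_diff = (scan["unsupported"] - scan["supported"]).to_numpy(float)

    report = ValidationReport(
        n_subjects=len(step),
        step_wilcoxon=wilcoxon_exact(step["unsupported"].to_numpy(float),
                                     step["supported"].to_numpy(float)),
        scanner_wilcoxon=wilcoxon_exact(scan["unsupported"].to_numpy(float),
                                        scan["supported"].to_numpy(float)),
        cross_task=spearman(step_diff, scan_diff),
        step_diff=step_diff, scanner_diff=scan_diff)

    if clinical is not None:
        clin = clinical.set_index("subject").sort_index()
        if list(clin.index) != list(step.index):
            raise ValidationError("clinical subject set differs from tasks")
        updrs = clin["updrs_motor"].to_numpy(float)
        report.updrs_vs_step = spearman(updrs, step_diff)
        report.updrs_vs_scanner = spearman(updrs, scan_diff)
    return report
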