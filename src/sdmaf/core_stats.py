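"""Sex-difference-in-MAF tests and Hardy-Weinberg disequilibrium machinery.

All tests are Wald-type chi-square statistics on 1 df, with the female
variance term adjusted for Hardy-Weinberg disequilibrium (HWD) through the
delta estimator  delta = freq(AA) - freq(A)^2.  P-values are carried as
-log10 p and computed in log space, so statistics far beyond the double
underflow limit (p < 1e-308) still yield finite, accurate -log10 values.

Two exact HWE tests are provided: the classic within-sex conditional test
(enumeration over heterozygote counts given the allele count) and the joint
X-chromosomal test that conditions on the total A-allele count with
hemizygous males contributing single alleles and females diploid genotypes.
Both use log-space combinatorics and define the two-sided p-value as the
sum of outcome probabilities <= the observed outcome's probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import gammaln, log_ndtr, logsumexp

from .errors import DataError, ValidationError
from .genotype_io import DIPLOID, HEMIZYGOUS, SexStratifiedCounts

_LN10 = math.log(10.0)

#: Relative slack when comparing outcome probabilities in exact tests, to
#: absorb floating-point noise among genuinely tied tables.
_EXACT_TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# log-space p-values

def chisq1_neg_log10_sf(statistic: float) -> float:
    """-log10 of the 1-df chi-square survival function, safe to ~1e7 df units.

    Uses sf(x) = 2 * Phi(-sqrt(x)) evaluated through ``log_ndtr`` so the
    result never underflows; an infinite statistic propagates to +inf.
    """
    if statistic != statistic:  # NaN
        return float("nan")
    if statistic < 0:
        raise ValidationError(f"chi-square statistic must be >= 0, got {statistic}")
    if math.isinf(statistic):
        return float("inf")
    log_p = math.log(2.0) + float(log_ndtr(-math.sqrt(statistic)))
    return -log_p / _LN10


def chisq1_neg_log10_sf_arr(statistic: np.ndarray) -> np.ndarray:
    """Vectorised :func:`chisq1_neg_log10_sf` (NaN and inf propagate)."""
    stat = np.asarray(statistic, dtype=float)
    if np.any(stat[~np.isnan(stat)] < 0):
        raise ValidationError("chi-square statistics must be >= 0")
    with np.errstate(invalid="ignore"):
        out = -(np.log(2.0) + log_ndtr(-np.sqrt(stat))) / _LN10
    out[np.isinf(stat)] = np.inf
    return out


def neg_log10_to_p(neg_log10_p: float) -> float:
    """10**(-x), underflowing to 0.0 for x beyond double range."""
    if neg_log10_p != neg_log10_p:
        return float("nan")
    if math.isinf(neg_log10_p):
        return 0.0
    try:
        return 10.0 ** (-neg_log10_p)
    except OverflowError:
        return 0.0


def format_pvalue(neg_log10_p: float, floor: float = 300.0) -> str:
    """Render a p-value the way the result tables print it.

    Values below 10**-floor are shown as '<1E-300'-style strings; the
    numeric -log10 value is kept in a separate column by the writers.
    """
    if neg_log10_p != neg_log10_p:
        return "NA"
    if neg_log10_p > floor:
        return f"<1E-{int(floor)}"
    return f"{neg_log10_to_p(neg_log10_p):.2E}"


# ---------------------------------------------------------------------------
# frequency and HWD estimation

@dataclass(frozen=True)
class FreqEstimate:
    """Per-sex allele-A frequency, variance and HWD estimates."""

    p_f: float
    p_m: float
    var_f: float
    var_m: float
    delta_f: float
    delta_m: Optional[float]  # absent for hemizygous males
    male_layout: str


def hwd_delta(triple: tuple[int, int, int]) -> float:
    """HWD estimate delta = freq(AA) - freq(A)^2 for a diploid triple."""
    n0, n1, n2 = triple
    n = n0 + n1 + n2
    if n == 0:
        raise DataError("empty genotype triple")
    p = (2 * n2 + n1) / (2 * n)
    return n2 / n - p * p


def estimate_freqs(counts: SexStratifiedCounts) -> FreqEstimate:
    """Per-sex frequency/variance/HWD estimates for the designated allele."""
    f = counts.n_female
    m = counts.n_male
    if f == 0:
        raise DataError("empty female stratum")
    if m == 0:
        raise DataError("empty male stratum")
    f0, f1, f2 = counts.female
    p_f = (2 * f2 + f1) / (2 * f)
    d_f = f2 / f - p_f * p_f
    var_f = (p_f * (1 - p_f) + d_f) / (2 * f)
    if counts.male_layout == HEMIZYGOUS:
        p_m = counts.male[1] / m
        return FreqEstimate(p_f=p_f, p_m=p_m, var_f=var_f,
                            var_m=p_m * (1 - p_m) / m,
                            delta_f=d_f, delta_m=None, male_layout=HEMIZYGOUS)
    m0, m1, m2 = counts.male
    p_m = (2 * m2 + m1) / (2 * m)
    d_m = m2 / m - p_m * p_m
    var_m = (p_m * (1 - p_m) + d_m) / (2 * m)
    return FreqEstimate(p_f=p_f, p_m=p_m, var_f=var_f, var_m=var_m,
                        delta_f=d_f, delta_m=d_m, male_layout=DIPLOID)


# ---------------------------------------------------------------------------
# sdMAF Wald tests

@dataclass(frozen=True)
class SdMafResult:
    """Result of one sdMAF test (female minus male designated-allele freq)."""

    sdmaf: float
    statistic: float
    neg_log10_p: float
    p_f: float
    p_m: float
    minor_allele_f: str
    minor_allele_m: str
    flip: bool
    degenerate: bool
    test: str  # 'T_X' (hemizygous males) or 'T_A' (diploid males)

    @property
    def p_value(self) -> float:
        return neg_log10_to_p(self.neg_log10_p)


def _within_sex_minor(p: float, allele_A: str, allele_a: str) -> str:
    if p < 0.5:
        return allele_A
    if p > 0.5:
        return allele_a
    return "tie"


def _finish_sdmaf(
    counts: SexStratifiedCounts, est: FreqEstimate, denom: float, test: str
) -> SdMafResult:
    diff = est.p_f - est.p_m
    if denom > 0:
        stat = diff * diff / denom
        nlp = chisq1_neg_log10_sf(stat)
        degenerate = False
    elif diff == 0:
        stat, nlp, degenerate = float("nan"), float("nan"), True
    else:
        stat, nlp, degenerate = float("inf"), float("inf"), True
    ma_f = _within_sex_minor(est.p_f, counts.allele_A, counts.allele_a)
    ma_m = _within_sex_minor(est.p_m, counts.allele_A, counts.allele_a)
    flip = "tie" not in (ma_f, ma_m) and ma_f != ma_m
    return SdMafResult(
        sdmaf=diff, statistic=stat, neg_log10_p=nlp,
        p_f=est.p_f, p_m=est.p_m,
        minor_allele_f=ma_f, minor_allele_m=ma_m,
        flip=flip, degenerate=degenerate, test=test,
    )


def sdmaf_test_npr(counts: SexStratifiedCounts) -> SdMafResult:
    """HWD-adjusted sdMAF test for NPR/PAR3 sites (hemizygous males).

    T = (p_f - p_m)^2 / [ (p_f(1-p_f)+delta_f)/(2f) + p_m(1-p_m)/m ],
    chi-square on 1 df under no sex difference.
    """
    if counts.male_layout != HEMIZYGOUS:
        raise ValidationError("sdmaf_test_npr requires hemizygous male layout")
    est = estimate_freqs(counts)
    return _finish_sdmaf(counts, est, est.var_f + est.var_m, "T_X")


def sdmaf_test_par(counts: SexStratifiedCounts) -> SdMafResult:
    """HWD-adjusted sdMAF test for PAR1/PAR2 sites (diploid males).

    T = (p_f - p_m)^2 / [ (p_f(1-p_f)+delta_f)/(2f)
                          + (p_m(1-p_m)+delta_m)/(2m) ].
    """
    if counts.male_layout != DIPLOID:
        raise ValidationError("sdmaf_test_par requires diploid male layout")
    est = estimate_freqs(counts)
    return _finish_sdmaf(counts, est, est.var_f + est.var_m, "T_A")


def sdmaf_test(counts: SexStratifiedCounts) -> SdMafResult:
    """Region-appropriate sdMAF test, dispatched on the male layout."""
    if counts.male_layout == HEMIZYGOUS:
        return sdmaf_test_npr(counts)
    return sdmaf_test_par(counts)


def sdmaf_stat_npr_arr(
    f0: np.ndarray, f1: np.ndarray, f2: np.ndarray,
    m_ref: np.ndarray, m_alt: np.ndarray,
) -> np.ndarray:
    """Vectorised T statistic of :func:`sdmaf_test_npr` over count arrays."""
    f = f0 + f1 + f2
    m = m_ref + m_alt
    p_f = (2 * f2 + f1) / (2 * f)
    d_f = f2 / f - p_f**2
    p_m = m_alt / m
    denom = (p_f * (1 - p_f) + d_f) / (2 * f) + p_m * (1 - p_m) / m
    num = (p_f - p_m) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, num / denom,
                        np.where(num > 0, np.inf, np.nan))
    return stat


def sdmaf_stat_par_arr(
    f0: np.ndarray, f1: np.ndarray, f2: np.ndarray,
    m0: np.ndarray, m1: np.ndarray, m2: np.ndarray,
) -> np.ndarray:
    """Vectorised T statistic of :func:`sdmaf_test_par` over count arrays."""
    f = f0 + f1 + f2
    m = m0 + m1 + m2
    p_f = (2 * f2 + f1) / (2 * f)
    d_f = f2 / f - p_f**2
    p_m = (2 * m2 + m1) / (2 * m)
    d_m = m2 / m - p_m**2
    denom = (p_f * (1 - p_f) + d_f) / (2 * f) + (p_m * (1 - p_m) + d_m) / (2 * m)
    num = (p_f - p_m) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, num / denom,
                        np.where(num > 0, np.inf, np.nan))
    return stat


# ---------------------------------------------------------------------------
# HWE chi-square tests

@dataclass(frozen=True)
class HweResult:
    """One HWE/HWD test result."""

    scope: str  # 'female' | 'male' | 'sex_combined'
    delta: float
    statistic: Optional[float]
    neg_log10_p: float
    method: str  # 'chisq' | 'exact_within_sex' | 'exact_x_joint'
    p_hat: Optional[float] = None
    n: Optional[int] = None
    n_female: Optional[int] = None
    n_male: Optional[int] = None

    @property
    def p_value(self) -> float:
        return neg_log10_to_p(self.neg_log10_p)


def hwe_chisq_stat_expected_form(triple: tuple[int, int, int]) -> float:
    """Pearson HWE chi-square via observed-vs-expected genotype counts.

    Expected counts use the estimated allele frequency: (n(1-p)^2, 2np(1-p),
    np^2).  Algebraically identical to the delta form; both are kept so they
    can be checked against each other.
    """
    n0, n1, n2 = triple
    n = n0 + n1 + n2
    if n == 0:
        raise DataError("empty genotype triple")
    p = (2 * n2 + n1) / (2 * n)
    q = 1 - p
    e0, e1, e2 = n * q * q, 2 * n * p * q, n * p * p
    if e0 == 0 or e1 == 0 or e2 == 0:  # monomorphic
        return float("nan")
    return ((n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2)


def hwe_chisq_stat_delta_form(triple: tuple[int, int, int]) -> float:
    """Pearson HWE chi-square as  delta^2 / [ p^2 (1-p)^2 / n ]."""
    n0, n1, n2 = triple
    n = n0 + n1 + n2
    if n == 0:
        raise DataError("empty genotype triple")
    p = (2 * n2 + n1) / (2 * n)
    if p == 0.0 or p == 1.0:
        return float("nan")
    d = n2 / n - p * p
    return d * d * n / (p * p * (1 - p) * (1 - p))


def hwe_chisq(counts: SexStratifiedCounts, scope: str) -> HweResult:
    """HWD chi-square test in one of three scopes.

    'female' tests the female triple; 'male' and 'sex_combined' require the
    diploid male layout ('sex_combined' pools the two triples and uses the
    pooled frequency and delta).  A monomorphic scope yields NaN statistic
    and p (the NA-equivalent).
    """
    if scope == "female":
        triple = counts.female
    elif scope == "male":
        if counts.male_layout != DIPLOID:
            raise ValidationError(
                "male-scope HWE test requires diploid male layout"
            )
        triple = counts.male  # type: ignore[assignment]
    elif scope == "sex_combined":
        if counts.male_layout != DIPLOID:
            raise ValidationError(
                "sex-combined HWE test requires diploid male layout"
            )
        triple = tuple(a + b for a, b in zip(counts.female, counts.male))
    else:
        raise ValidationError(f"unknown scope {scope!r}")
    n0, n1, n2 = triple
    n = n0 + n1 + n2
    if n == 0:
        raise DataError(f"empty {scope} stratum")
    p = (2 * n2 + n1) / (2 * n)
    delta = hwd_delta(triple)
    stat = hwe_chisq_stat_delta_form(triple)
    nlp = chisq1_neg_log10_sf(stat) if stat == stat else float("nan")
    return HweResult(
        scope=scope, delta=delta, statistic=stat, neg_log10_p=nlp,
        method="chisq", p_hat=p, n=n,
        n_female=counts.n_female, n_male=counts.n_male,
    )


# ---------------------------------------------------------------------------
# exact HWE tests

def _log_binom(n: int, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _exact_two_sided(log_probs: np.ndarray, log_obs: float) -> float:
    """Two-sided exact p on the -log10 scale: sum P(outcome) <= P(observed)."""
    keep = log_probs <= log_obs + _EXACT_TIE_TOL
    log_p = float(logsumexp(log_probs[keep]) - logsumexp(log_probs))
    return min(-log_p / _LN10, float("inf"))


def hwe_exact_within_sex(triple: tuple[int, int, int]) -> HweResult:
    """Conditional exact HWE test for one diploid sex stratum.

    Enumerates heterozygote counts with the parity of the minor-allele count,
    conditional on the allele count; two-sided p sums probabilities <= the
    observed table's.  Monomorphic strata give p = 1.
    """
    n0, n1, n2 = triple
    n = n0 + n1 + n2
    if n == 0:
        raise DataError("empty genotype triple")
    nA = 2 * n2 + n1
    nB = 2 * n0 + n1
    n_minor = min(nA, nB)
    if n_minor == 0:
        return HweResult(scope="within_sex", delta=hwd_delta(triple),
                         statistic=None, neg_log10_p=0.0,
                         method="exact_within_sex", n=n)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    homA = (nA - hets) // 2
    homB = (nB - hets) // 2
    # P(n1 = h | nA, n) proportional to n! 2^h / (homA! h! homB!)
    log_w = (hets * math.log(2.0) - gammaln(homA + 1) - gammaln(hets + 1)
             - gammaln(homB + 1))
    log_obs = float(log_w[np.searchsorted(hets, n1)])
    nlp = _exact_two_sided(log_w, log_obs)
    return HweResult(scope="within_sex", delta=hwd_delta(triple),
                     statistic=None, neg_log10_p=nlp,
                     method="exact_within_sex", n=n)


def hwe_exact_x_joint(
    female: tuple[int, int, int], male: tuple[int, int]
) -> HweResult:
    """Joint X-chromosomal exact HWE test for females plus hemizygous males.

    Conditions on the total A-allele count and the two sample sizes;
    enumerates (male A-carrier count, female heterozygote count)
    configurations where males contribute single alleles and females diploid
    genotypes.  Under the null, allele frequencies are equal across sexes
    and female genotypes are in HWE, so the configuration probability is
    proportional to C(m, mA) * f!/(fAA! fAB! fBB!) * 2^fAB.  Two-sided p
    sums configuration probabilities <= the observed configuration's.
    """
    f0, f1, f2 = female
    m_ref, m_alt = male
    f = f0 + f1 + f2
    m = m_ref + m_alt
    if f + m == 0 or (2 * f + m) == 0:
        raise DataError("no alleles in input")
    if m == 0:
        res = hwe_exact_within_sex(female)
        return HweResult(scope="sex_combined", delta=res.delta,
                         statistic=None, neg_log10_p=res.neg_log10_p,
                         method="exact_x_joint", n=f + m,
                         n_female=f, n_male=m)
    nA = 2 * f2 + f1 + m_alt
    nB = 2 * f0 + f1 + m_ref
    if nA == 0 or nB == 0:  # monomorphic overall
        return HweResult(scope="sex_combined", delta=hwd_delta(female),
                         statistic=None, neg_log10_p=0.0,
                         method="exact_x_joint", n=f + m,
                         n_female=f, n_male=m)
    log_terms = []
    log_obs = None
    for mA in range(max(0, nA - 2 * f), min(m, nA) + 1):
        fem_A = nA - mA
        if fem_A > 2 * f:
            continue
        hets = np.arange(fem_A % 2, min(f, fem_A) + 1, 2)
        fAA = (fem_A - hets) // 2
        fBB = f - fAA - hets
        ok = fBB >= 0
        hets, fAA, fBB = hets[ok], fAA[ok], fBB[ok]
        if hets.size == 0:
            continue
        log_w = (float(_log_binom(m, mA)) + hets * math.log(2.0)
                 - gammaln(fAA + 1) - gammaln(hets + 1) - gammaln(fBB + 1))
        log_terms.append(log_w)
        if mA == m_alt:
            idx = np.searchsorted(hets, f1)
            if idx < hets.size and hets[idx] == f1:
                log_obs = float(log_w[idx])
    if log_obs is None:
        raise DataError("observed configuration not reachable; inconsistent input")
    all_logs = np.concatenate(log_terms)
    nlp = _exact_two_sided(all_logs, log_obs)
    return HweResult(scope="sex_combined", delta=hwd_delta(female),
                     statistic=None, neg_log10_p=nlp,
                     method="exact_x_joint", n=f + m, n_female=f, n_male=m)
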