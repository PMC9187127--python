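"""Population-stratified sdMAF analysis, sqrt(n)-weighted meta-analysis,
minor-allele-flip detection, and Bland-Altman summaries."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy.special import log_ndtr

from .core_stats import SdMafResult, estimate_freqs, sdmaf_test
from .errors import DataError
from .genotype_io import HEMIZYGOUS, SexStratifiedCounts

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class StratumResult:
    """One stratum's sdMAF result with its weighting sample size."""

    stratum: str
    result: Optional[SdMafResult]
    n: int  # allele-count (default) or individual-count contribution
    polymorphic: bool


def _allele_n(counts: SexStratifiedCounts) -> int:
    if counts.male_layout == HEMIZYGOUS:
        return 2 * counts.n_female + counts.n_male
    return 2 * (counts.n_female + counts.n_male)


def stratified_sdmaf(
    strata: dict[str, SexStratifiedCounts],
    weight: str = "alleles",
) -> list[StratumResult]:
    """Run the region-appropriate sdMAF test separately per stratum.

    The designated allele must already be fixed from the pooled sample on
    every stratum's counts (stratification never re-designates the minor
    allele).  Strata monomorphic in both sexes are flagged non-polymorphic
    and carry no test result; empty strata are flagged, not fatal.
    ``weight`` selects the n_i reported for meta-analysis: 'alleles'
    (2f + m in hemizygous regions, 2(f + m) otherwise) or 'individuals'.
    """
    if weight not in ("alleles", "individuals"):
        raise ValueError(f"unknown weight scheme {weight!r}")
    out = []
    for label, counts in strata.items():
        n = _allele_n(counts) if weight == "alleles" \
            else counts.n_female + counts.n_male
        if counts.n_female == 0 or counts.n_male == 0:
            logger.warning("stratum %s has an empty sex stratum; skipped", label)
            out.append(StratumResult(label, None, n, polymorphic=False))
            continue
        fa, fA = counts.female_allele_counts
        ma, mA = counts.male_allele_counts
        polymorphic = (fa + ma) > 0 and (fA + mA) > 0
        if not polymorphic:
            out.append(StratumResult(label, None, n, polymorphic=False))
            continue
        out.append(StratumResult(label, sdmaf_test(counts), n, polymorphic=True))
    return out


@dataclass(frozen=True)
class MetaResult:
    """sqrt(n)-weighted Z-score meta-analysis of per-stratum sdMAF tests."""

    z: float
    neg_log10_p: float
    z_per_stratum: dict[str, float]
    weights: dict[str, float]
    included: tuple[str, ...]
    sign_heterogeneity: bool
    infinite: bool
    empty: bool


def meta_sdmaf(strata: Sequence[StratumResult]) -> MetaResult:
    """Combine per-stratum sdMAF Z-scores: Z = sum(w_i Z_i) / sqrt(sum w_i^2),
    with w_i = sqrt(n_i).

    Only polymorphic strata with a test result enter.  An infinite-statistic
    stratum (sex-fixed genotype: zero variance) is excluded from the
    weighted sum but flags the combined result as infinite.
    """
    z_per: dict[str, float] = {}
    weights: dict[str, float] = {}
    included: list[str] = []
    infinite = False
    signs = set()
    for s in strata:
        if s.result is None or not s.polymorphic:
            continue
        if s.result.degenerate and math.isinf(s.result.statistic):
            infinite = True
            logger.warning(
                "stratum %s has an infinite sdMAF statistic; excluded from "
                "the weighted sum", s.stratum)
            continue
        if s.result.statistic != s.result.statistic:  # NaN (degenerate 0/0)
            continue
        z = math.copysign(math.sqrt(s.result.statistic), s.result.sdmaf) \
            if s.result.sdmaf != 0 else 0.0
        z_per[s.stratum] = z
        weights[s.stratum] = math.sqrt(s.n)
        included.append(s.stratum)
        if z != 0:
            signs.add(z > 0)
    if not included:
        return MetaResult(
            z=float("nan"), neg_log10_p=float("nan"), z_per_stratum={},
            weights={}, included=(), sign_heterogeneity=False,
            infinite=infinite, empty=True,
        )
    num = sum(weights[k] * z_per[k] for k in included)
    den = math.sqrt(sum(weights[k] ** 2 for k in included))
    z = num / den
    if infinite:
        nlp = float("inf")
    else:
        nlp = -(math.log(2.0) + float(log_ndtr(-abs(z)))) / _LN10
    return MetaResult(
        z=z, neg_log10_p=nlp, z_per_stratum=z_per, weights=weights,
        included=tuple(included), sign_heterogeneity=len(signs) > 1,
        infinite=infinite, empty=False,
    )


def detect_minor_flip(
    counts: SexStratifiedCounts,
) -> tuple[bool, str, str]:
    """Whether the within-female and within-male minor alleles differ.

    Returns (flip, minor_allele_f, minor_allele_m); a within-sex frequency
    of exactly 0.5 is reported as 'tie' and never counts as a flip.
    """
    est = estimate_freqs(counts)

    def minor(p: float) -> str:
        if p < 0.5:
            return counts.allele_A
        if p > 0.5:
            return counts.allele_a
        return "tie"

    ma_f, ma_m = minor(est.p_f), minor(est.p_m)
    flip = "tie" not in (ma_f, ma_m) and ma_f != ma_m
    return flip, ma_f, ma_m


# ---------------------------------------------------------------------------
# Bland-Altman

@dataclass(frozen=True)
class BlandAltmanPoint:
    """difference-vs-level point: sex-combined MAF against sdMAF."""

    x: float  # sex-combined MAF of the designated (pooled-minor) allele
    y: float  # female-minus-male frequency difference
    region: str
    flip: bool


def bland_altman_point(
    counts: SexStratifiedCounts, region: str
) -> BlandAltmanPoint:
    """Construct the point for one variant from its sex-stratified counts."""
    est = estimate_freqs(counts)
    fa, fA = counts.female_allele_counts
    ma, mA = counts.male_allele_counts
    total = fa + fA + ma + mA
    if total == 0:
        raise DataError("zero total allele count")
    x = (fA + mA) / total
    flip, _, _ = detect_minor_flip(counts)
    return BlandAltmanPoint(x=x, y=est.p_f - est.p_m, region=region, flip=flip)


def bland_altman(
    per_variant: Sequence[tuple[SexStratifiedCounts, str]],
) -> list[BlandAltmanPoint]:
    """Bland-Altman points for a collection of (counts, region) pairs."""
    return [bland_altman_point(c, r) for c, r in per_variant]


def flip_bounds(
    x: float, w_f: float
) -> tuple[float, float, float, float]:
    """Theoretical sdMAF bounds for variants whose minor allele flips by sex.

    Write the sex-combined frequency of the designated allele as
    x = w_f p_f + (1 - w_f) p_m with w_f the female share of the pooled
    allele count.  Then p_f = x + (1-w_f) y and p_m = x - w_f y, where
    y = p_f - p_m.  A flip puts one sex's frequency above 1/2 and the
    other's below, so positive-y flips satisfy
        (1/2 - x)/(1 - w_f) <= y <= min(x/w_f, (1 - x)/(1 - w_f)),
    the upper limit coming from 0 <= p_m and p_f <= 1; negative-y flips are
    the mirror image.  Returns (y_pos_min, y_pos_max, y_neg_max, y_neg_min),
    i.e. the positive band then the negative band.
    """
    if not (0 <= x <= 1):
        raise ValueError("x must be a frequency")
    if not (0 < w_f < 1):
        raise ValueError("w_f must be strictly between 0 and 1")
    w_m = 1.0 - w_f
    y_pos_min = (0.5 - x) / w_m
    y_pos_max = min(x / w_f, (1.0 - x) / w_m)
    y_neg_max = -(0.5 - x) / w_f
    y_neg_min = max(-x / w_m, -(1.0 - x) / w_f)
    return y_pos_min, y_pos_max, y_neg_max, y_neg_min


def in_flip_bounds(x: float, y: float, w_f: float) -> bool:
    """True if (x, y) lies inside the flipped-minor-allele bands."""
    pos_min, pos_max, neg_max, neg_min = flip_bounds(x, w_f)
    eps = 1e-12
    if y >= 0:
        return pos_min - eps <= y <= pos_max + eps
    return neg_min - eps <= y <= neg_max + eps
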