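"""Synthetic sex-stratified genotype data with configurable structure.

Generates per-population genotype counts (and matching individual-level
VCFs) under a trinomial female model with explicit Hardy-Weinberg
disequilibrium deltas, Bernoulli hemizygous males or trinomial diploid
males, sex-differential missingness, and a hemizygote-miscall error model.
Every draw is reproducible: one seed per run, with per-variant substreams
derived deterministically so variant order never changes the draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .core_stats import (
    chisq1_neg_log10_sf_arr,
    sdmaf_stat_npr_arr,
    sdmaf_stat_par_arr,
)
from .errors import ValidationError
from .genotype_io import DIPLOID, HEMIZYGOUS, SexStratifiedCounts
from .regions import RegionMap

MISSING = -1


def _check_delta(p: float, delta: float, who: str) -> None:
    lo = max(-p * p, -(1 - p) * (1 - p))
    hi = p * (1 - p)
    if not (lo - 1e-12 <= delta <= hi + 1e-12):
        raise ValidationError(
            f"{who}: delta {delta} outside feasible range [{lo:.6g}, {hi:.6g}] "
            f"for p = {p}"
        )


@dataclass(frozen=True)
class PopulationConfig:
    """One population's sample sizes and per-sex allele model."""

    label: str
    n_female: int
    n_male: int
    p_f: float
    p_m: float
    delta_f: float = 0.0
    delta_m: float = 0.0  # used only with diploid males

    def validate(self, male_layout: str) -> None:
        for name, p in (("p_f", self.p_f), ("p_m", self.p_m)):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{self.label}: {name} must be in [0, 1]")
        if self.n_female < 0 or self.n_male < 0:
            raise ValidationError(f"{self.label}: sample sizes must be >= 0")
        _check_delta(self.p_f, self.delta_f, f"{self.label} females")
        if male_layout == DIPLOID:
            _check_delta(self.p_m, self.delta_m, f"{self.label} males")


@dataclass(frozen=True)
class ErrorModel:
    """Sex-differential missingness and hemizygote-miscall probabilities.

    ``male_het_miscall`` is the probability that a hemizygous
    alternate-carrying male is miscalled as heterozygous (a low-coverage
    artefact); under the 'set_missing' tallying policy such calls become
    missing, depressing the observed male alternate frequency.
    """

    female_missing: float = 0.0
    male_missing: float = 0.0
    male_het_miscall: float = 0.0

    def validate(self) -> None:
        for name in ("female_missing", "male_missing", "male_het_miscall"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"error-model rate {name} must be in [0, 1]")

    @property
    def is_identity(self) -> bool:
        return (self.female_missing == 0 and self.male_missing == 0
                and self.male_het_miscall == 0)


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic dataset."""

    populations: tuple[PopulationConfig, ...]
    region: str = "NPR"
    error_model: ErrorModel = field(default_factory=ErrorModel)
    seed: int = 0

    @property
    def male_layout(self) -> str:
        return HEMIZYGOUS if self.region in ("NPR", "PAR3") else DIPLOID

    def validate(self) -> None:
        if self.region not in ("NPR", "PAR1", "PAR2", "PAR3"):
            raise ValidationError(f"unknown region {self.region!r}")
        if not self.populations:
            raise ValidationError("at least one population required")
        self.error_model.validate()
        for pop in self.populations:
            pop.validate(self.male_layout)


def default_config(seed: int = 0, region: str = "NPR") -> SimulationConfig:
    """Five populations of ~500 with near-equal sex ratios."""
    freqs = (0.1, 0.2, 0.3, 0.4, 0.5)
    pops = tuple(
        PopulationConfig(label=f"POP{i+1}", n_female=250, n_male=250,
                         p_f=p, p_m=p)
        for i, p in enumerate(freqs)
    )
    return SimulationConfig(populations=pops, region=region, seed=seed)


def _variant_rng(seed: int, variant_index: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(entropy=seed, spawn_key=(variant_index,))
    ))


def _female_probs(p: float, delta: float) -> np.ndarray:
    q = 1 - p
    probs = np.array([q * q + delta, 2 * p * q - 2 * delta, p * p + delta])
    probs = np.clip(probs, 0.0, None)
    return probs / probs.sum()


def _draw_genotypes(
    pop: PopulationConfig, layout: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Individual-level genotype codes (female array, male array)."""
    fem_counts = rng.multinomial(pop.n_female, _female_probs(pop.p_f, pop.delta_f))
    female = np.repeat(np.array([0, 1, 2]), fem_counts)
    rng.shuffle(female)
    if layout == HEMIZYGOUS:
        male = 2 * rng.binomial(1, pop.p_m, size=pop.n_male)
    else:
        male_counts = rng.multinomial(pop.n_male, _female_probs(pop.p_m, pop.delta_m))
        male = np.repeat(np.array([0, 1, 2]), male_counts)
        rng.shuffle(male)
    return female, male


def apply_error_model(
    female: np.ndarray,
    male: np.ndarray,
    model: ErrorModel,
    rng: np.random.Generator,
    male_layout: str = HEMIZYGOUS,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply miscalls and missingness to true genotype-code arrays.

    With all rates zero this is the identity.  Hemizygote miscalls turn a
    male code 2 (alt carrier) into code 1 (spurious heterozygote); the
    downstream tallying policy decides that call's fate.  Missingness sets
    codes to ``MISSING`` at the configured per-sex rates.
    """
    model.validate()
    female = female.copy()
    male = male.copy()
    if model.male_het_miscall > 0 and male_layout == HEMIZYGOUS:
        carriers = np.flatnonzero(male == 2)
        hit = carriers[rng.random(carriers.size) < model.male_het_miscall]
        male[hit] = 1
    if model.female_missing > 0:
        female[rng.random(female.size) < model.female_missing] = MISSING
    if model.male_missing > 0:
        male[rng.random(male.size) < model.male_missing] = MISSING
    return female, male


def _tally_codes(
    female: np.ndarray, male: np.ndarray, layout: str, pop: PopulationConfig
) -> SexStratifiedCounts:
    f = tuple(int(np.sum(female == g)) for g in (0, 1, 2))
    miss_f = int(np.sum(female == MISSING))
    if layout == HEMIZYGOUS:
        # spurious heterozygote male calls (code 1) count as missing here,
        # matching the 'set_missing' tallying policy
        m: tuple[int, ...] = (int(np.sum(male == 0)), int(np.sum(male == 2)))
        miss_m = int(np.sum(male == MISSING) + np.sum(male == 1))
    else:
        m = tuple(int(np.sum(male == g)) for g in (0, 1, 2))
        miss_m = int(np.sum(male == MISSING))
    return SexStratifiedCounts(
        female=f, male=m, male_layout=layout,
        missing_female=miss_f, missing_male=miss_m,
    )


def simulate_counts(
    config: SimulationConfig, n_variants: int
) -> list[dict[str, SexStratifiedCounts]]:
    """Draw per-variant, per-population sex-stratified genotype counts."""
    config.validate()
    layout = config.male_layout
    out = []
    for v in range(n_variants):
        rng = _variant_rng(config.seed, v)
        per_pop = {}
        for pop in config.populations:
            female, male = _draw_genotypes(pop, layout, rng)
            female, male = apply_error_model(
                female, male, config.error_model, rng, layout)
            per_pop[pop.label] = _tally_codes(female, male, layout, pop)
        out.append(per_pop)
    return out


# ---------------------------------------------------------------------------
# VCF emission

def _gt_string(code: int, haploid: bool) -> str:
    if haploid:
        return {MISSING: ".", 0: "0", 1: "0/1", 2: "1"}[code]
    return {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}[code]


def simulate_vcf(
    config: SimulationConfig,
    n_variants: int,
    positions: Sequence[int],
    vcf_path: Union[str, Path],
    sex_map_path: Union[str, Path],
    region_map: Optional[RegionMap] = None,
    truth_path: Union[str, Path, None] = None,
) -> list[dict[str, SexStratifiedCounts]]:
    """Write a VCF + sex-map TSV whose tally reproduces ``simulate_counts``.

    Males in hemizygous regions are written haploid ('0'/'1'), except for
    error-model-induced spurious heterozygote calls which are written '0/1'.
    If a ``region_map`` is given, every position must map to the configured
    region.  Returns the drawn counts (same seed stream as
    :func:`simulate_counts`).
    """
    config.validate()
    if len(positions) != n_variants:
        raise ValidationError("need one position per variant")
    if region_map is not None:
        for pos in positions:
            got = region_map.assign(pos)
            if got != config.region:
                raise ValidationError(
                    f"position {pos} maps to {got}, config says {config.region}"
                )
    layout = config.male_layout
    haploid_males = layout == HEMIZYGOUS

    samples: list[str] = []
    sexes: list[str] = []
    for pop in config.populations:
        samples += [f"{pop.label}_F{i}" for i in range(pop.n_female)]
        sexes += ["F"] * pop.n_female
        samples += [f"{pop.label}_M{i}" for i in range(pop.n_male)]
        sexes += ["M"] * pop.n_male

    counts_out = []
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=X>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for v in range(n_variants):
            rng = _variant_rng(config.seed, v)
            per_pop = {}
            gt_fields = []
            for pop in config.populations:
                female, male = _draw_genotypes(pop, layout, rng)
                female, male = apply_error_model(
                    female, male, config.error_model, rng, layout)
                per_pop[pop.label] = _tally_codes(female, male, layout, pop)
                gt_fields += [_gt_string(int(c), False) for c in female]
                gt_fields += [_gt_string(int(c), haploid_males) for c in male]
            counts_out.append(per_pop)
            fh.write(f"X\t{positions[v]}\tvar{v}\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(gt_fields) + "\n")

    with open(sex_map_path, "w") as fh:
        fh.write("sample\tsex\n")
        for s, sx in zip(samples, sexes):
            fh.write(f"{s}\t{sx}\n")

    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("VARIANT\tPOS\tPOPULATION\tP_F\tP_M\tDELTA_F\tDELTA_M\n")
            for v in range(n_variants):
                for pop in config.populations:
                    fh.write(f"var{v}\t{positions[v]}\t{pop.label}\t"
                             f"{pop.p_f}\t{pop.p_m}\t{pop.delta_f}\t"
                             f"{pop.delta_m}\n")
    return counts_out


# ---------------------------------------------------------------------------
# operating-characteristic experiments

def _pooled_count_arrays(
    config: SimulationConfig, n_reps: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Vectorised pooled genotype counts across populations, one row per rep."""
    layout = config.male_layout
    keys = (["f0", "f1", "f2", "m_ref", "m_alt"] if layout == HEMIZYGOUS
            else ["f0", "f1", "f2", "m0", "m1", "m2"])
    total = {k: np.zeros(n_reps) for k in keys}
    for pop in config.populations:
        fem = rng.multinomial(
            pop.n_female, _female_probs(pop.p_f, pop.delta_f), size=n_reps)
        total["f0"] += fem[:, 0]
        total["f1"] += fem[:, 1]
        total["f2"] += fem[:, 2]
        if layout == HEMIZYGOUS:
            alt = rng.binomial(pop.n_male, pop.p_m, size=n_reps)
            total["m_alt"] += alt
            total["m_ref"] += pop.n_male - alt
        else:
            mal = rng.multinomial(
                pop.n_male, _female_probs(pop.p_m, pop.delta_m), size=n_reps)
            total["m0"] += mal[:, 0]
            total["m1"] += mal[:, 1]
            total["m2"] += mal[:, 2]
    return total


def null_typeI_experiment(
    config: SimulationConfig, n_reps: int, alpha: float = 0.05
) -> dict[str, float]:
    """Empirical rejection rate of the pooled-sample sdMAF test at ``alpha``.

    The configuration should satisfy the null p_f = p_m within every
    population (frequencies may differ across populations).  Populations are
    pooled before testing, so pooling HWE populations with unequal
    frequencies exercises the conservativeness of the female-HWD-adjusted
    denominator.  Returns the rejection rate, its Monte-Carlo standard
    error, and bookkeeping fields.
    """
    config.validate()
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    rng = _variant_rng(config.seed, 0)
    counts = _pooled_count_arrays(config, n_reps, rng)
    if config.male_layout == HEMIZYGOUS:
        stat = sdmaf_stat_npr_arr(
            counts["f0"], counts["f1"], counts["f2"],
            counts["m_ref"], counts["m_alt"])
        test = "T_X"
    else:
        stat = sdmaf_stat_par_arr(
            counts["f0"], counts["f1"], counts["f2"],
            counts["m0"], counts["m1"], counts["m2"])
        test = "T_A"
    nlp = chisq1_neg_log10_sf_arr(stat)
    valid = ~np.isnan(nlp)
    reject = nlp[valid] > -np.log10(alpha)
    rate = float(np.mean(reject))
    mc_se = float(np.sqrt(alpha * (1 - alpha) / reject.size))
    return {
        "test": test,
        "alpha": alpha,
        "rejection_rate": rate,
        "mc_se": mc_se,
        "n_reps": n_reps,
        "n_valid": int(reject.size),
    }


def power_experiment(
    config: SimulationConfig, n_reps: int, alpha: float = 0.05
) -> float:
    """Empirical rejection rate under whatever alternative ``config`` encodes."""
    return null_typeI_experiment(config, n_reps, alpha)["rejection_rate"]


def scaled(config: SimulationConfig, factor: int) -> SimulationConfig:
    """The same configuration with every sample size multiplied by ``factor``."""
    return replace(config, populations=tuple(
        replace(p, n_female=p.n_female * factor, n_male=p.n_male * factor)
        for p in config.populations
    ))
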