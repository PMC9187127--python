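"""Genotype input: VCF tallying, count tables, variant filtering.

Converts per-sample genotype calls (VCF) or aggregated sex-stratified count
tables into :class:`SexStratifiedCounts`, applies the biallelic-SNP /
MAF-threshold selection pipeline, and computes the global (sex-pooled) MAF
that designates the minor allele.

Genotype count layout follows the usual X-chromosome convention: females
always carry the diploid triple (f0, f1, f2) = counts of (aa, Aa, AA) where
``A`` is the designated allele; males are diploid (m0, m1, m2) in PAR1/PAR2
and hemizygous (ref-carriers, A-carriers) in NPR/PAR3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

from .errors import DataError, ValidationError
from .regions import RegionMap

logger = logging.getLogger(__name__)

DIPLOID = "diploid"
HEMIZYGOUS = "hemizygous"

_SEX_CODES = {
    "f": "female", "female": "female", "2": "female",
    "m": "male", "male": "male", "1": "male",
}


def read_sex_map(source: Union[str, Path]) -> dict[str, str]:
    """Read a two-column sample->sex TSV into {sample: 'female'|'male'}.

    Accepted sex codes: F/M, 1/2 (PED convention), female/male, any case.
    A header line whose second column is literally 'sex' is skipped.
    """
    mapping: dict[str, str] = {}
    with open(source) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValidationError(
                    f"{source}:{line_no}: expected two columns (sample, sex)"
                )
            sample, code = fields[0].strip(), fields[1].strip()
            if line_no == 1 and code.lower() == "sex":
                continue
            if sample in mapping:
                raise ValidationError(
                    f"{source}:{line_no}: duplicate sample {sample!r}"
                )
            try:
                mapping[sample] = _SEX_CODES[code.lower()]
            except KeyError:
                raise ValidationError(
                    f"{source}:{line_no}: unknown sex code {code!r} "
                    f"for sample {sample!r}"
                ) from None
    return mapping


@dataclass(frozen=True)
class SexStratifiedCounts:
    """Per-variant genotype counts split by sex.

    ``female`` is (f0, f1, f2): counts of (aa, Aa, AA) genotypes with A the
    designated allele.  ``male`` is (m0, m1, m2) when ``male_layout`` is
    'diploid', and (ref-carriers, A-carriers) when 'hemizygous' (no
    heterozygote slot exists for hemizygous males).
    """

    female: tuple[int, int, int]
    male: tuple[int, ...]
    male_layout: str = DIPLOID
    missing_female: int = 0
    missing_male: int = 0
    allele_a: str = "ref"
    allele_A: str = "alt"

    def __post_init__(self) -> None:
        if self.male_layout not in (DIPLOID, HEMIZYGOUS):
            raise ValidationError(f"bad male_layout {self.male_layout!r}")
        want = 3 if self.male_layout == DIPLOID else 2
        if len(self.female) != 3:
            raise ValidationError("female counts must be a (f0, f1, f2) triple")
        if len(self.male) != want:
            raise ValidationError(
                f"male counts must have {want} slots for {self.male_layout}"
            )
        if any(c < 0 for c in (*self.female, *self.male,
                               self.missing_female, self.missing_male)):
            raise ValidationError("genotype counts must be non-negative")

    @property
    def n_female(self) -> int:
        return sum(self.female)

    @property
    def n_male(self) -> int:
        return sum(self.male)

    @property
    def female_allele_counts(self) -> tuple[int, int]:
        """(a-count, A-count) contributed by females (two alleles each)."""
        f0, f1, f2 = self.female
        return (2 * f0 + f1, 2 * f2 + f1)

    @property
    def male_allele_counts(self) -> tuple[int, int]:
        """(a-count, A-count) contributed by males.

        Hemizygous males contribute one allele each; diploid males two.
        """
        if self.male_layout == HEMIZYGOUS:
            return (self.male[0], self.male[1])
        m0, m1, m2 = self.male
        return (2 * m0 + m1, 2 * m2 + m1)

    @property
    def total_allele_count(self) -> int:
        fa, fA = self.female_allele_counts
        ma, mA = self.male_allele_counts
        return fa + fA + ma + mA

    def swapped_alleles(self) -> "SexStratifiedCounts":
        """The same data with the designated allele A and allele a exchanged."""
        f0, f1, f2 = self.female
        male = tuple(reversed(self.male)) if self.male_layout == HEMIZYGOUS \
            else (self.male[2], self.male[1], self.male[0])
        return replace(
            self, female=(f2, f1, f0), male=male,
            allele_a=self.allele_A, allele_A=self.allele_a,
        )

    def pooled(self, other: "SexStratifiedCounts") -> "SexStratifiedCounts":
        """Element-wise sum of two count sets with the same layout/alleles."""
        if other.male_layout != self.male_layout:
            raise ValidationError("cannot pool counts with different layouts")
        if (other.allele_a, other.allele_A) != (self.allele_a, self.allele_A):
            raise ValidationError("cannot pool counts with different alleles")
        return replace(
            self,
            female=tuple(a + b for a, b in zip(self.female, other.female)),
            male=tuple(a + b for a, b in zip(self.male, other.male)),
            missing_female=self.missing_female + other.missing_female,
            missing_male=self.missing_male + other.missing_male,
        )


@dataclass
class VariantRecord:
    """One biallelic site with its region label and sex-stratified counts."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    region: str
    counts: SexStratifiedCounts
    population: str = "ALL"
    call_rate_female: Optional[float] = None
    call_rate_male: Optional[float] = None


FILTER_STAGES = ("multiallelic", "indel", "monomorphic", "low_maf", "malformed")


@dataclass
class FilterSummary:
    """Per-region tallies of variants removed at each selection stage."""

    removed: dict[str, dict[str, int]] = field(default_factory=dict)
    retained: dict[str, int] = field(default_factory=dict)
    input_count: int = 0

    def _bump(self, table: dict, region: str, stage: Optional[str] = None) -> None:
        if stage is None:
            table[region] = table.get(region, 0) + 1
        else:
            table.setdefault(region, {s: 0 for s in FILTER_STAGES})
            table[region][stage] += 1

    def record_removed(self, region: str, stage: str) -> None:
        self.input_count += 1
        self._bump(self.removed, region, stage)

    def record_retained(self, region: str) -> None:
        self.input_count += 1
        self._bump(self.retained, region)

    @property
    def n_removed(self) -> int:
        return sum(sum(v.values()) for v in self.removed.values())

    @property
    def n_retained(self) -> int:
        return sum(self.retained.values())

    def removed_by_stage(self) -> dict[str, int]:
        out = {s: 0 for s in FILTER_STAGES}
        for per_region in self.removed.values():
            for stage, n in per_region.items():
                out[stage] += n
        return out

    def to_tsv(self, path: Union[str, Path]) -> None:
        regions = sorted(set(self.removed) | set(self.retained))
        with open(path, "w") as fh:
            fh.write("REGION\t" + "\t".join(s.upper() for s in FILTER_STAGES)
                     + "\tRETAINED\n")
            for region in regions:
                row = self.removed.get(region, {s: 0 for s in FILTER_STAGES})
                fh.write(region + "\t"
                         + "\t".join(str(row[s]) for s in FILTER_STAGES)
                         + f"\t{self.retained.get(region, 0)}\n")


# genotype codes used internally: females 0/1/2 copies of ALT, -1 missing;
# males in hemizygous regions 0 (ref) / 2 (alt) / 1 (heterozygous call) / -1.
MISSING = -1


def tally_variant(
    genotypes: Sequence[tuple[str, int]],
    sex: dict[str, str],
    region: str,
    male_het_policy: str = "set_missing",
    allele_a: str = "ref",
    allele_A: str = "alt",
    chrom: str = "X",
    pos: int = 0,
) -> SexStratifiedCounts:
    """Tally (sample, genotype-code) pairs into sex-stratified counts.

    Genotype codes count copies of the ALT (designated) allele: 0/1/2 for
    diploid calls, 0/2 for haploid male calls in NPR/PAR3 (a diploid
    homozygote male call in those regions also contributes one allele),
    ``MISSING`` for no-calls.  ``male_het_policy`` controls heterozygous male
    calls in hemizygous regions: 'error' raises, 'set_missing' counts the
    call as missing with a warning.
    """
    if male_het_policy not in ("error", "set_missing"):
        raise ValidationError(f"bad male_het_policy {male_het_policy!r}")
    hemi = region in ("NPR", "PAR3")
    f = [0, 0, 0]
    m = [0, 0, 0]
    miss_f = miss_m = 0
    for sample, code in genotypes:
        try:
            s = sex[sample]
        except KeyError:
            raise ValidationError(f"sample {sample!r} missing from sex map") from None
        if s == "female":
            if code == MISSING:
                miss_f += 1
            else:
                f[code] += 1
        else:
            if code == MISSING:
                miss_m += 1
            elif hemi and code == 1:
                if male_het_policy == "error":
                    raise DataError(
                        f"heterozygous male call for sample {sample!r} at "
                        f"{chrom}:{pos} in hemizygous region {region}"
                    )
                logger.warning(
                    "heterozygous male call at %s:%s (sample %s) set to missing",
                    chrom, pos, sample,
                )
                miss_m += 1
            else:
                m[code] += 1
    if hemi:
        male: tuple[int, ...] = (m[0], m[2])
    else:
        male = (m[0], m[1], m[2])
    return SexStratifiedCounts(
        female=(f[0], f[1], f[2]), male=male,
        male_layout=HEMIZYGOUS if hemi else DIPLOID,
        missing_female=miss_f, missing_male=miss_m,
        allele_a=allele_a, allele_A=allele_A,
    )


def compute_global_maf(
    counts: SexStratifiedCounts, region: str
) -> tuple[float, str, bool]:
    """Sex-pooled minor allele frequency.

    Males contribute one allele in NPR/PAR3 and two in PAR1/PAR2 (the layout
    recorded on ``counts`` must match the region).  Returns
    (maf, minor_allele_symbol, tie_flag); a pooled frequency of exactly 0.5
    is a tie, resolved toward the A (alt) allele with the flag raised.
    """
    hemi = region in ("NPR", "PAR3")
    if hemi != (counts.male_layout == HEMIZYGOUS):
        raise ValidationError(
            f"male layout {counts.male_layout!r} inconsistent with region {region}"
        )
    fa, fA = counts.female_allele_counts
    ma, mA = counts.male_allele_counts
    total = fa + fA + ma + mA
    if total == 0:
        raise DataError("zero total allele count")
    freq_A = (fA + mA) / total
    if freq_A < 0.5:
        return freq_A, counts.allele_A, False
    if freq_A > 0.5:
        return 1.0 - freq_A, counts.allele_a, False
    return 0.5, counts.allele_A, True


def call_rate(counts: SexStratifiedCounts, sex: str) -> float:
    """Percentage of individuals of ``sex`` with a non-missing genotype."""
    if sex == "female":
        called, missing = counts.n_female, counts.missing_female
    elif sex == "male":
        called, missing = counts.n_male, counts.missing_male
    else:
        raise ValidationError(f"sex must be 'female' or 'male', got {sex!r}")
    denom = called + missing
    if denom == 0:
        raise DataError(f"no {sex} individuals (called or missing)")
    if called == 0:
        raise DataError(f"every {sex} genotype is missing")
    return 100.0 * called / denom


_NUCLEOTIDES = frozenset("ACGT")


def is_snp(ref: str, alts: Sequence[str]) -> bool:
    return (len(ref) == 1 and ref.upper() in _NUCLEOTIDES
            and all(len(a) == 1 and a.upper() in _NUCLEOTIDES for a in alts))


def filter_variants(
    candidates: Iterable["RawVariant"],
    sex: dict[str, str],
    region_map: RegionMap,
    maf_threshold: float = 0.05,
    male_het_policy: str = "set_missing",
) -> tuple[list[VariantRecord], FilterSummary]:
    """Apply the biallelic-SNP / global-MAF selection pipeline.

    Stages, in order: drop sites with >1 ALT allele; drop indels; tally and
    drop monomorphic sites; drop sites with global MAF below
    ``maf_threshold`` (inclusive comparison: MAF >= threshold is retained).
    Malformed records are logged and counted, never fatal.
    """
    retained: list[VariantRecord] = []
    summary = FilterSummary()
    for raw in candidates:
        region = region_map.assign(raw.pos)
        if len(raw.alts) != 1:
            summary.record_removed(region, "multiallelic")
            continue
        if not is_snp(raw.ref, raw.alts):
            summary.record_removed(region, "indel")
            continue
        try:
            counts = tally_variant(
                raw.genotypes, sex, region, male_het_policy,
                allele_a=raw.ref, allele_A=raw.alts[0],
                chrom=raw.chrom, pos=raw.pos,
            )
            maf, minor, _tie = compute_global_maf(counts, region)
        except (DataError, ValidationError) as exc:
            logger.warning("dropping malformed record %s:%s: %s",
                           raw.chrom, raw.pos, exc)
            summary.record_removed(region, "malformed")
            continue
        if maf == 0.0:
            summary.record_removed(region, "monomorphic")
            continue
        if maf < maf_threshold:
            summary.record_removed(region, "low_maf")
            continue
        summary.record_retained(region)
        retained.append(VariantRecord(
            chrom=raw.chrom, pos=raw.pos, id=raw.id, ref=raw.ref,
            alt=raw.alts[0], region=region, counts=counts,
        ))
    return retained, summary


@dataclass
class RawVariant:
    """Unfiltered site: possibly multiallelic, possibly an indel."""

    chrom: str
    pos: int
    id: str
    ref: str
    alts: tuple[str, ...]
    genotypes: list[tuple[str, int]]  # (sample, code) pairs


def _code_from_gt(alleles: tuple) -> int:
    """Map a pysam GT tuple to an internal genotype code."""
    called = [a for a in alleles if a is not None]
    if not called or len(called) != len(alleles):
        return MISSING
    if len(called) == 1:  # haploid call
        return 0 if called[0] == 0 else 2
    return sum(1 for a in called if a != 0)


def read_vcf(path: Union[str, Path]) -> Iterator[RawVariant]:
    """Stream RawVariant records from a VCF (plain or bgzipped)."""
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = tuple(rec.alts) if rec.alts else ()
            genotypes = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                code = MISSING if gt is None else _code_from_gt(tuple(gt))
                # multi-copy alt codes only meaningful for biallelic sites;
                # clamp so downstream tallying stays in range
                genotypes.append((s, min(code, 2)))
            yield RawVariant(
                chrom=rec.chrom, pos=rec.pos,
                id=rec.id or ".", ref=rec.ref or "", alts=alts,
                genotypes=genotypes,
            )


# ---------------------------------------------------------------------------
# Aggregated count tables (gnomAD-style: one row per SNP/population/sex)

_TABLE_COLUMNS = ("Region", "SNP", "Population", "Sex", "Call rate",
                  "RR", "RA", "AA", "Minor Allele")


def _parse_snp_name(name: str) -> tuple[str, int, str, str]:
    parts = name.split("-")
    if len(parts) != 4:
        raise ValidationError(
            f"SNP name {name!r} not in CHROM-POS-REF-ALT form"
        )
    chrom, pos, ref, alt = parts
    return chrom, int(pos), ref, alt


def read_count_table(source: Union[str, Path]) -> list[VariantRecord]:
    """Read a sex-stratified genotype-count TSV into VariantRecords.

    Expected columns: Region, SNP (CHROM-POS-REF-ALT), Population, Sex (F/M),
    Call rate, RR, RA, AA, Minor Allele.  RR/RA/AA are oriented to the
    ref/alt alleles of the SNP name; a male row with RA = NA denotes the
    hemizygous layout (RR = ref-carriers, AA = alt-carriers).  One record is
    assembled per (SNP, Population) from its F and M rows; counts are
    re-oriented so the designated allele A is the table's Minor Allele.
    """
    import csv

    rows_by_key: dict[tuple[str, str], dict[str, dict]] = {}
    order: list[tuple[str, str]] = []
    with open(source) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing_cols = [c for c in _TABLE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing_cols:
            raise ValidationError(f"{source}: missing columns {missing_cols}")
        for row in reader:
            key = (row["SNP"], row["Population"])
            sex = row["Sex"].strip().upper()
            if sex not in ("F", "M"):
                raise ValidationError(f"{source}: bad Sex value {row['Sex']!r}")
            if key not in rows_by_key:
                rows_by_key[key] = {}
                order.append(key)
            if sex in rows_by_key[key]:
                raise ValidationError(
                    f"{source}: duplicate {sex} row for {key}"
                )
            rows_by_key[key][sex] = row

    def _count(value: str, where: str) -> int:
        n = int(value)
        if n < 0:
            raise ValidationError(f"negative count in {where}")
        return n

    records = []
    for key in order:
        rows = rows_by_key[key]
        if set(rows) != {"F", "M"}:
            raise ValidationError(
                f"SNP {key[0]} population {key[1]}: need one F and one M row"
            )
        frow, mrow = rows["F"], rows["M"]
        chrom, pos, ref, alt = _parse_snp_name(frow["SNP"])
        region = frow["Region"].strip()
        minor = frow["Minor Allele"].strip()
        if minor not in (ref, alt):
            raise ValidationError(
                f"SNP {key[0]}: minor allele {minor!r} is neither ref nor alt"
            )
        female = tuple(_count(frow[c], f"{key} F") for c in ("RR", "RA", "AA"))
        hemi = mrow["RA"].strip().upper() == "NA"
        if hemi:
            male: tuple[int, ...] = (
                _count(mrow["RR"], f"{key} M"), _count(mrow["AA"], f"{key} M"))
        else:
            male = tuple(_count(mrow[c], f"{key} M") for c in ("RR", "RA", "AA"))
        counts = SexStratifiedCounts(
            female=female, male=male,
            male_layout=HEMIZYGOUS if hemi else DIPLOID,
            allele_a=ref, allele_A=alt,
        )
        if minor == ref:  # orient counts so A = the designated minor allele
            counts = counts.swapped_alleles()

        def _rate(row: dict) -> Optional[float]:
            v = row.get("Call rate", "").strip()
            return float(v) if v and v.upper() != "NA" else None

        records.append(VariantRecord(
            chrom=chrom, pos=pos, id=frow["SNP"], ref=ref, alt=alt,
            region=region, counts=counts, population=frow["Population"],
            call_rate_female=_rate(frow), call_rate_male=_rate(mrow),
        ))
    return records


def write_count_table(
    records: Iterable[VariantRecord], path: Union[str, Path]
) -> None:
    """Write VariantRecords as a count TSV; inverse of :func:`read_count_table`."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for rec in records:
            counts = rec.counts
            # table rows are oriented ref/alt; undo minor-allele orientation
            minor = counts.allele_A
            oriented = counts if counts.allele_A == rec.alt \
                else counts.swapped_alleles()
            f0, f1, f2 = oriented.female
            if oriented.male_layout == HEMIZYGOUS:
                m_cells = (str(oriented.male[0]), "NA", str(oriented.male[1]))
            else:
                m_cells = tuple(str(c) for c in oriented.male)

            def _fmt_rate(v: Optional[float]) -> str:
                return "NA" if v is None else f"{v:.2f}"

            fh.write("\t".join([
                rec.region, rec.id, rec.population, "F",
                _fmt_rate(rec.call_rate_female), str(f0), str(f1), str(f2),
                minor,
            ]) + "\n")
            fh.write("\t".join([
                rec.region, rec.id, rec.population, "M",
                _fmt_rate(rec.call_rate_male), *m_cells, minor,
            ]) + "\n")
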