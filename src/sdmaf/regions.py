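"""Four-region partition of the human X chromosome.

The X chromosome is split into the two tip pseudoautosomal regions (PAR1,
PAR2), the X-transposed region in Xq21.3 (labelled PAR3 here), and the
remaining non-pseudoautosomal region (NPR).  Males are diploid in PAR1/PAR2
and hemizygous in NPR/PAR3, so every downstream computation dispatches on
the region label.

Coordinates are 1-based inclusive, matching VCF POS.  PAR1/PAR2 defaults are
the Genome Reference Consortium published spans.  The PAR3/XTR default is
approximate (the region is ~3.9 Mb in Xq21.3, around 88.4-92.3 Mb on
GRCh37); exact replication work should override it via BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from .errors import ConfigurationError, ValidationError

PAR_LABELS = ("PAR1", "PAR2", "PAR3")
REGION_LABELS = PAR_LABELS + ("NPR",)

#: Regions where males carry a single allele.
HEMIZYGOUS_REGIONS = frozenset({"NPR", "PAR3"})

#: GRC PAR spans plus an approximate XTR interval, per build.
_DEFAULT_INTERVALS = {
    "GRCh37": (
        ("PAR1", 60_001, 2_699_520),
        ("PAR3", 88_400_000, 92_300_000),  # approximate XTR span
        ("PAR2", 154_931_044, 155_260_560),
    ),
    "GRCh38": (
        ("PAR1", 10_001, 2_781_479),
        ("PAR3", 89_140_000, 93_040_000),  # approximate XTR span
        ("PAR2", 155_701_383, 156_030_895),
    ),
}

_CHROM_LENGTH = {"GRCh37": 155_270_560, "GRCh38": 156_040_895}

SUPPORTED_BUILDS = tuple(_DEFAULT_INTERVALS)


@dataclass(frozen=True)
class RegionMap:
    """Labelled 1-based inclusive PAR intervals for one genome build.

    Every chrX position maps to exactly one label; positions covered by no
    PAR interval are NPR.
    """

    build: str
    intervals: tuple[tuple[str, int, int], ...]
    chrom_length: int = field(default=0)

    def __post_init__(self) -> None:
        seen: list[tuple[int, int]] = []
        for label, start, end in self.intervals:
            if label not in PAR_LABELS:
                raise ValidationError(f"unknown region label {label!r}")
            if not (1 <= start <= end):
                raise ValidationError(
                    f"{label}: invalid interval [{start}, {end}]"
                )
            for s, e in seen:
                if start <= e and s <= end:
                    raise ValidationError(
                        f"{label}: interval [{start}, {end}] overlaps another"
                    )
            seen.append((start, end))

    def assign(self, position: int) -> str:
        """Region label containing ``position`` (1-based); NPR if in no PAR."""
        if position < 1:
            raise ValidationError(f"position must be >= 1, got {position}")
        for label, start, end in self.intervals:
            if start <= position <= end:
                return label
        return "NPR"

    def male_layout(self, position_or_label: Union[int, str]) -> str:
        """'hemizygous' or 'diploid' for a position or a region label."""
        label = (
            position_or_label
            if isinstance(position_or_label, str)
            else self.assign(position_or_label)
        )
        return "hemizygous" if label in HEMIZYGOUS_REGIONS else "diploid"

    def to_bed(self, path: Union[str, Path]) -> None:
        """Write the PAR intervals as BED (0-based half-open)."""
        with open(path, "w") as fh:
            for label, start, end in self.intervals:
                fh.write(f"chrX\t{start - 1}\t{end}\t{label}\n")


def _read_bed_intervals(path: Union[str, Path]) -> dict[str, tuple[int, int]]:
    out: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValidationError(
                    f"{path}:{line_no}: BED override needs 4 columns "
                    "(chrom, start, end, label)"
                )
            _, start, end, label = fields[:4]
            if label not in PAR_LABELS:
                raise ValidationError(
                    f"{path}:{line_no}: label must be one of {PAR_LABELS}, "
                    f"got {label!r}"
                )
            if label in out:
                raise ValidationError(f"{path}:{line_no}: duplicate label {label}")
            out[label] = (int(start) + 1, int(end))  # to 1-based inclusive
    return out


def load_region_map(
    build: str, override: Union[str, Path, None] = None
) -> RegionMap:
    """Region map for ``build``, with optional label-by-label BED overrides.

    Parameters
    ----------
    build
        Genome build identifier, one of ``SUPPORTED_BUILDS``.
    override
        Optional BED file whose intervals (labelled PAR1/PAR2/PAR3) replace
        the packaged defaults for those labels only.
    """
    if build not in _DEFAULT_INTERVALS:
        raise ConfigurationError(
            f"unsupported build {build!r}; supported: {SUPPORTED_BUILDS}"
        )
    by_label = {lab: (s, e) for lab, s, e in _DEFAULT_INTERVALS[build]}
    if override is not None:
        by_label.update(_read_bed_intervals(override))
    intervals = tuple(
        (lab, s, e)
        for lab, (s, e) in sorted(by_label.items(), key=lambda kv: kv[1][0])
    )
    return RegionMap(
        build=build, intervals=intervals, chrom_length=_CHROM_LENGTH[build]
    )


def load_region_map_from_intervals(
    intervals: Iterable[tuple[str, int, int]],
    build: str = "custom",
    chrom_length: int = 0,
) -> RegionMap:
    """Build a RegionMap directly from (label, start, end) triples."""
    return RegionMap(
        build=build, intervals=tuple(intervals), chrom_length=chrom_length
    )
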