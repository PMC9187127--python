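"""Sliding-window smoothing of per-SNP -log10 p-values.

Windows contain a fixed number of consecutive SNPs (default 50) and advance
by a fixed SNP step (default 25); only full windows are emitted, each
positioned at its leftmost SNP.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowResult:
    start_index: int  # 1-based index of the leftmost SNP
    position: int  # position of the leftmost SNP
    mean_neg_log10_p: float
    n_snps: int
    n_excluded_infinite: int = 0


def sliding_mean_neglog10(
    positions: Sequence[int],
    neg_log10_p: Sequence[float],
    window_size: int = 50,
    step: int = 25,
) -> list[WindowResult]:
    """Mean -log10 p over sliding SNP-count windows.

    SNPs must be sorted by position.  Infinite sentinels (zero-variance
    degenerate tests) are excluded from the mean and counted per window;
    NaN entries are excluded the same way.
    """
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be >= 1")
    if len(positions) != len(neg_log10_p):
        raise ValueError("positions and p-values must have equal length")
    if any(b < a for a, b in zip(positions, positions[1:])):
        raise ValueError("SNPs must be sorted by position")
    n = len(positions)
    if n < window_size:
        logger.warning("fewer SNPs (%d) than window size (%d); no windows",
                       n, window_size)
        return []
    out = []
    for start in range(0, n - window_size + 1, step):
        chunk = neg_log10_p[start:start + window_size]
        finite = [v for v in chunk if math.isfinite(v)]
        excluded = window_size - len(finite)
        mean = sum(finite) / len(finite) if finite else float("nan")
        out.append(WindowResult(
            start_index=start + 1, position=positions[start],
            mean_neg_log10_p=mean, n_snps=window_size,
            n_excluded_infinite=excluded,
        ))
    return out


def write_windows_tsv(
    windows: Sequence[WindowResult], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("START_INDEX\tPOSITION\tMEAN_NEG_LOG10_P\tN_SNPS\tN_EXCLUDED\n")
        for w in windows:
            fh.write(f"{w.start_index}\t{w.position}\t"
                     f"{w.mean_neg_log10_p:.6g}\t{w.n_snps}\t"
                     f"{w.n_excluded_infinite}\n")
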