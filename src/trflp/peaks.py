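"""Capillary-electrophoresis peak-table ingestion and noise processing.

The instrument software (e.g. Peak Scanner) sizes each fluorescence peak
against an internal standard and exports a CSV with one row per called
peak.  This module reads that export, selects the labelled dye channel,
removes background noise with an iterative proportion threshold, and
converts heights to per-sample relative abundances on integer fragment
sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    """One called peak: fractional size (bp) and fluorescence height."""

    size: float
    height: float
    dye: Optional[str] = None

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"peak size must be > 0, got {self.size}")
        if self.height < 0:
            raise ValueError(f"peak height must be >= 0, got {self.height}")


@dataclass
class PeakTable:
    """Per-sample peak lists plus free-form acquisition metadata."""

    samples: dict[str, list[Peak]]
    metadata: dict = field(default_factory=dict)


@dataclass
class NoiseConfig:
    """Iterative background-noise threshold: a peak is noise while its
    height is below ``min_proportion`` of the current per-sample total."""

    min_proportion: float = 0.005
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if not 0 <= self.min_proportion < 1:
            raise ValueError(
                f"min_proportion must be in [0, 1), got {self.min_proportion}"
            )


def read_peak_csv(
    path: str | Path,
    *,
    size_col: str = "Size",
    height_col: str = "Height",
    dye_col: str = "Dye/Sample Peak",
    sample_col: str = "Sample File Name",
) -> PeakTable:
    """Read a peak-export CSV into a :class:`PeakTable`.

    ``size_col`` and ``height_col`` are mandatory; the dye and sample
    columns are used when present (otherwise all peaks share one sample
    named after the file and carry no dye tag).  Rows whose size is blank
    or non-numeric are skipped with a logged count; a negative height is
    an error naming the data row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    for col in (size_col, height_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")

    have_dye = dye_col in df.columns
    have_sample = sample_col in df.columns
    default_sample = path.stem

    samples: dict[str, list[Peak]] = {}
    skipped = 0
    for i in range(len(df)):
        row = df.iloc[i]
        rownum = i + 2  # header is row 1
        size = pd.to_numeric(row[size_col], errors="coerce")
        height = pd.to_numeric(row[height_col], errors="coerce")
        if pd.isna(size) or pd.isna(height):
            skipped += 1
            continue
        if height < 0:
            raise ValueError(f"{path}: negative height at data row {rownum}")
        dye = str(row[dye_col]) if have_dye and not pd.isna(row[dye_col]) else None
        sample = (
            str(row[sample_col])
            if have_sample and not pd.isna(row[sample_col])
            else default_sample
        )
        samples.setdefault(sample, []).append(
            Peak(size=float(size), height=float(height), dye=dye)
        )
    if skipped:
        logger.info("%s: skipped %d rows with unparsable size/height", path, skipped)
    if not samples:
        raise ValueError(f"{path}: no parsable peak rows")
    return PeakTable(samples=samples, metadata={"path": str(path), "skipped_rows": skipped})


def select_channel(table: PeakTable, dye_tag: Optional[str]) -> PeakTable:
    """Keep peaks whose dye tag starts with the requested channel letter
    (FAM = blue = ``"B"``).  ``None`` disables filtering.  Erroring when
    the requested channel is empty in every sample guards against a wrong
    tag silently discarding the run."""
    if dye_tag is None:
        return table
    kept = {
        name: [p for p in peaks if p.dye is not None and p.dye.startswith(dye_tag)]
        for name, peaks in table.samples.items()
    }
    if all(not peaks for peaks in kept.values()):
        raise ValueError(f"channel {dye_tag!r} yields zero peaks in every sample")
    return PeakTable(samples=kept, metadata=dict(table.metadata))


def noise_filter(
    peaks: list[Peak], config: Optional[NoiseConfig] = None
) -> tuple[list[Peak], int]:
    """Iteratively remove peaks whose height is below ``min_proportion`` of
    the current total fluorescence, until stable (or the iteration cap).

    Removing noise lowers the total, which can push further peaks under
    the threshold — hence the iteration.  Deterministic; returns the kept
    peaks (input order) and the number removed.  Removing everything is an
    error advising a lower threshold.
    """
    config = config or NoiseConfig()
    if not peaks:
        raise ValueError("noise_filter: no peaks")
    current = list(peaks)
    iterations = 0
    while iterations < config.max_iterations:
        total = sum(p.height for p in current)
        if total <= 0:
            break
        kept = [p for p in current if p.height / total >= config.min_proportion]
        iterations += 1
        if len(kept) == len(current):
            break
        current = kept
    if not current or sum(p.height for p in current) <= 0:
        raise ValueError(
            "noise_filter removed every peak; reduce min_proportion "
            f"(currently {config.min_proportion})"
        )
    logger.debug("noise_filter: %d iterations, removed %d peaks",
                 iterations, len(peaks) - len(current))
    return current, len(peaks) - len(current)


def round_half_away(x: float) -> int:
    """Round half away from zero (235.5 -> 236), the fixed rule for mapping
    called sizes to integer bp."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def relative_abundance(peaks: list[Peak]) -> dict[int, float]:
    """Relative abundance (%) per integer fragment size.

    Sizes are rounded half-away-from-zero; peaks sharing a rounded size
    are summed before normalisation.  The result sums to 100.
    """
    if not peaks:
        raise ValueError("relative_abundance: no peaks")
    total = sum(p.height for p in peaks)
    if total <= 0:
        raise ValueError("relative_abundance: zero total height")
    agg: dict[int, float] = {}
    for p in peaks:
        size = round_half_away(p.size)
        agg[size] = agg.get(size, 0.0) + p.height
    return {s: 100.0 * h / total for s, h in sorted(agg.items())}


def process_samples(
    table: PeakTable,
    *,
    dye: Optional[str] = None,
    noise: Optional[NoiseConfig] = None,
) -> dict[str, dict[int, float]]:
    """Channel selection, noise filtering and relative abundance for every
    sample; returns sample -> {integer size: RA %}."""
    table = select_channel(table, dye)
    out: dict[str, dict[int, float]] = {}
    for name, peaks in table.samples.items():
        if not peaks:
            logger.warning("sample %s: no peaks in selected channel", name)
            out[name] = {}
            continue
        kept, _ = noise_filter(peaks, noise)
        out[name] = relative_abundance(kept)
    return out
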