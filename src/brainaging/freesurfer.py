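"""Parsers for FreeSurfer tabular outputs and composite-region aggregation.

Consumes the standard ``aseg.stats`` and ``?h.aparc.DKTatlas.stats`` text
dialects: ``#``-prefixed header lines (including ``# Measure ...`` summary
rows and a ``# ColHeaders ...`` line naming the table columns) followed by
whitespace-delimited data rows.  Only the tabular outputs are consumed —
no image processing happens here.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .regions import DKT_PARCELS, RegionSet

__all__ = [
    "AsegStats",
    "AparcStats",
    "StatsParseError",
    "parse_aseg_stats",
    "parse_aparc_stats",
    "aggregate_regions",
    "subject_dir_to_row",
]

ETIV_MEASURE = "EstimatedTotalIntraCranialVol"


class StatsParseError(ValueError):
    """Malformed FreeSurfer stats content; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class AsegStats:
    """Parsed aseg.stats: structure volumes plus header summary measures."""

    volumes: Mapping[str, float]
    etiv: float
    measures: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.etiv > 0 and math.isfinite(self.etiv)):
            raise ValueError(f"eTIV must be finite and > 0, got {self.etiv}")


@dataclass(frozen=True)
class AparcStats:
    """Parsed cortical parcel gray-matter volumes for one hemisphere."""

    hemisphere: str
    gray_volumes: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.hemisphere not in ("lh", "rh"):
            raise ValueError(f"hemisphere must be 'lh' or 'rh', got {self.hemisphere!r}")
        unknown = set(self.gray_volumes) - DKT_PARCELS
        if unknown:
            raise ValueError(f"unknown DKT parcel names: {sorted(unknown)}")


def _iter_lines(stream: IO[str] | Iterable[str]):
    for lineno, raw in enumerate(stream, start=1):
        yield lineno, raw.rstrip("\n")


def _parse_measure_line(line: str) -> tuple[list[str], float] | None:
    # "# Measure BrainSegNotVent, BrainSegVolNotVent, <description>, 1.1e6, mm^3"
    # The first two comma-separated fields are the internal and short names;
    # the value is the last numeric field.  Indexed under both names.
    body = line[len("# Measure") :].strip()
    parts = [p.strip() for p in body.split(",")]
    if len(parts) < 2:
        return None
    for token in reversed(parts):
        try:
            value = float(token)
        except ValueError:
            continue
        names = [parts[0]]
        if len(parts) > 2 and parts[1] and not parts[1][0].isdigit():
            names.append(parts[1])
        return names, value
    return None


def parse_aseg_stats(stream: IO[str] | Iterable[str]) -> AsegStats:
    """Parse an ``aseg.stats`` text stream.

    Requires the eTIV header measure; unknown structures are retained
    verbatim.  Negative volumes and malformed rows raise
    :class:`StatsParseError` with the offending line number.
    """
    measures: dict[str, float] = {}
    col_headers: list[str] | None = None
    volumes: dict[str, float] = {}
    saw_any = False

    for lineno, line in _iter_lines(stream):
        saw_any = True
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.startswith("# Measure"):
                parsed = _parse_measure_line(line)
                if parsed is not None:
                    names, value = parsed
                    for name in names:
                        measures[name] = value
            elif line.startswith("# ColHeaders"):
                col_headers = line[len("# ColHeaders") :].split()
            continue
        if col_headers is None:
            raise StatsParseError("data row before ColHeaders header", lineno)
        fields = line.split()
        if len(fields) != len(col_headers):
            raise StatsParseError(
                f"expected {len(col_headers)} fields, got {len(fields)}", lineno
            )
        row = dict(zip(col_headers, fields))
        if "StructName" not in row or "Volume_mm3" not in row:
            raise StatsParseError("missing StructName/Volume_mm3 columns", lineno)
        try:
            volume = float(row["Volume_mm3"])
        except ValueError:
            raise StatsParseError(
                f"unparseable volume {row['Volume_mm3']!r}", lineno
            ) from None
        if not math.isfinite(volume) or volume < 0:
            raise StatsParseError(f"negative/non-finite volume {volume}", lineno)
        volumes[row["StructName"]] = volume

    if not saw_any:
        raise StatsParseError("empty stream")
    if ETIV_MEASURE not in measures:
        raise StatsParseError(f"missing '# Measure {ETIV_MEASURE}' header line")
    return AsegStats(volumes=volumes, etiv=measures[ETIV_MEASURE], measures=measures)


def parse_aparc_stats(stream: IO[str] | Iterable[str], hemisphere: str) -> AparcStats:
    """Parse a ``?h.aparc.DKTatlas.stats`` stream (StructName + GrayVol)."""
    col_headers: list[str] | None = None
    gray: dict[str, float] = {}
    saw_any = False

    for lineno, line in _iter_lines(stream):
        saw_any = True
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.startswith("# ColHeaders"):
                col_headers = line[len("# ColHeaders") :].split()
            continue
        if col_headers is None:
            raise StatsParseError("data row before ColHeaders header", lineno)
        if "GrayVol" not in col_headers or "StructName" not in col_headers:
            raise StatsParseError("missing StructName/GrayVol columns", lineno)
        fields = line.split()
        if len(fields) != len(col_headers):
            raise StatsParseError(
                f"expected {len(col_headers)} fields, got {len(fields)}", lineno
            )
        row = dict(zip(col_headers, fields))
        try:
            volume = float(row["GrayVol"])
        except ValueError:
            raise StatsParseError(f"unparseable GrayVol {row['GrayVol']!r}", lineno) from None
        if not math.isfinite(volume) or volume < 0:
            raise StatsParseError(f"negative/non-finite GrayVol {volume}", lineno)
        gray[row["StructName"]] = volume

    if not saw_any:
        raise StatsParseError("empty stream")
    if col_headers is None:
        raise StatsParseError("no ColHeaders line found")
    return AparcStats(hemisphere=hemisphere, gray_volumes=gray)


def aggregate_regions(
    aseg: AsegStats,
    aparc_lh: AparcStats,
    aparc_rh: AparcStats,
    mapping: RegionSet,
) -> tuple[dict[str, float], float]:
    """Assemble composite-region volumes and ICV from parsed stats.

    Each composite is the sum of its constituent left+right volumes;
    measure-backed composites come from the aseg header.  Missing
    constituents raise with the full list of absent names.
    """
    missing: list[str] = []
    volumes: dict[str, float] = {}
    for region in mapping:
        if region.measure is not None:
            if region.measure not in aseg.measures:
                missing.append(f"measure:{region.measure}")
            else:
                volumes[region.name] = aseg.measures[region.measure]
        elif region.aseg:
            total = 0.0
            for name in region.aseg:
                if name not in aseg.volumes:
                    missing.append(f"aseg:{name}")
                else:
                    total += aseg.volumes[name]
            volumes[region.name] = total
        else:
            total = 0.0
            for name in region.dkt:
                for hemi in (aparc_lh, aparc_rh):
                    if name not in hemi.gray_volumes:
                        missing.append(f"{hemi.hemisphere}:{name}")
                    else:
                        total += hemi.gray_volumes[name]
            volumes[region.name] = total
    if missing:
        raise KeyError(f"parcels required by the region mapping are absent: {missing}")
    return volumes, aseg.etiv


def subject_dir_to_row(subject_dir: str, mapping: RegionSet) -> dict[str, float | str]:
    """Read one FreeSurfer subject directory into a cohort-table row fragment.

    Expects ``stats/aseg.stats`` plus ``stats/{lh,rh}.aparc.DKTatlas.stats``
    under ``subject_dir``; returns ``subject_id``, ``icv_mm3``, and one
    ``vol_<region>_mm3`` entry per composite.
    """
    stats_dir = os.path.join(subject_dir, "stats")
    with open(os.path.join(stats_dir, "aseg.stats"), encoding="utf-8") as fh:
        aseg = parse_aseg_stats(fh)
    hemis = {}
    for hemi in ("lh", "rh"):
        with open(
            os.path.join(stats_dir, f"{hemi}.aparc.DKTatlas.stats"), encoding="utf-8"
        ) as fh:
            hemis[hemi] = parse_aparc_stats(fh, hemi)
    volumes, icv = aggregate_regions(aseg, hemis["lh"], hemis["rh"], mapping)
    row: dict[str, float | str] = {
        "subject_id": os.path.basename(os.path.normpath(subject_dir)),
        "icv_mm3": icv,
    }
    for name, value in volumes.items():
        row[f"vol_{name}_mm3"] = value
    return row
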