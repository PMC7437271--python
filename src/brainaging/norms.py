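"""Normative volume tables by ethnicity x sex x 5-year age bin.

Norms are built on both the relative (% of ICV) and absolute (mm^3)
scales; each stratum carries n, mean, sd, and the p5/p25/p50/p75/p95
percentiles (median-unbiased estimator).  Individual subjects are
z-scored against the matching stratum on the relative scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CohortTable, SubjectRecord
from .slopes import relative_volume

__all__ = [
    "AGE_BINS",
    "assign_age_bin",
    "NormTable",
    "build_norms",
    "zscore_subject",
]

#: Half-open 5-year bins covering ages 65-85; the final bin is closed so
#: the stated upper age limit is included.
AGE_BINS: tuple[tuple[float, float, str], ...] = (
    (65.0, 70.0, "65-69"),
    (70.0, 75.0, "70-74"),
    (75.0, 80.0, "75-79"),
    (80.0, 85.0, "80-85"),
)

_PERCENTILES = (5, 25, 50, 75, 95)


def assign_age_bin(age: float) -> str:
    """Map an age in [65, 85] to its 5-year bin label."""
    if not (AGE_BINS[0][0] <= age <= AGE_BINS[-1][1]):
        raise ValueError(f"age {age} outside [{AGE_BINS[0][0]}, {AGE_BINS[-1][1]}]")
    for lo, hi, label in AGE_BINS[:-1]:
        if lo <= age < hi:
            return label
    return AGE_BINS[-1][2]


@dataclass(frozen=True)
class NormTable:
    """Tidy normative table.

    One row per (ethnicity, sex, age_bin, region, scale) with columns
    ``n, mean, sd, p5, p25, p50, p75, p95, low_n``; ``scale`` is
    ``relative`` (% of ICV) or ``absolute`` (mm^3).
    """

    frame: pd.DataFrame
    low_n_floor: int = 10

    def lookup(
        self, ethnicity: str, sex: str, age_bin: str, region: str, scale: str = "relative"
    ) -> pd.Series:
        df = self.frame
        match = df[
            (df["ethnicity"] == ethnicity)
            & (df["sex"] == sex)
            & (df["age_bin"] == age_bin)
            & (df["region"] == region)
            & (df["scale"] == scale)
        ]
        if match.empty:
            raise KeyError(
                f"no norm stratum for ({ethnicity}, {sex}, {age_bin}, {region}, {scale})"
            )
        return match.iloc[0]

    def strata(self) -> pd.DataFrame:
        return self.frame[["ethnicity", "sex", "age_bin"]].drop_duplicates()


def build_norms(cohort: CohortTable, low_n_floor: int = 10) -> NormTable:
    """Summarize a screened cohort into per-stratum normative statistics.

    Strata below ``low_n_floor`` subjects are still emitted but flagged.
    """
    if len(cohort) == 0:
        raise ValueError("cannot build norms from an empty cohort")
    rows = []
    for (ethnicity, sex), records in cohort.groups(("ethnicity", "sex")):
        by_bin: dict[str, list[SubjectRecord]] = {}
        for rec in records:
            by_bin.setdefault(assign_age_bin(rec.age), []).append(rec)
        for _, _, label in AGE_BINS:
            members = by_bin.get(label)
            if not members:
                continue
            for region in cohort.region_set.names:
                absolute = np.array([r.volumes[region] for r in members], dtype=float)
                icv = np.array([r.icv for r in members], dtype=float)
                relative = relative_volume(absolute, icv)
                for scale, values in (("relative", relative), ("absolute", absolute)):
                    pcts = np.percentile(values, _PERCENTILES, method="median_unbiased")
                    rows.append(
                        {
                            "ethnicity": ethnicity,
                            "sex": sex,
                            "age_bin": label,
                            "region": region,
                            "scale": scale,
                            "n": len(members),
                            "mean": float(values.mean()),
                            "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
                            **{f"p{p}": float(v) for p, v in zip(_PERCENTILES, pcts)},
                            "low_n": len(members) < low_n_floor,
                        }
                    )
    return NormTable(frame=pd.DataFrame(rows), low_n_floor=low_n_floor)


def zscore_subject(
    record: SubjectRecord, norms: NormTable, scale: str = "relative"
) -> dict[str, float]:
    """Z-score one subject's regional volumes against the matching stratum.

    Returns region -> z; regions whose stratum sd is zero come back as NaN
    (flagged undefined).  Raises if no matching stratum exists.
    """
    age_bin = assign_age_bin(record.age)
    out: dict[str, float] = {}
    for region in record.volumes:
        stratum = norms.lookup(record.ethnicity, record.sex, age_bin, region, scale)
        value = (
            relative_volume(record.volumes[region], record.icv)
            if scale == "relative"
            else record.volumes[region]
        )
        sd = float(stratum["sd"])
        out[region] = math.nan if sd == 0 else (value - float(stratum["mean"])) / sd
    return out
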