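"""Group-stratified aging slopes with bootstrap CIs and APOE effect sizes.

The estimand is the annual percent change (APC) of a structure's relative
volume (percent of ICV): the OLS slope of relative volume on age within a
group, expressed as percent of the group-mean relative volume per year.
Uncertainty comes from a subject-level percentile bootstrap; group
comparisons use CI non-overlap; APOE effects are bootstrapped differences
between carrier and non-carrier slopes.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import CohortTable, SubjectRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SlopeEstimate",
    "SlopeComparison",
    "ApoeEffect",
    "relative_volume",
    "fit_group_slope",
    "bootstrap_slope_ci",
    "compare_cis",
    "apoe_effect",
    "group_slopes",
    "group_apoe_effects",
    "substream_rng",
]


@dataclass(frozen=True)
class SlopeEstimate:
    group: str
    region: str
    slope: float  # annual percent change, %/yr
    ci_low: float
    ci_high: float
    n: int
    B: int
    seed: int | None
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")

    @property
    def significant(self) -> bool:
        """CI excludes zero."""
        return self.ci_low > 0.0 or self.ci_high < 0.0


@dataclass(frozen=True)
class SlopeComparison:
    group_a: str
    group_b: str
    region: str
    significant: bool
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]

    @property
    def decision(self) -> str:
        return "significant" if self.significant else "not_significant"


@dataclass(frozen=True)
class ApoeEffect:
    group: str
    region: str
    effect: float  # carrier APC - non-carrier APC, %/yr
    ci_low: float
    ci_high: float
    n_carrier: int
    n_noncarrier: int
    B: int
    seed: int | None
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")

    @property
    def significant(self) -> bool:
        return self.ci_low > 0.0 or self.ci_high < 0.0


def relative_volume(volume, icv):
    """Volume as a percentage of intracranial volume: ``100 * volume/icv``."""
    volume = np.asarray(volume, dtype=float)
    icv = np.asarray(icv, dtype=float)
    if np.any(icv <= 0):
        raise ValueError("icv must be > 0")
    out = 100.0 * volume / icv
    return float(out) if out.ndim == 0 else out


def substream_rng(master_seed: int, *labels: str) -> np.random.Generator:
    """Deterministic, order-independent substream for a labelled analysis cell.

    The labels (e.g. group and region) are hashed into extra entropy words so
    every (group, region) pair gets its own stream regardless of the order in
    which cells are processed.
    """
    digest = hashlib.blake2b("|".join(labels).encode(), digest_size=16).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *words]))


def _check_group(ages: np.ndarray, rel: np.ndarray) -> None:
    if ages.shape != rel.shape or ages.ndim != 1:
        raise ValueError("ages and relative volumes must be 1-D arrays of equal length")
    if len(ages) < 3:
        raise ValueError("need at least 3 records to fit a group slope")
    if np.unique(ages).size < 2:
        raise ValueError("all ages equal; slope undefined")


def _apc_from_arrays(ages: np.ndarray, rel: np.ndarray) -> tuple[float, float]:
    """(apc, raw slope in %ICV/yr) for one group."""
    age_c = ages - ages.mean()
    raw = float(age_c @ (rel - rel.mean()) / (age_c @ age_c))
    mean_rel = float(rel.mean())
    if mean_rel == 0.0:
        raise ValueError("group mean relative volume is zero; APC undefined")
    return 100.0 * raw / mean_rel, raw


def _group_arrays(records: Sequence[SubjectRecord], region: str):
    ages = np.array([r.age for r in records], dtype=float)
    rel = np.array([relative_volume(r.volumes[region], r.icv) for r in records])
    return ages, rel


def fit_group_slope(
    records: Sequence[SubjectRecord], region: str
) -> tuple[float, float]:
    """Within-group OLS of relative volume on age.

    Returns ``(apc, raw_slope)``: the annual percent change (raw slope as a
    percentage of the group-mean relative volume) and the raw slope in
    %ICV/yr.
    """
    ages, rel = _group_arrays(records, region)
    _check_group(ages, rel)
    return _apc_from_arrays(ages, rel)


def _bootstrap_apcs(
    ages: np.ndarray,
    rel: np.ndarray,
    B: int,
    rng: np.random.Generator,
    chunk: int = 2000,
) -> np.ndarray:
    """B bootstrap APCs; degenerate resamples (no age spread) are redrawn."""
    n = len(ages)
    out = np.empty(B)
    filled = 0
    redrawn = 0
    while filled < B:
        m = min(chunk, B - filled)
        idx = rng.integers(0, n, size=(m, n))
        a = ages[idx]
        r = rel[idx]
        a_mean = a.mean(axis=1, keepdims=True)
        var = ((a - a_mean) ** 2).sum(axis=1)
        ok = var > 0
        redrawn += int(m - ok.sum())
        a, r, a_mean, var = a[ok], r[ok], a_mean[ok], var[ok]
        raw = ((a - a_mean) * (r - r.mean(axis=1, keepdims=True))).sum(axis=1) / var
        mean_r = r.mean(axis=1)
        take = len(raw)
        out[filled : filled + take] = 100.0 * raw / mean_r
        filled += take
    if redrawn:
        logger.info("redrew %d degenerate bootstrap resamples", redrawn)
    return out


def bootstrap_slope_ci(
    records: Sequence[SubjectRecord],
    region: str,
    B: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    group: str = "",
) -> SlopeEstimate:
    """Percentile-bootstrap CI for a group's aging slope.

    The point estimate is the full-sample fit; the CI is the percentile
    interval of ``B`` subject-resampled APCs.  Deterministic given the seed.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < 100:
        warnings.warn(f"B={B} is very small for a percentile CI", stacklevel=2)
    ages, rel = _group_arrays(records, region)
    _check_group(ages, rel)
    apc, _ = _apc_from_arrays(ages, rel)
    if rng is None:
        rng = np.random.default_rng(seed)
    apcs = _bootstrap_apcs(ages, rel, B, rng)
    alpha = 1.0 - level
    lo, hi = np.quantile(apcs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return SlopeEstimate(
        group=group,
        region=region,
        slope=apc,
        ci_low=float(lo),
        ci_high=float(hi),
        n=len(records),
        B=B,
        seed=seed,
        level=level,
    )


def compare_cis(a: SlopeEstimate, b: SlopeEstimate) -> SlopeComparison:
    """Declare two group slopes different iff their CIs are disjoint.

    Touching endpoints count as overlap; the test is symmetric and
    conservative relative to a difference test.
    """
    if a.region != b.region:
        raise ValueError(f"region mismatch: {a.region!r} vs {b.region!r}")
    if a.level != b.level:
        raise ValueError("confidence levels differ")
    disjoint = max(a.ci_low, b.ci_low) > min(a.ci_high, b.ci_high)
    return SlopeComparison(
        group_a=a.group,
        group_b=b.group,
        region=a.region,
        significant=bool(disjoint),
        ci_a=(a.ci_low, a.ci_high),
        ci_b=(b.ci_low, b.ci_high),
    )


def apoe_effect(
    records: Sequence[SubjectRecord],
    region: str,
    B: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    group: str = "",
) -> ApoeEffect:
    """Bootstrapped APOE-e4 effect: carrier APC minus non-carrier APC.

    Records without a carrier flag are dropped (logged).  Each bootstrap
    iteration resamples carriers and non-carriers independently, preserving
    the stratum structure.
    """
    flagged = [r for r in records if r.apoe_carrier is not None]
    dropped = len(records) - len(flagged)
    if dropped:
        logger.info("apoe_effect: dropping %d records without APOE data", dropped)
    carriers = [r for r in flagged if r.apoe_carrier]
    noncarriers = [r for r in flagged if not r.apoe_carrier]
    if not carriers or not noncarriers:
        raise ValueError("both APOE strata must be non-empty")
    ages_c, rel_c = _group_arrays(carriers, region)
    ages_n, rel_n = _group_arrays(noncarriers, region)
    _check_group(ages_c, rel_c)
    _check_group(ages_n, rel_n)
    apc_c, _ = _apc_from_arrays(ages_c, rel_c)
    apc_n, _ = _apc_from_arrays(ages_n, rel_n)
    if rng is None:
        rng = np.random.default_rng(seed)
    diffs = _bootstrap_apcs(ages_c, rel_c, B, rng) - _bootstrap_apcs(ages_n, rel_n, B, rng)
    alpha = 1.0 - level
    lo, hi = np.quantile(diffs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return ApoeEffect(
        group=group,
        region=region,
        effect=apc_c - apc_n,
        ci_low=float(lo),
        ci_high=float(hi),
        n_carrier=len(carriers),
        n_noncarrier=len(noncarriers),
        B=B,
        seed=seed,
        level=level,
    )


def _group_label(key: tuple) -> str:
    return "/".join(str(k) for k in key)


def group_slopes(
    cohort: CohortTable,
    B: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    group_keys: Sequence[str] = ("ethnicity", "sex"),
    regions: Sequence[str] | None = None,
) -> list[SlopeEstimate]:
    """Bootstrap slope estimates for every (group, region) cell.

    One master seed expands into a deterministic substream per cell, so the
    result does not depend on iteration order.
    """
    regions = list(regions or cohort.region_set.names)
    out = []
    for key, records in cohort.groups(group_keys):
        label = _group_label(key)
        # canonical record order makes the result invariant to row permutation
        records = sorted(records, key=lambda r: r.subject_id)
        for region in regions:
            rng = substream_rng(seed, "slope", label, region)
            out.append(
                bootstrap_slope_ci(
                    records, region, B=B, level=level, seed=seed, rng=rng, group=label
                )
            )
    return out


def group_apoe_effects(
    cohort: CohortTable,
    B: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    group_keys: Sequence[str] = ("ethnicity", "sex"),
    regions: Sequence[str] | None = None,
) -> list[ApoeEffect]:
    """APOE-e4 effect sizes for every (group, region) cell with both strata."""
    regions = list(regions or cohort.region_set.names)
    out = []
    for key, records in cohort.groups(group_keys):
        label = _group_label(key)
        records = sorted(records, key=lambda r: r.subject_id)
        flagged = [r for r in records if r.apoe_carrier is not None]
        strata = (
            [r for r in flagged if r.apoe_carrier],
            [r for r in flagged if not r.apoe_carrier],
        )
        if any(len({r.age for r in s}) < 3 for s in strata):
            logger.warning("group %s lacks two viable APOE strata; skipped", label)
            continue
        for region in regions:
            rng = substream_rng(seed, "apoe", label, region)
            out.append(
                apoe_effect(
                    records, region, B=B, level=level, seed=seed, rng=rng, group=label
                )
            )
    return out
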