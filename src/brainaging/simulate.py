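"""Synthetic cohort generation.

Generates cohorts with the statistical structure the downstream analysis
assumes: four ethnicity x sex groups with published demographics, APOE-e4
carrier frequencies, lognormal ICV, and per-region relative volumes that
follow a group-specific linear age trend with Gaussian noise.

The generative line is parameterized by the annual percent change (APC)
under the estimator's own convention — slope as a percentage of the
group-mean relative volume — anchored at the *empirical* mean age of the
generated stratum.  In the noise-free limit the fitted APC therefore
recovers ``true_apc`` exactly, making parameter recovery a sharp test.

Default group specs encode the source study's cohort table (group sizes,
age/education/MMSE distributions, e4 frequencies) and its published
group-level APCs; per-region noise SDs are calibrated in closed form so
bootstrap CI widths roughly match the published intervals.  Baseline
relative volumes (percent of ICV at age 65) are plausibility values, not
measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .cohort import COGNITIVE_DOMAINS, CohortTable, SubjectRecord
from .regions import RegionSet, default_region_set

__all__ = [
    "RegionParams",
    "GroupSpec",
    "default_specs",
    "generate_cohort",
    "specs_to_yaml",
    "specs_from_yaml",
]


@dataclass(frozen=True)
class RegionParams:
    """Generative parameters for one region within one group."""

    intercept: float  # relative volume, % of ICV, at age 65
    true_apc: float  # annual percent change, %/yr
    noise_sd: float  # residual SD on the relative-volume scale, % of ICV
    carrier_apc: float | None = None  # APC for APOE-e4 carriers, if distinct
    carrier_intercept_shift: float = 0.0  # additive %ICV shift for carriers

    def __post_init__(self) -> None:
        if self.intercept < 0:
            raise ValueError("intercept must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroupSpec:
    """Everything needed to simulate one ethnicity x sex group."""

    ethnicity: str
    sex: str
    n: int
    age_mean: float
    age_sd: float
    education_mean: float
    education_sd: float
    apoe_e4_freq: float
    icv_mean: float
    icv_sd: float
    regions: Mapping[str, RegionParams]
    apoe_missing_rate: float = 0.0
    mmse_mean: float = 27.5
    mmse_sd: float = 2.0
    age_min: float = 65.0
    age_max: float = 85.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name, value in (
            ("age_sd", self.age_sd),
            ("education_sd", self.education_sd),
            ("icv_sd", self.icv_sd),
            ("mmse_sd", self.mmse_sd),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        for name, value in (
            ("apoe_e4_freq", self.apoe_e4_freq),
            ("apoe_missing_rate", self.apoe_missing_rate),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for fname, fval in asdict(self).items():
            if isinstance(fval, (int, float)) and not math.isfinite(fval):
                raise ValueError(f"{fname} is not finite")

    @property
    def label(self) -> str:
        return f"{self.ethnicity}/{self.sex}"


# ---------------------------------------------------------------------------
# Default specifications
# ---------------------------------------------------------------------------

# Baseline relative volumes (% of ICV at age 65).  Plausibility values chosen
# to be anatomically reasonable; the Caucasian groups get small multipliers
# reflecting the pooled-regression sign pattern (cortex smaller, ventricle
# and caudate larger relative to ICV).
_BASE_INTERCEPT = {
    "brain": 80.0,
    "frontal": 10.5,
    "temporal": 7.3,
    "parietal": 5.7,
    "occipital": 3.2,
    "cingulate": 1.75,
    "insular": 0.95,
    "ventricle": 2.2,
    "thalamus": 0.95,
    "putamen": 0.62,
    "hippocampus": 0.55,
    "caudate": 0.46,
    "amygdala": 0.23,
    "pallidus": 0.24,
    "accumbens": 0.072,
}
_CAUCASIAN_INTERCEPT_FACTOR = {"ventricle": 1.10, "caudate": 1.05, "putamen": 1.0}
_CAUCASIAN_DEFAULT_FACTOR = 0.95

# Published group-level APCs with 95% CIs, keyed by region then group
# (caucasian/female, korean/female, caucasian/male, korean/male).
_GROUP_APC: dict[str, dict[str, tuple[float, float, float]]] = {
    "brain": {
        "caucasian/female": (-0.791, -1.152, -0.574),
        "korean/female": (-0.408, -0.486, -0.329),
        "caucasian/male": (-0.612, -0.760, -0.457),
        "korean/male": (-0.513, -0.598, -0.428),
    },
    "frontal": {
        "caucasian/female": (-0.664, -1.018, -0.342),
        "korean/female": (-0.155, -0.257, -0.050),
        "caucasian/male": (-0.491, -0.741, -0.245),
        "korean/male": (-0.323, -0.422, -0.221),
    },
    "temporal": {
        "caucasian/female": (-0.941, -1.268, -0.632),
        "korean/female": (-0.439, -0.544, -0.338),
        "caucasian/male": (-0.684, -0.955, -0.433),
        "korean/male": (-0.570, -0.691, -0.456),
    },
    "parietal": {
        "caucasian/female": (-0.828, -1.141, -0.517),
        "korean/female": (-0.207, -0.315, -0.098),
        "caucasian/male": (-0.584, -0.848, -0.315),
        "korean/male": (-0.349, -0.473, -0.222),
    },
    "occipital": {
        "caucasian/female": (-1.114, -1.541, -0.722),
        "korean/female": (-0.344, -0.480, -0.205),
        "caucasian/male": (-0.615, -0.903, -0.309),
        "korean/male": (-0.659, -0.820, -0.496),
    },
    "cingulate": {
        "caucasian/female": (-0.649, -1.069, -0.275),
        "korean/female": (-0.218, -0.364, -0.074),
        "caucasian/male": (-0.196, -0.460, 0.059),
        "korean/male": (-0.347, -0.515, -0.182),
    },
    "insular": {
        "caucasian/female": (-0.478, -0.835, -0.145),
        "korean/female": (0.025, -0.105, 0.162),
        "caucasian/male": (-0.130, -0.448, 0.177),
        "korean/male": (-0.048, -0.203, 0.110),
    },
    "ventricle": {
        "caucasian/female": (2.187, 0.549, 3.741),
        "korean/female": (4.176, 3.527, 4.815),
        "caucasian/male": (2.869, 1.935, 3.904),
        "korean/male": (2.796, 2.181, 3.427),
    },
    "thalamus": {
        "caucasian/female": (-0.832, -1.286, -0.534),
        "korean/female": (-0.210, -0.381, -0.023),
        "caucasian/male": (-0.490, -0.774, -0.207),
        "korean/male": (-0.406, -0.605, -0.205),
    },
    "putamen": {
        "caucasian/female": (-0.550, -1.058, 0.008),
        "korean/female": (-0.734, -0.960, -0.500),
        "caucasian/male": (-0.496, -0.835, -0.136),
        "korean/male": (-0.714, -0.976, -0.441),
    },
    "hippocampus": {
        "caucasian/female": (-1.588, -2.074, -1.122),
        "korean/female": (-0.886, -1.057, -0.723),
        "caucasian/male": (-1.220, -1.605, -0.825),
        "korean/male": (-0.977, -1.193, -0.761),
    },
    "caudate": {
        "caucasian/female": (-0.010, -0.520, 0.571),
        "korean/female": (-0.144, -0.322, 0.036),
        "caucasian/male": (-0.058, -0.433, 0.351),
        "korean/male": (-0.236, -0.476, 0.003),
    },
    "amygdala": {
        "caucasian/female": (-1.697, -2.375, -1.078),
        "korean/female": (-0.652, -0.835, -0.468),
        "caucasian/male": (-1.046, -1.558, -0.531),
        "korean/male": (-0.918, -1.159, -0.683),
    },
    "pallidus": {
        "caucasian/female": (-0.243, -0.664, 0.187),
        "korean/female": (0.383, 0.140, 0.613),
        "caucasian/male": (-0.183, -0.493, 0.149),
        "korean/male": (0.236, -0.089, 0.575),
    },
    "accumbens": {
        "caucasian/female": (-1.635, -2.409, -0.759),
        "korean/female": (-1.465, -1.784, -1.147),
        "caucasian/male": (-1.602, -2.345, -0.932),
        "korean/male": (-1.137, -1.502, -0.772),
    },
}

# Published female APOE-e4 carrier APCs (used as carrier_apc defaults).
_CARRIER_APC: dict[str, dict[str, float]] = {
    "caucasian/female": {
        "brain": -1.234,
        "frontal": -1.078,
        "temporal": -1.446,
        "parietal": -1.370,
        "occipital": -1.830,
        "cingulate": -0.960,
        "insular": -1.135,
        "ventricle": 3.116,
        "thalamus": -1.261,
        "putamen": -1.693,
        "hippocampus": -2.104,
        "caudate": -0.942,
        "amygdala": -2.419,
        "pallidus": -1.263,
        "accumbens": -2.899,
    },
    "korean/female": {
        "brain": -0.573,
        "frontal": -0.264,
        "temporal": -0.381,
        "parietal": -0.270,
        "occipital": -0.512,
        "cingulate": -0.261,
        "insular": 0.277,
        "ventricle": 4.360,
        "thalamus": -0.465,
        "putamen": -0.602,
        "hippocampus": -0.636,
        "caudate": -0.288,
        "amygdala": -0.700,
        "pallidus": 0.343,
        "accumbens": -1.364,
    },
}

# Group demographics: (n, age mean, age sd, edu mean, edu sd, mmse mean,
# mmse sd, e4 freq, apoe missing rate, icv mean, icv sd).
_DEMOGRAPHICS = {
    "korean/female": (638, 72.1, 4.3, 8.4, 4.1, 27.1, 2.2, 0.170, 1 - 534 / 638, 1.40e6, 1.2e5),
    "korean/male": (370, 74.3, 5.0, 12.2, 4.0, 27.8, 1.6, 0.176, 1 - 296 / 370, 1.56e6, 1.3e5),
    "caucasian/female": (163, 74.5, 4.8, 15.5, 2.6, 29.2, 1.1, 0.292, 1 - 161 / 163, 1.43e6, 1.2e5),
    "caucasian/male": (179, 75.6, 5.2, 17.0, 2.6, 29.0, 1.1, 0.246, 0.0, 1.58e6, 1.3e5),
}


def _truncnorm_moments(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    if sd == 0:
        return mean, 0.0
    a, b = (lo - mean) / sd, (hi - mean) / sd
    dist = stats.truncnorm(a, b, loc=mean, scale=sd)
    return float(dist.mean()), float(dist.std())


def _calibrated_noise_sd(
    ci_width: float,
    apc: float,
    intercept: float,
    n: int,
    age_mean: float,
    age_sd: float,
    age_min: float,
    age_max: float,
) -> float:
    """Residual SD such that a 95% bootstrap CI has roughly ``ci_width``.

    Inverts width = 2 * 1.96 * 100 * sigma / (mean_rel * sd_age * sqrt(n)).
    """
    mu_age, sd_age = _truncnorm_moments(age_mean, age_sd, age_min, age_max)
    g = apc / 100.0
    mean_rel = intercept / (1.0 - g * (mu_age - 65.0)) if g * (mu_age - 65.0) < 1 else intercept
    sigma = (ci_width / (2 * 1.959964)) * (mean_rel / 100.0) * sd_age * math.sqrt(max(n, 2))
    return max(sigma, 1e-6 * max(intercept, 1.0))


def default_specs() -> list[GroupSpec]:
    """The four default group specs (Korean/Caucasian x female/male)."""
    specs = []
    for label in ("korean/female", "korean/male", "caucasian/female", "caucasian/male"):
        ethnicity, sex = label.split("/")
        (n, age_m, age_s, edu_m, edu_s, mmse_m, mmse_s, e4, miss, icv_m, icv_s) = _DEMOGRAPHICS[label]
        regions = {}
        for region, base in _BASE_INTERCEPT.items():
            apc, lo, hi = _GROUP_APC[region][label]
            if ethnicity == "caucasian":
                base = base * _CAUCASIAN_INTERCEPT_FACTOR.get(region, _CAUCASIAN_DEFAULT_FACTOR)
            regions[region] = RegionParams(
                intercept=base,
                true_apc=apc,
                noise_sd=_calibrated_noise_sd(hi - lo, apc, base, n, age_m, age_s, 65.0, 85.0),
                carrier_apc=_CARRIER_APC.get(label, {}).get(region),
            )
        specs.append(
            GroupSpec(
                ethnicity=ethnicity,
                sex=sex,
                n=n,
                age_mean=age_m,
                age_sd=age_s,
                education_mean=edu_m,
                education_sd=edu_s,
                apoe_e4_freq=e4,
                icv_mean=icv_m,
                icv_sd=icv_s,
                regions=regions,
                apoe_missing_rate=miss,
                mmse_mean=mmse_m,
                mmse_sd=mmse_s,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _draw_genotypes(carrier: np.ndarray, rng: np.random.Generator) -> list[tuple[str, str]]:
    genotypes = []
    for c in carrier:
        if c:
            genotypes.append(("e4", "e4") if rng.random() < 0.12 else ("e3", "e4"))
        else:
            genotypes.append(("e2", "e3") if rng.random() < 0.10 else ("e3", "e3"))
    return genotypes


def _stratum_relative_volumes(
    ages: np.ndarray,
    params: RegionParams,
    carrier: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Relative volumes (% ICV) for one region of one group.

    Each APC stratum (carriers vs the rest when ``carrier_apc`` is set,
    otherwise everyone) gets a line anchored at the stratum's empirical
    mean age so that the stratum's fitted APC equals the target exactly in
    the noise-free limit.
    """
    rel = np.empty_like(ages)
    if params.carrier_apc is None:
        strata = [(np.ones(len(ages), dtype=bool), params.true_apc, 0.0)]
    else:
        strata = [
            (~carrier, params.true_apc, 0.0),
            (carrier, params.carrier_apc, params.carrier_intercept_shift),
        ]
    for mask, apc, shift in strata:
        if not mask.any():
            continue
        sub_ages = ages[mask]
        g = apc / 100.0
        mean_shift = g * (sub_ages.mean() - 65.0)
        if mean_shift >= 1.0:
            raise ValueError("APC too large for the anchored-line parameterization")
        slope = g * (params.intercept + shift) / (1.0 - mean_shift)
        line = (params.intercept + shift) + slope * (sub_ages - 65.0)
        rel[mask] = line
    if params.noise_sd > 0:
        rel = rel + rng.normal(0.0, params.noise_sd, size=len(ages))
    return np.clip(rel, 0.0, None)


def generate_cohort(
    specs: Sequence[GroupSpec],
    seed: int,
    region_set: RegionSet | None = None,
) -> CohortTable:
    """Generate a cohort from group specs; bit-reproducible given the seed."""
    region_set = region_set or default_region_set()
    missing_regions = [
        (spec.label, r) for spec in specs for r in region_set.names if r not in spec.regions
    ]
    if missing_regions:
        raise ValueError(f"specs missing region parameters: {missing_regions}")

    root = np.random.SeedSequence(seed)
    children = root.spawn(len(specs))
    records: list[SubjectRecord] = []
    for spec_idx, (spec, child) in enumerate(zip(specs, children)):
        rng = np.random.default_rng(child)
        n = spec.n
        if n == 0:
            continue
        a, b = (
            (spec.age_min - spec.age_mean) / spec.age_sd,
            (spec.age_max - spec.age_mean) / spec.age_sd,
        )
        ages = stats.truncnorm.rvs(
            a, b, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng
        )
        mu, sigma = _lognormal_params(spec.icv_mean, spec.icv_sd)
        icv = rng.lognormal(mu, sigma, size=n)
        education = np.clip(rng.normal(spec.education_mean, spec.education_sd, size=n), 0.0, None)
        mmse_lo, mmse_hi = (
            (19.0 - spec.mmse_mean) / spec.mmse_sd,
            (30.0 - spec.mmse_mean) / spec.mmse_sd,
        )
        mmse = stats.truncnorm.rvs(
            mmse_lo, mmse_hi, loc=spec.mmse_mean, scale=spec.mmse_sd, size=n, random_state=rng
        )
        # Domain z-scores truncated above the screening cut so generated
        # cohorts represent an already-screened sample.
        zs = stats.truncnorm.rvs(
            (-1.5 - 0.3) / 0.9, np.inf, loc=0.3, scale=0.9, size=(n, len(COGNITIVE_DOMAINS)),
            random_state=rng,
        )
        carrier = rng.random(n) < spec.apoe_e4_freq
        observed = rng.random(n) >= spec.apoe_missing_rate
        genotypes = _draw_genotypes(carrier, rng)

        rel = {
            region: _stratum_relative_volumes(ages, spec.regions[region], carrier, rng)
            for region in region_set.names
        }
        for i in range(n):
            records.append(
                SubjectRecord(
                    subject_id=f"G{spec_idx}-{spec.ethnicity[:3].upper()}{spec.sex[:1].upper()}-{i:05d}",
                    age=float(ages[i]),
                    sex=spec.sex,
                    ethnicity=spec.ethnicity,
                    education=float(education[i]),
                    icv=float(icv[i]),
                    volumes={
                        region: float(rel[region][i] / 100.0 * icv[i])
                        for region in region_set.names
                    },
                    apoe_genotype=genotypes[i] if observed[i] else None,
                    apoe_carrier=bool(carrier[i]) if observed[i] else None,
                    mmse=float(mmse[i]),
                    domain_z={d: float(zs[i, j]) for j, d in enumerate(COGNITIVE_DOMAINS)},
                )
            )
    return CohortTable(
        records=tuple(records),
        region_set=region_set,
        provenance=f"synthetic cohort, seed={seed}, {len(specs)} group specs",
    )


# ---------------------------------------------------------------------------
# YAML round-trip for spec files
# ---------------------------------------------------------------------------


def specs_to_yaml(specs: Sequence[GroupSpec], path) -> None:
    payload = []
    for spec in specs:
        entry = asdict(spec)
        entry["regions"] = {
            name: {k: v for k, v in asdict(params).items() if v is not None}
            for name, params in spec.regions.items()
        }
        payload.append(entry)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"groups": payload}, fh, sort_keys=False)


def specs_from_yaml(path) -> list[GroupSpec]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    specs = []
    for entry in payload["groups"]:
        regions = {
            name: RegionParams(**params) for name, params in entry.pop("regions").items()
        }
        specs.append(GroupSpec(regions=regions, **entry))
    return specs
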