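"""Shared fixtures and builders for the test suite.

All fixtures are generated programmatically; FreeSurfer stats fixtures are
emitted by small writer helpers so parser tests can round-trip them.
"""

from __future__ import annotations

import numpy as np
import pytest

from brainaging.cohort import COGNITIVE_DOMAINS, CohortTable, SubjectRecord
from brainaging.regions import RegionDef, RegionSet, default_region_set
from brainaging.simulate import GroupSpec, RegionParams


@pytest.fixture(scope="session")
def region_set() -> RegionSet:
    return default_region_set()


@pytest.fixture(scope="session")
def small_region_set() -> RegionSet:
    """Two-region set for fast simulation tests."""
    return RegionSet(
        regions=(
            RegionDef(name="brain", measure="BrainSegVolNotVent"),
            RegionDef(name="hippocampus", aseg=("Left-Hippocampus", "Right-Hippocampus")),
        )
    )


def make_record(
    subject_id: str = "s1",
    age: float = 70.0,
    sex: str = "female",
    ethnicity: str = "korean",
    education: float = 10.0,
    icv: float = 1.5e6,
    region_names=None,
    rel_volumes=None,
    mmse: float | None = 27.0,
    domain_z=None,
    **kwargs,
) -> SubjectRecord:
    """Build a valid record; volumes default to 1% of ICV per region."""
    region_names = region_names or default_region_set().names
    if rel_volumes is None:
        rel_volumes = {r: 1.0 for r in region_names}
    if domain_z is None:
        domain_z = {d: 0.0 for d in COGNITIVE_DOMAINS}
    return SubjectRecord(
        subject_id=subject_id,
        age=age,
        sex=sex,
        ethnicity=ethnicity,
        education=education,
        icv=icv,
        volumes={r: rel_volumes[r] / 100.0 * icv for r in region_names},
        mmse=mmse,
        domain_z=domain_z,
        **kwargs,
    )


def make_group_records(
    ages,
    rel,
    region: str = "brain",
    icv: float = 1.5e6,
    carriers=None,
    **kwargs,
):
    """Records for one group with prescribed relative volumes in one region."""
    names = default_region_set().names
    records = []
    for i, (age, r) in enumerate(zip(ages, rel)):
        rel_volumes = {name: 1.0 for name in names}
        rel_volumes[region] = r
        extra = dict(kwargs)
        if carriers is not None:
            extra["apoe_carrier"] = bool(carriers[i])
            extra["apoe_genotype"] = ("e3", "e4") if carriers[i] else ("e3", "e3")
        records.append(
            make_record(
                subject_id=f"g{i:04d}", age=float(age), icv=icv, rel_volumes=rel_volumes, **extra
            )
        )
    return records


def make_spec(
    n: int = 300,
    true_apc: float = -0.5,
    noise_sd: float = 0.5,
    intercept: float = 80.0,
    carrier_apc: float | None = None,
    regions=("brain", "hippocampus"),
    apoe_e4_freq: float = 0.2,
    **kwargs,
) -> GroupSpec:
    defaults = dict(
        ethnicity="korean",
        sex="female",
        n=n,
        age_mean=72.0,
        age_sd=4.5,
        education_mean=10.0,
        education_sd=4.0,
        apoe_e4_freq=apoe_e4_freq,
        icv_mean=1.45e6,
        icv_sd=1.2e5,
    )
    defaults.update(kwargs)
    return GroupSpec(
        regions={
            r: RegionParams(
                intercept=intercept, true_apc=true_apc, noise_sd=noise_sd, carrier_apc=carrier_apc
            )
            for r in regions
        },
        **defaults,
    )


# ---------------------------------------------------------------------------
# FreeSurfer stats fixture writers
# ---------------------------------------------------------------------------


def write_aseg_text(
    volumes: dict[str, float],
    etiv: float = 1.5e6,
    brain_not_vent: float | None = 1.1e6,
    extra_header: str = "",
) -> str:
    lines = [
        "# Title Segmentation Statistics",
        "# subjectname test",
    ]
    if brain_not_vent is not None:
        lines.append(
            "# Measure BrainSegNotVent, BrainSegVolNotVent, "
            f"Brain Segmentation Volume Without Ventricles, {brain_not_vent}, mm^3"
        )
    lines.append(
        "# Measure EstimatedTotalIntraCranialVol, eTIV, "
        f"Estimated Total Intracranial Volume, {etiv}, mm^3"
    )
    if extra_header:
        lines.append(extra_header)
    lines.append("# ColHeaders Index SegId NVoxels Volume_mm3 StructName")
    for i, (name, vol) in enumerate(volumes.items(), start=1):
        lines.append(f"{i} {i + 1} {int(abs(vol))} {vol} {name}")
    return "\n".join(lines) + "\n"


def write_aparc_text(gray_volumes: dict[str, float], hemisphere: str = "lh") -> str:
    lines = [
        "# Table of FreeSurfer cortical parcellation anatomical statistics",
        f"# hemi {hemisphere}",
        "# ColHeaders StructName NumVert SurfArea GrayVol",
    ]
    for name, vol in gray_volumes.items():
        lines.append(f"{name} 1000 800 {vol}")
    return "\n".join(lines) + "\n"


def full_parcel_volumes(value: float = 1000.0, rng: np.random.Generator | None = None):
    """GrayVol for every DKT parcel; random values when an rng is given."""
    from brainaging.regions import DKT_PARCELS

    if rng is None:
        return {p: value for p in sorted(DKT_PARCELS)}
    return {p: float(rng.uniform(500, 20000)) for p in sorted(DKT_PARCELS)}


def full_aseg_volumes(value: float = 2000.0, rng: np.random.Generator | None = None):
    """Volumes for every aseg structure the default mapping needs."""
    names = [
        "Left-Lateral-Ventricle",
        "Right-Lateral-Ventricle",
        "Left-Inf-Lat-Vent",
        "Right-Inf-Lat-Vent",
        "3rd-Ventricle",
        "4th-Ventricle",
        "Left-Thalamus-Proper",
        "Right-Thalamus-Proper",
        "Left-Putamen",
        "Right-Putamen",
        "Left-Hippocampus",
        "Right-Hippocampus",
        "Left-Caudate",
        "Right-Caudate",
        "Left-Amygdala",
        "Right-Amygdala",
        "Left-Pallidum",
        "Right-Pallidum",
        "Left-Accumbens-area",
        "Right-Accumbens-area",
    ]
    if rng is None:
        return {n: value for n in names}
    return {n: float(rng.uniform(100, 8000)) for n in names}


@pytest.fixture
def cohort_small(region_set) -> CohortTable:
    """Deterministic 12-record cohort spanning groups and carrier status."""
    rng = np.random.default_rng(7)
    records = []
    i = 0
    for ethnicity in ("korean", "caucasian"):
        for sex in ("female", "male"):
            for _ in range(3):
                age = float(rng.uniform(65, 85))
                records.append(
                    make_record(
                        subject_id=f"s{i:03d}",
                        age=age,
                        sex=sex,
                        ethnicity=ethnicity,
                        education=float(rng.uniform(6, 18)),
                        icv=float(rng.uniform(1.3e6, 1.7e6)),
                        rel_volumes={r: float(rng.uniform(0.5, 5.0)) for r in region_set.names},
                        apoe_carrier=bool(i % 2),
                        apoe_genotype=("e3", "e4") if i % 2 else ("e3", "e3"),
                    )
                )
                i += 1
    return CohortTable(records=tuple(records), region_set=region_set)
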