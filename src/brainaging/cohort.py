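"""Subject-level domain types, cognitive screening, APOE calls, cohort I/O.

A cohort is a flat table: one row per subject with demographics, APOE
status, intracranial volume (ICV), and one absolute volume per composite
region.  This module owns validation of that table and the two small
rule-based operations attached to it: the cognitively-normal screen and
the APOE genotype call from the two defining SNPs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .regions import RegionSet, default_region_set

logger = logging.getLogger(__name__)

__all__ = [
    "COGNITIVE_DOMAINS",
    "SubjectRecord",
    "CohortTable",
    "ScreenResult",
    "ApoeCall",
    "CohortValidationError",
    "screen_cognitively_normal",
    "apoe_from_snps",
    "read_cohort",
    "write_cohort",
]

#: The five cognitive domains assessed by the screening battery, in the
#: order screening failures are reported.
COGNITIVE_DOMAINS: tuple[str, ...] = (
    "attention",
    "language",
    "visuospatial",
    "memory",
    "executive",
)

_VALID_APOE_ALLELES = frozenset({"e2", "e3", "e4"})


class CohortValidationError(ValueError):
    """Structured validation failure; ``problems`` lists offending rows."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "cohort validation failed:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: demographics, APOE status, ICV, regional volumes."""

    subject_id: str
    age: float
    sex: str
    ethnicity: str
    education: float
    icv: float
    volumes: Mapping[str, float]
    apoe_genotype: tuple[str, str] | None = None
    apoe_carrier: bool | None = None
    mmse: float | None = None
    domain_z: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.apoe_genotype is not None:
            genotype = tuple(sorted(self.apoe_genotype))
            if len(genotype) != 2 or not set(genotype) <= _VALID_APOE_ALLELES:
                raise ValueError(
                    f"{self.subject_id}: invalid APOE genotype {self.apoe_genotype!r}"
                )
            object.__setattr__(self, "apoe_genotype", genotype)

    def validate(
        self,
        region_names: Sequence[str],
        age_bounds: tuple[float, float] = (65.0, 85.0),
    ) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        sid = self.subject_id
        lo, hi = age_bounds
        if not (lo <= self.age <= hi):
            problems.append(f"{sid}: age {self.age} outside [{lo}, {hi}]")
        if not (self.icv > 0 and math.isfinite(self.icv)):
            problems.append(f"{sid}: icv must be finite and > 0, got {self.icv}")
        for region in region_names:
            if region not in self.volumes:
                problems.append(f"{sid}: missing volume for region {region!r}")
                continue
            vol = self.volumes[region]
            if not math.isfinite(vol) or vol < 0:
                problems.append(f"{sid}: volume[{region}] = {vol} is negative/non-finite")
            elif self.icv > 0 and vol >= self.icv:
                problems.append(f"{sid}: volume[{region}] = {vol} >= icv = {self.icv}")
        if self.apoe_genotype is not None and self.apoe_carrier is not None:
            if self.apoe_carrier != ("e4" in self.apoe_genotype):
                problems.append(
                    f"{sid}: apoe_carrier={self.apoe_carrier} inconsistent with "
                    f"genotype {'/'.join(self.apoe_genotype)}"
                )
        return problems


@dataclass(frozen=True)
class CohortTable:
    """Validated collection of subject records sharing one region set."""

    records: tuple[SubjectRecord, ...]
    region_set: RegionSet = field(default_factory=default_region_set)
    provenance: str = ""
    age_bounds: tuple[float, float] = (65.0, 85.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        problems: list[str] = []
        seen: dict[str, int] = {}
        for i, rec in enumerate(self.records):
            if rec.subject_id in seen:
                problems.append(
                    f"row {i}: duplicate subject_id {rec.subject_id!r} "
                    f"(first seen at row {seen[rec.subject_id]})"
                )
            else:
                seen[rec.subject_id] = i
            problems.extend(rec.validate(self.region_set.names, self.age_bounds))
        if problems:
            raise CohortValidationError(problems)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, predicate) -> "CohortTable":
        return replace(self, records=tuple(r for r in self.records if predicate(r)))

    def groups(self, keys: Sequence[str] = ("ethnicity", "sex")):
        """Yield ``(key_tuple, records)`` grouped by the given attributes,
        in first-appearance order."""
        out: dict[tuple, list[SubjectRecord]] = {}
        for rec in self.records:
            out.setdefault(tuple(getattr(rec, k) for k in keys), []).append(rec)
        return list(out.items())

    def with_apoe(self) -> "CohortTable":
        """Drop records without a carrier flag, logging how many were lost."""
        kept = tuple(r for r in self.records if r.apoe_carrier is not None)
        dropped = len(self.records) - len(kept)
        if dropped:
            logger.info("dropping %d of %d records without APOE data", dropped, len(self))
        return replace(self, records=kept)


@dataclass(frozen=True)
class ScreenResult:
    include: bool
    reason: str | None = None


def screen_cognitively_normal(
    record: SubjectRecord,
    mmse_min: float = 19.0,
    z_cut: float = -1.5,
) -> ScreenResult:
    """Apply the cognitively-normal screen to one subject.

    Excludes when MMSE is below ``mmse_min`` or any cognitive-domain
    z-score falls below ``z_cut``; the reason names the first failing
    criterion (MMSE first, then domains in canonical order).
    """
    if record.mmse is None:
        raise ValueError("insufficient neuropsychological data: mmse missing")
    if record.domain_z is None or any(
        d not in record.domain_z or record.domain_z[d] is None
        or not math.isfinite(record.domain_z[d])
        for d in COGNITIVE_DOMAINS
    ):
        raise ValueError("insufficient neuropsychological data: domain z-scores missing")
    if record.mmse < mmse_min:
        return ScreenResult(include=False, reason="mmse")
    for domain in COGNITIVE_DOMAINS:
        if record.domain_z[domain] < z_cut:
            return ScreenResult(include=False, reason=domain)
    return ScreenResult(include=True)


@dataclass(frozen=True)
class ApoeCall:
    """Result of an APOE genotype call; ``ambiguous`` means the unphased
    SNP pair cannot be resolved and genotype/carrier are None."""

    genotype: tuple[str, str] | None
    carrier: bool | None
    ambiguous: bool = False


def _normalize_pair(pair: Iterable[str], name: str) -> tuple[str, str]:
    alleles = tuple(str(a).upper() for a in pair)
    if len(alleles) != 2 or not set(alleles) <= {"C", "T"}:
        raise ValueError(f"{name}: alleles must be a diploid pair from {{C, T}}, got {pair!r}")
    return tuple(sorted(alleles))  # type: ignore[return-value]


# haplotype (rs429358, rs7412) -> epsilon allele
_HAPLOTYPE = {("T", "T"): "e2", ("T", "C"): "e3", ("C", "C"): "e4", ("C", "T"): "e1"}


def apoe_from_snps(rs429358: Iterable[str], rs7412: Iterable[str]) -> ApoeCall:
    """Derive the APOE genotype from unphased rs429358 and rs7412 calls.

    Haplotype table: e2 = T+T, e3 = T+C, e4 = C+C (rs429358 first).  The
    double heterozygote (C/T at both SNPs) is intrinsically phase-ambiguous
    (e2/e4 vs e1/e3) and is flagged rather than resolved.  Combinations
    that force the rare e1 haplotype raise, since e1 is outside the
    supported allele set.
    """
    snp1 = _normalize_pair(rs429358, "rs429358")
    snp2 = _normalize_pair(rs7412, "rs7412")
    if snp1 == ("C", "T") and snp2 == ("C", "T"):
        return ApoeCall(genotype=None, carrier=None, ambiguous=True)
    # Any other combination has a unique phasing: pair the alleles both ways
    # and keep the assignment that avoids e1 if one exists.
    candidates = []
    for a, b in ((0, 1), (1, 0)):
        hap1 = _HAPLOTYPE[(snp1[0], snp2[a])]
        hap2 = _HAPLOTYPE[(snp1[1], snp2[b])]
        candidates.append(tuple(sorted((hap1, hap2))))
    viable = [g for g in candidates if "e1" not in g]
    if not viable:
        raise ValueError(
            f"SNP combination rs429358={'/'.join(snp1)}, rs7412={'/'.join(snp2)} "
            "implies the unsupported e1 haplotype"
        )
    genotype = viable[0]
    return ApoeCall(genotype=genotype, carrier="e4" in genotype)


# ---------------------------------------------------------------------------
# Delimited-text cohort I/O
# ---------------------------------------------------------------------------

_BASE_COLUMNS = ["subject_id", "age", "sex", "ethnicity", "education", "icv_mm3"]


def _volume_column(region: str) -> str:
    return f"vol_{region}_mm3"


def cohort_to_frame(cohort: CohortTable) -> pd.DataFrame:
    """Flatten a cohort into the canonical wide table."""
    rows = []
    for rec in cohort:
        row: dict = {
            "subject_id": rec.subject_id,
            "age": rec.age,
            "sex": rec.sex,
            "ethnicity": rec.ethnicity,
            "education": rec.education,
            "icv_mm3": rec.icv,
            "apoe_genotype": (
                "/".join(rec.apoe_genotype) if rec.apoe_genotype is not None else ""
            ),
            "apoe_carrier": "" if rec.apoe_carrier is None else int(rec.apoe_carrier),
            "mmse": "" if rec.mmse is None else rec.mmse,
        }
        for domain in COGNITIVE_DOMAINS:
            z = None if rec.domain_z is None else rec.domain_z.get(domain)
            row[f"z_{domain}"] = "" if z is None else z
        for region in cohort.region_set.names:
            row[_volume_column(region)] = rec.volumes[region]
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(cohort: CohortTable, path, sep: str = ",") -> None:
    # repr() gives shortest-roundtrip float text, so read_cohort(write_cohort(c))
    # reproduces every real-valued field bit-exactly.
    cohort_to_frame(cohort).to_csv(
        path, sep=sep, index=False, float_format=lambda v: repr(float(v))
    )


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def frame_to_cohort(
    df: pd.DataFrame,
    region_set: RegionSet | None = None,
    provenance: str = "",
    age_bounds: tuple[float, float] = (65.0, 85.0),
) -> CohortTable:
    region_set = region_set or default_region_set()
    required = _BASE_COLUMNS + [_volume_column(r) for r in region_set.names]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError([f"missing required columns: {missing}"])

    has_snps = "apoe_rs429358" in df.columns and "apoe_rs7412" in df.columns
    z_cols = {d: f"z_{d}" for d in COGNITIVE_DOMAINS if f"z_{d}" in df.columns}

    records = []
    for _, row in df.iterrows():
        genotype: tuple[str, str] | None = None
        carrier: bool | None = None
        raw_geno = row.get("apoe_genotype")
        if isinstance(raw_geno, str) and raw_geno.strip():
            genotype = tuple(sorted(raw_geno.strip().split("/")))  # type: ignore[assignment]
            carrier = "e4" in genotype
        elif has_snps:
            a1, a2 = row["apoe_rs429358"], row["apoe_rs7412"]
            if isinstance(a1, str) and a1.strip() and isinstance(a2, str) and a2.strip():
                call = apoe_from_snps(a1.strip().split("/"), a2.strip().split("/"))
                if not call.ambiguous:
                    genotype, carrier = call.genotype, call.carrier
        if carrier is None and "apoe_carrier" in df.columns:
            flag = _opt_float(row["apoe_carrier"])
            if flag is not None:
                carrier = bool(flag)

        domain_z = None
        if z_cols:
            values = {d: _opt_float(row[c]) for d, c in z_cols.items()}
            if any(v is not None for v in values.values()):
                domain_z = {d: v for d, v in values.items() if v is not None}

        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                ethnicity=str(row["ethnicity"]),
                education=float(row["education"]),
                icv=float(row["icv_mm3"]),
                volumes={r: float(row[_volume_column(r)]) for r in region_set.names},
                apoe_genotype=genotype,
                apoe_carrier=carrier,
                mmse=_opt_float(row.get("mmse")),
                domain_z=domain_z,
            )
        )
    return CohortTable(
        records=tuple(records),
        region_set=region_set,
        provenance=provenance,
        age_bounds=age_bounds,
    )


def read_cohort(
    path,
    sep: str | None = None,
    region_set: RegionSet | None = None,
    age_bounds: tuple[float, float] = (65.0, 85.0),
) -> CohortTable:
    """Read a cohort CSV/TSV.  ``sep=None`` sniffs the delimiter."""
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return frame_to_cohort(
        df, region_set=region_set, provenance=str(path), age_bounds=age_bounds
    )
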