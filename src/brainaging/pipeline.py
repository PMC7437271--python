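"""End-to-end pipeline: screen -> regress -> slopes -> compare -> APOE -> norms.

A :class:`RunConfig` fully determines the outputs; each run writes the
stage CSVs plus a manifest recording the config hash, seed, and library
versions (the reproducibility contract: identical config+seed implies
byte-identical CSVs).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortTable, read_cohort, screen_cognitively_normal, write_cohort
from .regions import RegionSet, default_region_set
from .regression import fit_volume_model, regression_frame
from .slopes import compare_cis, group_apoe_effects, group_slopes

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "slopes_frame", "comparisons_frame", "apoe_frame"]


@dataclass(frozen=True)
class RunConfig:
    cohort_path: str
    out_dir: str
    B: int = 10_000
    level: float = 0.95
    seed: int = 0
    alpha: float = 0.05
    m_regions: int = 15
    mmse_min: float = 19.0
    z_cut: float = -1.5
    screen: bool = True
    region_mapping: str | None = None  # YAML path; None = shipped default

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")

    def validate_paths(self) -> None:
        if not Path(self.cohort_path).exists():
            raise FileNotFoundError(self.cohort_path)
        if self.region_mapping is not None and not Path(self.region_mapping).exists():
            raise FileNotFoundError(self.region_mapping)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def slopes_frame(estimates) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": e.group,
                "region": e.region,
                "slope": e.slope,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n": e.n,
                "B": e.B,
                "level": e.level,
                "significant": e.significant,
            }
            for e in estimates
        ]
    )


def comparisons_frame(estimates) -> pd.DataFrame:
    by_region: dict[str, list] = {}
    for e in estimates:
        by_region.setdefault(e.region, []).append(e)
    rows = []
    for region, ests in by_region.items():
        for a, b in itertools.combinations(ests, 2):
            cmp_ = compare_cis(a, b)
            rows.append(
                {
                    "region": region,
                    "group_a": cmp_.group_a,
                    "group_b": cmp_.group_b,
                    "decision": cmp_.decision,
                    "ci_a_low": cmp_.ci_a[0],
                    "ci_a_high": cmp_.ci_a[1],
                    "ci_b_low": cmp_.ci_b[0],
                    "ci_b_high": cmp_.ci_b[1],
                }
            )
    return pd.DataFrame(rows)


def apoe_frame(effects) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": e.group,
                "region": e.region,
                "effect": e.effect,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n_carrier": e.n_carrier,
                "n_noncarrier": e.n_noncarrier,
                "B": e.B,
                "level": e.level,
                "significant": e.significant,
            }
            for e in effects
        ]
    )


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns output paths."""
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    region_set: RegionSet = (
        RegionSet.from_yaml(config.region_mapping)
        if config.region_mapping
        else default_region_set()
    )

    cohort = _stage("read")(read_cohort)(config.cohort_path, region_set=region_set)

    if config.screen and all(
        r.mmse is not None and r.domain_z is not None for r in cohort
    ):
        kept = _stage("screen")(cohort.subset)(
            lambda r: screen_cognitively_normal(r, config.mmse_min, config.z_cut).include
        )
        logger.info("screen: kept %d of %d records", len(kept), len(cohort))
        cohort = kept
    elif config.screen:
        logger.warning("screen skipped: cohort lacks neuropsychological columns")

    outputs: dict[str, Path] = {}

    @_stage("regress")
    def _regress():
        results = [
            fit_volume_model(cohort, region, alpha=config.alpha, m=config.m_regions)
            for region in region_set.names
        ]
        return regression_frame(results)

    @_stage("slopes")
    def _slopes():
        return group_slopes(cohort, B=config.B, level=config.level, seed=config.seed)

    @_stage("apoe")
    def _apoe():
        return group_apoe_effects(cohort, B=config.B, level=config.level, seed=config.seed)

    @_stage("norms")
    def _norms():
        from .norms import build_norms

        return build_norms(cohort).frame

    frames = {
        "regression": _regress(),
        "screened_cohort": None,
    }
    estimates = _slopes()
    frames["slopes"] = slopes_frame(estimates)
    frames["comparisons"] = comparisons_frame(estimates)
    frames["apoe_effects"] = apoe_frame(_apoe())
    frames["norms"] = _norms()

    for name, frame in frames.items():
        if frame is None:
            continue
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        outputs[name] = path
    screened_path = out_dir / "screened_cohort.csv"
    write_cohort(cohort, screened_path)
    outputs["screened_cohort"] = screened_path

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_records": len(cohort),
        "versions": _versions(),
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest"] = manifest_path
    return outputs


def _versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy

    return {
        "brainaging": __version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
    }
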