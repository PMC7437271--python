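"""Composite brain regions and their parcel composition.

The analysis works on 15 composite regions: whole brain, six cortical
lobes/areas, and eight subcortical structures.  Each composite is defined
either by an aseg header measure, a list of aseg segmentation structures,
or a list of DKT cortical parcels (summed over hemispheres).  The default
composition ships as an editable YAML resource (``data/regions.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import yaml

__all__ = ["RegionDef", "RegionSet", "default_region_set", "DKT_PARCELS"]

#: The 31 DKT cortical parcels per hemisphere.
DKT_PARCELS: frozenset[str] = frozenset(
    {
        "caudalanteriorcingulate",
        "caudalmiddlefrontal",
        "cuneus",
        "entorhinal",
        "fusiform",
        "inferiorparietal",
        "inferiortemporal",
        "isthmuscingulate",
        "lateraloccipital",
        "lateralorbitofrontal",
        "lingual",
        "medialorbitofrontal",
        "middletemporal",
        "parahippocampal",
        "paracentral",
        "parsopercularis",
        "parsorbitalis",
        "parstriangularis",
        "pericalcarine",
        "postcentral",
        "posteriorcingulate",
        "precentral",
        "precuneus",
        "rostralanteriorcingulate",
        "rostralmiddlefrontal",
        "superiorfrontal",
        "superiorparietal",
        "superiortemporal",
        "supramarginal",
        "transversetemporal",
        "insula",
    }
)


@dataclass(frozen=True)
class RegionDef:
    """How a single composite region is assembled from FreeSurfer outputs."""

    name: str
    #: aseg header measure name (e.g. ``BrainSegVolNotVent``), exclusive
    #: with the parcel lists.
    measure: str | None = None
    #: aseg segmentation structure names, summed.
    aseg: tuple[str, ...] = ()
    #: DKT parcel names, summed over left and right hemispheres.
    dkt: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        sources = sum([self.measure is not None, bool(self.aseg), bool(self.dkt)])
        if sources != 1:
            raise ValueError(
                f"region {self.name!r} must have exactly one source "
                "(measure, aseg, or dkt)"
            )


@dataclass(frozen=True)
class RegionSet:
    """Ordered collection of composite regions.

    Invariants: names are unique and the default set has exactly 15 regions.
    """

    regions: tuple[RegionDef, ...]
    _by_name: Mapping[str, RegionDef] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        object.__setattr__(self, "_by_name", {r.name: r for r in self.regions})

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __contains__(self, name: object) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> RegionDef:
        return self._by_name[name]

    def __iter__(self):
        return iter(self.regions)

    def cortical_partition_ok(self) -> bool:
        """True if no DKT parcel is claimed by more than one composite."""
        seen: set[str] = set()
        for region in self.regions:
            for parcel in region.dkt:
                if parcel in seen:
                    return False
                seen.add(parcel)
        return True

    @classmethod
    def from_mapping(cls, config: Mapping) -> "RegionSet":
        order: Sequence[str] = config["order"]
        raw = config["regions"]
        missing = [name for name in order if name not in raw]
        if missing:
            raise ValueError(f"regions listed in order but undefined: {missing}")
        defs = []
        for name in order:
            entry = raw[name]
            defs.append(
                RegionDef(
                    name=name,
                    measure=entry.get("measure"),
                    aseg=tuple(entry.get("aseg", ())),
                    dkt=tuple(entry.get("dkt", ())),
                )
            )
        return cls(regions=tuple(defs))

    @classmethod
    def from_yaml(cls, path) -> "RegionSet":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def default_region_set() -> RegionSet:
    """Load the shipped 15-region composition."""
    text = (
        resources.files("brainaging").joinpath("data/regions.yaml").read_text("utf-8")
    )
    region_set = RegionSet.from_mapping(yaml.safe_load(text))
    if len(region_set) != 15:
        raise RuntimeError("shipped region config must define exactly 15 regions")
    return region_set
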