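"""Desikan-Killiany feature naming and region-to-lobe assignment.

Brain features are named ``{hemi}_{region}_{metric}`` for the 34 cortical
regions per hemisphere (metrics: volume mm^3, thickness mm, area mm^2) and
``{hemi}_{structure}_volume`` for subcortical segmentation volumes.  The
default lobe assignment (six labels: frontal, parietal, temporal, occipital,
insular, subcortex) ships as a versioned JSON data file and can be overridden
by the user; the cingulate split between frontal and parietal is a
convention, not an anatomical necessity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

HEMISPHERES = ("lh", "rh")
CORTICAL_METRICS = ("volume", "thickness", "area")

LOBE_LABELS = ("frontal", "parietal", "temporal", "occipital", "insular", "subcortex")


def _default_map_dict() -> dict:
    with resources.files("devgap.data").joinpath("dk_lobe_map.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class RegionLobeMap:
    """Maps every brain feature column to exactly one lobe label."""

    cortical: dict = field(default_factory=dict)
    subcortical: dict = field(default_factory=dict)
    version: str = "1.0"

    @classmethod
    def default(cls) -> "RegionLobeMap":
        d = _default_map_dict()
        return cls(cortical=d["cortical"], subcortical=d["subcortical"], version=d["version"])

    @classmethod
    def from_json(cls, path) -> "RegionLobeMap":
        with open(path) as fh:
            d = json.load(fh)
        return cls(cortical=d["cortical"], subcortical=d["subcortical"],
                   version=d.get("version", "custom"))

    def feature_columns(self) -> list[str]:
        cols = []
        for hemi in HEMISPHERES:
            for region in self.cortical:
                for metric in CORTICAL_METRICS:
                    cols.append(f"{hemi}_{region}_{metric}")
        for hemi in HEMISPHERES:
            for structure in self.subcortical:
                cols.append(f"{hemi}_{structure}_volume")
        return cols

    def lobe_of(self, feature: str) -> str:
        hemi, rest = feature.split("_", 1)
        name, metric = rest.rsplit("_", 1)
        if name in self.cortical:
            return self.cortical[name]
        if name in self.subcortical:
            return self.subcortical[name]
        raise KeyError(f"feature {feature!r} is not in the region-lobe map")

    def lobes(self) -> list[str]:
        seen = dict.fromkeys(list(self.cortical.values()) + list(self.subcortical.values()))
        return list(seen)

    def features_in_lobe(self, lobe: str) -> list[str]:
        if lobe not in self.lobes():
            raise KeyError(f"unknown lobe label {lobe!r}")
        return [c for c in self.feature_columns() if self.lobe_of(c) == lobe]

    def region_of(self, feature: str) -> str:
        """Region name without hemisphere or metric (e.g. 'superiorfrontal')."""
        hemi, rest = feature.split("_", 1)
        name, _metric = rest.rsplit("_", 1)
        return name


def brain_feature_columns() -> list[str]:
    return RegionLobeMap.default().feature_columns()
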