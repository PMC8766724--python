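"""Scalp montage and region-of-interest definitions.

The recording montage is a 34-channel extended 10-20 layout. Channels are
grouped into four region clusters used for regional power and connectivity
aggregation: frontal (F), central-parietal (C), occipital (O) and temporal
(T). Two channels (F7, F8) belong to no cluster and are excluded from
region aggregates while remaining part of whole-scalp computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "MONTAGE_34",
    "REDUCED_16",
    "RegionMap",
    "default_region_map",
    "normalize_label",
]

#: The full recording montage, in acquisition channel order (channels 1-34).
MONTAGE_34: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FT7", "FC3", "FCz",
    "FC4", "FT8", "T7", "C3", "Cz", "C4", "T8", "TP7", "CP3", "CPz",
    "CP4", "TP8", "P7", "P3", "Pz", "P4", "P8", "PO3", "PO4", "O1",
    "Oz", "O2", "AF3", "AF4",
)

#: Reduced sub-montage for fast smoke-profile runs; covers all four regions.
REDUCED_16: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "Fz", "F4",
    "C3", "Cz", "C4", "Pz",
    "O1", "Oz", "O2",
    "T7", "T8", "TP7", "TP8",
)

# Older 10-20 temporal names used in some cluster listings map onto the
# modern labels actually recorded.
_NOMENCLATURE_ALIASES: dict[str, str] = {
    "T3": "T7",
    "T4": "T8",
    "T5": "P7",
    "T6": "P8",
}

_REGION_CHANNELS: dict[str, tuple[str, ...]] = {
    "F": ("Fp1", "Fp2", "F3", "Fz", "F4", "FC3", "FCz", "FC4", "AF3", "AF4"),
    "C": ("C3", "Cz", "C4", "CP3", "CPz", "CP4", "P3", "Pz", "P4"),
    "O": ("PO3", "PO4", "O1", "Oz", "O2"),
    "T": ("FT7", "FT8", "T7", "T8", "TP7", "TP8", "P7", "P8"),
}

REGION_NAMES: tuple[str, ...] = ("F", "C", "O", "T")


def normalize_label(label: str) -> str:
    """Map a channel label to the montage's canonical spelling.

    Case-insensitive; resolves legacy temporal names (T3/T4/T5/T6) to the
    recorded equivalents (T7/T8/P7/P8). Unknown labels pass through
    stripped, so non-montage channels can still be carried along.
    """
    stripped = label.strip()
    canon = {ch.lower(): ch for ch in MONTAGE_34}
    low = stripped.lower()
    if low in canon:
        return canon[low]
    alias = {k.lower(): v for k, v in _NOMENCLATURE_ALIASES.items()}
    if low in alias:
        return alias[low]
    return stripped


@dataclass(frozen=True)
class RegionMap:
    """Mapping from channel label to region label (F/C/O/T/unassigned)."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        for region in REGION_NAMES:
            if not self.channels_in(region):
                raise ValueError(f"region {region!r} has no channels")

    def region_of(self, channel: str) -> str:
        return self.mapping.get(normalize_label(channel), "unassigned")

    def channels_in(self, region: str) -> tuple[str, ...]:
        return tuple(ch for ch, r in self.mapping.items() if r == region)

    def restricted(self, channels: Iterable[str]) -> "RegionMap":
        """Region map restricted to the given channels (e.g. a sub-montage).

        Raises if any of the four regions ends up empty.
        """
        keep = {normalize_label(c) for c in channels}
        sub = {ch: r for ch, r in self.mapping.items() if ch in keep}
        return RegionMap(sub)

    @property
    def regions(self) -> tuple[str, ...]:
        return REGION_NAMES


def default_region_map() -> RegionMap:
    """Region map for the 34-channel montage.

    F has 10 channels, C 9, O 5, T 8; F7 and F8 are unassigned (they are
    recorded but belong to no cluster).
    """
    mapping: dict[str, str] = {}
    for region, channels in _REGION_CHANNELS.items():
        for ch in channels:
            mapping[ch] = region
    for ch in MONTAGE_34:
        mapping.setdefault(ch, "unassigned")
    return RegionMap(mapping)
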