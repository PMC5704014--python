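"""Study configuration: wing-sector label sets and analysis defaults.

Eyespots are indexed by wing sector (the vein-bounded field of wing tissue
they sit in).  Sector numbering differs between forewing and hindwing in
the literature, so the two eight-label sets are configuration, not
constants.  Defaults: forewing ``-1..6``, hindwing ``0..7``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

WINGS = ("fore", "hind")
SURFACES = ("dorsal", "ventral")

DEFAULT_FORE_SECTORS = tuple(str(i) for i in range(-1, 7))
DEFAULT_HIND_SECTORS = tuple(str(i) for i in range(0, 8))


@dataclass(frozen=True)
class SectorConfig:
    """Ordered sector label sets, one set of eight per wing."""

    fore: tuple[str, ...] = DEFAULT_FORE_SECTORS
    hind: tuple[str, ...] = DEFAULT_HIND_SECTORS

    def __post_init__(self) -> None:
        for wing in WINGS:
            labels = self.sectors(wing)
            if len(labels) != len(set(labels)):
                raise ValueError(f"duplicate sector labels for {wing}wing: {labels}")

    def sectors(self, wing: str) -> tuple[str, ...]:
        if wing not in WINGS:
            raise ValueError(f"unknown wing {wing!r}; expected one of {WINGS}")
        return self.fore if wing == "fore" else self.hind

    @classmethod
    def from_yaml(cls, path: str) -> "SectorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for wing in WINGS:
            if wing in raw:
                kwargs[wing] = tuple(str(s) for s in raw[wing])
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"fore": list(self.fore), "hind": list(self.hind)}, fh)


DEFAULT_SECTOR_CONFIG = SectorConfig()
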