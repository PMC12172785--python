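"""The fixed three-region vocabulary of the core face-perception network.

Every matrix in the package uses the same row/column convention:
row = target region, column = source region, in the fixed order
(OFA, FFA, STS).
"""

from __future__ import annotations

from dataclasses import dataclass, field


REGIONS: tuple[str, str, str] = ("OFA", "FFA", "STS")

OFA, FFA, STS = 0, 1, 2


@dataclass(frozen=True)
class RegionSet:
    """Ordered set of network nodes.

    The core system of face perception is modelled with exactly three
    right-hemisphere regions: the occipital face area (OFA), the fusiform
    face area (FFA) and the posterior superior temporal sulcus (STS).
    The order is fixed package-wide and shared by every coupling matrix.
    """

    labels: tuple[str, ...] = REGIONS

    def __post_init__(self) -> None:
        if len(self.labels) != 3:
            raise ValueError(f"exactly 3 regions required, got {len(self.labels)}")
        if len(set(self.labels)) != 3:
            raise ValueError("region labels must be unique")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        """0-based index of a region label."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown region {label!r}; regions are {self.labels}") from None


DEFAULT_REGIONS = RegionSet()
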