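"""Candidate network structures for the three-region face network.

A candidate model is a pattern of directed inter-regional couplings among
OFA, FFA and STS. The space is generated by three structural rules:

1. the driving input ("faces") enters at the OFA only;
2. FFA and STS must each be reachable from the OFA through the
   endogenous (A-matrix) edges, so the input can be distributed to all
   downstream regions by at least one route;
3. a backward edge onto the OFA (FFA→OFA or STS→OFA) is admitted only
   when the matching forward edge from the OFA is present.

Under these rules exactly 24 of the 2^6 possible edge sets survive.
Every admitted inter-regional edge is also open to modulation (B-matrix)
by each modulatory input; self-connections are never modulated.

Matrix convention (package-wide): entry [i, j] couples source region j
to target region i, regions ordered (OFA, FFA, STS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regions import DEFAULT_REGIONS, FFA, OFA, STS, RegionSet

#: Bit order used to index the six directed inter-regional edges, as
#: (source, target) region indices. Model ids are assigned by ascending
#: bitmask over this order, which places the fully connected model last.
EDGE_BITS: tuple[tuple[int, int], ...] = (
    (OFA, FFA),  # bit 0: OFA→FFA
    (OFA, STS),  # bit 1: OFA→STS
    (FFA, OFA),  # bit 2: FFA→OFA
    (FFA, STS),  # bit 3: FFA→STS
    (STS, OFA),  # bit 4: STS→OFA
    (STS, FFA),  # bit 5: STS→FFA
)


@dataclass(frozen=True)
class NetworkStructure:
    """Binary structure masks (A/B/C) of one candidate model.

    Attributes
    ----------
    id : int
        1-based model number within the enumerated space.
    a_mask : (3, 3) int array
        Presence of endogenous couplings; diagonal always 1
        (self-connections are always present).
    b_masks : dict[str, (3, 3) int array]
        One mask per modulatory input; off-diagonals equal the A-mask
        off-diagonals, diagonal always 0.
    c_mask : (3,) int array
        Driving-input targets; exactly one nonzero entry, at the OFA.
    """

    id: int
    a_mask: np.ndarray
    b_masks: dict[str, np.ndarray]
    c_mask: np.ndarray
    regions: RegionSet = field(default=DEFAULT_REGIONS)

    def __post_init__(self) -> None:
        a = np.asarray(self.a_mask, dtype=int)
        if a.shape != (3, 3):
            raise ValueError("a_mask must be 3x3")
        if not np.all(np.diag(a) == 1):
            raise ValueError("a_mask diagonal must be all 1 (self-connections always present)")
        c = np.asarray(self.c_mask, dtype=int)
        if c.shape != (3,):
            raise ValueError("c_mask must be length 3")
        for name, b in self.b_masks.items():
            b = np.asarray(b, dtype=int)
            if np.any(np.diag(b) != 0):
                raise ValueError(f"b_mask[{name!r}] diagonal must be 0 (self-connections not modulated)")
            off = ~np.eye(3, dtype=bool)
            if np.any(b[off] & ~a[off]):
                raise ValueError(f"b_mask[{name!r}] must be a subset of a_mask off-diagonals")
        object.__setattr__(self, "a_mask", a)
        object.__setattr__(self, "c_mask", c)
        object.__setattr__(self, "b_masks", {k: np.asarray(v, dtype=int) for k, v in self.b_masks.items()})

    @property
    def edge_bitmask(self) -> int:
        """Bitmask of present inter-regional A-edges over :data:`EDGE_BITS`."""
        mask = 0
        for bit, (src, tgt) in enumerate(EDGE_BITS):
            if self.a_mask[tgt, src]:
                mask |= 1 << bit
        return mask

    @property
    def n_edges(self) -> int:
        return int(bin(self.edge_bitmask).count("1"))

    def to_dict(self) -> dict:
        """JSON-serializable representation (masks row-major, row = target)."""
        return {
            "id": self.id,
            "regions": list(self.regions.labels),
            "a_mask": self.a_mask.tolist(),
            "b_masks": {k: v.tolist() for k, v in self.b_masks.items()},
            "c_mask": self.c_mask.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkStructure":
        return cls(
            id=int(d["id"]),
            a_mask=np.asarray(d["a_mask"], dtype=int),
            b_masks={k: np.asarray(v, dtype=int) for k, v in d["b_masks"].items()},
            c_mask=np.asarray(d["c_mask"], dtype=int),
            regions=RegionSet(tuple(d.get("regions", DEFAULT_REGIONS.labels))),
        )


@dataclass(frozen=True)
class ModelSpace:
    """Ordered collection of candidate structures sharing one modulator set."""

    structures: tuple[NetworkStructure, ...]
    modulator_names: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.structures]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("structure ids must be unique and consecutive from 1")

    def __len__(self) -> int:
        return len(self.structures)

    def __getitem__(self, model_id: int) -> NetworkStructure:
        """Structure by 1-based model id."""
        s = self.structures[model_id - 1]
        assert s.id == model_id
        return s

    @property
    def full_model(self) -> NetworkStructure:
        """The fully interconnected structure (all 6 inter-regional edges)."""
        return self.structures[-1]

    @property
    def forward_only_model(self) -> NetworkStructure:
        """The structure with edges exactly {OFA→FFA, OFA→STS}."""
        want = 0b000011
        for s in self.structures:
            if s.edge_bitmask == want:
                return s
        raise LookupError("forward-only structure absent from space")


def _admissible(bitmask: int) -> bool:
    """Structural rules over one edge subset (see module docstring)."""
    e = [(bitmask >> bit) & 1 for bit in range(6)]
    ofa_ffa, ofa_sts, ffa_ofa, ffa_sts, sts_ofa, sts_ffa = e
    # backward edges onto OFA need the matching forward edge
    if ffa_ofa and not ofa_ffa:
        return False
    if sts_ofa and not ofa_sts:
        return False
    # FFA and STS reachable from OFA
    ffa_reached = ofa_ffa or (ofa_sts and sts_ffa)
    sts_reached = ofa_sts or (ofa_ffa and ffa_sts)
    return bool(ffa_reached and sts_reached)


def _structure_from_bitmask(model_id: int, bitmask: int, modulators: tuple[str, ...]) -> NetworkStructure:
    a = np.eye(3, dtype=int)
    for bit, (src, tgt) in enumerate(EDGE_BITS):
        if (bitmask >> bit) & 1:
            a[tgt, src] = 1
    b_off = a.copy()
    np.fill_diagonal(b_off, 0)
    c = np.zeros(3, dtype=int)
    c[OFA] = 1
    return NetworkStructure(
        id=model_id,
        a_mask=a,
        b_masks={m: b_off.copy() for m in modulators},
        c_mask=c,
    )


def enumerate_model_space(modulators: list[str] | tuple[str, ...] = ("faces",)) -> ModelSpace:
    """Enumerate every admissible candidate structure.

    Parameters
    ----------
    modulators : sequence of str
        Modulatory input labels; the first must be the driving/modulating
        input ``"faces"``. Each modulator is allowed to act on every
        admitted inter-regional edge of each structure.

    Returns
    -------
    ModelSpace
        Structures sorted by ascending edge-set bitmask (deterministic;
        the fully connected model is last, id 24 for the default rules).

    Notes
    -----
    Model ids here are a deterministic package convention; they need not
    match any published figure numbering, except that the fully
    interconnected model is always the last (#24).
    """
    modulators = tuple(modulators)
    if not modulators:
        raise ValueError("modulators must be non-empty")
    if modulators[0] != "faces":
        raise ValueError('first modulator must be the driving input "faces"')
    masks = [m for m in range(64) if _admissible(m)]
    masks.sort()
    structures = tuple(
        _structure_from_bitmask(i + 1, m, modulators) for i, m in enumerate(masks)
    )
    return ModelSpace(structures=structures, modulator_names=modulators)


def structure_to_edge_list(structure: NetworkStructure) -> list[tuple[str, str, str]]:
    """Lossless, order-stable listing of a structure's entries.

    Returns tuples ``(source_label, target_label, tag)`` where tag is
    ``"A"``, ``"B:<input>"`` or ``"C:<input>"``. A-entries cover the
    off-diagonal mask only (self-connections are implicit: always present).
    """
    labels = structure.regions.labels
    edges: list[tuple[str, str, str]] = []
    for src, tgt in EDGE_BITS:
        if structure.a_mask[tgt, src]:
            edges.append((labels[src], labels[tgt], "A"))
    for name, b in structure.b_masks.items():
        for src, tgt in EDGE_BITS:
            if b[tgt, src]:
                edges.append((labels[src], labels[tgt], f"B:{name}"))
    for tgt in range(3):
        if structure.c_mask[tgt]:
            edges.append(("input", labels[tgt], "C:faces"))
    return edges


def structure_from_edge_list(
    edges: list[tuple[str, str, str]],
    model_id: int = 0,
    regions: RegionSet = DEFAULT_REGIONS,
) -> NetworkStructure:
    """Inverse of :func:`structure_to_edge_list` (round-trip identity)."""
    a = np.eye(3, dtype=int)
    b_masks: dict[str, np.ndarray] = {}
    c = np.zeros(3, dtype=int)
    for src_label, tgt_label, tag in edges:
        tgt = regions.index_of(tgt_label)
        if tag == "A":
            a[tgt, regions.index_of(src_label)] = 1
        elif tag.startswith("B:"):
            name = tag[2:]
            b_masks.setdefault(name, np.zeros((3, 3), dtype=int))
            b_masks[name][tgt, regions.index_of(src_label)] = 1
        elif tag.startswith("C:"):
            c[tgt] = 1
        else:
            raise ValueError(f"unknown edge tag {tag!r}")
    return NetworkStructure(id=model_id, a_mask=a, b_masks=b_masks, c_mask=c, regions=regions)
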