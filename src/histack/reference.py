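"""Reference histone definition and the inter-dimer stacking-pair catalog.

All scoring in this package is expressed in 1-based HMfB numbering (Histone B
of *Methanothermus fervidus*), the conventional coordinate system for archaeal
histone-fold comparisons.  The bundled reference carries the annotated
functional position sets that the assessment rules consult:

* DNA-anchor arginines (10, 19) that dock the dimer into DNA minor grooves,
* the hydrophobic dimerization core (24, 28, 32, 39, 43),
* the intramolecular fold salt bridge (52-59),
* the dimer-dimer (tetramerization) interface (46, 49, 59, 62),
* the stacking-interface loop (15-17, pivotal glycine 16).

The stacking-pair catalog lists candidate position pairs through which a dimer
*i* can hydrogen-bond or salt-bridge to dimers *i*+2 / *i*+3 in the adjacent
superhelical turn of a hypernucleosome.  It is shipped as editable TSV data:
the pairs were derived from structural superposition onto the stacked-dimer
crystal arrangement, so users with structures can regenerate or extend it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ReferenceHistone",
    "StackingPairEntry",
    "StackingPairCatalog",
    "GeometryParams",
    "load_reference",
    "default_catalog",
    "default_geometry_params",
]

_DATA = resources.files("histack") / "data"


class ReferenceValidationError(ValueError):
    """Raised when a reference definition or catalog fails validation."""


@dataclass(frozen=True)
class ReferenceHistone:
    """HMfB-style numbering scaffold with annotated functional positions."""

    name: str
    length: int
    sequence: str | None = None
    helix_bounds: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    dna_anchor_positions: frozenset[int] = frozenset()
    hydrophobic_core_positions: frozenset[int] = frozenset()
    fold_salt_bridge: tuple[int, int] = (0, 0)
    dimer_interface_positions: frozenset[int] = frozenset()
    stacking_interface_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ReferenceValidationError(f"length must be positive, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ReferenceValidationError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )
        for pos in self._all_annotated_positions():
            if not 1 <= pos <= self.length:
                raise ReferenceValidationError(
                    f"annotated position {pos} outside [1, {self.length}]"
                )
        bounds = [tuple(b) for b in self.helix_bounds.values()]
        for lo, hi in bounds:
            if lo > hi:
                raise ReferenceValidationError(f"helix range {lo}-{hi} reversed")
        for (_, hi), (lo2, _) in zip(sorted(bounds), sorted(bounds)[1:]):
            if lo2 <= hi:
                raise ReferenceValidationError("helix ranges overlap or are unordered")
        if self.dimer_interface_positions & self.stacking_interface_positions:
            raise ReferenceValidationError(
                "dimer-interface and stacking-interface positions must be disjoint"
            )

    def _all_annotated_positions(self) -> Iterable[int]:
        yield from self.dna_anchor_positions
        yield from self.hydrophobic_core_positions
        yield from self.fold_salt_bridge
        yield from self.dimer_interface_positions
        yield from self.stacking_interface_positions
        for lo, hi in self.helix_bounds.values():
            yield lo
            yield hi


@dataclass(frozen=True)
class StackingPairEntry:
    """One candidate inter-dimer contact: an unordered reference position pair.

    ``layer_offset`` records whether the contact belongs to the *i*+2 or *i*+3
    layer interface when known ("unknown" for all bundled entries).
    ``backbone_allowed`` permits a backbone-carbonyl acceptor at either
    position, so a pair can still score when one side chain is apolar.
    """

    pos_a: int
    pos_b: int
    layer_offset: str = "unknown"
    backbone_allowed: bool = False
    uncertain: bool = False

    def __post_init__(self) -> None:
        if self.pos_a > self.pos_b:
            a, b = self.pos_b, self.pos_a
            object.__setattr__(self, "pos_a", a)
            object.__setattr__(self, "pos_b", b)
        if self.layer_offset not in ("2", "3", "unknown"):
            raise ReferenceValidationError(f"bad layer_offset {self.layer_offset!r}")

    @property
    def positions(self) -> tuple[int, int]:
        return (self.pos_a, self.pos_b)


@dataclass(frozen=True)
class StackingPairCatalog:
    entries: tuple[StackingPairEntry, ...]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.pos_a, e.pos_b, e.layer_offset)
            if key in seen:
                raise ReferenceValidationError(f"duplicate catalog entry {key}")
            seen.add(key)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def position_pairs(self) -> set[tuple[int, int]]:
        return {e.positions for e in self.entries}

    def positions(self) -> set[int]:
        return {p for e in self.entries for p in e.positions}

    def validate_against(self, reference: ReferenceHistone) -> None:
        for e in self.entries:
            if e.pos_b > reference.length:
                raise ReferenceValidationError(
                    f"catalog position {e.pos_b} exceeds reference length {reference.length}"
                )


@dataclass(frozen=True)
class GeometryParams:
    """Coarse geometry of the idealized superhelical rod (lengths in nm)."""

    bp_per_dimer: float
    rise_per_dimer: float
    bp_rise: float = 0.34
    superhelix_radius: float = 3.25
    dimers_per_turn: float = 3.0

    def __post_init__(self) -> None:
        for name in ("bp_per_dimer", "rise_per_dimer", "bp_rise", "superhelix_radius", "dimers_per_turn"):
            if getattr(self, name) <= 0:
                raise ReferenceValidationError(f"{name} must be strictly positive")


def _as_range(value) -> tuple[int, int]:
    lo, hi = value
    return int(lo), int(hi)


def load_reference(config_source: str | Path | Mapping | None = None) -> ReferenceHistone:
    """Load a reference definition from YAML (path or mapping).

    With no argument, returns the bundled HMfB definition.
    """
    if config_source is None:
        cfg = yaml.safe_load((_DATA / "hmfb_reference.yaml").read_text())
    elif isinstance(config_source, Mapping):
        cfg = dict(config_source)
    else:
        cfg = yaml.safe_load(Path(config_source).read_text())
    try:
        return ReferenceHistone(
            name=cfg["name"],
            length=int(cfg["length"]),
            sequence=cfg.get("sequence"),
            helix_bounds={k: _as_range(v) for k, v in cfg.get("helix_bounds", {}).items()},
            dna_anchor_positions=frozenset(cfg.get("dna_anchor_positions", ())),
            hydrophobic_core_positions=frozenset(cfg.get("hydrophobic_core_positions", ())),
            fold_salt_bridge=tuple(cfg.get("fold_salt_bridge", (0, 0))),
            dimer_interface_positions=frozenset(cfg.get("dimer_interface_positions", ())),
            stacking_interface_positions=frozenset(cfg.get("stacking_interface_positions", ())),
        )
    except KeyError as exc:  # missing mandatory key
        raise ReferenceValidationError(f"reference config missing key {exc}") from exc


def _parse_bool(token: str) -> bool:
    return token.strip().lower() in ("true", "1", "yes")


def load_catalog(source: str | Path | None = None) -> StackingPairCatalog:
    """Read a stacking-pair catalog from TSV (bundled file when source is None)."""
    text = (
        (_DATA / "stacking_catalog.tsv").read_text()
        if source is None
        else Path(source).read_text()
    )
    entries = []
    header: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        entries.append(
            StackingPairEntry(
                pos_a=int(row["pos_a"]),
                pos_b=int(row["pos_b"]),
                layer_offset=row.get("layer_offset", "unknown"),
                backbone_allowed=_parse_bool(row.get("backbone_allowed", "false")),
                uncertain=_parse_bool(row.get("uncertain", "false")),
            )
        )
    return StackingPairCatalog(entries=tuple(entries))


def default_catalog() -> StackingPairCatalog:
    """The bundled catalog of candidate inter-dimer contact position pairs."""
    return load_catalog(None)


def default_geometry_params() -> GeometryParams:
    """Bundled idealized-rod geometry (30 bp and 1.02 nm axial rise per dimer)."""
    cfg = yaml.safe_load((_DATA / "geometry_defaults.yaml").read_text())
    return GeometryParams(**cfg)
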