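"""Core data types for tracked mother-machine lineages.

A *mother machine* traps the cell inheriting the old pole at the closed end
of each growth well; its new-pole sibling (the daughter) is followed for a
single cell cycle before being washed out.  Every analysis in this package
starts from a :class:`LineageTable` of :class:`CellCycleRecord` objects --
one record per tracked cell cycle, from an observed birth to the next
observed division -- together with a 1D fluorescence transect sampled on
the first fluorescence frame of the cycle.

Times are minutes since the first captured frame (minute 0); pixel spans
are 0-based half-open ``[start, end)`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "TransectProfile",
    "CellCycleRecord",
    "DivisionPair",
    "LineageTable",
    "PairingResult",
    "PairingConflictError",
    "filter_complete_cycles",
    "pair_divisions",
]


class Role(str, Enum):
    """Pole identity of a tracked cell: old-pole mother or new-pole daughter."""

    MOTHER = "mother"
    DAUGHTER = "daughter"


class PairingConflictError(ValueError):
    """Two records claim the same sibling at one fission event."""


@dataclass
class TransectProfile:
    """Pixel-by-pixel fluorescence profile along the cell's long axis.

    Index 0 is the old pole; the last pixel is the new pole.  Intensities
    are arbitrary units (a.u.), non-negative.
    """

    intensities: np.ndarray
    pixel_size: float  # µm per pixel
    cell_length: float  # µm

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ValueError("transect intensities must be one-dimensional")
        if np.any(self.intensities < 0):
            raise ValueError("transect intensities must be non-negative")
        if self.pixel_size <= 0 or self.cell_length <= 0:
            raise ValueError("pixel_size and cell_length must be positive")

    @property
    def n_pixels(self) -> int:
        return int(self.intensities.size)

    def reversed(self) -> "TransectProfile":
        """Profile with the pole orientation flipped (new pole at index 0)."""
        return TransectProfile(self.intensities[::-1].copy(), self.pixel_size, self.cell_length)


@dataclass
class CellCycleRecord:
    """One tracked cell from its birth to its next division.

    ``division_time`` is ``None`` when the cycle was not captured to
    completion (e.g. truncated by the end of imaging or washed out);
    such records are removed by :func:`filter_complete_cycles`.
    """

    lineage_id: str
    well_id: str
    role: Role
    generation: int
    birth_time: float  # minutes since imaging start
    division_time: Optional[float]
    length_series: List[Tuple[float, float]]  # (time min, length µm)
    width: float  # µm
    cycle_id: str = ""
    sibling_id: Optional[str] = None
    transect: Optional[TransectProfile] = None

    def __post_init__(self) -> None:
        if isinstance(self.role, str):
            self.role = Role(self.role)
        if self.generation < 1:
            raise ValueError("generation index starts at 1")
        if self.division_time is not None and self.division_time <= self.birth_time:
            raise ValueError("division_time must exceed birth_time")
        times = [t for t, _ in self.length_series]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("length_series times must be strictly increasing")
        if any(length <= 0 for _, length in self.length_series):
            raise ValueError("all lengths must be positive")
        if self.width <= 0:
            raise ValueError("cell width must be positive")
        if not self.cycle_id:
            self.cycle_id = f"{self.lineage_id}:{self.role.value}:g{self.generation}"

    @property
    def birth_length(self) -> float:
        """First observed length of the cycle (µm)."""
        if not self.length_series:
            raise ValueError("record has no length observations")
        return self.length_series[0][1]

    @property
    def is_complete(self) -> bool:
        return self.division_time is not None

    @property
    def has_transect(self) -> bool:
        return self.transect is not None


@dataclass
class DivisionPair:
    """Mother and daughter cycle records born at the same fission."""

    mother: CellCycleRecord
    daughter: CellCycleRecord

    def __post_init__(self) -> None:
        if self.mother.role is not Role.MOTHER or self.daughter.role is not Role.DAUGHTER:
            raise ValueError("pair must consist of one mother and one daughter record")
        if not np.isclose(self.mother.birth_time, self.daughter.birth_time):
            raise ValueError("paired records must share a birth time (same fission)")

    @property
    def asymmetry(self) -> float:
        """Birth-length ratio A = L0_mother / L0_daughter (>1: off-center fission)."""
        from .growth import asymmetry_ratio

        return asymmetry_ratio(self)


class PairingResult(List[DivisionPair]):
    """List of division pairs; ``n_unpaired`` counts omitted singleton records."""

    def __init__(self, pairs: Iterable[DivisionPair] = (), n_unpaired: int = 0):
        super().__init__(pairs)
        self.n_unpaired = n_unpaired


@dataclass
class LineageTable:
    """Collection of cell-cycle records plus a log of filtered counts."""

    records: List[CellCycleRecord] = field(default_factory=list)
    filter_log: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_role(self, role: Role | str) -> List[CellCycleRecord]:
        role = Role(role)
        return [r for r in self.records if r.role is role]

    def to_frame(self) -> pd.DataFrame:
        """One row per cycle with the scalar fields (no series/transects)."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "cycle_id": r.cycle_id,
                    "lineage_id": r.lineage_id,
                    "well_id": r.well_id,
                    "role": r.role.value,
                    "generation": r.generation,
                    "birth_time_min": r.birth_time,
                    "division_time_min": r.division_time,
                    "birth_length_um": r.birth_length if r.length_series else np.nan,
                    "width_um": r.width,
                    "sibling_id": r.sibling_id,
                }
            )
        return pd.DataFrame(rows)


def filter_complete_cycles(table: LineageTable) -> LineageTable:
    """Keep only cycles with an observed birth and an observed next division.

    Two exclusion rules apply: cycles whose next division was not captured
    (``division_time`` absent) and cycles that began before imaging started
    (negative birth time).  Removed counts are recorded per rule in the
    returned table's ``filter_log``; the operation is idempotent and the
    log counts plus survivors always sum to the input count.
    """
    kept: List[CellCycleRecord] = []
    log = {"incomplete": 0, "pre_imaging": 0}
    for rec in table.records:
        if rec.birth_time < 0:
            log["pre_imaging"] += 1
        elif not rec.is_complete:
            log["incomplete"] += 1
        else:
            kept.append(rec)
    return LineageTable(records=kept, filter_log=log)


def pair_divisions(table: LineageTable) -> PairingResult:
    """Match mother and daughter records born at the same fission.

    Matching uses ``sibling_id`` as populated by tracking or simulation.
    Records whose sibling is absent from the table (e.g. a daughter washed
    out before its first fluorescence frame) are omitted and counted in
    ``PairingResult.n_unpaired``.  A sibling claimed by two records raises
    :class:`PairingConflictError`.
    """
    by_id: Dict[str, CellCycleRecord] = {}
    for rec in table.records:
        if rec.cycle_id in by_id:
            raise PairingConflictError(f"duplicate cycle_id {rec.cycle_id!r}")
        by_id[rec.cycle_id] = rec

    claimed: Dict[str, str] = {}  # sibling_id -> claiming cycle_id
    pairs: List[DivisionPair] = []
    n_unpaired = 0
    for rec in table.records:
        if rec.role is not Role.MOTHER:
            continue
        sib = rec.sibling_id
        if sib is None or sib not in by_id:
            n_unpaired += 1
            continue
        if sib in claimed:
            raise PairingConflictError(
                f"records {claimed[sib]!r} and {rec.cycle_id!r} both claim sibling {sib!r}"
            )
        other = by_id[sib]
        if other.sibling_id is not None and other.sibling_id != rec.cycle_id:
            raise PairingConflictError(
                f"sibling link {rec.cycle_id!r} -> {sib!r} is not reciprocal"
            )
        claimed[sib] = rec.cycle_id
        pairs.append(DivisionPair(mother=rec, daughter=other))
    # daughters whose mother record is missing are unpaired too
    paired_daughters = set(claimed)
    for rec in table.records:
        if rec.role is Role.DAUGHTER and rec.cycle_id not in paired_daughters:
            n_unpaired += 1
    return PairingResult(pairs, n_unpaired=n_unpaired)
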