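"""Core value types shared across the PKT screening toolkit.

The phagokinetic-track (PKT) assay quantifies cell migration from the
bead-free track a cell clears while crawling over a latex-bead lawn.
These dataclasses carry the domain vocabulary: per-track morphometry,
plate layouts with their replicate structure, motility parameters for
the simulators, and the result records of the downstream statistics.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

__all__ = [
    "MotilityParams",
    "Treatment",
    "PlateLayout",
    "TrackFeatures",
    "WellRecord",
    "Trajectory",
    "MigrationStats",
    "PhenotypeCall",
    "DeconvolutionResult",
    "CellMorphology",
    "well_ids_96",
    "FEATURE_COLUMNS",
    "PARAMETERS",
]

#: Track-level feature-table schema (CSV column order).
FEATURE_COLUMNS = [
    "plate_id", "well_id", "track_id",
    "net_area", "gross_area", "major_axis", "minor_axis",
    "axial_ratio", "roughness", "perimeter", "solidity",
    "n_cells_in_track",
]

#: The eight morphometric parameters quantified per track.
PARAMETERS = [
    "net_area", "gross_area", "major_axis", "minor_axis",
    "axial_ratio", "roughness", "perimeter", "solidity",
]


def well_ids_96() -> list[str]:
    """Row-major well identifiers of a 96-well plate (A1..H12)."""
    return [f"{r}{c}" for r in string.ascii_uppercase[:8] for c in range(1, 13)]


_WELL_SET = frozenset(well_ids_96())


@dataclass(frozen=True)
class MotilityParams:
    """Ground-truth motility parameters of one simulated cell/condition.

    speed            root speed of the persistent random walk, um/min (>= 0;
                     zero gives a stationary cell).
    persistence_time directional correlation time, min (0 = uncorrelated
                     steps; ``math.inf`` = ballistic).
    track_width      width of the bead-free swath the cell clears, um.
    duration         assay duration, min (PKT plates are fixed after 7 h).
    turn_noise       extra per-step angular jitter (rad, dimensionless wrt
                     dt); 0 by default.
    protrusiveness   boundary-roughness control for rendered tracks (>= 0).
    """

    speed: float
    persistence_time: float = 30.0
    track_width: float = 15.0
    duration: float = 420.0
    turn_noise: float = 0.0
    protrusiveness: float = 0.0

    def __post_init__(self) -> None:
        if not (self.speed >= 0) or not np.isfinite(self.speed):
            raise ValueError(f"speed must be finite and >= 0, got {self.speed}")
        if not (self.persistence_time >= 0):
            raise ValueError("persistence_time must be >= 0")
        if not (self.track_width > 0):
            raise ValueError("track_width must be > 0")
        if not (self.duration > 0):
            raise ValueError("duration must be > 0")
        if not (self.turn_noise >= 0):
            raise ValueError("turn_noise must be >= 0")
        if not (self.protrusiveness >= 0):
            raise ValueError("protrusiveness must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "MotilityParams":
        return cls(**{k: float(v) for k, v in d.items()})


#: siRNA reagent kinds appearing on a plate.
SIRNA_KINDS = ("smartpool", "single_1", "single_2", "single_3", "single_4",
               "mock", "control")


@dataclass(frozen=True)
class Treatment:
    """What went into a well: a gene reagent or a control."""

    name: str
    kind: str = "smartpool"

    def __post_init__(self) -> None:
        if self.kind not in SIRNA_KINDS:
            raise ValueError(f"unknown siRNA kind {self.kind!r}")

    @property
    def is_mock(self) -> bool:
        return self.kind == "mock"


@dataclass
class PlateLayout:
    """96-well plate layout with replicate annotation.

    Every plate must carry at least two mock (transfection-reagent-only)
    wells: they define the null migratory phenotype used for robust-Z
    normalization.
    """

    plate_id: str
    wells: dict[str, Treatment]
    replicate: tuple[int, int] = (1, 1)  # (technical, biological)
    cell_line: str = "Hs578T"

    def __post_init__(self) -> None:
        bad = sorted(set(self.wells) - _WELL_SET)
        if bad:
            raise ValueError(f"invalid 96-well ids: {bad}")
        if len(self.mock_wells) < 2:
            raise ValueError(
                f"plate {self.plate_id!r} has {len(self.mock_wells)} mock "
                "wells; at least 2 are required"
            )
        t, b = self.replicate
        if t not in (1, 2) or b not in (1, 2):
            raise ValueError("replicate indices must be 1 or 2")

    @property
    def mock_wells(self) -> list[str]:
        return [w for w, t in self.wells.items() if t.is_mock]

    def treatment(self, well_id: str) -> Treatment:
        return self.wells[well_id]


@dataclass(frozen=True)
class TrackFeatures:
    """Eight morphometric parameters of one accepted migratory track.

    Units are quantifier-native pixels; invariants: net_area <= gross_area,
    axial_ratio >= 1, 0 < solidity <= 1, roughness >= 1.
    """

    net_area: float
    gross_area: float
    major_axis: float
    minor_axis: float
    axial_ratio: float
    roughness: float
    perimeter: float
    solidity: float

    def __post_init__(self) -> None:
        if self.net_area <= 0:
            raise ValueError("net_area must be > 0")
        if self.net_area > self.gross_area * (1 + 1e-9):
            raise ValueError("net_area must not exceed gross_area")
        if self.axial_ratio < 1 - 1e-9:
            raise ValueError("axial_ratio must be >= 1")
        if not (0 < self.solidity <= 1 + 1e-9):
            raise ValueError("solidity must be in (0, 1]")
        if self.roughness < 1 - 1e-6:
            raise ValueError("roughness must be >= 1")

    def as_row(self) -> dict:
        return asdict(self)


@dataclass
class WellRecord:
    """Quantification result of one well: accepted tracks plus QC context."""

    plate_id: str
    well_id: str
    tracks: list[TrackFeatures] = field(default_factory=list)
    n_rejected: int = 0
    n_images: int = 36
    treatment: Treatment | None = None
    qc_warnings: list[str] = field(default_factory=list)

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)


@dataclass
class Trajectory:
    """Time-stamped single-cell path from overlap tracking.

    ``samples`` is an (n, 3) float array of (t_min, x_um, y_um) with
    strictly increasing, evenly spaced timestamps.
    """

    cell_id: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array of (t, x, y)")
        if self.samples.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        dt = np.diff(self.samples[:, 0])
        if not np.all(dt > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.allclose(dt, dt[0]):
            raise ValueError("timestamps must be evenly spaced")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return float(self.samples[-1, 0] - self.samples[0, 0])

    @property
    def dt(self) -> float:
        return float(self.samples[1, 0] - self.samples[0, 0])


@dataclass(frozen=True)
class MigrationStats:
    """Per-cell migration summary.

    speed is the mean frame-to-frame displacement divided by the frame
    interval (um/min); directionality = net displacement / path length,
    reported as 0 for a stationary cell.
    """

    cell_id: int
    speed: float
    displacement: float
    path_length: float
    directionality: float
    duration: float
    n_samples: int


PHENOTYPE_CLASSES = ("small", "small_round", "big_round",
                     "long_rough", "long_smooth")


@dataclass(frozen=True)
class PhenotypeCall:
    """Migratory phenotype assignment for one aggregated knockdown."""

    primary_class: str
    all_matching_classes: frozenset[str]
    thresholds_version: str

    def __post_init__(self) -> None:
        ok = set(PHENOTYPE_CLASSES) | {"unclassified"}
        if self.primary_class not in ok:
            raise ValueError(f"unknown phenotype class {self.primary_class!r}")
        if self.primary_class != "unclassified" and \
                self.primary_class not in self.all_matching_classes:
            raise ValueError("primary class must be among matching classes")


@dataclass
class DeconvolutionResult:
    """Outcome of the SMARTpool vs four-single-siRNA validation rule."""

    gene: str
    pool_z: dict[str, float]
    single_z: list[dict[str, float] | None]
    n_significant_singles: int
    valid: bool
    missing_singles: int = 0


@dataclass(frozen=True)
class CellMorphology:
    """Single-cell morphology record (CellProfiler-style size/shape)."""

    cell_id: int
    area: float
    perimeter: float
    form_factor: float
    spike_count: int
    nucleus_area: float
    has_cell_body: bool

    def __post_init__(self) -> None:
        if self.has_cell_body and not (0 < self.form_factor <= 1 + 1e-9):
            raise ValueError("form factor must be in (0, 1]")
        if self.spike_count < 0:
            raise ValueError("spike count must be >= 0")
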