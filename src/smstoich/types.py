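"""Shared dataclasses carried between pipeline stages.

Coordinates are 0-based pixel indices; a spot "position" is the continuous
centre of mass with pixel (0, 0) spanning [0, 1) x [0, 1).  Positions are
stored as (x, y) = (column, row).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError


@dataclass
class ChannelTransform:
    """Affine map from channel-A (client) coordinates to channel-B (sHsp)
    coordinates, estimated from fiducial-bead image pairs.

    ``matrix`` is 2x3: ``[x_b, y_b]^T = A @ [x_a, y_a]^T + t`` with
    ``A = matrix[:, :2]`` and ``t = matrix[:, 2]``.
    """

    matrix: np.ndarray
    residual_rms_px: float = 0.0
    n_beads: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise InvalidParameterError(
                f"transform matrix must be 2x3, got {self.matrix.shape}"
            )
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise InvalidParameterError("transform linear part is singular")
        if self.residual_rms_px < 0:
            raise InvalidParameterError("residual RMS must be >= 0")

    @classmethod
    def identity(cls) -> "ChannelTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "ChannelTransform":
        return cls(np.array([[1.0, 0.0, dx], [0.0, 1.0, dy]]))

    @classmethod
    def rotation(cls, angle_deg: float, centre: tuple[float, float]) -> "ChannelTransform":
        """Pure rotation by ``angle_deg`` about ``centre`` (x, y)."""
        th = np.deg2rad(angle_deg)
        c, s = np.cos(th), np.sin(th)
        cx, cy = centre
        rot = np.array([[c, -s], [s, c]])
        t = np.array([cx, cy]) - rot @ np.array([cx, cy])
        return cls(np.column_stack([rot, t]))

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Map (n, 2) channel-A points into channel-B coordinates."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return xy @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "ChannelTransform":
        lin = np.linalg.inv(self.matrix[:, :2])
        t = -lin @ self.matrix[:, 2]
        return ChannelTransform(
            np.column_stack([lin, t]), self.residual_rms_px, self.n_beads
        )


@dataclass
class Spot:
    """A detected fluorescent molecule in one channel of one field."""

    x: float
    y: float
    channel: str
    field_id: str = ""
    peak_intensity: float = 0.0
    detect_frames: tuple[int, int] = (0, 10)
    index: int = -1

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class Trajectory:
    """Background-corrected intensity versus frame for one spot."""

    intensity: np.ndarray
    frame_interval_s: float = 0.5
    channel: str = ""
    spot: Spot | None = None
    timepoint_h: float | None = None
    replicate: str | None = None
    bleach_frame_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1 or self.intensity.size < 1:
            raise InvalidParameterError("trajectory must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.intensity)):
            raise InvalidParameterError("trajectory contains non-finite values")

    def __len__(self) -> int:
        return self.intensity.size


@dataclass
class StepFit:
    """Change-point segmentation of a photobleaching trajectory."""

    changepoints: np.ndarray            # sorted frame indices, each in (0, n)
    segment_means: np.ndarray           # one per segment (= n_cp + 1)
    step_sizes: np.ndarray              # consecutive mean differences (drops)
    final_step: float | None            # magnitude of the last bleach step
    score: float = 0.0                  # penalised residual cost of the fit
    label: str = "stepwise"             # {"stepwise", "reject"}
    incomplete_bleach: bool = False     # no terminal baseline segment
    no_steps: bool = False              # zero change points
    trajectory: Trajectory | None = None

    @property
    def n_steps(self) -> int:
        return int(len(self.changepoints))


@dataclass
class MoleculeSize:
    """Per-molecule subunit estimate from I_initial / I_step."""

    i_initial: float
    i_step: float
    subunits_raw: float
    fluors_per_monomer: float = 1.0
    subunits_corrected: float | None = None
    subunits_int: int | None = None
    channel: str = ""
    spot_index: int = -1

    def __post_init__(self) -> None:
        if self.subunits_corrected is None:
            self.subunits_corrected = self.subunits_raw / self.fluors_per_monomer
        if self.subunits_int is None:
            # round half-up, floored at 1: any accepted molecule has >= 1 subunit
            self.subunits_int = max(1, int(np.floor(self.subunits_corrected + 0.5)))


@dataclass
class ComplexRecord:
    """A client molecule, optionally joined with its colocalised sHsp."""

    timepoint_h: float
    replicate: str
    client_subunits: float
    shsp_subunits: float | None = None
    colocalised: bool = False
    pair_distance_px: float | None = None

    @property
    def molar_ratio(self) -> float | None:
        """sHsp:client subunit ratio; defined only for colocalised records."""
        if not self.colocalised or self.shsp_subunits is None:
            return None
        if self.client_subunits <= 0:
            return None
        return self.shsp_subunits / self.client_subunits


@dataclass
class TrueStep:
    """Ground truth for one fluorophore in a simulated trajectory."""

    bleach_frame: int
    height: float


@dataclass
class TrueMolecule:
    """Simulator ground truth for one molecule (client or sHsp)."""

    molecule_id: int
    channel: str
    subunits: int
    n_fluorophores: int
    complex_id: int | None = None
    position: tuple[float, float] | None = None   # channel-A frame of reference
    steps: list[TrueStep] = field(default_factory=list)


@dataclass
class GroundTruthManifest:
    """Complete simulator truth for one rendered field."""

    molecules: list[TrueMolecule]
    transform: ChannelTransform
    seed: int
    params: dict = field(default_factory=dict)
    separation_violations: int = 0

    def positions(self, channel: str) -> np.ndarray:
        """True (x, y) positions for one channel, in that channel's frame."""
        pos = np.array(
            [m.position for m in self.molecules if m.channel == channel and m.position is not None]
        ).reshape(-1, 2)
        if channel != "client" and len(pos):
            pos = self.transform.apply(pos)
        return pos

    @property
    def total_fluorophores(self) -> int:
        return sum(m.n_fluorophores for m in self.molecules)


def as_xy_array(spots: Sequence[Spot]) -> np.ndarray:
    """Stack spot centres into an (n, 2) array of (x, y)."""
    if len(spots) == 0:
        return np.empty((0, 2))
    return np.array([[s.x, s.y] for s in spots])
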