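"""Run configuration: every stage parameter with its pipeline default, plus
deterministic per-stage seed fan-out from one master seed."""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidParameterError


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of the stage name mixed with the
    master seed, reduced below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class FieldEntry:
    """One dual-channel acquisition: paths plus its annotations."""

    client_stack: str
    shsp_stack: str
    timepoint_h: float
    replicate: str


@dataclass
class RunConfig:
    """All pipeline inputs and stage parameters.

    Defaults are the pipeline's documented stage defaults; the config
    round-trips losslessly through YAML.
    """

    out_dir: str = "results/run"
    bead_image_a: str = ""
    bead_image_b: str = ""
    fields: list[FieldEntry] = field(default_factory=list)
    seed: int = 0

    # stage parameters
    dark_offset: float = 0.0
    flatfield_path: str = ""
    transform_model: str = "affine"
    detect_frames: int = 10
    min_sigma: float = 1.0
    max_sigma: float = 2.0
    threshold_nsigma: float = 5.0
    aperture_radius_px: float = 3.0
    annulus_px: tuple[float, float] = (5.0, 8.0)
    match_radius_px: float = 2.0
    field_px: tuple[int, int] = (128, 128)
    classifier: str = "heuristic"          # or "trained"
    step_method: str = "ls"                # or "bayes"
    penalty_beta: float = 4.0
    k_initial: int = 20
    frame_interval_s: float = 0.5
    # measured fluorophores-per-monomer for the labelling correction
    client_fluors_per_monomer: float = 1.0
    shsp_fluors_per_monomer: float = 1.0
    bootstrap_resamples: int = 1000

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["annulus_px"] = list(self.annulus_px)
        d["field_px"] = list(self.field_px)
        d["fields"] = [dataclasses.asdict(f) for f in self.fields]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if "fields" in d:
            d["fields"] = [FieldEntry(**f) for f in d["fields"]]
        if "annulus_px" in d:
            d["annulus_px"] = tuple(d["annulus_px"])
        if "field_px" in d:
            d["field_px"] = tuple(d["field_px"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
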