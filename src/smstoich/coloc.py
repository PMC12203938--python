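"""Dual-channel colocalisation with flipped-channel chance correction.

A sHsp-client complex appears as one spot per channel at (nearly) the same
registered position.  Spots are paired by one-to-one mutual-nearest-neighbour
matching inside a match radius, after mapping the sHsp channel into the
client frame through the inverse channel transform.  Chance coincidence is
estimated by rotating the sHsp coordinates 180 degrees about the field
centre and repeating the matching; the chance fraction is subtracted from
the raw colocalised fraction (clamped at zero — a negative corrected
fraction is not physically reportable).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InvalidParameterError
from .types import ChannelTransform, Spot, as_xy_array

DEFAULT_MATCH_RADIUS_PX = 2.0


@dataclass
class ColocalisationResult:
    """Matched pairs and the raw / chance / corrected colocalised fractions
    of client spots in one field."""

    pairs: list[tuple[int, int, float]]     # (client idx, shsp idx, distance px)
    raw_fraction: float
    chance_fraction: float
    corrected_fraction: float
    match_radius_px: float
    n_client: int
    n_shsp: int
    extras: dict = field(default_factory=dict)


def _mutual_nn_pairs(
    pos_client: np.ndarray, pos_shsp: np.ndarray, radius_px: float
) -> list[tuple[int, int, float]]:
    """One-to-one mutual-nearest-neighbour pairs within the radius.

    Exact distance ties break to the smaller distance first (trivially) and
    then to the lower spot index, which is what ``argmin`` returns.
    """
    if len(pos_client) == 0 or len(pos_shsp) == 0:
        return []
    d = cdist(pos_client, pos_shsp)
    nn_cs = np.argmin(d, axis=1)
    nn_sc = np.argmin(d, axis=0)
    pairs = []
    for i, j in enumerate(nn_cs):
        if nn_sc[j] == i and d[i, j] <= radius_px:
            pairs.append((i, int(j), float(d[i, j])))
    return pairs


def match_spots(
    spots_client: list[Spot],
    spots_shsp: list[Spot],
    transform: ChannelTransform,
    radius_px: float = DEFAULT_MATCH_RADIUS_PX,
) -> list[tuple[int, int, float]]:
    """Pair client spots with sHsp spots mapped into the client frame.

    Returns (client index, sHsp index, pair distance px) triples.
    """
    if radius_px <= 0:
        raise InvalidParameterError("radius_px must be > 0")
    pos_client = as_xy_array(spots_client)
    pos_shsp = as_xy_array(spots_shsp)
    if len(pos_shsp):
        pos_shsp = transform.inverse().apply(pos_shsp)
    return _mutual_nn_pairs(pos_client, pos_shsp, radius_px)


def flip_positions(pos: np.ndarray, field_px: tuple[int, int]) -> np.ndarray:
    """Rotate coordinates 180 degrees about the field centre:
    x -> W-1-x, y -> H-1-y.  An involution: applying it twice is identity."""
    w, h = field_px
    pos = np.atleast_2d(np.asarray(pos, float))
    return np.column_stack([w - 1.0 - pos[:, 0], h - 1.0 - pos[:, 1]])


def chance_fraction(
    spots_client: list[Spot],
    spots_shsp: list[Spot],
    transform: ChannelTransform,
    radius_px: float,
    field_px: tuple[int, int],
) -> float:
    """Fraction of client spots matched after flipping the sHsp channel
    180 degrees — an estimate of coincidental colocalisation at the field's
    spot density."""
    pos_client = as_xy_array(spots_client)
    pos_shsp = as_xy_array(spots_shsp)
    if len(pos_client) == 0 or len(pos_shsp) == 0:
        return 0.0
    mapped = transform.inverse().apply(pos_shsp)
    flipped = flip_positions(mapped, field_px)
    pairs = _mutual_nn_pairs(pos_client, flipped, radius_px)
    return len(pairs) / len(pos_client)


def colocalise(
    spots_client: list[Spot],
    spots_shsp: list[Spot],
    transform: ChannelTransform,
    radius_px: float = DEFAULT_MATCH_RADIUS_PX,
    field_px: tuple[int, int] = (128, 128),
) -> ColocalisationResult:
    """Full chance-corrected colocalisation for one field:
    ``corrected = max(raw - chance, 0)``."""
    pairs = match_spots(spots_client, spots_shsp, transform, radius_px)
    n_client = len(spots_client)
    raw = len(pairs) / n_client if n_client else 0.0
    chance = chance_fraction(spots_client, spots_shsp, transform, radius_px, field_px)
    return ColocalisationResult(
        pairs=pairs,
        raw_fraction=raw,
        chance_fraction=chance,
        corrected_fraction=max(raw - chance, 0.0),
        match_radius_px=radius_px,
        n_client=n_client,
        n_shsp=len(spots_shsp),
    )
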