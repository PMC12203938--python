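"""Synthetic single-molecule TIRF data with full ground truth.

This module generates the three kinds of raw data the pipeline consumes —
photobleaching trajectories, dual-channel image stacks and fiducial-bead
registration pairs — together with a manifest recording every true position,
fluorophore count and bleach time, so that each downstream stage can be
validated against known truth.

The emulated acquisition follows a standard objective-type TIRF setup:
160 nm pixels, 0.5 s exposure and stacks of 600-1000 frames recorded until
essentially all fluorophores have photobleached.  Photobleaching is modelled
as a per-frame geometric hazard per fluorophore; per-fluorophore brightness
is lognormal (strictly positive, with the heavy right tail seen in measured
step-height distributions); noise is Poisson shot noise on the total signal
plus Gaussian read noise.  Blinking is available but off by default: the
step-counting method assumes monotone staircases, and blinking serves as an
opt-in stress test.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .errors import CapacityError, InvalidParameterError
from .types import (
    ChannelTransform,
    GroundTruthManifest,
    Trajectory,
    TrueMolecule,
    TrueStep,
)

# --------------------------------------------------------------------------
# parameter objects


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera/illumination settings of the emulated TIRF acquisition.

    Defaults match the target instrument: 500 ms exposure, 600 frames per
    stack, 160 nm pixel pitch.
    """

    exposure_s: float = 0.5
    n_frames: int = 600
    pixel_nm: float = 160.0
    field_px: tuple[int, int] = (128, 128)      # (width, height)
    psf_sigma_px: float = 1.1
    background_mean: float = 100.0
    read_noise_sd: float = 10.0
    shot_noise: bool = True
    em_channels: tuple[str, str] = ("AF647", "AF488")   # (client, sHsp)
    excitation_scheme: str = "simultaneous"             # or "alternate"

    def __post_init__(self) -> None:
        if self.exposure_s <= 0:
            raise InvalidParameterError("exposure_s must be > 0")
        if self.n_frames < 1:
            raise InvalidParameterError("n_frames must be >= 1")
        if self.psf_sigma_px <= 0:
            raise InvalidParameterError("psf_sigma_px must be > 0")
        if self.excitation_scheme not in ("simultaneous", "alternate"):
            raise InvalidParameterError(
                f"unknown excitation scheme {self.excitation_scheme!r}"
            )


@dataclass(frozen=True)
class FluorophoreModel:
    """Photophysics of one dye species.

    ``i_step_mean`` is the mean intensity contributed by a single fluorophore
    (counts per frame); ``i_step_cv`` the coefficient of variation of the
    lognormal per-fluorophore brightness; ``bleach_rate`` the per-frame
    bleaching hazard.  ``blink_on_rate``/``blink_off_rate`` are per-frame
    hazards of a two-state telegraph process (0 disables blinking).
    """

    i_step_mean: float = 200.0
    i_step_cv: float = 0.2
    bleach_rate: float = 0.005
    blink_on_rate: float = 0.0
    blink_off_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.i_step_mean <= 0:
            raise InvalidParameterError("i_step_mean must be > 0")
        if self.i_step_cv < 0:
            raise InvalidParameterError("i_step_cv must be >= 0")
        if not (0 < self.bleach_rate < 1):
            raise InvalidParameterError("bleach_rate must be in (0, 1)")
        if self.blink_on_rate < 0 or self.blink_off_rate < 0:
            raise InvalidParameterError("blink rates must be >= 0")


@dataclass(frozen=True)
class LabellingModel:
    """Distribution of fluorophores conjugated per protein monomer.

    Maleimide labelling at engineered cysteines leaves some monomers dark
    and puts two dyes on others; ``p_fluors`` maps fluorophore count to
    probability (support over non-negative integers, summing to 1).
    """

    p_fluors: dict[int, float] = field(default_factory=lambda: {1: 1.0})

    def __post_init__(self) -> None:
        ks = np.array(sorted(self.p_fluors))
        ps = np.array([self.p_fluors[k] for k in ks], dtype=float)
        if len(ks) == 0 or np.any(ks < 0) or not np.all(ks == ks.astype(int)):
            raise InvalidParameterError("support must be non-negative integers")
        if np.any(ps < 0) or abs(ps.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("probabilities must be >= 0 and sum to 1")

    def sample(self, n_monomers: int, rng: np.random.Generator) -> int:
        """Total fluorophores on a molecule of ``n_monomers`` subunits."""
        ks = np.array(sorted(self.p_fluors))
        ps = np.array([self.p_fluors[k] for k in ks], dtype=float)
        ps = ps / ps.sum()
        return int(rng.choice(ks, size=n_monomers, p=ps).sum())

    @property
    def mean(self) -> float:
        return float(sum(k * p for k, p in self.p_fluors.items()))


@dataclass(frozen=True)
class TimepointState:
    """Population parameters at one incubation timepoint.

    Subunit counts per molecule are discretised lognormals: a molecule of
    median ``m`` subunits is ``max(1, round(exp(N(log m, sigma))))``.  For a
    colocalised complex, sHsp subunits are generated from the client count
    through a lognormal ratio with median ``median_ratio``, so the true
    sHsp:client molar-ratio distribution has (up to integer rounding) the
    preset median.
    """

    frac_colocalised: float
    median_ratio: float
    client_median_coloc: float
    client_median_free: float
    shsp_median_free: float = 2.0
    sigma_client: float = 0.45
    sigma_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_colocalised <= 1.0):
            raise InvalidParameterError("frac_colocalised must be in [0, 1]")


@dataclass(frozen=True)
class PopulationKinetics:
    """Time-evolving composition of a chaperone/client mixture."""

    name: str
    states: dict[float, TimepointState]

    @property
    def timepoints_h(self) -> list[float]:
        return sorted(self.states)

    def state(self, timepoint_h: float) -> TimepointState:
        if timepoint_h not in self.states:
            raise InvalidParameterError(
                f"timepoint {timepoint_h} h not in preset {self.name!r}; "
                f"available: {self.timepoints_h}"
            )
        return self.states[timepoint_h]


def preset_kinetics(name: str) -> PopulationKinetics:
    """Named population presets.

    ``aBc-FLUC``: alphaB-crystallin with firefly luciferase.  ~40% of client
    molecules are in complexes from the first timepoint; the median sHsp:client
    molar ratio rises from 0.08 (0 h) to 2.5 (1 h) as further chaperone
    subunits are recruited; client molecules start as dimers and grow to
    ~8-subunit oligomers.

    ``Hsp27-rhodanese``: Hsp27 with rhodanese.  ~40% colocalised early; the
    median ratio climbs steadily from 0.15 (0 h) to 0.67 (7 h).

    ``negative-control``: a non-chaperone protein pair — no true complexes at
    any timepoint, mirroring the SSB/client control.
    """
    if name == "aBc-FLUC":
        states = {
            0.0: TimepointState(0.10, 0.08, 2.0, 2.0),
            0.3: TimepointState(0.40, 0.50, 4.0, 3.0),
            0.6: TimepointState(0.40, 1.20, 6.0, 5.0),
            1.0: TimepointState(0.40, 2.50, 8.0, 8.0),
        }
    elif name == "Hsp27-rhodanese":
        states = {
            0.0: TimepointState(0.30, 0.15, 3.0, 2.0),
            0.3: TimepointState(0.40, 0.20, 4.0, 3.0),
            0.6: TimepointState(0.42, 0.30, 5.0, 4.0),
            1.0: TimepointState(0.45, 0.40, 5.0, 5.0),
            4.0: TimepointState(0.45, 0.55, 5.0, 5.0),
            7.0: TimepointState(0.45, 0.67, 5.0, 5.0),
        }
    elif name == "negative-control":
        states = {
            t: TimepointState(0.0, 1.0, 2.0, 2.0) for t in (0.0, 1.0)
        }
    else:
        raise InvalidParameterError(f"unknown kinetics preset {name!r}")
    return PopulationKinetics(name, states)


# --------------------------------------------------------------------------
# trajectory-level simulation


def _draw_heights(n: int, fluor: FluorophoreModel, rng: np.random.Generator) -> np.ndarray:
    """Lognormal per-fluorophore brightness with mean i_step_mean, CV i_step_cv."""
    if n == 0:
        return np.empty(0)
    if fluor.i_step_cv == 0:
        return np.full(n, fluor.i_step_mean)
    sigma2 = np.log1p(fluor.i_step_cv**2)
    mu = np.log(fluor.i_step_mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def _draw_bleach_frames(
    n: int, fluor: FluorophoreModel, rng: np.random.Generator
) -> np.ndarray:
    """Geometric bleach frames: fluorophore i emits during frames < b_i."""
    if n == 0:
        return np.empty(0, dtype=int)
    return rng.geometric(fluor.bleach_rate, size=n)


def _emission_matrix(
    heights: np.ndarray,
    bleach_frames: np.ndarray,
    fluor: FluorophoreModel,
    n_frames: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_fluor, n_frames) per-fluorophore emitted intensity, blinking included."""
    frames = np.arange(n_frames)
    alive = frames[None, :] < bleach_frames[:, None]
    emit = alive * heights[:, None]
    if fluor.blink_on_rate > 0 and fluor.blink_off_rate > 0:
        # two-state telegraph per fluorophore, starting in the on state
        for i in range(len(heights)):
            on = True
            for f in range(n_frames):
                if not on:
                    emit[i, f] = 0.0
                if on and rng.random() < fluor.blink_off_rate:
                    on = False
                elif not on and rng.random() < fluor.blink_on_rate:
                    on = True
    return emit


def _add_noise(
    signal: np.ndarray, acq: AcquisitionParams, rng: np.random.Generator
) -> np.ndarray:
    """Poisson shot noise on total counts plus Gaussian read noise."""
    out = np.asarray(signal, dtype=float)
    if acq.shot_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if acq.read_noise_sd > 0:
        out = out + rng.normal(0.0, acq.read_noise_sd, size=out.shape)
    return out


def simulate_trajectory(
    n_fluorophores: int,
    fluor: FluorophoreModel,
    acq: AcquisitionParams,
    seed: int | np.random.Generator,
    bleach_frames: np.ndarray | None = None,
    subtract_background: bool = False,
) -> tuple[Trajectory, list[TrueStep]]:
    """Simulate one spot's photobleaching trace.

    Returns the trajectory (expected intensity at frame f = background +
    sum of surviving fluorophores' step heights) and the true step record,
    one entry per fluorophore with its bleach frame and height.
    ``bleach_frames`` may be supplied to force deterministic bleach times.
    """
    if n_fluorophores < 0:
        raise InvalidParameterError("n_fluorophores must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    heights = _draw_heights(n_fluorophores, fluor, rng)
    if bleach_frames is None:
        bleach = _draw_bleach_frames(n_fluorophores, fluor, rng)
    else:
        bleach = np.asarray(bleach_frames, dtype=int)
        if bleach.shape != (n_fluorophores,):
            raise InvalidParameterError("bleach_frames must have one entry per fluorophore")

    emit = _emission_matrix(heights, bleach, fluor, acq.n_frames, rng)
    signal = emit.sum(axis=0) if n_fluorophores else np.zeros(acq.n_frames)
    trace = _add_noise(signal + acq.background_mean, acq, rng)
    if subtract_background:
        trace = trace - acq.background_mean
    steps = [TrueStep(int(b), float(h)) for b, h in zip(bleach, heights)]
    traj = Trajectory(trace, frame_interval_s=acq.exposure_s)
    return traj, steps


# --------------------------------------------------------------------------
# population-level simulation


def _sample_subunits(
    median: float, sigma: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    vals = np.exp(rng.normal(np.log(median), sigma, size=n))
    return np.maximum(1, np.rint(vals)).astype(int)


def simulate_population(
    kin: PopulationKinetics,
    label_client: LabellingModel,
    n_molecules: int,
    timepoint_h: float,
    seed: int | np.random.Generator,
    label_shsp: LabellingModel | None = None,
) -> list[TrueMolecule]:
    """Draw a ground-truth population of client molecules (with their sHsp
    partners where colocalised) for one incubation timepoint.

    Each of the ``n_molecules`` clients is independently in a complex with
    probability ``frac_colocalised(t)``; subunit counts come from the preset's
    per-timepoint distributions, and fluorophore counts are drawn per subunit
    from the labelling model.
    """
    if n_molecules < 0:
        raise InvalidParameterError("n_molecules must be >= 0")
    st = kin.state(timepoint_h)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    label_shsp = label_shsp or LabellingModel({1: 1.0})

    coloc = rng.random(n_molecules) < st.frac_colocalised
    molecules: list[TrueMolecule] = []
    mol_id = 0
    complex_id = 0
    for i in range(n_molecules):
        if coloc[i]:
            client_sub = int(_sample_subunits(st.client_median_coloc, st.sigma_client, 1, rng)[0])
            ratio = float(np.exp(rng.normal(np.log(st.median_ratio), st.sigma_ratio)))
            shsp_sub = max(1, int(np.rint(client_sub * ratio)))
            cid = complex_id
            complex_id += 1
        else:
            client_sub = int(_sample_subunits(st.client_median_free, st.sigma_client, 1, rng)[0])
            cid = None
        molecules.append(
            TrueMolecule(
                molecule_id=mol_id,
                channel="client",
                subunits=client_sub,
                n_fluorophores=label_client.sample(client_sub, rng),
                complex_id=cid,
            )
        )
        mol_id += 1
        if coloc[i]:
            molecules.append(
                TrueMolecule(
                    molecule_id=mol_id,
                    channel="shsp",
                    subunits=shsp_sub,
                    n_fluorophores=label_shsp.sample(shsp_sub, rng),
                    complex_id=cid,
                )
            )
            mol_id += 1
    return molecules


def add_free_shsp(
    molecules: list[TrueMolecule],
    n_free: int,
    median_subunits: float,
    label_shsp: LabellingModel,
    seed: int | np.random.Generator,
    sigma: float = 0.45,
) -> list[TrueMolecule]:
    """Append non-colocalised sHsp molecules (free chaperone background)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    next_id = max((m.molecule_id for m in molecules), default=-1) + 1
    out = list(molecules)
    subs = _sample_subunits(median_subunits, sigma, n_free, rng)
    for s in subs:
        out.append(
            TrueMolecule(
                molecule_id=next_id,
                channel="shsp",
                subunits=int(s),
                n_fluorophores=label_shsp.sample(int(s), rng),
                complex_id=None,
            )
        )
        next_id += 1
    return out


# --------------------------------------------------------------------------
# image rendering


def _integrated_psf(
    shape_hw: tuple[int, int],
    x: float,
    y: float,
    sigma: float,
    radius_px: int,
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Unit-amplitude PSF integrated over pixels in a local window.

    Returns the weight patch (summing to ~1 for an interior spot) and the
    slices placing it in the full frame.
    """
    h, w = shape_hw
    x0 = max(0, int(np.floor(x)) - radius_px)
    x1 = min(w, int(np.floor(x)) + radius_px + 1)
    y0 = max(0, int(np.floor(y)) - radius_px)
    y1 = min(h, int(np.floor(y)) + radius_px + 1)
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    # integral of a 2-D Gaussian over pixel [i, i+1) x [j, j+1)
    def cdf(e: np.ndarray, c: float) -> np.ndarray:
        return 0.5 * (1 + erf((e - c) / (np.sqrt(2) * sigma)))
    wx = cdf(xs + 1.0, x) - cdf(xs, x)
    wy = cdf(ys + 1.0, y) - cdf(ys, y)
    patch = np.outer(wy, wx)
    return patch, (slice(y0, y1), slice(x0, x1))


def _place_positions(
    n: int,
    field_px: tuple[int, int],
    min_separation_px: float,
    rng: np.random.Generator,
    margin_px: float = 10.0,
    max_tries: int = 200,
) -> tuple[np.ndarray, int]:
    """Uniform positions with a minimum pairwise separation (rejection
    sampling).  Returns positions and the number of separation violations
    accepted after exhausting retries."""
    w, h = field_px
    if w - 2 * margin_px <= 1 or h - 2 * margin_px <= 1:
        raise CapacityError("field too small for the requested margin")
    pos = np.empty((n, 2))
    violations = 0
    for i in range(n):
        ok = False
        for _ in range(max_tries):
            p = rng.uniform([margin_px, margin_px], [w - margin_px, h - margin_px])
            if i == 0 or np.min(np.hypot(*(pos[:i] - p).T)) >= min_separation_px:
                ok = True
                break
        if not ok:
            violations += 1
            # density sanity check: give up if most spots collide
            if violations > max(1, n // 10):
                raise CapacityError(
                    f"cannot place {n} spots at separation {min_separation_px} px "
                    f"in a {w}x{h} px field"
                )
        pos[i] = p
    return pos, violations


def _render_channel(
    positions: np.ndarray,
    emissions: list[np.ndarray],
    acq: AcquisitionParams,
    rng: np.random.Generator,
    frame_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """Render one channel's stack from per-molecule emission time courses."""
    w, h = acq.field_px
    n_frames = acq.n_frames
    radius = int(np.ceil(5 * acq.psf_sigma_px))
    stack = np.zeros((n_frames, h, w))
    for (x, y), emit in zip(positions, emissions):
        patch, sl = _integrated_psf((h, w), x, y, acq.psf_sigma_px, radius)
        e = np.zeros(n_frames)
        if frame_range is None:
            e[: len(emit)] = emit[:n_frames]
        else:
            f0, f1 = frame_range
            seg = emit[: f1 - f0]
            e[f0 : f0 + len(seg)] = seg
        stack[:, sl[0], sl[1]] += e[:, None, None] * patch[None, :, :]
    stack += acq.background_mean
    return _add_noise(stack, acq, rng)


def render_field(
    molecules: list[TrueMolecule],
    acq: AcquisitionParams,
    transform: ChannelTransform,
    seed: int,
    fluor_client: FluorophoreModel | None = None,
    fluor_shsp: FluorophoreModel | None = None,
    min_separation_px: float | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruthManifest]:
    """Render a two-channel image stack for a ground-truth population.

    Client molecules are placed uniformly in the channel-A field at a minimum
    pairwise separation (default 4 x psf_sigma); complex partners share the
    (transformed) position in channel B.  Pixel values are the integrated
    Gaussian PSF times the surviving-fluorophore intensity plus background
    and noise.  Under the ``alternate`` excitation scheme channel B bleaches
    in the first half of the stack and channel A in the second half
    (mirroring alternate-excitation imaging used to avoid FRET).

    Returns ``(stack_client, stack_shsp, manifest)``.
    """
    rng = np.random.default_rng(seed)
    fluor_client = fluor_client or FluorophoreModel()
    fluor_shsp = fluor_shsp or FluorophoreModel()
    if min_separation_px is None:
        min_separation_px = 4.0 * acq.psf_sigma_px

    clients = [m for m in molecules if m.channel == "client"]
    shsps = [m for m in molecules if m.channel == "shsp"]
    by_complex = {m.complex_id: m for m in shsps if m.complex_id is not None}
    free_shsps = [m for m in shsps if m.complex_id is None]

    pos_a, violations = _place_positions(
        len(clients) + len(free_shsps), acq.field_px, min_separation_px, rng
    )
    client_pos = pos_a[: len(clients)]
    free_pos = pos_a[len(clients):]

    if acq.excitation_scheme == "alternate":
        half = acq.n_frames // 2
        range_shsp: tuple[int, int] | None = (0, half)
        range_client: tuple[int, int] | None = (half, acq.n_frames)
    else:
        range_shsp = range_client = None

    def draw_emission(m: TrueMolecule, fl: FluorophoreModel, n_frames: int) -> np.ndarray:
        heights = _draw_heights(m.n_fluorophores, fl, rng)
        bleach = _draw_bleach_frames(m.n_fluorophores, fl, rng)
        m.steps = [TrueStep(int(b), float(h)) for b, h in zip(bleach, heights)]
        emit = _emission_matrix(heights, bleach, fl, n_frames, rng)
        return emit.sum(axis=0) if m.n_fluorophores else np.zeros(n_frames)

    n_cl = acq.n_frames if range_client is None else range_client[1] - range_client[0]
    n_sh = acq.n_frames if range_shsp is None else range_shsp[1] - range_shsp[0]

    client_emit = []
    for m, p in zip(clients, client_pos):
        m.position = (float(p[0]), float(p[1]))
        client_emit.append(draw_emission(m, fluor_client, n_cl))

    shsp_positions_a = []
    shsp_emit = []
    shsp_order: list[TrueMolecule] = []
    for m, p in zip(clients, client_pos):
        partner = by_complex.get(m.complex_id) if m.complex_id is not None else None
        if partner is not None:
            partner.position = (float(p[0]), float(p[1]))   # channel-A frame
            shsp_positions_a.append(p)
            shsp_emit.append(draw_emission(partner, fluor_shsp, n_sh))
            shsp_order.append(partner)
    for m, p in zip(free_shsps, free_pos):
        m.position = (float(p[0]), float(p[1]))
        shsp_positions_a.append(p)
        shsp_emit.append(draw_emission(m, fluor_shsp, n_sh))
        shsp_order.append(m)

    shsp_pos_b = (
        transform.apply(np.asarray(shsp_positions_a))
        if shsp_positions_a
        else np.empty((0, 2))
    )

    stack_client = _render_channel(client_pos, client_emit, acq, rng, range_client)
    stack_shsp = _render_channel(shsp_pos_b, shsp_emit, acq, rng, range_shsp)

    manifest = GroundTruthManifest(
        molecules=clients + shsp_order,
        transform=transform,
        seed=seed,
        params={
            "acquisition": dataclasses.asdict(acq),
            "fluor_client": dataclasses.asdict(fluor_client),
            "fluor_shsp": dataclasses.asdict(fluor_shsp),
            "min_separation_px": min_separation_px,
        },
        separation_violations=violations,
    )
    return stack_client, stack_shsp, manifest


def make_bead_pair(
    n_beads: int,
    transform: ChannelTransform,
    acq: AcquisitionParams,
    seed: int,
    bead_intensity: float = 20000.0,
    min_separation_px: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a single-frame fiducial-bead image pair for registration.

    Beads appear in both channels; channel-B positions are the transform of
    the channel-A positions.  Returns ``(img_a, img_b, true_positions_a)``.
    """
    if n_beads < 1:
        raise InvalidParameterError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    if min_separation_px is None:
        min_separation_px = 8.0 * acq.psf_sigma_px
    pos_a, _ = _place_positions(n_beads, acq.field_px, min_separation_px, rng)
    pos_b = transform.apply(pos_a)
    one_frame = dataclasses.replace(acq, n_frames=1)
    emissions = [np.full(1, bead_intensity) for _ in range(n_beads)]
    img_a = _render_channel(pos_a, emissions, one_frame, rng)[0]
    img_b = _render_channel(pos_b, emissions, one_frame, rng)[0]
    return img_a, img_b, pos_a


def place_population(
    molecules: list[TrueMolecule],
    acq: AcquisitionParams,
    transform: ChannelTransform,
    seed: int | np.random.Generator,
    min_separation_px: float | None = None,
    localisation_error_px: float = 0.1,
) -> tuple[list, list]:
    """Assign field positions and produce per-channel spot lists without
    rendering images — a fast path for validating colocalisation at spot
    densities where full image stacks would be impractical.

    Complex partners share the (transformed) position; every detected-spot
    centre gets isotropic Gaussian localisation error.  Returns
    ``(client_spots, shsp_spots)`` with channel-B spots in channel-B
    coordinates; molecule positions (channel-A frame) are filled in place.
    """
    from .types import Spot

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if min_separation_px is None:
        min_separation_px = 4.0 * acq.psf_sigma_px
    clients = [m for m in molecules if m.channel == "client"]
    shsps = [m for m in molecules if m.channel == "shsp"]
    by_complex = {m.complex_id: m for m in shsps if m.complex_id is not None}
    free_shsps = [m for m in shsps if m.complex_id is None]

    pos, _ = _place_positions(
        len(clients) + len(free_shsps), acq.field_px, min_separation_px, rng
    )
    client_spots, shsp_pos_a = [], []
    for i, (m, p) in enumerate(zip(clients, pos[: len(clients)])):
        m.position = (float(p[0]), float(p[1]))
        xy = p + rng.normal(0, localisation_error_px, 2)
        client_spots.append(Spot(x=xy[0], y=xy[1], channel="client", index=i))
        partner = by_complex.get(m.complex_id) if m.complex_id is not None else None
        if partner is not None:
            partner.position = m.position
            shsp_pos_a.append(p)
    for m, p in zip(free_shsps, pos[len(clients):]):
        m.position = (float(p[0]), float(p[1]))
        shsp_pos_a.append(p)
    shsp_spots = []
    if shsp_pos_a:
        mapped = transform.apply(np.asarray(shsp_pos_a))
        mapped = mapped + rng.normal(0, localisation_error_px, mapped.shape)
        shsp_spots = [
            Spot(x=float(p[0]), y=float(p[1]), channel="shsp", index=j)
            for j, p in enumerate(mapped)
        ]
    return client_spots, shsp_spots


# --------------------------------------------------------------------------
# cohort convenience + artefact traces for classifier training


def simulate_cohort(
    subunit_counts: np.ndarray,
    labelling: LabellingModel,
    fluor: FluorophoreModel,
    acq: AcquisitionParams,
    seed: int,
) -> tuple[list[Trajectory], list[int]]:
    """Background-corrected trajectories for molecules with the given true
    subunit counts; returns (trajectories, true fluorophore counts)."""
    rng = np.random.default_rng(seed)
    trajs, fluors = [], []
    for s in np.asarray(subunit_counts, dtype=int):
        nf = labelling.sample(int(s), rng)
        traj, _ = simulate_trajectory(
            nf, fluor, acq, rng, subtract_background=True
        )
        trajs.append(traj)
        fluors.append(nf)
    return trajs, fluors


def make_artefact_trace(
    kind: str,
    acq: AcquisitionParams,
    fluor: FluorophoreModel,
    rng: np.random.Generator,
) -> Trajectory:
    """Engineered reject-class traces for classifier training.

    ``flat``: pure noise around 0.  ``drift``: smooth monotone decay with no
    discrete steps.  ``non_bleaching``: constant bright level that never
    bleaches.  ``erratic``: heavy random-walk intensity (aggregate/junk).
    """
    n = acq.n_frames
    noise_sd = np.sqrt(acq.background_mean) + acq.read_noise_sd
    if kind == "flat":
        trace = rng.normal(0.0, noise_sd, n)
    elif kind == "drift":
        amp = fluor.i_step_mean * rng.uniform(2, 8)
        tau = rng.uniform(0.2, 1.0) * n
        trace = amp * np.exp(-np.arange(n) / tau) + rng.normal(0, noise_sd, n)
    elif kind == "non_bleaching":
        amp = fluor.i_step_mean * rng.uniform(2, 8)
        trace = amp + rng.normal(0, noise_sd, n)
    elif kind == "erratic":
        steps = rng.normal(0, fluor.i_step_mean / 4, n)
        walk = np.abs(np.cumsum(steps)) + fluor.i_step_mean
        trace = walk + rng.normal(0, noise_sd, n)
    else:
        raise InvalidParameterError(f"unknown artefact kind {kind!r}")
    return Trajectory(trace, frame_interval_s=acq.exposure_s)
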