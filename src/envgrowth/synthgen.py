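"""Synthetic single-cell data with the dynamics the analysis chain assumes.

The generator emulates the measured phenomenology of nondividing
rod-shaped Gram-negative cells under cell-wall-synthesis arrest:

* exponential biomass growth with surface area strictly proportional to
  mass (``S = sm_ratio * M``), through arrest and nutrient shifts alike —
  so any deviation of the *measured* S/M ratio from constancy is
  attributable to the pipeline, not the data;
* after synthesis arrest the cell keeps growing its surface, widens slowly,
  and lyses abruptly once the post-arrest surface gain reaches a programmed
  fraction (15–30% in the experiments; default 20%), modelled as a
  single-frame collapse of mass and volume;
* directed, constant-velocity MreB tracks whose motion stops at a
  programmed arrest time, leaving only localisation jitter;
* diffusion-limited hypo-osmotic ramps producing an elastic plus plastic
  relative width response;
* rendered image stacks (spherocylinder masks + quantitative-phase images)
  consistent with the phase→mass calibration, for end-to-end tests.

Observation noise is multiplicative log-normal per frame and per quantity.
Every output is a pure function of the scenario's ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry, quantphase
from .kinetics import CellTrajectory

__all__ = [
    "GrowthScenario",
    "MrebScenario",
    "simulate_cell_trajectory",
    "simulate_population",
    "simulate_mreb_tracks",
    "render_frames",
    "render_spot_frame",
    "simulate_osmotic_width_response",
    "calibrate_ramp_gains",
]

LYSIS_COLLAPSE = 0.35  # mass/volume fraction retained at lysis (<50%)


@dataclass(frozen=True)
class GrowthScenario:
    """Parameters of one synthetic growth experiment.

    Parameters
    ----------
    mass_rate : float
        Exponential biomass growth rate ``lambda_M`` (min⁻¹).  The default
        0.01 min⁻¹ corresponds to a ~69 min doubling time, typical of
        minimal-medium growth at 30 °C.
    sm_ratio : float
        Surface-to-mass coupling ``S/M`` (μm²/pg); with the default initial
        mass and width this yields a ~3 μm cell.
    initial_mass : float
        Dry mass at t = 0 (pg).
    initial_width : float
        Cell diameter at t = 0 (μm).
    arrest_time : float or None
        Time cell-wall synthesis (and MreB motion) stops (min).
    widening_rate : float
        Relative width increase per minute after arrest; default +10% over
        40 min.
    lysis_surface_gain : float
        Additional fractional surface growth between arrest and lysis.
    shift_profile : tuple of (t_start_min, mass_rate) or None
        Piecewise-constant modulation of the mass growth rate (nutrient
        shifts); segments apply from their start time onward.
    noise_cv : float
        Coefficient of variation of multiplicative log-normal observation
        noise per frame per quantity.
    seed : int
        Seed making the scenario fully reproducible.
    """

    mass_rate: float = 0.01
    sm_ratio: float = 19.0
    initial_mass: float = 0.5
    initial_width: float = 1.0
    arrest_time: float | None = None
    widening_rate: float = 0.0025
    lysis_surface_gain: float = 0.20
    shift_profile: tuple | None = None
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.mass_rate < 0:
            raise ValueError("mass_rate must be non-negative")
        if self.lysis_surface_gain < 0:
            raise ValueError("lysis_surface_gain must be non-negative")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if min(self.sm_ratio, self.initial_mass, self.initial_width) <= 0:
            raise ValueError("sm_ratio, initial_mass, initial_width must be positive")

    def rate_at(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous mass growth rate lambda_M(t) (min⁻¹)."""
        t = np.asarray(t, dtype=float)
        lam = np.full_like(t, self.mass_rate)
        if self.shift_profile:
            for t_start, rate in self.shift_profile:
                lam[t >= t_start] = rate
        return lam


@dataclass(frozen=True)
class MrebScenario:
    """Parameters of a synthetic MreB tracking movie.

    Directed tracks are straight constant-velocity segments (the activity
    statistic is insensitive to the true circumferential geometry); after
    ``arrest_time`` spots only jitter by the localisation noise.
    """

    track_speed: float = 0.6  # um/min (10 nm/s)
    track_density: float = 0.7  # tracks per um^2 per min
    track_duration: float = 0.5  # min; mean directed lifetime
    arrest_time: float | None = None
    frame_interval: float = 1.0  # s
    localization_noise: float = 0.01  # um
    seed: int = 0

    def __post_init__(self):
        if min(self.track_speed, self.track_density, self.track_duration) < 0:
            raise ValueError("speeds, densities and durations must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.localization_noise < 0:
            raise ValueError("localization_noise must be non-negative")

    @property
    def expected_activity(self) -> float:
        """Expected MreB activity before arrest:
        ``track_density * track_speed * track_duration`` (μm⁻¹ min⁻¹)."""
        return self.track_density * self.track_speed * self.track_duration


# ---------------------------------------------------------------------------
# growth trajectories
# ---------------------------------------------------------------------------

def simulate_cell_trajectory(
    scenario: GrowthScenario,
    duration: float,
    dt: float,
    cell_id: int = 0,
) -> CellTrajectory:
    """Simulate one cell's M, S, V, L, W time series.

    Ground truth: ``M(t) = M0 exp(integral lambda_M dt)``; ``S = sm_ratio*M``
    exactly; width constant until arrest then growing exponentially at
    ``widening_rate``; length from spherocylinder inversion ``L = S/(pi W)``;
    volume from the spherocylinder closed form.  Lysis occurs at the first
    frame where the post-arrest surface gain reaches ``lysis_surface_gain``:
    mass and volume collapse to a <50% fraction in a single frame.  The
    returned trajectory holds the noisy observations; the exact series are
    in ``trajectory.extra["truth"]``.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if dt >= duration:
        raise ValueError("dt must be smaller than duration")
    t = np.arange(0.0, duration + 0.5 * dt, dt)

    # cumulative growth integral on the frame grid (trapezoid on lambda)
    lam = scenario.rate_at(t)
    integral = np.concatenate([[0.0], np.cumsum(0.5 * (lam[1:] + lam[:-1]) * np.diff(t))])
    M = scenario.initial_mass * np.exp(integral)
    S = scenario.sm_ratio * M

    W = np.full_like(t, scenario.initial_width)
    arrest = scenario.arrest_time
    if arrest is not None:
        after = t > arrest
        W[after] = scenario.initial_width * np.exp(
            scenario.widening_rate * (t[after] - arrest)
        )
    L = geometry.spherocylinder_length_from_surface(S, W)
    V = geometry.spherocylinder_volume(L, W)

    lysis_time = None
    if arrest is not None and arrest < t[-1]:
        s_arrest = float(np.interp(arrest, t, S))
        gain = S / s_arrest - 1.0
        hit = np.nonzero((t > arrest) & (gain >= scenario.lysis_surface_gain))[0]
        if hit.size:
            k = int(hit[0])
            lysis_time = float(t[k])
            M[k:] = M[k - 1] * LYSIS_COLLAPSE
            V[k:] = V[k - 1] * LYSIS_COLLAPSE

    truth = pd.DataFrame(
        {
            "t_min": t,
            "mass_pg": M,
            "surface_um2": S,
            "volume_um3": V,
            "length_um": L,
            "width_um": W,
        }
    )

    rng = np.random.default_rng(scenario.seed + 7919 * cell_id)
    if scenario.noise_cv > 0:
        sigma = np.sqrt(np.log1p(scenario.noise_cv**2))
        noisy = {
            col: truth[col].to_numpy()
            * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(t)))
            for col in ("mass_pg", "surface_um2", "volume_um3", "length_um", "width_um")
        }
    else:
        noisy = {
            col: truth[col].to_numpy().copy()
            for col in ("mass_pg", "surface_um2", "volume_um3", "length_um", "width_um")
        }

    return CellTrajectory(
        times_min=t,
        cell_id=cell_id,
        drug_add_time=arrest,
        mreb_stop_time=arrest,
        lysis_time=lysis_time,
        extra={"truth": truth, "scenario": scenario},
        **noisy,
    )


def simulate_population(
    scenario: GrowthScenario, duration: float, dt: float, n_cells: int
) -> list[CellTrajectory]:
    """Independent noise realisations of one scenario (seed offset per cell)."""
    return [
        simulate_cell_trajectory(scenario, duration, dt, cell_id=i)
        for i in range(n_cells)
    ]


# ---------------------------------------------------------------------------
# MreB tracks
# ---------------------------------------------------------------------------

def simulate_mreb_tracks(
    scenario: MrebScenario,
    cell_area: float,
    duration: float,
) -> pd.DataFrame:
    """Generate MreB spot samples (``frame, t_s, x_um, y_um, track_id``).

    Track nucleation is a Poisson process at ``track_density * cell_area``
    per minute over a square field of area ``cell_area``; each track moves
    with constant velocity ``track_speed`` in a random direction for
    ``track_duration`` minutes.  From ``arrest_time`` onward positions are
    frozen, so remaining motion is pure localisation jitter.
    """
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(scenario.seed)
    side = np.sqrt(cell_area)
    n_tracks = rng.poisson(scenario.track_density * cell_area * duration)
    dt_min = scenario.frame_interval / 60.0
    arrest = np.inf if scenario.arrest_time is None else scenario.arrest_time

    rows = []
    for tid in range(n_tracks):
        t0 = rng.uniform(0.0, duration)
        start = rng.uniform(0.0, side, size=2)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        vel = scenario.track_speed * np.array([np.cos(theta), np.sin(theta)])
        t_end = min(t0 + scenario.track_duration, duration)
        n_frames = int(np.floor((t_end - t0) / dt_min)) + 1
        for k in range(n_frames):
            t = t0 + k * dt_min
            moving_until = min(t, arrest)
            pos = start + vel * max(moving_until - t0, 0.0)
            pos = pos + rng.normal(0.0, scenario.localization_noise, size=2)
            rows.append((int(round(t / dt_min)), t * 60.0, pos[0], pos[1], tid))
    df = pd.DataFrame(rows, columns=["frame", "t_s", "x_um", "y_um", "track_id"])
    return df.sort_values(["frame", "track_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def _spherocylinder_thickness(shape, pixel_size, length, width, center_rc):
    """Projected 3D chord thickness of an axis-aligned spherocylinder (μm)."""
    rows = (np.arange(shape[0]) - center_rc[0]) * pixel_size
    cols = (np.arange(shape[1]) - center_rc[1]) * pixel_size
    yy, xx = np.meshgrid(rows, cols, indexing="ij")
    half_axis = (length - width) / 2.0
    dx = np.clip(np.abs(xx) - half_axis, 0.0, None)
    d2 = dx**2 + yy**2
    r = width / 2.0
    return 2.0 * np.sqrt(np.clip(r**2 - d2, 0.0, None))


def render_frames(
    trajectory: CellTrajectory,
    pixel_size: float = 0.05,
    cal: quantphase.MassCalibration | None = None,
    field_shape: tuple[int, int] | None = None,
    background_noise: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a trajectory into phase images and binary masks.

    Each frame holds one horizontal spherocylinder centred in the field.
    The phase image distributes the frame's ground-truth mass over the cell
    in proportion to the projected chord thickness, normalised so that the
    integrated positive phase maps back to the mass exactly through the
    calibration (before background noise).  Returns
    ``(phase_stack float32, mask_stack uint8)``.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if cal is None:
        cal = quantphase.MassCalibration(pixel_area=pixel_size**2)
    if abs(cal.pixel_area - pixel_size**2) > 1e-12:
        raise ValueError("calibration pixel_area must equal pixel_size**2")
    truth = trajectory.extra.get("truth")
    if truth is None:
        truth = trajectory.to_frame().rename(columns={"t_min": "t_min"})
    L = truth["length_um"].to_numpy(dtype=float)
    W = truth["width_um"].to_numpy(dtype=float)
    M = truth["mass_pg"].to_numpy(dtype=float)

    margin = 10
    if field_shape is None:
        field_shape = (
            int(np.ceil(W.max() / pixel_size)) + 2 * margin,
            int(np.ceil(L.max() / pixel_size)) + 2 * margin,
        )
    if (
        W.max() / pixel_size > field_shape[0] - 2
        or L.max() / pixel_size > field_shape[1] - 2
    ):
        raise ValueError("cell larger than field of view")

    rng = np.random.default_rng(
        trajectory.extra.get("scenario", GrowthScenario()).seed + 104729
    )
    center = ((field_shape[0] - 1) / 2.0, (field_shape[1] - 1) / 2.0)
    phase = np.zeros((len(L),) + field_shape, dtype=np.float32)
    masks = np.zeros((len(L),) + field_shape, dtype=np.uint8)
    for i in range(len(L)):
        thick = _spherocylinder_thickness(field_shape, pixel_size, L[i], W[i], center)
        masks[i] = (thick > 0).astype(np.uint8)
        total = thick.sum()
        if total > 0 and M[i] > 0:
            phi_target = quantphase.mass_to_phase(M[i], cal)
            phase[i] = (thick / total * phi_target).astype(np.float32)
        if background_noise > 0:
            phase[i] += rng.normal(0.0, background_noise, size=field_shape).astype(
                np.float32
            )
    return phase, masks


def render_spot_frame(
    positions_um: np.ndarray,
    pixel_size: float,
    shape: tuple[int, int],
    amplitude: float = 1.0,
    spot_sigma_um: float = 0.053,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render Gaussian spots at given (x, y) μm positions onto a frame.

    ``spot_sigma_um`` defaults to the LoG-matched sigma of a 0.15 μm spot.
    """
    rng = np.random.default_rng(seed)
    img = np.zeros(shape, dtype=float)
    rr = np.arange(shape[0])[:, None] * pixel_size
    cc = np.arange(shape[1])[None, :] * pixel_size
    for x, y in np.atleast_2d(positions_um):
        img += amplitude * np.exp(
            -((cc - x) ** 2 + (rr - y) ** 2) / (2.0 * spot_sigma_um**2)
        )
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=shape)
    return img


# ---------------------------------------------------------------------------
# osmotic width response
# ---------------------------------------------------------------------------

def simulate_osmotic_width_response(
    times_min: np.ndarray,
    osmolality: np.ndarray,
    elastic_gain: float,
    plastic_rate: float,
) -> pd.DataFrame:
    """Relative cell width under a hypo-osmotic ramp.

    ``width_rel(t) = 1 + elastic_gain * dPi(t) + integral plastic_rate *
    dPi(t') dt'`` where ``dPi`` is the osmolality *drop* from the start.
    The elastic term is instantaneous and reversible; the plastic term
    accumulates.  Osmolality must be monotone non-increasing.
    """
    t = np.asarray(times_min, dtype=float)
    osm = np.asarray(osmolality, dtype=float)
    if np.any(np.diff(osm) > 1e-9):
        raise ValueError("osmolality must be monotone non-increasing (hypo-osmotic ramp)")
    drop = osm[0] - osm
    plastic = np.concatenate(
        [[0.0], np.cumsum(0.5 * (drop[1:] + drop[:-1]) * np.diff(t))]
    )
    width_rel = 1.0 + elastic_gain * drop + plastic_rate * plastic
    return pd.DataFrame(
        {"t_min": t, "osmolality_mosm": osm, "width_rel": width_rel}
    )


def calibrate_ramp_gains(
    times_min: np.ndarray,
    osmolality: np.ndarray,
    total_widening: float = 0.08,
    elastic_widening: float = 0.025,
    elastic_ref_drop: float = 520.0,
    at_time: float = 20.0,
) -> tuple[float, float]:
    """Gains reproducing the observed ramp response.

    The elastic gain comes from the step-shock observation (2.5% widening at
    a 520 mOsm sudden drop); the plastic rate is then set so the *total*
    widening at ``at_time`` minutes matches ``total_widening`` (8% at 20 min
    in the ramp experiments).
    """
    t = np.asarray(times_min, dtype=float)
    osm = np.asarray(osmolality, dtype=float)
    elastic_gain = elastic_widening / elastic_ref_drop
    drop = osm[0] - osm
    plastic_int = np.concatenate(
        [[0.0], np.cumsum(0.5 * (drop[1:] + drop[:-1]) * np.diff(t))]
    )
    drop_at = float(np.interp(at_time, t, drop))
    int_at = float(np.interp(at_time, t, plastic_int))
    if int_at <= 0:
        raise ValueError("ramp shows no osmolality drop before at_time")
    plastic_rate = (total_widening - elastic_gain * drop_at) / int_at
    return elastic_gain, plastic_rate
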