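"""Switching-diffusion trajectory simulator with known ground truth.

Particles diffuse in 2D, switching among mobility states according to a
continuous-time Markov chain. The chain is simulated in continuous time
(Gillespie) and sampled at frame boundaries, so dwell times are exponential
in real time and the per-frame state sequence is the exact discretization of
the chain. The displacement over a frame uses the state occupied at the
frame start; sub-frame mixing is not modelled because it is unidentifiable
at the ~80 ms frame intervals this simulator emulates.

Track lengths are photobleaching-limited: lifetimes are exponential with
rate ``bleach_rate``, truncated at 2000 frames (one movie), minimum two
frames so every track has at least one step.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf

from sptstates.config import SimulationConfig, ImagingParams, MAX_FRAMES

TRAJECTORY_COLUMNS = ["particle_id", "frame", "x_um", "y_um", "state_true"]


def _sample_track_lengths(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Frame counts per particle: exponential lifetime, clipped to [2, MAX_FRAMES]."""
    if config.bleach_rate > 0:
        lifetimes = rng.exponential(1.0 / config.bleach_rate, size=config.n_particles)
        n_frames = np.ceil(lifetimes / config.frame_interval).astype(int)
    else:
        n_frames = np.full(config.n_particles, MAX_FRAMES, dtype=int)
    return np.clip(n_frames, 2, MAX_FRAMES)


def simulate_state_paths(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Sample per-particle state sequences at frame resolution.

    Each particle's latent state follows the continuous-time chain defined
    by ``config.rate_matrix``; the returned integer arrays hold the state at
    each frame start.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    q = config.generator
    exit_rates = -np.diag(q)
    t = config.frame_interval
    if config.initial_occupancy is not None:
        p0 = np.asarray(config.initial_occupancy, dtype=float)
    else:
        p0 = config.stationary_distribution()

    n_frames = _sample_track_lengths(config, rng)
    paths: list[np.ndarray] = []
    for n in n_frames:
        path = np.empty(n, dtype=np.int64)
        state = int(rng.choice(config.n_states, p=p0))
        t_now = 0.0  # time of the current jump
        t_next_jump = np.inf
        if exit_rates[state] > 0:
            t_next_jump = rng.exponential(1.0 / exit_rates[state])
        for frame in range(n):
            t_frame = frame * t
            while t_now + t_next_jump <= t_frame:
                t_now += t_next_jump
                probs = q[state].copy()
                probs[state] = 0.0
                probs /= probs.sum()
                state = int(rng.choice(config.n_states, p=probs))
                t_next_jump = (
                    rng.exponential(1.0 / exit_rates[state])
                    if exit_rates[state] > 0
                    else np.inf
                )
            path[frame] = state
        paths.append(path)
    return paths


def simulate_trajectories(
    config: SimulationConfig,
    state_paths: list[np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Brownian trajectories with localization noise on top of state paths.

    Per-frame displacement along each axis is Gaussian with variance
    ``2*D(state)*t``; i.i.d. Gaussian localization noise of std ``loc_sigma``
    is added per coordinate. Both the true and the observed coordinates are
    retained.

    Returns
    -------
    DataFrame with columns particle_id, frame, x_um, y_um (observed),
    x_true_um, y_true_um, state_true.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if state_paths is None:
        state_paths = simulate_state_paths(config, rng)
    D = np.asarray(config.D_per_state, dtype=float)
    t = config.frame_interval
    frames_total = sum(len(p) for p in state_paths)

    pid = np.empty(frames_total, dtype=np.int64)
    frame = np.empty(frames_total, dtype=np.int64)
    xs = np.empty(frames_total)
    ys = np.empty(frames_total)
    states = np.empty(frames_total, dtype=np.int64)
    pos = 0
    for i, path in enumerate(state_paths):
        n = len(path)
        start = rng.uniform(0.0, config.field_size, size=2)
        # displacement from frame k to k+1 is governed by the state at frame k
        sigma = np.sqrt(2.0 * D[path[:-1]] * t)
        steps = rng.normal(0.0, 1.0, size=(n - 1, 2)) * sigma[:, None]
        xy = np.vstack([start, start + np.cumsum(steps, axis=0)])
        sl = slice(pos, pos + n)
        pid[sl] = i
        frame[sl] = np.arange(n)
        xs[sl] = xy[:, 0]
        ys[sl] = xy[:, 1]
        states[sl] = path
        pos += n

    noise = rng.normal(0.0, config.loc_sigma, size=(frames_total, 2))
    return pd.DataFrame(
        {
            "particle_id": pid,
            "frame": frame,
            "x_um": xs + noise[:, 0],
            "y_um": ys + noise[:, 1],
            "x_true_um": xs,
            "y_true_um": ys,
            "state_true": states,
        }
    )


def integrated_gaussian_psf(
    shape: tuple[int, int],
    x0: float,
    y0: float,
    sigma: float,
    photons: float,
    background: float = 0.0,
) -> np.ndarray:
    """Expected photon image of a point emitter: pixel-integrated 2D Gaussian.

    ``x0``/``y0`` are in pixel units with the convention that integer
    coordinates lie at pixel centres (x along columns, y along rows).
    """
    ny, nx = shape
    s = sigma * np.sqrt(2.0)
    xe = np.arange(nx + 1) - 0.5
    ye = np.arange(ny + 1) - 0.5
    fx = 0.5 * np.diff(erf((xe - x0) / s))
    fy = 0.5 * np.diff(erf((ye - y0) / s))
    return photons * np.outer(fy, fx) + background


def apply_emccd(
    photon_image: np.ndarray, params: ImagingParams, rng: np.random.Generator
) -> np.ndarray:
    """Forward camera model: shot noise, EM gain, offset, read noise.

    Returns a 16-bit image in ADU. The single-photon response is ``gain``
    ADU/photon; excess EM noise is not modelled, so the pixel variance obeys
    ``var = gain*(mean-offset) + read_noise^2``.
    """
    electrons = rng.poisson(np.clip(photon_image, 0.0, None))
    adu = (
        params.offset
        + params.gain * electrons
        + rng.normal(0.0, params.read_noise, size=photon_image.shape)
    )
    return np.clip(np.round(adu), 0, 65535).astype(np.uint16)


def render_movie(
    trajectories: pd.DataFrame,
    params: ImagingParams,
    field_size_um: float | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Render trajectories into a TIRF-like 16-bit image stack.

    Each particle in each frame becomes an integrated-Gaussian PSF of
    ``photons_per_spot`` photons on a uniform ``background_photons`` field;
    the image then passes through the EMCCD forward model. Particles outside
    the field contribute only the part of their PSF that overlaps it
    (off-field emitters are silently clipped).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if field_size_um is None:
        field_size_um = max(
            float(trajectories[["x_um", "y_um"]].to_numpy().max(initial=0.0)) + 1.0,
            5 * params.pixel_size_um,
        )
    npx = int(np.ceil(field_size_um / params.pixel_size_um))
    n_frames = int(trajectories["frame"].max()) + 1 if len(trajectories) else 1
    stack = np.empty((n_frames, npx, npx), dtype=np.uint16)
    by_frame = dict(list(trajectories.groupby("frame"))) if len(trajectories) else {}
    half = int(np.ceil(4 * params.psf_sigma_px))
    for f in range(n_frames):
        photons = np.full((npx, npx), params.background_photons, dtype=float)
        for _, row in by_frame.get(f, pd.DataFrame()).iterrows():
            xp = row["x_um"] / params.pixel_size_um
            yp = row["y_um"] / params.pixel_size_um
            cx, cy = int(round(xp)), int(round(yp))
            x_lo, x_hi = max(cx - half, 0), min(cx + half + 1, npx)
            y_lo, y_hi = max(cy - half, 0), min(cy + half + 1, npx)
            if x_lo >= x_hi or y_lo >= y_hi:
                continue  # fully outside: clipped
            patch = integrated_gaussian_psf(
                (y_hi - y_lo, x_hi - x_lo),
                xp - x_lo,
                yp - y_lo,
                params.psf_sigma_px,
                params.photons_per_spot,
            )
            photons[y_lo:y_hi, x_lo:x_hi] += patch
        stack[f] = apply_emccd(photons, params, rng)
    return stack


def write_movie(
    path: str | Path,
    stack: np.ndarray,
    params: ImagingParams,
    frame_interval_s: float,
) -> None:
    """Write a multi-page TIFF plus a JSON metadata sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, stack)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size_um": params.pixel_size_um,
                "frame_interval_s": frame_interval_s,
                "gain": params.gain,
                "offset": params.offset,
                "read_noise": params.read_noise,
            },
            indent=2,
        )
    )


def write_trajectories(path: str | Path, trajectories: pd.DataFrame) -> None:
    """Trajectory CSV: particle_id, frame, x_um, y_um, state_true."""
    cols = [c for c in TRAJECTORY_COLUMNS if c in trajectories.columns]
    trajectories[cols].to_csv(path, index=False)


def read_trajectories(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"particle_id", "frame", "x_um", "y_um"} - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    return df
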