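"""Run configuration objects shared across modules."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

#: Frame interval of the reference TIRF acquisition (80 ms exposure,
#: 81 ms frame-to-frame), in seconds.
DEFAULT_FRAME_INTERVAL_S = 0.081

#: Physical pixel width of the reference camera, in micrometres.
DEFAULT_PIXEL_SIZE_UM = 0.160

#: Field of view of the reference camera (512 px at 160 nm), in micrometres.
DEFAULT_FIELD_SIZE_UM = 81.92

#: Hard cap on track length: acquisitions run 2000 frames per movie.
MAX_FRAMES = 2000


@dataclass
class SimulationConfig:
    """Ground-truth model for the switching-diffusion simulator.

    The default configuration emulates the experimental regime of surface
    SPT of lipases on a lipid film: three mobility states (immobile / slow /
    fast), millisecond-scale frame interval, localization noise whose
    magnitude makes the immobile-state mean step ~0.03 um, exchange rates of
    order 0.3-2.5 per second, and photobleaching-limited track lengths.

    Parameters
    ----------
    n_states:
        Number of diffusional states.
    D_per_state:
        Diffusion coefficient of each state, um^2/s. ``D = 0`` is a valid
        (arrested) state whose apparent motion is pure localization error.
    rate_matrix:
        Off-diagonal entries are transition rates k_ij in 1/s; the diagonal
        is ignored. Switching is simulated as a continuous-time Markov chain
        so dwell times are exponential in real time.
    initial_occupancy:
        Start-state probabilities. ``None`` uses the stationary distribution
        of the rate matrix.
    loc_sigma:
        Localization noise standard deviation per coordinate, um. The
        default ``0.03/sqrt(pi)`` puts the immobile-state mean observed step
        at 0.03 um (Rayleigh mean of the two-point difference).
    frame_interval:
        Time between frames, s.
    bleach_rate:
        Photobleaching rate, 1/s; track lifetimes are exponential with this
        rate, truncated at ``MAX_FRAMES``.
    n_particles:
        Number of independent trajectories to simulate.
    field_size:
        Side of the square field of view, um.
    seed:
        Mandatory seed for reproducibility.
    """

    n_states: int = 3
    D_per_state: tuple = (0.0, 0.01, 0.1)
    rate_matrix: tuple = (
        (0.0, 1.50, 0.27),
        (0.905, 0.0, 0.299),
        (1.35, 2.48, 0.0),
    )
    initial_occupancy: tuple | None = None
    loc_sigma: float = 0.03 / np.sqrt(np.pi)
    frame_interval: float = DEFAULT_FRAME_INTERVAL_S
    bleach_rate: float = 0.2
    n_particles: int = 1000
    field_size: float = DEFAULT_FIELD_SIZE_UM
    seed: int = 0

    def __post_init__(self):
        self.D_per_state = tuple(float(d) for d in np.atleast_1d(self.D_per_state))
        self.rate_matrix = tuple(
            tuple(float(x) for x in row) for row in np.atleast_2d(self.rate_matrix)
        )
        q = np.asarray(self.rate_matrix, dtype=float)
        if q.shape != (self.n_states, self.n_states):
            raise ValueError(
                f"rate_matrix shape {q.shape} does not match n_states={self.n_states}"
            )
        if len(self.D_per_state) != self.n_states:
            raise ValueError("D_per_state length must equal n_states")
        if any(d < 0 for d in self.D_per_state):
            raise ValueError("diffusion coefficients must be >= 0")
        off = q[~np.eye(self.n_states, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("transition rates must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.loc_sigma < 0:
            raise ValueError("loc_sigma must be >= 0")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")
        if self.initial_occupancy is not None:
            p = np.asarray(self.initial_occupancy, dtype=float)
            if p.shape != (self.n_states,) or np.any(p < 0):
                raise ValueError("initial_occupancy must be a probability vector")
            if not np.isclose(p.sum(), 1.0, atol=1e-8):
                raise ValueError("initial_occupancy must sum to 1")
            self.initial_occupancy = tuple(float(x) for x in p)

    @property
    def generator(self) -> np.ndarray:
        """Infinitesimal generator Q: off-diagonal rates, rows sum to 0."""
        q = np.asarray(self.rate_matrix, dtype=float).copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary_distribution(self) -> np.ndarray:
        """Stationary probability vector of the continuous-time chain."""
        q = self.generator
        if np.allclose(q, 0.0):
            # no switching: stationary set is anything; use uniform
            return np.full(self.n_states, 1.0 / self.n_states)
        # left null vector of Q
        w, v = np.linalg.eig(q.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        d = json.loads(Path(path).read_text())
        if "seed" not in d:
            raise ValueError("config JSON must carry an explicit seed")
        return cls(**d)


@dataclass
class ImagingParams:
    """Camera and PSF parameters for rendering and calibration.

    ``gain`` is the single-photon response in ADU per photon after electron
    multiplication; ``offset`` the bias level; ``read_noise`` the Gaussian
    readout noise in ADU.
    """

    psf_sigma_px: float = 1.1
    photons_per_spot: float = 500.0
    background_photons: float = 5.0
    gain: float = 20.0
    offset: float = 100.0
    read_noise: float = 5.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.read_noise < 0:
            raise ValueError("read_noise must be >= 0")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be > 0")
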