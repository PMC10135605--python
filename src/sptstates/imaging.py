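"""EMCCD calibration, spot detection, PSF fitting, localization error.

The localization-error procedure follows the simulation route used in
surface SPT: fit each detected PSF, re-render synthetic PSFs with the
fitted parameters through the calibrated camera model at known sub-pixel
centres, re-estimate the centres, and take the distribution of Euclidean
distances to the truth as the localization-error distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from skimage.feature import peak_local_max

from sptstates.config import ImagingParams, DEFAULT_PIXEL_SIZE_UM
from sptstates.simulate import integrated_gaussian_psf, apply_emccd

LOCALIZATION_COLUMNS = [
    "frame",
    "x_px",
    "y_px",
    "x_um",
    "y_um",
    "photons",
    "bg",
    "width_px",
    "loc_error_um",
]


@dataclass
class EMCCDModel:
    """Linear photon-transfer model: ADU = offset + gain * photons (+ noise)."""

    offset: float
    gain: float  # ADU per photon
    read_noise: float  # ADU std at zero illumination

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.read_noise < 0:
            raise ValueError("read_noise must be >= 0")

    def to_photons(self, frame: np.ndarray) -> np.ndarray:
        return (np.asarray(frame, dtype=float) - self.offset) / self.gain


@dataclass
class PSFFit:
    """Symmetric 2D Gaussian fit of one cropped spot (photon units)."""

    x: float  # sub-pixel, crop coordinates
    y: float
    width: float  # Gaussian sigma, px
    photons: float
    background: float  # photons per pixel
    converged: bool


def calibrate_emccd(background_stack: np.ndarray, saturation: int = 65000) -> EMCCDModel:
    """Photon-transfer calibration from a particle-free background stack.

    Uses the per-pixel mean-variance relation ``var = gain*(mean - offset)
    + read_noise^2``: the gain is the OLS slope of variance on mean, the
    offset is a robust floor of the per-pixel means (the stack is assumed
    to contain some essentially unilluminated pixels), and the read noise
    is the residual std at zero illumination.

    Parameters
    ----------
    background_stack:
        (n_frames, ny, nx) array, >= 10 frames, no particles. Pixels that
        ever reach ``saturation`` ADU are excluded.
    """
    stack = np.asarray(background_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 10:
        raise ValueError("need a (n_frames, ny, nx) stack with >= 10 frames")
    ok = stack.max(axis=0) < saturation
    means = stack.mean(axis=0)[ok].ravel()
    variances = stack.var(axis=0, ddof=1)[ok].ravel()
    if means.size < 2 or np.ptp(means) < 1e-9 or variances.max() < 1e-12:
        raise ValueError("background stack carries no mean-variance spread; "
                         "gain is indeterminate")
    slope, intercept = np.polyfit(means, variances, 1)
    if slope <= 0:
        raise ValueError("non-positive mean-variance slope; gain indeterminate")
    offset = float(np.percentile(means, 0.5))
    rn_var = slope * offset + intercept
    read_noise = float(np.sqrt(max(rn_var, 0.0)))
    return EMCCDModel(offset=offset, gain=float(slope), read_noise=read_noise)


def detect_spots(
    frame: np.ndarray,
    emccd: EMCCDModel | None = None,
    min_separation: int = 5,
    threshold: float = 10.0,
) -> np.ndarray:
    """Local-maximum spot candidates in photon units.

    Returns an (n, 2) array of (x, y) pixel positions. Maxima closer than
    ``min_separation`` pixels are merged into the brightest one
    (non-maximum suppression), so near-coincident emitters yield a single
    detection.
    """
    img = emccd.to_photons(frame) if emccd is not None else np.asarray(frame, float)
    bg = np.median(img)
    peaks = peak_local_max(
        img, min_distance=min_separation, threshold_abs=bg + threshold
    )
    if peaks.size == 0:
        return np.empty((0, 2))
    return peaks[:, ::-1].astype(float)  # (row, col) -> (x, y)


def _psf_residual(p, crop, yy, xx):
    x0, y0, sigma, photons, bg = p
    model = integrated_gaussian_psf(crop.shape, x0, y0, sigma, photons, bg)
    return (model - crop).ravel()


def fit_psf(crop: np.ndarray, initial_guess: dict | None = None) -> PSFFit:
    """Least-squares fit of a symmetric integrated 2D Gaussian + background.

    ``crop`` is a square patch in photon units (default use: 9x9 px around a
    detection). The centre is reported in crop pixel coordinates.
    """
    crop = np.asarray(crop, dtype=float)
    ny, nx = crop.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    if initial_guess is None:
        bg0 = float(np.percentile(crop, 20))
        w = np.clip(crop - bg0, 0, None)
        total = w.sum()
        if total <= 0:
            x0, y0, n0 = (nx - 1) / 2, (ny - 1) / 2, 1.0
        else:
            x0 = float((w * xx).sum() / total)
            y0 = float((w * yy).sum() / total)
            n0 = float(total)
        p0 = [x0, y0, 1.2, max(n0, 1.0), max(bg0, 0.0)]
    else:
        p0 = [
            initial_guess.get("x", (nx - 1) / 2),
            initial_guess.get("y", (ny - 1) / 2),
            initial_guess.get("width", 1.2),
            initial_guess.get("photons", max(float(crop.sum()), 1.0)),
            initial_guess.get("background", 0.0),
        ]
    bounds = ([-2.0, -2.0, 0.2, 0.0, -np.inf], [nx + 1.0, ny + 1.0, nx, np.inf, np.inf])
    p0 = np.clip(p0, bounds[0], bounds[1])
    try:
        res = least_squares(
            _psf_residual, p0, args=(crop, yy, xx), bounds=bounds, xtol=1e-12, ftol=1e-12
        )
        converged = res.success
        x0, y0, sigma, photons, bg = res.x
    except Exception:
        converged = False
        x0, y0, sigma, photons, bg = p0
    return PSFFit(
        x=float(x0), y=float(y0), width=float(sigma),
        photons=float(photons), background=float(bg), converged=bool(converged),
    )


@dataclass
class LocalizationError:
    """Simulation-based localization-error distribution."""

    errors_um: np.ndarray
    mean_um: float


def estimate_localization_error(
    psf_fits: list[PSFFit],
    emccd: EMCCDModel,
    n_sim: int = 100,
    seed: int = 0,
    crop_size: int = 9,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> LocalizationError:
    """Monte-Carlo localization error from fitted PSF parameters.

    For every converged fit, ``n_sim`` synthetic PSFs with the fitted
    photon count, width and background are rendered at known random
    sub-pixel centres, passed through the camera model, converted back to
    photons, and re-fitted with the same Gaussian estimator; the Euclidean
    distance between the re-estimated and true centre is one error sample.
    """
    fits = [f for f in psf_fits if f.converged]
    if not fits:
        raise ValueError("need at least one converged PSF fit")
    if n_sim < 10:
        raise ValueError("n_sim must be >= 10")
    rng = np.random.default_rng(seed)
    params = ImagingParams(
        gain=emccd.gain, offset=emccd.offset, read_noise=emccd.read_noise,
        pixel_size_um=pixel_size_um,
    )
    c = (crop_size - 1) / 2
    errors = []
    for fit in fits:
        for _ in range(n_sim):
            x0 = c + rng.uniform(-0.5, 0.5)
            y0 = c + rng.uniform(-0.5, 0.5)
            photons = integrated_gaussian_psf(
                (crop_size, crop_size), x0, y0, fit.width,
                fit.photons, max(fit.background, 0.0),
            )
            adu = apply_emccd(photons, params, rng)
            refit = fit_psf(emccd.to_photons(adu))
            if not refit.converged:
                continue
            errors.append(np.hypot(refit.x - x0, refit.y - y0) * pixel_size_um)
    errors = np.asarray(errors)
    return LocalizationError(errors_um=errors, mean_um=float(errors.mean()))


def localize_movie(
    stack: np.ndarray,
    emccd: EMCCDModel,
    min_separation: int = 5,
    threshold: float = 10.0,
    crop_size: int = 9,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    loc_error_um: float | None = None,
) -> pd.DataFrame:
    """Detect and fit all spots in a stack; one localization per row.

    ``loc_error_um`` fills the per-row localization-error column (e.g. the
    sample mean from :func:`estimate_localization_error`); NaN when not
    supplied.
    """
    half = crop_size // 2
    rows = []
    for f, frame in enumerate(stack):
        photons = emccd.to_photons(frame)
        for x, y in detect_spots(photons, None, min_separation, threshold):
            cx, cy = int(round(x)), int(round(y))
            if (cx - half < 0 or cy - half < 0
                    or cx + half + 1 > photons.shape[1]
                    or cy + half + 1 > photons.shape[0]):
                continue
            crop = photons[cy - half:cy + half + 1, cx - half:cx + half + 1]
            fit = fit_psf(crop)
            if not fit.converged:
                continue
            x_px = cx - half + fit.x
            y_px = cy - half + fit.y
            rows.append(
                {
                    "frame": f,
                    "x_px": x_px,
                    "y_px": y_px,
                    "x_um": x_px * pixel_size_um,
                    "y_um": y_px * pixel_size_um,
                    "photons": fit.photons,
                    "bg": fit.background,
                    "width_px": fit.width,
                    "loc_error_um": np.nan if loc_error_um is None else loc_error_um,
                }
            )
    return pd.DataFrame(rows, columns=LOCALIZATION_COLUMNS)
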