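"""Polychromatic measurement model: Beer-Lambert projection with an
energy-integrating detector, the beam-hardening mismatch term, photon and
electronic noise, and per-view rigid motion corruption.

For a discrete spectrum with weights ``w_k`` at energies ``E_k`` the
measured log-attenuation along a ray is::

    P = -ln( sum_k w_k * exp(-F u_{E_k}) )

with ``F`` the discrete X-ray transform and ``u_E`` the attenuation
image at energy ``E``.  The mismatch relative to a chosen monochromatic
reference image ``u`` is ``zeta_u = P - F u``; the decomposition
``P = F u + zeta_u`` is an algebraic identity and is preserved here to
floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import logsumexp

from .geometry import ProjectionGeometry, SystemMatrix, forward_project
from .materials import Spectrum, monochrome_image
from .phantoms import MotionTrajectory, Phantom

__all__ = [
    "Sinogram",
    "poly_project",
    "mismatch_zeta_u",
    "add_photon_noise",
    "motion_corrupt",
]


@dataclass(frozen=True)
class Sinogram:
    """Log-attenuation projection values with their geometry."""

    values: np.ndarray
    geometry: ProjectionGeometry
    provenance: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.geometry.sinogram_shape:
            raise ValueError(
                f"values shape {v.shape} != geometry shape {self.geometry.sinogram_shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("sinogram values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_views(self) -> int:
        return self.values.shape[0]


def _energy_line_integrals(phantom: Phantom, spectrum: Spectrum, matrix: SystemMatrix):
    """Line integrals of u_E for every spectrum energy; shape (n_bins, n_rays)."""
    out = np.empty((spectrum.n_bins, matrix.n_rays))
    for k, E in enumerate(spectrum.energies):
        # attenuation tables are per unit length; Siddon lengths carry
        # the physical pixel size, so no extra scaling is applied here
        out[k] = forward_project(matrix, monochrome_image(phantom, E)).ravel()
    return out


def _eid_log(line_integrals: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """-ln(sum_k w_k exp(-l_k)) with log-sum-exp stabilisation."""
    return -logsumexp(-line_integrals, axis=0, b=weights[:, None])


def poly_project(phantom: Phantom, spectrum: Spectrum, matrix: SystemMatrix,
                 provenance: str = "poly_project") -> Sinogram:
    """Polychromatic Beer-Lambert projection of a phantom.

    For a delta (single-energy) spectrum this reduces exactly to the
    monochromatic forward projection of ``u_E0``.
    """
    li = _energy_line_integrals(phantom, spectrum, matrix)
    P = _eid_log(li, spectrum.weights)
    return Sinogram(P.reshape(matrix.geometry.sinogram_shape), matrix.geometry, provenance)


def mismatch_zeta_u(phantom: Phantom, spectrum: Spectrum, matrix: SystemMatrix,
                    reference_image: np.ndarray) -> Sinogram:
    """Beam-hardening mismatch of the polychromatic data relative to the
    monochromatic model ``F reference_image``.

    Satisfies ``poly_project = forward_project(reference) + zeta_u``
    identically (up to round-off).
    """
    ref = np.asarray(reference_image, dtype=float)
    if ref.size != matrix.n_pixels:
        raise ValueError("reference image does not match the grid")
    li = _energy_line_integrals(phantom, spectrum, matrix)
    r = forward_project(matrix, ref).ravel()
    zeta = _eid_log(li - r[None, :], spectrum.weights)
    return Sinogram(zeta.reshape(matrix.geometry.sinogram_shape), matrix.geometry,
                    "mismatch_zeta_u")


def add_photon_noise(sinogram: Sinogram, phantom: Phantom, spectrum: Spectrum,
                     matrix: SystemMatrix, I_in: float, electronic_sd: float = 0.0,
                     rng_seed: int = 0) -> Sinogram:
    """Quantum + electronic noise for an energy-integrating detector.

    Per ray and energy bin, photon counts are Poisson with mean
    ``I_in * w_k * exp(-l_k)``; bin counts are summed, zero-mean Gaussian
    electronic noise of standard deviation ``electronic_sd`` is added,
    the total is clamped to one count, and the noisy log value is
    ``-ln(total / I_in)``.  Reproducible for a fixed seed.
    """
    if I_in <= 0:
        raise ValueError("I_in must be positive")
    rng = np.random.default_rng(rng_seed)
    li = _energy_line_integrals(phantom, spectrum, matrix)
    mean_counts = I_in * spectrum.weights[:, None] * np.exp(-li)
    counts = rng.poisson(mean_counts).astype(float).sum(axis=0)
    if electronic_sd > 0:
        counts = counts + rng.normal(0.0, electronic_sd, size=counts.shape)
    counts = np.maximum(counts, 1.0)
    P = -np.log(counts / I_in)
    return Sinogram(P.reshape(matrix.geometry.sinogram_shape), matrix.geometry,
                    f"{sinogram.provenance} | noise(I_in={I_in:g}, sd={electronic_sd:g}, seed={rng_seed})")


def _shifted_mono_images(phantom: Phantom, spectrum: Spectrum, shift_rows: float):
    """Attenuation images per energy, rigidly shifted along y.

    Labels are never interpolated: the material-derived attenuation
    images are resampled bilinearly.  A displacement of +d (towards the
    top of the image, +y) maps output row i to input row i + d/px.
    """
    out = []
    for E in spectrum.energies:
        uE = monochrome_image(phantom, E)
        if shift_rows != 0.0:
            uE = ndimage.shift(uE, (-shift_rows,) + (0,) * (uE.ndim - 1),
                               order=1, mode="constant", cval=0.0, prefilter=False)
        out.append(uE)
    return out


def motion_corrupt(phantom: Phantom, trajectory: MotionTrajectory,
                   matrix: SystemMatrix, spectrum: Spectrum) -> Sinogram:
    """Polychromatic projection of a phantom that rigidly translates
    along y between views.

    Views with zero displacement are bitwise identical to the static
    :func:`poly_project` result (the same matrix rows act on the same
    attenuation images).
    """
    geom = matrix.geometry
    if trajectory.n_views != geom.n_views:
        raise ValueError("trajectory length must equal n_views")
    shape = geom.sinogram_shape
    rays_per_view = int(np.prod(shape[1:]))
    static_mono = _shifted_mono_images(phantom, spectrum, 0.0)
    P = np.empty(geom.n_rays)
    A = matrix.matrix
    for v in range(geom.n_views):
        d = trajectory.displacements[v]
        mono = static_mono if d == 0.0 else _shifted_mono_images(
            phantom, spectrum, d / phantom.pixel_size)
        rows = slice(v * rays_per_view, (v + 1) * rays_per_view)
        Av = A[rows]
        li = np.stack([Av @ m.ravel() for m in mono])
        P[v * rays_per_view:(v + 1) * rays_per_view] = _eid_log(li, spectrum.weights)
    prov = f"motion_corrupt(window={trajectory.active_window})"
    return Sinogram(P.reshape(shape), geom, prov)
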