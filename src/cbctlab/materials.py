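"""Energy grids, fractional X-ray spectra and material attenuation curves.

An energy-integrated detector measures ``P = -ln( sum_k w_k exp(-line
integral of u_{E_k}) )`` where the weights ``w_k`` form a discrete
fractional spectrum (they sum to one) and ``u_E`` is the linear
attenuation coefficient of the traversed materials at energy ``E``.
This module provides the two ingredients every forward model needs:
:class:`Spectrum` (the ``w_k`` at energies ``E_k``) and :class:`Material`
(a tabulated attenuation curve ``E -> u_E``).

Units: toy-model attenuation values are per pixel side length
(dimensionless path lengths); the dental presets use per-pixel values on
the same convention, with the phantom carrying the physical pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "Material",
    "make_spectrum",
    "attenuation_at",
    "monochrome_image",
    "SPECTRUM_PRESETS",
    "MATERIAL_PRESETS",
]


@dataclass(frozen=True)
class Spectrum:
    """Discrete fractional photon-energy distribution.

    Parameters
    ----------
    energies : ndarray
        Photon energies in keV, strictly increasing.
    weights : ndarray
        Fractional intensities; nonnegative, summing to one.
    """

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.ndim != 1 or e.size < 1:
            raise ValueError("spectrum needs at least one energy")
        if e.size != w.size:
            raise ValueError("energies and weights must have equal length")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        s = w.sum()
        if not np.isclose(s, 1.0, atol=1e-12):
            raise ValueError("weights must sum to 1 (use make_spectrum)")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)

    @property
    def n_bins(self) -> int:
        return self.energies.size


@dataclass(frozen=True)
class Material:
    """A named material with a tabulated attenuation curve.

    ``atten_table`` rows are ``(energy_keV, mu)`` pairs with strictly
    increasing energies and nonnegative attenuation values.
    """

    name: str
    atten_table: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.atleast_2d(np.asarray(self.atten_table, dtype=float))
        if t.shape[0] < 1 or t.shape[1] != 2:
            raise ValueError("atten_table must be a nonempty (n, 2) array")
        if np.any(np.diff(t[:, 0]) <= 0):
            raise ValueError("table energies must be strictly increasing")
        if np.any(t[:, 1] < 0):
            raise ValueError("attenuation values must be nonnegative")
        object.__setattr__(self, "atten_table", t)


def make_spectrum(energies, weights) -> Spectrum:
    """Build a normalized :class:`Spectrum`.

    Weights are divided by their sum, so any nonnegative, not-all-zero
    intensity list is accepted.
    """
    e = np.asarray(energies, dtype=float)
    w = np.asarray(weights, dtype=float)
    if e.size == 0 or w.size == 0:
        raise ValueError("empty spectrum")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    s = w.sum()
    if s <= 0:
        raise ValueError("weights must not all be zero")
    return Spectrum(e, w / s)


def attenuation_at(material: Material, energy: float):
    """Attenuation of ``material`` at ``energy`` (keV).

    Exact at tabulated energies; log-linear interpolation in between
    (standard for attenuation-vs-energy curves, and exact on two-point
    tables); clamped to the nearest endpoint outside the table range.
    Zero table values fall back to linear interpolation since the
    logarithm is undefined there.
    """
    t = material.atten_table
    e_grid, mu = t[:, 0], t[:, 1]
    # clamp onto the table range so endpoint values return exactly
    energy = np.clip(np.asarray(energy, dtype=float), e_grid[0], e_grid[-1])
    if np.all(mu > 0):
        out = np.exp(np.interp(energy, e_grid, np.log(mu)))
    else:
        out = np.interp(energy, e_grid, mu)
    # snap exactly onto grid points to avoid interpolation round-off
    exact = energy[..., None] == e_grid if energy.ndim else energy == e_grid
    if energy.ndim == 0:
        if np.any(exact):
            return float(mu[np.argmax(exact)])
        return float(out)
    hit = exact.any(axis=-1)
    if np.any(hit):
        out = np.where(hit, mu[np.argmax(exact, axis=-1)], out)
    return out


def monochrome_image(phantom, energy: float) -> np.ndarray:
    """Map a material-label phantom to its attenuation image ``u_E``.

    Every label must be registered in ``phantom.material_map``; the
    output has the phantom's grid shape.  The map is label-local:
    changing one pixel's label changes exactly one output pixel.
    """
    labels = np.asarray(phantom.labels)
    out = np.zeros(labels.shape, dtype=float)
    present = np.unique(labels)
    for lab in present:
        if lab not in phantom.material_map:
            raise KeyError(f"label {lab} has no registered material")
        out[labels == lab] = attenuation_at(phantom.material_map[lab], energy)
    return out


def _mat(name, table):
    return Material(name, np.asarray(table, dtype=float))


#: Bichromatic 64/80 keV spectrum of the 3x3 worked example.
SPECTRUM_PRESETS = {
    "toy_bichromatic": make_spectrum([64.0, 80.0], [0.5, 0.5]),
    # three-bin spectrum for the dental phantom experiments
    "water_bone_metal_3bin": make_spectrum([50.0, 70.0, 90.0], [0.3, 0.4, 0.3]),
    "dental_bichromatic": make_spectrum([60.0, 90.0], [0.5, 0.5]),
}

#: Attenuation tables.  Toy values reproduce the printed worked example;
#: the dental values are per-pixel coefficients chosen so that metal
#: dominates beam hardening while tissue and bone vary mildly with E.
MATERIAL_PRESETS = {
    "air": _mat("air", [[1.0, 0.0], [200.0, 0.0]]),
    "toy_metal": _mat("toy_metal", [[64.0, 64.0], [80.0, 5.0]]),
    "soft_tissue": _mat(
        "soft_tissue", [[50.0, 0.022], [60.0, 0.021], [70.0, 0.021], [90.0, 0.020]]
    ),
    "bone": _mat("bone", [[50.0, 0.048], [60.0, 0.046], [70.0, 0.045], [90.0, 0.044]]),
    "tooth": _mat("tooth", [[50.0, 0.058], [60.0, 0.056], [70.0, 0.054], [90.0, 0.052]]),
    "metal": _mat("metal", [[50.0, 0.90], [60.0, 0.60], [70.0, 0.40], [90.0, 0.12]]),
}
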