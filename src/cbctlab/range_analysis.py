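"""Sinogram range-space consistency analysis.

The sinogram space splits orthogonally into the range of the discrete
X-ray transform and its complement; least-squares reconstruction only
ever sees the range component, so a *local* inconsistency (e.g. beam
hardening confined to the metal trace) spreads *globally* once the data
are projected onto the range.  This module computes that orthogonal
decomposition, checks the fidelity equivalence between fitting ``P`` and
fitting ``P_range``, runs the two-metal nonlinear interaction
experiment, and probes empirical restricted-isometry bounds of the
forward operator on the phantom distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict

import numpy as np
from scipy.sparse.linalg import lsmr

from .forward import Sinogram, poly_project
from .geometry import SystemMatrix, forward_project
from .materials import Spectrum
from .phantoms import Phantom, insert_metal
from .recon import fbp2d

__all__ = [
    "RangeDecomposition",
    "project_onto_range",
    "fidelity_equivalence_check",
    "interaction_experiment",
    "empirical_rip",
]


@dataclass(frozen=True)
class RangeDecomposition:
    """Orthogonal split ``P = P_range + P_perp`` with the LS solution."""

    p_range: Sinogram
    p_perp: Sinogram
    ls_solution: np.ndarray
    residual_norm: float


def _ls_solve(matrix: SystemMatrix, p: np.ndarray, tol: float) -> np.ndarray:
    A = matrix.matrix
    if A.shape[0] * A.shape[1] <= 512 * 512 * 16:
        from scipy.linalg import lstsq

        x, *_ = lstsq(A.toarray(), p, lapack_driver="gelsd")
        return x
    res = lsmr(A, p, atol=tol, btol=tol, maxiter=8 * A.shape[1])
    return res[0]


def project_onto_range(matrix: SystemMatrix, sinogram, tol: float = 1e-10) -> RangeDecomposition:
    """Orthogonally project a sinogram onto the range of the forward
    operator via least squares on the explicit sparse matrix.

    ``p_range = A u_ls`` and ``p_perp = P - p_range`` satisfy
    ``A^T p_perp ~ 0`` to solver tolerance, hence Pythagoras
    ``||P||^2 = ||p_range||^2 + ||p_perp||^2``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    p = sinogram.values.ravel() if isinstance(sinogram, Sinogram) else np.asarray(sinogram, float).ravel()
    geom = matrix.geometry
    x = _ls_solve(matrix, p, tol)
    pr = matrix.matrix @ x
    pp = p - pr
    shape = geom.sinogram_shape
    return RangeDecomposition(
        p_range=Sinogram(pr.reshape(shape), geom, "p_range"),
        p_perp=Sinogram(pp.reshape(shape), geom, "p_perp"),
        ls_solution=x.reshape(matrix.grid_shape),
        residual_norm=float(np.linalg.norm(pp)),
    )


def fidelity_equivalence_check(matrix: SystemMatrix, sinogram, tol: float = 1e-6) -> Dict:
    """Verify that minimising ``||P - Au||`` and ``||P_range - Au||``
    give the same solution (they differ only by the orthogonal
    component, which no ``Au`` can reach)."""
    dec = project_onto_range(matrix, sinogram, min(tol, 1e-8))
    u1 = dec.ls_solution.ravel()
    u2 = _ls_solve(matrix, dec.p_range.values.ravel(), min(tol, 1e-8))
    denom = max(np.linalg.norm(u1), 1e-30)
    rel = float(np.linalg.norm(u1 - u2) / denom)
    return {"relative_difference": rel, "passed": rel < tol, "tol": tol}


def interaction_experiment(base_phantom: Phantom, disk1, disk2,
                           spectrum: Spectrum, matrix: SystemMatrix,
                           pixel_size: float = 1.0) -> Dict:
    """Two-metal nonlinear interaction experiment.

    Builds four phantoms (metal-free, D1 only, D2 only, D1 and D2),
    projects each polychromatically, and forms the combination
    ``P_{D1 u D2} + P_free - (P_{D1} + P_{D2})`` together with its FBP
    difference image.  Along rays that miss at least one metal the four
    material compositions cancel pairwise, so the difference vanishes
    identically; along rays crossing both metals the combined beam
    hardening is stronger, making the difference nonpositive.

    ``disk1``/``disk2`` are ``(center, radius)`` pairs; the disks must
    be disjoint.
    """
    (c1, r1), (c2, r2) = disk1, disk2
    if np.linalg.norm(np.asarray(c1, float) - np.asarray(c2, float)) <= r1 + r2:
        raise ValueError("metal disks must be disjoint")
    free = base_phantom
    ph1 = insert_metal(free, c1, r1)
    ph2 = insert_metal(free, c2, r2)
    ph12 = insert_metal(ph1, c2, r2)
    P = {name: poly_project(ph, spectrum, matrix).values
         for name, ph in (("free", free), ("d1", ph1), ("d2", ph2), ("d12", ph12))}
    diff = P["d12"] + P["free"] - P["d1"] - P["d2"]
    mask1 = (ph1.labels != free.labels).astype(float)
    mask2 = (ph2.labels != free.labels).astype(float)
    hits1 = forward_project(matrix, mask1) > 1e-12
    hits2 = forward_project(matrix, mask2) > 1e-12
    classification = np.zeros(hits1.shape, dtype=np.int8)
    classification[hits1 ^ hits2] = 1
    classification[hits1 & hits2] = 2
    geom = matrix.geometry
    diff_sino = Sinogram(diff, geom, "interaction difference")
    result = {
        "difference_sinogram": diff_sino,
        "classification": classification,  # 0 miss, 1 one metal, 2 both
        "projections": P,
    }
    if geom.kind == "parallel2d":
        result["difference_image"] = fbp2d(
            diff_sino, grid_shape=matrix.grid_shape, pixel_size=pixel_size).image
    return result


def empirical_rip(matrix: SystemMatrix, phantom_sampler: Callable[[int], np.ndarray],
                  n_pairs: int = 20, seed: int = 0) -> Dict:
    """Empirical restricted-isometry diagnostic of the forward operator.

    Samples image pairs from ``phantom_sampler`` (a callable mapping a
    seed to an image on the matrix grid) and reports the extreme ratios
    ``||A(u - u')|| / ||u - u'||`` plus the implied isometry constant
    ``C = max(c_high, 1/c_low)``.  This is a diagnostic on the sampled
    image family, not a certificate.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    rng = np.random.default_rng(seed)
    ratios = []
    A = matrix.matrix
    for _ in range(n_pairs):
        s1, s2 = rng.integers(0, 2**31 - 1, size=2)
        u1 = np.asarray(phantom_sampler(int(s1)), dtype=float).ravel()
        u2 = np.asarray(phantom_sampler(int(s2)), dtype=float).ravel()
        d = u1 - u2
        nd = np.linalg.norm(d)
        if nd == 0:
            continue
        ratios.append(np.linalg.norm(A @ d) / nd)
    ratios = np.asarray(ratios)
    if ratios.size == 0:
        raise ValueError("sampler produced only identical pairs")
    c_low, c_high = float(ratios.min()), float(ratios.max())
    return {"c_low": c_low, "c_high": c_high,
            "C": float(max(c_high, 1.0 / c_low)) if c_low > 0 else np.inf,
            "n_pairs": int(ratios.size)}
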