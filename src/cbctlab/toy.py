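"""The bichromatic 3x3 worked example, end to end.

A 3x3 grid with two metal pixels is measured at three views (0, pi/4,
pi/2) and three detector positions by a two-energy beam (64 and 80 keV,
equal weights; metal attenuation 64 and 5 per unit path).  Rays crossing
one metal pixel read -ln(0.5 e^-64 + 0.5 e^-5) = 5.693 and the ray
through both metals reads 10.693 < 2 * 5.693: beam hardening makes the
data subadditive, so the nine linear equations are inconsistent and the
least-squares image smears artefacts over the whole grid.

The projection values are always recomputed through the polychromatic
forward model, so this doubles as an integration test of the materials
and projection modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .forward import poly_project
from .geometry import TOY_RAY_LABELS, build_system_matrix, toy_geometry
from .materials import SPECTRUM_PRESETS
from .phantoms import make_toy_phantom
from .recon import lsq_minnorm

__all__ = ["ToySystem", "toy_system", "toy_reconstruct", "PRINTED_RECONSTRUCTION"]

#: Reconstructed image printed in the source material for this example,
#: shipped for side-by-side comparison only.  It does not satisfy the
#: normal equations of the system below (the solver that produced it is
#: unidentified), so no equality is asserted anywhere.
PRINTED_RECONSTRUCTION = np.array([
    [-1.0, 2.2, 0.4],
    [6.8, 2.5, 6.3],
    [0.2, -0.5, 0.7],
])


@dataclass(frozen=True)
class ToySystem:
    """The 9x9 incidence matrix, its projections and ray labels."""

    matrix: np.ndarray
    p: np.ndarray
    ray_labels: List[Tuple[float, int]]


def toy_system() -> ToySystem:
    """Build the toy system with projections computed from the
    bichromatic Beer-Lambert model (never hard-coded)."""
    phantom = make_toy_phantom()
    sm = build_system_matrix(toy_geometry(), (3, 3), 1.0)
    sino = poly_project(phantom, SPECTRUM_PRESETS["toy_bichromatic"], sm)
    return ToySystem(sm.matrix.toarray(), sino.values.ravel(), list(TOY_RAY_LABELS))


def toy_reconstruct(consistent: bool = False) -> Dict:
    """Minimum-norm least-squares reconstruction of the toy system.

    With ``consistent=True`` the double-metal reading is replaced by
    twice the single-metal value; the system then has the ideal image as
    its exact minimum-norm solution (the ideal is orthogonal to the
    one-dimensional null space).  With the measured (inconsistent) data
    the solution spreads artefacts onto non-metal pixels.
    """
    sys = toy_system()
    sm = build_system_matrix(toy_geometry(), (3, 3), 1.0)
    p = sys.p.copy()
    single = p[0]
    if consistent:
        p[7] = 2.0 * single
    sol = lsq_minnorm(sm, p.reshape(3, 3)).image
    ideal = np.zeros((3, 3))
    ideal[1, 0] = ideal[1, 2] = single
    return {
        "solution": sol,
        "ideal": ideal,
        "paper_printed": PRINTED_RECONSTRUCTION,
        "deltas": {
            "vs_ideal": sol - ideal,
            "vs_printed": sol - PRINTED_RECONSTRUCTION,
        },
        "residual_norm": float(np.linalg.norm(sys.matrix @ sol.ravel() - p)),
        "p": p,
    }
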