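"""Orientation of shift tensors relative to their local peptide plane.

For an amide nitrogen the peptide plane P_N is spanned by the {N, H, CA}
coordinates of the residue; for a carbonyl carbon the plane P_C uses
{C', O', CA}. Three angles locate the tensor eigenframe:

15N (eigenvectors xi1, xi2, xi3 for sigma11 >= sigma22 >= sigma33; xi3 is
the least-shielded / delta33 direction):

* alpha — elevation of xi3 out of P_N (0 when xi3 lies in the plane);
* beta  — angle between xi3 and the N-H bond vector;
* gamma — angle between xi2 and the normal of P_N.

13C swaps the roles: alpha is the elevation of xi2 out of P_C, beta the
angle between xi2 and the C'=O' bond, gamma the angle between xi1 and the
normal of P_C (the carbonyl delta22 direction lies nearly along C=O, with
delta11 near the plane normal).

Eigenvectors are axes, not arrows, so every angle is folded to its acute
value in [0, 90] degrees; this makes all three angles insensitive to any
eigenvector sign choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .peptide_geometry import ResidueFrame, acute_angle, unit
from .tensor_core import PrincipalFrame

__all__ = [
    "PeptidePlane",
    "OrientationAngles",
    "UndefinedPlaneError",
    "plane_N",
    "plane_C",
    "orientation_angles_15N",
    "orientation_angles_13C",
]


class UndefinedPlaneError(ValueError):
    """The residue cannot define the requested peptide plane (e.g. Pro for P_N)."""


@dataclass
class PeptidePlane:
    """A peptide plane: origin at the nucleus, unit normal, in-plane bond."""

    origin: np.ndarray
    normal: np.ndarray
    in_plane_bond: np.ndarray  # N->H for P_N, C'->O' for P_C
    triple: tuple = ()

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.normal = unit(self.normal)
        self.in_plane_bond = unit(self.in_plane_bond)
        if abs(np.dot(self.normal, self.in_plane_bond)) > 1e-8:
            raise ValueError("plane normal not perpendicular to in-plane bond")


@dataclass
class OrientationAngles:
    alpha: float
    beta: float
    gamma: float
    site_key: Optional[tuple] = None

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not (0.0 <= v <= 90.0 + 1e-9):
                raise ValueError(f"{name}={v} outside [0, 90] degrees")


def _make_plane(origin, bond_target, third, labels) -> PeptidePlane:
    bond = bond_target - origin
    arm = third - origin
    n = np.cross(bond, arm)
    if np.linalg.norm(n) < 1e-10:
        raise UndefinedPlaneError(f"collinear atoms {labels}: plane undefined")
    n = unit(n)
    if n[2] < 0:  # sign convention only; downstream angles are sign-insensitive
        n = -n
    return PeptidePlane(origin=origin, normal=n, in_plane_bond=unit(bond), triple=labels)


def plane_N(residue: ResidueFrame) -> PeptidePlane:
    """Amide plane P_N through {N, H, CA}; in-plane bond is N->H.

    Prolines (no amide H) and residues missing any of the three atoms raise
    :class:`UndefinedPlaneError` — their orientation angles are undefined.
    """
    if residue.residue_class == "Pro":
        raise UndefinedPlaneError(f"residue {residue.index} is proline: no amide H")
    if residue.N is None or residue.H is None or residue.CA is None:
        raise UndefinedPlaneError(
            f"residue {residue.index}: N/H/CA required for the amide plane"
        )
    return _make_plane(residue.N, residue.H, residue.CA,
                       labels=(residue.index, "N", "H", "CA"))


def plane_C(residue: ResidueFrame) -> PeptidePlane:
    """Carbonyl plane P_C through {C', O', CA}; in-plane bond is C'->O'.

    Defined for prolines too (they have a carbonyl); a C-terminal residue
    without carbonyl oxygen (e.g. phenylalaninol) raises.
    """
    if residue.C is None or residue.O is None or residue.CA is None:
        raise UndefinedPlaneError(
            f"residue {residue.index}: C'/O'/CA required for the carbonyl plane"
        )
    return _make_plane(residue.C, residue.O, residue.CA,
                       labels=(residue.index, "C", "O", "CA"))


def _angles(in_plane_vec, normal_vec, plane, site_key) -> OrientationAngles:
    # alpha: out-of-plane elevation = 90 deg minus the (acute) angle to the normal
    alpha = 90.0 - acute_angle(in_plane_vec, plane.normal)
    beta = acute_angle(in_plane_vec, plane.in_plane_bond)
    gamma = acute_angle(normal_vec, plane.normal)
    return OrientationAngles(alpha=alpha, beta=beta, gamma=gamma, site_key=site_key)


def orientation_angles_15N(
    frame: PrincipalFrame, plane: PeptidePlane, site_key: Optional[tuple] = None
) -> OrientationAngles:
    """Amide-nitrogen tensor orientation (alpha, beta, gamma) in P_N."""
    if frame.degenerate:
        raise ValueError("degenerate principal frame: orientation undefined")
    return _angles(frame.xi3, frame.xi2, plane, site_key)


def orientation_angles_13C(
    frame: PrincipalFrame, plane: PeptidePlane, site_key: Optional[tuple] = None
) -> OrientationAngles:
    """Carbonyl-carbon tensor orientation (alpha, beta, gamma) in P_C."""
    if frame.degenerate:
        raise ValueError("degenerate principal frame: orientation undefined")
    return _angles(frame.xi2, frame.xi1, plane, site_key)
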