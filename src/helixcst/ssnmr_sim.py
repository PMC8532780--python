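"""Oriented-sample SSNMR observables for helical peptides.

A helical peptide in a magnetically oriented bilayer, with the membrane
normal along the field, exhibits rotationally averaged shift components.
Two closed forms drive the analysis:

* the parallel 15N component,

      delta_par(tau) = d11 sin^2(tau) + d33 cos^2(tau),             (tilt law)

  where d11, d33 are principal elements of the amide CST and tau the helix
  tilt; measuring delta_par and inverting this law yields tau. The law
  confines delta_par between d11 and d33, so a reported value outside that
  interval cannot arise from any tilt (``invert_tilt`` raises a domain
  error naming the violated bound; see the note in docs/methods.md on the
  literature value 292.2 ppm vs. the consistent 229.2 ppm).

* the total 13C anisotropy of a carbonyl at azimuth rho,

      ddelta(rho, tau) = 3/2 sin^2(tau) (d11 cos^2(rho) + d33 sin^2(rho) - d22)
                         + d22 - (d11 + d33)/2,

  an oscillation about the axial anisotropy d22 - (d11+d33)/2 with period
  180 degrees in rho; at tau = 0 it reduces to the axial term.

Angles are degrees at every interface (radians only internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "OrientedObservables",
    "ScanResult",
    "TiltDomainError",
    "delta_parallel",
    "invert_tilt",
    "total_anisotropy",
    "scan_tilt",
    "scan_oscillation",
]


class TiltDomainError(ValueError):
    """delta_par lies outside the [min(d11,d33), max(d11,d33)] band."""


@dataclass
class OrientedObservables:
    """One site's oriented-sample observables at a given (rho, tau)."""

    delta_parallel: float
    total_anisotropy: float
    tau: float
    rho: Optional[float] = None

    @property
    def delta_perp(self) -> float:
        return self.delta_parallel - self.total_anisotropy


@dataclass
class ScanResult:
    """A scan over tau or rho: curves per site plus discrete site points."""

    abscissa: np.ndarray                      # degrees, strictly increasing
    curves: dict = field(default_factory=dict)  # site label -> ppm array
    points: list = field(default_factory=list)  # (label, abscissa_deg, ppm)

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        if self.abscissa.size and np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("scan grid must be strictly increasing")


def _check_tau(tau: float) -> float:
    if not 0.0 <= tau <= 90.0:
        raise ValueError(f"tau={tau} outside [0, 90] degrees")
    return np.radians(tau)


def delta_parallel(d11: float, d33: float, tau: float) -> float:
    """Parallel shift component d11 sin^2(tau) + d33 cos^2(tau), ppm."""
    t = _check_tau(float(tau))
    return float(d11 * np.sin(t) ** 2 + d33 * np.cos(t) ** 2)


def invert_tilt(delta_par: float, d11: float, d33: float) -> float:
    """Tilt angle from a measured parallel component (principal branch).

    tau = arcsin(sqrt((d33 - delta_par) / (d33 - d11))), in [0, 90] degrees.
    The mirror solution 180 - tau maps to the same observable and is not
    enumerated. Out-of-band delta_par raises :class:`TiltDomainError`.
    """
    if d11 == d33:
        raise ValueError("d11 == d33: tilt indeterminate (isotropic in this plane)")
    lo, hi = min(d11, d33), max(d11, d33)
    if delta_par < lo - 1e-9:
        raise TiltDomainError(
            f"delta_par={delta_par} ppm below the lower bound min(d11,d33)={lo} ppm"
        )
    if delta_par > hi + 1e-9:
        raise TiltDomainError(
            f"delta_par={delta_par} ppm above the upper bound max(d11,d33)={hi} ppm"
        )
    s2 = (d33 - delta_par) / (d33 - d11)
    s2 = min(max(s2, 0.0), 1.0)
    return float(np.degrees(np.arcsin(np.sqrt(s2))))


def total_anisotropy(d11: float, d22: float, d33: float, rho: float, tau: float) -> float:
    """Total anisotropy ddelta(rho, tau) of a carbonyl CST, ppm.

    Principal values must be sorted ascending; rho is the site azimuth
    about the helix axis, tau the helix tilt.
    """
    if not (d11 <= d22 <= d33):
        raise ValueError("principal values must be sorted ascending (d11<=d22<=d33)")
    t = _check_tau(float(tau))
    r = np.radians(float(rho))
    osc = 1.5 * np.sin(t) ** 2 * (
        d11 * np.cos(r) ** 2 + d33 * np.sin(r) ** 2 - d22
    )
    return float(osc + d22 - (d11 + d33) / 2.0)


def scan_tilt(
    shift_sets: dict[str, tuple[float, float]], tau_grid: Sequence[float]
) -> ScanResult:
    """delta_par(tau) curves for named (d11, d33) pairs over a tau grid."""
    grid = np.asarray(tau_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty tau grid")
    result = ScanResult(abscissa=grid)
    for label, (d11, d33) in shift_sets.items():
        result.curves[label] = np.array([delta_parallel(d11, d33, t) for t in grid])
    return result


def scan_oscillation(
    sites: dict[str, tuple[float, float, float, float]],
    tau: float,
    rho_grid: Sequence[float],
    reference_values: Optional[tuple[float, float, float]] = None,
) -> ScanResult:
    """Carbonyl anisotropy oscillation: continuous curve plus site points.

    ``sites`` maps a residue label to (d11, d22, d33, rho). Each site
    contributes one discrete point at its own azimuth; the continuous curve
    over ``rho_grid`` uses ``reference_values`` (default: the mean of the
    sites' principal values, a smooth guide through the site points).
    Sites with undefined (NaN) rho are skipped with a warning.
    """
    import warnings

    grid = np.asarray(rho_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty rho grid")
    usable = {}
    for label, (d11, d22, d33, rho) in sites.items():
        if rho is None or (isinstance(rho, float) and np.isnan(rho)):
            warnings.warn(f"site {label}: undefined azimuth, skipped", stacklevel=2)
            continue
        usable[label] = (d11, d22, d33, float(rho))
    if not usable:
        raise ValueError("no site has a defined azimuth")

    if reference_values is None:
        vals = np.array([v[:3] for v in usable.values()])
        reference_values = tuple(vals.mean(axis=0))
    r11, r22, r33 = reference_values

    result = ScanResult(abscissa=grid)
    result.curves["reference"] = np.array(
        [total_anisotropy(r11, r22, r33, r, tau) for r in grid]
    )
    for label, (d11, d22, d33, rho) in usable.items():
        result.points.append((label, rho, total_anisotropy(d11, d22, d33, rho, tau)))
    return result
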