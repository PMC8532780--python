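"""Chemical-shielding tensor algebra and shielding-to-shift calibration.

A DFT calculation delivers a raw (generally non-symmetric) shielding tensor
sigma per nucleus. Only the symmetric part is observable in the chemical
shift, so the antisymmetric part is discarded before diagonalization.
Principal shieldings are ordered sigma11 >= sigma22 >= sigma33; calibrated
"theoretical chemical shifts" eps follow the opposite (shift) ordering
eps11 <= eps22 <= eps33, related by a negative-slope linear map

    eps_pp = slope * sigma_qq + intercept        (slope < 0)

fitted against single-crystal shift measurements on reference compounds.
The two calibration lines shipped here are the amide-nitrogen (15N) and
carbonyl-carbon (13C) lines used for the crystalline alamethicin E18 model:

    15N: eps = -0.93574 sigma + 209.54 ppm
    13C: eps = -0.99314 sigma + 172.50 ppm   (sd 1.8 ppm, adj R^2 0.99918)

Scalar descriptors: eps_iso = mean of the principal values; the axial
anisotropy eps_aniso = eps22 - (eps11 + eps33)/2, the quantity that drives
the carbonyl shift oscillation in oriented samples; and the Haeberlen
ordering (by deviation from the isotropic value) with its anisotropy and
asymmetry parameters.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PrincipalFrame",
    "TheoreticalShift",
    "CalibrationLine",
    "ExperimentalShiftSet",
    "CALIBRATION_15N",
    "CALIBRATION_13C",
    "DEGENERACY_GAP_PPM",
    "principal_frame",
    "shielding_to_shift",
    "shift_to_shielding",
    "fit_calibration",
    "isotropic",
    "axial_anisotropy",
    "haeberlen_order",
    "round_report",
    "read_shift_table",
    "load_alm_e18_table",
]

#: Eigenvalue gap (ppm) below which a principal frame is flagged degenerate.
DEGENERACY_GAP_PPM = 1e-6


@dataclass
class PrincipalFrame:
    """Principal shieldings (descending) with their unit eigenvectors."""

    sigma: tuple[float, float, float]  # sigma11 >= sigma22 >= sigma33, ppm
    vectors: np.ndarray  # rows xi1, xi2, xi3
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        s = self.sigma
        if not (s[0] >= s[1] >= s[2]):
            raise ValueError("principal values must be ordered descending")
        if not np.allclose(self.vectors @ self.vectors.T, np.eye(3), atol=1e-8):
            raise ValueError("eigenvectors must be orthonormal")

    @property
    def xi1(self) -> np.ndarray:
        return self.vectors[0]

    @property
    def xi2(self) -> np.ndarray:
        return self.vectors[1]

    @property
    def xi3(self) -> np.ndarray:
        return self.vectors[2]


@dataclass
class TheoreticalShift:
    """Calibrated principal shifts eps11 <= eps22 <= eps33 (ppm)."""

    eps: tuple[float, float, float]
    eps_iso: float
    eps_aniso: float

    def __post_init__(self) -> None:
        e = self.eps
        if not (e[0] <= e[1] <= e[2]):
            raise ValueError("eps must be ordered ascending")
        if abs(self.eps_iso - sum(e) / 3.0) > 1e-9:
            raise ValueError("eps_iso inconsistent with principal values")
        if abs(self.eps_aniso - (e[1] - (e[0] + e[2]) / 2.0)) > 1e-9:
            raise ValueError("eps_aniso inconsistent with principal values")


@dataclass
class CalibrationLine:
    """Linear shielding-to-shift map for one nucleus."""

    slope: float
    intercept: float
    nucleus: str  # "15N" or "13C"
    sd: Optional[float] = None
    adj_r2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("calibration slope must be negative "
                             "(shielding and shift anti-correlate)")


@dataclass
class ExperimentalShiftSet:
    """Measured principal shifts delta11 <= delta22 <= delta33 (ppm)."""

    delta: tuple[float, float, float]
    delta_iso: float
    source: str = ""

    def __post_init__(self) -> None:
        d = self.delta
        if not (d[0] <= d[1] <= d[2]):
            raise ValueError("delta must be ordered ascending")
        if abs(self.delta_iso - sum(d) / 3.0) > 1e-9:
            raise ValueError("delta_iso inconsistent with principal values")


CALIBRATION_15N = CalibrationLine(slope=-0.93574, intercept=209.54, nucleus="15N")
CALIBRATION_13C = CalibrationLine(
    slope=-0.99314, intercept=172.50, nucleus="13C", sd=1.8, adj_r2=0.99918
)


def principal_frame(matrix: np.ndarray) -> PrincipalFrame:
    """Diagonalize the symmetric part of a 3x3 shielding tensor.

    Eigenvalues are sorted descending. Eigenvector signs are fixed so that
    xi1 and xi2 each have their largest-magnitude component positive and
    xi3 = xi1 x xi2, giving a right-handed frame. Frames with an eigenvalue
    gap below :data:`DEGENERACY_GAP_PPM` are flagged ``degenerate``;
    orientation analysis refuses them because eigenvector directions carry
    no information there.
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3) or not np.all(np.isfinite(m)):
        raise ValueError("need a finite 3x3 matrix")
    sym = 0.5 * (m + m.T)
    evals, evecs = np.linalg.eigh(sym)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    vectors = evecs[:, order].T.copy()
    for i in range(2):
        j = np.argmax(np.abs(vectors[i]))
        if vectors[i][j] < 0:
            vectors[i] = -vectors[i]
    vectors[2] = np.cross(vectors[0], vectors[1])
    gaps = (evals[0] - evals[1], evals[1] - evals[2])
    return PrincipalFrame(
        sigma=tuple(evals),
        vectors=vectors,
        degenerate=bool(min(gaps) < DEGENERACY_GAP_PPM),
    )


def shielding_to_shift(
    sigma: Sequence[float], line: CalibrationLine
) -> TheoreticalShift:
    """Map principal shieldings (descending) to theoretical shifts (ascending).

    The negative slope reverses the ordering: the largest shielding sigma11
    maps to the smallest shift eps11.
    """
    s = tuple(float(v) for v in sigma)
    if len(s) != 3:
        raise ValueError("need three principal shieldings")
    if not (s[0] >= s[1] >= s[2]):
        raise ValueError("shieldings must be ordered descending")
    eps = tuple(line.slope * v + line.intercept for v in s)
    return TheoreticalShift(
        eps=eps,
        eps_iso=sum(eps) / 3.0,
        eps_aniso=eps[1] - (eps[0] + eps[2]) / 2.0,
    )


def shift_to_shielding(eps: Sequence[float], line: CalibrationLine) -> tuple:
    """Analytic inverse of :func:`shielding_to_shift` (descending output)."""
    e = tuple(float(v) for v in eps)
    if not (e[0] <= e[1] <= e[2]):
        raise ValueError("shifts must be ordered ascending")
    return tuple((v - line.intercept) / line.slope for v in e)


def fit_calibration(
    pairs: Sequence[tuple[float, float]], nucleus: str
) -> CalibrationLine:
    """Ordinary least squares of shift on shielding over matched pairs.

    ``sd`` is the residual standard deviation with an n - 2 denominator;
    ``adj_r2`` the standard adjusted R^2 (one predictor).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (shielding, shift) pairs")
    sigma, delta = arr[:, 0], arr[:, 1]
    if np.ptp(sigma) == 0:
        raise np.linalg.LinAlgError("all shieldings identical: singular fit")
    n = len(sigma)
    slope, intercept = np.polyfit(sigma, delta, 1)
    resid = delta - (slope * sigma + intercept)
    sd = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    sst = float(np.sum((delta - delta.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return CalibrationLine(
        slope=float(slope), intercept=float(intercept),
        nucleus=nucleus, sd=sd, adj_r2=float(adj_r2),
    )


def isotropic(values: Sequence[float]) -> float:
    """Isotropic component: arithmetic mean of the three principal values."""
    v = tuple(float(x) for x in values)
    if len(v) != 3 or not all(np.isfinite(v)):
        raise ValueError("need three finite principal values")
    return sum(v) / 3.0


def axial_anisotropy(values: Sequence[float]) -> float:
    """Axial anisotropy v22 - (v11 + v33)/2 of ascending principal values."""
    v = tuple(float(x) for x in values)
    if len(v) != 3:
        raise ValueError("need three principal values")
    if not (v[0] <= v[1] <= v[2]):
        raise ValueError("principal values must be sorted ascending")
    return v[1] - (v[0] + v[2]) / 2.0


def haeberlen_order(values: Sequence[float]) -> dict:
    """Reorder principal values by deviation from the isotropic value.

    Haeberlen convention: |zz - iso| >= |xx - iso| >= |yy - iso|, with
    anisotropy zz - iso and asymmetry (yy - xx)/(zz - iso). An isotropic
    tensor leaves the asymmetry undefined (``None``, flagged).
    """
    v = sorted(float(x) for x in values)
    iso = sum(v) / 3.0
    ordered = sorted(v, key=lambda x: abs(x - iso), reverse=True)
    zz, xx, yy = ordered[0], ordered[1], ordered[2]
    aniso = zz - iso
    if abs(aniso) < 1e-12:
        return {"zz": zz, "xx": xx, "yy": yy, "anisotropy": 0.0,
                "asymmetry": None, "isotropic_flag": True}
    return {"zz": zz, "xx": xx, "yy": yy, "anisotropy": aniso,
            "asymmetry": (yy - xx) / aniso, "isotropic_flag": False}


def round_report(value: float, decimals: int = 1) -> float:
    """Half-up (away from zero on ties) rounding used for table output."""
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def read_shift_table(path: str | Path) -> pd.DataFrame:
    """Ingest a principal-value CSV table.

    Expected columns: ``residue,eps_iso,eps11,eps22,eps33,alpha,beta,gamma``
    and optionally ``eps_aniso``. Empty angle cells (prolines, caps) read as
    NaN.
    """
    df = pd.read_csv(path)
    required = {"residue", "eps_iso", "eps11", "eps22", "eps33"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"shift table missing columns: {sorted(missing)}")
    return df


def load_alm_e18_table(nucleus: str) -> pd.DataFrame:
    """Packaged reference shift table for the alamethicin E18 model.

    ``nucleus`` is ``"15N"`` (amide nitrogens, 20 rows incl. phenylalaninol)
    or ``"13C"`` (carbonyl carbons, 19 rows — the C-terminal phenylalaninol
    has no carbonyl).
    """
    fname = {"15N": "alm_e18_15n.csv", "13C": "alm_e18_13c.csv"}.get(nucleus)
    if fname is None:
        raise ValueError(f"unknown nucleus {nucleus!r}; expected '15N' or '13C'")
    with resources.files("helixcst.data").joinpath(fname).open("r") as fh:
        return read_shift_table(fh)
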