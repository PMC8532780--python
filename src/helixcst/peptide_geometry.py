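"""Backbone geometry: Ramachandran angles, hydrogen bonds, helix frame.

Works on the :class:`~helixcst.formats_io.StructureModel` container. The
helix frame (axis, per-residue azimuth rho, tilt tau against a membrane
normal) is obtained from a least-squares cylinder fit to the C-alpha trace:
the axis direction, a point on the axis and the radius are refined jointly
so that the spread of point-to-axis distances is minimal. For an ideal
alpha-helix this recovers the construction axis essentially exactly.

Azimuths are measured about the axis (right-handed, axis pointing from the
N- to the C-terminus) from a reference residue that defines rho = 0; the
default site vector is the carbonyl C'->O' bond projected perpendicular to
the axis, since the carbonyl orientation is what the oriented-sample 13C
observables probe. Successive residues of an ideal alpha-helix are then
spaced by ~100 degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .formats_io import StructureModel

__all__ = [
    "ResidueFrame",
    "HydrogenBond",
    "HelixFrame",
    "HBondCriteria",
    "dihedral",
    "ramachandran",
    "residue_frames",
    "reconstruct_amide_h",
    "detect_hbonds",
    "fit_helix_axis",
    "residue_azimuth",
    "helix_tilt",
    "angle_to_axis",
    "unit",
    "angle_between",
    "acute_angle",
]


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def angle_between(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    ua, ub = unit(a), unit(b)
    return float(np.degrees(np.arccos(np.clip(np.dot(ua, ub), -1.0, 1.0))))


def acute_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two axes (sign-insensitive) in degrees, in [0, 90]."""
    ua, ub = unit(a), unit(b)
    return float(np.degrees(np.arccos(np.clip(abs(np.dot(ua, ub)), 0.0, 1.0))))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC torsion angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.allclose(a, b):
            raise ValueError("consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("collinear triple: torsion undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), unit(b2))
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if np.isclose(ang, -180.0) else ang


@dataclass
class ResidueFrame:
    """Backbone atoms and dihedrals of one residue."""

    index: int
    name: str
    N: Optional[np.ndarray] = None
    H: Optional[np.ndarray] = None
    CA: Optional[np.ndarray] = None
    C: Optional[np.ndarray] = None   # carbonyl C'
    O: Optional[np.ndarray] = None   # carbonyl O'
    phi: Optional[float] = None
    psi: Optional[float] = None
    residue_class: str = "proteinogenic"


@dataclass
class HydrogenBond:
    """Backbone amide-to-carbonyl hydrogen bond (acceptor i -> donor i+n)."""

    donor: int      # residue providing N-H
    acceptor: int   # residue providing C'=O
    span: int       # donor - acceptor
    distance: float  # H...O, Å
    angle: float     # N-H...O, degrees

    def arrow(self, names: Optional[dict] = None) -> str:
        """Table notation from the acceptor's perspective, e.g. 'Aib1→Aib5'."""
        fmt = (lambda i: f"{names[i]}{i}") if names else str
        return f"{fmt(self.acceptor)}→{fmt(self.donor)}"


@dataclass
class HBondCriteria:
    max_distance: float = 2.5   # H...O, Å
    min_angle: float = 120.0    # N-H...O, degrees


@dataclass
class HelixFrame:
    """Fitted helix axis with per-residue azimuths and optional tilt."""

    axis: np.ndarray
    anchor: np.ndarray
    radius: float
    residue_azimuth: dict = field(default_factory=dict)  # residue -> rho, deg
    tilt: Optional[float] = None
    reference_residue: Optional[int] = None

    def __post_init__(self) -> None:
        self.axis = unit(self.axis)
        self.anchor = np.asarray(self.anchor, dtype=float)


_CLASS_BY_NAME = {"AIB": "Aib", "PRO": "Pro", "PHL": "Phl", "ACE": "cap"}


def residue_frames(model: StructureModel, chain_id: Optional[str] = None) -> list[ResidueFrame]:
    """Collect backbone atoms per residue (caps classified, not dropped)."""
    chain = chain_id or model.chains()[0]
    frames = []
    for idx in model.residue_indices(chain):
        name = model.residue_name(idx, chain)
        fr = ResidueFrame(
            index=idx, name=name,
            residue_class=_CLASS_BY_NAME.get(name.upper(), "proteinogenic"),
        )
        for attr, aname in (("N", "N"), ("H", "H"), ("CA", "CA"), ("C", "C"), ("O", "O")):
            a = model.get_atom(chain, idx, aname)
            if a is not None:
                setattr(fr, attr, a.coords)
        frames.append(fr)
    return frames


def ramachandran(model: StructureModel, chain_id: Optional[str] = None) -> list[ResidueFrame]:
    """Compute phi/psi for every residue; termini stay undefined (None).

    phi(i) needs C'(i-1); psi(i) needs N(i+1). Cap residues (class 'cap')
    get no dihedrals of their own but their carbonyl defines phi of the
    first residue. Residues without a C-alpha are skipped with a warning.
    """
    frames = residue_frames(model, chain_id)
    by_index = {fr.index: fr for fr in frames}
    out = []
    for fr in frames:
        if fr.CA is None and fr.residue_class != "cap":
            warnings.warn(f"residue {fr.index} has no CA; skipped", stacklevel=2)
            continue
        if fr.residue_class != "cap":
            prev = by_index.get(fr.index - 1)
            nxt = by_index.get(fr.index + 1)
            if (prev is not None and prev.C is not None
                    and fr.N is not None and fr.CA is not None and fr.C is not None):
                fr.phi = dihedral(prev.C, fr.N, fr.CA, fr.C)
            if (nxt is not None and nxt.N is not None
                    and fr.N is not None and fr.CA is not None and fr.C is not None):
                fr.psi = dihedral(fr.N, fr.CA, fr.C, nxt.N)
        out.append(fr)
    return out


def reconstruct_amide_h(frames: Sequence[ResidueFrame]) -> None:
    """Place missing amide hydrogens in the C'(i-1)-N-CA plane.

    The N-H bond (1.01 Å) points along the external bisector of the
    C'(i-1)-N-CA angle, the standard planar-amide construction for
    XRD-derived files that lack hydrogens. Prolines are left without H.
    """
    by_index = {fr.index: fr for fr in frames}
    for fr in frames:
        if fr.H is not None or fr.residue_class in ("Pro", "cap") or fr.N is None:
            continue
        prev = by_index.get(fr.index - 1)
        if prev is None or prev.C is None or fr.CA is None:
            continue
        u1 = unit(prev.C - fr.N)
        u2 = unit(fr.CA - fr.N)
        fr.H = fr.N - 1.01 * unit(u1 + u2)


def detect_hbonds(
    model_or_frames,
    criteria: HBondCriteria = HBondCriteria(),
    reconstruct_h: bool = True,
    chain_id: Optional[str] = None,
) -> list[HydrogenBond]:
    """Backbone H-bond inventory: amide N-H donors to carbonyl O acceptors.

    Each donor is assigned at most one acceptor — the geometrically closest
    H...O contact satisfying both criteria, with a minimum sequence span of
    2 (an alpha-helix gives i -> i+4, a 3_10 turn i -> i+3, counting from
    the acceptor). Donors without an amide H raise unless ``reconstruct_h``.
    """
    if isinstance(model_or_frames, StructureModel):
        frames = residue_frames(model_or_frames, chain_id)
    else:
        frames = list(model_or_frames)
    if reconstruct_h:
        reconstruct_amide_h(frames)
    donors = [fr for fr in frames if fr.N is not None and fr.residue_class not in ("Pro", "cap")]
    if any(fr.H is None for fr in donors) and not reconstruct_h:
        missing = [fr.index for fr in donors if fr.H is None]
        raise ValueError(f"residues {missing} lack amide H and reconstruction is disabled")
    acceptors = [fr for fr in frames if fr.C is not None and fr.O is not None]

    bonds = []
    for d in donors:
        if d.H is None:
            continue
        best = None
        for a in acceptors:
            span = d.index - a.index
            if span < 2:
                continue
            dist = float(np.linalg.norm(d.H - a.O))
            if dist > criteria.max_distance:
                continue
            ang = angle_between(d.N - d.H, a.O - d.H)
            if ang < criteria.min_angle:
                continue
            if best is None or dist < best.distance:
                best = HydrogenBond(donor=d.index, acceptor=a.index,
                                    span=span, distance=dist, angle=ang)
        if best is not None:
            bonds.append(best)
    return bonds


def _axis_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis of the plane perpendicular to d."""
    ref = np.eye(3)[np.argmin(np.abs(d))]
    e1 = unit(np.cross(d, ref))
    e2 = np.cross(d, e1)
    return e1, e2


def _cylinder_residuals(p, pts, centroid):
    theta, phi, a1, a2, r = p
    d = np.array([np.sin(theta) * np.cos(phi),
                  np.sin(theta) * np.sin(phi),
                  np.cos(theta)])
    e1, e2 = _axis_basis(d)
    anchor = centroid + a1 * e1 + a2 * e2
    rel = pts - anchor
    perp = rel - np.outer(rel @ d, d)
    return np.linalg.norm(perp, axis=1) - r


def fit_helix_axis(ca_coords: Sequence, window: Optional[slice] = None) -> HelixFrame:
    """Least-squares cylinder fit to an ordered C-alpha trace.

    Parameters are the axis direction, an anchor point and the radius; the
    objective is the spread of point-to-axis distances about the radius.
    The fit is started from both the largest and the smallest principal
    directions of the point cloud (the former suits elongated helices, the
    latter the flat circular-arc limit) and the lower-cost solution is
    kept. The axis sign is chosen to point from the N- to the C-terminus.
    """
    pts = np.asarray(ca_coords, dtype=float)
    if window is not None:
        pts = pts[window]
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("need at least 4 C-alpha points")
    centroid = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - centroid)
    if s[1] < 1e-10:
        raise ValueError("collinear points: cylinder fit degenerate")

    best = None
    for d0 in (vt[0], vt[2]):
        theta0 = float(np.arccos(np.clip(d0[2], -1, 1)))
        phi0 = float(np.arctan2(d0[1], d0[0]))
        rel = pts - centroid
        perp = rel - np.outer(rel @ d0, d0)
        r0 = float(np.linalg.norm(perp, axis=1).mean())
        res = least_squares(
            _cylinder_residuals, x0=[theta0, phi0, 0.0, 0.0, max(r0, 1e-3)],
            args=(pts, centroid), xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or res.cost < best.cost:
            best = res

    theta, phi, a1, a2, r = best.x
    d = np.array([np.sin(theta) * np.cos(phi),
                  np.sin(theta) * np.sin(phi),
                  np.cos(theta)])
    e1, e2 = _axis_basis(d)
    anchor = centroid + a1 * e1 + a2 * e2
    if np.dot(d, pts[-1] - pts[0]) < 0:
        d = -d
    return HelixFrame(axis=d, anchor=anchor, radius=abs(float(r)))


def residue_azimuth(
    model: StructureModel,
    frame: HelixFrame,
    site_vector: str = "CO",
    reference_residue: Optional[int] = None,
    chain_id: Optional[str] = None,
) -> dict:
    """Per-residue azimuth rho about the helix axis, in [0, 360).

    ``site_vector`` selects the bond whose perpendicular component is
    tracked: ``"CO"`` (carbonyl C'->O', default) or ``"CAC"`` (CA->C').
    rho = 0 at ``reference_residue`` (default: first residue with a defined
    vector); rho increases in the right-handed sense about the axis.
    Residues whose site vector is parallel to the axis are flagged (NaN).
    """
    frames = residue_frames(model, chain_id)
    vectors = {}
    for fr in frames:
        if site_vector == "CO":
            if fr.C is None or fr.O is None:
                continue
            v = fr.O - fr.C
        elif site_vector == "CAC":
            if fr.CA is None or fr.C is None:
                continue
            v = fr.C - fr.CA
        else:
            raise ValueError(f"unknown site_vector {site_vector!r}")
        perp = v - np.dot(v, frame.axis) * frame.axis
        vectors[fr.index] = perp

    usable = {i: v for i, v in vectors.items() if np.linalg.norm(v) > 1e-8}
    if not usable:
        raise ValueError("no residue has a site vector transverse to the axis")
    if reference_residue is None:
        reference_residue = min(usable)
    if reference_residue not in usable:
        raise ValueError(f"reference residue {reference_residue} has no usable site vector")

    e1 = unit(usable[reference_residue])
    e2 = np.cross(frame.axis, e1)
    rho = {}
    for i, v in vectors.items():
        if np.linalg.norm(v) <= 1e-8:
            warnings.warn(f"residue {i}: site vector parallel to axis", stacklevel=2)
            rho[i] = float("nan")
            continue
        ang = float(np.degrees(np.arctan2(np.dot(v, e2), np.dot(v, e1))) % 360.0)
        rho[i] = 0.0 if ang >= 360.0 - 1e-9 else ang
    frame.residue_azimuth = rho
    frame.reference_residue = reference_residue
    return rho


def helix_tilt(frame: HelixFrame, n: np.ndarray) -> float:
    """Tilt tau: acute angle between the helix axis and the membrane normal."""
    tau = acute_angle(frame.axis, n)
    frame.tilt = tau
    return tau


def angle_to_axis(v: np.ndarray, frame: HelixFrame) -> float:
    """Acute angle between a direction (e.g. a tensor eigenvector) and the axis."""
    return acute_angle(v, frame.axis)
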