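"""Synthetic helical peptides and planted shielding tensors.

Ground-truth inputs for every downstream stage: an ideal right-handed
alpha-helix backbone (amide H and carbonyl O included) built from internal
coordinates, and symmetric 3x3 shielding tensors whose principal values and
peptide-plane orientation angles are prescribed exactly.

The default sequence is the 20-residue alamethicin E18 peptaibol,

    Ac-Aib-Pro-Aib-Ala-Aib-Ala-Gln-Aib-Val-Aib-
       Gly-Leu-Aib-Pro-Val-Aib-Aib-Glu-Gln-Phl

with an N-terminal acetyl cap (residue 0) and a C-terminal phenylalaninol
(no carbonyl). Default backbone dihedrals are phi = -57, psi = -47 degrees,
the canonical alpha-helix, giving an emergent rise of ~1.5 Å/residue and
~100 degrees of twist per residue (3.6 residues/turn).

Tensor planting inverts the orientation-angle definitions constructively:
starting from the frame aligned with the peptide plane (reference
eigenvector along the N-H or C'=O bond, partner along the plane normal),
the eigenvectors are rotated to realize the requested (alpha, beta, gamma)
in that order, so the planted angles are exact by construction (pre-noise).
Feasibility requires beta >= alpha and gamma >= alpha, because alpha fixes
the out-of-plane elevation of the reference eigenvector and thereby bounds
the other two angles from below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import AtomSite, StructureModel, TensorRecord, write_magres, write_structure
from .peptide_geometry import residue_frames, unit
from .tensor_core import CALIBRATION_13C, CALIBRATION_15N, shielding_to_shift
from .tensor_orientation import OrientationAngles, plane_C, plane_N

__all__ = [
    "ALM_E18_SEQUENCE",
    "HelixSpec",
    "TensorPlantSpec",
    "build_helix",
    "plant_tensors",
    "write_fixture_bundle",
    "place_atom",
]

#: Alamethicin E18 sequence, 3-letter codes, N- to C-terminus.
ALM_E18_SEQUENCE = (
    "AIB", "PRO", "AIB", "ALA", "AIB", "ALA", "GLN", "AIB", "VAL", "AIB",
    "GLY", "LEU", "AIB", "PRO", "VAL", "AIB", "AIB", "GLU", "GLN", "PHL",
)

# Standard backbone internal coordinates (Å, degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_BOND_N_H = 1.01
_BOND_CA_CB = 1.53
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8
_ANGLE_C_CA_CB = 110.1
_OMEGA = 180.0


@dataclass
class HelixSpec:
    """Specification of an ideal helical peptide.

    ``phi``/``psi`` may be scalars (uniform helix) or per-residue sequences.
    ``rise`` and ``residues_per_turn`` record the expected emergent geometry
    of the canonical alpha-helix; the construction itself is from internal
    coordinates, so they are diagnostics, not inputs.
    """

    sequence: Sequence[str] = ALM_E18_SEQUENCE
    phi: float | Sequence[float] = -57.0
    psi: float | Sequence[float] = -47.0
    rise: float = 1.5
    residues_per_turn: float = 3.6
    acetyl_cap: bool = True
    seed: int = 0
    coordinate_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError("need at least 2 residues")
        if self.coordinate_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def phi_of(self, i: int) -> float:
        return float(self.phi) if np.isscalar(self.phi) else float(self.phi[i - 1])

    def psi_of(self, i: int) -> float:
        return float(self.psi) if np.isscalar(self.psi) else float(self.psi[i - 1])


@dataclass
class TensorPlantSpec:
    """Per-site principal shieldings and target peptide-plane angles.

    ``sites`` maps a residue index to ``(sigma, angles)`` where ``sigma``
    is (sigma11, sigma22, sigma33) descending in ppm and ``angles`` the
    target (alpha, beta, gamma) in degrees, each in [0, 90].
    """

    sites: dict[int, tuple[tuple[float, float, float], tuple[float, float, float]]]
    nucleus: str = "15N"
    tensor_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus not in ("15N", "13C"):
            raise ValueError("nucleus must be '15N' or '13C'")
        for i, (sigma, angles) in self.sites.items():
            if not (sigma[0] >= sigma[1] >= sigma[2]):
                raise ValueError(f"site {i}: shieldings must be descending")
            if not all(0.0 <= a <= 90.0 for a in angles):
                raise ValueError(f"site {i}: angles must lie in [0, 90] degrees")


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d bonded to c with given b-c-d angle and a-b-c-d torsion.

    The natural-extension reference frame construction; angle and torsion
    in degrees.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


_SIDECHAIN_FREE = {"GLY", "ACE"}


def build_helix(spec: HelixSpec) -> StructureModel:
    """Build an ideal helical peptide backbone from internal coordinates.

    Atoms per residue: N, H (absent for Pro), CA, C ('C prime'), O, and a CB
    stub where the residue has a sidechain. The chain is capped N-terminally
    with an acetyl group (residue 0: CH3, C, O) when ``spec.acetyl_cap``;
    a C-terminal phenylalaninol gets a hydroxymethyl carbon C but no
    carbonyl O. Achieved phi/psi match the spec to well under 0.1 degree.
    """
    seq = [s.upper() for s in spec.sequence]
    known = {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
        "AIB", "PHL",
    }
    for s in seq:
        if s == "ACE":
            raise ValueError("the cap is added automatically; do not list ACE")
        if s not in known:
            raise ValueError(f"unknown residue code {s!r}; known: {sorted(known)}")
    n_res = len(seq)

    coords: dict[tuple[int, str], np.ndarray] = {}
    names: dict[int, str] = {i + 1: seq[i] for i in range(n_res)}

    # Seed the chain with the acetyl cap (built even if not requested, then
    # dropped — it provides the reference frame for residue 1).
    ch3 = np.zeros(3)
    c0 = np.array([1.52, 0.0, 0.0])
    u = unit(ch3 - c0)
    ang = np.radians(_ANGLE_CA_C_N)
    n1 = c0 + _BOND_C_N * (np.cos(ang) * u + np.sin(ang) * np.array([0.0, 1.0, 0.0]))
    coords[(0, "CH3")] = ch3
    coords[(0, "C")] = c0
    coords[(1, "N")] = n1
    coords[(1, "CA")] = place_atom(ch3, c0, n1, _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)
    # cap carbonyl O: in the amide plane, anti to CA1 across the C-N bond
    coords[(0, "O")] = place_atom(coords[(1, "CA")], n1, c0, _BOND_C_O, 123.0, 0.0)

    for i in range(1, n_res + 1):
        prev_c = coords[(i - 1, "C")]
        n_i, ca_i = coords[(i, "N")], coords[(i, "CA")]
        coords[(i, "C")] = place_atom(prev_c, n_i, ca_i, _BOND_CA_C,
                                      _ANGLE_N_CA_C, spec.phi_of(i))
        if seq[i - 1] != "PRO":
            u1 = unit(prev_c - n_i)
            u2 = unit(ca_i - n_i)
            coords[(i, "H")] = n_i - _BOND_N_H * unit(u1 + u2)
        if seq[i - 1] not in _SIDECHAIN_FREE:
            coords[(i, "CB")] = place_atom(n_i, coords[(i, "C")], ca_i,
                                           _BOND_CA_CB, _ANGLE_C_CA_CB, 122.5)
        is_last = i == n_res
        if not is_last:
            coords[(i + 1, "N")] = place_atom(n_i, ca_i, coords[(i, "C")],
                                              _BOND_C_N, _ANGLE_CA_C_N, spec.psi_of(i))
            coords[(i + 1, "CA")] = place_atom(ca_i, coords[(i, "C")], coords[(i + 1, "N")],
                                               _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)
        if not (is_last and seq[i - 1] == "PHL"):
            # carbonyl O: anti to the (actual or would-be) next amide nitrogen
            coords[(i, "O")] = place_atom(n_i, ca_i, coords[(i, "C")], _BOND_C_O,
                                          _ANGLE_CA_C_O, spec.psi_of(i) + 180.0)

    if spec.coordinate_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        for key in coords:
            coords[key] = coords[key] + rng.normal(0.0, spec.coordinate_noise_sd, 3)

    model = StructureModel()
    order = {"CH3": 0, "N": 0, "H": 1, "CA": 2, "CB": 3, "C": 4, "O": 5}
    start = 0 if spec.acetyl_cap else 1
    for i in range(start, n_res + 1):
        rname = "ACE" if i == 0 else names[i]
        res_atoms = sorted(
            (key for key in coords if key[0] == i),
            key=lambda key: order.get(key[1], 9),
        )
        for _, aname in res_atoms:
            model.add(AtomSite(
                element=aname[0], name=aname, coords=coords[(i, aname)],
                residue_index=i, residue_name=rname, chain_id="A",
            ))
    return model


def _plant_eigenvectors(plane, alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Eigenvector triple realizing (alpha, beta, gamma) in a peptide plane.

    Returns rows (xi_ref, xi_partner) plus the completing vector:
    for 15N the rows are (xi3, xi2, xi1-completion); roles are mapped by the
    caller. xi_ref carries alpha (elevation) and beta (angle to the bond);
    xi_partner carries gamma (angle to the normal).
    """
    al, be, ga = (np.radians(v) for v in (alpha, beta, gamma))
    b, m = plane.in_plane_bond, plane.normal
    p = np.cross(m, b)
    ca = np.cos(al)
    if ca < 1e-12:
        raise ValueError("alpha = 90 deg: reference eigenvector along the normal "
                         "leaves beta/gamma unrealizable unless both are 90 deg")
    if np.cos(be) > ca + 1e-12:
        raise ValueError(
            f"infeasible angles: need beta >= alpha (beta={beta}, alpha={alpha})"
        )
    if np.cos(ga) > ca + 1e-12:
        raise ValueError(
            f"infeasible angles: need gamma >= alpha (gamma={gamma}, alpha={alpha})"
        )
    theta = np.arccos(np.clip(np.cos(be) / ca, -1.0, 1.0))
    xi_ref = ca * (np.cos(theta) * b + np.sin(theta) * p) + np.sin(al) * m
    # basis of the plane perpendicular to xi_ref; u is the normal's component
    u = unit(m - np.dot(m, xi_ref) * xi_ref)
    w = np.cross(xi_ref, u)
    phi2 = np.arccos(np.clip(np.cos(ga) / ca, -1.0, 1.0))
    xi_partner = np.cos(phi2) * u + np.sin(phi2) * w
    return xi_ref, xi_partner


def plant_tensors(
    model: StructureModel, spec: TensorPlantSpec, chain_id: str = "A"
) -> tuple[list[TensorRecord], dict[int, OrientationAngles]]:
    """Plant shielding tensors with exact peptide-plane orientation angles.

    Returns the tensor records (site atom: N for 15N, C for 13C) and the
    exact pre-noise ground-truth angles per residue. Gaussian symmetric
    noise of ``tensor_noise_sd`` ppm is added after construction when
    requested; ground truth always refers to the noiseless tensor.
    """
    frames = {fr.index: fr for fr in residue_frames(model, chain_id)}
    rng = np.random.default_rng(spec.seed)
    records: list[TensorRecord] = []
    truth: dict[int, OrientationAngles] = {}
    atom_name = "N" if spec.nucleus == "15N" else "C"

    for idx, (sigma, angles) in sorted(spec.sites.items()):
        fr = frames.get(idx)
        if fr is None:
            raise KeyError(f"residue {idx} not in structure")
        plane = plane_N(fr) if spec.nucleus == "15N" else plane_C(fr)
        alpha, beta, gamma = angles
        xi_ref, xi_partner = _plant_eigenvectors(plane, alpha, beta, gamma)
        if spec.nucleus == "15N":
            xi3, xi2 = xi_ref, xi_partner
            xi1 = np.cross(xi2, xi3)
        else:
            xi2, xi1 = xi_ref, xi_partner
            xi3 = np.cross(xi1, xi2)
        vectors = np.vstack([xi1, xi2, xi3])
        tensor = sum(s * np.outer(v, v) for s, v in zip(sigma, vectors))
        if spec.tensor_noise_sd > 0:
            noise = rng.normal(0.0, spec.tensor_noise_sd, (3, 3))
            tensor = tensor + 0.5 * (noise + noise.T)
        records.append(TensorRecord(site_key=(chain_id, idx, atom_name), matrix=tensor))
        truth[idx] = OrientationAngles(alpha=alpha, beta=beta, gamma=gamma,
                                       site_key=(chain_id, idx, atom_name))
    return records, truth


def write_fixture_bundle(
    model: StructureModel,
    tensors: Sequence[TensorRecord],
    out_dir: str | Path,
    truth: Optional[dict[int, OrientationAngles]] = None,
    nucleus: str = "15N",
    membrane_normal=(0.0, 0.0, 1.0),
) -> dict[str, Path]:
    """Write a PDB + magres + ground-truth CSV bundle readable by formats_io.

    The truth CSV carries, per planted site, the principal shieldings, the
    calibrated theoretical shifts, the planted orientation angles, and the
    helix-frame azimuth/tilt of the structure (from the fitted axis).
    """
    from .peptide_geometry import fit_helix_axis, helix_tilt, residue_azimuth

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "structure": write_structure(model, out_dir / "structure.pdb", "pdb"),
        "magres": write_magres(model, tensors, out_dir / "tensors.magres"),
    }

    rows = []
    if tensors:
        chain = model.chains()[0]
        ca = [model.atom(chain, i, "CA").coords
              for i in model.residue_indices(chain)
              if model.get_atom(chain, i, "CA") is not None]
        frame = fit_helix_axis(ca)
        tau = helix_tilt(frame, np.asarray(membrane_normal, dtype=float))
        rho = residue_azimuth(model, frame, site_vector="CO")
        line = CALIBRATION_15N if nucleus == "15N" else CALIBRATION_13C
        for rec in tensors:
            _, idx, _ = rec.site_key
            sym = 0.5 * (rec.matrix + rec.matrix.T)
            sigma = tuple(sorted(np.linalg.eigvalsh(sym), reverse=True))
            shift = shielding_to_shift(sigma, line)
            ang = truth.get(idx) if truth else None
            rows.append({
                "residue": idx,
                "sigma11": sigma[0], "sigma22": sigma[1], "sigma33": sigma[2],
                "eps11": shift.eps[0], "eps22": shift.eps[1], "eps33": shift.eps[2],
                "eps_iso": shift.eps_iso, "eps_aniso": shift.eps_aniso,
                "alpha": ang.alpha if ang else np.nan,
                "beta": ang.beta if ang else np.nan,
                "gamma": ang.gamma if ang else np.nan,
                "rho": rho.get(idx, np.nan),
                "tau": tau,
            })
    columns = ["residue", "sigma11", "sigma22", "sigma33", "eps11", "eps22",
               "eps33", "eps_iso", "eps_aniso", "alpha", "beta", "gamma",
               "rho", "tau"]
    paths["truth"] = out_dir / "truth.csv"
    pd.DataFrame(rows, columns=columns).to_csv(paths["truth"], index=False)
    return paths
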