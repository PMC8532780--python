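"""Residue-class statistics and table emission.

Groups residues into Aib / Pro / proteinogenic / Phl / cap classes, computes
per-group summaries (mean, sample standard deviation, extremes) of shift or
angle columns, and writes the pipeline's tab-separated output tables:
a backbone-geometry table (phi, psi, phi+psi, hydrogen-bond partners in
arrow notation), and per-nucleus shift/orientation tables.

Reported "mean ± sd" values use the sample (n-1) standard deviation; table
cells are rounded half-up to one decimal; undefined cells render as an
em dash. The phi+psi column is emitted as the signed sum — helical residues
give values near -105 degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import StructureModel
from .peptide_geometry import HelixFrame, HydrogenBond, ramachandran
from .tensor_core import round_report

__all__ = [
    "GroupSummary",
    "classify_residue",
    "group_stats",
    "value_range",
    "emit_report",
]

_UNDEFINED = "—"

_PROTEINOGENIC = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "SER", "THR", "TRP", "TYR", "VAL",
}
_SPECIAL = {"AIB": "Aib", "PRO": "Pro", "PHL": "Phl", "ACE": "cap"}


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: Optional[float]  # sample sd; None for singletons unless sd_zero_for_singleton
    minimum: float
    maximum: float

    @property
    def range(self) -> float:
        return self.maximum - self.minimum


def classify_residue(name: str) -> str:
    """Residue class: Aib, Pro, Phl, cap, or proteinogenic (Gly included).

    Proline and the C-terminal phenylalaninol are kept out of the
    'proteinogenic' averaging group — their amide/carbonyl environments are
    atypical (no amide H; amino-alcohol terminus).
    """
    key = name.strip().upper()
    if key in _SPECIAL:
        return _SPECIAL[key]
    if key in _PROTEINOGENIC:
        return "proteinogenic"
    raise ValueError(
        f"unknown residue code {name!r}; known: "
        f"{sorted(_PROTEINOGENIC | set(_SPECIAL))}"
    )


def group_stats(
    values: Mapping[str, float] | pd.Series,
    grouping: Mapping[str, str],
    sd_zero_for_singleton: bool = False,
) -> dict[str, GroupSummary]:
    """Per-group mean / sample sd / extremes of labelled values.

    ``grouping`` maps each label to its group. Labels missing from the
    grouping are ignored; empty groups are omitted with a warning.
    """
    series = pd.Series(dict(values), dtype=float).dropna()
    out: dict[str, GroupSummary] = {}
    groups: dict[str, list[float]] = {}
    for label, value in series.items():
        g = grouping.get(label)
        if g is not None:
            groups.setdefault(g, []).append(float(value))
    for g in set(grouping.values()):
        vals = groups.get(g, [])
        if not vals:
            warnings.warn(f"group {g!r} is empty; omitted", stacklevel=2)
            continue
        arr = np.asarray(vals)
        if len(arr) > 1:
            sd = float(arr.std(ddof=1))
        else:
            sd = 0.0 if sd_zero_for_singleton else None
        out[g] = GroupSummary(
            label=g, n=len(arr), mean=float(arr.mean()), sd=sd,
            minimum=float(arr.min()), maximum=float(arr.max()),
        )
    return out


def value_range(values: Iterable[float]) -> tuple[float, float, float]:
    """(min, max, max - min) of a non-empty collection."""
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        raise ValueError("empty value collection")
    return float(arr.min()), float(arr.max()), float(arr.max() - arr.min())


def _fmt(v, decimals: int = 1) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return _UNDEFINED
    return f"{round_report(float(v), decimals):.{decimals}f}"


def emit_report(
    model: StructureModel,
    out_dir: str | Path,
    shifts_15n: Optional[pd.DataFrame] = None,
    shifts_13c: Optional[pd.DataFrame] = None,
    hbonds: Optional[Sequence[HydrogenBond]] = None,
    frame: Optional[HelixFrame] = None,
    membrane_normal=(0.0, 0.0, 1.0),
) -> dict:
    """Write the TSV bundle and run log; returns paths and log lines.

    Always emits the backbone-geometry table from ``model``. Shift tables
    (columns residue, eps_iso, eps11, eps22, eps33, alpha, beta, gamma, and
    eps_aniso for 13C) are emitted when the corresponding DataFrame is
    given. The run log records group statistics per nucleus and, if a helix
    frame is supplied, the tilt against ``membrane_normal``.
    """
    if not model.atoms:
        raise ValueError("empty structure model: nothing to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    paths: dict[str, Path] = {}

    frames = ramachandran(model)
    names = {fr.index: _short_name(fr.name) for fr in frames}
    hb_by_acceptor: dict[int, list[str]] = {}
    hb_by_donor: dict[int, list[str]] = {}
    for hb in hbonds or []:
        hb_by_acceptor.setdefault(hb.acceptor, []).append(f"→{names.get(hb.donor, hb.donor)}{hb.donor}")
        hb_by_donor.setdefault(hb.donor, []).append(f"{names.get(hb.acceptor, hb.acceptor)}{hb.acceptor}←")
    rows = []
    for fr in frames:
        if fr.residue_class == "cap":
            continue
        involvement = ", ".join(
            hb_by_acceptor.get(fr.index, []) + hb_by_donor.get(fr.index, [])
        )
        sum_fp = None if fr.phi is None or fr.psi is None else fr.phi + fr.psi
        rows.append({
            "residue": f"{names[fr.index]}{fr.index}",
            "phi": _fmt(fr.phi, 0), "psi": _fmt(fr.psi, 0),
            "phi_plus_psi": _fmt(sum_fp, 0),
            "hbonds": involvement or _UNDEFINED,
        })
    geom = pd.DataFrame(rows)
    paths["geometry"] = out_dir / "backbone_geometry.tsv"
    geom.to_csv(paths["geometry"], sep="\t", index=False)
    log.append(f"backbone geometry: {len(geom)} residues, "
               f"{len(hbonds or [])} hydrogen bonds")

    for nucleus, df in (("15N", shifts_15n), ("13C", shifts_13c)):
        if df is None:
            continue
        table = df.copy()
        known = {f"{names[i]}{i}" for i in names}
        unknown = set(table["residue"]) - known
        if unknown and model.atoms:
            raise ValueError(
                f"{nucleus} shift table rows {sorted(unknown)} missing from structure "
                "(upstream stage incomplete?)"
            )
        out = table.copy()
        for col in out.columns:
            if col != "residue":
                out[col] = [
                    _fmt(v) if pd.notna(v) else _UNDEFINED for v in out[col]
                ]
        key = f"shifts_{nucleus.lower()}"
        paths[key] = out_dir / f"shift_table_{nucleus.lower()}.tsv"
        out.to_csv(paths[key], sep="\t", index=False)

        grouping = {
            r: classify_residue(_code_from_label(r)) for r in table["residue"]
        }
        for col in ("eps_iso", "beta"):
            if col not in table.columns:
                continue
            vals = dict(zip(table["residue"], table[col]))
            stats = group_stats(vals, grouping)
            for g in ("Aib", "proteinogenic"):
                if g in stats:
                    s = stats[g]
                    sd = "" if s.sd is None else f" ± {round_report(s.sd):.1f}"
                    log.append(
                        f"{nucleus} {col} [{g}, n={s.n}]: "
                        f"{round_report(s.mean):.1f}{sd}"
                    )

    if frame is not None:
        from .peptide_geometry import helix_tilt

        tau = helix_tilt(frame, np.asarray(membrane_normal, dtype=float))
        log.append(f"helix tilt vs membrane normal: {round_report(tau):.1f} deg")
        if frame.residue_azimuth:
            inc = _mean_azimuth_increment(frame.residue_azimuth)
            if inc is not None:
                log.append(f"mean azimuth increment: {round_report(inc):.1f} deg/residue")

    paths["log"] = out_dir / "run_log.txt"
    paths["log"].write_text("\n".join(log) + "\n")
    return {"paths": paths, "log": log}


_NAME3_TO_SHORT = {
    "AIB": "Aib", "PRO": "Pro", "ALA": "Ala", "GLN": "Gln", "VAL": "Val",
    "GLY": "Gly", "LEU": "Leu", "GLU": "Glu", "PHL": "Phl", "ACE": "Ace",
    "ARG": "Arg", "ASN": "Asn", "ASP": "Asp", "CYS": "Cys", "HIS": "His",
    "ILE": "Ile", "LYS": "Lys", "MET": "Met", "PHE": "Phe", "SER": "Ser",
    "THR": "Thr", "TRP": "Trp", "TYR": "Tyr",
}
_SHORT_TO_NAME3 = {v: k for k, v in _NAME3_TO_SHORT.items()}


def _short_name(name3: str) -> str:
    return _NAME3_TO_SHORT.get(name3.upper(), name3.capitalize())


def _code_from_label(label: str) -> str:
    short = label.rstrip("0123456789")
    return _SHORT_TO_NAME3.get(short, short.upper())


def _mean_azimuth_increment(rho: Mapping[int, float]) -> Optional[float]:
    idx = sorted(i for i, v in rho.items() if np.isfinite(v))
    diffs = [
        (rho[b] - rho[a]) % 360.0
        for a, b in zip(idx, idx[1:])
        if b - a == 1
    ]
    return float(np.mean(diffs)) if diffs else None
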