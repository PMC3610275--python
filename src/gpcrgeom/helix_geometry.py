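"""Backbone dihedrals and local helix-axis geometry.

Local axes follow the Sugeta-Miyazawa construction over sliding windows of
four consecutive C-alpha atoms: for window (i..i+3) the difference of
successive chain bisectors defines two axis-normal vectors whose cross
product is the local axis, whose mutual angle is the per-window unit twist,
and whose axial displacement is the rise.

Profile conventions (per position i):
  * unit twist(i)  = per-window twist of window (i-3 .. i)
  * unit bend(i)   = angle between the axes of windows (i-3..i) and (i..i+3)

Angles are degrees; positions lacking a complete window are NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from ._geom import DegenerateGeometryError, dihedral
from .structure_io import StructureModel

__all__ = [
    "LocalAxisFrame",
    "HelixProfile",
    "dihedral",
    "phi_psi",
    "fit_local_axes",
    "unit_twist_profile",
    "unit_bend_profile",
    "helix_profile",
]

_EPS = 1e-8


@dataclass
class LocalAxisFrame:
    window_start: int
    axis: np.ndarray
    origin: np.ndarray
    per_window_twist: float
    per_window_rise: float


@dataclass
class HelixProfile:
    """Per-position geometry indexed by offset relative to a motif residue."""

    positions: List[int]
    phi: Dict[int, float] = field(default_factory=dict)
    psi: Dict[int, float] = field(default_factory=dict)
    unit_bend: Dict[int, float] = field(default_factory=dict)
    unit_twist: Dict[int, float] = field(default_factory=dict)

    CHANNELS = ("phi", "psi", "unit_bend", "unit_twist")

    def channel(self, name: str) -> Dict[int, float]:
        if name not in self.CHANNELS:
            raise KeyError(name)
        return getattr(self, name)

    def as_array(self, name: str) -> np.ndarray:
        ch = self.channel(name)
        return np.array([ch.get(p, math.nan) for p in self.positions])

    def to_tsv(self) -> str:
        lines = ["position\tphi\tpsi\tunit_bend\tunit_twist"]
        for p in self.positions:
            vals = [self.channel(c).get(p, math.nan) for c in self.CHANNELS]
            lines.append(
                "\t".join([str(p)] + [f"{v:.3f}" if math.isfinite(v) else "NA" for v in vals])
            )
        return "\n".join(lines) + "\n"


def phi_psi(
    model: StructureModel, chain: str
) -> Dict[Tuple[int, str], Tuple[float, float]]:
    """Backbone (phi, psi) per residue, keyed by (res_seq, icode).

    Phi(i) = C(i-1)-N-CA-C, Psi(i) = N-CA-C-N(i+1); termini and residues with
    missing backbone atoms get NaN for the affected angle.
    """
    residues = [r for r in model.residues(chain) if not r.is_water]
    out: Dict[Tuple[int, str], Tuple[float, float]] = {}

    def _bb(res, name):
        try:
            return res.atom(name).coords
        except LookupError:
            return None

    for i, res in enumerate(residues):
        n, ca, c = _bb(res, "N"), _bb(res, "CA"), _bb(res, "C")
        phi = psi = math.nan
        if n is not None and ca is not None and c is not None:
            if i > 0 and _is_bonded_pred(residues[i - 1], res):
                c_prev = _bb(residues[i - 1], "C")
                if c_prev is not None:
                    try:
                        phi = dihedral(c_prev, n, ca, c)
                    except DegenerateGeometryError:
                        pass
            if i + 1 < len(residues) and _is_bonded_pred(res, residues[i + 1]):
                n_next = _bb(residues[i + 1], "N")
                if n_next is not None:
                    try:
                        psi = dihedral(n, ca, c, n_next)
                    except DegenerateGeometryError:
                        pass
        out[(res.res_seq, res.icode)] = (phi, psi)
    return out


def _is_bonded_pred(prev, cur) -> bool:
    """Heuristic chain continuity: author numbering consecutive (or icodes)."""
    if prev.chain_id != cur.chain_id:
        return False
    if prev.icode or cur.icode:
        return True  # insertion-code runs share a number; trust file order
    return cur.res_seq - prev.res_seq == 1


def fit_local_axes(ca_coords: Sequence) -> List[LocalAxisFrame]:
    """Sugeta-Miyazawa local axis for every window of 4 consecutive C-alphas."""
    ca = np.asarray(ca_coords, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3 or ca.shape[0] < 4:
        raise ValueError("need >= 4 C-alpha positions of shape (n, 3)")
    frames: List[LocalAxisFrame] = []
    for w in range(ca.shape[0] - 3):
        p1, p2, p3, p4 = ca[w : w + 4]
        v1, v2, v3 = p2 - p1, p3 - p2, p4 - p3
        u1 = v1 - v2  # axis-normal at p2
        u2 = v2 - v3  # axis-normal at p3
        n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
        axis = np.cross(u1, u2)
        na = np.linalg.norm(axis)
        if n1 < _EPS or n2 < _EPS or na < _EPS:
            raise DegenerateGeometryError(
                f"degenerate (collinear) C-alpha window starting at index {w}"
            )
        axis /= na
        cos_t = np.clip(np.dot(u1, u2) / (n1 * n2), -1.0, 1.0)
        twist = float(np.degrees(np.arccos(cos_t)))
        rise = float(abs(np.dot(v2, axis)))
        # Axis origin: step from the mid-bond point toward the axis along the
        # mean inward normal by the helix radius implied by the twist.
        mid = p2 + 0.5 * v2
        origin = mid
        radius = 0.5 * (n1 + n2) / (2.0 * max(np.sin(np.radians(twist) / 2.0), _EPS))
        inward = -(u1 / n1 + u2 / n2)
        inward -= axis * np.dot(inward, axis)
        nin = np.linalg.norm(inward)
        if nin > _EPS:
            origin = mid + radius * inward / nin
        frames.append(
            LocalAxisFrame(
                window_start=w,
                axis=axis,
                origin=origin,
                per_window_twist=twist,
                per_window_rise=rise,
            )
        )
    return frames


def _axis_angle(a1: np.ndarray, a2: np.ndarray) -> float:
    c = np.clip(abs(float(np.dot(a1, a2))), 0.0, 1.0)
    # Axes of successive windows of a continuous helix are near-parallel and
    # consistently oriented; the absolute value guards against sign flips for
    # kinks below 90 degrees.
    return float(np.degrees(np.arccos(c)))


def _ca_trace(model: StructureModel, chain: str, residue_range=None):
    residues = [
        r
        for r in model.residues(chain)
        if not r.is_water and r.has_atom("CA")
    ]
    if residue_range is not None:
        lo, hi = residue_range
        residues = [r for r in residues if lo <= r.res_seq <= hi]
    coords = np.array([r.atom("CA").coords for r in residues])
    return residues, coords


def unit_twist_profile(
    model: StructureModel, chain: str, residue_range=None
) -> Dict[int, float]:
    """Unit twist per residue number: twist(i) from C-alpha window (i-3..i)."""
    residues, coords = _ca_trace(model, chain, residue_range)
    out = {r.res_seq: math.nan for r in residues}
    if len(residues) < 4:
        return out
    frames = fit_local_axes(coords)
    for f in frames:
        out[residues[f.window_start + 3].res_seq] = f.per_window_twist
    return out


def unit_bend_profile(
    model: StructureModel, chain: str, residue_range=None
) -> Dict[int, float]:
    """Unit bend per residue number: angle between axes of windows (i-3..i)
    and (i..i+3)."""
    residues, coords = _ca_trace(model, chain, residue_range)
    out = {r.res_seq: math.nan for r in residues}
    if len(residues) < 7:
        return out
    frames = {f.window_start: f for f in fit_local_axes(coords)}
    for idx in range(3, len(residues) - 3):
        left = frames.get(idx - 3)
        right = frames.get(idx)
        if left is not None and right is not None:
            out[residues[idx].res_seq] = _axis_angle(left.axis, right.axis)
    return out


def helix_profile(
    model: StructureModel,
    chain: str,
    motif_res_seq: int,
    offsets: Sequence[int] = tuple(range(-7, 5)),
) -> HelixProfile:
    """Phi/psi/bend/twist profile at offsets relative to a motif residue."""
    residues = [
        r for r in model.residues(chain) if not r.is_water and r.has_atom("CA")
    ]
    seq_nums = [r.res_seq for r in residues]
    if motif_res_seq not in seq_nums:
        raise LookupError(f"motif residue {motif_res_seq} absent in chain {chain}")
    angles = phi_psi(model, chain)
    twists = unit_twist_profile(model, chain)
    bends = unit_bend_profile(model, chain)
    profile = HelixProfile(positions=list(offsets))
    for off in offsets:
        res_seq = motif_res_seq + off
        if res_seq not in seq_nums:
            continue
        phi, psi = angles.get((res_seq, ""), (math.nan, math.nan))
        profile.phi[off] = phi
        profile.psi[off] = psi
        profile.unit_bend[off] = bends.get(res_seq, math.nan)
        profile.unit_twist[off] = twists.get(res_seq, math.nan)
    return profile
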