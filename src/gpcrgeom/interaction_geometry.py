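"""TM6-TM7 interaction geometry: donor-acceptor distances, Cbeta-D...A
angles, hydrogen-bond verdicts, amide-flip assessment and hydrogen-bond
network scans over a configured set of generic positions.

Hydrogen-bond criteria are heavy-atom and element-dependent: thiol sulfur
donors use a long, direction-free distance cutoff (sulfur hydrogen bonds are
weakly directional, with flat attractive potentials at long range); hydroxyl
oxygen donors use a conventional shorter cutoff plus a loose angular floor.
Both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._geom import angle, distance
from .bw_numbering import BWMap
from .structure_io import Residue, StructureModel

__all__ = [
    "HBondCriteria",
    "HBondGeometry",
    "FlipAssessment",
    "NetworkReport",
    "measure_pair",
    "hbond_verdict",
    "assess_amide_flip",
    "network_scan",
    "table1_report",
]


@dataclass(frozen=True)
class HBondCriteria:
    # S cutoff calibrated so a 4.3 A thiol-amide pair still qualifies while
    # a 4.4 A one does not (long, weakly directional sulfur hydrogen bonds).
    s_donor_max_distance: float = 4.35
    o_donor_max_distance: float = 3.5
    o_donor_min_angle: float = 60.0
    n_donor_max_distance: float = 3.5

    def max_distance(self, donor_element: str) -> float:
        return {
            "S": self.s_donor_max_distance,
            "O": self.o_donor_max_distance,
            "N": self.n_donor_max_distance,
        }.get(donor_element.upper(), self.o_donor_max_distance)


DEFAULT_CRITERIA = HBondCriteria()

# Side-chain donor heavy atoms by residue type (terminal H-bearing atoms).
DONOR_ATOMS: Dict[str, Tuple[str, ...]] = {
    "CYS": ("SG",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "TRP": ("NE1",),
}

# Side-chain acceptor heavy atoms by residue type.
ACCEPTOR_ATOMS: Dict[str, Tuple[str, ...]] = {
    "ASN": ("OD1", "ND2"),  # amide orientation ambiguity: nearer atom chosen
    "GLN": ("OE1", "NE2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "CYS": ("SG",),
    "MET": ("SD",),
}

_AMIDE_PAIRS = {"ASN": ("OD1", "ND2"), "GLN": ("OE1", "NE2")}


@dataclass
class HBondGeometry:
    donor_address: Tuple[str, int, str]
    donor_atom: str
    acceptor_address: Tuple[str, int, str]
    acceptor_atom: str
    da_distance: float
    cb_d_a_angle: float
    facing_group: str  # "CO" | "NH2" | "-"
    is_hbond: bool
    donor_position: str = ""
    acceptor_position: str = ""

    @property
    def pair_label(self) -> str:
        return f"{self.donor_position}-{self.acceptor_position}"


def _element_of(atom_name: str) -> str:
    return atom_name.strip()[0]


def _pick_donor_atom(residue: Residue, reference: Optional[np.ndarray]):
    names = DONOR_ATOMS.get(residue.res_name)
    if not names:
        raise LookupError(
            f"no side-chain donor defined for {residue.res_name} "
            f"{residue.chain_id}{residue.res_seq}"
        )
    atoms = [residue.atom(n) for n in names if residue.has_atom(n)]
    if not atoms:
        raise LookupError(
            f"donor atom(s) {names} missing in {residue.res_name} "
            f"{residue.chain_id}{residue.res_seq}"
        )
    if reference is None or len(atoms) == 1:
        return atoms[0]
    return min(atoms, key=lambda a: distance(a.coords, reference))


def _pick_acceptor_atom(residue: Residue, reference: np.ndarray, backbone: bool):
    """Acceptor atom and the Table-1-style facing group annotation."""
    if backbone:
        return residue.atom("O"), "-"
    names = ACCEPTOR_ATOMS.get(residue.res_name)
    if not names:
        raise LookupError(
            f"no side-chain acceptor defined for {residue.res_name} "
            f"{residue.chain_id}{residue.res_seq}"
        )
    atoms = [residue.atom(n) for n in names if residue.has_atom(n)]
    if not atoms:
        raise LookupError(
            f"acceptor atom(s) {names} missing in {residue.res_name} "
            f"{residue.chain_id}{residue.res_seq}"
        )
    chosen = min(atoms, key=lambda a: distance(a.coords, reference))
    facing = "-"
    amide = _AMIDE_PAIRS.get(residue.res_name)
    if amide:
        facing = "CO" if chosen.name == amide[0] else "NH2"
    return chosen, facing


def hbond_verdict(
    geometry: "HBondGeometry | float",
    donor_element: str,
    criteria: HBondCriteria = DEFAULT_CRITERIA,
) -> bool:
    """Distance-dominant hydrogen-bond call.

    Sulfur donors: distance cutoff only.  Oxygen/nitrogen donors: distance
    cutoff plus a loose angular floor on the Cbeta-D...A angle.
    """
    if isinstance(geometry, HBondGeometry):
        d, theta = geometry.da_distance, geometry.cb_d_a_angle
    else:
        d, theta = float(geometry), 180.0
    el = donor_element.upper()
    if d > criteria.max_distance(el):
        return False
    if el == "S":
        return True
    return theta >= criteria.o_donor_min_angle


def measure_pair(
    model: StructureModel,
    bw_map: BWMap,
    donor_pos: str,
    acceptor_pos: str,
    backbone_acceptor: bool = False,
    criteria: HBondCriteria = DEFAULT_CRITERIA,
) -> HBondGeometry:
    """Donor-acceptor geometry between two generic positions.

    Donor atom: side-chain terminal heavy atom of the donor residue.
    Acceptor atom: nearer amide atom for Asn/Gln (recorded as facing CO/NH2),
    the hydroxyl oxygen for Ser/Thr, the backbone carbonyl O when
    ``backbone_acceptor`` is set.
    """
    d_chain, d_seq = bw_map.address(donor_pos)
    a_chain, a_seq = bw_map.address(acceptor_pos)
    donor_res = model.residue(d_chain, d_seq)
    acceptor_res = model.residue(a_chain, a_seq)

    acceptor_probe = acceptor_res.atom("CA").coords
    donor_atom = _pick_donor_atom(donor_res, acceptor_probe)
    acceptor_atom, facing = _pick_acceptor_atom(
        acceptor_res, donor_atom.coords, backbone_acceptor
    )
    da = distance(donor_atom.coords, acceptor_atom.coords)
    cb_name = "CB" if donor_res.has_atom("CB") else "CA"
    theta = angle(
        donor_res.atom(cb_name).coords, donor_atom.coords, acceptor_atom.coords
    )
    geom = HBondGeometry(
        donor_address=donor_res.address(),
        donor_atom=donor_atom.name,
        acceptor_address=acceptor_res.address(),
        acceptor_atom=acceptor_atom.name,
        da_distance=da,
        cb_d_a_angle=theta,
        facing_group=facing,
        is_hbond=False,
        donor_position=donor_pos,
        acceptor_position=acceptor_pos,
    )
    geom.is_hbond = hbond_verdict(geom, _element_of(donor_atom.name), criteria)
    return geom


@dataclass
class FlipAssessment:
    residue_address: Tuple[str, int, str]
    score_deposited: int
    score_flipped: int

    @property
    def preferred(self) -> str:
        if self.score_deposited > self.score_flipped:
            return "deposited"
        if self.score_flipped > self.score_deposited:
            return "flipped"
        return "tie"


_POLAR_DONOR_ATOMS = {
    "SG", "OG", "OG1", "OH", "ND2", "NE2", "ND1", "NZ", "NE", "NH1", "NH2",
    "NE1", "N",
}
_POLAR_ACCEPTOR_ATOMS = {
    "O", "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH", "ND1", "NE2", "SD",
}


def _environment_polar_atoms(model, amide_res, radius):
    center = np.mean([a.coords for a in amide_res.atoms], axis=0)
    out = []
    for res in model.iter_residues():
        if res is amide_res:
            continue
        for atom in res.atoms:
            if atom.element not in ("N", "O", "S"):
                continue
            if np.linalg.norm(atom.coords - center) > radius:
                continue
            is_water = res.is_water
            name = atom.name
            donor = is_water or name in _POLAR_DONOR_ATOMS
            acceptor = is_water or name in _POLAR_ACCEPTOR_ATOMS
            if donor or acceptor:
                out.append((atom, donor, acceptor))
    return out


def _amide_contact_score(o_coord, n_coord, env, criteria: HBondCriteria) -> int:
    """Favorable complementary contacts minus 2x like-atom clashes."""
    favorable = clashes = 0
    for atom, is_donor, is_acceptor in env:
        el = atom.element
        d_o = float(np.linalg.norm(atom.coords - o_coord))
        d_n = float(np.linalg.norm(atom.coords - n_coord))
        cutoff = 4.2 if el == "S" else 3.5
        # amide oxygen accepts from environment donors
        if is_donor and el != "O" and d_o <= cutoff:
            favorable += 1
        # amide nitrogen donates to environment acceptors
        if is_acceptor and el != "N" and d_n <= cutoff:
            favorable += 1
        if el == "O" and d_o < 3.0:
            clashes += 1
        if el == "N" and d_n < 3.0:
            clashes += 1
    return favorable - 2 * clashes


def assess_amide_flip(
    model: StructureModel,
    bw_map: BWMap,
    asn_pos: str,
    environment_radius: float = 6.0,
    criteria: HBondCriteria = DEFAULT_CRITERIA,
) -> FlipAssessment:
    """Score the deposited vs flipped orientation of an Asn/Gln amide.

    The flipped orientation swaps the terminal O/N coordinates.  The score is
    a qualitative contact count (complementary polar contacts within
    hydrogen-bond cutoffs, minus 2 per like-atom clash under 3.0 A), a
    documented surrogate for knowledge-based amide-flip tools.
    """
    chain, res_seq = bw_map.address(asn_pos)
    res = model.residue(chain, res_seq)
    amide = _AMIDE_PAIRS.get(res.res_name)
    if amide is None:
        raise ValueError(f"{res.res_name} at {asn_pos} carries no flippable amide")
    o_name, n_name = amide
    if not (res.has_atom(o_name) and res.has_atom(n_name)):
        raise LookupError(f"incomplete amide in {res.res_name} {chain}{res_seq}")
    o_coord = res.atom(o_name).coords
    n_coord = res.atom(n_name).coords
    env = _environment_polar_atoms(model, res, environment_radius)
    deposited = _amide_contact_score(o_coord, n_coord, env, criteria)
    flipped = _amide_contact_score(n_coord, o_coord, env, criteria)
    return FlipAssessment(
        residue_address=res.address(),
        score_deposited=deposited,
        score_flipped=flipped,
    )


def apply_amide_flip(model: StructureModel, chain: str, res_seq: int) -> None:
    """Swap the terminal amide O/N coordinates of an Asn/Gln in place."""
    res = model.residue(chain, res_seq)
    amide = _AMIDE_PAIRS.get(res.res_name)
    if amide is None:
        raise ValueError(f"{res.res_name} {chain}{res_seq} carries no amide")
    a, b = res.atom(amide[0]), res.atom(amide[1])
    a.coords, b.coords = b.coords.copy(), a.coords.copy()


@dataclass
class NetworkReport:
    edges: List[HBondGeometry]
    present_pairs: List[str]
    absent_pairs: List[str]
    water_bridges: List[Tuple[str, str, Tuple[str, int]]] = field(default_factory=list)


def network_scan(
    model: StructureModel,
    bw_map: BWMap,
    position_set: Sequence[str],
    include_backbone: bool = False,
    water_bridges: bool = False,
    criteria: HBondCriteria = DEFAULT_CRITERIA,
) -> NetworkReport:
    """Hydrogen-bond edges among all ordered pairs of the configured positions.

    An unordered pair is "present" when at least one direction (or, with
    ``include_backbone``, a side-chain-to-backbone-carbonyl contact) passes
    the hydrogen-bond criteria.  With ``water_bridges``, crystallographic
    waters within 3.5 A of polar atoms of two set members are reported.
    """
    edges: List[HBondGeometry] = []
    present: Dict[frozenset, bool] = {}
    for donor_pos in position_set:
        for acceptor_pos in position_set:
            if donor_pos == acceptor_pos:
                continue
            key = frozenset((donor_pos, acceptor_pos))
            present.setdefault(key, False)
            variants = [False, True] if include_backbone else [False]
            for backbone in variants:
                try:
                    geom = measure_pair(
                        model, bw_map, donor_pos, acceptor_pos,
                        backbone_acceptor=backbone, criteria=criteria,
                    )
                except LookupError:
                    continue
                edges.append(geom)
                if geom.is_hbond:
                    present[key] = True

    def _label(key) -> str:
        a, b = sorted(key, key=lambda p: (p.split(".")[0], p))
        return f"{a}-{b}"

    present_pairs = sorted(_label(k) for k, v in present.items() if v)
    absent_pairs = sorted(_label(k) for k, v in present.items() if not v)

    bridges = []
    if water_bridges:
        polar = {}
        for pos in position_set:
            try:
                chain, seq = bw_map.address(pos)
                res = model.residue(chain, seq)
            except LookupError:
                continue
            polar[pos] = [
                a for a in res.atoms if a.element in ("N", "O", "S")
            ]
        waters = [r for r in model.iter_residues() if r.is_water]
        for water in waters:
            try:
                w = water.atom("O").coords
            except LookupError:
                continue
            near = [
                pos
                for pos, atoms in polar.items()
                if any(np.linalg.norm(a.coords - w) <= 3.5 for a in atoms)
            ]
            for i in range(len(near)):
                for j in range(i + 1, len(near)):
                    bridges.append(
                        (near[i], near[j], (water.chain_id, water.res_seq))
                    )
    return NetworkReport(
        edges=edges,
        present_pairs=present_pairs,
        absent_pairs=absent_pairs,
        water_bridges=bridges,
    )


def table1_report(
    entries: Sequence[dict],
    criteria: HBondCriteria = DEFAULT_CRITERIA,
) -> pd.DataFrame:
    """One row per structure: pair label, facing group, distance, angle, verdict.

    Each entry is a dict with keys ``structure`` (StructureModel),
    ``anchors`` ("auto" or explicit config) or a precomputed ``bw_map``,
    ``donor_pos``, ``acceptor_pos`` and optional ``label`` /
    ``backbone_acceptor``.  Per-row failures are collected into the
    ``error`` column rather than raised.
    """
    from .bw_numbering import build_bw_map

    rows = []
    for entry in entries:
        row = {
            "structure": entry.get("label", ""),
            "pdb_id": "",
            "pair": "",
            "facing": "-",
            "da_distance": "-",
            "cb_d_a_angle": "-",
            "is_hbond": "-",
            "error": "",
        }
        try:
            model = entry["structure"]
            row["pdb_id"] = model.source_id
            bw_map = entry.get("bw_map")
            if bw_map is None:
                bw_map = build_bw_map(model, entry.get("anchors", "auto"))
            geom = measure_pair(
                model,
                bw_map,
                entry["donor_pos"],
                entry["acceptor_pos"],
                backbone_acceptor=entry.get("backbone_acceptor", False),
                criteria=criteria,
            )
            donor_letter = {"CYS": "C", "THR": "T", "SER": "S", "GLN": "Q"}.get(
                geom.donor_address[2], geom.donor_address[2]
            )
            acceptor_letter = {
                "ASN": "N", "THR": "T", "SER": "S", "HIS": "H",
            }.get(geom.acceptor_address[2], geom.acceptor_address[2])
            row["pair"] = (
                f"{donor_letter}{geom.donor_position}-"
                f"{acceptor_letter}{geom.acceptor_position}"
            )
            row["facing"] = geom.facing_group
            row["da_distance"] = f"{geom.da_distance:.1f}"
            row["cb_d_a_angle"] = f"{geom.cb_d_a_angle:.1f}"
            row["is_hbond"] = bool(geom.is_hbond)
        except Exception as exc:  # per-row errors are reported, not fatal
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    columns = [
        "structure", "pdb_id", "pair", "facing",
        "da_distance", "cb_d_a_angle", "is_hbond", "error",
    ]
    return pd.DataFrame(rows, columns=columns)
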