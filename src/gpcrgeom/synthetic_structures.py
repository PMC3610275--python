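"""Synthetic fixtures: ideal and kinked helical peptides with controlled
backbone/side-chain geometry, perturbed conformational ensembles, engineered
donor-acceptor fixtures and toy alignments.

The peptide builder places atoms sequentially from internal coordinates
(standard bond lengths/angles, NeRF construction), so every requested
phi/psi/chi1 is recovered exactly by the analysis modules; a requested kink
is imposed as a rigid rotation of the C-terminal segment about an axis
through the apex C-alpha perpendicular to the local helix axis.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._geom import place_atom, rotation_about_axis
from .structure_io import Atom, Ensemble, Residue, StructureModel

__all__ = [
    "PeptideSpec",
    "EnsembleSpec",
    "build_peptide",
    "build_all_conformers",
    "perturb_ensemble",
    "build_hbond_fixture",
    "toy_alignment",
]

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# Backbone internal coordinates (lengths in Angstrom, angles in degrees).
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
A_C_N_CA = 121.7
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_CA_C_O = 120.8
OMEGA = 180.0

# Side-chain template values (CCD ideal geometry).
B_CA_CB = 1.529
A_C_CA_CB = 109.5
T_N_C_CA_CB = 120.0  # L-configuration chirality branch
GAMMA_TEMPLATES = {
    "CYS": ("SG", 1.814, 109.5),
    "SER": ("OG", 1.428, 109.5),
    "THR": ("OG1", 1.428, 109.5),
    "ASN": ("CG", 1.507, 109.5),
    "GLN": ("CG", 1.52, 109.5),
    "TRP": ("CG", 1.50, 113.6),
    "LEU": ("CG", 1.53, 116.3),
    "PRO": ("CG", 1.495, 104.5),
}
_NO_CHI1 = ("GLY", "ALA")


@dataclass
class PeptideSpec:
    sequence: str
    phi: float = -57.0
    psi: float = -47.0
    chi1_targets: Dict[int, float] = field(default_factory=dict)  # 0-based index
    kink: Optional[Tuple[int, float]] = None  # (apex 0-based index, degrees)
    chain_id: str = "A"
    start_res_seq: int = 1
    label: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = sorted(set(self.sequence) - set(ONE_TO_THREE))
        if bad:
            raise ValueError(f"invalid residue letters: {bad}")
        for idx in self.chi1_targets:
            if not 0 <= idx < len(self.sequence):
                raise ValueError(f"chi1 target index {idx} out of range")
            if ONE_TO_THREE[self.sequence[idx]] in _NO_CHI1:
                raise ValueError(
                    f"chi1 target on {self.sequence[idx]} at index {idx}: "
                    "residue has no chi1"
                )
        if self.kink is not None:
            apex, _ = self.kink
            if not 0 < apex < len(self.sequence) - 1:
                raise ValueError("kink apex must be an interior residue")


@dataclass
class EnsembleSpec:
    base: PeptideSpec
    n_frames: int
    noise_sigma: float
    seed: int
    include_base_frame: bool = False

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _ls_axis(points: np.ndarray) -> np.ndarray:
    """Total-least-squares line direction through a run of points."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if np.dot(axis, points[-1] - points[0]) < 0:
        axis = -axis
    return axis


def _place_sidechain(res_name, atoms, n, ca, c, chi1_target):
    """CB (and the gamma/remaining template atoms) for one residue."""
    if res_name == "GLY":
        return
    cb_len, cb_ang = (1.543, 110.4) if res_name == "PRO" else (B_CA_CB, A_C_CA_CB)
    t_cb = 115.3 if res_name == "PRO" else T_N_C_CA_CB
    cb = place_atom(n, c, ca, cb_len, cb_ang, t_cb)
    atoms.append(Atom("CB", "C", cb))
    if res_name == "ALA":
        return
    template = GAMMA_TEMPLATES.get(res_name)
    if template is None:
        return  # backbone + CB is enough for unlisted residue types
    gname, glen, gang = template
    chi1 = -23.8 if res_name == "PRO" and chi1_target is None else chi1_target
    if chi1 is None:
        chi1 = -60.0
    gamma = place_atom(n, ca, cb, glen, gang, chi1)
    atoms.append(Atom(gname, gname[0], gamma))
    if res_name == "THR":
        cg2 = place_atom(n, ca, cb, 1.530, 109.5, chi1 - 120.0)
        atoms.append(Atom("CG2", "C", cg2))
    elif res_name == "ASN":
        od1 = place_atom(ca, cb, gamma, 1.213, 120.0, -60.0)
        nd2 = place_atom(ca, cb, gamma, 1.348, 120.0, 120.0)
        atoms.append(Atom("OD1", "O", od1))
        atoms.append(Atom("ND2", "N", nd2))
    elif res_name == "GLN":
        cd = place_atom(ca, cb, gamma, 1.52, 112.6, 180.0)
        atoms.append(Atom("CD", "C", cd))
        atoms.append(Atom("OE1", "O", place_atom(cb, gamma, cd, 1.213, 120.0, -60.0)))
        atoms.append(Atom("NE2", "N", place_atom(cb, gamma, cd, 1.348, 120.0, 120.0)))
    elif res_name == "PRO":
        cd = place_atom(ca, cb, gamma, 1.544, 105.6, 0.0)
        atoms.append(Atom("CD", "C", cd))


def build_peptide(spec: PeptideSpec) -> StructureModel:
    """Construct a peptide from internal coordinates honoring the spec.

    Backbone phi/psi are honored exactly (omega fixed at 180); side-chain
    chi1 targets are honored exactly; the optional kink rotates the
    C-terminal segment rigidly to the requested inter-segment axis angle.
    """
    seq = spec.sequence
    n_res = len(seq)
    phi = np.full(n_res, float(spec.phi))
    psi = np.full(n_res, float(spec.psi))

    backbone: List[Dict[str, np.ndarray]] = []
    for i in range(n_res):
        if i == 0:
            n = np.zeros(3)
            ca = np.array([B_N_CA, 0.0, 0.0])
            alpha = np.radians(180.0 - A_N_CA_C)
            c = ca + B_CA_C * np.array([np.cos(alpha), np.sin(alpha), 0.0])
        else:
            prev = backbone[i - 1]
            n = place_atom(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psi[i - 1])
            ca = place_atom(prev["CA"], prev["C"], n, B_N_CA, A_C_N_CA, OMEGA)
            c = place_atom(prev["C"], n, ca, B_CA_C, A_N_CA_C, phi[i])
        backbone.append({"N": n, "CA": ca, "C": c})
    for i in range(n_res):
        bb = backbone[i]
        bb["O"] = place_atom(
            bb["N"], bb["CA"], bb["C"], B_C_O, A_CA_C_O, psi[i] + 180.0
        )

    residues: List[Residue] = []
    for i, letter in enumerate(seq):
        res_name = ONE_TO_THREE[letter]
        bb = backbone[i]
        atoms = [
            Atom("N", "N", bb["N"]),
            Atom("CA", "C", bb["CA"]),
            Atom("C", "C", bb["C"]),
            Atom("O", "O", bb["O"]),
        ]
        _place_sidechain(
            res_name, atoms, bb["N"], bb["CA"], bb["C"], spec.chi1_targets.get(i)
        )
        residues.append(
            Residue(
                res_name=res_name,
                res_seq=spec.start_res_seq + i,
                chain_id=spec.chain_id,
                atoms=atoms,
            )
        )

    if spec.kink is not None:
        _apply_kink(residues, *spec.kink)

    return StructureModel(
        model_id=1,
        chains={spec.chain_id: residues},
        source_id=spec.label or f"peptide-{seq[:8]}",
    )


def _apply_kink(residues: List[Residue], apex: int, kink_deg: float) -> None:
    """Rotate the C-terminal segment rigidly about an axis through the apex
    C-alpha, perpendicular to the N-segment helix axis."""
    ca = np.array([r.atom("CA").coords for r in residues])
    helix_axis = _ls_axis(ca[: apex + 1])
    seed_dir = np.eye(3)[np.argmin(np.abs(helix_axis))]
    rot_axis = np.cross(helix_axis, seed_dir)
    rot_axis /= np.linalg.norm(rot_axis)
    rot = rotation_about_axis(rot_axis, kink_deg)
    pivot = residues[apex].atom("CA").coords

    def _rotate(atom: Atom):
        atom.coords = pivot + rot @ (atom.coords - pivot)

    for name in ("C", "O"):
        if residues[apex].has_atom(name):
            _rotate(residues[apex].atom(name))
    for res in residues[apex + 1 :]:
        for atom in res.atoms:
            _rotate(atom)


_CHI1_BY_LABEL = {"g+": -60.0, "g-": 60.0, "t": 180.0}


def build_all_conformers(
    x_residues: Sequence[str] = ("C", "S", "T"),
    motif: str = "XAAP",
    length: int = 25,
    phi: float = -57.0,
    psi: float = -47.0,
) -> Dict[str, Tuple[PeptideSpec, StructureModel]]:
    """The reference AAAP peptide plus every chi1 conformer of each X.

    For the default three X residues this yields 10 labeled systems:
    "AAAP" and "<X><label>" for label in g+/g-/t (chi1 -60/+60/180).
    """
    if motif not in ("XAAP", "XWAP"):
        raise ValueError("motif must be XAAP or XWAP")
    x_index = length // 2 - 2  # X at i; P lands at i+3
    core = "AAP" if motif == "XAAP" else "WAP"
    out: Dict[str, Tuple[PeptideSpec, StructureModel]] = {}

    def _sequence(x: str) -> str:
        seq = ["A"] * length
        seq[x_index : x_index + 4] = list(x + core)
        return "".join(seq)

    ref_label = "A" + core
    ref = PeptideSpec(sequence=_sequence("A"), phi=phi, psi=psi, label=ref_label)
    out[ref_label] = (ref, build_peptide(ref))
    for x in x_residues:
        for rot_label, chi in _CHI1_BY_LABEL.items():
            label = f"{x}{rot_label}{core}"
            spec = PeptideSpec(
                sequence=_sequence(x.upper()),
                phi=phi,
                psi=psi,
                chi1_targets={x_index: chi},
                label=label,
            )
            out[label] = (spec, build_peptide(spec))
    return out


def motif_x_index(length: int = 25) -> int:
    """0-based index of the X residue used by :func:`build_all_conformers`."""
    return length // 2 - 2


def perturb_ensemble(spec: EnsembleSpec) -> Ensemble:
    """Gaussian-perturbed copies of the base peptide, deterministic per seed."""
    base = build_peptide(spec.base)
    rng = np.random.default_rng(spec.seed)
    models: List[StructureModel] = []
    for frame in range(spec.n_frames):
        model = copy.deepcopy(base)
        model.model_id = frame + 1
        if spec.noise_sigma > 0 and not (spec.include_base_frame and frame == 0):
            for res in model.iter_residues():
                for atom in res.atoms:
                    atom.coords = atom.coords + rng.normal(
                        0.0, spec.noise_sigma, size=3
                    )
        models.append(model)
    return Ensemble(models=models, source_id=spec.base.label or "ensemble")


def build_hbond_fixture(
    donor_res: str,
    acceptor_res: str,
    da_distance: float,
    approach_angle: float,
) -> StructureModel:
    """Two residues engineered so the donor terminal atom and the acceptor
    atom sit at exactly the requested distance and Cbeta-D...A angle.

    The donor occupies residue 1, the acceptor residue 2, both chain A.
    For Asn/Gln acceptors the carbonyl-like atom (OD1/OE1) is placed at the
    target point and the amide nitrogen strictly farther from the donor.
    """
    donor_res = donor_res.upper()
    acceptor_res = acceptor_res.upper()
    if da_distance <= 0:
        raise ValueError("da_distance must be positive")
    if not 0.0 < approach_angle <= 180.0:
        raise ValueError("approach_angle must be in (0, 180]")
    donor_atom_name = {"CYS": "SG", "SER": "OG", "THR": "OG1"}.get(donor_res)
    if donor_atom_name is None:
        raise ValueError(f"unsupported donor residue {donor_res}")

    donor_spec = PeptideSpec(sequence={"CYS": "C", "SER": "S", "THR": "T"}[donor_res])
    donor = build_peptide(donor_spec).residues("A")[0]
    cb = donor.atom("CB").coords
    d = donor.atom(donor_atom_name).coords

    u = cb - d
    u /= np.linalg.norm(u)  # from donor atom toward CB
    seed_dir = np.eye(3)[np.argmin(np.abs(u))]
    p = np.cross(u, seed_dir)
    p /= np.linalg.norm(p)
    theta = np.radians(approach_angle)
    acceptor_point = d + da_distance * (np.cos(theta) * u + np.sin(theta) * p)

    e1 = acceptor_point - d
    e1 /= np.linalg.norm(e1)  # away from the donor
    e2 = np.cross(e1, p)
    if np.linalg.norm(e2) < 1e-8:
        e2 = np.cross(e1, u)
    e2 /= np.linalg.norm(e2)

    atoms: List[Atom] = []
    if acceptor_res in ("ASN", "GLN"):
        o_name, n_name, c_name = (
            ("OD1", "ND2", "CG") if acceptor_res == "ASN" else ("OE1", "NE2", "CD")
        )
        cg = acceptor_point + 1.231 * e1
        nd = cg + 1.348 * (np.cos(np.radians(124)) * (-e1) + np.sin(np.radians(124)) * e2)
        # push the amide nitrogen to the far side of the donor if needed
        if np.linalg.norm(nd - d) <= np.linalg.norm(acceptor_point - d):
            nd = cg + 1.348 * (
                np.cos(np.radians(124)) * (-e1) - np.sin(np.radians(124)) * e2
            )
        cb_a = cg + 1.507 * (np.cos(np.radians(116)) * (-e1) - np.sin(np.radians(116)) * e2)
        atoms = [
            Atom(o_name, "O", acceptor_point),
            Atom(c_name, "C", cg),
            Atom(n_name, "N", nd),
            Atom("CB", "C", cb_a),
        ]
        anchor = cb_a
    elif acceptor_res in ("SER", "THR"):
        og = {"SER": "OG", "THR": "OG1"}[acceptor_res]
        cb_a = acceptor_point + 1.428 * e1
        atoms = [Atom(og, "O", acceptor_point), Atom("CB", "C", cb_a)]
        anchor = cb_a
    else:
        raise ValueError(f"unsupported acceptor residue {acceptor_res}")
    ca_a = anchor + 1.53 * e1
    n_a = ca_a + 1.458 * e2
    atoms.append(Atom("CA", "C", ca_a))
    atoms.append(Atom("N", "N", n_a))

    acceptor = Residue(res_name=acceptor_res, res_seq=2, chain_id="A", atoms=atoms)
    return StructureModel(
        model_id=1,
        chains={"A": [donor, acceptor]},
        source_id=f"hbond-fixture-{donor_res}-{acceptor_res}",
    )


def toy_alignment(
    n_seqs: int,
    column_spec: Mapping[str, Mapping[str, float]],
    seed: int,
    filler: str = "A",
) -> Tuple[MultipleSeqAlignment, Dict[str, int]]:
    """Generate an aligned FASTA-ready toy alignment with controlled columns.

    ``column_spec`` maps generic positions to per-residue compositions.
    Integer compositions are exact counts (remainder of ``n_seqs`` becomes
    gaps); float compositions are sampling probabilities (must sum to <= 1,
    remainder is the gap probability).  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    positions = list(column_spec)
    column_map = {pos: i for i, pos in enumerate(positions)}
    columns = []
    for pos in positions:
        comp = dict(column_spec[pos])
        if not comp:
            raise ValueError(f"empty composition for {pos}")
        if all(float(v).is_integer() for v in comp.values()):
            total = int(sum(comp.values()))
            if total > n_seqs:
                raise ValueError(f"counts for {pos} exceed n_seqs")
            col = []
            for aa, count in comp.items():
                col.extend([aa] * int(count))
            col.extend(["-"] * (n_seqs - total))
        else:
            probs = {aa: float(v) for aa, v in comp.items()}
            psum = sum(probs.values())
            if psum > 1.0 + 1e-9 or any(v < 0 for v in probs.values()):
                raise ValueError(f"invalid probabilities for {pos}")
            choices = list(probs) + ["-"]
            weights = list(probs.values()) + [max(0.0, 1.0 - psum)]
            weights = np.asarray(weights) / np.sum(weights)
            col = list(rng.choice(choices, size=n_seqs, p=weights))
        columns.append(col)
    records = []
    for s in range(n_seqs):
        seq = "".join(columns[c][s] for c in range(len(columns)))
        records.append(SeqRecord(Seq(seq), id=f"seq{s+1}", description=""))
    return MultipleSeqAlignment(records), column_map
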