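"""Chi1 side-chain dihedrals and g+/g-/t rotamer classification.

Label convention: ``g+`` is the chi1 ~ -60 degree well, ``g-`` the +60 well
and ``t`` the 180 well, with class boundaries at thirds of the circle:
g+ = [-120, 0), g- = [0, 120), t otherwise.  The convention is anchored
empirically on deposited receptor structures (the 6.47 cysteine of the
inactive beta2-adrenergic receptor classifies g+).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

from ._geom import dihedral
from .structure_io import Residue, StructureModel

__all__ = [
    "Chi1UndefinedError",
    "Chi1NotApplicableError",
    "RotamerAssignment",
    "RotamerPopulation",
    "GAMMA_ATOMS",
    "gamma_atom_name",
    "chi1",
    "classify_rotamer",
    "assign_rotamer",
    "rotamer_population",
]


class Chi1UndefinedError(LookupError):
    """Required chi1 atoms are missing."""


class Chi1NotApplicableError(ValueError):
    """The residue type has no chi1 (Gly/Ala) or no gamma heavy atom."""


# Gamma heavy atom defining chi1 = N-CA-CB-gamma, per residue type.
GAMMA_ATOMS: Dict[str, str] = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}


def gamma_atom_name(res_name: str) -> str:
    try:
        return GAMMA_ATOMS[res_name]
    except KeyError:
        raise Chi1NotApplicableError(
            f"chi1 not applicable to residue type {res_name}"
        ) from None


def chi1(residue: Residue) -> float:
    """Chi1 dihedral N-CA-CB-gamma in (-180, 180] degrees."""
    gamma = gamma_atom_name(residue.res_name)
    coords = []
    for name in ("N", "CA", "CB", gamma):
        try:
            coords.append(residue.atom(name).coords)
        except LookupError:
            raise Chi1UndefinedError(
                f"atom {name} missing in {residue.res_name} "
                f"{residue.chain_id}{residue.res_seq}; chi1 undefined"
            ) from None
    return dihedral(*coords)


def classify_rotamer(chi1_deg: float) -> str:
    """g+ for chi1 in [-120, 0); g- for [0, 120); t otherwise."""
    x = float(chi1_deg)
    if not -180.0 < x <= 180.0 or x != x:
        x = ((x + 180.0) % 360.0) - 180.0
    if -120.0 <= x < 0.0:
        return "g+"
    if 0.0 <= x < 120.0:
        return "g-"
    return "t"


@dataclass
class RotamerAssignment:
    residue_address: Tuple[str, int, str]  # (chain, res_seq, res_name)
    chi1: float
    label: str
    gamma_atom: str

    @classmethod
    def from_residue(cls, residue: Residue) -> "RotamerAssignment":
        value = chi1(residue)
        return cls(
            residue_address=residue.address(),
            chi1=value,
            label=classify_rotamer(value),
            gamma_atom=gamma_atom_name(residue.res_name),
        )


def assign_rotamer(residue: Residue) -> RotamerAssignment:
    return RotamerAssignment.from_residue(residue)


@dataclass
class RotamerPopulation:
    res_name: str
    counts: Dict[str, int]

    LABELS = ("g-", "g+", "t")

    @property
    def n_observations(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> Dict[str, float]:
        n = self.n_observations
        return {lab: 100.0 * self.counts.get(lab, 0) / n for lab in self.LABELS}


def _in_region(res: Residue, region_filter) -> bool:
    if region_filter is None:
        return True
    for entry in region_filter:
        if len(entry) == 3:
            chain, lo, hi = entry
            if res.chain_id == chain and lo <= res.res_seq <= hi:
                return True
        else:
            lo, hi = entry
            if lo <= res.res_seq <= hi:
                return True
    return False


def rotamer_population(
    structures: Iterable[StructureModel],
    residue_filter: Sequence[str],
    region_filter: Optional[Sequence] = None,
) -> Dict[str, RotamerPopulation]:
    """Tabulate g-/g+/t counts for every qualifying residue across models.

    ``residue_filter`` holds 3-letter codes; ``region_filter`` optionally
    restricts to residue ranges given as (lo, hi) or (chain, lo, hi).
    Residues with undefined chi1 (missing atoms) are skipped.
    """
    wanted = {r.upper() for r in residue_filter}
    pops: Dict[str, RotamerPopulation] = {
        name: RotamerPopulation(res_name=name, counts={}) for name in sorted(wanted)
    }
    n_found = 0
    for model in structures:
        for res in model.iter_residues():
            if res.res_name not in wanted or not _in_region(res, region_filter):
                continue
            try:
                label = classify_rotamer(chi1(res))
            except (Chi1UndefinedError, Chi1NotApplicableError):
                continue
            counts = pops[res.res_name].counts
            counts[label] = counts.get(label, 0) + 1
            n_found += 1
    if n_found == 0:
        import warnings

        warnings.warn("no qualifying residues found; population table is empty")
    return pops


def rotamer_report_tsv(
    model: StructureModel, residue_filter: Sequence[str], bw_map=None
) -> str:
    wanted = {r.upper() for r in residue_filter}
    lines = ["chain\tres_seq\tres_name\tbw\tchi1\tlabel"]
    for res in model.iter_residues():
        if res.res_name not in wanted:
            continue
        try:
            a = assign_rotamer(res)
        except (Chi1UndefinedError, Chi1NotApplicableError):
            continue
        bw = ""
        if bw_map is not None:
            bw = bw_map.generic(res.chain_id, res.res_seq) or ""
        lines.append(
            f"{res.chain_id}\t{res.res_seq}\t{res.res_name}\t{bw}"
            f"\t{a.chi1:.1f}\t{a.label}"
        )
    return "\n".join(lines) + "\n"
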