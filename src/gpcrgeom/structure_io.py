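"""PDB reading/writing and the coordinate/topology model used everywhere else.

Design notes
------------
* Hydrogens are dropped on input: all downstream geometry is heavy-atom based.
* Alternate locations are resolved at parse time to the highest-occupancy
  conformer; ties broken by alphabetical alt-loc identifier.
* Residues are addressed by author numbering exactly as printed in the file.
* Multi-model files become an :class:`Ensemble` whose models must share an
  identical topology (same chains, residues and atom names).
"""

from __future__ import annotations

import gzip
import io
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Tuple, Union

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "Ensemble",
    "PDBParseError",
    "EmptyStructureError",
    "TopologyError",
    "ResidueNotFoundError",
    "AtomNotFoundError",
    "read_pdb",
    "write_pdb",
    "get_atom",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues seen in deposited GPCR entries
    "MSE": "M", "CSO": "C", "SEP": "S", "TPO": "T", "PTR": "Y",
}

STANDARD_AA = frozenset(list(THREE_TO_ONE)[:20])


class PDBParseError(ValueError):
    """Malformed PDB input."""


class EmptyStructureError(PDBParseError):
    """Input contained no protein atoms."""


class TopologyError(ValueError):
    """Models of an ensemble do not share identical topology."""


class ResidueNotFoundError(LookupError):
    """The requested (chain, residue) address does not exist."""


class AtomNotFoundError(LookupError):
    """The residue exists but lacks the requested atom."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    alt_loc: str = ""
    b_factor: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    res_name: str
    res_seq: int
    chain_id: str
    atoms: List[Atom] = field(default_factory=list)
    icode: str = ""
    is_hetero: bool = False

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    @property
    def is_water(self) -> bool:
        return self.res_name in ("HOH", "WAT", "DOD")

    @property
    def is_amino_acid(self) -> bool:
        return self.res_name in THREE_TO_ONE

    def atom_names(self) -> List[str]:
        return [a.name for a in self.atoms]

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise AtomNotFoundError(
            f"atom {name!r} absent in residue {self.res_name} "
            f"{self.chain_id}{self.res_seq}{self.icode}"
        )

    def address(self) -> Tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.res_name)


@dataclass
class StructureModel:
    model_id: int
    chains: Dict[str, List[Residue]]
    source_id: str = ""

    def chain_ids(self) -> List[str]:
        return list(self.chains)

    def residues(self, chain_id: str) -> List[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise ResidueNotFoundError(f"chain {chain_id!r} absent") from None

    def iter_residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def residue(self, chain_id: str, res_seq: int, icode: str = "") -> Residue:
        for res in self.residues(chain_id):
            if res.res_seq == res_seq and res.icode == icode:
                return res
        raise ResidueNotFoundError(
            f"residue {res_seq}{icode} absent in chain {chain_id!r}"
        )

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter sequence of the amino-acid residues of a chain."""
        return "".join(
            r.one_letter for r in self.residues(chain_id) if not r.is_water
        )

    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())


@dataclass
class Ensemble:
    models: List[StructureModel]
    source_id: str = ""

    def __post_init__(self):
        if not self.models:
            raise EmptyStructureError("ensemble holds no models")
        ids = [m.model_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise TopologyError(f"duplicate model ids: {ids}")
        ref = _topology_signature(self.models[0])
        for m in self.models[1:]:
            if _topology_signature(m) != ref:
                raise TopologyError(
                    f"model {m.model_id} topology differs from model "
                    f"{self.models[0].model_id}"
                )

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self) -> Iterator[StructureModel]:
        return iter(self.models)

    @property
    def first(self) -> StructureModel:
        return self.models[0]


def _topology_signature(model: StructureModel):
    return [
        (cid, res.res_name, res.res_seq, res.icode, tuple(res.atom_names()))
        for cid, residues in model.chains.items()
        for res in residues
    ]


def _open_source(path_or_text: Union[str, Path, io.IOBase]):
    if isinstance(path_or_text, io.IOBase):
        return path_or_text
    if isinstance(path_or_text, Path) or (
        isinstance(path_or_text, str)
        and "\n" not in path_or_text
        and os.path.exists(path_or_text)
    ):
        p = Path(path_or_text)
        if p.suffix == ".gz":
            return gzip.open(p, "rt")
        return open(p)
    if isinstance(path_or_text, str):
        return io.StringIO(path_or_text)
    raise TypeError(f"unsupported PDB source: {type(path_or_text)!r}")


def _pick_conformer(atom) -> "Bio.PDB.Atom.Atom":
    """Highest occupancy wins; alphabetical alt-loc id breaks ties."""
    if not isinstance(atom, DisorderedAtom):
        return atom
    children = list(atom.child_dict.values())
    return min(children, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))


def read_pdb(path_or_text, source_id: str = "") -> Ensemble:
    """Parse a PDB file (optionally gzipped) or raw PDB text into an Ensemble.

    One :class:`StructureModel` per MODEL record (a single model when the file
    has none).  Hydrogens are discarded; alternate locations are resolved per
    the module policy; HETATM amino acids are retained and flagged hetero.
    """
    handle = _open_source(path_or_text)
    parser = PDBParser(PERMISSIVE=True, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(source_id or "structure", handle)
    except PDBConstructionException as exc:
        raise PDBParseError(f"malformed PDB input: {exc}") from exc
    finally:
        if not isinstance(path_or_text, io.IOBase):
            handle.close()

    models: List[StructureModel] = []
    for bio_model in structure:
        chains: Dict[str, List[Residue]] = {}
        for bio_chain in bio_model:
            residues: List[Residue] = []
            for bio_res in bio_chain:
                hetflag, res_seq, icode = bio_res.get_id()
                res = Residue(
                    res_name=bio_res.get_resname().strip(),
                    res_seq=int(res_seq),
                    chain_id=bio_chain.id,
                    icode=icode.strip(),
                    is_hetero=hetflag.strip() != "",
                )
                for bio_atom in bio_res:
                    chosen = _pick_conformer(bio_atom)
                    element = (chosen.element or "").strip()
                    if element in ("H", "D"):
                        continue
                    res.atoms.append(
                        Atom(
                            name=chosen.get_name().strip(),
                            element=element,
                            coords=np.array(chosen.get_coord(), dtype=float),
                            occupancy=float(chosen.get_occupancy() or 1.0),
                            alt_loc=chosen.get_altloc().strip(),
                            b_factor=float(chosen.get_bfactor() or 0.0),
                        )
                    )
                if res.atoms:
                    residues.append(res)
            if residues:
                chains[bio_chain.id] = residues
        if chains:
            models.append(
                StructureModel(
                    model_id=int(bio_model.id) + 1,
                    chains=chains,
                    source_id=source_id,
                )
            )

    n_protein = sum(
        1
        for m in models[:1]
        for r in m.iter_residues()
        if r.is_amino_acid
        for _ in r.atoms
    )
    if not models or n_protein == 0:
        raise EmptyStructureError("no protein atoms in input")
    return Ensemble(models=models, source_id=source_id)


_PDB_LINE = (
    "{record:<6s}{serial:>5d} {name:<4s}{alt:1s}{resname:>3s} {chain:1s}"
    "{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def _format_atom_name(name: str, element: str) -> str:
    # Single-letter elements start in column 14 unless the name is 4 chars.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(ensemble: Ensemble, path: Union[str, Path, io.IOBase]) -> None:
    """Write an ensemble as PDB; MODEL/ENDMDL blocks when multiple models."""
    if not isinstance(ensemble, Ensemble) or len(ensemble) == 0:
        raise EmptyStructureError("cannot write an empty ensemble")
    own = not isinstance(path, io.IOBase)
    handle = open(path, "w") if own else path
    try:
        multi = len(ensemble) > 1
        for model in ensemble:
            if multi:
                handle.write(f"MODEL     {model.model_id:>4d}\n")
            serial = 1
            for chain_id, residues in model.chains.items():
                last = None
                for res in residues:
                    record = "HETATM" if res.is_hetero else "ATOM"
                    for atom in res.atoms:
                        handle.write(
                            _PDB_LINE.format(
                                record=record,
                                serial=serial,
                                name=_format_atom_name(atom.name, atom.element),
                                alt=atom.alt_loc or " ",
                                resname=res.res_name,
                                chain=chain_id,
                                resseq=res.res_seq,
                                icode=res.icode or " ",
                                x=atom.coords[0],
                                y=atom.coords[1],
                                z=atom.coords[2],
                                occ=atom.occupancy,
                                b=atom.b_factor,
                                element=atom.element,
                            )
                        )
                        serial += 1
                    last = res
                if last is not None and not last.is_water:
                    handle.write(
                        f"TER   {serial:>5d}      {last.res_name:>3s} "
                        f"{chain_id:1s}{last.res_seq:>4d}{last.icode or ' '}\n"
                    )
                    serial += 1
            if multi:
                handle.write("ENDMDL\n")
        handle.write("END\n")
    finally:
        if own:
            handle.close()


def get_atom(model: StructureModel, chain: str, res_seq: int, atom_name: str) -> Atom:
    """Fetch one atom by author address; errors distinguish residue vs atom."""
    return model.residue(chain, res_seq).atom(atom_name)
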