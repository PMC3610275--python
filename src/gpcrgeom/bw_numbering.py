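"""Generic transmembrane position numbering anchored on conserved motifs,
plus per-column residue frequencies from multiple sequence alignments.

Positions use the T.NN scheme: the most conserved residue of helix T is NN=50
and other positions number by sequence offset (6.47 is three residues
N-terminal of 6.50).  Anchors are found automatically from the TM6
[CSTAV]WxP and TM7 NPxxY motifs, or supplied explicitly for positions (2.50,
3.39, ...) that lack a locally unique motif.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple, Union

from Bio import AlignIO

from .structure_io import StructureModel

__all__ = [
    "AnchorNotFoundError",
    "AnchorAmbiguityError",
    "ChainGapError",
    "UnmappedPositionError",
    "BWMap",
    "ConservationTable",
    "find_motif_anchors",
    "build_bw_map",
    "conservation_frequencies",
]


class AnchorNotFoundError(ValueError):
    """A required anchoring motif is absent from the sequence."""


class AnchorAmbiguityError(ValueError):
    """A motif matches in more than one place."""


class ChainGapError(LookupError):
    """A numbering offset path crosses missing residues."""


class UnmappedPositionError(LookupError):
    """The requested generic position is not covered by the map."""


# TM6 anchor: P of [small]-W-x-P; TM7 anchor: P of N-P-x-x-Y.
_CWXP_STRICT = re.compile(r"[CSTAV]W.P")
_CWXP_LOOSE = re.compile(r"W.P")
_NPXXY_STRICT = re.compile(r"NP..Y")
_NPXXY_LOOSE = re.compile(r"NP")


def _matches(pattern: re.Pattern, sequence: str):
    return [m.start() for m in pattern.finditer(sequence)]


def find_motif_anchors(sequence: str) -> Dict[str, int]:
    """Locate the 6.50 and 7.50 anchor prolines in a one-letter sequence.

    Returns 0-based offsets ``{"6.50": ..., "7.50": ...}``.  The TM6 anchor is
    the P of a [CSTAV]WxP match (WxP fallback); the TM7 anchor is the P of an
    NPxxY match (NP fallback) C-terminal to the TM6 motif.
    """
    if len(sequence) < 20:
        raise ValueError("sequence too short for motif anchoring (<20 residues)")
    sequence = sequence.upper()

    tm6_starts = _matches(_CWXP_STRICT, sequence)
    if not tm6_starts:
        tm6_starts = _matches(_CWXP_LOOSE, sequence)
        offset_650 = 2
    else:
        offset_650 = 3
    if not tm6_starts:
        raise AnchorNotFoundError("TM6 motif [CSTAV]WxP (or WxP) not found")
    if len(tm6_starts) > 1:
        raise AnchorAmbiguityError(
            f"TM6 motif matches at offsets {tm6_starts}; supply anchors explicitly"
        )
    pos_650 = tm6_starts[0] + offset_650

    tm7_starts = [s for s in _matches(_NPXXY_STRICT, sequence) if s > pos_650]
    offset_750 = 1
    if not tm7_starts:
        tm7_starts = [s for s in _matches(_NPXXY_LOOSE, sequence) if s > pos_650]
    if not tm7_starts:
        raise AnchorNotFoundError("TM7 motif NPxxY (or NP) not found after TM6 motif")
    if len(tm7_starts) > 1:
        raise AnchorAmbiguityError(
            f"TM7 motif matches at offsets {tm7_starts}; supply anchors explicitly"
        )
    return {"6.50": pos_650, "7.50": tm7_starts[0] + offset_750}


_MAX_SPAN = 15  # generic positions assigned at most x.50 +/- 15


@dataclass
class BWMap:
    """Mapping between author residue numbers and generic T.NN positions."""

    entries: Dict[Tuple[str, int], str] = field(default_factory=dict)
    anchors: Dict[str, Tuple[str, int]] = field(default_factory=dict)
    source: str = "config"
    # per-helix truncation bounds hit before +/-MAX_SPAN because of chain gaps
    gap_limits: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        self._reverse = {}
        for addr, pos in self.entries.items():
            if pos in self._reverse:
                raise ValueError(f"generic position {pos} mapped twice")
            self._reverse[pos] = addr

    def generic(self, chain_id: str, res_seq: int) -> Optional[str]:
        return self.entries.get((chain_id, res_seq))

    def address(self, position: str) -> Tuple[str, int]:
        """(chain, res_seq) of a generic position; gap-aware error messages."""
        try:
            return self._reverse[position]
        except KeyError:
            pass
        helix, _, nn = position.partition(".")
        if helix in self.gap_limits:
            lo, hi = self.gap_limits[helix]
            offset = int(nn) - 50
            if not (lo <= offset <= hi):
                raise ChainGapError(
                    f"position {position} lies beyond a chain gap "
                    f"(helix {helix} mapped for offsets {lo}..{hi})"
                )
        raise UnmappedPositionError(f"generic position {position} not mapped")

    def positions(self) -> Dict[str, Tuple[str, int]]:
        return dict(self._reverse)

    def to_tsv(self, model: Optional[StructureModel] = None) -> str:
        lines = ["chain\tres_seq\tres_name\tbw"]
        for (chain, res_seq), pos in sorted(self.entries.items(), key=lambda kv: kv[1]):
            name = ""
            if model is not None:
                try:
                    name = model.residue(chain, res_seq).res_name
                except LookupError:
                    name = "?"
            lines.append(f"{chain}\t{res_seq}\t{name}\t{pos}")
        return "\n".join(lines) + "\n"


def _contiguous_offsets(residues, anchor_idx: int):
    """Map list-index offsets from the anchor, stopping at numbering gaps.

    Returns (offset -> res_seq, (lo, hi)) where lo/hi are the last offsets
    reached before a gap (or the +/-MAX_SPAN span edge).
    """
    out = {0: residues[anchor_idx].res_seq}
    hi = 0
    for off in range(1, _MAX_SPAN + 1):
        idx = anchor_idx + off
        if idx >= len(residues):
            break
        prev, cur = residues[idx - 1], residues[idx]
        if cur.icode or prev.icode or cur.res_seq != prev.res_seq + 1:
            break
        out[off] = cur.res_seq
        hi = off
    lo = 0
    for off in range(1, _MAX_SPAN + 1):
        idx = anchor_idx - off
        if idx < 0:
            break
        prev, cur = residues[idx + 1], residues[idx]
        if cur.icode or prev.icode or cur.res_seq != prev.res_seq - 1:
            break
        out[-off] = cur.res_seq
        lo = -off
    return out, (lo, hi)


AnchorConfig = Union[str, Mapping[str, Tuple[str, int]]]


def build_bw_map(model: StructureModel, anchors: AnchorConfig = "auto") -> BWMap:
    """Assign generic positions by residue-count offset from helix anchors.

    ``anchors`` is either ``"auto"`` (motif search over every chain; the TM6
    and TM7 anchors must land on the same chain) or a mapping
    ``{"6.50": ("A", 288), "2.50": ("A", 79), ...}`` of x.50 addresses.
    """
    resolved: Dict[str, Tuple[str, int]] = {}
    source = "config"
    if anchors == "auto":
        source = "motif"
        found = None
        for chain_id in model.chain_ids():
            residues = [r for r in model.residues(chain_id) if not r.is_water]
            seq = "".join(r.one_letter for r in residues)
            try:
                offs = find_motif_anchors(seq)
            except (AnchorNotFoundError, AnchorAmbiguityError, ValueError):
                continue
            found = {
                pos: (chain_id, residues[off].res_seq) for pos, off in offs.items()
            }
            break
        if found is None:
            raise AnchorNotFoundError(
                "no chain carries both TM6 and TM7 anchoring motifs"
            )
        resolved = found
    else:
        resolved = {str(k): (v[0], int(v[1])) for k, v in dict(anchors).items()}

    entries: Dict[Tuple[str, int], str] = {}
    gap_limits: Dict[str, Tuple[int, int]] = {}
    for anchor_pos, (chain_id, res_seq) in resolved.items():
        helix, _, nn = anchor_pos.partition(".")
        if nn != "50":
            raise ValueError(f"anchors must be x.50 positions, got {anchor_pos}")
        residues = [r for r in model.residues(chain_id) if not r.is_water]
        idx = next(
            (
                i
                for i, r in enumerate(residues)
                if r.res_seq == res_seq and not r.icode
            ),
            None,
        )
        if idx is None:
            raise UnmappedPositionError(
                f"anchor residue {chain_id}:{res_seq} absent from model"
            )
        offsets, limits = _contiguous_offsets(residues, idx)
        gap_limits[helix] = limits
        for off, seq_num in offsets.items():
            entries[(chain_id, seq_num)] = f"{helix}.{50 + off}"
    return BWMap(entries=entries, anchors=resolved, source=source, gap_limits=gap_limits)


def load_anchor_config(path) -> Dict[str, Tuple[str, int]]:
    """Anchor config from JSON {"6.50": "A:288", ...} or TSV lines."""
    text = open(path).read()
    out: Dict[str, Tuple[str, int]] = {}
    if text.lstrip().startswith("{"):
        raw = json.loads(text)
        items = raw.items()
    else:
        items = (
            line.split("\t")[:2]
            for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        )
    for pos, addr in items:
        if isinstance(addr, str):
            chain, _, num = addr.partition(":")
            out[pos] = (chain, int(num))
        else:
            out[pos] = (addr[0], int(addr[1]))
    return out


@dataclass
class ConservationTable:
    position: str
    counts: Dict[str, int]
    n_sequences: int
    gap_count: int

    @property
    def frequency(self) -> Dict[str, float]:
        """Percentages over all sequences; the remainder is the gap fraction."""
        return {
            aa: 100.0 * c / self.n_sequences for aa, c in self.counts.items()
        }

    @property
    def gap_fraction(self) -> float:
        return 100.0 * self.gap_count / self.n_sequences


def conservation_frequencies(
    alignment, column_map: Mapping[str, int]
) -> Dict[str, ConservationTable]:
    """Per-column residue counts/percentages for the mapped generic positions.

    ``alignment`` is a Bio.Align.MultipleSeqAlignment, a FASTA path, or an
    open handle of aligned FASTA.  Gaps ('-' or '.') are tallied separately.
    """
    if not hasattr(alignment, "get_alignment_length"):
        alignment = AlignIO.read(alignment, "fasta")
    length = alignment.get_alignment_length()
    n = len(alignment)
    for rec in alignment:
        if len(rec.seq) != length:  # pragma: no cover - AlignIO enforces this
            raise ValueError("ragged alignment")
    out: Dict[str, ConservationTable] = {}
    for position, col in column_map.items():
        if not (0 <= col < length):
            raise IndexError(f"column {col} outside alignment of length {length}")
        counts: Dict[str, int] = {}
        gaps = 0
        for rec in alignment:
            aa = str(rec.seq[col]).upper()
            if aa in ("-", "."):
                gaps += 1
            else:
                counts[aa] = counts.get(aa, 0) + 1
        out[position] = ConservationTable(
            position=position, counts=counts, n_sequences=n, gap_count=gaps
        )
    return out
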