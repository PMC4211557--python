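"""Peptide windows, motif registers, cleavage-site octamers and the
overlapping recognition-frame map.

Six registers are defined over 9-mer (class I) and 15-mer (class II)
windows.  The T-cell exposed registers (TCEM) and their groove-exposed
complements (GEM) partition each window:

======== ====== ==========================================
register window 1-based window positions
======== ====== ==========================================
TCEM_I      9   4 5 6 7 8
GEM_I       9   1 2 3 9
TCEM_IIA   15   5 6 8 10 11   (core 2,3,5,7,8)
GEM_IIA    15   1 2 3 4 7 9 12 13 14 15
TCEM_IIB   15   3 6 8 10 11   (core -1,3,5,7,8)
GEM_IIB    15   1 2 4 5 7 9 12 13 14 15
======== ====== ==========================================

Class II core numbering refers to the central 9-mer of the 15-mer (window
positions 4-12); core position ``p`` sits at window position ``p + 3`` and
position ``-1`` denotes the residue immediately N-terminal of the core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

from tcemrep.sequence_io import SequenceRecord

#: Offset between 15-mer window coordinates and central-core coordinates.
CORE_OFFSET = 3

#: Cleavage-site octamer flank: four residues on each side of a scissile bond.
CSO_FLANK = 4

WINDOW_LENGTHS = (8, 9, 15)


@dataclass(frozen=True)
class MotifRegister:
    """A named position mask over a fixed-length peptide window."""

    name: str
    window_length: int
    positions: tuple[int, ...]  # 1-based window indices, ascending

    def __post_init__(self) -> None:
        if any(not 1 <= p <= self.window_length for p in self.positions):
            raise ValueError(f"{self.name}: positions out of window range")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError(f"{self.name}: positions must be strictly ascending")

    @property
    def complement(self) -> tuple[int, ...]:
        """Window positions not in this register's mask."""
        used = set(self.positions)
        return tuple(p for p in range(1, self.window_length + 1) if p not in used)


def _complement_of(mask: tuple[int, ...], window_length: int) -> tuple[int, ...]:
    return tuple(p for p in range(1, window_length + 1) if p not in set(mask))


_TCEM_IIA_MASK = (5, 6, 8, 10, 11)
_TCEM_IIB_MASK = (3, 6, 8, 10, 11)

REGISTERS: dict[str, MotifRegister] = {
    "TCEM_I": MotifRegister("TCEM_I", 9, (4, 5, 6, 7, 8)),
    "GEM_I": MotifRegister("GEM_I", 9, (1, 2, 3, 9)),
    "TCEM_IIA": MotifRegister("TCEM_IIA", 15, _TCEM_IIA_MASK),
    "GEM_IIA": MotifRegister("GEM_IIA", 15, _complement_of(_TCEM_IIA_MASK, 15)),
    "TCEM_IIB": MotifRegister("TCEM_IIB", 15, _TCEM_IIB_MASK),
    "GEM_IIB": MotifRegister("GEM_IIB", 15, _complement_of(_TCEM_IIB_MASK, 15)),
}

TCEM_REGISTERS = ("TCEM_I", "TCEM_IIA", "TCEM_IIB")
GEM_REGISTERS = ("GEM_I", "GEM_IIA", "GEM_IIB")

#: Influence span of a single binding peptide including both cleavage-site
#: octamer flanks: 4 + 9 + 4 = 17 (class I) and 4 + 15 + 4 = 23 (class II).
INFLUENCE_SPAN = {"I": CSO_FLANK + 9 + CSO_FLANK, "II": CSO_FLANK + 15 + CSO_FLANK}


@dataclass(frozen=True)
class PeptideWindow:
    """A contiguous sub-peptide of a parent sequence.

    ``start`` is the 1-based index of the window's first residue in the
    parent.  Windows containing the ambiguity character X are flagged
    ``skip`` and yield no motifs.
    """

    parent_id: str
    start: int
    residues: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("window start must be >= 1")

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def skip(self) -> bool:
        return "X" in self.residues


@dataclass(frozen=True)
class Motif:
    """An extracted register motif: the residue letters plus a gapped
    display rendering with ``~`` marking skipped stretches (``AI~W~RQ``)."""

    register: str
    letters: str
    display: str


def enumerate_windows(record: SequenceRecord, k: int) -> list[PeptideWindow]:
    """All k-mer windows of *record* offset by a single residue.

    Returns exactly ``L - k + 1`` windows with starts ``1 .. L-k+1``; a
    record shorter than *k* yields an empty list with a warning.
    """
    if k not in WINDOW_LENGTHS:
        raise ValueError(f"window length must be one of {WINDOW_LENGTHS}, got {k}")
    L = len(record)
    if L < k:
        warnings.warn(
            f"record {record.id!r} length {L} < window length {k}; no windows",
            stacklevel=2,
        )
        return []
    seq = record.residues
    return [
        PeptideWindow(parent_id=record.id, start=s, residues=seq[s - 1 : s - 1 + k])
        for s in range(1, L - k + 2)
    ]


def extract_motif(window: PeptideWindow, register: MotifRegister | str) -> Motif:
    """Extract a register motif from a window.

    Letters are the window residues at the register's mask positions in
    N->C order.  The display string covers the span from the first to the
    last mask position, collapsing each maximal run of skipped positions
    into a single ``~`` (matching renderings such as ``AI~W~RQ`` and
    ``N~I~W~RQ``).
    """
    if isinstance(register, str):
        register = REGISTERS[register]
    if window.length != register.window_length:
        raise ValueError(
            f"window length {window.length} does not match register "
            f"{register.name} (expects {register.window_length})"
        )
    if window.skip:
        raise ValueError("window contains X and is flagged skip; no motif defined")
    letters = "".join(window.residues[p - 1] for p in register.positions)
    display_parts: list[str] = [window.residues[register.positions[0] - 1]]
    for prev, cur in zip(register.positions, register.positions[1:]):
        if cur - prev > 1:
            display_parts.append("~")
        display_parts.append(window.residues[cur - 1])
    return Motif(register=register.name, letters=letters, display="".join(display_parts))


def central_core(window: PeptideWindow) -> PeptideWindow:
    """The central 9-mer core (window positions 4-12) of a 15-mer."""
    if window.length != 15:
        raise ValueError(f"central_core requires a 15-mer, got length {window.length}")
    return PeptideWindow(
        parent_id=window.parent_id,
        start=window.start + CORE_OFFSET,
        residues=window.residues[CORE_OFFSET : CORE_OFFSET + 9],
    )


def cleavage_site_octomer(record: SequenceRecord, bond_after: int) -> PeptideWindow:
    """The cleavage-site octamer (CSO) around the scissile bond following
    residue *bond_after*.

    Covers residues ``bond_after-3 .. bond_after+4``; the bond lies between
    octamer positions 4 and 5 (P1|P1').  Requires
    ``4 <= bond_after <= L - 4``.
    """
    L = len(record)
    if not CSO_FLANK <= bond_after <= L - CSO_FLANK:
        raise ValueError(
            f"bond_after={bond_after} too close to a terminus for a CSO "
            f"(need {CSO_FLANK} <= bond_after <= {L - CSO_FLANK})"
        )
    start = bond_after - 3
    return PeptideWindow(
        parent_id=record.id, start=start, residues=record.residues[start - 1 : start + 7]
    )


def theoretical_motif_space(alphabet_size: int, motif_length: int) -> int:
    """Exact count of possible motifs: ``alphabet_size ** motif_length``
    (20**5 = 3,200,000 for a pentamer TCEM; 20**10 for a class II GEM)."""
    if alphabet_size < 1 or motif_length < 1:
        raise ValueError("alphabet_size and motif_length must be >= 1")
    return alphabet_size**motif_length


@dataclass(frozen=True)
class FrameRole:
    """One role a residue plays inside one binding window's influence span."""

    window_start: int  # 1-based start of the binding window (not the flank)
    window_length: int
    role: str  # register name or "CSO_position"


@dataclass
class RecognitionFrameMap:
    """Per-residue map of every overlapping recognition frame.

    Only complete influence spans are included: a binding window counts
    when the window plus both 4-residue cleavage flanks lie within the
    sequence, since presentation requires excision on both sides.  Under
    this rule an interior residue participates in exactly 23 class II
    spans (its own plus 22 more) or 17 class I spans.
    """

    parent_id: str
    mhc_class: str  # "I" or "II"
    sequence_length: int
    entries: dict[int, list[FrameRole]] = field(default_factory=dict)

    @property
    def span_length(self) -> int:
        return INFLUENCE_SPAN[self.mhc_class]

    def roles_at(self, position: int) -> list[FrameRole]:
        return self.entries.get(position, [])

    def spans_containing(self, position: int) -> set[int]:
        """Window starts of the distinct influence spans containing *position*."""
        return {fr.window_start for fr in self.entries.get(position, [])}

    def n_overlapping_spans(self, position: int) -> int:
        return len(self.spans_containing(position))


def build_frame_map(record: SequenceRecord, mhc_class: str) -> RecognitionFrameMap:
    """Build the overlapping recognition-frame map for one sequence.

    For every binding window (9-mer for class I, 15-mer for class II) whose
    full influence span — window plus 4-residue cleavage flanks on each
    side — fits in the sequence, each residue of the window is annotated
    with its TCEM/GEM role in every register of that class, and each flank
    residue with ``CSO_position``.
    """
    if mhc_class not in ("I", "II"):
        raise ValueError(f"mhc_class must be 'I' or 'II', got {mhc_class!r}")
    L = len(record)
    span = INFLUENCE_SPAN[mhc_class]
    fmap = RecognitionFrameMap(parent_id=record.id, mhc_class=mhc_class, sequence_length=L)
    if L < span:
        warnings.warn(
            f"record {record.id!r} length {L} < influence span {span}; empty frame map",
            stacklevel=2,
        )
        return fmap

    k = 9 if mhc_class == "I" else 15
    registers = (
        (REGISTERS["TCEM_I"], REGISTERS["GEM_I"])
        if mhc_class == "I"
        else (
            REGISTERS["TCEM_IIA"],
            REGISTERS["GEM_IIA"],
            REGISTERS["TCEM_IIB"],
            REGISTERS["GEM_IIB"],
        )
    )
    # complete spans only: flanks must exist on both sides
    for s in range(1 + CSO_FLANK, L - k - CSO_FLANK + 2):
        for reg in registers:
            mask = set(reg.positions)
            for p in range(1, k + 1):
                if p in mask:
                    fmap.entries.setdefault(s + p - 1, []).append(
                        FrameRole(window_start=s, window_length=k, role=reg.name)
                    )
        for flank_pos in range(s - CSO_FLANK, s):
            fmap.entries.setdefault(flank_pos, []).append(
                FrameRole(window_start=s, window_length=k, role="CSO_position")
            )
        for flank_pos in range(s + k, s + k + CSO_FLANK):
            fmap.entries.setdefault(flank_pos, []).append(
                FrameRole(window_start=s, window_length=k, role="CSO_position")
            )
    return fmap


def shared_tcem_registers(peptide_a: str, peptide_b: str) -> list[str]:
    """Registers among TCEM I, IIa and IIb whose motifs agree between two
    aligned 15-mer peptides (TCEM I taken from the central 9-mer core).

    Used for worked-example comparisons of co-centred peptides.
    """
    if len(peptide_a) != 15 or len(peptide_b) != 15:
        raise ValueError("shared_tcem_registers expects two 15-mer peptides")
    wa = PeptideWindow(parent_id="a", start=1, residues=peptide_a.upper())
    wb = PeptideWindow(parent_id="b", start=1, residues=peptide_b.upper())
    shared: list[str] = []
    core_a, core_b = central_core(wa), central_core(wb)
    if extract_motif(core_a, "TCEM_I").letters == extract_motif(core_b, "TCEM_I").letters:
        shared.append("TCEM_I")
    for name in ("TCEM_IIA", "TCEM_IIB"):
        if extract_motif(wa, name).letters == extract_motif(wb, name).letters:
            shared.append(name)
    return shared


def iter_register_motifs(
    record: SequenceRecord, register: MotifRegister | str
) -> Iterable[tuple[PeptideWindow, Motif]]:
    """Yield ``(window, motif)`` for every non-skipped window of *record*
    under *register*."""
    if isinstance(register, str):
        register = REGISTERS[register]
    for window in enumerate_windows(record, register.window_length):
        if window.skip:
            continue
        yield window, extract_motif(window, register)
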