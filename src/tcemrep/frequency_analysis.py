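"""Motif re-use counting, frequency-class assignment, origin attribution
and distributional summaries over a repertoire.

The frequency class (FC) of a motif is the reciprocal base-2 logarithmic
category of the fraction of repertoire molecules containing it: FC0 means
present in every molecule, FC2 in 1/4, FC10 in 1/1024.  Fractions that are
not exact powers of two round up (a singleton among 39,982 molecules,
-log2 = 15.29, is FC16).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tcemrep.motif_engine import (
    REGISTERS,
    MotifRegister,
    enumerate_windows,
    extract_motif,
)
from tcemrep.sequence_io import RepertoireDataset, SequenceRecord

ORIGIN_GERMLINE = "germline"
ORIGIN_SHM = "SHM"


@dataclass
class MotifEntry:
    """Counts for one motif within one register."""

    molecule_count: int = 0
    instance_count: int = 0
    position_histogram: Counter = field(default_factory=Counter)


@dataclass
class MotifFrequencyTable:
    """Per-register mapping of motif letters to re-use counts.

    ``molecule_count`` is the number of distinct records containing the
    motif at least once; ``instance_count`` the total number of window
    occurrences; ``position_histogram`` counts occurrences per window
    start.  Motif identity is by letters alone (position-agnostic).
    """

    register: str
    entries: dict[str, MotifEntry]
    total_molecules: int
    total_instances: int

    @property
    def motifs(self) -> set[str]:
        return set(self.entries)

    def frequency_class(self, motif: str, mode: str = "molecule") -> int:
        entry = self.entries[motif]
        if mode == "molecule":
            return assign_frequency_class(entry.molecule_count, self.total_molecules)
        if mode == "instance":
            return assign_frequency_class(entry.instance_count, self.total_instances)
        raise ValueError(f"unknown FC counting mode {mode!r}")


def build_frequency_table(
    dataset: RepertoireDataset, register: MotifRegister | str
) -> MotifFrequencyTable:
    """Count motif re-use for one register across every record of *dataset*.

    Every non-skipped window contributes one instance; windows containing
    X contribute nothing.
    """
    if isinstance(register, str):
        register = REGISTERS[register]
    if len(dataset) == 0:
        raise ValueError("cannot build a frequency table from an empty dataset")

    entries: dict[str, MotifEntry] = {}
    total_instances = 0
    for rec in dataset:
        seen_in_record: set[str] = set()
        for window in enumerate_windows(rec, register.window_length):
            if window.skip:
                continue
            letters = extract_motif(window, register).letters
            entry = entries.setdefault(letters, MotifEntry())
            entry.instance_count += 1
            entry.position_histogram[window.start] += 1
            if letters not in seen_in_record:
                entry.molecule_count += 1
                seen_in_record.add(letters)
            total_instances += 1
    return MotifFrequencyTable(
        register=register.name,
        entries=entries,
        total_molecules=len(dataset),
        total_instances=total_instances,
    )


def assign_frequency_class(molecule_count: int, total_molecules: int) -> int:
    """FC = ceil(-log2(molecule_count / total_molecules)), computed exactly.

    Exact powers of two map to their exponent (1/4 -> FC2, 1/1024 -> FC10)
    and a motif present in every molecule is FC0.
    """
    if molecule_count < 1 or total_molecules < 1:
        raise ValueError("counts must be >= 1")
    if molecule_count > total_molecules:
        raise ValueError(
            f"molecule_count {molecule_count} exceeds total_molecules {total_molecules}"
        )
    # smallest k >= 0 with molecule_count * 2**k >= total_molecules
    fc = 0
    scaled = molecule_count
    while scaled < total_molecules:
        scaled <<= 1
        fc += 1
    return fc


@dataclass
class FCHistogram:
    """FC-binned summary of a frequency table.

    ``bins`` has columns fc, unique_count, weighted_count, cumulative
    (cumulative fraction of the weighted counts); ``midpoint_fc`` is the
    smallest FC at which the cumulative weighted fraction reaches 0.5.
    """

    bins: pd.DataFrame
    midpoint_fc: int


def fc_histogram(
    table: MotifFrequencyTable,
    mode: str = "molecule",
    motifs: Iterable[str] | None = None,
) -> FCHistogram:
    """Bin motifs by frequency class.

    ``unique_count`` per bin sums to the number of unique motifs and
    ``weighted_count`` (instances) to the total instance count.  *motifs*
    restricts the histogram to a subset (e.g. one origin class); FC values
    are still computed against the full table totals.
    """
    if not table.entries:
        raise ValueError("cannot histogram an empty table")
    chosen = table.motifs if motifs is None else set(motifs) & table.motifs
    rows: dict[int, list[int]] = {}
    for motif in chosen:
        fc = table.frequency_class(motif, mode=mode)
        bucket = rows.setdefault(fc, [0, 0])
        bucket[0] += 1
        bucket[1] += table.entries[motif].instance_count
    bins = (
        pd.DataFrame(
            [(fc, u, w) for fc, (u, w) in rows.items()],
            columns=["fc", "unique_count", "weighted_count"],
        )
        .sort_values("fc")
        .reset_index(drop=True)
    )
    total_weight = bins["weighted_count"].sum()
    bins["cumulative"] = bins["weighted_count"].cumsum() / total_weight
    midpoint = int(bins.loc[bins["cumulative"] >= 0.5, "fc"].iloc[0])
    return FCHistogram(bins=bins, midpoint_fc=midpoint)


def germline_motif_set(
    germline_reference: Sequence[SequenceRecord], register: MotifRegister | str
) -> set[str]:
    """All motif letters of one register occurring anywhere in the
    germline reference."""
    if isinstance(register, str):
        register = REGISTERS[register]
    motifs: set[str] = set()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short germlines yield no windows
        for rec in germline_reference:
            for window in enumerate_windows(rec, register.window_length):
                if not window.skip:
                    motifs.add(extract_motif(window, register).letters)
    return motifs


def attribute_origin(
    table: MotifFrequencyTable,
    germline_reference: Sequence[SequenceRecord],
) -> dict[str, str]:
    """Label each motif ``germline`` if its letters occur at any position in
    any germline reference sequence for the same register, else ``SHM``."""
    if not germline_reference:
        raise ValueError("germline reference must be non-empty")
    reference = germline_motif_set(germline_reference, table.register)
    return {
        motif: (ORIGIN_GERMLINE if motif in reference else ORIGIN_SHM)
        for motif in table.entries
    }


def per_position_unique_motifs(
    dataset: RepertoireDataset,
    register: MotifRegister | str,
    origin_filter: str | None = None,
    germline_reference: Sequence[SequenceRecord] | None = None,
) -> dict[int, int]:
    """Count unique motifs whose window centre falls at each position.

    Centre of a 15-mer is start+7, of a 9-mer start+4.  With an
    *origin_filter* (``germline`` or ``SHM``) only motifs of that origin
    are counted; the germline reference defaults to the dataset's own.
    """
    if isinstance(register, str):
        register = REGISTERS[register]
    keep: set[str] | None = None
    if origin_filter is not None:
        if origin_filter not in (ORIGIN_GERMLINE, ORIGIN_SHM):
            raise ValueError(f"unknown origin filter {origin_filter!r}")
        reference = germline_reference or dataset.germline_reference
        if not reference:
            raise ValueError("origin filter requires a germline reference")
        germ = germline_motif_set(reference, register)

    per_position: dict[int, set[str]] = {}
    center_offset = register.window_length // 2
    for rec in dataset:
        for window in enumerate_windows(rec, register.window_length):
            if window.skip:
                continue
            letters = extract_motif(window, register).letters
            if origin_filter == ORIGIN_GERMLINE and letters not in germ:
                continue
            if origin_filter == ORIGIN_SHM and letters in germ:
                continue
            per_position.setdefault(window.start + center_offset, set()).add(letters)
    return {pos: len(motifs) for pos, motifs in sorted(per_position.items())}


def colocalization_fraction(
    dataset: RepertoireDataset, base: str = "TCEM_IIA", by: str = "motif"
) -> float:
    """Fraction of unique (singleton) base-register motifs whose defining
    window also carries a singleton motif of the other class II register.

    ``base`` selects TCEM_IIA (default) or TCEM_IIB as the reference set;
    ``by='window'`` counts window occurrences instead of unique motifs
    (identical for singletons of the base register, provided for the
    symmetric reading of "instances").  Degenerate repertoires with no
    singleton motifs return 0.0 with a warning.
    """
    if base not in ("TCEM_IIA", "TCEM_IIB"):
        raise ValueError("base register must be TCEM_IIA or TCEM_IIB")
    if by not in ("motif", "window"):
        raise ValueError("by must be 'motif' or 'window'")
    other = "TCEM_IIB" if base == "TCEM_IIA" else "TCEM_IIA"
    table_base = build_frequency_table(dataset, base)
    table_other = build_frequency_table(dataset, other)
    unique_base = {m for m, e in table_base.entries.items() if e.instance_count == 1}
    unique_other = {m for m, e in table_other.entries.items() if e.instance_count == 1}
    if not unique_base:
        warnings.warn(
            "no singleton motifs in base register; co-location undefined, returning 0",
            stacklevel=2,
        )
        return 0.0

    hits = 0
    total = 0
    for rec in dataset:
        for window in enumerate_windows(rec, 15):
            if window.skip:
                continue
            base_letters = extract_motif(window, base).letters
            if base_letters not in unique_base:
                continue
            total += 1
            if extract_motif(window, other).letters in unique_other:
                hits += 1
    # for by="motif" every singleton motif has exactly one window, so the
    # window tally equals the motif tally; keep the distinction explicit
    return hits / total


def motif_set_overlap(
    table_a: MotifFrequencyTable, table_b: MotifFrequencyTable
) -> tuple[float, float, int]:
    """Motif-set intersection: (shared fraction of A, of B, shared count)."""
    if table_a.register != table_b.register:
        raise ValueError(
            f"register mismatch: {table_a.register} vs {table_b.register}"
        )
    shared = table_a.motifs & table_b.motifs
    frac_a = len(shared) / len(table_a.motifs) if table_a.motifs else 0.0
    frac_b = len(shared) / len(table_b.motifs) if table_b.motifs else 0.0
    return frac_a, frac_b, len(shared)


@dataclass
class FCMapping:
    """Per-motif FC lookup against a reference table."""

    fc_by_motif: dict[str, int | None]
    unclassified_fraction: float


def map_fc_from_reference(
    query_table: MotifFrequencyTable,
    reference_table: MotifFrequencyTable,
    mode: str = "molecule",
) -> FCMapping:
    """Assign each query motif the FC it holds in the reference table.

    Motifs absent from the reference are flagged ``None`` and reported as
    an unclassified fraction of the query motif set.
    """
    if query_table.register != reference_table.register:
        raise ValueError(
            f"register mismatch: {query_table.register} vs {reference_table.register}"
        )
    fc_by_motif: dict[str, int | None] = {}
    n_unclassified = 0
    for motif in query_table.entries:
        if motif in reference_table.entries:
            fc_by_motif[motif] = reference_table.frequency_class(motif, mode=mode)
        else:
            fc_by_motif[motif] = None
            n_unclassified += 1
    frac = n_unclassified / len(fc_by_motif) if fc_by_motif else 0.0
    return FCMapping(fc_by_motif=fc_by_motif, unclassified_fraction=frac)


def usage_correlation(
    observed_usage: Mapping[str, float], reference_usage: Mapping[str, float]
) -> float:
    """Pearson correlation of germline usage fractions over shared keys."""
    shared = sorted(set(observed_usage) & set(reference_usage))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared keys, got {len(shared)}")
    x = np.array([observed_usage[k] for k in shared], dtype=float)
    y = np.array([reference_usage[k] for k in shared], dtype=float)
    return float(stats.pearsonr(x, y).statistic)


def origin_ratio(
    table: MotifFrequencyTable, origins: Mapping[str, str]
) -> dict[str, float]:
    """Germline:SHM composition both per unique motif and per instance.

    Returns fractions ``germline_motif_fraction``, ``shm_motif_fraction``,
    ``germline_instance_fraction``, ``shm_instance_fraction``.
    """
    n_germ = sum(1 for m in table.entries if origins.get(m) == ORIGIN_GERMLINE)
    n_total = len(table.entries)
    i_germ = sum(
        e.instance_count
        for m, e in table.entries.items()
        if origins.get(m) == ORIGIN_GERMLINE
    )
    i_total = table.total_instances
    return {
        "germline_motif_fraction": n_germ / n_total if n_total else 0.0,
        "shm_motif_fraction": (n_total - n_germ) / n_total if n_total else 0.0,
        "germline_instance_fraction": i_germ / i_total if i_total else 0.0,
        "shm_instance_fraction": (i_total - i_germ) / i_total if i_total else 0.0,
    }
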