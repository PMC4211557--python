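"""Synthetic germline libraries and somatic-hypermutation simulation.

The simulator works at the amino-acid level: every analysis downstream is
on protein sequences, so a per-position substitution-rate profile that
rises from the N-terminus toward the C-terminal hotspot region, plus
CDR-like hotspot windows, reproduces the observable structure (germline
motif retention decaying along the sequence, SHM motif diversity
concentrated in hotspots) without codon machinery.  No insertions or
deletions are generated, keeping all records positionally aligned.

All randomness flows from a single seed through counter-based seed
splitting (``numpy`` SeedSequence spawn keys), so per-clonotype generation
is order-independent and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tcemrep.sequence_io import AA20, RepertoireDataset, SequenceRecord

#: Default CDR-like hotspot windows for 130-residue variable regions,
#: (start, end, rate multiplier), 1-based inclusive.  Approximations of the
#: three CDR spans; configurable per run.
DEFAULT_HOTSPOTS: tuple[tuple[int, int, float], ...] = (
    (26, 35, 4.0),
    (50, 60, 4.0),
    (97, 112, 6.0),
)


@dataclass
class SHMParameters:
    """Somatic-hypermutation simulation parameters.

    ``base_rate`` is the per-residue substitution probability at the
    C-terminal end; the positional multiplier ``exp((pos - L) /
    decay_length)`` rises toward the C-terminus (the inverse of the
    transcription-proximal decay, expressed on the retained-germline
    observable).  ``hotspot_windows`` multiply the rate inside CDR-like
    spans.  Effective rates are clipped to [0, 1].
    """

    base_rate: float = 0.05
    decay_length: float = 60.0
    hotspot_windows: tuple[tuple[int, int, float], ...] = DEFAULT_HOTSPOTS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_rate <= 1.0:
            raise ValueError("base_rate must be in [0, 1]")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        for start, end, mult in self.hotspot_windows:
            if start > end or mult < 0:
                raise ValueError(f"invalid hotspot window ({start}, {end}, {mult})")

    def position_rates(self, length: int) -> np.ndarray:
        """Effective per-position substitution probabilities, clipped to [0,1]."""
        positions = np.arange(1, length + 1)
        rates = self.base_rate * np.exp((positions - length) / self.decay_length)
        for start, end, mult in self.hotspot_windows:
            mask = (positions >= start) & (positions <= end)
            rates[mask] *= mult
        return np.clip(rates, 0.0, 1.0)


@dataclass
class GermlineLibrary:
    """A set of equal-length germline sequences with usage weights."""

    sequences: list[SequenceRecord]
    usage_weights: np.ndarray

    def __post_init__(self) -> None:
        self.usage_weights = np.asarray(self.usage_weights, dtype=float)
        if len(self.sequences) != self.usage_weights.size:
            raise ValueError("one usage weight per germline sequence required")
        if np.any(self.usage_weights < 0):
            raise ValueError("usage weights must be non-negative")
        if abs(self.usage_weights.sum() - 1.0) > 1e-9:
            raise ValueError("usage weights must sum to 1 (within 1e-9)")
        lengths = {len(rec) for rec in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"germline sequences must share one length, got {lengths}")
        if any(not rec.is_germline for rec in self.sequences):
            raise ValueError("library records must have is_germline=True")


@dataclass
class SimulatedClonotype:
    """One SHM-derived clonotype with exact ground truth."""

    record: SequenceRecord
    germline_id: str
    mutated_positions: frozenset[int] = field(default_factory=frozenset)


_AA_ARRAY = np.frombuffer(AA20.encode(), dtype="S1")


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_AA_ARRAY, size=length).tobytes().decode()


def _mutate(residues: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    """Substitute each listed 1-based position with a uniform random
    different residue."""
    out = list(residues)
    for pos in positions:
        current = out[pos - 1]
        alternatives = [a for a in AA20 if a != current]
        out[pos - 1] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def make_germline_library(
    n_germlines: int,
    length: int = 130,
    n_families: int = 4,
    seed: int = 0,
    intra_family_divergence: float = 0.03,
    inter_family_divergence: float = 0.30,
    weight_concentration: float = 1.0,
) -> GermlineLibrary:
    """Generate a germline library with family structure and usage weights.

    Families share a random ancestor derived from a common root at
    *inter_family_divergence*; members diverge from their family ancestor
    at *intra_family_divergence*, so mean intra-family identity exceeds
    mean inter-family identity.  Usage weights are Dirichlet-distributed
    (concentration *weight_concentration*) and sum to 1.
    """
    if not n_germlines >= n_families >= 1:
        raise ValueError("need n_germlines >= n_families >= 1")
    root_rng = np.random.default_rng([seed, 0x47455243])
    root = _random_sequence(length, root_rng)

    family_of = np.arange(n_germlines) % n_families
    records: list[SequenceRecord] = []
    ancestors: dict[int, str] = {}
    for fam in range(n_families):
        fam_rng = np.random.default_rng([seed, 1, fam])
        n_sub = fam_rng.binomial(length, inter_family_divergence)
        positions = 1 + fam_rng.choice(length, size=n_sub, replace=False)
        ancestors[fam] = _mutate(root, positions, fam_rng)
    for i in range(n_germlines):
        fam = int(family_of[i])
        member_rng = np.random.default_rng([seed, 2, i])
        n_sub = member_rng.binomial(length, intra_family_divergence)
        positions = 1 + member_rng.choice(length, size=n_sub, replace=False)
        residues = _mutate(ancestors[fam], positions, member_rng)
        records.append(
            SequenceRecord(
                id=f"IGHV{fam + 1}-{i + 1:02d}",
                residues=residues,
                description=f"synthetic germline family {fam + 1}",
                is_germline=True,
            )
        )
    weight_rng = np.random.default_rng([seed, 3])
    weights = weight_rng.dirichlet(np.full(n_germlines, weight_concentration))
    return GermlineLibrary(sequences=records, usage_weights=weights)


def simulate_clonotype(
    germline: SequenceRecord,
    params: SHMParameters,
    rng: np.random.Generator,
    clonotype_id: str = "clonotype",
) -> SimulatedClonotype:
    """Apply one round of position-dependent somatic hypermutation.

    Each position mutates independently with probability
    ``base_rate * positional multiplier * hotspot multiplier``;
    substitutions are uniform over the 19 alternative residues.  The
    mutated position set is recorded exactly.
    """
    if len(germline) < 15:
        raise ValueError("germline must be at least 15 residues")
    rates = params.position_rates(len(germline))
    hits = np.flatnonzero(rng.random(len(germline)) < rates) + 1
    residues = _mutate(germline.residues, hits, rng)
    record = SequenceRecord(
        id=clonotype_id,
        residues=residues,
        description=f"SHM clonotype of {germline.id}",
        is_germline=False,
    )
    return SimulatedClonotype(
        record=record,
        germline_id=germline.id,
        mutated_positions=frozenset(int(p) for p in hits),
    )


def clonotype_rng(seed: int, index: int) -> np.random.Generator:
    """Counter-based per-clonotype generator: independent of draw order."""
    return np.random.default_rng([seed, 4, index])


@dataclass
class SimulatedRepertoire:
    """A simulated repertoire plus its exact ground truth."""

    dataset: RepertoireDataset
    clonotypes: list[SimulatedClonotype]
    library: GermlineLibrary

    @property
    def germline_assignment(self) -> dict[str, str]:
        return {c.record.id: c.germline_id for c in self.clonotypes}

    def empirical_usage(self) -> dict[str, float]:
        """Observed germline draw fractions."""
        counts: dict[str, int] = {}
        for c in self.clonotypes:
            counts[c.germline_id] = counts.get(c.germline_id, 0) + 1
        n = len(self.clonotypes)
        return {gid: cnt / n for gid, cnt in counts.items()}


def simulate_repertoire(
    library: GermlineLibrary,
    n_clonotypes: int,
    params: SHMParameters,
    seed: int | None = None,
) -> SimulatedRepertoire:
    """Draw clonotypes from the library by usage weight and mutate them.

    The returned dataset carries the library as its germline reference, so
    origin attribution can run directly on it.  *seed* defaults to
    ``params.seed``.
    """
    if n_clonotypes < 1:
        raise ValueError("n_clonotypes must be >= 1")
    seed = params.seed if seed is None else seed
    draw_rng = np.random.default_rng([seed, 5])
    draws = draw_rng.choice(
        len(library.sequences), size=n_clonotypes, p=library.usage_weights
    )
    clonotypes: list[SimulatedClonotype] = []
    for i, g_index in enumerate(draws):
        germline = library.sequences[int(g_index)]
        clone = simulate_clonotype(
            germline,
            params,
            clonotype_rng(seed, i),
            clonotype_id=f"clone{i + 1:06d}",
        )
        clonotypes.append(clone)
    dataset = RepertoireDataset(
        records=[c.record for c in clonotypes],
        max_length_applied=len(library.sequences[0]),
        provenance=(
            f"simulate_repertoire: n={n_clonotypes} seed={seed} "
            f"base_rate={params.base_rate} decay_length={params.decay_length}"
        ),
        germline_reference=list(library.sequences),
    )
    return SimulatedRepertoire(dataset=dataset, clonotypes=clonotypes, library=library)


def write_ground_truth(repertoire: SimulatedRepertoire, path) -> None:
    """TSV sidecar: clonotype_id, germline_id, mutated_positions (comma-joined)."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("clonotype_id\tgermline_id\tmutated_positions\n")
        for clone in repertoire.clonotypes:
            positions = ",".join(str(p) for p in sorted(clone.mutated_positions))
            fh.write(f"{clone.record.id}\t{clone.germline_id}\t{positions}\n")
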