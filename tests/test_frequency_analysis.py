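from collections import Counter, defaultdict

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcemrep.frequency_analysis import (
    MotifFrequencyTable,
    assign_frequency_class,
    attribute_origin,
    build_frequency_table,
    colocalization_fraction,
    fc_histogram,
    germline_motif_set,
    map_fc_from_reference,
    motif_set_overlap,
    origin_ratio,
    per_position_unique_motifs,
    usage_correlation,
)
from tcemrep.sequence_io import RepertoireDataset, SequenceRecord

# Masks restated literally so the oracle does not share code with the engine.
ORACLE_MASKS = {
    "TCEM_I": (9, (4, 5, 6, 7, 8)),
    "TCEM_IIA": (15, (5, 6, 8, 10, 11)),
    "TCEM_IIB": (15, (3, 6, 8, 10, 11)),
    "GEM_IIA": (15, (1, 2, 3, 4, 7, 9, 12, 13, 14, 15)),
}


def oracle_count(dataset, register):
    """Naive double-loop motif counter used as the independent oracle."""
    k, mask = ORACLE_MASKS[register]
    molecule = defaultdict(set)
    instances = Counter()
    positions = defaultdict(Counter)
    total_instances = 0
    for rec in dataset:
        for start in range(1, len(rec.residues) - k + 2):
            window = rec.residues[start - 1 : start - 1 + k]
            if "X" in window:
                continue
            letters = "".join(window[p - 1] for p in mask)
            molecule[letters].add(rec.id)
            instances[letters] += 1
            positions[letters][start] += 1
            total_instances += 1
    return molecule, instances, positions, total_instances


class TestBuildFrequencyTable:
    def test_two_records_one_occurrence_each(self):
        motif_window = "ACDEFGHIKLMNPQR"
        recs = [
            SequenceRecord("a", motif_window + "GGGGG"),
            SequenceRecord("b", "GGGGG" + motif_window),
        ]
        table = build_frequency_table(RepertoireDataset(records=recs), "TCEM_IIA")
        letters = "FGILM"  # positions 5,6,8,10,11 of the shared window
        assert table.entries[letters].molecule_count == 2
        assert table.entries[letters].instance_count == 2

    def test_one_record_two_occurrences(self):
        motif_window = "ACDEFGHIKLMNPQR"
        rec = SequenceRecord("a", motif_window + "GGGGG" + motif_window)
        table = build_frequency_table(RepertoireDataset(records=[rec]), "TCEM_IIA")
        assert table.entries["FGILM"].molecule_count == 1
        assert table.entries["FGILM"].instance_count == 2
        assert table.entries["FGILM"].position_histogram == Counter({1: 1, 21: 1})

    @pytest.mark.parametrize("register", list(ORACLE_MASKS))
    def test_matches_brute_force_oracle(self, toy_dataset, register):
        table = build_frequency_table(toy_dataset, register)
        molecule, instances, positions, total = oracle_count(toy_dataset, register)
        assert set(table.entries) == set(instances)
        assert table.total_instances == total
        for letters, entry in table.entries.items():
            assert entry.molecule_count == len(molecule[letters])
            assert entry.instance_count == instances[letters]
            assert entry.position_histogram == positions[letters]

    def test_x_windows_excluded(self):
        rec = SequenceRecord("a", "ACDEFGHIKXLMNPQRSTVWY")
        table = build_frequency_table(RepertoireDataset(records=[rec]), "TCEM_I")
        _, _, _, total = oracle_count(RepertoireDataset(records=[rec]), "TCEM_I")
        assert table.total_instances == total

    def test_empty_dataset_rejected(self):
        ds = RepertoireDataset(records=[SequenceRecord("a", "ACD")])
        ds.records = []
        with pytest.raises(ValueError, match="empty"):
            build_frequency_table(ds, "TCEM_I")

    def test_invariants_hold(self, toy_dataset):
        table = build_frequency_table(toy_dataset, "TCEM_IIB")
        n = table.total_molecules
        assert sum(e.instance_count for e in table.entries.values()) == table.total_instances
        for entry in table.entries.values():
            assert 1 <= entry.molecule_count <= n
            assert entry.molecule_count <= entry.instance_count


class TestAssignFrequencyClass:
    @pytest.mark.parametrize(
        "mc,total,fc",
        [
            (1, 4, 2),       # 1/4 = 1/2^2
            (1, 1024, 10),   # 1/1024 = 1/2^10
            (1, 32, 5),      # 1 in 32 clonotypes
            (1, 39982, 16),  # singleton in the curated-set size
            (5, 5, 0),       # in every molecule
            (1, 1, 0),
        ],
    )
    def test_definitional_identities(self, mc, total, fc):
        assert assign_frequency_class(mc, total) == fc

    def test_ceiling_between_powers(self):
        assert assign_frequency_class(3, 8) == 2  # -log2(3/8) = 1.415 -> 2
        assert assign_frequency_class(3, 4) == 1

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            assign_frequency_class(0, 10)
        with pytest.raises(ValueError):
            assign_frequency_class(11, 10)

    @settings(max_examples=100, deadline=None)
    @given(total=st.integers(1, 10**6), mc=st.integers(1, 10**6))
    def test_matches_float_ceiling(self, total, mc):
        if mc > total:
            mc = total
        fc = assign_frequency_class(mc, total)
        assert fc == int(np.ceil(-np.log2(mc / total) - 1e-12))

    @settings(max_examples=50, deadline=None)
    @given(total=st.integers(2, 10000), mc=st.integers(1, 9999))
    def test_monotone_in_molecule_count(self, total, mc):
        if mc >= total:
            mc = total - 1
        assert assign_frequency_class(mc, total) >= assign_frequency_class(mc + 1, total)

    @settings(max_examples=30, deadline=None)
    @given(k=st.integers(0, 20))
    def test_exact_powers(self, k):
        assert assign_frequency_class(1, 2**k) == k


def _table_from_counts(counts, total_molecules):
    from tcemrep.frequency_analysis import MotifEntry

    entries = {
        motif: MotifEntry(molecule_count=mc, instance_count=ic)
        for motif, (mc, ic) in counts.items()
    }
    return MotifFrequencyTable(
        register="TCEM_I",
        entries=entries,
        total_molecules=total_molecules,
        total_instances=sum(ic for _, ic in counts.values()),
    )


class TestFCHistogram:
    def test_all_motifs_in_every_molecule(self):
        table = _table_from_counts({"AAAAA": (4, 4), "CCCCC": (4, 4)}, 4)
        hist = fc_histogram(table)
        assert list(hist.bins["fc"]) == [0]
        assert hist.bins["unique_count"].iloc[0] == 2
        assert hist.midpoint_fc == 0

    def test_all_singletons_among_2k_molecules(self):
        table = _table_from_counts({m: (1, 1) for m in ("AAAAA", "CCCCC", "DDDDD")}, 8)
        hist = fc_histogram(table)
        assert list(hist.bins["fc"]) == [3]
        assert hist.midpoint_fc == 3

    def test_conservation_and_oracle(self, toy_dataset):
        table = build_frequency_table(toy_dataset, "TCEM_IIA")
        hist = fc_histogram(table)
        assert hist.bins["unique_count"].sum() == len(table.entries)
        assert hist.bins["weighted_count"].sum() == table.total_instances
        assert hist.bins["cumulative"].iloc[-1] == pytest.approx(1.0)
        # independent binning oracle
        expected = Counter()
        for motif, entry in table.entries.items():
            fc = int(np.ceil(-np.log2(entry.molecule_count / table.total_molecules) - 1e-12))
            expected[fc] += 1
        got = dict(zip(hist.bins["fc"], hist.bins["unique_count"]))
        assert got == dict(expected)

    def test_midpoint_is_smallest_fc_reaching_half(self):
        # FC0 weighted 4, FC2 weighted 4 -> cumulative 0.5 reached at FC0
        table = _table_from_counts({"AAAAA": (4, 4), "CCCCC": (1, 4)}, 4)
        hist = fc_histogram(table)
        assert hist.midpoint_fc == 0

    def test_empty_table_rejected(self):
        table = _table_from_counts({}, 4)
        with pytest.raises(ValueError):
            fc_histogram(table)


class TestAttributeOrigin:
    def test_verbatim_germline_motif(self):
        germ = [SequenceRecord("g", "ACDEFGHIKLMNPQR", is_germline=True)]
        ds = RepertoireDataset(records=[SequenceRecord("a", "ACDEFGHIKLMNPQR")])
        table = build_frequency_table(ds, "TCEM_IIA")
        origins = attribute_origin(table, germ)
        assert origins["FGILM"] == "germline"

    def test_absent_motif_is_shm(self):
        germ = [SequenceRecord("g", "A" * 20, is_germline=True)]
        ds = RepertoireDataset(records=[SequenceRecord("a", "ACDEFGHIKLMNPQR")])
        table = build_frequency_table(ds, "TCEM_IIA")
        assert attribute_origin(table, germ)["FGILM"] == "SHM"

    def test_every_motif_gets_exactly_one_label(self, small_repertoire):
        ds = small_repertoire.dataset
        table = build_frequency_table(ds, "TCEM_IIA")
        origins = attribute_origin(table, ds.germline_reference)
        assert set(origins) == set(table.entries)
        assert set(origins.values()) <= {"germline", "SHM"}

    def test_simulation_ground_truth(self, small_repertoire):
        """Motifs from windows untouched by mutation must be germline-origin;
        SHM labels only appear on motifs overlapping a mutated position."""
        ds = small_repertoire.dataset
        table = build_frequency_table(ds, "TCEM_IIA")
        origins = attribute_origin(table, ds.germline_reference)
        mutated = {c.record.id: c.mutated_positions for c in small_repertoire.clonotypes}
        mask = (5, 6, 8, 10, 11)
        for clone in small_repertoire.clonotypes:
            seq = clone.record.residues
            for start in range(1, len(seq) - 15 + 2):
                letters = "".join(seq[start - 1 + p - 1] for p in mask)
                touched = any(
                    (start + p - 1) in mutated[clone.record.id] for p in mask
                )
                if not touched:
                    # identical to the parent germline at all mask positions
                    assert origins[letters] == "germline"

    def test_zero_rate_all_germline(self):
        from tcemrep.synthetic_repertoire import (
            SHMParameters,
            make_germline_library,
            simulate_repertoire,
        )

        library = make_germline_library(4, length=60, n_families=2, seed=3)
        rep = simulate_repertoire(library, 10, SHMParameters(base_rate=0.0, seed=3))
        table = build_frequency_table(rep.dataset, "TCEM_IIB")
        origins = attribute_origin(table, rep.dataset.germline_reference)
        assert all(v == "germline" for v in origins.values())

    def test_germline_fraction_nonincreasing_in_rate(self):
        from tcemrep.synthetic_repertoire import (
            SHMParameters,
            make_germline_library,
            simulate_repertoire,
        )

        library = make_germline_library(4, length=100, n_families=2, seed=5)
        fractions = []
        for rate in (0.0, 0.03, 0.10, 0.25):
            rep = simulate_repertoire(library, 25, SHMParameters(base_rate=rate, seed=5))
            table = build_frequency_table(rep.dataset, "TCEM_IIA")
            origins = attribute_origin(table, rep.dataset.germline_reference)
            fractions.append(origin_ratio(table, origins)["germline_motif_fraction"])
        assert fractions[0] == 1.0
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_empty_reference_rejected(self, toy_dataset):
        table = build_frequency_table(toy_dataset, "TCEM_I")
        with pytest.raises(ValueError):
            attribute_origin(table, [])


class TestPerPositionUniqueMotifs:
    def test_identical_records(self):
        seq = "ACDEFGHIKLMNPQRSTVW"
        ds = RepertoireDataset(
            records=[SequenceRecord(f"r{i}", seq) for i in range(4)]
        )
        counts = per_position_unique_motifs(ds, "TCEM_I")
        # centres: start + 4 for a 9-mer
        assert set(counts) == {s + 4 for s in range(1, len(seq) - 9 + 2)}
        assert all(v == 1 for v in counts.values())

    def test_all_distinct_records(self, rng):
        from conftest import random_record

        ds = RepertoireDataset(records=[random_record(rng, f"r{i}", 15) for i in range(6)])
        counts = per_position_unique_motifs(ds, "TCEM_IIA")
        letters = {
            "".join(r.residues[p - 1] for p in (5, 6, 8, 10, 11)) for r in ds
        }
        assert counts == {8: len(letters)}

    def test_origin_filter_partitions(self, small_repertoire):
        ds = small_repertoire.dataset
        total = per_position_unique_motifs(ds, "TCEM_IIA")
        germ = per_position_unique_motifs(ds, "TCEM_IIA", origin_filter="germline")
        shm = per_position_unique_motifs(ds, "TCEM_IIA", origin_filter="SHM")
        for pos in total:
            assert germ.get(pos, 0) + shm.get(pos, 0) == total[pos]

    def test_unknown_filter(self, toy_dataset):
        with pytest.raises(ValueError):
            per_position_unique_motifs(toy_dataset, "TCEM_I", origin_filter="other")


class TestColocalization:
    def test_all_singleton_pairs(self, rng):
        from conftest import random_record

        # distinct random 15-mers: every IIa and IIb motif is a singleton
        ds = RepertoireDataset(records=[random_record(rng, f"r{i}", 15) for i in range(8)])
        table_a = build_frequency_table(ds, "TCEM_IIA")
        if all(e.instance_count == 1 for e in table_a.entries.values()):
            assert colocalization_fraction(ds) == 1.0

    def test_identical_records_degenerate(self):
        ds = RepertoireDataset(
            records=[SequenceRecord(f"r{i}", "ACDEFGHIKLMNPQR") for i in range(3)]
        )
        with pytest.warns(UserWarning, match="no singleton"):
            assert colocalization_fraction(ds) == 0.0

    def test_matches_exhaustive_pairing(self, rng):
        from conftest import random_record

        ds = RepertoireDataset(records=[random_record(rng, f"r{i}", 25) for i in range(3)])
        # oracle: enumerate all windows, find singleton IIa motifs, check IIb
        iia, iib = Counter(), Counter()
        windows = []
        for rec in ds:
            for start in range(1, len(rec.residues) - 15 + 2):
                w = rec.residues[start - 1 : start + 14]
                a = "".join(w[p - 1] for p in (5, 6, 8, 10, 11))
                b = "".join(w[p - 1] for p in (3, 6, 8, 10, 11))
                iia[a] += 1
                iib[b] += 1
                windows.append((a, b))
        singles_a = {m for m, c in iia.items() if c == 1}
        singles_b = {m for m, c in iib.items() if c == 1}
        hits = sum(1 for a, b in windows if a in singles_a and b in singles_b)
        expected = hits / len(singles_a)
        assert colocalization_fraction(ds) == pytest.approx(expected)

    def test_symmetric_variant(self, toy_dataset):
        f = colocalization_fraction(toy_dataset, base="TCEM_IIB")
        assert 0.0 <= f <= 1.0


class TestMotifSetOverlap:
    def test_self_overlap(self, toy_dataset):
        table = build_frequency_table(toy_dataset, "TCEM_I")
        assert motif_set_overlap(table, table) == (1.0, 1.0, len(table.entries))

    def test_disjoint(self):
        a = _table_from_counts({"AAAAA": (1, 1)}, 2)
        b = _table_from_counts({"CCCCC": (1, 1)}, 2)
        assert motif_set_overlap(a, b) == (0.0, 0.0, 0)

    def test_toy_intersection(self):
        a = _table_from_counts({"AAAAA": (1, 1), "CCCCC": (1, 1), "DDDDD": (1, 1)}, 3)
        b = _table_from_counts({"CCCCC": (1, 1), "DDDDD": (1, 1), "EEEEE": (1, 1), "FFFFF": (1, 1)}, 4)
        frac_a, frac_b, n = motif_set_overlap(a, b)
        assert (frac_a, frac_b, n) == (pytest.approx(2 / 3), pytest.approx(0.5), 2)

    def test_register_mismatch(self, toy_dataset):
        a = build_frequency_table(toy_dataset, "TCEM_I")
        b = build_frequency_table(toy_dataset, "TCEM_IIA")
        with pytest.raises(ValueError, match="register"):
            motif_set_overlap(a, b)


class TestMapFCFromReference:
    def test_query_subset_of_reference(self):
        ref = _table_from_counts({"AAAAA": (4, 8), "CCCCC": (1, 1)}, 4)
        query = _table_from_counts({"AAAAA": (1, 1)}, 1)
        mapping = map_fc_from_reference(query, ref)
        assert mapping.unclassified_fraction == 0.0
        assert mapping.fc_by_motif == {"AAAAA": 0}

    def test_disjoint_query(self):
        ref = _table_from_counts({"AAAAA": (4, 8)}, 4)
        query = _table_from_counts({"DDDDD": (1, 1)}, 1)
        mapping = map_fc_from_reference(query, ref)
        assert mapping.unclassified_fraction == 1.0
        assert mapping.fc_by_motif == {"DDDDD": None}

    def test_mixed_lookup(self):
        ref = _table_from_counts({"AAAAA": (2, 4), "CCCCC": (1, 2)}, 8)
        query = _table_from_counts({"AAAAA": (1, 1), "CCCCC": (1, 1), "EEEEE": (1, 1), "FFFFF": (1, 1)}, 2)
        mapping = map_fc_from_reference(query, ref)
        assert mapping.fc_by_motif["AAAAA"] == 2  # 2/8 -> FC2
        assert mapping.fc_by_motif["CCCCC"] == 3  # 1/8 -> FC3
        assert mapping.fc_by_motif["EEEEE"] is None
        assert mapping.unclassified_fraction == 0.5


class TestUsageCorrelation:
    def test_identical_vectors(self):
        usage = {"g1": 0.5, "g2": 0.3, "g3": 0.2}
        assert usage_correlation(usage, dict(usage)) == pytest.approx(1.0)

    def test_collinear_reversed(self):
        obs = {"g1": 0.1, "g2": 0.2, "g3": 0.3}
        ref = {"g1": 0.3, "g2": 0.2, "g3": 0.1}
        assert usage_correlation(obs, ref) == pytest.approx(-1.0)

    def test_closed_form_oracle(self, rng):
        keys = [f"g{i}" for i in range(10)]
        x = rng.random(10)
        y = rng.random(10)
        obs = dict(zip(keys, x))
        ref = dict(zip(keys, y))
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert usage_correlation(obs, ref) == pytest.approx(float(r))

    def test_too_few_shared_keys(self):
        with pytest.raises(ValueError, match="3 shared"):
            usage_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
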