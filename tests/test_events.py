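"""Event aggregation, branch mapping and synteny validation."""

import dendropy
import numpy as np
import pytest

from endovir.events import (
    EveRecord,
    GeneTreeClade,
    SyntenyThresholds,
    aggregate_cross_species,
    aggregate_within_species,
    calibrate_synteny_thresholds,
    find_hsps,
    map_event_to_branch,
    synteny_score,
    validate_shared_event,
)


def eve(i, species="A", scaffold="s1", family="Nudiviridae", structure="dsDNA"):
    return EveRecord(f"{species}:e{i}", species, scaffold, family, structure)


@pytest.fixture()
def species_tree():
    t = dendropy.Tree.get(
        data="((A:1,B:1):1,(C:1,(D:0.5,E:0.5):0.5):0.5);", schema="newick"
    )
    t.is_rooted = True
    return t


class TestWithinSpecies:
    def test_scaffold_and_family_closure(self):
        # two dsDNA EVEs co-scaffolded + one elsewhere of the same family
        eves = [
            eve(1, scaffold="s1"),
            eve(2, scaffold="s1"),
            eve(3, scaffold="s2"),
        ]
        events = aggregate_within_species(eves)
        assert len(events) == 1 and events[0].n_eves == 3

    def test_different_scaffold_and_family_stay_separate(self):
        eves = [eve(1, scaffold="s1"), eve(2, scaffold="s2", family="Reoviridae", structure="dsRNA")]
        assert len(aggregate_within_species(eves)) == 2

    def test_same_scaffold_different_structure_not_merged(self):
        eves = [
            eve(1, scaffold="s1", family="Nudiviridae", structure="dsDNA"),
            eve(2, scaffold="s1", family="Rhabdoviridae", structure="ssRNA(-)"),
        ]
        assert len(aggregate_within_species(eves)) == 2

    def test_partition_and_order_invariance(self):
        eves = [
            eve(i, scaffold=f"s{i % 3}", family=f"F{i % 4}") for i in range(12)
        ]
        a = aggregate_within_species(eves)
        b = aggregate_within_species(list(reversed(eves)))
        part_a = sorted(sorted(m.eve_id for m in ev.members) for ev in a)
        part_b = sorted(sorted(m.eve_id for m in ev.members) for ev in b)
        assert part_a == part_b
        assert sum(ev.n_eves for ev in a) == 12

    def test_unknown_family_never_merges_by_family(self):
        eves = [
            eve(1, scaffold="s1", family="unknown"),
            eve(2, scaffold="s2", family="unknown"),
        ]
        assert len(aggregate_within_species(eves)) == 2


class TestCrossSpecies:
    def families(self, fam="Figitidae"):
        return {s: fam for s in "ABCDE"}

    def base_events(self):
        return aggregate_within_species(
            [eve(1, species="A"), eve(1, species="B", scaffold="s9")]
        )

    def test_supported_clade_merges(self, species_tree):
        merged = aggregate_cross_species(
            self.base_events(),
            [GeneTreeClade(["A:e1", "B:e1"], support=95.0)],
            species_tree,
            self.families(),
        )
        assert len(merged) == 1 and merged[0].species == {"A", "B"}

    def test_low_support_keeps_events_separate(self, species_tree):
        merged = aggregate_cross_species(
            self.base_events(),
            [GeneTreeClade(["A:e1", "B:e1"], support=70.0)],
            species_tree,
            self.families(),
        )
        assert len(merged) == 2

    def test_loss_tolerance_20_percent(self, species_tree):
        # clade C,D,E: EVEs in C and D only -> 1/3 missing > 20% -> no merge
        events = aggregate_within_species(
            [eve(1, species="C"), eve(1, species="D", scaffold="s9")]
        )
        merged = aggregate_cross_species(
            events,
            [GeneTreeClade(["C:e1", "D:e1"], support=95.0)],
            species_tree,
            self.families(),
        )
        assert len(merged) == 2
        # D,E are sisters: no species missing -> merge
        events2 = aggregate_within_species(
            [eve(1, species="D"), eve(1, species="E", scaffold="s9")]
        )
        merged2 = aggregate_cross_species(
            events2,
            [GeneTreeClade(["D:e1", "E:e1"], support=95.0)],
            species_tree,
            self.families(),
        )
        assert len(merged2) == 1

    def test_host_family_must_match(self, species_tree):
        fams = {"A": "Figitidae", "B": "Braconidae", "C": "Figitidae",
                "D": "Figitidae", "E": "Figitidae"}
        merged = aggregate_cross_species(
            self.base_events(),
            [GeneTreeClade(["A:e1", "B:e1"], support=95.0)],
            species_tree,
            fams,
        )
        assert len(merged) == 2

    def test_co_scaffolding_propagates_merge(self, species_tree):
        # in species A, e1 and e2 share a scaffold; homologs of each exist
        # in B on different scaffolds -> everything collapses to one event
        eves = [
            eve(1, species="A", scaffold="s1"),
            eve(2, species="A", scaffold="s1"),
            eve(1, species="B", scaffold="sx", family="unknown"),
            eve(2, species="B", scaffold="sy", family="unknown"),
        ]
        events = aggregate_within_species(eves)
        clades = [
            GeneTreeClade(["A:e1", "B:e1"], support=99.0),
            GeneTreeClade(["A:e2", "B:e2"], support=99.0),
        ]
        merged = aggregate_cross_species(events, clades, species_tree, self.families())
        assert len(merged) == 1 and merged[0].n_eves == 4

    def test_unknown_species_raises(self, species_tree):
        events = aggregate_within_species(
            [eve(1, species="A"), eve(1, species="Z", scaffold="s9")]
        )
        with pytest.raises(ValueError, match="Z"):
            aggregate_cross_species(
                events,
                [GeneTreeClade(["A:e1", "Z:e1"], support=95.0)],
                species_tree,
                {**self.families(), "Z": "Figitidae"},
            )


class TestBranchMapping:
    def test_multi_species_maps_to_mrca_stem(self, species_tree):
        ev = aggregate_within_species(
            [eve(1, species="D"), eve(1, species="E", scaffold="s2")]
        )
        merged = aggregate_cross_species(
            ev, [GeneTreeClade(["D:e1", "E:e1"], support=95.0)], species_tree,
            {s: "Figitidae" for s in "ABCDE"},
        )
        shared = [e for e in merged if len(e.species) == 2][0]
        assert map_event_to_branch(shared, species_tree) == "D|E"

    def test_single_species_maps_to_terminal_branch(self, species_tree):
        ev = aggregate_within_species([eve(1, species="C")])[0]
        assert map_event_to_branch(ev, species_tree) == "C"

    def test_all_leaves_map_to_root_stem(self, species_tree):
        from endovir.events import EndogenizationEvent

        ev = EndogenizationEvent(
            "EV", members=[eve(1, species=s, scaffold=f"s{s}") for s in "ABCDE"]
        )
        assert map_event_to_branch(ev, species_tree) == "A|B|C|D|E"


class TestSyntenyScore:
    def test_no_hsps(self):
        assert synteny_score([]) == 0

    def test_bit_threshold(self):
        assert synteny_score([(0, 120, 60.0), (200, 280, 40.0)]) == 120

    def test_overlapping_hsps_union_oracle(self):
        # two 100-bp HSPs offset by 50 cover 150 distinct positions
        assert synteny_score([(0, 100, 60.0), (50, 150, 60.0)]) == 150


class TestSyntenyCalibration:
    @pytest.fixture(scope="class")
    def repeat_genome(self):
        rng = np.random.default_rng(3)
        bases = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
        seq = bases[rng.integers(4, size=120_000)]
        rep = bases[rng.integers(4, size=400)]
        for pos in rng.integers(0, 119_000, size=12):
            seq[pos : pos + 400] = rep
        return "".join(seq)

    def test_identical_windows_saturate(self, repeat_genome):
        w = repeat_genome[:4000]
        score = synteny_score(find_hsps(w, w))
        assert score == 4000

    def test_fp_bounded_and_threshold_monotone(self, repeat_genome):
        thr = calibrate_synteny_thresholds(
            repeat_genome, window_sizes=(5_000, 20_000), n_sim=80, seed=2
        )
        (t_small, fp_small, tp_small) = thr.thresholds[5_000]
        (t_large, fp_large, tp_large) = thr.thresholds[20_000]
        assert fp_small <= 0.02 and fp_large <= 0.02
        assert tp_small == 1.0 and tp_large == 1.0  # zero-divergence copies
        assert t_large >= t_small

    def test_reproducible_with_seed(self, repeat_genome):
        a = calibrate_synteny_thresholds(repeat_genome, window_sizes=(5_000,), n_sim=40, seed=9)
        b = calibrate_synteny_thresholds(repeat_genome, window_sizes=(5_000,), n_sim=40, seed=9)
        assert a.thresholds == b.thresholds

    def test_oversized_window_skipped(self, repeat_genome):
        thr = calibrate_synteny_thresholds(
            repeat_genome, window_sizes=(10_000_000,), n_sim=10, seed=0
        )
        assert thr.thresholds == {}


class TestValidateSharedEvent:
    def thresholds(self):
        return SyntenyThresholds({
            100_000_000: (172_737.0, 0.012, 0.922),
            100_000: (1_332.0, 0.012, 0.198),
        })

    def shared_event(self):
        ev = aggregate_within_species(
            [eve(1, species="A"), eve(1, species="B", scaffold="s9")]
        )
        merged = ev[0]
        merged.members = ev[0].members + ev[1].members
        return merged

    def test_score_above_threshold_validates(self):
        assert validate_shared_event(self.shared_event(), 200_000, 100_000_000, self.thresholds()) is True

    def test_zero_score_fails(self):
        assert validate_shared_event(self.shared_event(), 0, 100_000, self.thresholds()) is False

    def test_single_species_is_na(self):
        ev = aggregate_within_species([eve(1)])[0]
        assert validate_shared_event(ev, 10, 100_000, self.thresholds()) is None

    def test_nearest_class_log_scale(self):
        thr = self.thresholds()
        assert thr.nearest_class(3_000_000) == 100_000
        assert thr.nearest_class(80_000_000) == 100_000_000
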