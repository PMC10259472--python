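"""Synthetic-data generators: trees, lifestyles, counts, genomes, codons."""

import numpy as np
import pytest

from endovir.mk import build_rate_matrix, flatten_tree
from endovir.simulate.config import GenomeSpec, PlantedEve, SimulationConfig, TreeModel
from endovir.simulate.codons import pair_alignment, simulate_codon_alignment
from endovir.simulate.evolve import evolve_lifestyles, simulate_event_counts
from endovir.simulate.genome import default_planted_eves, simulate_genome_bundle
from endovir.simulate.trees import expected_yule_root_age, simulate_species_tree
from endovir.codonmodel import STOP_CODONS

STATES = ["free_living", "ectoparasitoid", "endoparasitoid"]


class TestSpeciesTree:
    def test_smallest_admissible_tree(self):
        tree = simulate_species_tree(n_species=3, birth_rate=0.1, seed=1)
        assert len(tree.leaf_nodes()) == 3
        edges = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
        assert len(edges) == 4
        assert all(n.edge.length > 0 for n in edges)

    def test_deterministic_newick(self):
        a = simulate_species_tree(n_species=12, birth_rate=0.1, seed=7)
        b = simulate_species_tree(n_species=12, birth_rate=0.1, seed=7)
        assert a.as_string(schema="newick") == b.as_string(schema="newick")

    def test_ultrametric(self):
        tree = simulate_species_tree(n_species=20, birth_rate=0.05, seed=2)
        depths = []
        for leaf in tree.leaf_node_iter():
            d, n = 0.0, leaf
            while n.parent_node is not None:
                d += n.edge.length
                n = n.parent_node
            depths.append(d)
        assert np.allclose(depths, depths[0])

    def test_mean_root_age_matches_yule_expectation(self):
        ages = []
        for seed in range(200):
            tree = simulate_species_tree(n_species=8, birth_rate=0.1, seed=seed)
            flat = flatten_tree(tree)
            ages.append(flat.node_age[flat.root])
        expected = expected_yule_root_age(8, 0.1)
        # sd of the mean over 200 Yule trees is ~0.6 My here; allow 3 sigma
        assert np.mean(ages) == pytest.approx(expected, abs=2.0)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(n_species=5, birth_rate=0.0, seed=0)
        with pytest.raises(ValueError):
            TreeModel(birth_rate=-0.1).validate()


class TestLifestyles:
    def test_zero_rates_keep_root_state(self):
        tree = simulate_species_tree(n_species=10, birth_rate=0.1, seed=3)
        _, node_states, tip_map = evolve_lifestyles(tree, np.zeros(6), STATES, STATES[2], seed=1)
        assert set(tip_map.values()) == {STATES[2]}
        assert np.all(node_states == 2)

    def test_every_node_assigned(self):
        tree = simulate_species_tree(n_species=10, birth_rate=0.1, seed=3)
        flat, node_states, tip_map = evolve_lifestyles(tree, np.full(6, 0.01), STATES, STATES[0], seed=4)
        assert node_states.shape == (flat.n_nodes,)
        assert len(tip_map) == 10

    def test_unknown_root_state_rejected(self):
        tree = simulate_species_tree(n_species=5, birth_rate=0.1, seed=0)
        with pytest.raises(ValueError):
            evolve_lifestyles(tree, np.full(6, 0.01), STATES, "aquatic", seed=0)

    def test_fixed_seed_identical_map(self):
        tree = simulate_species_tree(n_species=15, birth_rate=0.1, seed=5)
        _, a, _ = evolve_lifestyles(tree, np.full(6, 0.02), STATES, STATES[0], seed=9)
        _, b, _ = evolve_lifestyles(tree, np.full(6, 0.02), STATES, STATES[0], seed=9)
        assert np.array_equal(a, b)

    def test_symmetric_rates_reach_stationary_uniform(self):
        """On a long single branch the tip state distribution approaches
        the (uniform) stationary distribution of symmetric rates."""
        import dendropy

        tree = dendropy.Tree.get(data="(A:4000,B:4000);", schema="newick")
        counts = np.zeros(3)
        for seed in range(600):
            _, _, tips = evolve_lifestyles(tree, np.full(6, 0.01), STATES, STATES[0], seed=seed)
            counts[STATES.index(tips["A"])] += 1
        freq = counts / counts.sum()
        q = build_rate_matrix(np.full(6, 0.01), 3)
        vals, vecs = np.linalg.eig(q.T)
        stat = np.real(vecs[:, np.argmax(np.real(vals))])
        stat /= stat.sum()
        assert np.allclose(freq, stat, atol=0.06)


class TestEventCounts:
    @pytest.fixture(scope="class")
    def tree_and_states(self):
        tree = simulate_species_tree(n_species=40, birth_rate=0.05, seed=6)
        flat, node_states, _ = evolve_lifestyles(tree, np.full(6, 0.002), STATES, STATES[0], seed=7)
        return flat, node_states

    def test_full_zero_inflation_gives_all_zeros(self, tree_and_states):
        flat, ns = tree_and_states
        obs = simulate_event_counts(flat, ns, STATES, {s: 0.1 for s in STATES},
                                    zero_inflation=1.0, dispersion=5.0, seed=1)
        assert all(b.n_events == 0 for b in obs)
        assert len(obs) == flat.n_nodes - 1

    def test_invalid_dispersion_rejected(self, tree_and_states):
        flat, ns = tree_and_states
        with pytest.raises(ValueError):
            simulate_event_counts(flat, ns, STATES, {s: 0.1 for s in STATES},
                                  zero_inflation=0.2, dispersion=0.0, seed=1)

    def test_planted_rate_ratio_monte_carlo(self):
        """Sample mean rate ratio over many branches is within 3 SE of 2.5."""
        import dendropy

        newick = "(" + ",".join(f"t{i}:10" for i in range(2)) + ");"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        flat = flatten_tree(tree)
        rates = {"free_living": 0.02, "ectoparasitoid": 0.02, "endoparasitoid": 0.05}
        totals = {"free_living": 0, "endoparasitoid": 0}
        lengths = {"free_living": 0.0, "endoparasitoid": 0.0}
        for seed in range(1000):
            ns = np.array([0, 2, 0])  # tip0 free-living, tip1 endo, root ignored
            obs = simulate_event_counts(flat, ns, STATES, rates, 0.2, 10.0, seed=seed)
            for b in obs:
                if b.lifestyle in totals:
                    totals[b.lifestyle] += b.n_events
                    lengths[b.lifestyle] += b.length
        r_free = totals["free_living"] / lengths["free_living"]
        r_endo = totals["endoparasitoid"] / lengths["endoparasitoid"]
        ratio = r_endo / r_free
        se = ratio * np.sqrt(1 / totals["endoparasitoid"] + 1 / totals["free_living"])
        assert abs(ratio - 2.5) < 3 * se

    def test_poisson_limit_variance_over_mean(self):
        import dendropy

        tree = dendropy.Tree.get(data="(a:50,b:50);", schema="newick")
        flat = flatten_tree(tree)
        counts = []
        for seed in range(800):
            obs = simulate_event_counts(flat, np.zeros(3, dtype=int), STATES,
                                        {s: 0.04 for s in STATES},
                                        zero_inflation=0.0,
                                        dispersion=float("inf"), seed=seed)
            counts.append(obs[0].n_events)
        counts = np.asarray(counts, dtype=float)
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.2)

    def test_domesticated_never_exceed_events(self, tree_and_states):
        flat, ns = tree_and_states
        obs = simulate_event_counts(flat, ns, STATES, {s: 0.2 for s in STATES},
                                    0.1, 2.0, seed=3,
                                    domestication_probs={s: 0.5 for s in STATES})
        assert all(b.n_devents <= b.n_events for b in obs)
        assert any(b.n_devents > 0 for b in obs)


class TestGenomeBundle:
    def test_no_planted_eves_no_passing_hits(self):
        cfg = SimulationConfig(seed=1)
        cfg.genome_spec = GenomeSpec(n_planted_eves=0, n_decoy_loci=0,
                                     n_contaminant_scaffolds=0)
        bundle = simulate_genome_bundle(cfg)
        from endovir.detection import filter_viral_hits

        assert filter_viral_hits(bundle.viral_hits) == []

    def test_planted_eve_yields_overlapping_passing_hit(self):
        cfg = SimulationConfig(seed=2)
        cfg.genome_spec = GenomeSpec(
            planted_eves=[PlantedEve("scaf007", 1000, 1900)], n_decoy_loci=0,
            n_contaminant_scaffolds=0,
        )
        bundle = simulate_genome_bundle(cfg)
        from endovir.detection import filter_viral_hits

        passing = filter_viral_hits(bundle.viral_hits)
        assert any(
            h.scaffold_id == "scaf007" and h.start < 1900 and 1000 < h.end
            for h in passing
        )

    def test_out_of_bounds_planting_rejected(self):
        cfg = SimulationConfig(seed=0)
        cfg.genome_spec = GenomeSpec(planted_eves=[PlantedEve("scaf006", 39_000, 41_000)])
        with pytest.raises(ValueError, match="bounds"):
            simulate_genome_bundle(cfg)

    def test_overlapping_planting_rejected(self):
        cfg = SimulationConfig(seed=0)
        cfg.genome_spec = GenomeSpec(
            planted_eves=[
                PlantedEve("scaf006", 1000, 2000),
                PlantedEve("scaf006", 1500, 2500, family="Reoviridae", structure="dsRNA"),
            ]
        )
        with pytest.raises(ValueError, match="overlap"):
            simulate_genome_bundle(cfg)

    def test_contaminants_carry_no_genes(self, small_bundle):
        contaminated = {g["scaffold"] for g in small_bundle.genes}
        assert not any(s.startswith("contam") for s in contaminated)

    def test_deterministic_bundle(self):
        a = simulate_genome_bundle(SimulationConfig(seed=5))
        b = simulate_genome_bundle(SimulationConfig(seed=5))
        assert a.scaffolds == b.scaffolds
        assert a.truth.equals(b.truth)
        assert [h for h in a.viral_hits] == [h for h in b.viral_hits]

    def test_default_layout_unique_family_per_event(self):
        spec = GenomeSpec()
        planted = default_planted_eves(spec, n_eves=20, seed=1)
        by_event = {}
        for p in planted:
            by_event.setdefault(p.event_id, set()).add(p.family)
        families = [next(iter(v)) for v in by_event.values()]
        assert all(len(v) == 1 for v in by_event.values())
        assert len(set(families)) == len(families)


class TestCodonAlignment:
    def test_length_and_no_internal_stops(self):
        aln = simulate_codon_alignment("(a:0.2,b:0.4);", omega=0.5, n_codons=100, seed=1)
        for seq in aln.values():
            assert len(seq) == 300
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not codons & set(STOP_CODONS)

    def test_zero_branch_length_identical(self):
        aln = simulate_codon_alignment("(a:0.0,b:0.0);", omega=1.0, n_codons=50, seed=2)
        assert aln["a"] == aln["b"]

    def test_deterministic(self):
        a = simulate_codon_alignment("(a:0.3,b:0.3);", omega=0.5, n_codons=60, seed=9)
        b = simulate_codon_alignment("(a:0.3,b:0.3);", omega=0.5, n_codons=60, seed=9)
        assert a == b

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_codon_alignment("(a:0.1,b:0.1);", omega=-1.0)
        with pytest.raises(ValueError):
            pair_alignment(0.1, 0.1, omega=1.0, n_codons=0)


def test_config_yaml_round_trip(tmp_path):
    cfg = SimulationConfig(seed=33)
    path = tmp_path / "config.yaml"
    cfg.to_yaml(path)
    assert SimulationConfig.from_yaml(path) == cfg
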