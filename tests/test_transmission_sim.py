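"""The vertical/horizontal transmission simulator and its ground truth."""

import numpy as np

from culturetree.character_matrix import binarize, read_matrix, write_csv
from culturetree.parsimony import (
    ANCESTOR_NAME,
    SearchConfig,
    add_zero_ancestor,
    character_fit,
    ensemble_fit,
    heuristic_search,
    root_at,
)
from culturetree.transmission_sim import (
    BorrowingEvent,
    SimOutput,
    SimParams,
    apply_horizontal,
    default_category_counts,
    evolve_characters,
    simulate,
    simulate_genealogy,
    write_events,
)
from culturetree.tree import robinson_foulds
from culturetree.treeness import mean_character_distance, treeness_report


FAST_SEARCH = SearchConfig(
    n_addition_sequences=2, swap="spr", seed=99, max_saved_trees=100, max_plateau_sweeps=10
)


class TestGenealogy:
    def test_leaf_count_and_binary_shape(self):
        for n in (4, 9, 17):
            t = simulate_genealogy(SimParams(seed=2, n_taxa=n))
            assert t.n_leaves == n
            assert t.is_binary()
            # a rooted binary tree over n leaves has 2n-2 branches
            assert sum(1 for x in t.postorder() if x.parent is not None) == 2 * n - 2

    def test_same_seed_same_newick(self):
        a = simulate_genealogy(SimParams(seed=7, n_taxa=12))
        b = simulate_genealogy(SimParams(seed=7, n_taxa=12))
        assert a.newick() == b.newick()

    def test_branch_lengths_positive(self):
        t = simulate_genealogy(SimParams(seed=5, n_taxa=15))
        for n in t.postorder():
            if n.parent is not None:
                assert n.length > 0


class TestVerticalPhase:
    def test_zero_innovation_rate_gives_all_absent(self):
        p = SimParams(seed=3, n_taxa=6, n_characters=20, innovation_rate=0.0,
                      missing_fraction=0.0)
        t = simulate_genealogy(p)
        m, events = evolve_characters(t, p)
        assert not events
        assert all(c.is_absent for row in m.cells for c in row)

    def test_infinite_alleles_are_homoplasy_free(self):
        p = SimParams(seed=8, n_taxa=8, n_characters=60, allele_model="infinite",
                      missing_fraction=0.0)
        sim = simulate(p)
        sm = add_zero_ancestor(sim.matrix)
        res = heuristic_search(sm, FAST_SEARCH)
        score = ensemble_fit(res.trees[0], sm)
        assert score.ci == 1.0 and score.ri == 1.0

    def test_finite_alleles_at_high_rate_show_homoplasy(self):
        p = SimParams(seed=8, n_taxa=10, n_characters=40, allele_model="finite",
                      innovation_rate=1.2, alphabet_size=3, missing_fraction=0.0)
        sim = simulate(p)
        sm = add_zero_ancestor(sim.matrix)
        res = heuristic_search(sm, FAST_SEARCH)
        fits = character_fit(res.trees[0], sm)
        assert any(f.s > f.m for f in fits)

    def test_category_structure_follows_published_proportions(self):
        counts = default_category_counts(322)
        assert counts["repertoire"] == 161 and counts["rhythmic_cell"] == 64
        assert sum(default_category_counts(150).values()) == 150
        p = SimParams(seed=1, n_taxa=6, n_characters=100)
        sim = simulate(p)
        assert sim.matrix.category_counts() == default_category_counts(100)


class TestHorizontalPhase:
    def test_zero_rate_is_identity(self):
        p = SimParams(seed=4, n_taxa=8, n_characters=30)
        t = simulate_genealogy(p)
        m, _ = evolve_characters(t, p)
        out, events = apply_horizontal(m, t, p)
        assert out == m and events == []

    def test_full_rate_copies_every_cell_from_a_donor(self):
        p = SimParams(seed=4, n_taxa=6, n_characters=25, horizontal_rate=1.0,
                      missing_fraction=0.0)
        t = simulate_genealogy(p)
        m, _ = evolve_characters(t, p)
        out, events = apply_horizontal(m, t, p)
        assert len(events) == m.n_taxa * m.n_characters
        names = m.taxon_names()
        for e in events:
            i, j = names.index(e.recipient), e.char_index - 1
            donor = names.index(e.donor)
            assert e.donor != e.recipient
            assert out.cells[i][j] == m.cells[donor][j]

    def test_changed_cell_fraction_matches_analytic_expectation(self):
        p = SimParams(seed=13, n_taxa=10, n_characters=120, horizontal_rate=1.0,
                      missing_fraction=0.0)
        t = simulate_genealogy(p)
        m, _ = evolve_characters(t, p)
        out, _ = apply_horizontal(m, t, p)
        # P(change) for a cell = P(uniform donor differs from the original)
        names = m.taxon_names()
        n = m.n_taxa
        expect = np.mean(
            [
                sum(m.cells[d][j] != m.cells[i][j] for d in range(n) if d != i) / (n - 1)
                for i in range(n)
                for j in range(m.n_characters)
            ]
        )
        observed = np.mean(
            [
                out.cells[i][j] != m.cells[i][j]
                for i in range(n)
                for j in range(m.n_characters)
            ]
        )
        sigma = np.sqrt(expect * (1 - expect) / (n * m.n_characters))
        assert abs(observed - expect) < 5 * sigma

    def test_event_log_accounts_for_every_difference(self):
        p = SimParams(seed=21, n_taxa=8, n_characters=50, horizontal_rate=0.3)
        sim = simulate(p)
        borrowed_at = {
            (e.recipient, e.char_index)
            for e in sim.events
            if isinstance(e, BorrowingEvent)
        }
        names = sim.matrix.taxon_names()
        for i, name in enumerate(names):
            for j in range(sim.matrix.n_characters):
                if sim.matrix.cells[i][j] != sim.vertical_matrix.cells[i][j]:
                    assert (name, j + 1) in borrowed_at

    def test_neighbor_locality_prefers_close_donors(self):
        p = SimParams(seed=2, n_taxa=12, n_characters=200, horizontal_rate=1.0,
                      borrowing_locality="neighbor", missing_fraction=0.0)
        t = simulate_genealogy(p)
        m, _ = evolve_characters(t, p)
        _, events = apply_horizontal(m, t, p)
        from culturetree.treeness import patristic_distances

        D = patristic_distances(t)
        order = {n: i for i, n in enumerate(D.taxa)}
        picked = np.mean([D.values[order[e.recipient], order[e.donor]] for e in events])
        overall = np.mean(D.values[np.triu_indices(D.n, k=1)])
        assert picked < overall

    def test_borrowing_raises_delta_score(self):
        deltas = {0.0: [], 0.5: []}
        for seed in range(1, 5):
            for h in deltas:
                sim = simulate(
                    SimParams(seed=seed, n_taxa=12, n_characters=80, horizontal_rate=h)
                )
                D = mean_character_distance(binarize(sim.matrix))
                deltas[h].append(treeness_report(D).mean_delta)
        assert np.mean(deltas[0.5]) > np.mean(deltas[0.0])


class TestSimulateWrapper:
    def test_rerun_is_byte_identical(self, tmp_path):
        p = SimParams(seed=6, n_taxa=10, n_characters=40)
        a, b = simulate(p), simulate(p)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_csv(a.matrix, pa)
        write_csv(b.matrix, pb)
        assert pa.read_bytes() == pb.read_bytes()
        assert a.tree.newick() == b.tree.newick()

    def test_emulates_published_matrix_structure(self, tmp_path):
        sim = simulate(SimParams(seed=10, n_taxa=58, n_characters=322))
        path = tmp_path / "sim.csv"
        write_csv(sim.matrix, path)
        m = read_matrix(path)
        assert m.shape == (58, 322)
        assert add_zero_ancestor(m).n_taxa == 59

    def test_event_log_roundtrips_as_tsv(self, tmp_path):
        sim = simulate(SimParams(seed=6, n_taxa=6, n_characters=10, horizontal_rate=0.2))
        path = tmp_path / "events.tsv"
        write_events(sim.events, path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == ["type", "char", "where", "donor", "from", "to"]
        assert len(lines) == len(sim.events) + 1

    def test_vertical_recovery_of_true_genealogy(self):
        """Homoplasy-free vertical transmission lets parsimony recover the
        generating tree exactly."""
        hits = 0
        n_rep = 8
        for seed in range(1, n_rep + 1):
            sim = simulate(
                SimParams(seed=seed, n_taxa=12, n_characters=200,
                          allele_model="infinite", horizontal_rate=0.0)
            )
            sm = add_zero_ancestor(sim.matrix)
            res = heuristic_search(
                sm,
                SearchConfig(n_addition_sequences=2, swap="spr", seed=1000 + seed,
                             max_saved_trees=300, max_plateau_sweeps=30),
            )
            rfs = [
                robinson_foulds(root_at(t, ANCESTOR_NAME, prune=True), sim.tree)
                for t in res.trees
            ]
            hits += min(rfs) == 0
        assert hits >= 0.95 * n_rep
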