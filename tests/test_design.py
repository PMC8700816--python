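"""Simplex design construction: candidates, I-criterion, exchange, replicates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixsurf import (
    Blend,
    MixtureDesign,
    augment_replicates,
    candidate_set,
    coordinate_exchange,
    i_criterion,
    scheffe_terms,
    simplex_grid,
)


def _has(cands, point):
    return any(b.matches(Blend(point)) for b in cands.blends)


class TestBlend:
    def test_renormalizes_rounded_fractions(self):
        b = Blend((0.333333, 0.333333, 0.333333))
        assert sum(b.fractions) == pytest.approx(1.0, abs=1e-15)

    def test_rejects_bad_sum(self):
        with pytest.raises(ValueError, match="sum"):
            Blend((0.5, 0.52, 0.0))

    def test_rejects_negative(self):
        with pytest.raises(ValueError, match="negative"):
            Blend((1.1, -0.1, 0.0))

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_normalized_input_always_sums_to_one(self, raw):
        fr = np.asarray(raw) / np.sum(raw)
        assert sum(Blend(fr).fractions) == pytest.approx(1.0, abs=1e-12)


class TestCandidateSet:
    def test_endpoint_lattice_gives_vertices_centroid_axials(self):
        cands = candidate_set(3, [0.0, 1.0])
        assert len(cands.blends) == 7
        for v in np.eye(3):
            assert _has(cands, v)
        assert _has(cands, [1 / 3] * 3)
        assert _has(cands, [2 / 3, 1 / 6, 1 / 6])

    def test_contains_all_distinct_blends_of_bundled_study(self, study):
        design, _ = study
        cands = candidate_set(3, [0, 1 / 3, 1 / 2, 2 / 3, 1])
        distinct = [design.runs[g[0]] for g in design.replicate_groups]
        assert len(distinct) == 12
        for blend in distinct:
            assert any(b.matches(blend, tol=1e-5) for b in cands.blends)

    def test_two_component_lattice_dedupes_centroid(self):
        cands = candidate_set(2, [0, 0.5, 1])
        # (1,0), (0,1), (1/2,1/2); centroid/axials duplicate existing points
        assert len(cands.blends) == 5  # plus the two axial points (3/4,1/4),(1/4,3/4)
        assert _has(cands, [0.5, 0.5])

    def test_empty_lattice_rejected(self):
        with pytest.raises(ValueError, match="empty lattice"):
            candidate_set(3, [])


class TestICriterion:
    def test_vertices_design_linear_model_gives_unit_variance(self):
        design = MixtureDesign(runs=[Blend(v) for v in np.eye(3)])
        crit = i_criterion(design, scheffe_terms(3, "linear"),
                           eval_grid=np.eye(3))
        # X'X is the identity, so the scaled variance at each vertex is 1
        assert crit == pytest.approx(1.0, abs=1e-12)

    def test_single_run_linear_model_errors(self):
        design = MixtureDesign(runs=[Blend([1 / 3] * 3)])
        with pytest.raises(np.linalg.LinAlgError):
            i_criterion(design, scheffe_terms(3, "linear"))

    def test_grid_resolution_convergence(self, study):
        design, _ = study
        terms = scheffe_terms(3, "quadratic")
        coarse = i_criterion(design, terms, eval_grid=simplex_grid(3, 1 / 44))
        fine = i_criterion(design, terms, eval_grid=simplex_grid(3, 1 / 140))
        assert coarse == pytest.approx(fine, rel=0.05)


class TestCoordinateExchange:
    def test_saturated_selection_returns_all_candidates(self):
        cands = candidate_set(3, [0.0, 1.0])
        d = coordinate_exchange(cands, len(cands.blends), scheffe_terms(3, "linear"))
        assert d.n_runs == len(cands.blends)

    def test_deterministic_given_seed(self):
        cands = candidate_set(3, [0, 0.5, 1])
        terms = scheffe_terms(3, "quadratic")
        d1 = coordinate_exchange(cands, 8, terms, n_starts=3, seed=7)
        d2 = coordinate_exchange(cands, 8, terms, n_starts=3, seed=7)
        assert d1.as_array().tolist() == d2.as_array().tolist()

    def test_infeasible_run_count_rejected(self):
        cands = candidate_set(3, [0.0, 1.0])
        with pytest.raises(ValueError, match="infeasible"):
            coordinate_exchange(cands, 2, scheffe_terms(3, "linear"))

    def test_never_worse_than_random_subsets(self):
        """Exchange result beats a 200-random-subset baseline (smaller is better)."""
        cands = candidate_set(3, [0, 1 / 3, 1 / 2, 2 / 3, 1])
        terms = scheffe_terms(3, "quadratic")
        grid = simplex_grid(3, 0.1)
        d = coordinate_exchange(cands, 8, terms, n_starts=2, seed=0, eval_grid=grid)
        best = i_criterion(d, terms, eval_grid=grid)
        rng = np.random.default_rng(0)
        n = len(cands.blends)
        for _ in range(200):
            idx = rng.choice(n, size=8, replace=False)
            sub = MixtureDesign(runs=[cands.blends[i] for i in idx])
            try:
                val = i_criterion(sub, terms, eval_grid=grid)
            except np.linalg.LinAlgError:
                continue
            assert best <= val + 1e-9


class TestAugmentReplicates:
    def test_noop_when_total_equals_current(self, study):
        design, _ = study
        assert augment_replicates(design, design.n_runs) is design

    def test_duplicates_raise_pure_error_df_exactly(self):
        cands = candidate_set(3, [0, 0.5, 1])
        d = coordinate_exchange(cands, 7, scheffe_terms(3, "quadratic"), seed=0,
                                eval_grid=simplex_grid(3, 0.1))
        for k in (1, 3, 5):
            aug = augment_replicates(d, d.n_runs + k)
            assert aug.pure_error_df == d.pure_error_df + k
            assert aug.n_distinct == d.n_distinct

    def test_centroid_replicated_first(self):
        runs = [Blend(v) for v in np.eye(3)] + [Blend([1 / 3] * 3)]
        d = MixtureDesign(runs=runs)
        aug = augment_replicates(d, 5)
        assert aug.runs[-1].matches(Blend([1 / 3] * 3))

    def test_shrinking_rejected(self, study):
        design, _ = study
        with pytest.raises(ValueError):
            augment_replicates(design, design.n_runs - 1)


class TestDesignInvariants:
    def test_pure_error_df_is_runs_minus_distinct(self, study):
        design, _ = study
        assert design.pure_error_df == design.n_runs - design.n_distinct == 5

    def test_bundled_replicate_structure(self, study):
        design, _ = study
        sizes = sorted(len(g) for g in design.replicate_groups)
        assert sizes == [1] * 9 + [2, 2, 4]

    def test_simplex_grid_rows_sum_to_one(self):
        g = simplex_grid(4, 0.1)
        assert np.allclose(g.sum(axis=1), 1.0)
        assert len(g) == len({tuple(r) for r in g.round(12)})
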