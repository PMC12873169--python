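import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import microstab.robustness as rob
from microstab.data import PathwayMap
from microstab.simulate import GenomeContentConfig, generate_genome_content


def _content(matrix, rrn=None, pathways=None):
    n_taxa, n_fn = matrix.shape
    taxa = [f"g{i}" for i in range(n_taxa)]
    fns = [f"K{j}" for j in range(n_fn)]
    cn = pd.DataFrame(matrix, index=pd.Index(taxa, name="taxon_id"), columns=fns)
    if pathways is None:
        half = n_fn // 2 or 1
        pathways = pd.DataFrame(
            {
                "function_id": fns,
                "pathway_id": ["P1"] * half + ["P2"] * (n_fn - half),
                "superpathway_id": ["SP1"] * half + ["SP2"] * (n_fn - half),
            }
        )
    rrn = pd.Series(1 if rrn is None else rrn, index=cn.index)
    return rob.GenomeContent(cn, rrn, PathwayMap(pathways))


class TestFunctionalProfile:
    def test_identity_map(self, identity_content, uniform_abundance):
        prof = rob.functional_profile(uniform_abundance, identity_content)
        np.testing.assert_allclose(prof.values, uniform_abundance.values)

    def test_redundant_rows_collapse(self):
        gc = _content(np.ones((2, 4)))
        for split in (0.5, 0.9):
            ab = pd.Series([split, 1 - split], index=gc.copy_numbers.index)
            prof = rob.functional_profile(ab, gc)
            np.testing.assert_allclose(prof.values, 0.25)

    def test_rrn_correction(self):
        gc = _content(np.eye(2), rrn=[2, 1])
        ab = pd.Series([0.5, 0.5], index=gc.copy_numbers.index)
        prof = rob.functional_profile(ab, gc)
        np.testing.assert_allclose(prof.values, [1 / 3, 2 / 3])

    def test_unknown_taxon_errors(self, identity_content):
        ab = pd.Series([1.0], index=["unknown"])
        with pytest.raises(ValueError, match="absent"):
            rob.functional_profile(ab, identity_content)

    def test_zero_projection_errors(self):
        gc = _content(np.array([[0, 0], [1, 1]]))
        ab = pd.Series([1.0, 0.0], index=gc.copy_numbers.index)
        with pytest.raises(ValueError, match="no taxon"):
            rob.functional_profile(ab, gc)


class TestPerturb:
    def test_zero_magnitude_identity(self, uniform_abundance):
        rng = np.random.default_rng(0)
        out = rob.perturb(uniform_abundance, 0.0, rng)
        pd.testing.assert_series_equal(out, uniform_abundance)

    def test_uniform_ten_taxa_m03_removes_three(self, uniform_abundance):
        rng = np.random.default_rng(1)
        out = rob.perturb(uniform_abundance, 0.3, rng)
        assert int((out == 0).sum()) == 3

    def test_survivors_sum_to_one(self, uniform_abundance):
        rng = np.random.default_rng(2)
        out = rob.perturb(uniform_abundance, 0.5, rng)
        assert out.sum() == pytest.approx(1.0)

    def test_magnitude_out_of_range(self, uniform_abundance):
        with pytest.raises(ValueError):
            rob.perturb(uniform_abundance, 0.96, np.random.default_rng(0))

    def test_emptying_community_errors(self):
        ab = pd.Series([0.5, 0.5], index=["g0", "g1"])
        with pytest.raises(ValueError, match="empties"):
            rob.perturb(ab, 0.6, np.random.default_rng(3))


class TestBrayCurtis:
    def test_identity(self):
        x = np.array([0.2, 0.3, 0.5])
        assert rob.bray_curtis(x, x) == 0.0

    def test_disjoint(self):
        assert rob.bray_curtis([1.0, 0.0], [0.0, 1.0]) == 1.0

    def test_worked_example(self):
        assert rob.bray_curtis([0.5, 0.5, 0.0], [0.25, 0.25, 0.5]) == pytest.approx(0.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rob.bray_curtis([-0.1, 1.1], [0.5, 0.5])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.dirichlet(np.ones(6))
        y = rng.dirichlet(np.ones(6))
        d = rob.bray_curtis(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(rob.bray_curtis(y, x))


class TestPerturbationCurve:
    def test_identity_content_df_equals_dt(self, identity_content, uniform_abundance):
        curve = rob.perturbation_curve(
            uniform_abundance, identity_content, rng=np.random.default_rng(5)
        )
        np.testing.assert_allclose(curve.d_F, curve.d_T, atol=1e-12)

    def test_redundant_content_df_zero(self, uniform_abundance):
        gc = _content(np.ones((10, 6)))
        curve = rob.perturbation_curve(
            uniform_abundance.set_axis(gc.copy_numbers.index),
            gc,
            rng=np.random.default_rng(6),
        )
        assert (curve.d_F == 0).all()

    def test_cardinality(self, identity_content, uniform_abundance):
        mags = tuple(np.round(np.arange(1, 16) * 0.05, 2))
        curve = rob.perturbation_curve(
            uniform_abundance, identity_content, magnitudes=mags, reps=20,
            rng=np.random.default_rng(7),
        )
        assert curve.d_T.size == 300

    def test_global_scope_equals_all_function_scope(self, uniform_abundance):
        rng_a = np.random.default_rng(8)
        rng_b = np.random.default_rng(8)
        gc = _content(
            np.random.default_rng(0).integers(0, 3, size=(10, 6)),
            pathways=pd.DataFrame(
                {
                    "function_id": [f"K{j}" for j in range(6)],
                    "pathway_id": ["P1"] * 6,
                    "superpathway_id": ["SP1"] * 6,
                }
            ),
        )
        ab = uniform_abundance.set_axis(gc.copy_numbers.index)
        a = rob.perturbation_curve(ab, gc, "global", rng=rng_a)
        b = rob.perturbation_curve(ab, gc, "superpathway:SP1", rng=rng_b)
        np.testing.assert_allclose(a.d_F, b.d_F, atol=1e-12)

    def test_empty_scope_errors(self, identity_content, uniform_abundance):
        with pytest.raises(ValueError, match="no functions|bad scope"):
            rob.perturbation_curve(
                uniform_abundance, identity_content, "pathway:NOPE",
                rng=np.random.default_rng(9),
            )

    def test_deterministic_under_seed(self, identity_content, uniform_abundance):
        a = rob.perturbation_curve(
            uniform_abundance, identity_content, rng=np.random.default_rng(10)
        )
        b = rob.perturbation_curve(
            uniform_abundance, identity_content, rng=np.random.default_rng(10)
        )
        np.testing.assert_array_equal(a.d_F, b.d_F)
        np.testing.assert_array_equal(a.d_T, b.d_T)


class TestFitHinge:
    def _curve(self, d_t, d_f):
        return rob.PerturbationCurve("s", "global", np.asarray(d_t, float),
                                     np.asarray(d_f, float), (0.5,), 1)

    def test_noiseless_recovery(self):
        rng = np.random.default_rng(11)
        d_t = rng.uniform(0, 0.9, 50)
        d_f = 0.6 * np.clip(d_t - 0.1, 0, None)
        fit = rob.fit_hinge(self._curve(d_t, d_f))
        assert fit.offset == pytest.approx(0.1, abs=rob.HINGE_GRID_STEP)
        assert fit.slope == pytest.approx(0.6, abs=0.01)

    def test_identity_line(self):
        d_t = np.linspace(0.05, 0.9, 40)
        fit = rob.fit_hinge(self._curve(d_t, d_t))
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.offset == 0.0

    def test_flat_data(self):
        d_t = np.linspace(0.05, 0.9, 40)
        fit = rob.fit_hinge(self._curve(d_t, np.zeros(40)))
        assert fit.slope == 0.0
        assert fit.offset == 0.0

    def test_all_zero_dt_errors(self):
        with pytest.raises(ValueError, match="zero"):
            rob.fit_hinge(self._curve(np.zeros(20), np.zeros(20)))

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match=">= 10"):
            rob.fit_hinge(self._curve([0.5] * 5, [0.2] * 5))


class TestRobustnessScores:
    def test_degenerate_null_flagged(self, uniform_abundance):
        gc = _content(np.ones((10, 6)))
        ab = uniform_abundance.set_axis(gc.copy_numbers.index)
        curve = rob.perturbation_curve(ab, gc, rng=np.random.default_rng(12))
        obs = rob.fit_hinge(curve)
        score = rob.robustness_scores(
            obs, gc, ab, n_null=20, rng=np.random.default_rng(13)
        )
        assert not score.attenuation_defined
        assert np.isnan(score.attenuation)

    def test_observed_at_null_mean_gives_zero(self):
        s_null = np.array([0.2, 0.4, 0.6, 0.8])
        b_null = np.array([0.0, 0.1, 0.2, 0.1])
        obs = rob.HingeFit(
            slope=float(s_null.mean()), offset=float(b_null.mean()),
            rss=0.0, n_points=20,
        )
        score = rob._score_from_fits("s", "global", obs, s_null, b_null)
        assert score.attenuation == 0.0
        assert score.buffering == 0.0

    def test_sign_conventions(self):
        s_null = np.array([0.5, 0.6, 0.7])
        b_null = np.array([0.1, 0.2, 0.3])
        flat_tolerant = rob.HingeFit(slope=0.1, offset=0.5, rss=0.0, n_points=20)
        score = rob._score_from_fits("s", "global", flat_tolerant, s_null, b_null)
        assert score.attenuation > 0  # flatter response than null
        assert score.buffering > 0  # bigger perturbation tolerated than null

    def test_n_null_minimum(self, identity_content, uniform_abundance):
        obs = rob.fit_hinge(
            rob.perturbation_curve(
                uniform_abundance, identity_content, rng=np.random.default_rng(16)
            )
        )
        with pytest.raises(ValueError, match="n_null"):
            rob.robustness_scores(
                obs, identity_content, uniform_abundance, n_null=5,
                rng=np.random.default_rng(17),
            )

    def test_redundancy_sweep_monotone_slope(self):
        levels = [round(0.1 * i, 1) for i in range(1, 10)]
        means = []
        for r in levels:
            slopes = []
            for rep in range(5):
                gc = generate_genome_content(
                    GenomeContentConfig(
                        n_taxa=20, n_functions=60, redundancy=r,
                        n_pathways=6, n_superpathways=2, seed=100 + rep,
                    )
                )
                rng = np.random.default_rng(200 + rep)
                ab = pd.Series(
                    rng.dirichlet(np.ones(20)), index=gc.copy_numbers.index
                )
                curve = rob.perturbation_curve(
                    ab, gc, reps=8, rng=np.random.default_rng(300 + rep)
                )
                slopes.append(rob.fit_hinge(curve).slope)
            means.append(np.mean(slopes))
        assert all(b <= a + 1e-12 for a, b in zip(means, means[1:]))

    def test_taxon_relabeling_invariance(self, uniform_abundance):
        rng_mat = np.random.default_rng(18)
        mat = rng_mat.integers(0, 3, (10, 8))
        gc = _content(mat)
        ab = uniform_abundance.set_axis(gc.copy_numbers.index)
        curve = rob.perturbation_curve(ab, gc, rng=np.random.default_rng(19))
        # relabel taxa (same order, new names): identical scores
        renamed = mat.copy()
        gc2 = _content(renamed)
        gc2.copy_numbers.index = pd.Index(
            [f"z{i}" for i in range(10)], name="taxon_id"
        )
        gc2.rrn.index = gc2.copy_numbers.index
        ab2 = pd.Series(ab.values, index=gc2.copy_numbers.index)
        curve2 = rob.perturbation_curve(ab2, gc2, rng=np.random.default_rng(19))
        np.testing.assert_allclose(curve.d_F, curve2.d_F)


class TestPathwayRobustness:
    def test_one_record_per_superpathway(self, uniform_abundance):
        gc = _content(np.random.default_rng(2).integers(0, 3, (10, 8)))
        ab = uniform_abundance.set_axis(gc.copy_numbers.index)
        scores = rob.pathway_robustness(
            ab, gc, "superpathway", reps=5, n_null=20,
            rng=np.random.default_rng(20),
        )
        assert [s.scope for s in scores] == ["superpathway:SP1", "superpathway:SP2"]

    def test_uniform_pathway_blind_to_composition(self, uniform_abundance):
        # functions of P1 carried identically by every taxon: d_F = 0 in P1 scope
        mat = np.random.default_rng(3).integers(0, 3, (10, 8))
        mat[:, :4] = 2
        gc = _content(mat)
        ab = uniform_abundance.set_axis(gc.copy_numbers.index)
        curve = rob.perturbation_curve(
            ab, gc, "pathway:P1", rng=np.random.default_rng(21)
        )
        np.testing.assert_allclose(curve.d_F, 0.0, atol=1e-12)

    def test_same_seed_identical_scores(self, uniform_abundance):
        gc = _content(np.random.default_rng(4).integers(0, 3, (10, 8)))
        ab = uniform_abundance.set_axis(gc.copy_numbers.index)
        a = rob.pathway_robustness(ab, gc, "superpathway", reps=5, n_null=20,
                                   rng=np.random.default_rng(22))
        b = rob.pathway_robustness(ab, gc, "superpathway", reps=5, n_null=20,
                                   rng=np.random.default_rng(22))
        assert [(s.attenuation, s.buffering) for s in a] == [
            (s.attenuation, s.buffering) for s in b
        ]

    def test_bad_level_rejected(self, identity_content, uniform_abundance):
        with pytest.raises(ValueError, match="level"):
            rob.pathway_robustness(
                uniform_abundance, identity_content, "kingdom",
                rng=np.random.default_rng(23),
            )
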