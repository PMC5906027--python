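"""Synthetic-world generator: templates, item spaces, loadings, lesions, naming."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit
from scipy.stats import spearmanr

from lesion_rsa.core import GridSpec
from lesion_rsa import synth


def _is_connected(grid, voxels):
    """BFS oracle for 6-connectivity."""
    if len(voxels) <= 1:
        return True
    vox = set(int(v) for v in voxels)
    coords = {tuple(c) for c in grid.unravel(np.array(sorted(vox)))}
    start = next(iter(coords))
    seen = {start}
    stack = [start]
    while stack:
        x, y, z = stack.pop()
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            nb = (x + dx, y + dy, z + dz)
            if nb in coords and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(coords)


class TestMakeTemplate:
    def test_disjoint_contiguous_exact_sizes(self):
        grid = GridSpec((10, 10, 10))
        tpl = synth.make_template(grid, 3, 50, seed=1)
        all_vox = np.concatenate([r.voxels for r in tpl.regions.values()])
        assert len(all_vox) == len(np.unique(all_vox)) == 150
        for reg in tpl.regions.values():
            assert reg.n_voxels == 50
            assert _is_connected(grid, reg.voxels)

    def test_single_region_fills_grid(self):
        grid = GridSpec((2, 2, 2))
        tpl = synth.make_template(grid, 1, 8, seed=0)
        assert set(tpl["conn_000"].voxels) == set(range(8))

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="insufficient voxels"):
            synth.make_template(GridSpec((2, 2, 2)), 2, 8, seed=0)

    def test_deterministic(self):
        grid = GridSpec((8, 8, 8))
        a = synth.make_template(grid, 4, 30, seed=5)
        b = synth.make_template(grid, 4, 30, seed=5)
        for name in a.names:
            np.testing.assert_array_equal(a[name].voxels, b[name].voxels)


class TestMakeItemSpace:
    def test_attribute_targets_hit(self):
        truth = synth.make_item_space(30, 5, 3, seed=2)
        sem = pdist(truth.item_embeddings)
        for name, target in synth.DEFAULT_ATTR_TARGETS.items():
            r = spearmanr(pdist(truth.attribute_embeddings[name]), sem).statistic
            assert abs(r - target) <= 0.15, (name, r)

    def test_shape_coupling_matches_observed_level(self):
        # semantic-shape coupling r = 0.35 emulated within a wide band
        truth = synth.make_item_space(30, 5, 8, {"shape": 0.35}, seed=7)
        r = spearmanr(pdist(truth.attribute_embeddings["shape"]),
                      pdist(truth.item_embeddings)).statistic
        assert 0.20 <= r <= 0.50

    def test_deterministic_bitwise(self):
        a = synth.make_item_space(20, 5, 3, seed=9)
        b = synth.make_item_space(20, 5, 3, seed=9)
        np.testing.assert_array_equal(a.item_embeddings, b.item_embeddings)
        for k in a.attribute_embeddings:
            np.testing.assert_array_equal(a.attribute_embeddings[k],
                                          b.attribute_embeddings[k])

    def test_near_unity_target_rejected(self):
        with pytest.raises(ValueError, match="unattainable target"):
            synth.make_item_space(20, 5, 2, {"shape": 0.999}, seed=0)

    def test_divisibility_required(self):
        with pytest.raises(ValueError, match="divisible"):
            synth.make_item_space(21, 5, 3, seed=0)

    def test_coupling_override_identity(self):
        truth = synth.make_item_space(20, 5, 3, {"shape": 0.35}, seed=3,
                                      coupling_override={"shape": 1.0})
        np.testing.assert_allclose(truth.attribute_embeddings["shape"],
                                   truth.item_embeddings)

    def test_category_cluster_structure(self):
        truth = synth.make_item_space(30, 5, 3, seed=4)
        d = squareform(pdist(truth.item_embeddings))
        cats = np.array(truth.categories)
        within = d[(cats[:, None] == cats[None, :]) & (d > 0)].mean()
        between = d[cats[:, None] != cats[None, :]].mean()
        assert between > within


class TestMakeLoadings:
    def test_informative_loading_similarity_tracks_semantics(self):
        grid = GridSpec((10, 10, 10))
        tpl = synth.make_template(grid, 1, 100, seed=3)
        truth = synth.make_item_space(30, 5, 3, seed=3)
        synth.make_loadings(tpl, truth, [tpl.names[0]], gain=2.0, seed=3)
        L = truth.connection_loadings[tpl.names[0]]
        norms = np.linalg.norm(L, axis=1)
        cos = L @ L.T / np.outer(norms, norms)
        iu = np.triu_indices(30, 1)
        sem = squareform(pdist(truth.item_embeddings))
        r = spearmanr((1 - cos)[iu], sem[iu]).statistic
        assert r > 0.5

    def test_zero_gain_removes_structure(self):
        grid = GridSpec((10, 10, 10))
        tpl = synth.make_template(grid, 1, 100, seed=3)
        truth = synth.make_item_space(30, 5, 3, seed=3)
        synth.make_loadings(tpl, truth, [tpl.names[0]], gain=0.0, seed=3)
        L = truth.connection_loadings[tpl.names[0]]
        norms = np.linalg.norm(L, axis=1)
        cos = L @ L.T / np.outer(norms, norms)
        iu = np.triu_indices(30, 1)
        sem = squareform(pdist(truth.item_embeddings))
        r = spearmanr((1 - cos)[iu], sem[iu]).statistic
        assert abs(r) < 0.3

    def test_item_permutation_equivariance(self):
        grid = GridSpec((8, 8, 8))
        tpl = synth.make_template(grid, 1, 40, seed=6)
        t1 = synth.make_item_space(20, 5, 3, seed=6)
        synth.make_loadings(tpl, t1, [tpl.names[0]], gain=2.0, seed=6)
        perm = np.random.default_rng(1).permutation(20)
        t2 = synth.make_item_space(20, 5, 3, seed=6)
        t2.item_embeddings = t2.item_embeddings[perm]
        t2.item_ids = [t1.item_ids[p] for p in perm]
        t2.categories = [t1.categories[p] for p in perm]
        synth.make_loadings(tpl, t2, [tpl.names[0]], gain=2.0, seed=6)
        np.testing.assert_allclose(
            t2.connection_loadings[tpl.names[0]],
            t1.connection_loadings[tpl.names[0]][perm])

    def test_unknown_region_name(self):
        grid = GridSpec((8, 8, 8))
        tpl = synth.make_template(grid, 1, 40, seed=6)
        truth = synth.make_item_space(20, 5, 3, seed=6)
        with pytest.raises(ValueError, match="unknown connection"):
            synth.make_loadings(tpl, truth, ["nope"], gain=1.0, seed=6)

    def test_voxel_axis_matches_region(self, tiny_world):
        truth, template = tiny_world["truth"], tiny_world["template"]
        for name, reg in template.regions.items():
            assert truth.connection_loadings[name].shape == (truth.n_items,
                                                             reg.n_voxels)


class TestSimulateLesions:
    def test_single_blob_contiguous_sizes(self):
        grid = GridSpec((12, 12, 12))
        tpl = synth.make_template(grid, 4, 50, seed=2)
        cohort = synth.simulate_lesions(tpl, 20, (30, 300), seed=2)
        assert cohort.n_patients == 20
        for pid in cohort.patient_ids:
            mask = cohort.masks[pid]
            assert 30 <= len(mask) <= 300
            assert _is_connected(grid, mask)

    def test_zero_size_empty_masks(self):
        grid = GridSpec((6, 6, 6))
        tpl = synth.make_template(grid, 2, 20, seed=2)
        cohort = synth.simulate_lesions(tpl, 5, (0, 0), seed=2)
        assert all(cohort.masks[p].size == 0 for p in cohort.patient_ids)

    def test_deterministic(self):
        grid = GridSpec((10, 10, 10))
        tpl = synth.make_template(grid, 3, 40, seed=4)
        a = synth.simulate_lesions(tpl, 10, (20, 40), seed=7)
        b = synth.simulate_lesions(tpl, 10, (20, 40), seed=7)
        for pid in a.patient_ids:
            np.testing.assert_array_equal(a.masks[pid], b.masks[pid])

    def test_multifocal_confined_to_regions(self, tiny_world):
        cohort, template = tiny_world["cohort"], tiny_world["template"]
        tpl_vox = np.concatenate([r.voxels for r in template.regions.values()])
        for pid in cohort.patient_ids:
            assert np.isin(cohort.masks[pid], tpl_vox).all()

    def test_etiology_composition(self):
        grid = GridSpec((10, 10, 10))
        tpl = synth.make_template(grid, 3, 40, seed=4)
        cohort = synth.simulate_lesions(tpl, 80, (20, 40), seed=7)
        counts = cohort.patients["etiology"].value_counts()
        assert counts["stroke"] == 67 and counts["tbi"] == 13


class TestSimulateNaming:
    def test_zero_slope_fair_coin(self, tiny_world):
        truth = synth.make_item_space(30, 5, 3, seed=5)
        template, cohort = tiny_world["template"], tiny_world["cohort"]
        for name, reg in template.regions.items():
            truth.connection_loadings[name] = np.zeros((30, reg.n_voxels))
            truth.informative_flags[name] = False
        truth.logistic_params = (0.0, 0.0)
        naming = synth.simulate_naming(cohort, template, truth, seed=5)
        n = naming.values.size
        se = 0.5 / np.sqrt(n)
        assert abs(naming.values.mean() - 0.5) < 3 * se

    def test_empty_mask_closed_form(self):
        # unlesioned patients err at exactly expit(beta0)
        grid = GridSpec((6, 6, 6))
        tpl = synth.make_template(grid, 2, 20, seed=8)
        truth = synth.make_item_space(200, 5, 3, seed=8)
        synth.make_loadings(tpl, truth, [], gain=0.0, seed=8)
        truth.logistic_params = (-4.0, 1.0)
        cohort = synth.simulate_lesions(tpl, 4, (0, 0), seed=8)
        naming = synth.simulate_naming(cohort, tpl, truth, seed=8)
        p_wrong = 1 - naming.values.mean()
        expected = expit(-4.0)
        se = np.sqrt(expected * (1 - expected) / naming.values.size)
        assert abs(p_wrong - expected) < 4 * se

    def test_accuracy_nonincreasing_in_slope(self):
        grid = GridSpec((8, 8, 8))
        tpl = synth.make_template(grid, 3, 30, seed=9)
        truth = synth.make_item_space(10, 5, 3, seed=9)
        synth.make_loadings(tpl, truth, tpl.names[:1], gain=2.0, seed=9,
                            damage_scale=5.0)
        means = {b1: [] for b1 in (0.0, 1.0, 2.5)}
        for s in range(20):
            cohort = synth.simulate_lesions(tpl, 25, (10, 30), seed=100 + s)
            for b1 in means:
                truth.logistic_params = (-1.0, b1)
                nm = synth.simulate_naming(cohort, tpl, truth, seed=100 + s)
                means[b1].append(nm.values.mean())
        avg = {b1: np.mean(v) for b1, v in means.items()}
        assert avg[0.0] >= avg[1.0] >= avg[2.5]

    def test_target_accuracy_calibration(self, tiny_world):
        naming = tiny_world["naming"]
        assert abs(naming.values.mean() - 0.7) < 0.05
        # calibrated intercept is recorded in the ground truth
        assert tiny_world["truth"].logistic_params[1] == 1.5

    def test_missing_loadings_error(self, tiny_world):
        truth = synth.make_item_space(20, 5, 3, seed=1)
        with pytest.raises(ValueError, match="loadings missing"):
            synth.simulate_naming(tiny_world["cohort"], tiny_world["template"],
                                  truth, seed=1)


class TestSimulateArrangements:
    def test_first_trial_complete_and_subsets_valid(self):
        truth = synth.make_item_space(20, 5, 2, seed=3)
        trials = synth.simulate_arrangements(truth, n_raters=3, noise_sd=0.1,
                                             trials_per_rater=5, seed=3)
        items = set(truth.item_ids)
        for (r, t), grp in trials.groupby(["rater", "trial"]):
            assert set(grp["item"]) <= items
            if t == 0:
                assert set(grp["item"]) == items

    def test_noiseless_recovers_true_rdm(self):
        from lesion_rsa.behavior import aggregate_arrangement
        truth = synth.make_item_space(20, 5, 2, seed=4)  # 2-D space: exact layout
        trials = synth.simulate_arrangements(truth, n_raters=4, noise_sd=0.0,
                                             trials_per_rater=4, seed=4)
        rdm = aggregate_arrangement(trials, truth.item_ids)
        iu = np.triu_indices(20, 1)
        sem = squareform(pdist(truth.item_embeddings))
        r = spearmanr(rdm.values[iu], sem[iu]).statistic
        assert r > 0.95

    def test_rater_count_validated(self):
        truth = synth.make_item_space(10, 5, 2, seed=1)
        with pytest.raises(ValueError):
            synth.simulate_arrangements(truth, n_raters=0, seed=1)
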