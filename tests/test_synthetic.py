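"""Generator contracts: determinism, nesting, truth/image consistency."""

import numpy as np
import pytest

from mgquant import synthetic as syn
from mgquant.synthetic import (
    FieldTooCrowdedError,
    GeneratorConfig,
    generate_assay_table,
    generate_fish_field,
    generate_microglia_volume,
    generate_sholl_phantom,
    generate_synapse_field,
)

from conftest import tiny_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"lysosome_fraction": 1.5},
            {"engulfed_fraction": -0.1},
            {"soma_radius": 0.0},
            {"voxel_size": (0.3, -0.1, 0.1)},
            {"n_cells": -1},
            {"fish_type_means": {"glutamatergic": {"IL34": 0.0}}},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            GeneratorConfig(**kw)

    def test_too_small_explicit_field_raises_crowded(self):
        cfg = tiny_config(field_shape=(6, 40, 40), n_cells=10)
        with pytest.raises(FieldTooCrowdedError):
            generate_microglia_volume(cfg)


class TestMicrogliaVolume:
    def test_seeded_determinism_bit_exact(self):
        v1, t1 = generate_microglia_volume(tiny_config(seed=7))
        v2, t2 = generate_microglia_volume(tiny_config(seed=7))
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(t1.cell_labels, t2.cell_labels)
        assert np.array_equal(
            t1.per_cell_true_engulfed_volume, t2.per_cell_true_engulfed_volume
        )

    def test_empty_field_is_background_only(self):
        cfg = tiny_config(n_cells=0, n_synaptic_puncta=0)
        vol, truth = generate_microglia_volume(cfg)
        assert truth.n_cells == 0
        assert truth.per_cell_true_volume.size == 0
        assert not truth.cell_labels.any()
        # all channels pure noise around background
        assert vol.data.mean() == pytest.approx(cfg.background_level, rel=0.05)

    def test_zero_engulfed_fraction_forces_zero_engulfed_volume(self):
        _, truth = generate_microglia_volume(tiny_config(engulfed_fraction=0.0))
        assert np.all(truth.per_cell_true_engulfed_volume == 0)

    def test_exact_engulfed_puncta_count(self):
        cfg = tiny_config(engulfed_fraction=0.3, n_synaptic_puncta=21)
        _, truth = generate_microglia_volume(cfg)
        assert truth.extra["n_engulfed_puncta"] == round(0.3 * 21)
        assert truth.puncta_engulfed.sum() == round(0.3 * 21)

    def test_nesting_by_construction(self, tiny_field):
        _, truth = tiny_field
        assert np.all(
            truth.per_cell_true_engulfed_volume
            <= truth.per_cell_true_lysosome_volume + 1e-9
        )
        assert np.all(
            truth.per_cell_true_lysosome_volume
            <= truth.per_cell_true_volume + 1e-9
        )

    def test_cd68_voxels_all_inside_cells(self, tiny_field):
        _, truth = tiny_field
        assert np.all(truth.cell_labels[truth.lysosome_mask] > 0)

    def test_truth_matches_brute_force_voxel_recount(self, tiny_field):
        """Recomputing volumes from the emitted grids must equal the truth
        exactly — the truth is derived, not asserted."""
        _, truth = tiny_field
        voxvol = np.prod(truth.voxel_size)
        for k in range(truth.n_cells):
            cell = truth.cell_labels == k + 1
            assert truth.per_cell_true_volume[k] == pytest.approx(
                cell.sum() * voxvol
            )
            assert truth.per_cell_true_lysosome_volume[k] == pytest.approx(
                (cell & truth.lysosome_mask).sum() * voxvol
            )
            assert truth.per_cell_true_engulfed_volume[k] == pytest.approx(
                (cell & truth.lysosome_mask & truth.synaptic_mask).sum() * voxvol
            )

    def test_engulfed_volume_monotone_in_engulfed_fraction(self):
        totals = [
            generate_microglia_volume(tiny_config(seed=3, engulfed_fraction=f))[1]
            .per_cell_true_engulfed_volume.sum()
            for f in (0.0, 0.5, 1.0)
        ]
        assert totals[0] <= totals[1] <= totals[2]
        assert totals[0] < totals[2]

    def test_class_labels_cover_every_cell(self, tiny_field):
        _, truth = tiny_field
        assert len(truth.per_cell_class_label) == truth.n_cells
        assert set(truth.per_cell_class_label) <= {"Lo", "Mid", "Hi"}


@pytest.fixture(scope="module")
def small_fish():
    return generate_fish_field(syn.fish_config(seed=2, n_cells=40))


class TestFishField:
    def test_seeded_determinism(self):
        cfg = syn.fish_config(seed=9, n_cells=12)
        v1, t1 = generate_fish_field(cfg)
        v2, t2 = generate_fish_field(cfg)
        assert np.array_equal(v1.data, v2.data)
        for ch in t1.per_cell_true_puncta:
            assert np.array_equal(t1.per_cell_true_puncta[ch], t2.per_cell_true_puncta[ch])

    def test_channels_and_types(self, small_fish):
        vol, truth = small_fish
        assert vol.channel_names == ("DAPI", "VGlut1", "Gad2", "IL34")
        assert sorted(set(truth.per_cell_type)) == ["GABAergic", "glutamatergic"]
        assert len(truth.per_cell_type) == truth.n_cells

    def test_truth_mean_ratio_near_two_at_n200_per_type(self):
        """Brute-force average of generated truth counts: with target means
        10 vs 5 the per-type sample-mean ratio is 2 within sampling error."""
        _, truth = generate_fish_field(syn.fish_config(seed=4, n_cells=400))
        types = np.asarray(truth.per_cell_type)
        il34 = truth.per_cell_true_puncta["IL34"]
        ratio = il34[types == "glutamatergic"].mean() / il34[types == "GABAergic"].mean()
        assert ratio == pytest.approx(2.0, abs=0.3)

    def test_poisson_limit_variance_matches_mean(self):
        rng = syn.stage_rng(0, "nb-limit")
        x = syn._nb_counts(rng, 8.0, np.inf, 20000)
        assert x.var() == pytest.approx(x.mean(), rel=0.05)
        y = syn._nb_counts(rng, 8.0, 4.0, 20000)
        assert y.var() == pytest.approx(8.0 + 64.0 / 4.0, rel=0.1)

    def test_requires_both_neuron_types(self):
        cfg = syn.fish_config(seed=0, n_cells=4)
        cfg.fish_type_means = {"glutamatergic": {"IL34": 5.0}}
        with pytest.raises(ValueError, match="fish_type_means"):
            generate_fish_field(cfg)


class TestSynapseField:
    def test_full_colocalization_forced(self):
        cfg = syn.synapse_config(seed=1, n_synaptic_puncta=50, coloc_probability=1.0)
        _, truth = generate_synapse_field(cfg)
        assert truth.colocalized_pair_count == 50

    def test_zero_colocalization_forced(self):
        cfg = syn.synapse_config(seed=1, n_synaptic_puncta=50, coloc_probability=0.0)
        _, truth = generate_synapse_field(cfg)
        assert truth.colocalized_pair_count == 0
        # enforced separation: no pre mask voxel touches a post mask voxel
        assert not (truth.extra["pre_mask"] & truth.extra["post_mask"]).any()

    def test_seeded_determinism(self):
        cfg = syn.synapse_config(seed=5, n_synaptic_puncta=30)
        v1, t1 = generate_synapse_field(cfg)
        v2, t2 = generate_synapse_field(cfg)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(t1.extra["pre_centroids_um"], t2.extra["pre_centroids_um"])


class TestShollPhantom:
    def test_arm_count_validation(self):
        with pytest.raises(ValueError):
            generate_sholl_phantom(0, 20.0, 0.2)
        with pytest.raises(ValueError, match="beyond the soma"):
            generate_sholl_phantom(3, 2.0, 0.2, soma_radius_um=3.0)
        with pytest.raises(ValueError, match="distinct"):
            generate_sholl_phantom(2, 20.0, 0.2, angles_rad=np.array([0.1, 0.1]))

    def test_binary_star_geometry(self):
        vol, truth = generate_sholl_phantom(4, 15.0, 0.25, soma_radius_um=2.0)
        img = vol.data[0, 0] > 0
        assert truth.extra["n_arms"] == 4
        cy = int(round(truth.soma_centers_um[0][1] / 0.25))
        assert img[cy, cy]  # soma present at centre


class TestAssayTable:
    def test_zero_noise_recovers_fold_change_exactly(self):
        df, truth = generate_assay_table(seed=0, ct_noise_sd=0.0, elisa_cv=0.0)
        ctrl = df[df.group == "control"]
        treated = df[df.group == "treated"]
        dct_ctrl = (ctrl.ct_target - ctrl.ct_reference).mean()
        ddct = (treated.ct_target - treated.ct_reference) - dct_ctrl
        assert np.allclose(2.0 ** (-ddct), truth["fold_changes"]["treated"])

    def test_true_fold_4_centres_ddct_at_minus2(self):
        df, _ = generate_assay_table(seed=1, group_fold_changes={"c": 1.0, "t": 4.0})
        dct = df.ct_target - df.ct_reference
        ddct = dct[df.group == "t"].mean() - dct[df.group == "c"].mean()
        assert ddct == pytest.approx(-2.0, abs=0.25)

    def test_seeded_reproducibility(self):
        df1, _ = generate_assay_table(seed=3)
        df2, _ = generate_assay_table(seed=3)
        assert df1.equals(df2)
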