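import itertools

import numpy as np
import pytest

from embgan.synthetic_embryo import (
    InvalidConfigError,
    MaskCorruption,
    NucleusState,
    SimulationConfig,
    ground_truth_track_graph,
    make_masks,
    place_nuclei,
    render_dic,
    render_fluorescence,
    simulate_lineage,
    simulate_positions,
    true_masks,
)


def clean_config(**kw):
    defaults = dict(
        rng_seed=1,
        noise_sd=0.0,
        illumination_gradient=0.0,
        cytoplasm_texture=0.0,
        embryo_boundary_contrast=0.0,
        mask_corruption=MaskCorruption(0.0, 0.0, 0.0),
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestLineage:
    def test_complete_binary_tree_combinatorics(self):
        tree = simulate_lineage(clean_config(n_generations=3, cycle_cv=0.0))
        assert len(tree) == 15
        assert len(tree.leaves()) == 8

    def test_deterministic_under_seed(self):
        cfg = clean_config(cycle_cv=0.3)
        a, b = simulate_lineage(cfg), simulate_lineage(cfg)
        assert set(a.cells) == set(b.cells)
        for n in a.cells:
            assert a.cells[n].birth == b.cells[n].birth
            assert a.cells[n].end == b.cells[n].end

    def test_zero_cv_generation_birth_times(self):
        cfg = clean_config(cycle_cv=0.0, mean_cycle_minutes=(20.0,), n_generations=3)
        tree = simulate_lineage(cfg)
        gen2 = [c for n, c in tree.cells.items() if len(n) == 4]
        assert len(gen2) == 4
        assert all(c.birth == pytest.approx(40.0) for c in gen2)

    def test_daughter_names_and_consistency(self):
        tree = simulate_lineage(clean_config())
        tree.validate()
        for name, cell in tree.cells.items():
            if cell.daughters:
                assert set(cell.daughters) == {name + "a", name + "p"}

    def test_invalid_generations_raises(self):
        with pytest.raises(InvalidConfigError):
            clean_config(n_generations=0)

    def test_invalid_rates_raise(self):
        with pytest.raises(InvalidConfigError):
            clean_config(mask_corruption=MaskCorruption(miss_rate=1.5))
        with pytest.raises(InvalidConfigError):
            clean_config(nucleus_radius_voxels=(4.0, -1.0))


class TestPlacement:
    def test_single_cell_inside_ellipsoid(self):
        cfg = clean_config()
        tree = simulate_lineage(cfg)
        states = place_nuclei(tree, cfg, 0)
        assert len(states) == 1
        center = (np.array(cfg.shape) - 1) / 2
        rel = (states[0].center - center) / np.array(cfg.embryo_half_axes)
        assert np.sum(rel**2) <= 1.0

    def test_pairwise_separation(self):
        cfg = clean_config()
        frames = simulate_positions(cfg)
        for t in list(frames)[:: max(len(frames) // 8, 1)]:
            phys = np.array([cfg.anisotropy, 1.0, 1.0])
            for a, b in itertools.combinations(frames[t], 2):
                d = np.linalg.norm((a.center - b.center) * phys)
                assert d >= 0.8 * (a.radius + b.radius) - 1e-9

    def test_continuity_before_first_division(self):
        cfg = clean_config(cycle_cv=0.0, mean_cycle_minutes=(20.0,))
        tree = simulate_lineage(cfg)
        a = place_nuclei(tree, cfg, 3)[0]
        b = place_nuclei(tree, cfg, 4)[0]
        assert np.linalg.norm(a.center - b.center) <= 0.5 * a.radius

    def test_out_of_range_timepoint_raises(self):
        cfg = clean_config()
        tree = simulate_lineage(cfg)
        with pytest.raises(ValueError):
            place_nuclei(tree, cfg, 100000)


class TestRenderDic:
    def test_empty_scene_is_constant_mid_gray(self):
        cfg = clean_config()
        vol = render_dic([], cfg)
        assert np.allclose(vol.data, 0.5)

    def test_single_nucleus_slice_mean_stays_mid_gray(self):
        """The shear derivative of a compact bump integrates to ~0 per slice."""
        cfg = clean_config()
        center = (np.array(cfg.shape) - 1) / 2
        nuc = NucleusState("AB", 0, center, 5.0)
        vol = render_dic([nuc], cfg)
        for z in range(cfg.shape[0]):
            assert vol.data[z].mean() == pytest.approx(0.5, abs=1e-3)
        # but the relief itself is present
        assert vol.data.max() > 0.51 and vol.data.min() < 0.49

    def test_flipping_shear_negates_relief(self):
        cfg = clean_config(dic_shear_direction=(1.0, 1.0))
        cfg_flip = clean_config(dic_shear_direction=(-1.0, -1.0))
        center = (np.array(cfg.shape) - 1) / 2
        nuc = NucleusState("AB", 0, center, 5.0)
        a = render_dic([nuc], cfg).data - 0.5
        b = render_dic([nuc], cfg_flip).data - 0.5
        assert np.allclose(a, -b, atol=1e-12)

    def test_mitotic_nucleus_renders_as_dumbbell(self):
        cfg = clean_config()
        center = (np.array(cfg.shape) - 1) / 2
        inter = render_dic([NucleusState("AB", 0, center, 5.0, "interphase")], cfg)
        mito = render_dic([NucleusState("AB", 0, center, 5.0, "mitosis")], cfg)
        assert not np.allclose(inter.data, mito.data)


class TestRenderFluorescence:
    def test_empty_scene_is_zero(self):
        cfg = clean_config(fluor_photons=0.0)
        assert np.all(render_fluorescence([], cfg).data == 0)

    def test_argmax_at_nucleus_center(self):
        cfg = clean_config(fluor_photons=0.0)
        center = (np.array(cfg.shape) - 1) / 2 + 0.3
        vol = render_fluorescence([NucleusState("AB", 0, center, 5.0)], cfg)
        peak = np.unravel_index(np.argmax(vol.data), vol.data.shape)
        assert np.all(np.abs(np.array(peak) - center) <= 1.0)

    def test_two_separated_nuclei_two_local_maxima(self):
        cfg = clean_config(fluor_photons=0.0)
        c = (np.array(cfg.shape) - 1) / 2
        nuclei = [
            NucleusState("ABa", 0, c + [0, 0, -12], 4.0),
            NucleusState("ABp", 0, c + [0, 0, 12], 4.0),
        ]
        vol = render_fluorescence(nuclei, cfg).data
        from scipy.ndimage import label, maximum_filter

        # symmetric half-integer centers tie across voxel plateaus, so count
        # connected plateaus of local maxima rather than raw voxels
        local_max = (vol == maximum_filter(vol, size=3)) & (vol > 0.5 * vol.max())
        assert label(local_max)[1] == 2


class TestMasks:
    def test_zero_corruption_exact_cross_sections(self):
        cfg = clean_config()
        c = (np.array(cfg.shape) - 1) / 2
        nuclei = [NucleusState("AB", 0, c, 5.0)]
        assert np.array_equal(
            make_masks(nuclei, cfg).data, true_masks(nuclei, cfg).data
        )
        # analytic oracle: voxel in mask iff inside the sphere (physical z)
        vol = true_masks(nuclei, cfg).data
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in cfg.shape], indexing="ij")
        d2 = ((zz - c[0]) * cfg.anisotropy) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        assert np.array_equal(vol.astype(bool), d2 <= 25.0 + 1e-9)

    def test_full_miss_rate_empty_mask(self):
        cfg = clean_config(mask_corruption=MaskCorruption(1.0, 0.0, 0.0))
        c = (np.array(cfg.shape) - 1) / 2
        assert make_masks([NucleusState("AB", 0, c, 5.0)], cfg).data.sum() == 0

    def test_miss_rate_within_binomial_ci(self):
        """100 well-separated nuclei at miss rate 0.3: the omitted count must
        fall inside the exact binomial 99% interval [18, 42]."""
        cfg = clean_config(
            volume_shape=(3, 100, 100),
            mask_corruption=MaskCorruption(0.3, 0.0, 0.0),
        )
        nuclei = [
            NucleusState(f"n{i}", 0, (1.0, 5.0 + 9.0 * (i // 10), 5.0 + 9.0 * (i % 10)), 2.0)
            for i in range(100)
        ]
        mask = make_masks(nuclei, cfg).data
        from scipy.ndimage import label

        n_kept = label(mask)[1]
        n_missed = 100 - n_kept
        assert 18 <= n_missed <= 42

    def test_deterministic_under_seed(self):
        cfg = clean_config(mask_corruption=MaskCorruption(0.3, 1.0, 0.1))
        c = (np.array(cfg.shape) - 1) / 2
        nuclei = [NucleusState("AB", 0, c, 5.0), NucleusState("ABa", 0, c + 8, 4.0)]
        assert np.array_equal(
            make_masks(nuclei, cfg).data, make_masks(nuclei, cfg).data
        )


class TestGroundTruthGraph:
    def test_successor_structure(self):
        cfg = clean_config(cycle_cv=0.0, mean_cycle_minutes=(10.0,), n_generations=2)
        graph = ground_truth_track_graph(cfg)
        last_t = graph.timepoints()[-1]
        for t in graph.timepoints():
            for det in graph.detections(t):
                n_succ = len(graph.successors(det.key))
                if t == last_t:
                    assert n_succ == 0
                else:
                    cell_divides_now = not any(
                        d.name == det.name for d in graph.detections(t + 1)
                    )
                    assert n_succ == (2 if cell_divides_now else 1)

    def test_division_frames_have_two_successors(self):
        cfg = clean_config(cycle_cv=0.0, mean_cycle_minutes=(10.0,), n_generations=2)
        graph = ground_truth_track_graph(cfg)
        divisions = [
            d.key
            for t in graph.timepoints()
            for d in graph.detections(t)
            if graph.is_division(d.key)
        ]
        assert len(divisions) == 3  # AB, ABa, ABp
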