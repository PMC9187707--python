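"""Exclusion filters, intensity reads, and the per-site dependent measure."""

import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

import boutonquant as bq
from boutonquant.errors import InvalidParameterError, MissingChannelError, OrientationError
from boutonquant.preprocess import dog_channel
from boutonquant.quantify import (
    BoutonMeasurement,
    depth_filter,
    edge_filter,
    lipofuscin_exclusion,
    measure_boutons,
    overlap_exclusion,
    summarize_site,
)
from boutonquant.segment import iterative_segment, masks_to_measurements_grid
from boutonquant.stacks import ImageStack, SiteMetadata
from boutonquant.synthetic import (
    StackSpec,
    StudyDesign,
    generate_stack,
    generate_study,
    match_centroids,
)

from conftest import quiet_spec


def _measurement(x_vox=50.0, y_vox=50.0, z_vox=5.0, mean=500.0, object_id=1):
    return BoutonMeasurement(
        object_id=object_id, site_id="s", bouton_type="vgat",
        mean_cb1r_adu=mean, volume_um3=0.1,
        centroid_um=(0, 0, 0), centroid_vox=(x_vox, y_vox, z_vox),
    )


def _stack_of(nz=41, surface="zmax"):
    grid = np.zeros((nz, 100, 100), dtype=np.uint16)
    return ImageStack(channels={"cb1r": grid}, pixel_um=0.1, zstep_um=0.25,
                      surface=surface)


class TestDepthFilter:
    def test_band_membership_after_shrinkage_correction(self, meta_full_depth):
        stack = _stack_of()  # 41 planes, surface at index 40
        # measured depth of plane k is (40 - k) * 0.25 um; factor = 1.0
        kept = _measurement(z_vox=28.0)       # 3.0 um -> kept
        shallow = _measurement(z_vox=33.0)    # 1.75 um (< 2) -> excluded
        deep = _measurement(z_vox=23.5)       # 4.125 um (> 4) -> excluded
        depth_filter([kept, shallow, deep], stack, meta_full_depth)
        assert kept.corrected_depth_um == pytest.approx(3.0)
        assert (kept.depth_excluded, shallow.depth_excluded, deep.depth_excluded) == \
            (False, True, True)

    def test_boundaries_are_inclusive(self, meta_full_depth):
        stack = _stack_of()
        at2 = _measurement(z_vox=32.0)   # exactly 2.0 um
        at4 = _measurement(z_vox=24.0)   # exactly 4.0 um
        depth_filter([at2, at4], stack, meta_full_depth)
        assert not at2.depth_excluded and not at4.depth_excluded

    def test_shrinkage_rescales_measured_depth(self):
        meta = SiteMetadata("s", "x", "monkey", "PFC", "L3", 20.0)  # factor 0.5
        stack = _stack_of()
        m = _measurement(z_vox=34.0)  # measured 1.5 um -> corrected 3.0 um
        depth_filter([m], stack, meta)
        assert m.corrected_depth_um == pytest.approx(3.0)
        assert not m.depth_excluded

    def test_unknown_orientation_refuses_to_guess(self, meta_full_depth):
        stack = _stack_of(surface=None)
        with pytest.raises(OrientationError):
            depth_filter([_measurement()], stack, meta_full_depth)


class TestEdgeFilter:
    def test_bands_at_512_pixels(self):
        # 0.02 * 512 = 10.24: centroids below 10.24 or above 500.76 excluded
        inside = _measurement(x_vox=256.0, y_vox=256.0)
        low = _measurement(x_vox=5.0, y_vox=256.0)
        high = _measurement(x_vox=501.0, y_vox=256.0)
        edge_filter([inside, low, high], nx=512, ny=512)
        assert (inside.edge_excluded, low.edge_excluded, high.edge_excluded) == \
            (False, True, True)

    def test_bands_at_100_pixels(self):
        at_band = _measurement(x_vox=2.0, y_vox=50.0)     # 2.0 not < 2.0 -> kept
        below = _measurement(x_vox=1.9, y_vox=50.0)
        above = _measurement(x_vox=97.5, y_vox=50.0)      # > 97.0 -> excluded
        edge_filter([at_band, below, above], nx=100, ny=100)
        assert (at_band.edge_excluded, below.edge_excluded, above.edge_excluded) == \
            (False, True, True)

    def test_y_dimension_also_filtered(self):
        m = _measurement(x_vox=50.0, y_vox=1.0)
        edge_filter([m], nx=100, ny=100)
        assert m.edge_excluded

    def test_zero_fraction_rejected(self):
        with pytest.raises(InvalidParameterError):
            edge_filter([_measurement()], nx=100, ny=100, fraction=0.0)


def _toy_masksets(default_geometry, shift_vox=0):
    """Two single-object mask sets; overlapping voxels iff shift is small."""
    a = np.zeros((8, 24, 24))
    a[3:6, 6:12, 6:12] = 500.0
    b = np.zeros((8, 24, 24))
    b[3:6, 6 + shift_vox:12 + shift_vox, 6 + shift_vox:12 + shift_vox] = 500.0
    ms_a = iterative_segment(a, default_geometry, "vglut1", t0=100.0)
    ms_b = iterative_segment(b, default_geometry, "vgat", t0=100.0)
    meas_a = measure_boutons(ms_a, a, "s")
    meas_b = measure_boutons(ms_b, b, "s")
    return ms_a, meas_a, ms_b, meas_b


class TestOverlapExclusion:
    def test_disjoint_sets_have_no_flags(self, default_geometry):
        ms_a, meas_a, ms_b, meas_b = _toy_masksets(default_geometry, shift_vox=10)
        overlap_exclusion(ms_a, meas_a, ms_b, meas_b)
        assert not any(m.overlap_excluded for m in meas_a + meas_b)

    def test_single_shared_voxel_flags_both_sides(self, default_geometry):
        ms_a, meas_a, ms_b, meas_b = _toy_masksets(default_geometry, shift_vox=5)
        shared = (ms_a.label_grid > 0) & (ms_b.label_grid > 0)
        assert shared.sum() >= 1
        overlap_exclusion(ms_a, meas_a, ms_b, meas_b)
        assert sum(m.overlap_excluded for m in meas_a + meas_b) == 2


class TestLipofuscin:
    def test_no_lipofuscin_signal_no_flags(self, default_geometry, fast_config,
                                           meta_full_depth):
        spec = quiet_spec(n_puncta={"vglut1": 2, "vgat": 2, "lipofuscin": 0})
        stack, _ = generate_stack(spec, 8)
        res = bq.process_site(stack, meta_full_depth, fast_config, t0=150.0)
        assert res.counts["lipofuscin_excluded"] == 0

    def test_missing_channel_errors_without_opt_out(self, default_geometry):
        with pytest.raises(MissingChannelError):
            lipofuscin_exclusion({}, None)

    def test_exclusion_brings_recovered_mean_closer_to_truth(self, fast_config,
                                                             meta_full_depth):
        """Lipofuscin bleeds into the receptor channel; excluding covered
        boutons must reduce the recovery error of the inhibitory mean."""
        spec = StackSpec(
            nx=96, ny=96, nz=24,
            n_puncta={"vglut1": 0, "vgat": 30, "lipofuscin": 8},
            decoy_fractions={"lipofuscin_overlap": 0.8},
            cb1r_mean_adu={"vglut1": 500.0, "vgat": 1000.0}, bouton_cv=0.0,
        )
        stack, truth = generate_stack(spec, 12)
        cfg_on = fast_config
        cfg_off = fast_config.model_copy(deep=True)
        cfg_off.quantify.lipofuscin_exclusion = False
        errs = {}
        for name, cfg in (("on", cfg_on), ("off", cfg_off)):
            res = bq.process_site(stack, meta_full_depth, cfg)
            surv = res.boutons[res.boutons.surviving & (res.boutons.bouton_type == "vgat")]
            errs[name] = abs(surv.mean_cb1r_adu.mean() - 1000.0)
        assert errs["on"] < errs["off"]


class TestMeasureBoutons:
    def test_constant_grid_reads_constant(self, default_geometry):
        ms_a, _, _, _ = _toy_masksets(default_geometry, shift_vox=10)
        const = np.full(ms_a.label_grid.shape, 500.0)
        masks_to_measurements_grid(ms_a, const)
        assert all(m.mean_cb1r_adu == pytest.approx(500.0)
                   for m in measure_boutons(ms_a, const))

    def test_two_voxel_object_mean(self, default_geometry):
        dog = np.zeros((4, 8, 8))
        dog[1, 3, 3:5] = 500.0
        gate_free = iterative_segment(dog, default_geometry, t0=100.0,
                                      vmin=0.0, vmax=None)
        grid = np.zeros((4, 8, 8))
        grid[1, 3, 3] = 100.0
        grid[1, 3, 4] = 300.0
        masks_to_measurements_grid(gate_free, grid)
        assert measure_boutons(gate_free, grid)[0].mean_cb1r_adu == pytest.approx(200.0)

    def test_reads_rank_correlate_with_planted_intensities(self, default_geometry):
        """Zero noise, no deconvolution: per-bouton reads preserve the planted
        intensity ordering (rank correlation >= 0.95)."""
        spec = quiet_spec(nx=128, ny=128, nz=20, bouton_cv=0.8,
                          n_puncta={"vglut1": 0, "vgat": 25, "lipofuscin": 0})
        stack, truth = generate_stack(spec, 31)
        dog = dog_channel(stack.channels["vgat"].astype(float))
        ms = iterative_segment(dog, default_geometry, "vgat", t0=150.0)
        grid = stack.channels["cb1r"].astype(float)
        masks_to_measurements_grid(ms, grid)
        meas = measure_boutons(ms, grid, "s")
        truth_c = np.array([p.centroid_um for p in truth if p.channel_role == "vgat"])
        planted = [p.cb1r_mean_adu for p in truth if p.channel_role == "vgat"]
        found_c = np.array([m.centroid_um for m in meas])
        # pair reads with planted values through centroid matching
        pairs = []
        for m in meas:
            d = np.linalg.norm(truth_c - np.array(m.centroid_um), axis=1)
            j = int(np.argmin(d))
            if d[j] < 0.5:
                pairs.append((m.mean_cb1r_adu, planted[j]))
        assert len(pairs) >= 20
        rho = spearmanr([a for a, _ in pairs], [b for _, b in pairs]).statistic
        assert rho >= 0.95


class TestSummarize:
    def test_site_mean_is_arithmetic_mean_of_survivors(self, meta_full_depth):
        meas = [_measurement(mean=m, object_id=i) for i, m in enumerate((400, 500, 600))]
        rows = summarize_site(meas, meta_full_depth)
        assert len(rows) == 1
        assert rows.iloc[0].mean_cb1r_adu == pytest.approx(500.0)
        assert rows.iloc[0].n_boutons == 3

    def test_no_row_when_all_excluded(self, meta_full_depth, caplog):
        m = _measurement()
        m.depth_excluded = True
        with caplog.at_level("WARNING"):
            rows = summarize_site([m], meta_full_depth)
        assert rows.empty
        assert "no surviving" in caplog.text


def test_filter_order_independence(default_geometry, meta_full_depth, rng):
    """The four flags are independent predicates: any application order of
    depth/edge filters leaves the same surviving set."""
    stack = _stack_of()
    base = [_measurement(x_vox=rng.uniform(0, 99), y_vox=rng.uniform(0, 99),
                         z_vox=rng.uniform(0, 40), object_id=i) for i in range(40)]

    def apply_in_order(order):
        ms = [BoutonMeasurement(**{**m.__dict__}) for m in base]
        for step in order:
            if step == "depth":
                depth_filter(ms, stack, meta_full_depth)
            else:
                edge_filter(ms, nx=100, ny=100)
        return [m.surviving for m in ms]

    results = {tuple(apply_in_order(order)) for order in
               itertools.permutations(["depth", "edge"])}
    assert len(results) == 1


def test_conservation_identity(filter_demo, fast_config):
    stack, meta, expected, _ = filter_demo
    res = bq.process_site(stack, meta, fast_config, t0=expected["t0"])
    c = res.counts
    assert c["n_total"] == c["n_surviving"] + c["n_flagged"]
    assert c["n_flagged"] <= sum(c[f] for f in
                                 ("edge_excluded", "depth_excluded",
                                  "overlap_excluded", "lipofuscin_excluded"))


def test_study_with_no_variability_recovers_cell_means(fast_config):
    """SDs = 0 and no noise: every emitted site mean lies within 5% of the
    planted cell mean."""
    from boutonquant.synthetic import NoiseModel

    template = StackSpec(
        nx=80, ny=80, n_puncta={"vglut1": 8, "vgat": 8, "lipofuscin": 0},
        noise=NoiseModel(0.0, 0.0), bouton_cv=0.0, min_separation_z_um=2.4,
    )
    design = StudyDesign(between_subject_sd=0.0, between_site_sd=0.0,
                         bouton_cv=0.0, regions=("PFC", "A1"),
                         stack_template=template)
    stacks, truth = generate_study(design, 2)
    _, sites, _ = bq.process_study(stacks, fast_config)
    merged = sites.merge(truth.site_table, on=["site_id", "bouton_type"])
    rel = (merged.mean_cb1r_adu / merged.expected_cb1r_adu - 1).abs()
    assert (rel < 0.05).all(), rel.describe()


def test_overlap_decoys_are_flagged_in_generated_stacks(fast_config, meta_full_depth):
    """Planted coincident vGlut1/vGAT pairs are overlap-flagged when both
    members are detected."""
    spec = StackSpec(nx=96, ny=96, nz=24,
                     n_puncta={"vglut1": 15, "vgat": 15, "lipofuscin": 0},
                     decoy_fractions={"overlap": 0.2})
    stack, truth = generate_stack(spec, 17)
    res = bq.process_site(stack, meta_full_depth, fast_config)
    b = res.boutons
    planted = np.array([p.centroid_um for p in truth if p.decoy == "overlap"])
    flagged = b[b.overlap_excluded][["centroid_x_um", "centroid_y_um",
                                     "centroid_z_um"]].to_numpy()
    tp, _, _ = match_centroids(planted, flagged)
    # every detected decoy is flagged (both channels), no spurious flags
    assert len(flagged) >= tp >= len(planted) // 2
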