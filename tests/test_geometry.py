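import math

import numpy as np
import pytest

from aqpflux.geometry import (FilmGeometry, GeometryError, OcclusionMode,
                              OcclusionSpec, PackingDefinition,
                              PackingFraction, RegionLabel,
                              areal_pore_fraction, attainable_disk_coverages,
                              build_layered_domain, discrete_pore_fraction,
                              disk_for_pore_coverage, realize_packing,
                              realized_pore_occlusion, voxelize)


class TestArealPoreFraction:
    def test_study_coverage(self):
        geom = FilmGeometry.from_coverage(0.28, pore_diameter=1.0)
        assert areal_pore_fraction(geom) == pytest.approx(0.28, abs=1e-12)
        # the default geometry realizes the same spacing
        assert FilmGeometry().lattice_spacing == pytest.approx(
            math.sqrt(math.pi * 0.25 / 0.28))

    def test_hand_arithmetic(self):
        geom = FilmGeometry(pore_diameter=1.0, lattice_spacing=2.0)
        assert areal_pore_fraction(geom) == pytest.approx(math.pi / 16)

    def test_vanishing_pores(self):
        geom = FilmGeometry(pore_diameter=1e-6, lattice_spacing=2.0)
        assert areal_pore_fraction(geom) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("kwargs,message", [
        (dict(pore_diameter=-1.0), "pore_diameter"),
        (dict(film_thickness=0.0), "film_thickness"),
        (dict(pore_diameter=2.0, lattice_spacing=1.5), "lattice_spacing"),
        (dict(n_pores_y=0), "n_pores_y"),
    ])
    def test_invalid_geometry_names_invariant(self, kwargs, message):
        with pytest.raises(GeometryError, match=message):
            FilmGeometry(**kwargs)


class TestVoxelize:
    def test_reservoirs_open_and_labelled(self, study_geometry):
        dom = voxelize(study_geometry, None, 0.25)
        dom.validate()
        lo, hi = dom.film_layers
        assert np.all(dom.labels[:lo] == RegionLabel.LEFT_RESERVOIR)
        assert np.all(dom.labels[hi:] == RegionLabel.RIGHT_RESERVOIR)
        film = dom.labels[lo:hi]
        assert set(np.unique(film)) <= {int(RegionLabel.FILM_PORE),
                                        int(RegionLabel.FILM_SOLID)}

    def test_no_occlusion_without_capping(self, study_geometry):
        dom = voxelize(study_geometry, OcclusionSpec.none(), 0.25)
        assert not np.any(dom.labels == RegionLabel.OCCLUSION)

    def test_full_capping_seals_every_pore(self, study_geometry):
        occ = OcclusionSpec(mode=OcclusionMode.PORE_CAP, cap_fraction=1.0)
        dom = voxelize(study_geometry, occ, 0.25)
        lo, _ = dom.film_layers
        feed_face = dom.labels[lo]
        assert not np.any(feed_face == RegionLabel.FILM_PORE)
        assert np.any(feed_face == RegionLabel.OCCLUSION)

    def test_deterministic_bit_identical(self, study_geometry):
        occ = OcclusionSpec(mode=OcclusionMode.PORE_CAP, cap_fraction=0.64,
                            placement_seed=7)
        a = voxelize(study_geometry, occ, 0.25)
        b = voxelize(study_geometry, occ, 0.25)
        assert np.array_equal(a.labels, b.labels)

    def test_capping_16_of_25(self, study_geometry):
        occ = OcclusionSpec(mode=OcclusionMode.PORE_CAP, cap_fraction=0.64,
                            placement_seed=1)
        dom0 = voxelize(study_geometry, None, 0.25)
        dom = voxelize(study_geometry, occ, 0.25)
        assert realized_pore_occlusion(dom, dom0) == pytest.approx(16 / 25)

    def test_resolution_floor(self, study_geometry):
        with pytest.raises(GeometryError, match="too coarse"):
            voxelize(study_geometry, None, 0.5)

    def test_oversize_disk_rejected(self, study_geometry):
        occ = OcclusionSpec(mode=OcclusionMode.AGGREGATE_DISK,
                            disk_radius=100.0)
        with pytest.raises(GeometryError, match="exceeds"):
            voxelize(study_geometry, occ, 0.25)

    def test_monomer_patch_occludes_every_pore(self, study_geometry):
        occ = OcclusionSpec(mode=OcclusionMode.MONOMER_PATCH, patch_side=0.4)
        dom = voxelize(study_geometry, occ, 0.25)
        lo, _ = dom.film_layers
        occluded = dom.labels[lo] == RegionLabel.OCCLUSION
        # one patch footprint per pore
        assert occluded.sum() > 0
        assert occluded.sum() % study_geometry.n_pores == 0


class TestDiscretePoreFraction:
    def test_limits(self, study_geometry):
        dom = voxelize(study_geometry, None, 0.25)
        assert 0.0 < discrete_pore_fraction(dom) < 1.0

    def test_matches_target_at_fine_resolution(self):
        geom = FilmGeometry.from_coverage(0.28, n_pores_y=1, n_pores_z=1,
                                          film_thickness=2.0,
                                          reservoir_depth=0.5)
        dom = voxelize(geom, None, 0.1)
        assert discrete_pore_fraction(dom) == pytest.approx(0.28, abs=0.02)

    def test_converges_to_areal_fraction(self):
        geom = FilmGeometry(film_thickness=2.0, reservoir_depth=0.5,
                            n_pores_y=1, n_pores_z=1)
        target = areal_pore_fraction(geom)
        spacing = geom.lattice_spacing
        gaps = []
        for m in (12, 24, 48):
            dom = voxelize(geom, None, spacing / m)
            gaps.append(abs(discrete_pore_fraction(dom) - target))
        assert gaps[1] <= gaps[0] / 2
        assert gaps[2] <= gaps[1] / 2


class TestRealizePacking:
    def test_zero_target_is_empty(self, study_geometry):
        occ = realize_packing(study_geometry, PackingFraction(0.0), seed=1)
        dom = voxelize(study_geometry, occ, 0.25)
        assert not np.any(dom.labels == RegionLabel.OCCLUSION)

    def test_full_capping(self, study_geometry):
        occ = realize_packing(study_geometry, PackingFraction(1.0), seed=1)
        assert occ.cap_fraction == 1.0

    def test_different_seeds_different_subsets(self, study_geometry):
        occ1 = realize_packing(study_geometry, PackingFraction(0.64), seed=1)
        occ2 = realize_packing(study_geometry, PackingFraction(0.64), seed=2)
        a = voxelize(study_geometry, occ1, 0.25)
        b = voxelize(study_geometry, occ2, 0.25)
        assert occ1.cap_fraction == occ2.cap_fraction == 16 / 25
        assert not np.array_equal(a.labels, b.labels)

    def test_realized_fraction_within_quantum(self, study_geometry):
        rng = np.random.default_rng(0)
        n = study_geometry.n_pores
        dom0 = voxelize(study_geometry, None, 0.25)
        for _ in range(100):
            target = float(rng.uniform())
            seed = int(rng.integers(1 << 31))
            occ = realize_packing(study_geometry, PackingFraction(target),
                                  seed)
            assert abs(occ.cap_fraction - target) <= 0.5 / n + 1e-12
        # spot-check a rasterized realization
        occ = realize_packing(study_geometry, PackingFraction(0.48), seed=3)
        dom = voxelize(study_geometry, occ, 0.25)
        assert realized_pore_occlusion(dom, dom0) == pytest.approx(12 / 25)

    def test_surface_definition_solves_disk_radius(self, study_geometry):
        target = PackingFraction(
            0.3, PackingDefinition.FRACTION_OF_FILM_SURFACE_OCCLUDED)
        occ = realize_packing(study_geometry, target, seed=0)
        assert occ.mode is OcclusionMode.AGGREGATE_DISK
        Ly, Lz = study_geometry.lateral_extent
        # below the face half-width the disk is uncut: area check is exact
        assert math.pi * occ.disk_radius ** 2 / (Ly * Lz) == \
            pytest.approx(0.3, rel=1e-6)

    def test_disk_for_pore_coverage_realizes_target(self, study_geometry):
        dom0 = voxelize(study_geometry, None, 0.25)
        occ = disk_for_pore_coverage(study_geometry, 0.36, seed=0)
        dom = voxelize(study_geometry, occ, 0.25)
        assert realized_pore_occlusion(dom, dom0) == pytest.approx(0.36,
                                                                   abs=0.02)

    def test_attainable_ring_coverages(self, study_geometry):
        fracs, radii = attainable_disk_coverages(study_geometry)
        assert fracs[0] == 0.0 and fracs[-1] == 1.0
        assert np.all(np.diff(fracs) > 0) and np.all(np.diff(radii) > 0)
        # 5x5 lattice rings: 1, +4, +4, +4, +8, +4 pores
        assert list(np.round(fracs, 9)) == [0.0, 0.04, 0.2, 0.36, 0.52,
                                            0.84, 1.0]


def test_layered_domain_masks_are_nested():
    dom = build_layered_domain([(1.0, 1.0), (1.0, 0.5), (1.0, 0.25)],
                               lateral_n=8, h=0.25)
    lo, hi = dom.film_layers
    layers = dom.labels[lo:hi]
    open_counts = (layers == RegionLabel.FILM_PORE).sum(axis=(1, 2))
    assert open_counts.max() == 64 and open_counts.min() == 16
    # nested: wherever a later layer is open, every earlier layer is open
    o = layers == RegionLabel.FILM_PORE
    assert np.all(o[0] | ~o[-1])
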