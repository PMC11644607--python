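"""Trait extraction: height, stem caliper, OBB, triangulation, areas."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from phenopot3d import (PointCloud, RunConfig, extract_traits, leaf_area,
                        leaf_length_width, leaf_obb, plant_height,
                        stem_thickness, triangle_area_heron, triangulate_leaf)
from phenopot3d.cloud import LEAF, STEM, LabeledCloud


def ellipse_sample(rng, a=0.06, b=0.02, n=6000, sigma=0.0):
    r = np.sqrt(rng.uniform(0, 1, n))
    t = rng.uniform(0, 2 * np.pi, n)
    pts = np.column_stack([a * r * np.cos(t), b * r * np.sin(t), np.zeros(n)])
    if sigma:
        pts += rng.normal(0, sigma, pts.shape)
    return pts


def test_plant_height_examples():
    assert plant_height(PointCloud([[0, 0, 0], [1, 1, 0.3]])) == pytest.approx(0.3)
    assert plant_height(PointCloud([[0, 0, 0.1], [5, 5, 0.1]])) == 0.0
    with pytest.raises(ValueError):
        plant_height(PointCloud(np.empty((0, 3))))


def test_plant_height_matches_generator_truth_noise_free():
    from dataclasses import replace
    from phenopot3d.synthetic import generate_plant, straight_3leaf_spec
    spec = replace(straight_3leaf_spec(7), noise_sigma=0.0, outlier_fraction=0.0)
    cloud, truth = generate_plant(spec)
    plant = cloud.points[truth.organ != 2]  # exclude the pot
    measured = plant[:, 2].max() - plant[:, 2].min()
    assert measured == pytest.approx(truth.plant_height, abs=1e-3)


def test_stem_thickness_dense_cylinder(rng):
    n = 4000
    theta = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(0, 0.12, n)
    pts = np.column_stack([0.005 * np.cos(theta), 0.005 * np.sin(theta), z])
    t = stem_thickness(pts, pot_surface_z=0.0, offset=0.05, slab=0.01)
    assert t == pytest.approx(0.010, rel=0.05)


def test_stem_thickness_two_opposite_points_exact():
    pts = np.array([[0.004, 0, 0.05], [-0.004, 0, 0.05]])
    t = stem_thickness(pts, pot_surface_z=0.0, offset=0.05, slab=0.01)
    assert t == pytest.approx(0.008, abs=1e-12)


def test_stem_thickness_empty_slab_raises():
    pts = np.array([[0, 0, 0.0], [0, 0, 0.001]])
    with pytest.raises(ValueError, match="slab"):
        stem_thickness(pts, pot_surface_z=0.0, offset=0.05, slab=0.001)


def test_leaf_obb_extents_of_flat_rectangle():
    x, y = np.meshgrid(np.linspace(-0.05, 0.05, 60), np.linspace(-0.02, 0.02, 25))
    pts = np.column_stack([x.ravel(), y.ravel(), np.zeros(x.size)])
    box = leaf_obb(pts)
    assert box.extents[0] == pytest.approx(0.05, rel=1e-9)
    assert box.extents[1] == pytest.approx(0.02, rel=1e-9)
    assert box.extents[2] == pytest.approx(0.0, abs=1e-9)


def test_leaf_obb_rotation_invariant_extents(rng):
    pts = np.column_stack([rng.uniform(-0.05, 0.05, 2000),
                           rng.uniform(-0.02, 0.02, 2000), np.zeros(2000)])
    box = leaf_obb(pts)
    rot = Rotation.from_euler("xyz", rng.uniform(0, 360, 3), degrees=True).as_matrix()
    rotated = leaf_obb(pts @ rot.T + rng.normal(size=3))
    assert np.allclose(box.extents, rotated.extents, atol=1e-9)


def test_leaf_obb_sphere_symmetry(rng):
    v = rng.normal(size=(5000, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    box = leaf_obb(v)
    assert np.allclose(box.extents, 1.0, atol=0.02)


def test_leaf_obb_degenerate_raises():
    line = np.column_stack([np.linspace(0, 1, 30), np.zeros(30), np.zeros(30)])
    with pytest.raises(ValueError, match="rank"):
        leaf_obb(line)


def test_leaf_length_width_flat_ellipse(rng):
    pts = ellipse_sample(rng)
    length, width = leaf_length_width(pts)
    assert length == pytest.approx(0.12, rel=0.02)
    assert width == pytest.approx(0.04, rel=0.02)


def test_leaf_length_two_points():
    length, width = leaf_length_width(np.array([[0, 0, 0], [0.07, 0, 0]]))
    assert length == pytest.approx(0.07)


def test_leaf_length_matches_brute_force_max_pair(rng):
    pts = rng.normal(size=(500, 3))
    length, _ = leaf_length_width(pts)
    d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
    assert length == pytest.approx(d.max(), abs=1e-12)


def test_triangulate_unit_square_two_triangles():
    square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
    mesh = triangulate_leaf(square, max_edge=10.0)
    assert len(mesh.triangles) == 2
    assert leaf_area(mesh) == pytest.approx(1.0)


def test_triangulate_max_edge_too_small_raises():
    square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
    with pytest.raises(ValueError, match="max_edge"):
        triangulate_leaf(square, max_edge=0.1)


def test_disc_area_recovered(rng):
    r = np.sqrt(rng.uniform(0, 1, 8000)) * 0.05
    t = rng.uniform(0, 2 * np.pi, 8000)
    pts = np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros(8000)])
    mesh = triangulate_leaf(pts, max_edge=0.01)
    assert leaf_area(mesh) == pytest.approx(np.pi * 0.05 ** 2, rel=0.02)


def test_heron_examples_and_degenerate():
    assert triangle_area_heron([0, 0, 0], [1, 0, 0], [0, 1, 0]) == pytest.approx(0.5)
    assert triangle_area_heron([0, 0, 0], [1, 1, 1], [2, 2, 2]) == pytest.approx(0.0)


def test_heron_matches_cross_product_on_random_triangles(rng):
    a, b, c = rng.normal(size=(3, 10_000, 3))
    heron = triangle_area_heron(a, b, c)
    cross = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    assert np.abs(heron - cross).max() < 1e-10


def test_leaf_area_monotone_under_triangle_addition(rng):
    pts = ellipse_sample(rng, n=2000)
    mesh = triangulate_leaf(pts, max_edge=0.02)
    total = leaf_area(mesh)
    a, b, c = (mesh.vertices[mesh.triangles[:, i]] for i in range(3))
    areas = triangle_area_heron(a, b, c)
    assert total >= areas.max()
    assert total == pytest.approx(np.sum(areas))


def test_flat_ellipse_area_within_tolerance(rng):
    pts = ellipse_sample(rng, a=0.06, b=0.02, n=int(2e6 * np.pi * 0.06 * 0.02),
                         sigma=0.0005)
    from phenopot3d.preprocess import voxel_denoise
    den = voxel_denoise(PointCloud(pts), 0.003, min_count=2).points
    from phenopot3d.clustering import median_nn_distance
    mesh = triangulate_leaf(den, max_edge=4 * median_nn_distance(den))
    assert leaf_area(mesh) == pytest.approx(np.pi * 0.06 * 0.02, rel=0.05)


def test_traits_rigid_motion_invariant_and_scale_equivariant(rng):
    pts = ellipse_sample(rng, n=3000)
    length, width = leaf_length_width(pts)
    area = leaf_area(triangulate_leaf(pts, max_edge=0.02))
    rot = Rotation.from_euler("zyx", [33, 12, 71], degrees=True).as_matrix()
    moved = pts @ rot.T + [0.3, -0.2, 1.0]
    l2, w2 = leaf_length_width(moved)
    a2 = leaf_area(triangulate_leaf(moved, max_edge=0.02))
    assert l2 == pytest.approx(length, rel=1e-6)
    assert w2 == pytest.approx(width, rel=1e-6)
    assert a2 == pytest.approx(area, rel=1e-4)
    k = 2.5
    l3, w3 = leaf_length_width(pts * k)
    a3 = leaf_area(triangulate_leaf(pts * k, max_edge=0.02 * k))
    assert l3 == pytest.approx(k * length, rel=1e-9)
    assert w3 == pytest.approx(k * width, rel=1e-9)
    assert a3 == pytest.approx(k ** 2 * area, rel=1e-9)


def test_extract_traits_stemless_and_empty_instances(rng):
    pts = ellipse_sample(rng, n=1000) + [0, 0, 0.1]
    labeled = LabeledCloud(PointCloud(pts), np.full(1000, LEAF))
    report = extract_traits(labeled, None, RunConfig())
    assert report.stem_thickness is None
    assert report.plant_height > 0
    assert report.leaves == []


def test_full_trait_recovery_on_synthetic(straight_result):
    result, truth = straight_result
    report = result.traits
    assert report.plant_height == pytest.approx(truth.plant_height, rel=0.02)
    assert report.stem_thickness == pytest.approx(truth.stem_diameter, rel=0.07)
    from phenopot3d.evaluation import instance_jaccard
    tl = truth.leaf_id[result.input_mask]
    _, matching, _ = instance_jaccard(result.labeled.leaf_id, tl)
    for t_leaf in truth.leaf_traits:
        measured = next(l for l in report.leaves
                        if l.leaf_id == matching[t_leaf["leaf_id"]])
        assert measured.length == pytest.approx(t_leaf["length"], rel=0.05)
        assert measured.width == pytest.approx(t_leaf["width"], rel=0.05)
        assert measured.area == pytest.approx(t_leaf["area"], rel=0.08)
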