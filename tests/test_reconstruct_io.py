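"""Annotation parsing, coordinate transforms, and patch extraction."""

import json

import numpy as np
import pytest

from synemclass.reconstruct_io import (
    Patch,
    SectionTransform,
    SynapseAnnotation,
    annotation_centroid,
    extract_patch,
    identity_transform,
    map_to_image,
    map_to_section,
    parse_annotations,
)


def heptagon(cx, cy, r=5.0):
    ang = np.linspace(0, 2 * np.pi, 7, endpoint=False)
    return np.stack([cx + r * np.cos(ang), cy + r * np.sin(ang)], axis=1)


def write_manifest(path, annotations, transforms=None):
    data = {"pixel_size": 3.85, "annotations": annotations}
    if transforms:
        data["transforms"] = transforms
    path.write_text(json.dumps(data))
    return path


class TestParseAnnotations:
    def test_empty_manifest_gives_empty_list(self, tmp_path):
        annos, _ = parse_annotations(write_manifest(tmp_path / "m.json", []))
        assert annos == []

    def test_record_count_matches_manifest(self, tmp_path):
        records = [
            {"name": f"pre{i}-post{i % 3}", "z": i,
             "points": heptagon(10 * i, 5).tolist()}
            for i in range(12)
        ]
        annos, _ = parse_annotations(write_manifest(tmp_path / "m.json", records))
        assert len(annos) == 12
        assert annos[4].pre_cell_id == "pre4"
        assert annos[4].post_cell_id == "post1"

    def test_wrong_point_count_is_an_error(self, tmp_path):
        rec = [{"name": "a-b", "z": 0, "points": [[0, 0]] * 6}]
        with pytest.raises(ValueError, match="expected 7 points"):
            parse_annotations(write_manifest(tmp_path / "m.json", rec))

    def test_unparseable_name_is_an_error_not_a_skip(self, tmp_path):
        rec = [{"name": "no_separator_here!", "z": 0,
                "points": heptagon(0, 0).tolist()}]
        with pytest.raises(ValueError, match="cell IDs"):
            parse_annotations(write_manifest(tmp_path / "m.json", rec))

    def test_malformed_record_names_the_record(self, tmp_path):
        rec = [{"name": "a-b", "z": 0, "points": heptagon(0, 0).tolist()},
               {"name": "c-d"}]
        with pytest.raises(ValueError, match="#1"):
            parse_annotations(write_manifest(tmp_path / "m.json", rec))

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_annotations(tmp_path / "absent.json")

    def test_xml_dialect_same_contract(self, tmp_path):
        pts = ", ".join(f"{x} {y}" for x, y in heptagon(3, 4))
        xml = f"""<Series pixel_size="3.85">
          <Section index="7">
            <Transform role="trace" translation="1 2" rotation="0.1" scale="1.5"/>
            <Contour name="cellA-cellB" points="{pts}"/>
          </Section>
        </Series>"""
        path = tmp_path / "series.xml"
        path.write_text(xml)
        annos, transforms = parse_annotations(path)
        assert len(annos) == 1
        assert annos[0].z_index == 7
        assert annos[0].pre_cell_id == "cellA"
        assert transforms[7]["trace"].scale == 1.5


class TestTransforms:
    def test_identity_maps_point_to_itself(self):
        assert np.allclose(map_to_image((10.0, 20.0)), (10.0, 20.0))

    def test_pure_translation_forward_after_identity_inverse(self):
        t_img = SectionTransform(translation=(5.0, -3.0))
        assert np.allclose(map_to_image((0.0, 0.0), identity_transform(), t_img),
                           (5.0, -3.0))

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            SectionTransform(scale=0.0)

    def test_affine_polynomial_round_trip(self, rng):
        """Section -> image -> section round-trips to < 1e-6 px."""
        worst = 0.0
        for _ in range(100):
            t_trace = SectionTransform(
                translation=tuple(rng.uniform(-50, 50, 2)),
                rotation=rng.uniform(-np.pi, np.pi),
                scale=rng.uniform(0.5, 2.0),
                deformation_coeffs=(tuple(rng.uniform(-1e-6, 1e-6, 4)),
                                    tuple(rng.uniform(-1e-6, 1e-6, 4))),
            )
            t_img = SectionTransform(
                translation=tuple(rng.uniform(-50, 50, 2)),
                rotation=rng.uniform(-np.pi, np.pi),
                scale=rng.uniform(0.5, 2.0),
            )
            p = rng.uniform(-100, 100, (10, 2))
            q = map_to_image(p, t_trace, t_img)
            back = map_to_section(q, t_trace, t_img)
            worst = max(worst, float(np.max(np.abs(back - p))))
        assert worst < 1e-6

    def test_forward_inverse_identity_single_transform(self, rng):
        t = SectionTransform(translation=(3.0, 4.0), rotation=0.7, scale=1.3,
                             deformation_coeffs=((1e-4, -2e-4), (2e-4, 1e-4)))
        p = rng.uniform(-100, 100, (200, 2))
        assert np.max(np.abs(t.forward(t.inverse(p)) - p)) < 1e-6


class TestCentroid:
    def test_identical_points_centroid(self):
        a = SynapseAnnotation("a-b", 0, np.full((7, 2), 3.0), "a", "b")
        assert np.allclose(annotation_centroid(a), (3.0, 3.0))

    def test_heptagon_centroid_is_center(self):
        a = SynapseAnnotation("a-b", 0, heptagon(100, 100), "a", "b")
        assert np.allclose(annotation_centroid(a), (100.0, 100.0), atol=1e-9)

    def test_arbitrary_points_match_manual_mean(self, rng):
        pts = rng.uniform(0, 50, (7, 2))
        a = SynapseAnnotation("a-b", 0, pts, "a", "b")
        manual = np.array([sum(p[0] for p in pts) / 7, sum(p[1] for p in pts) / 7])
        assert np.allclose(annotation_centroid(a), manual)


class TestExtractPatch:
    def test_interior_crop_rows_and_cols(self):
        img = np.arange(1000 * 1000, dtype=float).reshape(1000, 1000)
        p = extract_patch(img, (500, 500), 500)
        assert p.image.shape == (500, 500)
        np.testing.assert_array_equal(p.image, img[250:750, 250:750])

    def test_border_crop_matches_manual_reflect_pad(self):
        rng = np.random.default_rng(0)
        img = rng.random((600, 600))
        p = extract_patch(img, (10, 10), 500)
        manual = np.pad(img, 250, mode="reflect")[10:510, 10:510]
        assert p.image.shape == (500, 500)
        np.testing.assert_array_equal(p.image, manual)

    def test_center_outside_image_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            extract_patch(np.zeros((100, 100)), (150, 50), 50)

    def test_size_exceeding_image_is_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            extract_patch(np.zeros((100, 100)), (50, 50), 128)

    def test_extraction_is_deterministic(self):
        img = np.random.default_rng(1).random((300, 300))
        a = extract_patch(img, (40.2, 260.7), 128)
        b = extract_patch(img, (40.2, 260.7), 128)
        np.testing.assert_array_equal(a.image, b.image)
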