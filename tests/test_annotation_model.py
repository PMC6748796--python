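"""Domain types and file-format round trips."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdseg import (
    ROI,
    AnnotationSet,
    AnnotationValidationError,
    ClassTaxonomy,
    LabelMask,
    Participant,
    PolygonAnnotation,
    TaxonomyEntry,
    TaxonomyError,
    read_annotation_document,
    read_label_mask,
    read_taxonomy,
    write_annotation_document,
    write_label_mask,
    write_taxonomy,
)

from conftest import random_mask


def make_roi(**kw) -> ROI:
    base = dict(roi_id="r1", slide_id="s1", institute_id="i1", origin=(0, 0),
                width=8, height=8, set_membership="evaluation")
    base.update(kw)
    return ROI(**base)


class TestTaxonomy:
    def test_duplicate_names_rejected_case_insensitively(self):
        e = TaxonomyEntry
        with pytest.raises(TaxonomyError, match="duplicate class names"):
            ClassTaxonomy((
                e("Tumor", "predominant", (1, 2, 3), 1),
                e("stroma", "predominant", (4, 5, 6), 2, is_default=True),
                e("tumor", "challenging", (7, 8, 9), 3),
            ))

    def test_duplicate_label_codes_rejected(self):
        e = TaxonomyEntry
        with pytest.raises(TaxonomyError, match="duplicate label codes"):
            ClassTaxonomy((
                e("tumor", "predominant", (1, 2, 3), 1),
                e("stroma", "predominant", (4, 5, 6), 1, is_default=True),
            ))

    @pytest.mark.parametrize("code", [0, -3])
    def test_label_code_zero_reserved(self, code):
        with pytest.raises(TaxonomyError, match="positive integer"):
            TaxonomyEntry("tumor", "predominant", (1, 2, 3), code)

    def test_exactly_one_default_class_of_predominant_tier(self):
        e = TaxonomyEntry
        with pytest.raises(TaxonomyError, match="exactly one default"):
            ClassTaxonomy((e("tumor", "predominant", (1, 2, 3), 1),))
        with pytest.raises(TaxonomyError, match="predominant"):
            ClassTaxonomy((
                e("tumor", "predominant", (1, 2, 3), 1),
                e("fat", "non_predominant", (2, 3, 4), 2, is_default=True),
            ))

    def test_default_taxonomy_lookups(self, taxonomy):
        assert taxonomy.default_class.class_name == "stroma"
        assert taxonomy.code("tumor") == 1
        assert taxonomy.name_of(1) == "tumor"
        assert "TUMOR" in taxonomy
        assert "vessel" not in taxonomy
        assert "exclude" not in taxonomy.analysis_classes()

    @settings(max_examples=50, derandomize=True)
    @given(codes=st.lists(st.integers(1, 50), min_size=2, max_size=8))
    def test_random_code_lists_accepted_iff_unique(self, codes):
        e = TaxonomyEntry
        entries = [e(f"c{i}", "predominant", (0, 0, 0), c, is_default=(i == 0))
                   for i, c in enumerate(codes)]
        if len(set(codes)) == len(codes):
            ClassTaxonomy(tuple(entries))
        else:
            with pytest.raises(TaxonomyError):
                ClassTaxonomy(tuple(entries))


class TestDomainInvariants:
    def test_polygon_needs_three_vertices(self):
        with pytest.raises(AnnotationValidationError, match=">= 3 vertices"):
            PolygonAnnotation("tumor", ((0, 0), (1, 1)), "p1")

    def test_participant_tier_validated(self):
        with pytest.raises(AnnotationValidationError):
            Participant("p1", "boss")

    def test_roi_dimensions_validated(self):
        with pytest.raises(AnnotationValidationError):
            make_roi(width=0)

    def test_annotation_set_rejects_foreign_polygons(self):
        poly = PolygonAnnotation("tumor", ((0, 0), (1, 0), (1, 1)), "someone_else")
        with pytest.raises(AnnotationValidationError, match="does not match"):
            AnnotationSet(make_roi(), Participant("p1", "NP"), (poly,))

    def test_label_mask_rejects_unknown_codes(self, taxonomy):
        with pytest.raises(TaxonomyError, match="not in taxonomy"):
            LabelMask(np.full((4, 4), 99), taxonomy)

    def test_label_mask_channels_partition_nonzero_pixels(self, taxonomy):
        m = random_mask(np.random.default_rng(0), taxonomy)
        stacked = np.stack([m.channel(c) for c in taxonomy.class_names])
        assert (stacked.sum(axis=0) == (m.labels != 0)).all()


class TestAnnotationDocuments:
    def _random_set(self, rng) -> AnnotationSet:
        part = Participant("p7", "NP")
        polys = tuple(
            PolygonAnnotation(
                class_name=rng.choice(["tumor", "necrosis", "stroma"]),
                vertices=tuple(map(tuple, rng.uniform(-5, 20, size=(rng.integers(3, 9), 2)))),
                participant_id="p7",
                is_correction=bool(rng.random() < 0.3),
                draw_order=i,
            )
            for i in range(rng.integers(0, 6))
        )
        return AnnotationSet(make_roi(), part, polys)

    def test_document_order_defines_draw_order(self, tmp_path, taxonomy):
        part = Participant("p1", "SP")
        polys = tuple(
            PolygonAnnotation(c, ((0, 0), (3, 0), (3, 3)), "p1", draw_order=i)
            for i, c in enumerate(["tumor", "necrosis"])
        )
        path = tmp_path / "doc.json"
        write_annotation_document(AnnotationSet(make_roi(), part, polys), path)
        loaded = read_annotation_document(path, taxonomy)
        assert [p.class_name for p in loaded.polygons] == ["tumor", "necrosis"]
        assert [p.draw_order for p in loaded.polygons] == [0, 1]

    def test_round_trip_preserves_vertices(self, tmp_path, taxonomy):
        rng = np.random.default_rng(42)
        for i in range(100):
            original = self._random_set(rng)
            path = tmp_path / f"doc{i}.json"
            write_annotation_document(original, path)
            loaded = read_annotation_document(path, taxonomy)
            assert loaded.roi == original.roi
            assert loaded.participant == original.participant
            assert len(loaded.polygons) == len(original.polygons)
            for a, b in zip(loaded.polygons, sorted(original.polygons, key=lambda p: p.draw_order)):
                assert a.class_name == b.class_name
                assert a.is_correction == b.is_correction
                np.testing.assert_allclose(a.vertex_array(), b.vertex_array(), atol=1e-6)

    def test_empty_polygon_list_round_trips(self, tmp_path, taxonomy):
        s = AnnotationSet(make_roi(), Participant("p1", "JP"), ())
        path = tmp_path / "empty.json"
        write_annotation_document(s, path)
        assert json.loads(path.read_text())["elements"] == []
        assert read_annotation_document(path, taxonomy).polygons == ()

    def test_correction_flag_round_trips(self, tmp_path, taxonomy):
        poly = PolygonAnnotation("necrosis", ((0, 0), (2, 0), (2, 2)), "p1",
                                 is_correction=True)
        path = tmp_path / "corr.json"
        write_annotation_document(AnnotationSet(make_roi(), Participant("p1", "SP"), (poly,)), path)
        assert json.loads(path.read_text())["elements"][0]["correction"] is True
        assert read_annotation_document(path, taxonomy).polygons[0].is_correction

    def test_unknown_class_raises_naming_it(self, tmp_path, taxonomy):
        path = tmp_path / "bad.json"
        s = AnnotationSet(make_roi(), Participant("p1", "NP"),
                          (PolygonAnnotation("tumor", ((0, 0), (1, 0), (1, 1)), "p1"),))
        write_annotation_document(s, path)
        doc = json.loads(path.read_text())
        doc["elements"][0]["group"] = "cartilage"
        path.write_text(json.dumps(doc))
        with pytest.raises(TaxonomyError, match="cartilage"):
            read_annotation_document(path, taxonomy)

    def test_two_vertex_polygon_raises_with_element_index(self, tmp_path, taxonomy):
        path = tmp_path / "bad.json"
        s = AnnotationSet(make_roi(), Participant("p1", "NP"),
                          (PolygonAnnotation("tumor", ((0, 0), (1, 0), (1, 1)), "p1"),))
        write_annotation_document(s, path)
        doc = json.loads(path.read_text())
        doc["elements"][0]["points"] = [[0, 0], [1, 1]]
        path.write_text(json.dumps(doc))
        with pytest.raises(AnnotationValidationError, match="element 0"):
            read_annotation_document(path, taxonomy)

    def test_malformed_json_reports_line(self, tmp_path, taxonomy):
        path = tmp_path / "broken.json"
        path.write_text('{"roi": \n nope}')
        with pytest.raises(AnnotationValidationError, match="line 2"):
            read_annotation_document(path, taxonomy)


class TestMaskFiles:
    def test_all_default_mask_pixels(self, tmp_path, taxonomy):
        code = taxonomy.default_class.label_code
        m = LabelMask(np.full((4, 4), code), taxonomy)
        write_label_mask(m, tmp_path / "m.png", tmp_path / "map.json")
        loaded = read_label_mask(tmp_path / "m.png", tmp_path / "map.json")
        assert (loaded.labels == code).all()

    def test_random_mask_round_trip_lossless(self, tmp_path, taxonomy):
        rng = np.random.default_rng(3)
        for i in range(20):
            m = random_mask(rng, taxonomy, shape=(13, 17))
            write_label_mask(m, tmp_path / f"{i}.png", tmp_path / "map.json")
            loaded = read_label_mask(tmp_path / f"{i}.png", tmp_path / "map.json")
            assert (loaded.labels == m.labels).all()
            assert loaded.taxonomy.class_names == m.taxonomy.class_names

    def test_unmapped_code_errors_listing_codes(self, tmp_path, taxonomy):
        from PIL import Image

        write_taxonomy(taxonomy, tmp_path / "map.json")
        Image.fromarray(np.full((4, 4), 255, dtype=np.uint8), mode="L").save(tmp_path / "bad.png")
        with pytest.raises(TaxonomyError, match="255"):
            read_label_mask(tmp_path / "bad.png", tmp_path / "map.json")

    def test_taxonomy_file_round_trip(self, tmp_path, taxonomy):
        write_taxonomy(taxonomy, tmp_path / "tax.json")
        assert read_taxonomy(tmp_path / "tax.json") == taxonomy
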