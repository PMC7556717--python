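import numpy as np
import pytest

from ctcdte import (
    CohortDesign,
    NoiseModel,
    PatientDesign,
    SceneSpec,
    TimepointDesign,
    ctc_phenotype,
    generate_cohort,
    leukocyte_phenotype,
    render_cell_stack,
    render_tile_scan,
    score_ctc,
)
from ctcdte.exceptions import DesignError, PlacementError, ValidationError
from ctcdte.synthetic_cytospin import recovery_design


class TestPhenotypes:
    def test_ctc_requires_ck_over_cd45(self):
        with pytest.raises(ValidationError):
            ctc_phenotype(marker_means={"DAPI": 1, "CK": 10, "CD45": 20, "TUB": 5, "AR": 5})

    def test_leukocyte_requires_cd45_over_ck(self):
        with pytest.raises(ValidationError):
            leukocyte_phenotype(marker_means={"DAPI": 1, "CK": 30, "CD45": 20, "TUB": 5, "AR": 5})

    def test_bundling_only_for_ctc(self):
        with pytest.raises(ValidationError):
            leukocyte_phenotype(bundling_level=0.5)

    def test_bundling_range(self):
        with pytest.raises(ValidationError):
            ctc_phenotype(bundling_level=1.5)


class TestRenderCellStack:
    def test_seeded_determinism(self):
        a, _ = render_cell_stack(ctc_phenotype(bundling_level=0.5), seed=9)
        b, _ = render_cell_stack(ctc_phenotype(bundling_level=0.5), seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_stack_geometry(self):
        stack, truth = render_cell_stack(ctc_phenotype(), seed=0)
        assert stack.n_z == 20
        assert stack.z_step_um == pytest.approx(0.24)
        assert stack.channel_names == ("DAPI", "CK", "CD45", "TUB", "AR")
        assert truth.kind == "CTC"

    def test_noiseless_diffuse_render_is_deterministic(self):
        pheno = ctc_phenotype(
            bundling_level=0.0,
            marker_cvs={ch: 0.0 for ch in ("DAPI", "CK", "CD45", "TUB", "AR")},
        )
        quiet = NoiseModel(gaussian_sd=0.0)
        a, _ = render_cell_stack(pheno, noise=quiet, seed=2)
        b, _ = render_cell_stack(pheno, noise=quiet, seed=2)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        # diffuse-only tubulin never exceeds its drawn level
        tub = a.channel("TUB")
        assert tub.max() <= pheno.marker_means["TUB"] + 1e-6

    def test_bundled_exceeds_diffuse_same_seed(self):
        lo, _ = render_cell_stack(ctc_phenotype(bundling_level=0.0), seed=3)
        hi, _ = render_cell_stack(ctc_phenotype(bundling_level=1.0), seed=3)
        assert (
            score_ctc(hi).integrated_density > score_ctc(lo).integrated_density
        )

    def test_leukocyte_ck_stays_below_gate(self):
        stack, truth = render_cell_stack(leukocyte_phenotype(), seed=4)
        assert truth.channel_levels["CK"] < 2000  # fixture CK gate

    def test_mean_score_increases_with_bundling(self):
        # coarse 3-point check; the full 5-level grid runs in the
        # acceptance suite
        means = []
        for b in (0.0, 0.5, 1.0):
            scores = [
                score_ctc(render_cell_stack(ctc_phenotype(bundling_level=b),
                                            seed=s)[0]).integrated_density
                for s in range(8)
            ]
            means.append(np.mean(scores))
        assert means[0] < means[1] < means[2]


class TestRenderTileScan:
    def test_empty_scene(self):
        tile, truth = render_tile_scan(SceneSpec(cells=(), field_size_px=(64, 64), seed=1))
        assert truth == []
        assert tile.pixels.shape == (5, 1, 64, 64)

    def test_count_conservation(self, small_tile):
        _, truth = small_tile
        assert len(truth) == 55
        kinds = [t.kind for t in truth]
        assert kinds.count("CTC") == 5 and kinds.count("leukocyte") == 50

    def test_seeded_determinism(self):
        spec = SceneSpec(cells=((ctc_phenotype(), 3),), field_size_px=(128, 128), seed=2)
        a, ta = render_tile_scan(spec)
        b, tb = render_tile_scan(spec)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert [t.centroid_px for t in ta] == [t.centroid_px for t in tb]

    def test_field_too_small_raises_placement_error(self):
        spec = SceneSpec(cells=((ctc_phenotype(), 40),), field_size_px=(64, 64), seed=0)
        with pytest.raises(PlacementError):
            render_tile_scan(spec)

    def test_centres_respect_overlap_constraint(self, small_tile):
        _, truth = small_tile
        for i, a in enumerate(truth):
            for b in truth[i + 1:]:
                d = np.hypot(a.centroid_px[0] - b.centroid_px[0],
                             a.centroid_px[1] - b.centroid_px[1])
                min_d = (a.diameter_um + b.diameter_um) / 2.0 * (1 - 0.05)
                assert d >= min_d - 1e-9


class TestCohortDesign:
    def _tp(self, mean=0.2, expected=5.0):
        return TimepointDesign(expected_ctc=expected, bundling_mean=mean, bundling_sd=0.05)

    def test_duplicate_timepoints_rejected(self):
        with pytest.raises(DesignError):
            PatientDesign("P1", "stable",
                          (("C1D1", self._tp()), ("C1D1", self._tp())))

    def test_unknown_label_rejected(self):
        with pytest.raises(DesignError):
            PatientDesign("P1", "stable", (("C9D9", self._tp()),))

    def test_responder_requires_week1_increase(self):
        with pytest.raises(DesignError):
            PatientDesign("P1", "responder",
                          (("C1D1", self._tp(0.3)), ("C1D8", self._tp(0.3))))

    def test_stable_rejects_week1_increase(self):
        with pytest.raises(DesignError):
            PatientDesign("P1", "stable",
                          (("C1D1", self._tp(0.1)), ("C1D8", self._tp(0.4))))

    def test_yaml_round_trip(self, tmp_path):
        design = recovery_design(seed=5)
        p = tmp_path / "design.yaml"
        design.to_yaml(p)
        assert CohortDesign.from_yaml(p) == design


class TestGenerateCohort:
    def _tiny_design(self, seed=0, expected=2.0):
        patient = PatientDesign(
            "P1", "stable",
            (("C1D1", TimepointDesign(expected_ctc=expected, bundling_mean=0.2,
                                      bundling_sd=0.05)),
             ("C1D8", TimepointDesign(expected_ctc=expected, bundling_mean=0.2,
                                      bundling_sd=0.05))),
        )
        return CohortDesign(patients=(patient,), seed=seed, count_model="fixed",
                            n_background_leukocytes=5)

    def test_zero_expectation_yields_empty_timepoint_row(self, tmp_path):
        manifest = generate_cohort(self._tiny_design(expected=0.0), tmp_path)
        assert set(manifest["timepoint"]) == {"C1D1", "C1D8"}
        assert (manifest["cell_id"] == "").all() or manifest["cell_id"].isna().all()

    def test_manifest_lists_written_stacks(self, tmp_path):
        manifest = generate_cohort(self._tiny_design(), tmp_path, write_tiles=False)
        cells = manifest[manifest["true_label"] == "CTC"]
        assert len(cells) == 4  # 2 timepoints x 2 cells
        for rel in cells["file"]:
            assert (tmp_path / rel).exists()

    def test_not_received_timepoint_has_no_files(self, tmp_path):
        patient = PatientDesign(
            "P1", "stable",
            (("C1D1", TimepointDesign(expected_ctc=2, bundling_mean=0.2,
                                      bundling_sd=0.05)),
             ("C2D8", TimepointDesign(expected_ctc=2, bundling_mean=0.2,
                                      bundling_sd=0.05,
                                      status="sample_not_received"))),
        )
        design = CohortDesign(patients=(patient,), seed=1, count_model="fixed")
        manifest = generate_cohort(design, tmp_path, write_tiles=False)
        nr = manifest[manifest["timepoint"] == "C2D8"]
        assert list(nr["status"]) == ["sample_not_received"]
        assert (nr["file"] == "").all() or nr["file"].isna().all()

    def test_manifest_byte_identical_for_same_seed(self, tmp_path):
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        generate_cohort(self._tiny_design(seed=3), d1)
        generate_cohort(self._tiny_design(seed=3), d2)
        assert (d1 / "manifest.csv").read_bytes() == (d2 / "manifest.csv").read_bytes()
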