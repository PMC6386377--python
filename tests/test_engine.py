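"""Candidate grids, recipe lifecycle, run/batch determinism and purity."""

import json

import numpy as np
import pandas as pd
import pytest

from morphoquant.engine import (PipelineRecipe, RecipeStateError,
                                SuggestionContext, batch_run, default_recipe,
                                run_recipe, select_candidate,
                                suggest_candidates)
from morphoquant.operators import OperatorSpec, apply_operator
from morphoquant.synth import SyntheticSpec, generate_particle_image


class TestRecipe:
    def test_stage_order_enforced(self, fluorescence_context):
        r = PipelineRecipe(context=fluorescence_context)
        with pytest.raises(RecipeStateError):
            r.extended(OperatorSpec("binarisation", "otsu_global"))
        with pytest.raises(RecipeStateError):
            r.extended(OperatorSpec("postprocessing", "fill_holes"))
        r = r.extended(OperatorSpec("noise_reduction", "gaussian",
                                    {"sigma": 1.0}))
        with pytest.raises(RecipeStateError):
            r.extended(OperatorSpec("noise_reduction", "median"))

    def test_postprocessing_repeats(self, fluorescence_context):
        r = (PipelineRecipe(context=fluorescence_context)
             .extended(OperatorSpec("noise_reduction", "gaussian", {"sigma": 1.0}))
             .extended(OperatorSpec("binarisation", "otsu_global"))
             .extended(OperatorSpec("postprocessing", "fill_holes"))
             .extended(OperatorSpec("postprocessing", "remove_small_objects",
                                    {"min_area": 5}))
             .with_watershed("none"))
        assert [s.name for _, s in r.iter_stages()][2:] == [
            "fill_holes", "remove_small_objects"]
        assert r.is_complete()

    def test_json_round_trip_identity(self, fluorescence_recipe):
        text = fluorescence_recipe.to_json()
        again = PipelineRecipe.from_json(text)
        assert again.to_json() == text
        assert again.to_dict() == fluorescence_recipe.to_dict()

    def test_incomplete_recipe_cannot_run(self, disjoint_image,
                                          fluorescence_context):
        image, _ = disjoint_image
        partial = PipelineRecipe(context=fluorescence_context)
        with pytest.raises(RecipeStateError):
            run_recipe(image, partial)


class TestSuggestCandidates:
    def test_grid_deterministic_and_capped(self, disjoint_image,
                                           fluorescence_context):
        image, _ = disjoint_image
        g1 = suggest_candidates(image, fluorescence_context, "noise_reduction")
        g2 = suggest_candidates(image, fluorescence_context, "noise_reduction")
        assert 2 <= len(g1) <= 12
        assert [s.to_json() for s, _ in g1.candidates] == \
               [s.to_json() for s, _ in g2.candidates]
        for (_, p1), (_, p2) in zip(g1.candidates, g2.candidates):
            assert np.array_equal(p1.pixels, p2.pixels)

    def test_fluorescence_binarisation_grid_rules(self, disjoint_image,
                                                  fluorescence_context):
        image, _ = disjoint_image
        recipe = PipelineRecipe(context=fluorescence_context).extended(
            OperatorSpec("noise_reduction", "gaussian", {"sigma": 1.0}))
        grid = suggest_candidates(image, fluorescence_context, "binarisation",
                                  recipe)
        names = [s.name for s, _ in grid.candidates]
        assert "otsu_global" in names
        assert all(not s.params.get("invert", False)
                   for s, _ in grid.candidates)

    def test_previews_match_independent_reapplication(self, disjoint_image,
                                                      fluorescence_context):
        image, _ = disjoint_image
        grid = suggest_candidates(image, fluorescence_context,
                                  "noise_reduction")
        for spec, preview in grid.candidates:
            redone, _ = apply_operator(image, spec)
            assert np.array_equal(redone.pixels, preview.pixels)

    def test_stage_out_of_order_rejected(self, disjoint_image,
                                         fluorescence_context):
        image, _ = disjoint_image
        fresh = PipelineRecipe(context=fluorescence_context)
        with pytest.raises(RecipeStateError):
            suggest_candidates(image, fluorescence_context, "postprocessing",
                               fresh)

    def test_selection_extends_recipe_without_mutating_grid(
            self, disjoint_image, fluorescence_context):
        image, _ = disjoint_image
        grid = suggest_candidates(image, fluorescence_context,
                                  "noise_reduction")
        r0 = select_candidate(grid, 0)
        r1 = select_candidate(grid, 1)  # re-selection allowed
        assert r0.noise_reduction.to_json() == grid.candidates[0][0].to_json()
        assert r1.noise_reduction.to_json() == grid.candidates[1][0].to_json()
        with pytest.raises(IndexError):
            select_candidate(grid, len(grid.candidates))

    def test_click_through_all_stages_completes(self, disjoint_image,
                                                fluorescence_context):
        image, _ = disjoint_image
        recipe = PipelineRecipe(context=fluorescence_context)
        for stage in ("noise_reduction", "binarisation", "postprocessing"):
            grid = suggest_candidates(image, fluorescence_context, stage,
                                      recipe)
            assert grid.provenance.to_json() == recipe.to_json()
            recipe = select_candidate(grid, 0)
        recipe = recipe.with_watershed("none")
        recipe.require_complete()

    def test_contact_sheet_written(self, tmp_path, disjoint_image,
                                   fluorescence_context):
        image, _ = disjoint_image
        grid = suggest_candidates(image, fluorescence_context,
                                  "noise_reduction")
        grid.to_contact_sheet(tmp_path / "sheet.png")
        assert (tmp_path / "sheet.png").stat().st_size > 0


class TestRunRecipe:
    def test_count_recovery_on_clean_image(self, fluorescence_context):
        spec = SyntheticSpec(width=256, height=256, n_particles=20,
                             axis_range=(4, 9), noise_model="none", seed=8)
        image, gt = generate_particle_image(spec)
        recipe = default_recipe(fluorescence_context)
        _, table = run_recipe(image, recipe)
        assert len(table) == len(gt) == 20

    def test_rerun_bit_identical(self, disjoint_image, fluorescence_recipe):
        image, _ = disjoint_image
        _, t1 = run_recipe(image, fluorescence_recipe)
        _, t2 = run_recipe(image, fluorescence_recipe)
        pd.testing.assert_frame_equal(t1, t2)

    def test_serialised_recipe_reruns_identically(self, disjoint_image,
                                                  fluorescence_recipe):
        image, _ = disjoint_image
        _, t1 = run_recipe(image, fluorescence_recipe)
        reloaded = PipelineRecipe.from_json(fluorescence_recipe.to_json())
        _, t2 = run_recipe(image, reloaded)
        pd.testing.assert_frame_equal(t1, t2)


class TestBatchRun:
    def test_batch_of_one_equals_run_recipe(self, disjoint_image,
                                            fluorescence_recipe):
        image, _ = disjoint_image
        result = batch_run([image], fluorescence_recipe)
        _, direct = run_recipe(image, fluorescence_recipe)
        assert len(result.tables) == 1
        pd.testing.assert_frame_equal(next(iter(result.tables.values())),
                                      direct)

    def test_corrupted_file_recorded_not_fatal(self, tmp_path,
                                               disjoint_image,
                                               fluorescence_recipe):
        image, _ = disjoint_image
        bad = tmp_path / "corrupt.tif"
        bad.write_bytes(b"not a tiff at all")
        result = batch_run([image, bad], fluorescence_recipe)
        assert len(result.tables) == 1
        assert str(bad) in result.failures

    def test_aggregation_totals_equal_sum_of_counts(self, fluorescence_recipe):
        images = []
        for seed in range(4):
            spec = SyntheticSpec(width=128, height=128, n_particles=6,
                                 axis_range=(3, 6), seed=seed)
            images.append(generate_particle_image(spec)[0])
        result = batch_run(images, fluorescence_recipe)
        assert result.summary["count"] == sum(result.counts.values())

    def test_group_comparison_on_batch_counts(self, fluorescence_recipe):
        # two treatment groups of images with shifted particle counts: the
        # shape of the validation experiment, at reduced size
        from morphoquant.features import compare_groups

        def group(n_particles, seeds):
            imgs = []
            for s in seeds:
                spec = SyntheticSpec(width=128, height=128,
                                     n_particles=n_particles,
                                     axis_range=(3, 5), seed=s)
                imgs.append(generate_particle_image(spec)[0])
            return imgs

        r_lo = batch_run(group(4, range(8)), fluorescence_recipe)
        r_hi = batch_run(group(14, range(100, 108)), fluorescence_recipe)
        res = compare_groups(list(r_lo.counts.values()),
                             list(r_hi.counts.values()), "count")
        assert res.p_value < 0.01

    def test_zero_inputs_rejected(self, fluorescence_recipe):
        with pytest.raises(ValueError):
            batch_run([], fluorescence_recipe)
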