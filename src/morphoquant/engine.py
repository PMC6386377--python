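"""Headless candidate-grid pipeline: suggest → select → run → batch.

The interactive paradigm this engine reproduces: instead of asking the user
to pick operators from a menu, the tool renders a small grid of alternative
processed previews at each stage (noise reduction, then binarisation, then
zero or more postprocessing passes, then watershed) and the user clicks the
best-looking one.  Headlessly, "clicking" is selecting a grid index — or
pre-specifying operator names and parameters in a config — and the chosen
sequence is recorded as a :class:`PipelineRecipe`, the unit of
reproducibility: any result is a pure function of (image bytes, recipe
JSON).

The suggestion-ordering rules per acquisition context are explicit
heuristics of this implementation (fluorescence favours gaussian/median/DoG
denoising with bright-foreground polarity; bright field allows inverted
polarity and favours median; electron microscopy favours adaptive
thresholds); they are fully overridable by selecting any whitelisted
operator directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .io import Image, read_image
from .operators import (BinaryMask, OperatorSpec, STAGES, apply_operator,
                        list_operators)
from .segmentation import LabelMap, WATERSHED_METHODS, watershed_split
from .features import measure_particles, summarize

__all__ = [
    "SuggestionContext", "PipelineRecipe", "CandidateGrid", "BatchResult",
    "suggest_candidates", "select_candidate", "run_recipe", "batch_run",
    "default_recipe",
]

IMAGING_METHODS = ("fluorescence", "bright_field", "electron_microscopy")
SPECIMEN_TYPES = ("bacteria", "yeast", "mammalian_cells", "brain_tissue",
                  "plant_cells", "other")

MAX_CANDIDATES = 12

RECIPE_SCHEMA_VERSION = 1

# priority order of operator names per (imaging method, stage); operators not
# listed follow in catalogue order
_CONTEXT_PRIORITY = {
    ("fluorescence", "noise_reduction"): ["gaussian", "median",
                                          "difference_of_gaussian"],
    ("fluorescence", "binarisation"): ["otsu_global", "triangle",
                                       "fixed_threshold"],
    ("bright_field", "noise_reduction"): ["median", "gaussian"],
    ("bright_field", "binarisation"): ["otsu_global", "adaptive_mean"],
    ("electron_microscopy", "noise_reduction"): ["median", "bilateral"],
    ("electron_microscopy", "binarisation"): ["adaptive_mean",
                                              "adaptive_gaussian",
                                              "otsu_global"],
}


@dataclass(frozen=True)
class SuggestionContext:
    """Acquisition context used to rank candidate operators."""

    imaging_method: str
    specimen_type: str

    def __post_init__(self) -> None:
        if self.imaging_method not in IMAGING_METHODS:
            raise ValueError(f"imaging_method must be one of {IMAGING_METHODS}")
        if self.specimen_type not in SPECIMEN_TYPES:
            raise ValueError(f"specimen_type must be one of {SPECIMEN_TYPES}")

    def to_dict(self) -> dict:
        return {"imaging_method": self.imaging_method,
                "specimen_type": self.specimen_type}

    @classmethod
    def from_dict(cls, d: dict) -> "SuggestionContext":
        return cls(d["imaging_method"], d["specimen_type"])


class RecipeStateError(RuntimeError):
    """A recipe stage was used out of order or before completion."""


@dataclass
class PipelineRecipe:
    """The ordered record of chosen operators — the unit of reproducibility.

    Stage order is fixed: noise_reduction → binarisation → postprocessing
    (repeatable) → watershed.  JSON round-trip is the identity.
    """

    context: Optional[SuggestionContext] = None
    noise_reduction: Optional[OperatorSpec] = None
    binarisation: Optional[OperatorSpec] = None
    postprocessing: List[OperatorSpec] = field(default_factory=list)
    watershed_method: Optional[str] = None
    watershed_params: Dict = field(default_factory=dict)
    connectivity: int = 8
    created_at: Optional[str] = None
    tool_version: str = __version__

    # -- state ------------------------------------------------------------

    def next_stage(self) -> str:
        if self.noise_reduction is None:
            return "noise_reduction"
        if self.binarisation is None:
            return "binarisation"
        if self.watershed_method is None:
            return "postprocessing"  # or watershed; postprocessing repeats
        return "complete"

    def is_complete(self) -> bool:
        return (self.noise_reduction is not None
                and self.binarisation is not None
                and self.watershed_method is not None)

    def require_complete(self) -> None:
        if not self.is_complete():
            raise RecipeStateError(
                f"recipe incomplete: next stage is {self.next_stage()!r}")

    def iter_stages(self):
        """Yield (stage name, spec) in execution order, watershed excluded."""
        if self.noise_reduction is not None:
            yield "noise_reduction", self.noise_reduction
        if self.binarisation is not None:
            yield "binarisation", self.binarisation
        for i, spec in enumerate(self.postprocessing):
            yield f"postprocessing[{i}]", spec

    def extended(self, spec: OperatorSpec) -> "PipelineRecipe":
        """A new recipe with *spec* recorded at its stage (non-mutating)."""
        new = self.copy()
        if spec.stage == "noise_reduction":
            if new.noise_reduction is not None:
                raise RecipeStateError("noise_reduction already chosen")
            new.noise_reduction = spec
        elif spec.stage == "binarisation":
            if new.noise_reduction is None:
                raise RecipeStateError("binarisation before noise_reduction")
            if new.binarisation is not None:
                raise RecipeStateError("binarisation already chosen")
            new.binarisation = spec
        elif spec.stage == "postprocessing":
            if new.binarisation is None:
                raise RecipeStateError("postprocessing before binarisation")
            new.postprocessing = list(new.postprocessing) + [spec]
        else:
            raise ValueError(f"unknown stage {spec.stage!r}")
        return new

    def with_watershed(self, method: str, params: Optional[Dict] = None
                       ) -> "PipelineRecipe":
        if method not in WATERSHED_METHODS:
            raise ValueError(f"watershed method must be one of {WATERSHED_METHODS}")
        if self.binarisation is None:
            raise RecipeStateError("watershed before binarisation")
        new = self.copy()
        new.watershed_method = method
        new.watershed_params = dict(params or {})
        return new

    def copy(self) -> "PipelineRecipe":
        return PipelineRecipe(
            context=self.context,
            noise_reduction=self.noise_reduction,
            binarisation=self.binarisation,
            postprocessing=list(self.postprocessing),
            watershed_method=self.watershed_method,
            watershed_params=dict(self.watershed_params),
            connectivity=self.connectivity,
            created_at=self.created_at,
            tool_version=self.tool_version,
        )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "schema_version": RECIPE_SCHEMA_VERSION,
            "tool_version": self.tool_version,
            "context": self.context.to_dict() if self.context else None,
            "noise_reduction": (self.noise_reduction.to_dict()
                                if self.noise_reduction else None),
            "binarisation": (self.binarisation.to_dict()
                             if self.binarisation else None),
            "postprocessing": [s.to_dict() for s in self.postprocessing],
            "watershed": {"method": self.watershed_method,
                          "params": dict(self.watershed_params)},
            "connectivity": self.connectivity,
        }
        if self.created_at is not None:
            d["created_at"] = self.created_at
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineRecipe":
        def spec(x):
            return OperatorSpec.from_dict(x) if x else None

        ws = d.get("watershed") or {}
        return cls(
            context=(SuggestionContext.from_dict(d["context"])
                     if d.get("context") else None),
            noise_reduction=spec(d.get("noise_reduction")),
            binarisation=spec(d.get("binarisation")),
            postprocessing=[OperatorSpec.from_dict(x)
                            for x in d.get("postprocessing", [])],
            watershed_method=ws.get("method"),
            watershed_params=dict(ws.get("params", {})),
            connectivity=d.get("connectivity", 8),
            created_at=d.get("created_at"),
            tool_version=d.get("tool_version", __version__),
        )

    @classmethod
    def from_json(cls, text: str) -> "PipelineRecipe":
        return cls.from_dict(json.loads(text))


@dataclass
class CandidateGrid:
    """Alternative processed previews for one stage, in deterministic order."""

    stage: str
    candidates: List[Tuple[OperatorSpec, Union[Image, BinaryMask]]]
    provenance: PipelineRecipe  # recipe-so-far
    source: Image

    def __len__(self) -> int:
        return len(self.candidates)

    def to_contact_sheet(self, path, columns: int = 4, pad: int = 2) -> None:
        """Assemble the previews into one PNG grid for manual inspection."""
        import imageio.v3 as iio

        tiles = []
        for _, preview in self.candidates:
            arr = preview.pixels.astype(np.float64)
            lo, hi = arr.min(), arr.max()
            tiles.append(((arr - lo) / (hi - lo) * 255 if hi > lo
                          else np.zeros_like(arr)).astype(np.uint8))
        h, w = tiles[0].shape
        ncol = min(columns, len(tiles))
        nrow = -(-len(tiles) // ncol)
        sheet = np.zeros((nrow * (h + pad) - pad, ncol * (w + pad) - pad),
                         dtype=np.uint8)
        for i, tile in enumerate(tiles):
            r, c = divmod(i, ncol)
            sheet[r * (h + pad): r * (h + pad) + h,
                  c * (w + pad): c * (w + pad) + w] = tile
        iio.imwrite(str(path), sheet)


def _enumerate_specs(stage: str, context: Optional[SuggestionContext],
                     cap: int = MAX_CANDIDATES) -> List[OperatorSpec]:
    """Context-ordered operator list crossed with each operator's param grid."""
    catalogue = {s.name: s for s in list_operators(stage)}
    priority = _CONTEXT_PRIORITY.get(
        (context.imaging_method, stage) if context else (None, stage), [])
    ordered = [catalogue[n] for n in priority if n in catalogue]
    ordered += [s for n, s in catalogue.items() if n not in priority]

    out: List[OperatorSpec] = []
    for base in ordered:
        grid = base.param_grid or {"": [None]}
        keys = sorted(grid)
        combos = [[]]
        for key in keys:
            combos = [c + [(key, v)] for c in combos for v in grid[key]]
        for combo in combos:
            params = dict(base.params)
            params.update({k: v for k, v in combo if k})
            if (context is not None and context.imaging_method == "fluorescence"
                    and params.get("invert")):
                continue  # fluorescence = bright particles, never inverted
            out.append(OperatorSpec(stage, base.name, params))
    # round-robin over operators so the cap keeps variety, preserving priority
    by_op: Dict[str, List[OperatorSpec]] = {}
    for s in out:
        by_op.setdefault(s.name, []).append(s)
    order = [s.name for s in ordered]
    capped: List[OperatorSpec] = []
    rank = 0
    while len(capped) < min(cap, len(out)):
        added = False
        for name in order:
            lst = by_op.get(name, [])
            if rank < len(lst) and len(capped) < cap:
                capped.append(lst[rank])
                added = True
        if not added:
            break
        rank += 1
    return capped


def suggest_candidates(image: Image, context: SuggestionContext, stage: str,
                       recipe_so_far: Optional[PipelineRecipe] = None,
                       max_candidates: int = MAX_CANDIDATES) -> CandidateGrid:
    """Enumerate candidate processed previews for the next stage.

    Previews are computed by applying the partial recipe to *image* and then
    each candidate spec — pure functions of (image, recipe, spec), hence
    re-computable and bit-reproducible.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    recipe = recipe_so_far if recipe_so_far is not None else PipelineRecipe(context=context)
    expected = recipe.next_stage()
    ok = (stage == expected
          or (stage == "postprocessing" and expected == "postprocessing"))
    if not ok:
        raise RecipeStateError(
            f"stage {stage!r} out of order; recipe expects {expected!r}")

    data: Union[Image, BinaryMask] = image
    for _, spec in recipe.iter_stages():
        data, _ = apply_operator(data, spec)

    specs = _enumerate_specs(stage, context, cap=max_candidates)
    candidates = []
    for spec in specs:
        preview, applied = apply_operator(data, spec)
        candidates.append((applied, preview))
    return CandidateGrid(stage=stage, candidates=candidates,
                         provenance=recipe, source=image)


def select_candidate(grid: CandidateGrid, index: int) -> PipelineRecipe:
    """Record the "click": extend the grid's recipe with candidate *index*.

    Side-effect free on the grid; selecting a different index from the same
    grid later is allowed.
    """
    if not 0 <= index < len(grid.candidates):
        raise IndexError(f"candidate index {index} out of range "
                         f"(grid has {len(grid.candidates)})")
    spec, _ = grid.candidates[index]
    return grid.provenance.extended(spec)


def run_recipe(image: Image, recipe: PipelineRecipe
               ) -> Tuple[LabelMap, pd.DataFrame]:
    """Execute a complete recipe on one image: labels + particle table."""
    recipe.require_complete()
    data: Union[Image, BinaryMask] = image
    for _, spec in recipe.iter_stages():
        data, _ = apply_operator(data, spec)
    assert isinstance(data, BinaryMask)
    labels = watershed_split(data, method=recipe.watershed_method,
                             params=recipe.watershed_params,
                             connectivity=recipe.connectivity)
    table = measure_particles(labels, image)
    return labels, table


@dataclass
class BatchResult:
    """Per-image tables plus recorded failures and a combined summary."""

    tables: Dict[str, pd.DataFrame]
    failures: Dict[str, str]
    summary: dict

    @property
    def counts(self) -> Dict[str, int]:
        return {name: len(t) for name, t in self.tables.items()}


def batch_run(inputs: Sequence, recipe: PipelineRecipe,
              channel_policy: Union[int, str] = "luminance") -> BatchResult:
    """Run one recipe over many images; per-image failures do not abort.

    *inputs* may mix paths and in-memory :class:`Image` objects.  The
    combined summary pools all detected particles; per-image counts are
    available via :attr:`BatchResult.counts` for group comparisons.
    """
    recipe.require_complete()
    if len(inputs) == 0:
        raise ValueError("batch_run needs at least one input")
    tables: Dict[str, pd.DataFrame] = {}
    failures: Dict[str, str] = {}
    for item in inputs:
        if isinstance(item, Image):
            name, image = item.provenance, item
        else:
            name = str(item)
            try:
                image = read_image(item, channel_policy=channel_policy)
            except Exception as exc:
                failures[name] = f"{type(exc).__name__}: {exc}"
                continue
        try:
            _, table = run_recipe(image, recipe)
        except Exception as exc:
            failures[name] = f"{type(exc).__name__}: {exc}"
            continue
        tables[name] = table
    if not tables and not failures:
        raise ValueError("no readable inputs")
    pooled = (pd.concat(tables.values(), ignore_index=True)
              if tables else pd.DataFrame())
    summary = summarize(pooled)
    summary["n_images"] = len(tables)
    summary["n_failures"] = len(failures)
    return BatchResult(tables=tables, failures=failures, summary=summary)


def default_recipe(context: SuggestionContext,
                   min_particle_area: int = 5,
                   watershed: str = "none",
                   watershed_params: Optional[Dict] = None) -> PipelineRecipe:
    """A sensible complete recipe for a context, without interaction.

    Fluorescence default: gaussian(σ=1) → Otsu → remove_small_objects →
    chosen watershed.  Serves as the headless starting point and as the
    measurement recipe behind whole-image morphometric features.
    """
    recipe = PipelineRecipe(context=context)
    recipe = recipe.extended(OperatorSpec("noise_reduction", "gaussian",
                                          {"sigma": 1.0}))
    recipe = recipe.extended(OperatorSpec("binarisation", "otsu_global",
                                          {"invert": False}))
    recipe = recipe.extended(OperatorSpec("postprocessing",
                                          "remove_small_objects",
                                          {"min_area": min_particle_area}))
    return recipe.with_watershed(watershed, watershed_params)
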