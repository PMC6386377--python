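"""Whitelisted image-processing operators for the three interactive stages.

The staged pipeline deliberately restricts what can be applied to a
micrograph: every operator is a named, parameterised registry entry that has
been vetted for bioimage integrity.  The non-local means filter is
deliberately *absent* — it smooths a region using similar intensity
distributions borrowed from distant regions regardless of whether those
regions are biologically identical, which can fabricate structure, so it is
blacklisted by name and :func:`integrity_check` fails it with that reason.

Stages and signatures:

* ``noise_reduction``: Image -> Image
* ``binarisation``:    Image -> BinaryMask
* ``postprocessing``:  BinaryMask -> BinaryMask

All convolution/rank filters pad by reflection to avoid dark-border
artefacts.  Binarisation assumes bright particles on a dark background
(fluorescence convention); an ``invert`` parameter handles bright-field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Callable, Dict, List, Tuple, Union

import numpy as np
import scipy.ndimage as ndi
from skimage import filters, morphology, restoration, segmentation as skseg

from .io import Image

__all__ = [
    "OperatorSpec",
    "BinaryMask",
    "STAGES",
    "list_operators",
    "get_operator",
    "apply_operator",
    "integrity_check",
]

STAGES = ("noise_reduction", "binarisation", "postprocessing")

# operators that violate bioimage integrity and must never enter the catalogue
BLACKLIST = {
    "non_local_means": (
        "performs smoothing by borrowing similar intensity distributions "
        "from distant regions regardless of whether those regions are "
        "biologically identical; fabricated local structure violates "
        "bioimage integrity"
    ),
}


@dataclass
class BinaryMask:
    """A {0,1} foreground mask with the same shape as its source image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("BinaryMask requires a non-empty 2-D array")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("BinaryMask values must be strictly binary")
        self.pixels = arr.astype(bool)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class OperatorSpec:
    """A stage + operator name + concrete parameters (+ candidate grid)."""

    stage: str
    name: str
    params: Dict[str, Any] = field(default_factory=dict)
    param_grid: Dict[str, List[Any]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"stage": self.stage, "name": self.name, "params": dict(self.params)}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)

    @classmethod
    def from_dict(cls, data: dict) -> "OperatorSpec":
        return cls(stage=data["stage"], name=data["name"],
                   params=dict(data.get("params", {})))

    @classmethod
    def from_json(cls, text: str) -> "OperatorSpec":
        return cls.from_dict(json.loads(text))

    def with_params(self, **params) -> "OperatorSpec":
        merged = {**self.params, **params}
        return OperatorSpec(self.stage, self.name, merged, dict(self.param_grid))


# ---------------------------------------------------------------------------
# registry

class _Entry:
    def __init__(self, name: str, stage: str, func: Callable,
                 defaults: Dict[str, Any], grid: Dict[str, List[Any]],
                 validate: Callable[[Dict[str, Any]], None] = None):
        self.name = name
        self.stage = stage
        self.func = func
        self.defaults = defaults
        self.grid = grid
        self.validate = validate

    def spec(self) -> OperatorSpec:
        return OperatorSpec(self.stage, self.name, dict(self.defaults),
                            {k: list(v) for k, v in self.grid.items()})


_REGISTRY: Dict[str, Dict[str, _Entry]] = {s: {} for s in STAGES}


def _register(stage, name, defaults, grid, validate=None):
    def deco(func):
        _REGISTRY[stage][name] = _Entry(name, stage, func, defaults, grid, validate)
        return func
    return deco


def _require_odd(params, key):
    v = params[key]
    if not (isinstance(v, (int, np.integer)) and v >= 1 and v % 2 == 1):
        raise ValueError(f"{key} must be an odd positive integer, got {v!r}")


def _require_positive(params, key, strict=True):
    v = params[key]
    if (v <= 0) if strict else (v < 0):
        raise ValueError(f"{key} must be {'positive' if strict else 'non-negative'}, got {v!r}")


# --- noise reduction -------------------------------------------------------

@_register("noise_reduction", "gaussian", {"sigma": 1.0},
           {"sigma": [0.5, 1.0, 2.0]},
           validate=lambda p: _require_positive(p, "sigma", strict=False))
def _gaussian(pixels, sigma):
    if sigma == 0:
        return pixels.copy()
    return ndi.gaussian_filter(pixels, sigma=sigma, mode="reflect")


@_register("noise_reduction", "median", {"size": 3}, {"size": [3, 5]},
           validate=lambda p: _require_odd(p, "size"))
def _median(pixels, size):
    return ndi.median_filter(pixels, size=size, mode="reflect")


@_register("noise_reduction", "mean", {"size": 3}, {"size": [3, 5]},
           validate=lambda p: _require_odd(p, "size"))
def _mean(pixels, size):
    return ndi.uniform_filter(pixels, size=size, mode="reflect")


@_register("noise_reduction", "difference_of_gaussian",
           {"sigma1": 1.0, "sigma2": 4.0},
           {"sigma1": [1.0, 2.0], "sigma2": [4.0, 8.0]})
def _dog(pixels, sigma1, sigma2):
    if not 0 <= sigma1 < sigma2:
        raise ValueError(f"difference_of_gaussian requires 0 <= sigma1 < sigma2, "
                         f"got {sigma1}, {sigma2}")
    low = ndi.gaussian_filter(pixels, sigma1, mode="reflect")
    high = ndi.gaussian_filter(pixels, sigma2, mode="reflect")
    # clamp at 0: downstream thresholding expects non-negative intensities
    return np.clip(low - high, 0.0, None)


@_register("noise_reduction", "bilateral",
           {"sigma_spatial": 2.0, "sigma_intensity": 0.1},
           {"sigma_spatial": [1.0, 2.0], "sigma_intensity": [0.05, 0.1]},
           validate=lambda p: (_require_positive(p, "sigma_spatial"),
                               _require_positive(p, "sigma_intensity")))
def _bilateral(pixels, sigma_spatial, sigma_intensity):
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi == lo:
        return pixels.copy()
    # denoise_bilateral wants non-negative floats; rescale to [0,1] and back
    norm = (pixels - lo) / (hi - lo)
    out = restoration.denoise_bilateral(norm, sigma_color=sigma_intensity,
                                        sigma_spatial=sigma_spatial,
                                        mode="reflect")
    return out * (hi - lo) + lo


# --- binarisation ----------------------------------------------------------

def _polarize(pixels, threshold, invert):
    mask = pixels <= threshold if invert else pixels > threshold
    return mask


@_register("binarisation", "otsu_global", {"invert": False},
           {"invert": [False]})
def _otsu(pixels, invert):
    if pixels.min() == pixels.max():
        # degenerate constant image: threshold equals the constant,
        # everything background; must not crash candidate enumeration
        return np.zeros(pixels.shape, dtype=bool)
    t = filters.threshold_otsu(pixels)
    return _polarize(pixels, t, invert)


@_register("binarisation", "fixed_threshold", {"threshold": 0.5, "invert": False},
           {"threshold": [0.25, 0.5, 0.75]})
def _fixed(pixels, threshold, invert):
    return _polarize(pixels, threshold, invert)


@_register("binarisation", "adaptive_mean",
           {"block_size": 51, "offset": 0.0, "invert": False},
           {"block_size": [31, 51], "offset": [0.0]},
           validate=lambda p: _require_odd(p, "block_size"))
def _adaptive_mean(pixels, block_size, offset, invert):
    t = filters.threshold_local(pixels, block_size=block_size, method="mean",
                                offset=offset, mode="reflect")
    return _polarize(pixels, t, invert)


@_register("binarisation", "adaptive_gaussian",
           {"block_size": 51, "offset": 0.0, "invert": False},
           {"block_size": [31, 51], "offset": [0.0]},
           validate=lambda p: _require_odd(p, "block_size"))
def _adaptive_gaussian(pixels, block_size, offset, invert):
    t = filters.threshold_local(pixels, block_size=block_size,
                                method="gaussian", offset=offset,
                                mode="reflect")
    return _polarize(pixels, t, invert)


@_register("binarisation", "triangle", {"invert": False}, {"invert": [False]})
def _triangle(pixels, invert):
    if pixels.min() == pixels.max():
        return np.zeros(pixels.shape, dtype=bool)
    t = filters.threshold_triangle(pixels)
    return _polarize(pixels, t, invert)


# --- postprocessing --------------------------------------------------------

@_register("postprocessing", "opening", {"radius": 1}, {"radius": [1, 2]},
           validate=lambda p: _require_positive(p, "radius"))
def _opening(mask, radius):
    return morphology.opening(mask, morphology.disk(radius))


@_register("postprocessing", "closing", {"radius": 1}, {"radius": [1, 2]},
           validate=lambda p: _require_positive(p, "radius"))
def _closing(mask, radius):
    return morphology.closing(mask, morphology.disk(radius))


@_register("postprocessing", "fill_holes", {"connectivity": 1},
           {"connectivity": [1, 2]})
def _fill_holes(mask, connectivity):
    if connectivity not in (1, 2):
        raise ValueError(f"connectivity must be 1 or 2, got {connectivity!r}")
    structure = ndi.generate_binary_structure(2, connectivity)
    return ndi.binary_fill_holes(mask, structure=structure)


@_register("postprocessing", "remove_small_objects", {"min_area": 10},
           {"min_area": [5, 10, 25]},
           validate=lambda p: _require_positive(p, "min_area"))
def _remove_small(mask, min_area):
    # keep exactly the components with area >= min_area (8-connectivity)
    labels, n = ndi.label(mask, structure=np.ones((3, 3), bool))
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


@_register("postprocessing", "clear_border", {"buffer_size": 0},
           {"buffer_size": [0]},
           validate=lambda p: _require_positive(p, "buffer_size", strict=False))
def _clear_border(mask, buffer_size):
    return skseg.clear_border(mask, buffer_size=buffer_size)


# ---------------------------------------------------------------------------
# public API

def list_operators(stage: str) -> List[OperatorSpec]:
    """Default-parameterised specs of every whitelisted operator of a stage."""
    if stage not in _REGISTRY:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return [entry.spec() for entry in _REGISTRY[stage].values()]


def get_operator(stage: str, name: str) -> OperatorSpec:
    if stage not in _REGISTRY:
        raise ValueError(f"unknown stage {stage!r}")
    try:
        return _REGISTRY[stage][name].spec()
    except KeyError:
        raise ValueError(f"operator {name!r} is not whitelisted for stage {stage!r}")


def integrity_check(spec: OperatorSpec) -> Tuple[bool, str]:
    """Verdict on whether a spec may run: (pass, reason)."""
    if spec.name in BLACKLIST:
        return False, f"{spec.name}: {BLACKLIST[spec.name]}"
    if spec.stage not in _REGISTRY:
        return False, f"unknown stage {spec.stage!r}"
    entry = _REGISTRY[spec.stage].get(spec.name)
    if entry is None:
        return False, f"{spec.name!r} is not on the {spec.stage} whitelist"
    unknown = set(spec.params) - set(entry.defaults)
    if unknown:
        return False, f"unknown parameters for {spec.name}: {sorted(unknown)}"
    if entry.validate is not None:
        try:
            entry.validate({**entry.defaults, **spec.params})
        except ValueError as exc:
            return False, str(exc)
    return True, "ok"


def apply_operator(data: Union[Image, BinaryMask], spec: OperatorSpec
                   ) -> Tuple[Union[Image, BinaryMask], OperatorSpec]:
    """Apply one whitelisted operator; returns (result, applied spec).

    The applied spec (defaults merged with the given params) is returned
    alongside the result so the caller can record it in a recipe.
    """
    ok, reason = integrity_check(spec)
    if not ok:
        raise ValueError(f"integrity check failed: {reason}")
    entry = _REGISTRY[spec.stage][spec.name]
    params = {**entry.defaults, **spec.params}
    if entry.validate is not None:
        entry.validate(params)
    applied = OperatorSpec(spec.stage, spec.name, params)

    if spec.stage == "noise_reduction":
        if not isinstance(data, Image):
            raise TypeError("noise_reduction operators take an Image")
        out = entry.func(data.pixels, **params)
        return Image(out, pixel_size=data.pixel_size,
                     provenance=data.provenance), applied
    if spec.stage == "binarisation":
        if not isinstance(data, Image):
            raise TypeError("binarisation operators take an Image")
        return BinaryMask(entry.func(data.pixels, **params)), applied
    # postprocessing
    if not isinstance(data, BinaryMask):
        raise TypeError("postprocessing operators take a BinaryMask")
    return BinaryMask(entry.func(data.pixels, **params)), applied
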