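"""Synthetic scenes with known reflectance/illumination ground truth.

Every scene obeys the multiplicative image model exactly,

    composite = 255 * reflectance_true * illumination_true,

with reflectance bounded away from zero (>= 0.2) so the constraint
L >= I > 0 is satisfiable, and illumination that is smooth in most regions
but may contain a non-smooth part (a shadow with a sharp edge and a flat
interior).  Solver accuracy is therefore directly measurable: log-domain
RMSE against the true illumination, patch statistics against the true
reflectance.

The checkerboard scene reproduces the classic checker-shadow illusion: a
dark check in direct light (patch A) and a light check inside the shadow
(patch B) are given exactly the same composite intensity (120), while their
true reflectances differ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

TEXTURE_KINDS = ("checker_fine", "stripes", "filtered_noise")
ILLUMINATION_PROFILES = ("smooth_ramp", "gaussian_spot", "sharp_shadow")


@dataclass
class SyntheticScene:
    reflectance_true: np.ndarray
    illumination_true: np.ndarray
    composite: np.ndarray
    region_masks: dict = field(default_factory=dict)
    seed: int | None = None
    params: dict = field(default_factory=dict)


def make_texture(height: int, width: int, kind: str = "filtered_noise", seed: int = 0,
                 *, cell: int = 4, period: float = 12.0, smoothing: float = 3.0) -> np.ndarray:
    """Textured reflectance field with values in [0.2, 1], seed-deterministic.

    kinds: ``checker_fine`` (two-valued fine checkerboard), ``stripes``
    (sinusoidal bands with a seeded phase), ``filtered_noise``
    (Gaussian-filtered white noise, correlation length set by ``smoothing``).
    """
    if height <= 0 or width <= 0:
        raise ValueError("dimensions must be positive")
    if kind not in TEXTURE_KINDS:
        raise ValueError(f"unknown texture kind: {kind!r}")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width]
    if kind == "checker_fine":
        board = ((yy // cell + xx // cell) % 2).astype(float)
        return 0.45 + 0.5 * board  # exactly two values: 0.45 and 0.95
    if kind == "stripes":
        phase = rng.uniform(0.0, 2.0 * np.pi)
        angle = rng.uniform(0.0, np.pi)
        coord = xx * np.cos(angle) + yy * np.sin(angle)
        return 0.625 + 0.325 * np.sin(2.0 * np.pi * coord / period + phase)
    noise = rng.standard_normal((height, width))
    sm = gaussian_filter(noise, smoothing, mode="wrap")
    lo, hi = sm.min(), sm.max()
    return 0.2 + 0.8 * (sm - lo) / max(hi - lo, 1e-12)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def make_illumination(height: int, width: int, profile: str = "smooth_ramp",
                      edge_sharpness: float = 4.0, seed: int = 0, *,
                      low: float = 0.3, high: float = 1.0,
                      spot_center: tuple | None = None,
                      spot_sigma: float | None = None) -> np.ndarray:
    """Illumination field in (0, 1].

    ``smooth_ramp``: linear ramp low -> high across columns (max gradient
    (high-low)/(width-1)); ``gaussian_spot``: bright spot over a dim floor
    (center/width seeded unless given explicitly); ``sharp_shadow``: flat
    interior at ``low`` with a transition to ``high`` narrower than
    ``edge_sharpness`` pixels.
    """
    if profile not in ILLUMINATION_PROFILES:
        raise ValueError(f"unknown illumination profile: {profile!r}")
    if edge_sharpness < 0:
        raise ValueError("edge_sharpness must be nonnegative")
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    if profile == "smooth_ramp":
        return low + (high - low) * xx / max(width - 1, 1)
    if profile == "gaussian_spot":
        rng = np.random.default_rng(seed)
        if spot_center is None:
            spot_center = (height * rng.uniform(0.4, 0.6),
                           width * rng.uniform(0.4, 0.6))
        if spot_sigma is None:
            spot_sigma = 0.25 * min(height, width)
        cy, cx = spot_center
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        return low + (high - low) * np.exp(-0.5 * r2 / spot_sigma**2)
    # sharp_shadow: shadow occupies the right part of the frame
    x0 = 0.55 * width
    wdt = max(edge_sharpness, 1e-6)
    s = _smoothstep((xx - x0) / wdt + 0.5)
    return high - (high - low) * s


def compose(reflectance_true: np.ndarray, illumination_true: np.ndarray,
            region_masks: dict | None = None, seed: int | None = None,
            params: dict | None = None) -> SyntheticScene:
    """Multiply reflectance and illumination into a [0, 255] composite."""
    r = np.asarray(reflectance_true, dtype=float)
    L = np.asarray(illumination_true, dtype=float)
    if r.shape != L.shape:
        raise ValueError("reflectance/illumination shape mismatch")
    for name, a in (("reflectance", r), ("illumination", L)):
        if np.any(a <= 0) or np.any(a > 1):
            raise ValueError(f"{name} must lie in (0, 1]")
    return SyntheticScene(
        reflectance_true=r,
        illumination_true=L,
        composite=255.0 * r * L,
        region_masks=dict(region_masks or {}),
        seed=seed,
        params=dict(params or {}),
    )


def make_shadow_scene(height: int = 128, width: int = 128,
                      texture_kind: str = "filtered_noise",
                      interior_level: float = 0.3, edge_sharpness: float = 4.0,
                      seed: int = 0) -> SyntheticScene:
    """Textured reflectance under a sharp-edged flat shadow, with masks for
    the shadow interior, exterior and boundary band."""
    r = make_texture(height, width, texture_kind, seed)
    L = make_illumination(height, width, "sharp_shadow", edge_sharpness,
                          seed, low=interior_level)
    interior = L <= interior_level + 1e-9
    exterior = L >= 1.0 - 1e-9
    boundary = ~(interior | exterior)
    masks = {"shadow_interior": interior, "shadow_exterior": exterior,
             "shadow_boundary": boundary}
    return compose(r, L, masks, seed, {
        "generator": "make_shadow_scene", "height": height, "width": width,
        "texture_kind": texture_kind, "interior_level": interior_level,
        "edge_sharpness": edge_sharpness, "seed": seed})


def make_checkerboard_shadow(size: int = 128) -> SyntheticScene:
    """Checker-shadow illusion board.

    Patch A is a dark check (true reflectance 120/255) in direct light,
    patch B a light check (true reflectance 0.85) inside a penumbral shadow
    whose interior level makes B's composite exactly 120 as well.  Masks
    'patch_a' and 'patch_b' cover the central halves of those checks;
    'shadow_interior' / 'shadow_exterior' / 'shadow_boundary' partition the
    board by the illumination.
    """
    if size < 64:
        raise ValueError("size must be at least 64 to place the patches")
    n_checks = 8
    cell = size // n_checks
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    r_dark = 120.0 / 255.0
    r_light = 0.85
    board = ((yy.astype(int) // cell + xx.astype(int) // cell) % 2)
    r = np.where(board == 0, r_light, r_dark)

    l_shadow = 120.0 / (255.0 * r_light)
    penumbra = max(size // 16, 4)
    s = _smoothstep((xx + yy - 1.25 * size) / penumbra + 0.5)
    L = 1.0 - (1.0 - l_shadow) * s

    def check_mask(row: int, col: int) -> np.ndarray:
        m = np.zeros((size, size), dtype=bool)
        q = cell // 4
        m[row * cell + q : (row + 1) * cell - q,
          col * cell + q : (col + 1) * cell - q] = True
        return m

    patch_a = check_mask(1, 2)   # dark check, fully in direct light
    patch_b = check_mask(6, 6)   # light check, fully inside the shadow
    assert np.all(L[patch_a] >= 1.0 - 1e-12)
    assert np.all(np.abs(L[patch_b] - l_shadow) <= 1e-12)

    interior = np.abs(L - l_shadow) <= 1e-9
    exterior = L >= 1.0 - 1e-9
    masks = {
        "patch_a": patch_a,
        "patch_b": patch_b,
        "shadow_interior": interior,
        "shadow_exterior": exterior,
        "shadow_boundary": ~(interior | exterior),
    }
    scene = compose(r, L, masks, seed=None,
                    params={"generator": "make_checkerboard_shadow", "size": size})
    # both marked patches print exactly 120
    assert np.allclose(scene.composite[patch_a], 120.0)
    assert np.allclose(scene.composite[patch_b], 120.0)
    return scene


# ---------------------------------------------------------------------------
# fixture persistence: PNGs plus a JSON sidecar
# ---------------------------------------------------------------------------


def _mask_to_runs(mask: np.ndarray) -> list:
    flat = np.asarray(mask, dtype=bool).ravel()
    edges = np.flatnonzero(np.diff(np.concatenate(([False], flat, [False])).astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [[int(s), int(e - s)] for s, e in zip(starts, ends)]


def _runs_to_mask(runs: list, shape) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for s, n in runs:
        flat[s : s + n] = True
    return flat.reshape(shape)


def save_scene(scene: SyntheticScene, directory, prefix: str = "scene") -> Path:
    """Write composite/reflectance/illumination as 16-bit PNGs plus a JSON
    sidecar (parameters, seed, run-length-encoded masks).  Returns the
    sidecar path."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / f"{prefix}_composite.png",
                np.round(scene.composite / 255.0 * 65535.0).astype(np.uint16))
    iio.imwrite(directory / f"{prefix}_reflectance.png",
                np.round(scene.reflectance_true * 65535.0).astype(np.uint16))
    iio.imwrite(directory / f"{prefix}_illumination.png",
                np.round(scene.illumination_true * 65535.0).astype(np.uint16))
    sidecar = {
        "seed": scene.seed,
        "params": scene.params,
        "shape": list(scene.composite.shape),
        "masks": {k: _mask_to_runs(v) for k, v in scene.region_masks.items()},
    }
    path = directory / f"{prefix}.json"
    path.write_text(json.dumps(sidecar))
    return path


def load_scene(sidecar_path) -> SyntheticScene:
    """Rebuild a scene from its sidecar by re-running its generator, so the
    ground truth is exact (not quantized); masks come from the sidecar."""
    meta = json.loads(Path(sidecar_path).read_text())
    params = dict(meta["params"])
    gen = params.pop("generator", None)
    if gen == "make_shadow_scene":
        scene = make_shadow_scene(**params)
    elif gen == "make_checkerboard_shadow":
        scene = make_checkerboard_shadow(**params)
    else:
        raise ValueError(f"sidecar does not name a known generator: {gen!r}")
    shape = tuple(meta["shape"])
    scene.region_masks = {k: _runs_to_mask(v, shape) for k, v in meta["masks"].items()}
    return scene
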