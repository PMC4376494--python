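"""Seeded synthetic fundus phantoms with known vessel and bias ground truth.

Vessels are tree-structured random walks seeded on the aperture rim; the
rendered cross-section is a Gaussian-shaped intensity dip, the illumination
inhomogeneity is a smooth low-frequency multiplicative field applied in the
log domain, and pixel noise is additive Gaussian.  Everything is deterministic
given the spec seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = ["PhantomSpec", "RenderResult", "generate_vessel_tree",
           "render_fundus", "generate_phantom"]

#: acceptable vessel-pixel fraction of the aperture area
VESSEL_FRACTION_RANGE = (0.05, 0.18)

#: per-channel background level and vessel-contrast scale (green carries full contrast)
_CHANNELS = ((185.0, 0.5), (160.0, 1.0), (100.0, 0.3))

# vessels thinner than ~4 px would not survive the pipeline's radius-1
# morphological opening, so walks terminate at this half-width
_MIN_HALF_WIDTH = 2.0
def _centerline_budget(spec: "PhantomSpec", aperture_area: int) -> int:
    """Centerline-point budget aiming at the middle of the fraction window.

    Branching walks would otherwise fill the aperture; the budget stops growth
    once roughly ``target_fraction`` of the aperture would be vessel.
    """
    target = 0.5 * (VESSEL_FRACTION_RANGE[0] + VESSEL_FRACTION_RANGE[1])
    mean_width = 1.2 * spec.width_root  # rough average over generations, ~2*hw_mean
    return max(100, int(target * aperture_area / mean_width))


@dataclass
class PhantomSpec:
    width: int = 512
    height: int = 512
    n_trees: int = 4
    branch_prob: float = 0.08
    width_root: float = 4.0
    width_decay: float = 0.8
    vessel_contrast: float = 0.35
    profile_sigma_factor: float = 0.7
    bias_amplitude: float = 0.5
    noise_sigma: float = 4.0
    aperture_radius: float = 240.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1 or self.aperture_radius <= 0:
            raise ConfigurationError("dimensions must be positive")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ConfigurationError("branch_prob must be in [0, 1]")
        if not 0.0 < self.width_decay <= 1.0:
            raise ConfigurationError("width_decay must be in (0, 1]")
        if self.width_root > self.aperture_radius:
            raise ConfigurationError("width_root exceeds the aperture radius")
        if self.n_trees < 0 or self.noise_sigma < 0 or self.bias_amplitude < 0:
            raise ConfigurationError("counts and amplitudes must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RenderResult:
    image: np.ndarray       # H x W x 3 float in [0, 255]
    bias_truth: np.ndarray  # H x W log-domain field
    fov: np.ndarray         # H x W bool aperture mask
    clean: np.ndarray       # H x W x 3 uncorrupted image (no bias, no noise)


def _aperture_mask(spec: PhantomSpec) -> np.ndarray:
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    cy, cx = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.aperture_radius ** 2


def _walk_tree(rng: np.random.Generator, spec: PhantomSpec,
               budget: list, rim_angle: float | None = None) -> list:
    """Random branching walk from a rim seed point; returns centerline paths.

    Each path is an array of (row, col, half_width) triples sampled at ~1 px
    steps.  At a branching event the parent terminates and two children
    continue with decayed width.
    """
    cy, cx = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    theta = rng.uniform(0.0, 2.0 * np.pi) if rim_angle is None else rim_angle
    start = np.array([cy + (spec.aperture_radius - 2.0) * np.sin(theta),
                      cx + (spec.aperture_radius - 2.0) * np.cos(theta)])
    heading = theta + np.pi + rng.normal(0.0, 0.3)

    paths = []
    stack = [(start, heading, float(spec.width_root))]
    while stack:
        pos, ang, hw = stack.pop()
        pts = []
        while hw >= _MIN_HALF_WIDTH and budget[0] > 0:
            pos = pos + np.array([np.sin(ang), np.cos(ang)])
            rad = np.hypot(pos[0] - cy, pos[1] - cx)
            if rad > spec.aperture_radius - 1.0:
                break
            pts.append((pos[0], pos[1], hw))
            budget[0] -= 1
            # meander with an inward pull so trees cross the disc instead of
            # clustering at the rim
            inward = np.arctan2(cy - pos[0], cx - pos[1])
            turn = rng.normal(0.0, 0.03)
            pull = 0.02 * np.sin(inward - ang) * (rad / spec.aperture_radius)
            ang = ang + turn + pull
            hw *= 0.9995
            if rng.random() < spec.branch_prob:
                split = rng.uniform(0.3, 0.8) * (1 if rng.random() < 0.5 else -1)
                child_hw = hw * spec.width_decay
                if child_hw >= _MIN_HALF_WIDTH:
                    stack.append((pos.copy(), ang + split, child_hw))
                ang -= 0.2 * split  # parent recoils slightly and keeps going
        if pts:
            paths.append(np.asarray(pts))
    return paths


def _stamp_disks(mask: np.ndarray, paths: list) -> None:
    h, w = mask.shape
    for path in paths:
        for y, x, hw in path:
            r = int(np.ceil(hw))
            y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 2)
            x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 2)
            if y0 >= y1 or x0 >= x1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            mask[y0:y1, x0:x1] |= (yy - y) ** 2 + (xx - x) ** 2 <= hw * hw


def generate_vessel_tree(spec: PhantomSpec) -> tuple:
    """Generate a branching vessel ground truth.

    Returns ``(truth_mask, centerlines)`` where ``centerlines`` is a list of
    (row, col, half_width) arrays.  The vessel-pixel fraction of the aperture
    area is forced into ``VESSEL_FRACTION_RANGE`` by regenerating with a
    perturbed seed (bit-identical output for identical specs).
    """
    aperture = _aperture_mask(spec)
    aperture_area = int(aperture.sum())
    if spec.n_trees == 0:
        return np.zeros((spec.height, spec.width), dtype=bool), []

    lo, hi = VESSEL_FRACTION_RANGE
    for attempt in range(40):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, attempt]))
        total_budget = _centerline_budget(spec, aperture_area)
        base = rng.uniform(0.0, 2.0 * np.pi)
        paths = []
        for i in range(spec.n_trees):
            # stratified rim angles keep trees from crowding one sector
            angle = base + 2.0 * np.pi * (i + rng.uniform(-0.25, 0.25)) / spec.n_trees
            budget = [total_budget // spec.n_trees]
            paths.extend(_walk_tree(rng, spec, budget, rim_angle=angle))
        mask = np.zeros((spec.height, spec.width), dtype=bool)
        _stamp_disks(mask, paths)
        mask &= aperture
        fraction = mask.sum() / aperture_area
        if lo <= fraction <= hi:
            return mask, paths
    raise ConfigurationError(
        "could not reach the target vessel fraction; adjust the phantom spec")


def _bias_surface(rng: np.random.Generator, spec: PhantomSpec,
                  fov: np.ndarray) -> np.ndarray:
    """Smooth band-limited log-domain field with the requested range."""
    if spec.bias_amplitude == 0:
        return np.zeros((spec.height, spec.width))
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    u = xx / max(spec.width - 1, 1)
    v = yy / max(spec.height - 1, 1)
    g = np.zeros((spec.height, spec.width))
    freqs = [(1, 0), (0, 1), (1, 1), (2, 0), (0, 2), (2, 1), (1, 2)]
    for fx, fy in freqs:
        amp = rng.normal(0.0, 1.0) / (fx + fy)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        g += amp * np.cos(2.0 * np.pi * (fx * u + fy * v) + phase)
    rng_range = g.max() - g.min()
    g *= spec.bias_amplitude / rng_range
    g -= g[fov].mean()
    return g


def render_fundus(truth: np.ndarray, centerlines: list,
                  spec: PhantomSpec) -> RenderResult:
    """Render a colour fundus phantom from a vessel ground truth.

    The uncorrupted image is a constant background with Gaussian-profile
    intensity dips along the centerlines; it is multiplied by
    ``exp(bias_truth)``, Gaussian noise is added, values are clipped to
    [0, 255] and zeroed outside the aperture.
    """
    truth = np.asarray(truth, dtype=bool)
    if truth.shape != (spec.height, spec.width):
        raise ConfigurationError("truth mask shape does not match spec dimensions")
    h, w = truth.shape
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 977]))
    fov = _aperture_mask(spec)

    depth = np.zeros((h, w))
    for path in centerlines:
        for y, x, hw in path:
            sigma = max(spec.profile_sigma_factor * hw, 0.5)
            r = int(np.ceil(hw + 3.0 * sigma))
            y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 2)
            x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 2)
            if y0 >= y1 or x0 >= x1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d2 = (yy - y) ** 2 + (xx - x) ** 2
            block = depth[y0:y1, x0:x1]
            np.maximum(block, np.exp(-0.5 * d2 / (sigma * sigma)), out=block)

    bias = _bias_surface(rng, spec, fov)
    gain = np.exp(bias)

    clean = np.zeros((h, w, 3))
    image = np.zeros((h, w, 3))
    for c, (level, contrast_scale) in enumerate(_CHANNELS):
        chan = level * (1.0 - spec.vessel_contrast * contrast_scale * depth)
        clean[:, :, c] = chan
        noisy = chan * gain + rng.normal(0.0, spec.noise_sigma, size=(h, w))
        image[:, :, c] = np.clip(noisy, 0.0, 255.0)
    clean *= fov[:, :, None]
    image *= fov[:, :, None]
    return RenderResult(image=image, bias_truth=bias, fov=fov, clean=clean)


def generate_phantom(spec: PhantomSpec) -> tuple:
    """Convenience wrapper: returns ``(truth_mask, centerlines, RenderResult)``."""
    truth, centerlines = generate_vessel_tree(spec)
    return truth, centerlines, render_fundus(truth, centerlines, spec)
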