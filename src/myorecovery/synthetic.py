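"""Synthetic data generators: tissue phantoms, feature simulations, augmentation.

No public image dataset accompanies the muscle-regeneration study this
package reimplements, so everything is testable against synthetic inputs
with exact ground truth:

* **Tissue phantoms** — white-background rasters populated by
  dart-throwing non-overlapping cells whose appearance mimics the four
  recovery phases of cardiotoxin-injured muscle (stable: large packed
  pink polygons; early: large pale "ghost fiber" outlines; mid: small
  round dark myoblasts; late: medium myotubes with a central nucleus
  dot), together with the exact label mask, per-cell classes, a rough
  palette annotation and the realized class-pixel proportions.
* **Feature simulations** — class-conditional isotropic Gaussian
  instances with day-indexed mixing proportions: the statistical
  structure the proportion-loss training assumes, with controllable
  class-mean separation.
* **The augmentation scheme** — each square training image yields 16
  variants: 4 right-angle rotations x {flip, no flip} (8 geometric
  variants), each emitted as-is and once more with photometric jitter
  (brightness / contrast / gamma each applied with probability 0.5).
* **Random crops** — 100 random 64 px crops per 256 px grid image is the
  reference cropping scheme for classifier training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk, polygon

from .scheme import ClassScheme, DEFAULT_SCHEME

#: day -> class-proportion schedule emulating recovery after cardiotoxin
#: injury: day 0 pre-injury (all stable), day 3 dominated by ghost fibers
#: (early), day 5 by proliferating myoblasts (mid), day 7 by young
#: myotubes (late).  By day 14 regeneration is well advanced but most
#: fibers still carry central myonuclei — the defining late-phase
#: appearance — so the late class dominates with partial restabilization.
DEFAULT_RECOVERY_SCHEDULE: dict[int, tuple[float, ...]] = {
    0: (1.00, 0.00, 0.00, 0.00),
    3: (0.05, 0.75, 0.15, 0.05),
    5: (0.05, 0.25, 0.50, 0.20),
    7: (0.06, 0.06, 0.33, 0.55),
    14: (0.25, 0.02, 0.08, 0.65),
}


# ---------------------------------------------------------------------------
# feature simulation

@dataclass
class FeatureSimConfig:
    """Class-conditional Gaussian feature simulation.

    ``separation`` is the minimum pairwise Euclidean distance between
    class means in units of the shared isotropic ``sigma``; means are
    placed at (separation / sqrt(2)) * e_k so all pairwise distances
    equal ``separation * sigma`` exactly.
    """

    D: int = 32
    K: int = 4
    separation: float = 6.0
    sigma: float = 1.0
    schedule: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_RECOVERY_SCHEDULE)
    )
    n_per_day: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for day, p in self.schedule.items():
            p = np.asarray(p, dtype=np.float64)
            if len(p) != self.K or p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"day {day}: mixing proportions not on the simplex")

    def class_means(self) -> np.ndarray:
        means = np.zeros((self.K, self.D))
        scale = self.separation * self.sigma / np.sqrt(2.0)
        for k in range(self.K):
            means[k, k % self.D] = scale
        return means


def generate_feature_dataset(config: FeatureSimConfig):
    """Draw (features, day_labels, true_classes) from the simulation.

    For each day, classes follow that day's mixing proportions and
    features are Gaussian around the class mean.  Fully seeded.
    """
    rng = np.random.default_rng(config.seed)
    means = config.class_means()
    feats, days, classes = [], [], []
    for day in sorted(config.schedule):
        p = np.asarray(config.schedule[day], dtype=np.float64)
        cls = rng.choice(config.K, size=config.n_per_day, p=p / p.sum())
        x = means[cls] + rng.normal(0.0, config.sigma, size=(config.n_per_day, config.D))
        feats.append(x)
        days.append(np.full(config.n_per_day, day))
        classes.append(cls)
    return (np.vstack(feats), np.concatenate(days), np.concatenate(classes))


# ---------------------------------------------------------------------------
# tissue phantoms

#: per-phase appearance: (radius range, fill RGB, edge RGB, central dot)
_PHASE_STYLE = {
    0: ((12, 20), (232, 158, 168), (178, 92, 110), False),  # stable fibers
    1: ((10, 16), (226, 221, 240), (198, 192, 224), False), # early: pale ghosts
    2: ((3, 5), (96, 62, 122), (96, 62, 122), False),       # mid: dark myoblasts
    3: ((7, 10), (204, 128, 158), (160, 86, 120), True),    # late: central nucleus
}


@dataclass
class PhantomConfig:
    """Configuration of one synthetic tissue slide."""

    size: tuple[int, int] = (512, 512)
    day: int = 0
    target_proportions: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0)
    cell_pixel_budget: float = 0.30  # fraction of canvas covered by cells
    background: tuple[int, int, int] = (250, 224, 232)  # pale eosin wash
    noise_level: float = 2.0
    pen_scale: float = 1.35  # rough-annotation pen radius / cell radius
    n_zone_seeds: int = 12   # Voronoi seeds forming contiguous class zones
    proportion_tolerance: float = 0.05
    max_attempts: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.target_proportions, dtype=np.float64)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("target proportions must lie on the simplex")


@dataclass
class PhantomSample:
    """One phantom slide with exact ground truth."""

    image: np.ndarray                    # (H, W, 3) uint8
    gt_mask: np.ndarray                  # (H, W) int32 label mask
    gt_classes: dict[int, int]           # cell_id -> class index
    rough_annotation: np.ndarray         # (H, W, 3) uint8 palette raster
    realized_proportions: np.ndarray     # per-class gt pixel proportions
    config: PhantomConfig
    day: int = 0


def _cell_footprint(rng, style, cy, cx, shape):
    (rmin, rmax), _, _, _ = style
    r = rng.uniform(rmin, rmax)
    if rmax >= 12:  # large fibers: jittered polygon, roughly convex
        ang = np.sort(rng.uniform(0, 2 * np.pi, size=8))
        rad = r * rng.uniform(0.75, 1.15, size=8)
        rr, cc = polygon(cy + rad * np.sin(ang), cx + rad * np.cos(ang), shape=shape)
    else:
        rr, cc = disk((cy, cx), r, shape=shape)
    return rr, cc, r


def _class_zones(rng, shape, targets, n_seeds):
    """Voronoi partition of the canvas into contiguous per-class zones.

    Recovery phases appear in spatially contiguous foci in real tissue
    (necrotic patches, regenerating areas), so each class gets a number
    of Voronoi seeds roughly proportional to its target share and cells
    are placed inside their class's zone.
    """
    h, w = shape
    active = [k for k, p in enumerate(targets) if p > 0]
    seed_classes = []
    for k in active:
        seed_classes += [k] * max(1, int(round(n_seeds * targets[k])))
    pts = rng.uniform(0, 1, size=(len(seed_classes), 2)) * np.array([h, w])
    yy, xx = np.indices((h, w))
    d2 = (yy[..., None] - pts[:, 0]) ** 2 + (xx[..., None] - pts[:, 1]) ** 2
    return np.asarray(seed_classes)[d2.argmin(axis=2)]


def generate_tissue_phantom(config: PhantomConfig) -> PhantomSample:
    """Dart-throw non-overlapping phase-typical cells onto a stained canvas.

    The canvas is first partitioned into contiguous per-class zones
    (classes cluster spatially, as recovery phases do in tissue); cells
    of each class are then placed inside their zone until that class's
    share of the cell pixel budget is met (within the configured
    tolerance) or the attempt budget is exhausted, in which case the
    realized proportions are still reported exactly.  Everything is
    driven by the config seed.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.size
    img = np.zeros((h, w, 3), dtype=np.float64)
    img[:] = config.background
    gt = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)
    annot = np.full((h, w, 3), 255, dtype=np.uint8)
    scheme = DEFAULT_SCHEME

    targets = np.asarray(config.target_proportions, dtype=np.float64)
    zones = _class_zones(rng, (h, w), targets, config.n_zone_seeds)
    budget_total = config.cell_pixel_budget * h * w
    budgets = targets * budget_total
    placed = np.zeros(len(targets))
    gt_classes: dict[int, int] = {}
    next_id = 1

    # place large classes first so small cells can fill the gaps
    order = sorted(range(len(targets)), key=lambda k: -_PHASE_STYLE[k][0][1])
    for k in order:
        if budgets[k] <= 0:
            continue
        style = _PHASE_STYLE[k]
        zy, zx = np.nonzero(zones == k)
        if len(zy) == 0:
            continue
        attempts = 0
        while placed[k] < budgets[k] and attempts < config.max_attempts:
            attempts += 1
            j = int(rng.integers(len(zy)))
            cy = float(np.clip(zy[j] + rng.uniform(-2, 2), style[0][1], h - style[0][1]))
            cx = float(np.clip(zx[j] + rng.uniform(-2, 2), style[0][1], w - style[0][1]))
            rr, cc, r = _cell_footprint(rng, style, cy, cx, (h, w))
            if len(rr) == 0 or occupied[rr, cc].any():
                continue
            # local footprint mask (bbox + 2 px margin) for cheap morphology
            y0b, x0b = rr.min() - 2, cc.min() - 2
            y1b, x1b = rr.max() + 3, cc.max() + 3
            y0b, x0b = max(0, y0b), max(0, x0b)
            y1b, x1b = min(h, y1b), min(w, x1b)
            local = np.zeros((y1b - y0b, x1b - x0b), dtype=bool)
            local[rr - y0b, cc - x0b] = True
            # 2 px clearance so neighbouring cells stay separable
            grown = ndi.binary_dilation(local, iterations=2)
            if (occupied[y0b:y1b, x0b:x1b] & grown).any():
                continue
            occupied[y0b:y1b, x0b:x1b] |= grown
            gt[rr, cc] = next_id
            _, fill, edge, dot = style
            img[rr, cc] = fill
            # darker boundary ring: footprint pixels near its border
            ring = local & ~ndi.binary_erosion(local, iterations=2)
            img[y0b:y1b, x0b:x1b][ring] = edge
            if dot:
                dr, dc = disk((cy, cx), max(1.5, r * 0.25), shape=(h, w))
                img[dr, dc] = (70, 46, 88)
            # pen radius proportional to the cell so annotated area stays
            # roughly proportional to true class pixel area
            ar, ac = disk((cy, cx), r * config.pen_scale + 1.5, shape=(h, w))
            annot[ar, ac] = scheme.colors[k]
            placed[k] += len(rr)
            gt_classes[next_id] = k
            next_id += 1

    if config.noise_level > 0:
        img += rng.normal(0.0, config.noise_level, size=img.shape)
    image = np.clip(img, 0, 255).astype(np.uint8)

    total = placed.sum()
    realized = placed / total if total > 0 else np.full(len(targets), np.nan)
    return PhantomSample(
        image=image,
        gt_mask=gt,
        gt_classes=gt_classes,
        rough_annotation=annot,
        realized_proportions=realized,
        config=config,
        day=config.day,
    )


def phantom_day_series(
    days=None,
    schedule: dict[int, tuple[float, ...]] | None = None,
    size: tuple[int, int] = (512, 512),
    seed: int = 0,
    **kwargs,
) -> dict[int, PhantomSample]:
    """One phantom slide per recovery day following the mixing schedule."""
    schedule = dict(schedule or DEFAULT_RECOVERY_SCHEDULE)
    days = list(days) if days is not None else sorted(schedule)
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(len(days)) % (2**31)
    out = {}
    for day, s in zip(days, child):
        cfg = PhantomConfig(
            size=size, day=day, target_proportions=tuple(schedule[day]),
            seed=int(s), **kwargs,
        )
        out[day] = generate_tissue_phantom(cfg)
    return out


# ---------------------------------------------------------------------------
# augmentation and cropping

def _geometric_variants(image: np.ndarray):
    for k in range(4):
        rot = np.rot90(image, k)
        yield rot
        yield rot[:, ::-1]


def _photometric_jitter(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Brightness / contrast / gamma, each applied with probability 0.5."""
    out = image.astype(np.float64) / 255.0
    if rng.random() < 0.5:  # brightness shift
        out = out + rng.uniform(-0.2, 0.2)
    if rng.random() < 0.5:  # contrast around mid-gray
        out = 0.5 + (out - 0.5) * rng.uniform(0.8, 1.2)
    if rng.random() < 0.5:  # gamma
        out = np.clip(out, 0.0, 1.0) ** rng.uniform(0.8, 1.25)
    return (np.clip(out, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def augment_geometric_photometric(images, seed: int = 0, masks=None):
    """x16 augmentation of square training images.

    Each input yields its 8 geometric variants (4 right-angle rotations x
    {no flip, horizontal flip}) plus one seeded photometric-jitter copy
    of each variant — 16 outputs per input.  When ``masks`` is given the
    geometric transforms are applied to them in lockstep (photometric
    copies reuse the geometric mask), so image/mask pairs stay aligned.
    """
    rng = np.random.default_rng(seed)
    out_images, out_masks = [], []
    for i, image in enumerate(images):
        image = np.asarray(image)
        if image.shape[0] != image.shape[1]:
            raise ValueError("augmentation expects square rasters")
        mask = np.asarray(masks[i]) if masks is not None else None
        geo_masks = list(_geometric_variants(mask)) if mask is not None else None
        for g, var in enumerate(_geometric_variants(image)):
            out_images.append(var.copy())
            out_images.append(_photometric_jitter(var, rng))
            if geo_masks is not None:
                out_masks.append(geo_masks[g].copy())
                out_masks.append(geo_masks[g].copy())
    if masks is not None:
        return out_images, out_masks
    return out_images


def random_crops(tile: np.ndarray, n: int = 100, size: int = 64, seed: int = 0):
    """n random size-square crops fully inside a tile (seeded uniform)."""
    tile = np.asarray(tile)
    h, w = tile.shape[:2]
    if size > h or size > w:
        raise ValueError(f"crop size {size} exceeds tile side ({h}, {w})")
    rng = np.random.default_rng(seed)
    crops = []
    for _ in range(n):
        y = int(rng.integers(0, h - size + 1))
        x = int(rng.integers(0, w - size + 1))
        crops.append(tile[y : y + size, x : x + size].copy())
    return crops
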