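"""Synthetic visual sets: binary images of object arrays with controlled numerosity.

The generator produces small binary rasters containing ``n`` disjoint objects
(axis-aligned rectangles by default) while controlling the continuous visual
properties that naturally covary with numerosity: cumulative surface area
(total count of "on" pixels), total contour length, and individual item size.
Comparison pairs can be built so that all three continuous properties are
*congruent* with the numerosity difference (more items -> more area, longer
contour, bigger items), *incongruent* (all three reversed), or left
uncontrolled.

Conventions
-----------
* objects are 4-connected components of on pixels; distinct objects never
  touch, not even diagonally, so the component count is unambiguous;
* contour length counts object pixels with at least one off 4-neighbour
  (pixels outside the grid count as off);
* all randomness flows through a ``numpy.random.Generator``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image as PILImage
from scipy import ndimage

GRID_SIDE = 30
MAX_NUMEROSITY = 32
#: cumulative-area levels crossed with numerosity in the default corpus,
#: decorrelating total area from object count across the training set.
AREA_LEVELS = (32, 64, 96)
#: numerosity ratios used for the comparison task (small:large).
COMPARISON_RATIOS = ((1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7))

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class PlacementError(RuntimeError):
    """Object placement failed: too many objects / too much area for the grid."""


class CongruencyError(ValueError):
    """A congruency-controlled pair could not satisfy its sign constraints."""


def _as_pixel_array(image) -> np.ndarray:
    pixels = image.pixels if isinstance(image, StimulusImage) else np.asarray(image)
    if pixels.ndim != 2:
        raise ValueError("expected a 2D binary grid")
    return (pixels != 0)


def count_objects(image) -> int:
    """Number of 4-connected components of on pixels (ground-truth count)."""
    _, n = ndimage.label(_as_pixel_array(image), structure=_FOUR_CONN)
    return int(n)


def contour_length(image) -> int:
    """Count of on pixels having at least one off 4-neighbour (border = off)."""
    pix = _as_pixel_array(image)
    padded = np.pad(pix, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return int((pix & ~interior).sum())


@dataclass(frozen=True)
class StimulusImage:
    """A binary raster of disjoint objects with ground-truth metadata.

    Attributes
    ----------
    pixels : (H, W) uint8 array of {0, 1}
    numerosity : number of objects (4-connected components)
    cumulative_area : total on-pixel count
    contour_length : total count of object boundary pixels
    item_areas : per-object pixel counts, in placement order
    seed_tag : identifier of the random stream that produced the image
    """

    pixels: np.ndarray
    numerosity: int
    cumulative_area: int
    contour_length: int
    item_areas: tuple[int, ...]
    seed_tag: str = ""

    @classmethod
    def from_pixels(cls, pixels, item_areas=None, seed_tag="") -> "StimulusImage":
        """Build an image whose metadata is recomputed from the pixels."""
        pix = _as_pixel_array(pixels).astype(np.uint8)
        n = count_objects(pix)
        area = int(pix.sum())
        if item_areas is None:
            labels, _ = ndimage.label(pix, structure=_FOUR_CONN)
            item_areas = tuple(
                int(a) for a in np.bincount(labels.ravel())[1:] if a > 0
            )
        item_areas = tuple(int(a) for a in item_areas)
        if sum(item_areas) != area:
            raise ValueError("item_areas inconsistent with on-pixel count")
        if len(item_areas) != n:
            raise ValueError("item_areas inconsistent with component count")
        pix.setflags(write=False)
        return cls(
            pixels=pix,
            numerosity=n,
            cumulative_area=area,
            contour_length=contour_length(pix),
            item_areas=item_areas,
            seed_tag=str(seed_tag),
        )

    @property
    def mean_item_area(self) -> float:
        return self.cumulative_area / self.numerosity if self.numerosity else 0.0


# ---------------------------------------------------------------------------
# single-image generation
# ---------------------------------------------------------------------------

def _partition_area(n: int, total: int, rng: np.random.Generator,
                    max_item: int) -> list[int]:
    """Split ``total`` pixels over ``n`` items, each in [1, max_item]."""
    if total < n or total > n * max_item:
        raise PlacementError(
            f"cannot split area {total} over {n} items (max item {max_item})"
        )
    areas = np.ones(n, dtype=int)
    remaining = total - n
    while remaining > 0:
        open_items = np.flatnonzero(areas < max_item)
        take = rng.choice(open_items)
        areas[take] += 1
        remaining -= 1
    return [int(a) for a in areas]


def _rect_dims(area: int, rng: np.random.Generator, side: int) -> tuple[int, int]:
    """Pick (height, width) with height*width == area, fitting the grid."""
    limit = side - 2
    options = []
    for h in range(1, int(np.sqrt(area)) + 1):
        if area % h == 0:
            w = area // h
            if h <= limit and w <= limit:
                options.append((h, w))
                if w != h and w <= limit and h <= limit:
                    options.append((w, h))
    if not options:
        raise PlacementError(f"item area {area} has no rectangle fitting the grid")
    return options[rng.integers(len(options))]


_SHAPE_FAMILIES = ("rect",)


def generate_image(n: int, area_target="free", shape_family: str = "rect",
                   rng: np.random.Generator | None = None, side: int = GRID_SIDE,
                   max_item_area: int | None = None, retries: int = 1000,
                   seed_tag: str = "") -> StimulusImage:
    """Generate one binary image with exactly ``n`` disjoint objects.

    Parameters
    ----------
    n : requested numerosity (>= 1).
    area_target : exact cumulative area in pixels, or ``"free"`` to draw each
        item's area uniformly from [1, 16] (the widest item-size spread that
        still packs at the maximum numerosity).
    shape_family : object shape family; only axis-aligned rectangles for now.
    max_item_area : optional cap on single-item area.
    retries : per-object placement attempts before declaring infeasibility.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n < 1:
        raise ValueError(f"numerosity must be >= 1, got {n}")
    if shape_family not in _SHAPE_FAMILIES:
        raise ValueError(f"unknown shape family {shape_family!r}")
    cap = max_item_area if max_item_area is not None else (side - 2) ** 2

    for _attempt in range(20):
        if area_target == "free":
            areas = [int(rng.integers(1, 17)) for _ in range(n)]
        else:
            areas = _partition_area(n, int(area_target), rng, cap)
        try:
            dims = [_rect_dims(a, rng, side) for a in areas]
        except PlacementError:
            continue
        # place big items first: greatly improves packing success
        order = np.argsort([-a for a in areas], kind="stable")
        occupied = np.zeros((side, side), dtype=bool)
        pixels = np.zeros((side, side), dtype=np.uint8)
        ok = True
        for idx in order:
            h, w = dims[idx]
            placed = False
            for _try in range(retries):
                r = int(rng.integers(0, side - h + 1))
                c = int(rng.integers(0, side - w + 1))
                r0, c0 = max(r - 1, 0), max(c - 1, 0)
                if occupied[r0:r + h + 1, c0:c + w + 1].any():
                    continue
                occupied[r:r + h, c:c + w] = True
                pixels[r:r + h, c:c + w] = 1
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return StimulusImage.from_pixels(
                pixels, item_areas=tuple(areas), seed_tag=seed_tag
            )
    raise PlacementError(
        f"could not place {n} objects (area_target={area_target!r}) "
        f"on a {side}x{side} grid"
    )


# ---------------------------------------------------------------------------
# corpora
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorpusSpec:
    """Recipe for a reproducible corpus of object-set images."""

    image_count: int
    numerosity_range: tuple[int, int] = (1, MAX_NUMEROSITY)
    image_side: int = GRID_SIDE
    area_levels: tuple[int, ...] = AREA_LEVELS
    shape_family: str = "rect"
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.numerosity_range
        if self.image_count <= 0:
            raise ValueError("image_count must be positive")
        if not (1 <= lo <= hi <= MAX_NUMEROSITY):
            raise ValueError(
                f"numerosity_range must lie within [1, {MAX_NUMEROSITY}]"
            )


def generate_corpus(spec: CorpusSpec) -> list[StimulusImage]:
    """Generate ``spec.image_count`` images, numerosity and area levels crossed.

    Numerosities are drawn uniformly over the range; the cumulative-area level
    is drawn uniformly among the feasible levels (level >= numerosity), which
    decorrelates total area from numerosity across the corpus.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.numerosity_range
    images = []
    for i in range(spec.image_count):
        n = int(rng.integers(lo, hi + 1))
        feasible = [a for a in spec.area_levels if a >= n]
        area = int(rng.choice(feasible)) if feasible else "free"
        try:
            images.append(
                generate_image(
                    n, area_target=area, shape_family=spec.shape_family,
                    rng=rng, side=spec.image_side,
                    seed_tag=f"{spec.seed}:{i}",
                )
            )
        except PlacementError as err:
            raise PlacementError(f"image {i}: {err}") from err
    return images


# ---------------------------------------------------------------------------
# comparison pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusPair:
    """Two images for the comparison task.

    ``ratio`` is min(N)/max(N) in (0, 1); ``correct_side`` is the side with
    the larger numerosity; ``congruency`` records how the continuous
    properties relate to the numerosity difference.
    """

    left: StimulusImage
    right: StimulusImage
    ratio: float
    ratio_frac: tuple[int, int]
    correct_side: str  # "left" | "right"
    congruency: str    # "congruent" | "incongruent" | "uncontrolled"

    def __post_init__(self):
        if self.left.numerosity == self.right.numerosity:
            raise ValueError("comparison pairs require distinct numerosities")
        larger = "left" if self.left.numerosity > self.right.numerosity else "right"
        if self.correct_side != larger:
            raise ValueError("correct_side inconsistent with numerosities")


def _normalize_ratio(ratio) -> tuple[int, int]:
    if isinstance(ratio, str):
        p, q = (int(x) for x in ratio.split(":"))
    elif isinstance(ratio, Fraction):
        p, q = ratio.numerator, ratio.denominator
    else:
        p, q = (int(x) for x in ratio)
    f = Fraction(p, q)
    p, q = f.numerator, f.denominator
    if p > q:
        p, q = q, p
    if p == q:
        raise ValueError("ratio 1:1 is not a comparison (equal numerosities)")
    return p, q


def _make_pair(small: StimulusImage, large: StimulusImage, p: int, q: int,
               congruency: str, rng: np.random.Generator) -> StimulusPair:
    if rng.random() < 0.5:
        left, right, correct = large, small, "left"
    else:
        left, right, correct = small, large, "right"
    return StimulusPair(
        left=left, right=right, ratio=p / q, ratio_frac=(p, q),
        correct_side=correct, congruency=congruency,
    )


def _property_signs(small: StimulusImage, large: StimulusImage):
    """Signs of (large - small) for area, contour and mean item area."""
    return (
        np.sign(large.cumulative_area - small.cumulative_area),
        np.sign(large.contour_length - small.contour_length),
        np.sign(large.mean_item_area - small.mean_item_area),
    )


def generate_congruency_pairs(ratio, congruency: str, count: int,
                              rng: np.random.Generator | None = None,
                              side: int = GRID_SIDE,
                              max_numerosity: int = MAX_NUMEROSITY,
                              retries: int = 200) -> list[StimulusPair]:
    """Build comparison pairs with congruency-controlled continuous cues.

    ``uncontrolled`` draws every item's area from the shared free item-size
    distribution, so continuous properties covary with numerosity only
    statistically (the natural stimulus regime). ``congruent`` pairs are
    rejection-sampled from that same distribution until cumulative area,
    contour length and mean item area are all strictly larger in the more
    numerous image. ``incongruent`` pairs reverse all three signs by the
    minimal sufficient perturbation: the less numerous image receives a
    cumulative area only slightly above the other side's, keeping the
    stimuli as close to the natural regime as the reversal allows.
    Constraints are verified by recomputing every property from the pixels;
    an unsatisfiable request raises :class:`CongruencyError` naming the
    violated property.
    """
    if rng is None:
        rng = np.random.default_rng()
    if congruency not in ("congruent", "incongruent", "uncontrolled"):
        raise ValueError(f"unknown congruency {congruency!r}")
    if count < 1:
        raise ValueError("count must be >= 1")
    p, q = _normalize_ratio(ratio)
    k_max = max_numerosity // q
    if k_max < 1:
        raise CongruencyError(f"ratio {p}:{q} needs numerosity > {max_numerosity}")

    pairs = []
    names = ("cumulative_area", "contour_length", "mean_item_area")
    for _ in range(count):
        last_violation = None
        for _try in range(retries):
            k = int(rng.integers(1, k_max + 1))
            n_s, n_l = p * k, q * k
            if congruency in ("uncontrolled", "congruent"):
                area_s = area_l = "free"
            else:  # incongruent: minimal sufficient reversal of all cues
                m_l = rng.uniform(1.0, 2.5)
                area_l = max(n_l, round(n_l * m_l))
                area_s = int(np.ceil(area_l * rng.uniform(1.05, 1.3)))
                if area_s > 16 * n_s:   # outside the free item-size range
                    continue
            try:
                small = generate_image(n_s, area_target=area_s, rng=rng, side=side)
                large = generate_image(n_l, area_target=area_l, rng=rng, side=side)
            except PlacementError as err:
                last_violation = str(err)
                continue
            if congruency == "uncontrolled":
                pairs.append(_make_pair(small, large, p, q, congruency, rng))
                break
            signs = _property_signs(small, large)
            want = 1 if congruency == "congruent" else -1
            bad = [nm for nm, s in zip(names, signs) if s != want]
            if not bad:
                pairs.append(_make_pair(small, large, p, q, congruency, rng))
                break
            last_violation = f"sign constraint failed for {bad[0]}"
        else:
            raise CongruencyError(
                f"{congruency} pair at ratio {p}:{q} infeasible: {last_violation}"
            )
    return pairs


def generate_comparison_pairs(ratios: Iterable = COMPARISON_RATIOS,
                              count_per_ratio: int = 100,
                              congruency: str = "uncontrolled",
                              rng: np.random.Generator | None = None,
                              side: int = GRID_SIDE) -> list[StimulusPair]:
    """Pairs across several ratios (the comparison-task stimulus set)."""
    if rng is None:
        rng = np.random.default_rng()
    pairs = []
    for ratio in ratios:
        pairs.extend(
            generate_congruency_pairs(ratio, congruency, count_per_ratio,
                                      rng=rng, side=side)
        )
    return pairs


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_image_png(image: StimulusImage, path) -> None:
    """Persist the raster as a 1-bit PNG."""
    PILImage.fromarray((image.pixels * 255).astype(np.uint8)).convert("1").save(path)


def load_image_png(path, seed_tag: str = "") -> StimulusImage:
    pix = np.asarray(PILImage.open(path).convert("1"), dtype=np.uint8)
    return StimulusImage.from_pixels(pix, seed_tag=seed_tag)


def metadata_table(images: Sequence[StimulusImage]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": np.arange(len(images)),
            "numerosity": [im.numerosity for im in images],
            "cumulative_area": [im.cumulative_area for im in images],
            "contour_length": [im.contour_length for im in images],
            "item_areas": [",".join(map(str, im.item_areas)) for im in images],
            "seed_tag": [im.seed_tag for im in images],
        }
    )


def save_corpus(images: Sequence[StimulusImage], directory,
                prefix: str = "stim") -> Path:
    """Write one PNG per image plus a tab-separated metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, im in enumerate(images):
        save_image_png(im, directory / f"{prefix}_{i:06d}.png")
    table = metadata_table(images)
    table.to_csv(directory / f"{prefix}_metadata.tsv", sep="\t", index=False)
    return directory


def load_corpus(directory, prefix: str = "stim") -> list[StimulusImage]:
    directory = Path(directory)
    meta = pd.read_csv(directory / f"{prefix}_metadata.tsv", sep="\t",
                       keep_default_na=False)
    images = []
    for _, row in meta.iterrows():
        im = load_image_png(directory / f"{prefix}_{int(row['id']):06d}.png",
                            seed_tag=str(row["seed_tag"]))
        images.append(im)
    return images


def save_corpus_hdf5(images: Sequence[StimulusImage], path) -> None:
    """Persist a corpus as a single HDF5 container (pixels + metadata)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset(
            "pixels", data=np.stack([im.pixels for im in images]).astype(np.uint8),
            compression="gzip",
        )
        f.create_dataset("numerosity", data=[im.numerosity for im in images])
        f.create_dataset("cumulative_area",
                         data=[im.cumulative_area for im in images])
        f.create_dataset("contour_length",
                         data=[im.contour_length for im in images])
        str_dt = h5py.string_dtype()
        f.create_dataset(
            "item_areas", dtype=str_dt,
            data=[",".join(map(str, im.item_areas)) for im in images],
        )
        f.create_dataset("seed_tag", dtype=str_dt,
                         data=[im.seed_tag for im in images])


def load_corpus_hdf5(path) -> list[StimulusImage]:
    import h5py

    with h5py.File(path, "r") as f:
        pixels = f["pixels"][...]
        item_areas = [s.decode() for s in f["item_areas"][...]]
        seed_tags = [s.decode() for s in f["seed_tag"][...]]
    return [
        StimulusImage.from_pixels(
            pix, item_areas=tuple(int(x) for x in areas.split(",")),
            seed_tag=tag,
        )
        for pix, areas, tag in zip(pixels, item_areas, seed_tags)
    ]
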