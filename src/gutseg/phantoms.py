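"""Synthetic abdominal phantom slices with three organ classes.

Emulates the structure of the UW-Madison-style GI-tract dataset: a cohort of
cases, each scanned on 1–6 days, each scan a stack of 80 or 144 axial
slices, with per-slice run-length-encoded masks for large bowel, small
bowel, and stomach in an ``id,class,segmentation`` CSV.

The anatomy model is deliberately simple but geometrically distinct:

* stomach — a filled ellipse biased to the upper-left quadrant;
* large bowel — a thick annulus arc hugging the body periphery;
* small bowel — a cluster of small blobs near the center.

Shapes vary smoothly across consecutive slices through a sinusoidal axial
profile (peripheral slices carry no organs), classes are pairwise disjoint
by construction, and organs are brighter than the surrounding tissue by
fixed contrasts with additive Gaussian noise — enough signal for a
scaled-down network to learn on CPU, and enough noise for the Gaussian
filter stage to matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .rle import CLASSES, encode_rle


class PhantomConfigError(ValueError):
    """Invalid phantom generation settings."""


class SplitError(ValueError):
    """Case-level split cannot be formed."""


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort structure and image model for the generator.

    ``slices_per_scan=None`` draws 80 or 144 per case, mirroring the real
    cohort; tests and desk-scale runs pass an explicit small value.
    Intensities are 8-bit; contrasts are organ-over-tissue differences.
    """

    n_cases: int = 3
    min_days: int = 1
    max_days: int = 6
    slices_per_scan: int | None = None
    image_size: int = 160
    noise_std: float = 10.0  # 8-bit intensity units
    background_level: float = 30.0
    tissue_level: float = 70.0
    organ_levels: tuple[float, float, float] = (170.0, 210.0, 240.0)  # lb, sb, stomach
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1:
            raise PhantomConfigError("n_cases must be >= 1")
        if not 1 <= self.min_days <= self.max_days <= 6:
            raise PhantomConfigError("days per case must satisfy 1 <= min <= max <= 6")
        if self.slices_per_scan is not None and self.slices_per_scan < 1:
            raise PhantomConfigError("slices_per_scan must be >= 1")
        if self.image_size < 16:
            raise PhantomConfigError("image_size must be >= 16")
        if self.noise_std < 0:
            raise PhantomConfigError("noise_std must be >= 0")


@dataclass
class PhantomSlice:
    """One generated slice: 8-bit image, (H,W,3) truth stack, provenance."""

    image: np.ndarray
    mask: np.ndarray
    case: int
    day: int
    slice_index: int

    @property
    def slice_id(self) -> str:
        return f"case{self.case}_day{self.day}_slice_{self.slice_index:04d}"


def _scan_geometry(rng: np.random.Generator, size: int) -> dict:
    """Draw the per-scan organ geometry (fractions of the image size)."""
    return {
        # stomach ellipse, upper-left quadrant bias
        "st_c": (rng.uniform(0.30, 0.40), rng.uniform(0.28, 0.38)),  # (row, col)
        "st_ax": (rng.uniform(0.10, 0.15), rng.uniform(0.07, 0.11)),
        "st_angle": rng.uniform(-0.6, 0.6),
        # large-bowel annulus arc along the periphery
        "lb_r": rng.uniform(0.33, 0.38),
        "lb_w": rng.uniform(0.045, 0.065),
        "lb_a0": rng.uniform(-2.4, -1.9),  # radians; arc sweeps the lower half
        "lb_a1": rng.uniform(1.6, 2.2),
        # small-bowel blob cluster near the center
        "sb_n": int(rng.integers(5, 9)),
        "sb_pos": rng.uniform(-0.10, 0.10, size=(8, 2)) + np.array([0.55, 0.52]),
        "sb_r": rng.uniform(0.028, 0.042, size=8),
        "sb_drift": rng.uniform(-0.03, 0.03, size=(8, 2)),
        "body_ax": (rng.uniform(0.42, 0.47), rng.uniform(0.44, 0.49)),
    }


def _render_slice(
    geom: dict, w_axial: float, size: int, noise_std: float, cfg: PhantomConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one slice's image and disjoint 3-channel mask.

    ``w_axial`` in [0, 1] scales organ presence/size along the stack;
    organs vanish below a presence threshold so peripheral slices are empty.
    """
    yy, xx = np.mgrid[0:size, 0:size] / float(size)
    cy, cx = 0.5, 0.5

    body = ((yy - cy) / geom["body_ax"][0]) ** 2 + ((xx - cx) / geom["body_ax"][1]) ** 2 <= 1.0

    mask = np.zeros((size, size, 3), dtype=np.uint8)
    if w_axial > 0.25:
        s = 0.4 + 0.6 * w_axial  # smooth size modulation
        # stomach: rotated filled ellipse
        scy, scx = geom["st_c"]
        a, b = geom["st_ax"][0] * s, geom["st_ax"][1] * s
        th = geom["st_angle"]
        dy, dx = yy - scy, xx - scx
        u = dy * math.cos(th) + dx * math.sin(th)
        v = -dy * math.sin(th) + dx * math.cos(th)
        stomach = (u / a) ** 2 + (v / b) ** 2 <= 1.0

        # large bowel: annulus arc
        r = np.hypot(yy - cy, xx - cx)
        ang = np.arctan2(yy - cy, xx - cx)
        in_ring = np.abs(r - geom["lb_r"] * (0.85 + 0.15 * s)) <= geom["lb_w"] * s
        a0, a1 = geom["lb_a0"], geom["lb_a1"]
        in_arc = (ang >= a0) & (ang <= a1)
        large_bowel = in_ring & in_arc & body

        # small bowel: blob cluster, centers drifting with the axial position
        small_bowel = np.zeros((size, size), dtype=bool)
        for i in range(geom["sb_n"]):
            py, px = geom["sb_pos"][i] + geom["sb_drift"][i] * (w_axial - 0.5) * 2.0
            rr = geom["sb_r"][i] * s
            small_bowel |= np.hypot(yy - py, xx - px) <= rr

        # enforce pairwise disjointness: stomach > large bowel > small bowel
        large_bowel &= ~stomach
        small_bowel &= ~(stomach | large_bowel)

        mask[:, :, 0] = large_bowel
        mask[:, :, 1] = small_bowel
        mask[:, :, 2] = stomach

    img = np.full((size, size), cfg.background_level, dtype=np.float64)
    img[body] = cfg.tissue_level
    for ch, level in enumerate(cfg.organ_levels):
        img[mask[:, :, ch] == 1] = level
    img += rng.normal(0.0, noise_std, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), mask


def generate_slices(config: PhantomConfig) -> list[PhantomSlice]:
    """Generate the full cohort in memory, deterministically from the seed.

    Each (case, day) scan uses its own seed stream derived from
    ``(config.seed, case, day)``, so any subset regenerates identically.
    """
    cohort_rng = np.random.default_rng([config.seed, 0xC0])
    out: list[PhantomSlice] = []
    for case in range(1, config.n_cases + 1):
        n_days = int(cohort_rng.integers(config.min_days, config.max_days + 1))
        n_slices = (
            config.slices_per_scan
            if config.slices_per_scan is not None
            else int(cohort_rng.choice([80, 144]))
        )
        for day in range(1, n_days + 1):
            rng = np.random.default_rng([config.seed, case, day])
            geom = _scan_geometry(rng, config.image_size)
            for s in range(n_slices):
                w = math.sin(math.pi * (s + 0.5) / n_slices)
                img, mask = _render_slice(
                    geom, w, config.image_size, config.noise_std, config, rng
                )
                out.append(PhantomSlice(img, mask, case, day, s))
    return out


def slices_to_records(slices: Sequence[PhantomSlice]) -> pd.DataFrame:
    """One ``id,class,segmentation`` row per slice per class (RLE, possibly
    empty), in fixed class order."""
    rows = []
    for sl in slices:
        for ch, cls in enumerate(CLASSES):
            rows.append((sl.slice_id, cls, encode_rle(sl.mask[:, :, ch])))
    return pd.DataFrame(rows, columns=["id", "class", "segmentation"])


def generate_dataset(config: PhantomConfig, out_dir: str | Path | None = None):
    """Generate the cohort and, optionally, write it in the dataset layout.

    On disk: ``case{c}/case{c}_day{d}/scans/slice_{ssss}.png`` grayscale
    images plus ``train.csv`` at the root. Returns ``(slices, records)``.
    """
    slices = generate_slices(config)
    records = slices_to_records(slices)
    if out_dir is not None:
        root = Path(out_dir)
        for sl in slices:
            scan_dir = root / f"case{sl.case}" / f"case{sl.case}_day{sl.day}" / "scans"
            scan_dir.mkdir(parents=True, exist_ok=True)
            Image.fromarray(sl.image, mode="L").save(
                scan_dir / f"slice_{sl.slice_index:04d}.png"
            )
        records.to_csv(root / "train.csv", index=False)
    return slices, records


def case_of(slice_id: str) -> int:
    """Extract the case number from a ``case{c}_day{d}_slice_{ssss}`` id."""
    return int(slice_id.split("_")[0].removeprefix("case"))


def train_val_split(
    cases: Sequence[int] | pd.DataFrame | Sequence[PhantomSlice],
    val_fraction: float,
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Partition cases into disjoint train/validation groups.

    Accepts a list of case numbers, a records frame (cases parsed from the
    ``id`` column), or a list of slices. No case straddles the boundary;
    deterministic under ``seed``.
    """
    if not 0.0 < val_fraction < 1.0:
        raise SplitError("val_fraction must be in (0, 1)")
    if isinstance(cases, pd.DataFrame):
        case_ids = sorted({case_of(i) for i in cases["id"]})
    elif len(cases) and isinstance(cases[0], PhantomSlice):
        case_ids = sorted({sl.case for sl in cases})
    else:
        case_ids = sorted(set(int(c) for c in cases))
    if len(case_ids) < 2:
        raise SplitError(f"need at least 2 cases to split, got {len(case_ids)}")
    rng = np.random.default_rng([seed, 0x5E])
    order = list(rng.permutation(case_ids))
    n_val = min(len(case_ids) - 1, max(1, round(val_fraction * len(case_ids))))
    val = sorted(int(c) for c in order[:n_val])
    train = sorted(int(c) for c in order[n_val:])
    return train, val
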