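"""Labelled patch datasets for the two networks.

From a B-scan with known boundary lines this module builds

* U-Net patches: 256x32 image/label pairs on a 4-pixel horizontal
  stride (32-wide patches overlapping by 28 px), one baseline patch per
  position plus one patch vertically centred on each defined boundary
  line at the patch's centre column;
* sliding-window patches: 33x33 patches centred on every defined
  boundary pixel (labels 1..5 for ILM, dINL, EZ, pRPE, BM) plus a
  configurable number of uniformly sampled background pixels per column
  (label 0), with mirror reflection at image borders;

and the random 80/20 patch-level train/validation split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .boundaries import BoundaryLineSet, InvalidBoundariesError, LINE_NAMES

UNET_PATCH_SHAPE = (256, 32)
UNET_H_OVERLAP = 28
SW_PATCH_SIZE = 33


@dataclass
class PatchSet:
    """A homogeneous set of labelled patches.

    ``images`` is (n, h, w) float32.  For flavor ``"unet"`` ``labels``
    is (n, h, w) int8 region classes; for ``"sw"`` it is (n,) int8
    centre-pixel classes in {0..5}.  ``provenance`` records
    (scan id, row, col) of each patch's top-left (U-Net) or centre (SW).
    """

    flavor: str
    images: np.ndarray
    labels: np.ndarray
    provenance: list[tuple] = field(default_factory=list)

    def __post_init__(self):
        if self.flavor not in ("unet", "sw"):
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if self.flavor == "unet" and self.labels.shape != self.images.shape:
            raise ValueError("unet labels must be dense label patches")
        if self.flavor == "sw":
            if self.labels.ndim != 1 or len(self.labels) != len(self.images):
                raise ValueError("sw labels must be one class per patch")
            if len(self.labels) and not (0 <= self.labels.min() <= self.labels.max() <= 5):
                raise ValueError("sw labels must lie in {0..5}")

    def __len__(self) -> int:
        return self.images.shape[0]

    def subset(self, idx: np.ndarray) -> "PatchSet":
        prov = [self.provenance[i] for i in idx] if self.provenance else []
        return PatchSet(self.flavor, self.images[idx], self.labels[idx], prov)

    @staticmethod
    def concatenate(sets: list["PatchSet"]) -> "PatchSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        flavor = sets[0].flavor
        if any(s.flavor != flavor for s in sets):
            raise ValueError("mixed flavors")
        return PatchSet(flavor,
                        np.concatenate([s.images for s in sets]),
                        np.concatenate([s.labels for s in sets]),
                        [p for s in sets for p in s.provenance])

    # ---- shard directory + JSON manifest ---------------------------------
    def save(self, out_dir: str | Path, shard_size: int = 4096) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        n_shards = max(1, -(-len(self) // shard_size))
        for s in range(n_shards):
            sel = slice(s * shard_size, (s + 1) * shard_size)
            np.savez(out / f"shard{s:04d}.npz",
                     images=self.images[sel], labels=self.labels[sel])
        (out / "manifest.json").write_text(json.dumps(
            {"flavor": self.flavor, "count": len(self),
             "patch_shape": list(self.images.shape[1:]),
             "n_shards": n_shards}, indent=2))
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "PatchSet":
        src = Path(in_dir)
        meta = json.loads((src / "manifest.json").read_text())
        imgs, labs = [], []
        for s in range(meta["n_shards"]):
            z = np.load(src / f"shard{s:04d}.npz")
            imgs.append(z["images"])
            labs.append(z["labels"])
        return cls(meta["flavor"], np.concatenate(imgs), np.concatenate(labs))


# ---------------------------------------------------------------------------
# region labelling
# ---------------------------------------------------------------------------

def label_regions(boundaries: BoundaryLineSet, n_rows: int,
                  n_cols: int | None = None) -> np.ndarray:
    """Fill the 5 boundary lines into a per-pixel region label map.

    Classes: 0 background, 1 = [ILM, dINL), 2 = [dINL, EZ) (or
    [dINL, pRPE) in columns where EZ is undefined), 3 = [EZ, pRPE),
    4 = [pRPE, BM] with BM inclusive.
    """
    if n_cols is None:
        n_cols = boundaries.n_cols
    elif n_cols != boundaries.n_cols:
        raise ValueError("n_cols disagrees with the boundary set")
    boundaries.validate(n_rows)
    r = np.arange(n_rows)[:, None].astype(float)
    ilm, dinl, ez, prpe, bm = (boundaries.line(n) for n in LINE_NAMES)
    labels = np.zeros((n_rows, n_cols), dtype=np.int8)
    with np.errstate(invalid="ignore"):
        labels[(r >= ilm) & (r < dinl)] = 1
        lower2 = np.where(np.isnan(ez), prpe, ez)
        labels[(r >= dinl) & (r < lower2)] = 2
        labels[(r >= ez) & (r < prpe)] = 3
        labels[(r >= prpe) & (r <= bm)] = 4
    return labels


# ---------------------------------------------------------------------------
# U-Net patch extraction
# ---------------------------------------------------------------------------

def _h_positions(width: int, patch_w: int, stride: int) -> list[int]:
    if width < patch_w:
        raise ValueError("image narrower than a patch")
    return list(range(0, width - patch_w + 1, stride))


def extract_unet_patches(image: np.ndarray, labels: np.ndarray,
                         boundaries: BoundaryLineSet,
                         patch_shape: tuple[int, int] = UNET_PATCH_SHAPE,
                         h_overlap: int = UNET_H_OVERLAP,
                         scan_id: str = "scan") -> PatchSet:
    """Extract 256x32 image/label patches with boundary-centred augmentation.

    Horizontal stride is ``patch width - h_overlap`` (32 - 28 = 4).  At
    each position one baseline patch is taken, vertically centred on the
    ILM/BM midpoint at the patch's centre column, plus one patch centred
    on each boundary line defined there; patches are shifted to stay
    inside the image.
    """
    ph, pw = patch_shape
    h, w = image.shape
    if h < ph or w < pw:
        raise ValueError(f"image {image.shape} smaller than patch {patch_shape}")
    if labels.shape != image.shape:
        raise ValueError("image/label shape mismatch")
    stride = pw - h_overlap
    if stride < 1:
        raise ValueError("overlap must be smaller than the patch width")
    imgs, labs, prov = [], [], []
    for c0 in _h_positions(w, pw, stride):
        cc = c0 + pw // 2
        centers = []
        ilm, bm = boundaries.ilm[cc], boundaries.bm[cc]
        if not np.isnan(ilm) and not np.isnan(bm):
            centers.append(0.5 * (ilm + bm))        # baseline placement
        else:
            centers.append(h / 2.0)
        for name in LINE_NAMES:
            row = boundaries.line(name)[cc]
            if not np.isnan(row):
                centers.append(row)
        for center in centers:
            r0 = int(np.clip(round(center - ph / 2), 0, h - ph))
            imgs.append(image[r0:r0 + ph, c0:c0 + pw])
            labs.append(labels[r0:r0 + ph, c0:c0 + pw])
            prov.append((scan_id, r0, c0))
    return PatchSet("unet",
                    np.asarray(imgs, dtype=np.float32),
                    np.asarray(labs, dtype=np.int8), prov)


# ---------------------------------------------------------------------------
# sliding-window patch extraction
# ---------------------------------------------------------------------------

def extract_sw_patches(image: np.ndarray, boundaries: BoundaryLineSet,
                       bg_per_column: int = 2, seed: int = 0,
                       patch_size: int = SW_PATCH_SIZE,
                       scan_id: str = "scan") -> PatchSet:
    """33x33 patches on boundary pixels plus sampled background pixels.

    Boundary pixels take the class of their line (1..5 for ILM..BM);
    ``bg_per_column`` background pixels per column are sampled uniformly
    outside the boundary rows and a 1-px guard band around them.  The
    image is mirror-reflected so border-centred patches are full size.
    """
    if bg_per_column < 0:
        raise ValueError("bg_per_column must be >= 0")
    h, w = image.shape
    half = patch_size // 2
    padded = np.pad(image, half, mode="reflect")
    rng = np.random.default_rng(seed)
    imgs, labs, prov = [], [], []

    def grab(r, c, label):
        imgs.append(padded[r:r + patch_size, c:c + patch_size])
        labs.append(label)
        prov.append((scan_id, r, c))

    for c in range(w):
        excluded = np.zeros(h, dtype=bool)
        for li, name in enumerate(LINE_NAMES):
            row = boundaries.line(name)[c]
            if np.isnan(row):
                continue
            r = int(row)
            grab(r, c, li + 1)
            excluded[max(r - 1, 0):r + 2] = True   # boundary + 1-px guard
        if bg_per_column:
            candidates = np.flatnonzero(~excluded)
            if candidates.size:
                take = min(bg_per_column, candidates.size)
                for r in rng.choice(candidates, size=take, replace=False):
                    grab(int(r), c, 0)
    return PatchSet("sw",
                    np.asarray(imgs, dtype=np.float32),
                    np.asarray(labs, dtype=np.int8), prov)


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------

def split_dataset(patches: PatchSet, train_fraction: float = 0.8,
                  seed: int = 0) -> tuple[PatchSet, PatchSet]:
    """Random patch-level split into disjoint, exhaustive train/validation.

    Sizes are within one patch of the exact fractions; patches from a
    single scan may land in both halves (patch-level randomisation).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(patches)
    if n == 0:
        raise ValueError("empty patch set")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(train_fraction * n))
    return patches.subset(order[:n_train]), patches.subset(order[n_train:])
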