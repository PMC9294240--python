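"""Synthetic Spectralis-like SD-OCT phantoms with exact ground truth.

Generates single B-scans and 9-mm 121-line macular volumes of a layered
retina-like object: five smooth boundary surfaces (ILM, dINL, EZ, pRPE,
BM) drawn as low-order cosine/parabolic height fields over the
(line, column) grid, an elliptical ellipsoid-zone (EZ) footprint outside
which the EZ band is absent (the dINL region then extends down to pRPE,
as at a real transition zone), per-region mean reflectances,
multiplicative speckle-like noise and an additive Gaussian floor.

Surfaces are parameterised as ILM plus strictly positive layer
thicknesses, so the top-to-bottom ordering invariant holds by
construction.  Every product (image, boundary rows, label map, EZ
presence map, analytic footprint area) is mutually consistent, which is
what makes the phantoms usable as segmentation oracles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .boundaries import BoundaryLineSet, LINE_NAMES


class InvalidSpecError(ValueError):
    """Raised when phantom parameters cannot yield ordered surfaces."""


@dataclass(frozen=True)
class ScanGeometry:
    """Physical geometry of a Spectralis-like macular volume scan."""

    width_mm: float = 9.0      # lateral scan width (fast axis)
    n_lines: int = 121         # B-scans per volume (slow axis)
    n_cols: int = 1536         # A-scans per B-scan (1536 hi-res, 768 hi-speed)
    n_rows: int = 496          # axial samples per A-scan
    z_res: float = 0.0039      # axial mm/pixel
    y_res: float | None = None  # fundus slow-axis mm/pixel; default = x_res

    def __post_init__(self):
        if min(self.width_mm, self.z_res) <= 0 or min(self.n_cols, self.n_rows) < 1:
            raise InvalidSpecError("geometry dimensions must be positive")
        if self.n_lines < 2:
            raise InvalidSpecError("a volume needs at least 2 lines")
        if self.y_res is not None and self.y_res <= 0:
            raise InvalidSpecError("y_res must be positive")

    @property
    def x_res(self) -> float:
        """Lateral mm/pixel along a B-scan."""
        return self.width_mm / self.n_cols

    @property
    def fundus_y_res(self) -> float:
        return self.x_res if self.y_res is None else self.y_res

    @property
    def line_spacing(self) -> float:
        """Distance between adjacent B-scan lines in mm."""
        return self.width_mm / (self.n_lines - 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(x_res=self.x_res, line_spacing=self.line_spacing,
                 fundus_y_res=self.fundus_y_res)
        return d


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic volume.

    ``thickness_px`` holds the four mean layer thicknesses (ILM-dINL,
    dINL-EZ, EZ-pRPE, pRPE-BM) in pixels; ``surface_mod`` scales smooth
    cosine modulations of ILM depth and layer thicknesses (bounded so
    ordering always holds); ``ez_center_mm``/``ez_semi_axes_mm`` place
    the elliptical EZ footprint on the fundus plane (semi-axes a, b in
    mm; analytic footprint area = pi*a*b).
    """

    geometry: ScanGeometry = ScanGeometry()
    ilm_base_row: float = 140.0
    thickness_px: tuple[float, float, float, float] = (70.0, 30.0, 20.0, 12.0)
    surface_mod: float = 0.15          # in [0, 0.45]
    ez_center_mm: tuple[float, float] | None = None  # (x, y); None = scan centre
    ez_semi_axes_mm: tuple[float, float] = (3.0, 2.5)
    layer_intensities: tuple[float, ...] = (0.08, 0.40, 0.18, 0.62, 0.82)
    noise_level: float = 0.15          # multiplicative speckle std
    noise_floor: float = 0.01          # additive Gaussian std
    seed: int = 0

    def __post_init__(self):
        if len(self.thickness_px) != 4:
            raise InvalidSpecError("four layer thicknesses required")
        if not 0 <= self.surface_mod <= 0.45:
            raise InvalidSpecError("surface_mod must lie in [0, 0.45]")
        # modulated thickness must stay >= ~1 px so rounded surfaces keep
        # their strict top-to-bottom ordering
        if min(self.thickness_px) * (1 - self.surface_mod) < 1.01:
            raise InvalidSpecError("layer thicknesses too thin for ordering")
        if min(self.ez_semi_axes_mm) < 0:
            raise InvalidSpecError("ellipse semi-axes must be >= 0")
        if len(self.layer_intensities) != 5:
            raise InvalidSpecError("five region intensities required")
        if self.noise_level < 0 or self.noise_floor < 0:
            raise InvalidSpecError("noise levels must be >= 0")
        # worst-case deepest BM row: ILM base + curvature + max thicknesses
        g = self.geometry
        deepest = (self.ilm_base_row
                   + 0.12 * g.n_rows * (self.surface_mod / 0.45)
                   + (1 + self.surface_mod) * sum(self.thickness_px))
        shallowest = self.ilm_base_row - 0.06 * g.n_rows * (self.surface_mod / 0.45)
        if shallowest < 0 or deepest >= g.n_rows:
            raise InvalidSpecError(
                f"surfaces may leave the image (deepest row {deepest:.1f} "
                f">= n_rows {g.n_rows})")

    @property
    def ez_center(self) -> tuple[float, float]:
        if self.ez_center_mm is not None:
            return self.ez_center_mm
        g = self.geometry
        return (g.width_mm / 2.0, g.width_mm / 2.0)

    @property
    def analytic_footprint_area(self) -> float:
        """Exact area of the elliptical EZ footprint, pi*a*b, in mm^2."""
        a, b = self.ez_semi_axes_mm
        return float(np.pi * a * b)

    @classmethod
    def flat(cls, geometry: ScanGeometry, rows: tuple[float, ...],
             **kwargs) -> "PhantomSpec":
        """Spec with flat surfaces at the given five absolute rows."""
        r = np.asarray(rows, dtype=float)
        if r.shape != (5,):
            raise InvalidSpecError("five rows required")
        return cls(geometry=geometry, ilm_base_row=float(r[0]),
                   thickness_px=tuple(np.diff(r)), surface_mod=0.0, **kwargs)


@dataclass
class VolumeScan:
    """Ordered stack of B-scan intensity grids plus physical geometry."""

    images: np.ndarray          # (n_lines, n_rows, n_cols) float32 in [0, 1]
    geometry: ScanGeometry

    def __post_init__(self):
        g = self.geometry
        if self.images.shape != (g.n_lines, g.n_rows, g.n_cols):
            raise ValueError("image stack does not match geometry")


# ---------------------------------------------------------------------------
# surface construction
# ---------------------------------------------------------------------------

def _grid_coords(g: ScanGeometry, line_index: np.ndarray | int):
    u = np.arange(g.n_cols) / max(g.n_cols - 1, 1) - 0.5
    v = np.atleast_1d(np.asarray(line_index, float)) / max(g.n_lines - 1, 1) - 0.5
    return u[None, :], v[:, None]


def surface_rows(spec: PhantomSpec, line_index) -> dict[str, np.ndarray]:
    """Continuous (un-rounded) rows of the 5 surfaces on selected lines.

    Returns arrays of shape (n_selected_lines, n_cols); the EZ footprint
    is not applied here — rows are defined everywhere.
    """
    g = spec.geometry
    u, v = _grid_coords(g, line_index)
    m = spec.surface_mod
    scale = m / 0.45
    # ILM: gentle parabolic curvature plus a foveal-dip-like cosine bump,
    # both scaled by surface_mod (zero modulation = truly flat surfaces)
    ilm = (spec.ilm_base_row
           + 0.06 * g.n_rows * scale * (4 * u**2 + 4 * v**2) / 2.0
           + 0.06 * g.n_rows * scale * np.cos(2 * np.pi * u) * np.cos(np.pi * v))
    rows = {"ilm": np.broadcast_to(ilm, (v.shape[0], g.n_cols)).copy()}
    cur = rows["ilm"]
    phases = (0.0, 0.7, 1.9, 3.1)
    for name, t, ph in zip(LINE_NAMES[1:], spec.thickness_px, phases):
        mod = 1.0 + m * np.cos(2 * np.pi * u + ph) * np.cos(np.pi * v + 0.5 * ph)
        cur = cur + t * mod
        rows[name] = cur
    return rows


def ez_footprint_mask(spec: PhantomSpec, line_index) -> np.ndarray:
    """Boolean EZ presence on selected lines (ellipse on the fundus plane)."""
    g = spec.geometry
    a, b = spec.ez_semi_axes_mm
    lines = np.atleast_1d(np.asarray(line_index, float))
    x = np.arange(g.n_cols) * g.x_res
    y = lines * g.line_spacing
    if a == 0 or b == 0:
        return np.zeros((lines.shape[0], g.n_cols), dtype=bool)
    cx, cy = spec.ez_center
    return (((x[None, :] - cx) / a) ** 2 + ((y[:, None] - cy) / b) ** 2) <= 1.0


def _label_map_from_rows(rows: dict[str, np.ndarray], ez_present: np.ndarray,
                         n_rows: int) -> np.ndarray:
    """Rasterise surfaces into the 0..4 region label map for one line."""
    r = np.arange(n_rows)[:, None]
    ilm, dinl, ez, prpe, bm = (np.round(rows[n][0]) for n in LINE_NAMES)
    labels = np.zeros((n_rows, ilm.shape[0]), dtype=np.int8)
    labels[(r >= ilm) & (r < dinl)] = 1
    lower2 = np.where(ez_present[0], ez, prpe)
    labels[(r >= dinl) & (r < lower2)] = 2
    labels[(r >= ez) & (r < prpe) & ez_present[0][None, :]] = 3
    labels[(r >= prpe) & (r <= bm)] = 4
    return labels


def _boundaries_from_rows(rows, ez_present) -> BoundaryLineSet:
    vals = {n: np.round(rows[n][0]).astype(float) for n in LINE_NAMES}
    vals["ez"] = np.where(ez_present[0], vals["ez"], np.nan)
    return BoundaryLineSet(**vals)


def generate_bscan(spec: PhantomSpec, line_index: int
                   ) -> tuple[np.ndarray, BoundaryLineSet, np.ndarray]:
    """Generate one B-scan: (intensity image, boundary lines, label map).

    The label map is exactly the region filling of the boundary rows;
    noise is seeded per (spec.seed, line_index), so repeated calls are
    bit-identical and volume generation matches per-line calls.
    """
    g = spec.geometry
    if not 0 <= line_index < g.n_lines:
        raise IndexError(f"line_index {line_index} outside [0, {g.n_lines})")
    rows = surface_rows(spec, line_index)
    if np.round(rows["bm"]).max() >= g.n_rows or np.round(rows["ilm"]).min() < 0:
        raise InvalidSpecError("surfaces leave the image")
    present = ez_footprint_mask(spec, line_index)
    labels = _label_map_from_rows(rows, present, g.n_rows)
    lines = _boundaries_from_rows(rows, present)
    img = np.asarray(spec.layer_intensities, dtype=np.float32)[labels]
    if spec.noise_level > 0 or spec.noise_floor > 0:
        rng = np.random.default_rng([spec.seed, line_index])
        if spec.noise_level > 0:
            shape = 1.0 / spec.noise_level ** 2
            img = img * rng.gamma(shape, 1.0 / shape, size=img.shape)
        if spec.noise_floor > 0:
            img = img + rng.normal(0.0, spec.noise_floor, size=img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32), lines, labels


def generate_volume(spec: PhantomSpec
                    ) -> tuple[VolumeScan, list[BoundaryLineSet], np.ndarray]:
    """Generate a full volume: scan stack, per-line boundaries, EZ map.

    The returned EZ presence map has shape (n_lines, n_cols) and equals
    the rasterised elliptical footprint.
    """
    g = spec.geometry
    images = np.empty((g.n_lines, g.n_rows, g.n_cols), dtype=np.float32)
    all_lines: list[BoundaryLineSet] = []
    for i in range(g.n_lines):
        img, lines, _ = generate_bscan(spec, i)
        images[i] = img
        all_lines.append(lines)
    presence = ez_footprint_mask(spec, np.arange(g.n_lines))
    return VolumeScan(images, g), all_lines, presence


def random_spec(rng: np.random.Generator, geometry: ScanGeometry | None = None,
                noise_level: float | None = None) -> PhantomSpec:
    """A random valid phantom spec, for property tests and demo data."""
    g = geometry or ScanGeometry()
    head = 0.32 * g.n_rows
    t_total = 0.38 * g.n_rows
    w = rng.uniform(0.5, 1.5, size=4)
    t = np.maximum(t_total * w / w.sum(), 2.0)
    a = rng.uniform(0.3, 0.42 * g.width_mm)
    b = rng.uniform(0.3, 0.42 * g.width_mm)
    cx = g.width_mm / 2 + rng.uniform(-0.05, 0.05) * g.width_mm
    cy = g.width_mm / 2 + rng.uniform(-0.05, 0.05) * g.width_mm
    return PhantomSpec(
        geometry=g,
        ilm_base_row=rng.uniform(0.1, 0.2) * g.n_rows,
        thickness_px=tuple(t),
        surface_mod=rng.uniform(0.0, 0.3),
        ez_center_mm=(cx, cy),
        ez_semi_axes_mm=(a, b),
        noise_level=float(rng.uniform(0.05, 0.25)) if noise_level is None else noise_level,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# on-disk formats: multi-page TIFF + JSON sidecar + ground-truth CSV
# ---------------------------------------------------------------------------

def write_volume(out_dir: str | Path, volume: VolumeScan,
                 lines: list[BoundaryLineSet] | None = None,
                 bit_depth: int = 16) -> Path:
    """Write a volume as multi-page TIFF with a JSON metadata sidecar.

    Optionally writes ground-truth boundaries as ``boundaries.csv`` with
    columns (line, column, ilm_row, ..., bm_row); empty cell = undefined.
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scale = (2**bit_depth - 1)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    tifffile.imwrite(out / "volume.tiff",
                     (volume.images * scale + 0.5).astype(dtype))
    (out / "volume.json").write_text(json.dumps(
        {"geometry": volume.geometry.to_dict(), "bit_depth": bit_depth}, indent=2))
    if lines is not None:
        write_boundaries_csv(out / "boundaries.csv", lines)
    return out


def read_volume(in_dir: str | Path) -> VolumeScan:
    import tifffile

    src = Path(in_dir)
    meta = json.loads((src / "volume.json").read_text())
    gm = meta["geometry"]
    geometry = ScanGeometry(width_mm=gm["width_mm"], n_lines=gm["n_lines"],
                            n_cols=gm["n_cols"], n_rows=gm["n_rows"],
                            z_res=gm["z_res"], y_res=gm["y_res"])
    raw = tifffile.imread(src / "volume.tiff")
    scale = 2 ** meta["bit_depth"] - 1
    return VolumeScan(raw.astype(np.float32) / scale, geometry)


def write_boundaries_csv(path: str | Path,
                         lines: list[BoundaryLineSet]) -> None:
    import pandas as pd

    frames = []
    for i, bls in enumerate(lines):
        f = bls.to_frame()
        f.insert(0, "line", i)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_boundaries_csv(path: str | Path) -> list[BoundaryLineSet]:
    import pandas as pd

    df = pd.read_csv(path)
    return [BoundaryLineSet.from_frame(grp.sort_values("column"))
            for _, grp in df.groupby("line", sort=True)]
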