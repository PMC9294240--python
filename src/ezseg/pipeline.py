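"""Post-network logic of the hybrid model.

After the U-Net labels a B-scan, single-pixel boundary lines are read
off the semantic map (top/bottom pixels of the region classes), checked
for discontinuities — gaps (undefined columns inside a line's extent)
and jumps (row steps larger than ``max_jump``) — and repaired with the
sliding-window classifier, which re-scores pixels in a window around
each break; columns where no class wins convincingly fall back to
linear interpolation between the break's flanks.  The EZ line is
exempt from gap repair by default: it legitimately ends at the
transition zone, and multiple disconnected EZ fragments need rules this
model does not attempt.  At volume level, small off-centre connected
components of the EZ presence map are removed as likely segmentation
errors before any area is measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .boundaries import BoundaryLineSet, InvalidBoundariesError, LINE_NAMES
from .phantom import ScanGeometry, VolumeScan
from . import networks
from .networks import TrainedModel

REPAIRABLE_LINES = ("ilm", "dinl", "prpe", "bm")


@dataclass(frozen=True)
class Break:
    line: str
    start: int            # first column involved
    end: int              # last column involved (inclusive)
    kind: str             # "gap" | "jump"


@dataclass
class BreakReport:
    breaks: list[Break] = field(default_factory=list)

    def for_line(self, name: str) -> list[Break]:
        return [b for b in self.breaks if b.line == name]

    def __len__(self):
        return len(self.breaks)


@dataclass(frozen=True)
class HybridConfig:
    """Tunables of the hybrid post-processing.

    The break/repair thresholds are conservative defaults, exposed here
    because no published values exist for them.
    """

    max_jump: int = 5              # px; larger adjacent-column steps are breaks
    repair_half_height: int = 15   # px; +-W search window around interpolation
    p_min: float = 0.5             # min SW probability to accept a repair row
    repair_ez: bool = False        # EZ band is not re-examined by default
    # SW confirm/eliminate pass over suspect EZ detections: every column's
    # claimed EZ pixel is re-classified by the SW model and dropped when
    # its EZ-class probability falls below p_min.  Off by default; it
    # suppresses the semantic model's sub-resolution false EZ detections
    # (interface slivers, band tails) at the cost of an extra SW sweep.
    ez_confirm: bool = False
    unet_only: bool = False        # skip SW repair entirely
    min_island_area_mm2: float = 0.5
    max_center_dist_mm: float = 1.5
    h_stride: int = 16             # U-Net tile stride, fast axis
    v_stride: int = 128            # U-Net tile stride, axial


# ---------------------------------------------------------------------------
# boundary extraction from a semantic map
# ---------------------------------------------------------------------------

def _top_of_first_run(mask: np.ndarray) -> np.ndarray:
    """Per column: row of the first True (NaN where none)."""
    any_ = mask.any(axis=0)
    top = mask.argmax(axis=0).astype(float)
    top[~any_] = np.nan
    return top


def extract_boundaries(labels: np.ndarray) -> BoundaryLineSet:
    """Single-pixel boundary lines from a region label map.

    ILM = top pixel of class 1; dINL = top of class 2 (or of class 3
    where class 2 is absent); EZ = top of class 3; pRPE = top of class
    4; BM = bottom pixel of class 4.  With fragmented runs the topmost
    run is used (and BM is the bottom of the topmost class-4 run); a
    column with no pixels of the class leaves the line undefined.
    Noisy maps yield gaps, never errors.
    """
    if labels.ndim != 2:
        raise ValueError("label map must be 2-D")
    is1, is2, is3, is4 = (labels == k for k in (1, 2, 3, 4))
    ilm = _top_of_first_run(is1)
    dinl = _top_of_first_run(is2)
    ez = _top_of_first_run(is3)
    dinl = np.where(np.isnan(dinl), ez, dinl)
    prpe = _top_of_first_run(is4)
    # BM: bottom of the topmost class-4 run = first run end at/below pRPE
    below = np.vstack([is4[1:], np.zeros((1, labels.shape[1]), dtype=bool)])
    run_end = is4 & ~below
    r = np.arange(labels.shape[0])[:, None].astype(float)
    with np.errstate(invalid="ignore"):
        run_end &= r >= np.nan_to_num(prpe, nan=np.inf)
    bm = _top_of_first_run(run_end)
    return BoundaryLineSet(ilm, dinl, ez, prpe, bm)


# ---------------------------------------------------------------------------
# break detection
# ---------------------------------------------------------------------------

def find_breaks(lines: BoundaryLineSet, max_jump: int = 5,
                check_lines: tuple[str, ...] | None = None) -> BreakReport:
    """Detect gaps and jumps along each boundary line.

    A gap is a maximal run of undefined columns strictly inside the
    line's defined extent; a jump is an adjacent-column row step larger
    than ``max_jump``.  The EZ line is exempt from gap flagging (it
    legitimately ends) unless explicitly requested via ``check_lines``.
    """
    if max_jump < 1:
        raise ValueError("max_jump must be >= 1")
    names = check_lines if check_lines is not None else LINE_NAMES
    report = BreakReport()
    for name in names:
        row = lines.line(name)
        defined = np.flatnonzero(~np.isnan(row))
        if defined.size < 2:
            continue
        flag_gaps = name != "ez" or check_lines is not None
        lo, hi = defined[0], defined[-1]
        if flag_gaps:
            inside = np.isnan(row[lo:hi + 1])
            if inside.any():
                lab, n = ndimage.label(inside)
                for k in range(1, n + 1):
                    cols = np.flatnonzero(lab == k) + lo
                    report.breaks.append(Break(name, int(cols[0]), int(cols[-1]), "gap"))
        steps = np.abs(np.diff(row[defined]))
        for i in np.flatnonzero(steps > max_jump):
            report.breaks.append(Break(name, int(defined[i]), int(defined[i + 1]), "jump"))
    report.breaks.sort(key=lambda b: (b.line, b.start))
    return report


# ---------------------------------------------------------------------------
# break repair with the sliding-window model
# ---------------------------------------------------------------------------

def _interp_rows(row: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Linear interpolation of defined rows onto ``cols``."""
    defined = np.flatnonzero(~np.isnan(row))
    return np.interp(cols, defined, row[defined])


def _enforce_order(lines: BoundaryLineSet) -> None:
    """Clip rows downward so the top-to-bottom ordering holds per column."""
    min_gap = {("ilm", "dinl"): 1, ("dinl", "ez"): 0, ("ez", "prpe"): 1,
               ("prpe", "bm"): 0, ("dinl", "prpe"): 1}
    with np.errstate(invalid="ignore"):
        for col in range(lines.n_cols):
            prev_name = prev = None
            for name in LINE_NAMES:
                v = lines.line(name)[col]
                if np.isnan(v):
                    continue
                if prev is not None:
                    gap = min_gap.get((prev_name, name), 0)
                    if v < prev + gap:
                        lines.line(name)[col] = prev + gap
                        v = prev + gap
                prev_name, prev = name, v


def repair_boundaries(image: np.ndarray, lines: BoundaryLineSet,
                      sw: TrainedModel, cfg: HybridConfig = HybridConfig(),
                      report: BreakReport | None = None) -> BoundaryLineSet:
    """Repair line breaks by re-classifying pixels with the SW model.

    For each break on a repairable line, every column across the break
    is scanned within ±``repair_half_height`` rows of the linear
    interpolation between the flanks; the row with the highest SW
    probability for the line's class is taken when that probability
    reaches ``p_min``, otherwise the interpolated row is used.  Columns
    outside reported breaks are never modified; with no breaks the
    input is returned unchanged (idempotence).
    """
    h, w = image.shape
    names = REPAIRABLE_LINES + (("ez",) if cfg.repair_ez else ())
    if report is None:
        report = find_breaks(lines, cfg.max_jump, check_lines=names)
    out = lines.copy()
    class_of = {name: i + 1 for i, name in enumerate(LINE_NAMES)}
    # gather all search-window pixels of every break, score them in one
    # SW sweep, then resolve each column
    coords: list[tuple[int, int]] = []
    jobs = []   # (line name, column, interpolated row, coord slice)
    for brk in report.breaks:
        if brk.line not in names:
            continue
        if brk.kind == "gap":
            cols = np.arange(brk.start, brk.end + 1)
        else:
            cols = np.arange(brk.start + 1, brk.end + 1)  # re-place the far side
        if cols.size == 0:
            continue
        guess = _interp_rows(lines.line(brk.line), cols)
        for c, g0 in zip(cols, guess):
            r_lo = int(max(0, np.floor(g0) - cfg.repair_half_height))
            r_hi = int(min(h - 1, np.ceil(g0) + cfg.repair_half_height))
            start = len(coords)
            coords.extend((r, int(c)) for r in range(r_lo, r_hi + 1))
            jobs.append((brk.line, int(c), g0, slice(start, len(coords))))
    if jobs:
        if isinstance(sw, OracleSW):
            probs = sw.probs_at(image, coords)
        else:
            _, probs = networks.classify_pixels(sw, image, coords)
        for name, c, g0, sel in jobs:
            p_line = probs[sel, class_of[name]]
            best = int(np.argmax(p_line))
            if p_line[best] >= cfg.p_min:
                out.line(name)[c] = coords[sel][best][0]
            else:
                out.line(name)[c] = np.round(g0)
    _enforce_order(out)
    return out


def confirm_ez(image: np.ndarray, lines: BoundaryLineSet, sw,
               p_min: float = 0.5) -> BoundaryLineSet:
    """Confirm or eliminate each column's EZ detection with the SW model.

    The pixel on the claimed EZ row of every EZ-bearing column is
    re-classified; columns where the SW probability of the EZ class
    falls below ``p_min`` lose their EZ row (the OS band there becomes
    absent).  Other lines are untouched.
    """
    out = lines.copy()
    cols = np.flatnonzero(out.defined("ez"))
    if cols.size == 0:
        return out
    coords = [(int(out.ez[c]), int(c)) for c in cols]
    if isinstance(sw, OracleSW):
        probs = sw.probs_at(image, coords)
    else:
        _, probs = networks.classify_pixels(sw, image, coords)
    rejected = cols[probs[:, 3] < p_min]
    out.ez[rejected] = np.nan
    return out


# ---------------------------------------------------------------------------
# volume-level EZ island removal
# ---------------------------------------------------------------------------

def remove_isolated_ez(ez_map: np.ndarray, geometry: ScanGeometry,
                       min_area_mm2: float = 0.5,
                       max_center_dist_mm: float = 1.5) -> np.ndarray:
    """Drop small, off-centre connected components of the EZ presence map.

    Components are 8-connected on the (line, column) grid; physical
    area uses the per-cell area ``line_spacing * x_res`` and centroid
    distances are measured in mm from the scan centre.  The component
    containing (or, failing that, nearest to) the centre is always
    kept; any other component is removed iff its area is below
    ``min_area_mm2`` AND its centroid is farther than
    ``max_center_dist_mm`` from the centre.  Idempotent; never adds
    presence.
    """
    if min_area_mm2 < 0 or max_center_dist_mm < 0:
        raise ValueError("thresholds must be >= 0")
    ez_map = np.asarray(ez_map, dtype=bool)
    if not ez_map.any():
        return ez_map.copy()
    lab, n = ndimage.label(ez_map, structure=np.ones((3, 3), dtype=int))
    dy, dx = geometry.line_spacing, geometry.x_res
    cy = (ez_map.shape[0] - 1) / 2.0 * dy
    cx = (ez_map.shape[1] - 1) / 2.0 * dx
    cell = dy * dx
    keep = np.zeros(n + 1, dtype=bool)
    center_comp, center_best = 0, np.inf
    for k in range(1, n + 1):
        rows, cols = np.nonzero(lab == k)
        area = rows.size * cell
        dist = np.hypot(rows * dy - cy, cols * dx - cx)
        if dist.min() < center_best:
            center_best, center_comp = dist.min(), k
        centroid_dist = np.hypot(rows.mean() * dy - cy, cols.mean() * dx - cx)
        keep[k] = not (area < min_area_mm2 and centroid_dist > max_center_dist_mm)
    keep[center_comp] = True
    return keep[lab]


# ---------------------------------------------------------------------------
# full hybrid driver
# ---------------------------------------------------------------------------

def ez_presence_from_lines(lines: BoundaryLineSet) -> np.ndarray:
    """EZ presence per column: EZ and pRPE defined with pRPE above BM depth."""
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(lines.prpe - lines.ez, nan=0.0) > 0


def run_hybrid(volume: VolumeScan, unet: TrainedModel, sw: TrainedModel | None,
               cfg: HybridConfig = HybridConfig()
               ) -> tuple[list[BoundaryLineSet], np.ndarray]:
    """Segment a volume with the hybrid model.

    Per B-scan: U-Net tiling -> boundary extraction -> break detection
    on ILM/dINL/pRPE/BM -> SW repair (skipped in ``unet_only`` mode);
    then the volume-level EZ presence map is cleaned of isolated
    off-centre islands.  Deterministic given models and volume.
    """
    if not cfg.unet_only and sw is None:
        raise ValueError("hybrid mode needs a SW model (or set unet_only)")
    g = volume.geometry
    all_lines: list[BoundaryLineSet] = []
    presence = np.zeros((g.n_lines, g.n_cols), dtype=bool)
    for i in range(g.n_lines):
        image = volume.images[i]
        labels = segment_with(unet, image, cfg)
        lines = extract_boundaries(labels)
        if not cfg.unet_only:
            lines = repair_boundaries(image, lines, sw, cfg)
            if cfg.ez_confirm:
                lines = confirm_ez(image, lines, sw, cfg.p_min)
        all_lines.append(lines)
        presence[i] = ez_presence_from_lines(lines)
    cleaned = remove_isolated_ez(presence, g, cfg.min_island_area_mm2,
                                 cfg.max_center_dist_mm)
    return all_lines, cleaned


def segment_with(unet: TrainedModel, image: np.ndarray,
                 cfg: HybridConfig) -> np.ndarray:
    if isinstance(unet, OracleUNet):
        return unet.segment(image)
    return networks.segment_bscan(unet, image, cfg.h_stride, cfg.v_stride)


# ---------------------------------------------------------------------------
# oracle stand-ins (ground-truth-backed models, for tests and validation)
# ---------------------------------------------------------------------------

class OracleUNet:
    """A U-Net stand-in that returns stored ground-truth label maps.

    Keyed by image identity via an exact pixel hash, so it can serve a
    whole volume.  Used to validate the post-network pipeline.
    """

    flavor = "unet"
    trained = True

    def __init__(self):
        self._maps: dict[bytes, np.ndarray] = {}

    def add(self, image: np.ndarray, labels: np.ndarray) -> "OracleUNet":
        self._maps[image.tobytes()] = np.asarray(labels, dtype=np.int8)
        return self

    def segment(self, image: np.ndarray) -> np.ndarray:
        return self._maps[image.tobytes()].copy()


class OracleSW:
    """A SW stand-in returning probability 1 for the true boundary class."""

    flavor = "sw"
    trained = True
    config = networks.SWConfig()

    def __init__(self):
        self._lines: dict[bytes, BoundaryLineSet] = {}

    def add(self, image: np.ndarray, lines: BoundaryLineSet) -> "OracleSW":
        self._lines[image.tobytes()] = lines
        return self

    def probs_at(self, image: np.ndarray, coords) -> np.ndarray:
        lines = self._lines[image.tobytes()]
        out = np.zeros((len(coords), 6), dtype=np.float32)
        for i, (r, c) in enumerate(coords):
            label = 0
            for li, name in enumerate(LINE_NAMES):
                row = lines.line(name)[c]
                if not np.isnan(row) and int(row) == r:
                    label = li + 1
                    break
            out[i, label] = 1.0
        return out
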