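"""Per-column boundary-line container shared across the package.

Five ordered retinal surfaces are tracked per B-scan column: ILM,
dINL, EZ, pRPE and BM (top to bottom).  Rows are stored as floats with
``NaN`` marking columns where a line is undefined — the EZ line, in
particular, legitimately ends at the transition zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LINE_NAMES = ("ilm", "dinl", "ez", "prpe", "bm")

# strictness of the ordering between vertically adjacent lines:
# ILM < dINL <= EZ < pRPE <= BM; where EZ is absent, dINL < pRPE.
_STRICT_PAIRS = {("ilm", "dinl"), ("ez", "prpe"), ("dinl", "prpe")}


class InvalidBoundariesError(ValueError):
    """Raised when boundary rows violate the top-to-bottom ordering."""


@dataclass
class BoundaryLineSet:
    """Row indices of the five boundary lines for each image column."""

    ilm: np.ndarray
    dinl: np.ndarray
    ez: np.ndarray
    prpe: np.ndarray
    bm: np.ndarray

    def __post_init__(self):
        n = None
        for name in LINE_NAMES:
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, arr)
            if n is None:
                n = arr.shape[0]
            elif arr.shape != (n,):
                raise ValueError("all lines must share one length")

    @classmethod
    def empty(cls, n_cols: int) -> "BoundaryLineSet":
        nan = np.full(n_cols, np.nan)
        return cls(*(nan.copy() for _ in LINE_NAMES))

    @property
    def n_cols(self) -> int:
        return self.ilm.shape[0]

    def line(self, name: str) -> np.ndarray:
        if name not in LINE_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def defined(self, name: str) -> np.ndarray:
        """Boolean mask of columns where line ``name`` is defined."""
        return ~np.isnan(self.line(name))

    def copy(self) -> "BoundaryLineSet":
        return BoundaryLineSet(*(self.line(n).copy() for n in LINE_NAMES))

    def __eq__(self, other) -> bool:
        if not isinstance(other, BoundaryLineSet):
            return NotImplemented
        return all(np.array_equal(self.line(n), other.line(n), equal_nan=True)
                   for n in LINE_NAMES)

    def validate(self, n_rows: int | None = None) -> None:
        """Check per-column ordering (and optionally the image extent).

        Raises :class:`InvalidBoundariesError` on the first violation.
        """
        with np.errstate(invalid="ignore"):
            for col in range(self.n_cols):
                prev_name, prev_row = None, None
                for name in LINE_NAMES:
                    row = self.line(name)[col]
                    if np.isnan(row):
                        continue
                    if n_rows is not None and not (0 <= row < n_rows):
                        raise InvalidBoundariesError(
                            f"{name} row {row} outside [0, {n_rows}) at column {col}")
                    if prev_row is not None:
                        strict = (prev_name, name) in _STRICT_PAIRS
                        if (row < prev_row) or (strict and row == prev_row):
                            raise InvalidBoundariesError(
                                f"ordering {prev_name}={prev_row} vs {name}={row} "
                                f"violated at column {col}")
                    prev_name, prev_row = name, row

    def is_valid(self, n_rows: int | None = None) -> bool:
        try:
            self.validate(n_rows)
        except InvalidBoundariesError:
            return False
        return True

    def to_frame(self):
        """Ground-truth/prediction CSV schema: one row per column."""
        import pandas as pd

        return pd.DataFrame({"column": np.arange(self.n_cols),
                             **{f"{n}_row": self.line(n) for n in LINE_NAMES}})

    @classmethod
    def from_frame(cls, frame) -> "BoundaryLineSet":
        return cls(*(frame[f"{n}_row"].to_numpy(dtype=np.float64)
                     for n in LINE_NAMES))
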