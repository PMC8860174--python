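"""Rectangular multi-electrode array geometry and border bookkeeping.

The bundle-detection rule declares axonal activation when the set of
time-locked recording electrodes touches at least two borders of the
rectangular array — the spatial signature of a spike travelling
bidirectionally along an axon bundle and exiting the array on both sides.
This module owns the electrode layout, the four border sets and the
border-counting primitives that rule relies on.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

BORDER_NAMES = ("left", "right", "top", "bottom")


@dataclass(frozen=True)
class ElectrodeArray:
    """A rectangular grid of extracellular electrodes.

    Electrodes are indexed 0-based, row-major: electrode ``i`` sits at
    row ``i // n_cols``, column ``i % n_cols``.  Positions are in μm with
    x increasing along columns and y along rows; "top" is row 0 and
    "bottom" is the last row.
    """

    n_rows: int
    n_cols: int
    pitch: float = 60.0
    positions: np.ndarray = field(repr=False, default=None)
    border_sets: Mapping[str, frozenset[int]] = field(repr=False, default=None)

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    def validate_indices(self, electrodes: Iterable[int]) -> None:
        n = self.n_electrodes
        for e in electrodes:
            if not (0 <= int(e) < n):
                raise IndexError(
                    f"electrode index {e} out of range for array with {n} electrodes"
                )

    def row_col(self, electrode: int) -> tuple[int, int]:
        self.validate_indices([electrode])
        return divmod(int(electrode), self.n_cols)

    def border_membership(self, electrode: int) -> frozenset[str]:
        """Names of the borders a single electrode lies on (0, 1 or 2)."""
        self.validate_indices([electrode])
        return frozenset(
            name for name, s in self.border_sets.items() if electrode in s
        )

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {"n_rows": self.n_rows, "n_cols": self.n_cols, "pitch": self.pitch}
        )

    @classmethod
    def from_json(cls, payload: str) -> "ElectrodeArray":
        d = json.loads(payload)
        return make_array(int(d["n_rows"]), int(d["n_cols"]), float(d["pitch"]))


def make_array(n_rows: int, n_cols: int, pitch: float = 60.0) -> ElectrodeArray:
    """Build a rectangular array with its four border sets.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; both must be at least 2 so that every border is
        a distinct, non-empty set of electrodes.
    pitch
        Electrode spacing in μm (60 μm for the 512-electrode arrays this
        models).
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError(
            f"array must be at least 2x2 (got {n_rows}x{n_cols}); "
            "smaller grids have degenerate borders"
        )
    if pitch <= 0:
        raise ValueError(f"pitch must be positive, got {pitch}")

    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    positions = np.column_stack([cols * pitch, rows * pitch]).astype(float)

    border_sets = {
        "left": frozenset(np.flatnonzero(cols == 0).tolist()),
        "right": frozenset(np.flatnonzero(cols == n_cols - 1).tolist()),
        "top": frozenset(np.flatnonzero(rows == 0).tolist()),
        "bottom": frozenset(np.flatnonzero(rows == n_rows - 1).tolist()),
    }
    return ElectrodeArray(
        n_rows=n_rows,
        n_cols=n_cols,
        pitch=float(pitch),
        positions=positions,
        border_sets=border_sets,
    )


def borders_touched(electrodes: Iterable[int], array: ElectrodeArray) -> int:
    """Number of the four borders intersected by a set of electrodes.

    A corner electrode lies on two borders and therefore contributes two
    by itself; see :func:`satisfies_border_rule` for the stricter variant
    requiring distinct electrodes on distinct borders.
    """
    electrodes = set(int(e) for e in electrodes)
    array.validate_indices(electrodes)
    return sum(1 for s in array.border_sets.values() if electrodes & s)


def max_distinct_border_cover(
    electrodes: Iterable[int], array: ElectrodeArray
) -> int:
    """Largest number of borders coverable by *distinct* electrodes.

    Size of a maximum bipartite matching between the given electrodes
    and the four borders.  With at most four borders a subset of borders
    admits a system of distinct representatives iff Hall's condition
    holds, which is checked exhaustively.
    """
    electrodes = set(int(e) for e in electrodes)
    array.validate_indices(electrodes)
    touched = [name for name, s in array.border_sets.items() if electrodes & s]
    border_electrodes = {
        name: electrodes & array.border_sets[name] for name in touched
    }

    def has_sdr(combo: tuple[str, ...]) -> bool:
        for r in range(1, len(combo) + 1):
            for sub in itertools.combinations(combo, r):
                union = set().union(*(border_electrodes[name] for name in sub))
                if len(union) < r:
                    return False
        return True

    for k in range(len(touched), 0, -1):
        if any(has_sdr(c) for c in itertools.combinations(touched, k)):
            return k
    return 0


def satisfies_border_rule(
    electrodes: Iterable[int],
    array: ElectrodeArray,
    min_borders: int = 2,
    corner_rule: str = "literal",
) -> bool:
    """Apply the ≥ ``min_borders`` border rule to an electrode set.

    ``corner_rule='literal'`` counts borders touched, so a lone corner
    electrode already touches two.  ``corner_rule='two-electrode'``
    additionally requires the borders to be covered by distinct
    electrodes, so a lone corner does not qualify.
    """
    if corner_rule == "literal":
        return borders_touched(electrodes, array) >= min_borders
    if corner_rule == "two-electrode":
        return max_distinct_border_cover(electrodes, array) >= min_borders
    raise ValueError(f"unknown corner_rule {corner_rule!r}")
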