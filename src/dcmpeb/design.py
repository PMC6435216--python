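"""Second-level design matrices of temporal basis functions.

Between-window changes in connectivity are modelled as a linear
combination of a constant, a few discrete cosine transform (DCT-II)
components, and a mono-exponential decay aligned to recording onset:

    constant   X[n, 0] = 1
    dct-k      X[n, k] = sqrt(2/W) * cos(pi/W * (n + 1/2) * k),  k = 2..4
    decay      X[n, -1] = exp(-n / tau),                         tau = 16

for windows n = 0..W-1.  The DCT columns are orthonormal and orthogonal
to the constant; the decay column is strictly decreasing, so a negative
decay coefficient produces a monotonically increasing trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DesignMatrix", "build_design"]


@dataclass
class DesignMatrix:
    """W x P regressor matrix with labelled columns; column 0 is the constant."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.labels):
            raise ValueError("one label per column required")
        if not np.allclose(self.matrix[:, 0], 1.0):
            raise ValueError("first design column must be the constant (all ones)")

    @property
    def W(self) -> int:
        return self.matrix.shape[0]

    @property
    def P(self) -> int:
        return self.matrix.shape[1]

    @property
    def optional_labels(self) -> list[str]:
        """Labels of the switchable regressors (everything but the constant)."""
        return self.labels[1:]

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]

    def to_text(self) -> str:
        header = "\t".join(self.labels)
        rows = "\n".join("\t".join(f"{v:.10g}" for v in row) for row in self.matrix)
        return f"{header}\n{rows}\n"


def build_design(W: int, dct_orders: tuple[int, ...] = (2, 3, 4), decay_tau: float = 16.0) -> DesignMatrix:
    """Build the default 5-column temporal design for W windows."""
    if W < 2:
        raise ValueError("need at least 2 windows to model temporal effects")
    n = np.arange(W)
    cols = [np.ones(W)]
    labels = ["constant"]
    for k in dct_orders:
        cols.append(np.sqrt(2.0 / W) * np.cos(np.pi / W * (n + 0.5) * k))
        labels.append(f"dct{k}")
    cols.append(np.exp(-n / decay_tau))
    labels.append("decay")
    return DesignMatrix(np.column_stack(cols), labels)
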