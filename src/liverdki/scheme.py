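"""Diffusion acquisition schemes (b-value tables).

A scheme is the ordered list of diffusion weightings (b-values, s/mm^2) at
which a multi-b DWI volume was acquired.  The default is the four-shell
liver DKI protocol b = 0, 800, 1500, 2000 s/mm^2; the mono-exponential ADC
is computed from the b = 0 and b = 800 points of the same scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_B_VALUES = (0.0, 800.0, 1500.0, 2000.0)

#: b-value (s/mm^2) used together with b=0 for the two-point ADC fit.
ADC_B_VALUE = 800.0


@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered diffusion weightings of a multi-b acquisition.

    Parameters
    ----------
    b_values
        Strictly increasing b-values in s/mm^2; the first must be 0.
        At least two values are required for ADC fitting and at least
        three for the quadratic (kurtosis) fit.
    """

    b_values: tuple[float, ...] = field(default=DEFAULT_B_VALUES)

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.b_values)
        object.__setattr__(self, "b_values", b)
        if len(b) < 2:
            raise ValueError("scheme needs at least 2 b-values")
        if b[0] != 0.0:
            raise ValueError("first b-value must be 0")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("b-values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.b_values)

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    @property
    def supports_kurtosis_fit(self) -> bool:
        """Three or more shells are needed to separate D from K."""
        return len(self.b_values) >= 3

    def index_of(self, b_value: float) -> int:
        """Index of an exact b-value; raises ``ValueError`` if absent."""
        try:
            return self.b_values.index(float(b_value))
        except ValueError:
            raise ValueError(f"b-value {b_value} not in scheme {self.b_values}") from None

    # -- FSL-dialect bval text (one whitespace-separated row) ------------

    @classmethod
    def from_bval_file(cls, path: str | Path) -> "AcquisitionScheme":
        values = Path(path).read_text().split()
        return cls(tuple(float(v) for v in values))

    def to_bval_file(self, path: str | Path) -> None:
        Path(path).write_text(" ".join(f"{b:g}" for b in self.b_values) + "\n")
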