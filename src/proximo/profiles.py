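"""Core 1D density-profile container.

A :class:`DensityProfile` is the normalized cell density along the
proximo-distal (PD) axis of a regenerating limb at one timepoint for one
replicate: positions ``x`` in micrometres from the proximal end, densities
``rho`` (dimensionless).  Measured (image-collapsed) profiles are normalized
so that ``max(rho) == 1``; forward-model profiles keep their absolute scale,
since total mass grows with proliferation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["DensityProfile"]


@dataclass
class DensityProfile:
    """Cell density along the PD axis at a single timepoint.

    Parameters
    ----------
    x : array_like
        Strictly increasing positions along the PD axis, in μm.  ``x = 0``
        is the proximal end of the traced axis (re-referencing to the
        amputation plane is an explicit option, see :mod:`proximo.axis`).
    rho : array_like
        Density values, one per position.  Measured profiles are
        non-negative (enforced at the IO layer); profiles carrying
        unclipped additive observation noise may dip below zero.
    timepoint : float
        Days post-electroporation (dpe).
    condition : str
        Experimental condition label (e.g. ``"control"``, ``"tig1"``).
    replicate : str
        Replicate identifier.
    L : float, optional
        Domain (limb) length in μm; defaults to ``x[-1]``.
    """

    x: np.ndarray
    rho: np.ndarray
    timepoint: float = 0.0
    condition: str = ""
    replicate: str = ""
    L: float | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.x.ndim != 1 or self.rho.ndim != 1:
            raise ValueError("x and rho must be one-dimensional")
        if len(self.x) != len(self.rho):
            raise ValueError(
                f"x and rho length mismatch: {len(self.x)} vs {len(self.rho)}"
            )
        if len(self.x) >= 2 and not np.all(np.diff(self.x) > 0):
            raise ValueError("x must be strictly increasing")
        if not np.all(np.isfinite(self.x)) or not np.all(np.isfinite(self.rho)):
            raise ValueError("x and rho must be finite")
        if self.L is None:
            self.L = float(self.x[-1]) if len(self.x) else 0.0

    def __len__(self) -> int:
        return len(self.x)

    def normalized(self) -> "DensityProfile":
        """Return a copy scaled so that ``max(rho) == 1``.

        An all-zero profile is returned unchanged (the convention for
        images with no above-threshold signal).
        """
        m = self.rho.max() if len(self.rho) else 0.0
        if m == 0:
            return self.copy()
        return replace(self, x=self.x.copy(), rho=self.rho / m)

    def interp(self, x_new: np.ndarray) -> np.ndarray:
        """Linear interpolation of ``rho`` at positions ``x_new`` (μm).

        Positions outside the profile support evaluate to 0.
        """
        return np.interp(np.asarray(x_new, dtype=float), self.x, self.rho,
                         left=0.0, right=0.0)

    def copy(self) -> "DensityProfile":
        return replace(self, x=self.x.copy(), rho=self.rho.copy())
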