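"""Diffusion acquisition schemes (b-values and encoding directions).

A scheme is fittable for the kurtosis model only when it carries at least
two distinct non-zero b shells and at least 15 distinct encoding directions
(22 unknowns: ln S0, 6 diffusion and 15 kurtosis components).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "validate_scheme",
    "default_directions",
    "default_scheme",
    "read_bval_bvec",
    "write_bval_bvec",
]

_B0_THRESHOLD = 50.0  # s/mm^2; b below this counts as an unweighted volume
_DIR_NORM_TOL = 1e-6


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume b-values (s/mm^2) and unit encoding directions."""

    bvalues: np.ndarray          # (n_volumes,)
    directions: np.ndarray       # (n_volumes, 3), unit rows for b > 0
    shells: tuple[float, ...]    # distinct non-zero b-values
    fittable: bool               # enough shells/directions for the 22-parameter fit

    @property
    def n_volumes(self) -> int:
        return int(self.bvalues.size)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues < _B0_THRESHOLD

    def unique_nonzero_directions(self) -> np.ndarray:
        """Distinct encoding directions over the non-zero shells (antipodes merged)."""
        dirs = self.directions[~self.b0_mask]
        canon = np.array([_canonical(d) for d in dirs])
        return np.unique(np.round(canon, 9), axis=0)


def _canonical(d: np.ndarray) -> np.ndarray:
    """Antipodally canonical representative (diffusion encoding is sign-blind)."""
    for v in d:
        if abs(v) > 1e-12:
            return d if v > 0 else -d
    return d


def validate_scheme(bvalues, directions) -> AcquisitionScheme:
    """Validate and normalize an acquisition scheme.

    Directions at non-zero b are renormalized to unit length; a direction
    whose norm is off unit by more than a factor-level discrepancy is still
    accepted and normalized (scanner tables often carry scaled vectors), but
    a zero vector at non-zero b is rejected.
    """
    b = np.asarray(bvalues, dtype=float).ravel()
    dirs = np.asarray(directions, dtype=float)
    if dirs.ndim != 2 or dirs.shape[1] != 3:
        raise ValueError(f"directions must be (n, 3), got {dirs.shape}")
    if b.size != dirs.shape[0]:
        raise ValueError(
            f"bvalues ({b.size}) and directions ({dirs.shape[0]}) differ in length"
        )
    if np.any(b < 0):
        raise ValueError("negative b-values are not allowed")

    weighted = b >= _B0_THRESHOLD
    if not np.any(~weighted):
        raise ValueError("scheme must contain at least one b=0 volume")

    norms = np.linalg.norm(dirs, axis=1)
    if np.any(norms[weighted] < 1e-12):
        raise ValueError("zero-length direction at non-zero b")
    dirs = dirs.copy()
    dirs[weighted] /= norms[weighted, None]

    shells = tuple(sorted(set(np.round(b[weighted], 6))))
    scheme = AcquisitionScheme(
        bvalues=b, directions=dirs, shells=shells, fittable=False
    )
    n_dirs = scheme.unique_nonzero_directions().shape[0]
    fittable = len(shells) >= 2 and n_dirs >= 15
    object.__setattr__(scheme, "fittable", fittable)
    return scheme


def default_directions(n: int = 15, seed: int = 7) -> np.ndarray:
    """A deterministic, well-spread set of n unit directions on the hemisphere.

    Fibonacci-lattice points on the upper hemisphere; adequate angular
    coverage for kurtosis estimation without vendor-specific tables.
    """
    del seed  # layout is fully deterministic; kept for interface stability
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + np.sqrt(5.0)) * i
    z = i / n  # upper hemisphere only (antipodal symmetry of diffusion encoding)
    r = np.sqrt(1 - z**2)
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def default_scheme(
    bshells: tuple[float, ...] = (1000.0, 2000.0),
    n_directions: int = 15,
    n_b0: int = 1,
) -> AcquisitionScheme:
    """The default acquisition: n_b0 unweighted volumes plus each shell over
    the same n_directions encoding directions (default 1 + 15 x {1000, 2000},
    i.e. 31 volumes)."""
    dirs15 = default_directions(n_directions)
    b = [0.0] * n_b0
    d = [np.array([0.0, 0.0, 0.0])] * n_b0
    for shell in bshells:
        for v in dirs15:
            b.append(shell)
            d.append(v)
    return validate_scheme(b, np.array(d))


def read_bval_bvec(bval_path: str | Path, bvec_path: str | Path) -> AcquisitionScheme:
    """Read FSL-dialect gradient tables: one row of b-values; three rows x/y/z."""
    b = np.loadtxt(bval_path, ndmin=1).ravel()
    vec = np.loadtxt(bvec_path, ndmin=2)
    if vec.shape[0] == 3 and vec.shape[1] != 3:
        vec = vec.T
    elif vec.shape == (3, 3):
        vec = vec.T  # FSL convention: rows are x/y/z
    return validate_scheme(b, vec)


def write_bval_bvec(scheme: AcquisitionScheme, bval_path: str | Path,
                    bvec_path: str | Path) -> None:
    np.savetxt(bval_path, scheme.bvalues[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.8f")
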