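"""Diffusion kurtosis model: forward signal prediction and voxelwise fitting.

The signal model for encoding direction n and diffusion weighting b is

    ln[S(n, b) / S0] = -b * D(n) + (1/6) * b^2 * MD^2 * W(n)

with D(n) = sum_ij n_i n_j D_ij the apparent diffusivity, MD = trace(D)/3
the mean diffusivity, and W(n) = sum_ijkl n_i n_j n_k n_l W_ijkl the
directional projection of the kurtosis tensor.  The directional apparent
kurtosis is K(n) = (MD / D(n))^2 * W(n); mean kurtosis (MK) averages K(n)
over a direction set, each value clamped to a configurable interval first.

Fitting is the standard two-stage linearization: the model is linear in
(ln S0, D_ij, V_ijkl) with V = MD^2 * W, so a 22-parameter weighted linear
least-squares problem is solved against ln S — an ordinary pass first, then
a pass weighted by the squared predicted signals (which is the proper
weighting for log-transformed Rician/Gaussian magnitude data).  W is then
recovered as V / MD^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scheme import AcquisitionScheme
from .tensors import (
    D_INDEX_TUPLES,
    D_MULTIPLICITY,
    W_INDEX_TUPLES,
    W_MULTIPLICITY,
    apparent_kurtosis,
    d_from_vec,
    d_to_vec,
    tensor_metrics,
    w_from_vec,
    w_to_vec,
)

__all__ = ["FitOptions", "DKIFitResult", "predict_signal", "mean_kurtosis",
           "build_design_matrix", "fit_dki_voxel", "fit_dki_volume",
           "sphere_directions"]

MISSING = np.nan


@dataclass(frozen=True)
class FitOptions:
    """Tunable fitting constraints.

    eps_d: floor on diffusion-tensor eigenvalues (mm^2/s).
    k_min/k_max: clamp interval applied to each directional K(n) before MK
        averaging (standard noise-robustness practice).
    mk_directions: "scheme" averages K(n) over the acquisition's distinct
        encoding directions (default, mirrors a 15-direction vendor
        computation); "sphere" uses a dense deterministic 256-point set.
    """

    eps_d: float = 1e-6
    k_min: float = 0.0
    k_max: float = 3.0
    mk_directions: str = "scheme"


@dataclass
class DKIFitResult:
    """Per-voxel fit: baseline signal, tensors, and derived scalar metrics."""

    s0: float
    d: np.ndarray          # 3x3 diffusion tensor, mm^2/s
    w: np.ndarray          # 3x3x3x3 kurtosis tensor, dimensionless
    md: float              # mm^2/s
    fa: float              # dimensionless, [0, 1]
    mk: float              # dimensionless, within [k_min, k_max]
    fit_ok: bool
    residual_norm: float


def predict_signal(s0: float, d_mat: np.ndarray, w_full: np.ndarray,
                   scheme: AcquisitionScheme) -> np.ndarray:
    """Forward-model the signal for every volume of the scheme.

    At b = 0 the prediction is exactly s0.
    """
    if s0 <= 0:
        raise ValueError("baseline signal must be positive")
    d_mat = np.asarray(d_mat, dtype=float)
    md = float(np.trace(d_mat)) / 3.0
    if md <= 0:
        raise ValueError("mean diffusivity must be positive")
    b = scheme.bvalues
    n = scheme.directions
    d_n = np.einsum("vi,ij,vj->v", n, d_mat, n)
    w_n = np.einsum("vi,vj,vk,vl,ijkl->v", n, n, n, n, np.asarray(w_full, float))
    log_att = -b * d_n + (b**2) * (md**2) * w_n / 6.0
    sig = s0 * np.exp(log_att)
    sig[scheme.b0_mask] = s0
    return sig


def sphere_directions(n: int = 256) -> np.ndarray:
    """Deterministic Fibonacci-lattice direction set on the hemisphere."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + np.sqrt(5.0)) * i
    z = i / n
    r = np.sqrt(1 - z**2)
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def mean_kurtosis(d_mat: np.ndarray, w_full: np.ndarray,
                  directions: np.ndarray,
                  k_min: float = 0.0, k_max: float = 3.0) -> float:
    """MK: arithmetic mean of K(n) over the direction set, clamped per direction."""
    directions = np.asarray(directions, dtype=float)
    if directions.size == 0:
        raise ValueError("direction set must be non-empty")
    ks = np.array([apparent_kurtosis(d_mat, w_full, n) for n in directions])
    return float(np.mean(np.clip(ks, k_min, k_max)))


def build_design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """(n_volumes x 22) design for the linearized model.

    Columns: [1 | -b * m_ij n_i n_j (6) | b^2/6 * m_ijkl n_i n_j n_k n_l (15)],
    with m the index multiplicities, against y = ln S; parameters are
    (ln S0, D components, V components) with V = MD^2 W.
    """
    b = scheme.bvalues
    n = scheme.directions
    cols = [np.ones_like(b)]
    for (i, j), m in zip(D_INDEX_TUPLES, D_MULTIPLICITY):
        cols.append(-b * m * n[:, i] * n[:, j])
    for idx, m in zip(W_INDEX_TUPLES, W_MULTIPLICITY):
        i, j, k, l = idx
        cols.append((b**2 / 6.0) * m * n[:, i] * n[:, j] * n[:, k] * n[:, l])
    return np.stack(cols, axis=1)


def _mk_direction_set(scheme: AcquisitionScheme, options: FitOptions) -> np.ndarray:
    if options.mk_directions == "sphere":
        return sphere_directions(256)
    return scheme.unique_nonzero_directions()


def _failed(n: int = 3) -> DKIFitResult:
    return DKIFitResult(s0=MISSING, d=np.full((3, 3), MISSING),
                        w=np.full((3, 3, 3, 3), MISSING), md=MISSING,
                        fa=MISSING, mk=MISSING, fit_ok=False,
                        residual_norm=MISSING)


def fit_dki_voxel(signal: np.ndarray, scheme: AcquisitionScheme,
                  options: FitOptions = FitOptions(),
                  design: np.ndarray | None = None) -> DKIFitResult:
    """Fit the 22-parameter kurtosis model to one voxel's signal vector.

    Non-positive or non-finite signal values mark the voxel as unfittable
    (fit_ok False) rather than raising, so volume-level sweeps never abort.
    """
    if not scheme.fittable:
        raise ValueError(
            "scheme is not fittable for the kurtosis model "
            "(needs >= 2 non-zero shells and >= 15 distinct directions)"
        )
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.size != scheme.n_volumes:
        raise ValueError(
            f"signal length {signal.size} != scheme volumes {scheme.n_volumes}"
        )
    if np.any(~np.isfinite(signal)) or np.any(signal <= 0):
        return _failed()

    x = design if design is not None else build_design_matrix(scheme)
    y = np.log(signal)

    # stage 1: ordinary least squares
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    # stage 2: weights = squared predicted signals from the first pass
    w_sqrt = np.exp(x @ beta)
    beta, _, rank, _ = np.linalg.lstsq(x * w_sqrt[:, None], y * w_sqrt, rcond=None)
    if rank < x.shape[1]:
        return _failed()

    s0 = float(np.exp(beta[0]))
    d_mat = d_from_vec(beta[1:7])
    v_full = w_from_vec(beta[7:22])

    # constraint: floor the diffusion eigenvalues
    lam, vec = np.linalg.eigh(d_mat)
    lam = np.maximum(lam, options.eps_d)
    d_mat = vec @ np.diag(lam) @ vec.T
    d_mat = (d_mat + d_mat.T) / 2.0  # remove eigen-reconstruction round-off
    md, fa, _ = tensor_metrics(d_mat)
    if md <= options.eps_d:
        return _failed()

    w_full = v_full / md**2
    dirs = _mk_direction_set(scheme, options)
    mk = mean_kurtosis(d_mat, w_full, dirs, options.k_min, options.k_max)
    resid = y - x @ beta
    return DKIFitResult(s0=s0, d=d_mat, w=w_full, md=md, fa=fa, mk=mk,
                        fit_ok=True, residual_norm=float(np.linalg.norm(resid)))


def fit_dki_volume(dwi: np.ndarray, mask: np.ndarray, scheme: AcquisitionScheme,
                   options: FitOptions = FitOptions()):
    """Voxelwise kurtosis fit over a 4-D volume.

    Returns (maps, summary) where maps is a dict with 3-D "MK", "FA", "MD"
    arrays (NaN outside the mask and at failed voxels) and summary reports
    the fraction of in-mask voxels that fitted successfully (NaN when the
    mask is empty).
    """
    dwi = np.asarray(dwi, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if dwi.ndim != 4 or dwi.shape[3] != scheme.n_volumes:
        raise ValueError(
            f"dwi must be 4-D with {scheme.n_volumes} volumes, got {dwi.shape}"
        )
    if mask.shape != dwi.shape[:3]:
        raise ValueError(f"mask shape {mask.shape} != volume grid {dwi.shape[:3]}")

    design = build_design_matrix(scheme)
    shape = dwi.shape[:3]
    maps = {name: np.full(shape, MISSING) for name in ("MK", "FA", "MD")}
    n_ok = 0
    coords = np.argwhere(mask)
    for i, j, k in coords:
        res = fit_dki_voxel(dwi[i, j, k], scheme, options, design=design)
        if res.fit_ok:
            n_ok += 1
            maps["MK"][i, j, k] = res.mk
            maps["FA"][i, j, k] = res.fa
            maps["MD"][i, j, k] = res.md
    n_in_mask = coords.shape[0]
    summary = {
        "n_in_mask": int(n_in_mask),
        "n_fit_ok": int(n_ok),
        "fraction_fit_ok": (n_ok / n_in_mask) if n_in_mask else float("nan"),
    }
    return maps, summary
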