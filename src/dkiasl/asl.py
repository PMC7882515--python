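"""Arterial spin labeling CBF quantification (single-delay pcASL).

The perfusion-weighted difference signal dS = control - label is converted
to cerebral blood flow by

    CBF = lambda * (1 - exp(-t_sat/T1g)) * dS * exp(omega/T1b)
          -----------------------------------------------------
          2 * alpha * T1b * (1 - exp(-tau/T1b)) * S0

in (mL blood)/(g tissue)/s, then scaled by 6000 to the conventional
mL/100 g/min.  The quantification is exactly linear in dS/S0, so the model
inverts in closed form (used by the phantom generator).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from math import exp

import numpy as np

__all__ = ["ASLConstants", "difference_signal", "quantify_cbf",
           "predict_delta_signal", "UNIT_SCALE_ML_100G_MIN"]

#: (mL/g/s) -> mL/100 g/min: x100 (per 100 g) and x60 (per minute)
UNIT_SCALE_ML_100G_MIN = 6000.0


@dataclass(frozen=True)
class ASLConstants:
    """Physiological constants of the CBF equation (consensus 3 T pcASL values).

    lambda_coeff: brain/blood partition coefficient (mL/g)
    alpha: labeling efficiency (dimensionless, in (0, 1])
    t1b / t1g: longitudinal relaxation time of blood / gray matter (s)
    t_sat: duration of the pre-imaging saturation pulse (s)
    tau: labeling duration (s)
    omega: post-labeling delay (s)
    """

    lambda_coeff: float = 0.9
    alpha: float = 0.85
    t1b: float = 1.65
    t1g: float = 1.2
    t_sat: float = 2.0
    tau: float = 1.5
    omega: float = 1.5

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"ASL constant {name} must be positive, got {value}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")

    def scale_factor(self) -> float:
        """Multiplier turning dS/S0 into CBF in mL/g/s."""
        num = self.lambda_coeff * (1.0 - exp(-self.t_sat / self.t1g)) \
            * exp(self.omega / self.t1b)
        den = 2.0 * self.alpha * self.t1b * (1.0 - exp(-self.tau / self.t1b))
        return num / den


def difference_signal(control: np.ndarray, label: np.ndarray) -> np.ndarray:
    """Perfusion-weighted difference dS = control - label, elementwise."""
    control = np.asarray(control, dtype=float)
    label = np.asarray(label, dtype=float)
    if control.shape != label.shape:
        raise ValueError(
            f"control {control.shape} and label {label.shape} shapes differ"
        )
    return control - label


def quantify_cbf(delta_s: np.ndarray, s0_ref: np.ndarray,
                 constants: ASLConstants = ASLConstants(),
                 unit_scale: float = UNIT_SCALE_ML_100G_MIN) -> np.ndarray:
    """CBF map from the difference signal and the reference (S0) image.

    Voxels with non-positive reference signal are set to NaN (missing);
    output units are mL/100 g/min under the default unit_scale.
    """
    delta_s = np.asarray(delta_s, dtype=float)
    s0_ref = np.asarray(s0_ref, dtype=float)
    if delta_s.shape != s0_ref.shape:
        raise ValueError(
            f"difference {delta_s.shape} and reference {s0_ref.shape} shapes differ"
        )
    factor = constants.scale_factor() * unit_scale
    with np.errstate(divide="ignore", invalid="ignore"):
        cbf = factor * delta_s / s0_ref
    cbf = np.where(s0_ref > 0, cbf, np.nan)
    return cbf


def predict_delta_signal(cbf_truth: np.ndarray, s0_ref: np.ndarray,
                         constants: ASLConstants = ASLConstants(),
                         unit_scale: float = UNIT_SCALE_ML_100G_MIN) -> np.ndarray:
    """Exact algebraic inverse of :func:`quantify_cbf` (phantom generation)."""
    cbf_truth = np.asarray(cbf_truth, dtype=float)
    s0_ref = np.asarray(s0_ref, dtype=float)
    factor = constants.scale_factor() * unit_scale
    return cbf_truth * s0_ref / factor
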