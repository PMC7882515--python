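"""Synthetic phantoms and cohorts with the statistical structure the
analysis stages assume.

The phantom is a block phantom: the 24 mirror-symmetric ROI blocks of the
default atlas placed on a 48 x 48 x 12 grid at 0.9375 x 0.9375 x 4 mm
(240 mm field of view over a 256 matrix, scaled to a 48-voxel desk grid;
4 mm slices).  Each region carries a scalar ground truth (MD, FA, MK,
CBF); diffusion signals are produced by the forward kurtosis model over
the default 31-volume scheme (1 b0 + 15 directions x {1000, 2000} s/mm2)
and ASL difference signals by the exact algebraic inverse of the CBF
equation, with optional Rician noise.

The cohort generator emulates a three-group study (EC n=33, SCD plus
n=27, aMCI n=31) with Gaussian region-metric values, configurable group
effects whose default directions follow the study's reported pattern
(e.g. reduced MK/CBF in the hippocampal head and posterior cingulate of
the SCD-plus group, broader reductions in aMCI, an elevated left
precuneus), group-matched covariates, and neuropsychological scores
linearly coupled to selected region metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .asl import ASLConstants, predict_delta_signal
from .dki import predict_signal
from .roi import REGION_NAMES, ROISpec, default_atlas_specs, mirror_roi
from .scheme import AcquisitionScheme, default_scheme
from .stats import GROUPS, metric_column
from .tensors import kurtosis_tensor_for_constant_k

__all__ = [
    "RegionTruth", "PhantomConfig", "CohortConfig", "PhantomData",
    "make_phantom", "add_rician_noise", "make_cohort",
    "default_study_config", "build_label_map", "axially_symmetric_tensor",
    "DEFAULT_REGION_TRUTH", "METRIC_SD", "DEFAULT_EFFECTS_SD", "SCORE_MODELS",
]

METRICS = ("MK", "FA", "MD", "CBF")


@dataclass(frozen=True)
class RegionTruth:
    """Scalar ground truth of one region: MD (mm^2/s), FA, MK, CBF (mL/100g/min)."""

    md: float
    fa: float
    mk: float
    cbf: float


# Plausible gray/white-matter values; white-matter regions (FLWM, OLWM) get
# higher anisotropy and kurtosis, lower diffusivity and perfusion.
DEFAULT_REGION_TRUTH: dict[str, RegionTruth] = {
    "Hip (h)": RegionTruth(md=0.95e-3, fa=0.16, mk=0.80, cbf=55.0),
    "Hip (b)": RegionTruth(md=0.93e-3, fa=0.17, mk=0.78, cbf=53.0),
    "Hip (t)": RegionTruth(md=0.92e-3, fa=0.18, mk=0.77, cbf=52.0),
    "PCC": RegionTruth(md=0.88e-3, fa=0.20, mk=0.82, cbf=62.0),
    "Pr": RegionTruth(md=0.90e-3, fa=0.18, mk=0.79, cbf=58.0),
    "DT (a)": RegionTruth(md=0.85e-3, fa=0.24, mk=0.86, cbf=50.0),
    "DT (vl)": RegionTruth(md=0.84e-3, fa=0.26, mk=0.87, cbf=49.0),
    "DT (m)": RegionTruth(md=0.86e-3, fa=0.23, mk=0.85, cbf=50.0),
    "LN": RegionTruth(md=0.80e-3, fa=0.22, mk=0.88, cbf=48.0),
    "CNC": RegionTruth(md=0.82e-3, fa=0.15, mk=0.83, cbf=50.0),
    "FLWM": RegionTruth(md=0.74e-3, fa=0.45, mk=1.02, cbf=24.0),
    "OLWM": RegionTruth(md=0.76e-3, fa=0.42, mk=0.99, cbf=23.0),
}

#: within-group SD of each region-metric in the cohort generator
METRIC_SD = {"MK": 0.06, "FA": 0.04, "MD": 0.06e-3, "CBF": 6.0}

#: group effects in SD units relative to the EC baseline; directions follow
#: the reported pattern (SCD plus: MK/CBF deficits in hippocampal head and
#: PCC, elevation in left precuneus; aMCI: broader, deeper deficits).
DEFAULT_EFFECTS_SD: dict[tuple[str, str, str, str], float] = {
    # --- SCD plus vs EC ---
    ("SCDplus", "MK", "left", "Hip (h)"): -1.0,
    ("SCDplus", "MK", "right", "Hip (h)"): -0.6,
    ("SCDplus", "MK", "left", "PCC"): -0.6,
    ("SCDplus", "MK", "left", "DT (a)"): -0.5,
    ("SCDplus", "MK", "left", "OLWM"): -0.5,
    ("SCDplus", "MK", "left", "Pr"): 0.5,
    ("SCDplus", "CBF", "left", "Hip (h)"): -0.9,
    ("SCDplus", "CBF", "left", "PCC"): -0.7,
    ("SCDplus", "CBF", "right", "PCC"): -0.6,
    ("SCDplus", "CBF", "left", "Pr"): 0.6,
    ("SCDplus", "FA", "left", "OLWM"): -0.7,
    # --- aMCI vs EC ---
    ("aMCI", "MK", "left", "Hip (h)"): -1.5,
    ("aMCI", "MK", "right", "Hip (h)"): -1.1,
    ("aMCI", "MK", "left", "Hip (b)"): -0.9,
    ("aMCI", "MK", "left", "PCC"): -1.4,
    ("aMCI", "MK", "right", "PCC"): -0.9,
    ("aMCI", "MK", "left", "DT (a)"): -1.1,
    ("aMCI", "MK", "right", "DT (a)"): -0.9,
    ("aMCI", "MK", "left", "DT (vl)"): -0.9,
    ("aMCI", "MK", "left", "OLWM"): -1.1,
    ("aMCI", "MK", "right", "OLWM"): -0.9,
    ("aMCI", "MK", "left", "CNC"): -0.9,
    ("aMCI", "MK", "left", "Pr"): -0.2,
    ("aMCI", "CBF", "left", "Hip (h)"): -1.3,
    ("aMCI", "CBF", "right", "Hip (h)"): -0.9,
    ("aMCI", "CBF", "left", "PCC"): -1.3,
    ("aMCI", "CBF", "right", "PCC"): -0.9,
    ("aMCI", "CBF", "left", "DT (a)"): -1.0,
    ("aMCI", "CBF", "right", "DT (a)"): -0.8,
    ("aMCI", "CBF", "left", "OLWM"): -0.8,
    ("aMCI", "CBF", "left", "CNC"): -0.8,
    ("aMCI", "CBF", "left", "FLWM"): -0.8,
    ("aMCI", "CBF", "left", "Pr"): -0.2,
    ("aMCI", "FA", "left", "PCC"): -0.8,
    ("aMCI", "FA", "right", "PCC"): -0.8,
    ("aMCI", "FA", "left", "Pr"): -0.8,
    ("aMCI", "FA", "left", "OLWM"): -0.9,
    ("aMCI", "FA", "right", "OLWM"): -0.9,
    ("aMCI", "FA", "left", "FLWM"): -0.8,
    ("aMCI", "FA", "right", "FLWM"): -0.8,
    ("aMCI", "MD", "left", "Hip (h)"): 0.8,
    ("aMCI", "MD", "left", "PCC"): 0.8,
    ("aMCI", "MD", "left", "DT (a)"): 0.8,
    ("aMCI", "MD", "left", "OLWM"): 0.8,
}

#: per-group covariate distributions (means/SDs and female fraction match
#: the emulated study's demographics table)
COVARIATES = {
    "EC": {"age": (67.061, 6.067), "education": (10.061, 1.619), "p_female": 20 / 33},
    "SCDplus": {"age": (68.074, 7.014), "education": (9.852, 1.747), "p_female": 15 / 27},
    "aMCI": {"age": (68.645, 6.879), "education": (9.907, 1.578), "p_female": 19 / 31},
}

#: score models: per-group means, SD, and couplings (metric, hemisphere,
#: region, weight) to the standardized within-group region-metric deviation.
SCORE_MODELS: dict[str, dict] = {
    "AVLT-IR": {
        "means": {"EC": 8.727, "SCDplus": 8.111, "aMCI": 7.335}, "sd": 1.25,
        "couplings": [("MK", "left", "Hip (h)", 0.30)],
    },
    "AVLT-DR": {
        "means": {"EC": 8.970, "SCDplus": 7.556, "aMCI": 5.387}, "sd": 1.10,
        "couplings": [("MK", "left", "Hip (h)", 0.45),
                      ("MK", "left", "PCC", 0.25),
                      ("CBF", "left", "Hip (h)", 0.30)],
    },
    "AVLT-recognition": {
        "means": {"EC": 10.061, "SCDplus": 9.370, "aMCI": 8.419}, "sd": 1.23,
        "couplings": [("MK", "left", "Hip (h)", 0.30)],
    },
    "MMSE": {
        "means": {"EC": 27.879, "SCDplus": 26.856, "aMCI": 25.386}, "sd": 1.80,
        "couplings": [("MK", "left", "Hip (h)", 0.20)],
    },
    "MoCA": {
        "means": {"EC": 26.324, "SCDplus": 25.763, "aMCI": 22.365}, "sd": 2.60,
        "couplings": [("MK", "left", "Hip (h)", 0.20)],
    },
}


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (48, 48, 12)
    voxel_dims: tuple[float, float, float] = (0.9375, 0.9375, 4.0)
    region_truth: dict[str, RegionTruth] = field(
        default_factory=lambda: dict(DEFAULT_REGION_TRUTH))
    noise: str = "none"               # "none" | "rician"
    snr: float = 50.0                 # at the b=0 signal level
    s0_dwi: float = 100.0
    s0_ref: float = 100.0
    anisotropic_kurtosis: bool = False  # randomly orient each region's tensor
    seed: int = 0

    def __post_init__(self):
        if self.noise not in ("none", "rician"):
            raise ValueError(f"unknown noise model: {self.noise}")
        if self.noise == "rician" and not self.snr > 0:
            raise ValueError("SNR must be positive when noise is enabled")
        missing = set(REGION_NAMES) - set(self.region_truth)
        if missing:
            raise ValueError(f"region_truth lacks regions: {sorted(missing)}")


@dataclass
class CohortConfig:
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"EC": 33, "SCDplus": 27, "aMCI": 31})
    region_truth: dict[str, RegionTruth] = field(
        default_factory=lambda: dict(DEFAULT_REGION_TRUTH))
    metric_sd: dict[str, float] = field(default_factory=lambda: dict(METRIC_SD))
    effects_sd: dict[tuple[str, str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS_SD))
    between_region_corr: float = 0.3  # equicorrelation within (subject, metric)
    covariates: dict = field(default_factory=lambda: {g: dict(v) for g, v in COVARIATES.items()})
    score_models: dict = field(default_factory=lambda: {
        k: {"means": dict(v["means"]), "sd": v["sd"],
            "couplings": list(v["couplings"])} for k, v in SCORE_MODELS.items()})
    distribution: str = "gaussian"    # "gaussian" | "lognormal"
    seed: int = 0

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g} needs n >= 2")
        for m, sd in self.metric_sd.items():
            if not sd > 0:
                raise ValueError(f"SD for {m} must be positive")
        if not 0 <= self.between_region_corr < 1:
            raise ValueError("between_region_corr must lie in [0, 1)")
        if self.distribution not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown distribution: {self.distribution}")


@dataclass
class PhantomData:
    dwi: np.ndarray
    scheme: AcquisitionScheme
    asl_control: np.ndarray
    asl_label: np.ndarray
    s0_ref: np.ndarray
    label_map: np.ndarray
    specs: list[ROISpec]
    mask: np.ndarray
    truth: dict
    voxel_dims: tuple[float, float, float]


def axially_symmetric_tensor(md: float, fa: float) -> np.ndarray:
    """Diffusion tensor diag(l1, l2, l2) with the prescribed MD and FA.

    With l1 = MD(1+2f), l2 = l3 = MD(1-f) the FA closed form reduces to
    FA = 3f / sqrt(3 + 6 f^2), inverted here for f.
    """
    if not 0 <= fa < 1:
        raise ValueError("FA must lie in [0, 1)")
    if md <= 0:
        raise ValueError("MD must be positive")
    f = fa * np.sqrt(1.0 / (3.0 - 2.0 * fa**2))
    return np.diag([md * (1 + 2 * f), md * (1 - f), md * (1 - f)])


def build_label_map(shape: tuple[int, int, int] = (48, 48, 12)):
    """The 24-region block atlas: 12 left blocks mirrored to the right.

    Each region is a 4 x 6 in-plane block (24 voxels/slice, 21.1 mm^2 at
    the default 0.9375 mm in-plane spacing — inside the 18-22 mm^2
    protocol window) over 2 slices.  Right-hemisphere blocks are the exact
    left-to-right mirror of their left partners.
    """
    nx, ny, nz = shape
    if nx < 16 or ny < 44 or nz < 12:
        raise ValueError(f"grid {shape} too small for the default atlas layout")
    label = np.zeros(shape, dtype=np.int16)
    specs = default_atlas_specs()
    for i, name in enumerate(REGION_NAMES):
        yslot, zslot = i % 6, i // 6
        y0 = 2 + 7 * yslot
        z0 = 2 + 6 * zslot
        left = np.zeros(shape, dtype=bool)
        left[6:10, y0:y0 + 6, z0:z0 + 2] = True
        right = mirror_roi(left, flip_axis=0)
        label[left] = i + 1
        label[right] = i + 13
    return label, specs


def add_rician_noise(signal: np.ndarray, sigma: float,
                     rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Magnitude-MRI Rician noise: sqrt((s + g1*sigma)^2 + (g2*sigma)^2)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    g1 = rng.standard_normal(signal.shape)
    g2 = rng.standard_normal(signal.shape)
    return np.sqrt((signal + g1 * sigma) ** 2 + (g2 * sigma) ** 2)


def make_phantom(config: PhantomConfig = PhantomConfig(),
                 scheme: AcquisitionScheme | None = None,
                 constants: ASLConstants = ASLConstants()) -> PhantomData:
    """Generate the block phantom: DWI 4-D volume, ASL pair, labels, truth.

    Signals are produced per region by the forward kurtosis model (the
    kurtosis tensor is constructed so the directional apparent kurtosis is
    constant at the region's MK — exactly recoverable by the fitter) and
    by the algebraic ASL inverse.  Deterministic under a fixed seed.
    """
    if scheme is None:
        scheme = default_scheme()
    label_map, specs = build_label_map(config.shape)
    mask = label_map > 0
    rng = np.random.default_rng(config.seed)

    dwi = np.zeros(config.shape + (scheme.n_volumes,))
    cbf_truth_map = np.zeros(config.shape)
    truth_regions = {}
    for spec in specs:
        rt = config.region_truth[spec.name]
        d_mat = axially_symmetric_tensor(rt.md, rt.fa)
        if config.anisotropic_kurtosis:
            # random orientation per region; MK is rotation invariant
            from scipy.stats import special_ortho_group
            rot = special_ortho_group.rvs(3, random_state=rng)
            d_mat = rot @ d_mat @ rot.T
        w_full = kurtosis_tensor_for_constant_k(d_mat, rt.mk)
        sig = predict_signal(config.s0_dwi, d_mat, w_full, scheme)
        sel = label_map == spec.label_id
        dwi[sel] = sig
        cbf_truth_map[sel] = rt.cbf
        truth_regions[f"{spec.hemisphere}:{spec.name}"] = {
            "MD": rt.md, "FA": rt.fa, "MK": rt.mk, "CBF": rt.cbf,
        }

    s0_ref = np.where(mask, config.s0_ref, 0.0)
    delta = predict_delta_signal(cbf_truth_map, s0_ref, constants)
    control = s0_ref + delta / 2.0
    label_img = s0_ref - delta / 2.0

    if config.noise == "rician":
        sigma = config.s0_dwi / config.snr
        dwi = add_rician_noise(dwi, sigma, rng)
        sigma_asl = config.s0_ref / config.snr
        control = add_rician_noise(control, sigma_asl, rng)
        label_img = add_rician_noise(label_img, sigma_asl, rng)

    truth = {
        "regions": truth_regions,
        "config": {
            "shape": list(config.shape),
            "voxel_dims": list(config.voxel_dims),
            "noise": config.noise,
            "snr": config.snr,
            "s0_dwi": config.s0_dwi,
            "s0_ref": config.s0_ref,
            "seed": config.seed,
        },
        "asl_constants": asdict(constants),
    }
    return PhantomData(dwi=dwi, scheme=scheme, asl_control=control,
                       asl_label=label_img, s0_ref=s0_ref,
                       label_map=label_map, specs=specs, mask=mask,
                       truth=truth, voxel_dims=config.voxel_dims)


def make_cohort(config: CohortConfig = CohortConfig()) -> tuple[pd.DataFrame, dict]:
    """Generate the three-group cohort table (wide format) and its ground truth.

    Region-metric values are Gaussian with an equicorrelated between-region
    structure within each (subject, metric); scores are linear in the
    standardized within-group deviations of their coupled region metrics
    plus independent Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    rho = config.between_region_corr
    rows = []
    sid = 0
    z_store: dict[tuple[int, str, str, str], float] = {}
    region_cols = [(m, h, r) for m in METRICS for h in ("left", "right")
                   for r in REGION_NAMES]
    for group in GROUPS:
        n = config.group_sizes[group]
        cov = config.covariates[group]
        for _ in range(n):
            row = {"subject_id": f"S{sid:03d}", "group": group}
            row["age"] = rng.normal(*cov["age"])
            row["sex"] = "F" if rng.random() < cov["p_female"] else "M"
            row["education"] = rng.normal(*cov["education"])
            shared = {m: rng.standard_normal() for m in METRICS}
            for m, h, r in region_cols:
                base = getattr(config.region_truth[r], m.lower())
                delta = config.effects_sd.get((group, m, h, r), 0.0)
                sd = config.metric_sd[m]
                z = np.sqrt(rho) * shared[m] + np.sqrt(1 - rho) * rng.standard_normal()
                if config.distribution == "lognormal":
                    # heavy-tailed option to exercise the rank-test branch
                    z = (np.exp(0.8 * z) - np.exp(0.32)) / \
                        np.sqrt((np.exp(0.64) - 1) * np.exp(0.64))
                value = base + sd * (delta + z)
                row[metric_column(m, h, r)] = value
                z_store[(sid, m, h, r)] = z
            for score, model in config.score_models.items():
                c_total = 0.0
                signal = 0.0
                for m, h, r, w in model["couplings"]:
                    signal += w * z_store[(sid, m, h, r)]
                    c_total += w**2
                resid_sd = np.sqrt(max(1.0 - c_total, 0.05))
                row[score] = model["means"][group] + model["sd"] * (
                    signal + resid_sd * rng.standard_normal())
            rows.append(row)
            sid += 1
    table = pd.DataFrame(rows)
    truth = {
        "group_sizes": dict(config.group_sizes),
        "metric_sd": dict(config.metric_sd),
        "between_region_corr": rho,
        "effects_sd": {"|".join(k): v for k, v in config.effects_sd.items()},
        "score_couplings": {s: [list(c) for c in m["couplings"]]
                            for s, m in config.score_models.items()},
        "distribution": config.distribution,
        "seed": config.seed,
    }
    return table, truth


def default_study_config() -> tuple[PhantomConfig, CohortConfig]:
    """The shipped study-default configuration pair.

    Phantom: 31-volume scheme (1 b0 + 15 directions x {1000, 2000} s/mm2)
    on the 48 x 48 x 12 grid.  Cohort: group sizes EC/SCD plus/aMCI =
    33/27/31 with the default effect pattern; the ASL post-labeling delay
    default is 1.5 s.
    """
    return PhantomConfig(), CohortConfig()
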