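"""End-to-end orchestration of the analysis stages.

The four stages mirror how the study's data flowed: ``simulate`` writes a
synthetic dataset (DWI + gradient tables, ASL pair + reference, ROI atlas,
cohort table, ground truth); ``fit`` turns DWI/ASL into MK/FA/MD/CBF maps;
``roi`` extracts the two-rater, three-replicate ROI measurement table and
its ICC report; ``stats`` runs the group comparisons, covariate-adjusted
correlations and ROC analysis on a cohort table.  Every stage writes a
JSON report embedding the package version, a config hash, and the seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asl import ASLConstants, difference_signal, quantify_cbf
from .dki import FitOptions, fit_dki_volume
from .io import read_volume, write_map, write_volume
from .roi import (REGION_NAMES, average_replicates, default_atlas_specs,
                  extract_roi_values, icc_two_rater)
from .scheme import read_bval_bvec, write_bval_bvec
from .stats import (GROUPS, combined_auc, metric_column, partial_pearson,
                    regionwise_group_analysis, roc_auc)
from .synth import CohortConfig, PhantomConfig, make_cohort, make_phantom

log = logging.getLogger("dkiasl")

__all__ = ["RunConfig", "load_config", "run_simulate", "run_fit", "run_roi",
           "run_stats", "DEFAULT_ROC_CONTRASTS", "DEFAULT_CORRELATIONS",
           "ConfigError", "DataError"]


class ConfigError(ValueError):
    """Malformed or unknown configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Inconsistent input data (CLI exit code 3)."""


#: default ROC feature sets: the study's combined-biomarker contrasts
#: (metric, positive group, reference group, [(hemisphere, region), ...])
DEFAULT_ROC_CONTRASTS = [
    {"metric": "MK", "positive": "SCDplus", "reference": "EC",
     "features": [("left", "Hip (h)"), ("right", "Hip (h)"), ("left", "PCC"),
                  ("left", "Pr"), ("left", "DT (a)"), ("left", "OLWM")]},
    {"metric": "CBF", "positive": "SCDplus", "reference": "EC",
     "features": [("left", "Hip (h)"), ("left", "PCC"), ("left", "Pr"),
                  ("right", "PCC")]},
    {"metric": "MK", "positive": "SCDplus", "reference": "aMCI",
     "features": [("left", "PCC"), ("left", "Pr"), ("right", "PCC")]},
    {"metric": "CBF", "positive": "SCDplus", "reference": "aMCI",
     "features": [("left", "Pr"), ("left", "DT (a)")]},
]

#: default covariate-adjusted correlations, computed within the SCD-plus
#: group: (score, metric, hemisphere, region)
DEFAULT_CORRELATIONS = [
    ("AVLT-DR", "MK", "left", "Hip (h)"),
    ("AVLT-DR", "MK", "left", "PCC"),
    ("AVLT-DR", "CBF", "left", "Hip (h)"),
]

_KNOWN_KEYS = {
    "seed": int,
    "phantom": {"noise", "snr", "seed", "anisotropic_kurtosis", "shape",
                "voxel_dims", "s0_dwi", "s0_ref"},
    "cohort": {"seed", "distribution", "between_region_corr", "group_sizes"},
    "asl": {"lambda_coeff", "alpha", "t1b", "t1g", "t_sat", "tau", "omega"},
    "fit": {"eps_d", "k_min", "k_max", "mk_directions"},
    "roi": {"rater_jitter", "n_replicates", "icc_form", "seed"},
    "stats": {"q", "icc_form", "ci_method", "seed", "correlation_group"},
}


@dataclass
class RunConfig:
    seed: int = 0
    phantom: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    asl: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    roi: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def asl_constants(self) -> ASLConstants:
        return ASLConstants(**self.asl)

    def fit_options(self) -> FitOptions:
        return FitOptions(**self.fit)


def load_config(path: str | Path | None) -> RunConfig:
    """Parse a YAML run configuration, rejecting unknown keys."""
    if path is None:
        return RunConfig()
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    unknown = set(raw) - set(_KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in _KNOWN_KEYS.items():
        if section == "seed" or section not in raw:
            continue
        if not isinstance(raw[section], dict):
            raise ConfigError(f"config section '{section}' must be a mapping")
        extra = set(raw[section]) - allowed
        if extra:
            raise ConfigError(f"unknown keys in '{section}': {sorted(extra)}")
    return RunConfig(**{k: v for k, v in raw.items()})


def _report(outdir: Path, name: str, payload: dict, config: RunConfig) -> dict:
    payload = dict(payload)
    payload["package_version"] = __version__
    payload["config_hash"] = config.hash()
    payload["config"] = asdict(config)
    path = outdir / name
    path.write_text(json.dumps(payload, indent=2, default=str))
    return payload


# ---------------------------------------------------------------------------
# stages


def run_simulate(config: RunConfig, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pcfg_kwargs = dict(config.phantom)
    pcfg_kwargs.setdefault("seed", config.seed)
    if "shape" in pcfg_kwargs:
        pcfg_kwargs["shape"] = tuple(pcfg_kwargs["shape"])
    if "voxel_dims" in pcfg_kwargs:
        pcfg_kwargs["voxel_dims"] = tuple(pcfg_kwargs["voxel_dims"])
    ccfg_kwargs = dict(config.cohort)
    ccfg_kwargs.setdefault("seed", config.seed)
    try:
        pcfg = PhantomConfig(**pcfg_kwargs)
        ccfg = CohortConfig(**ccfg_kwargs)
        constants = config.asl_constants()
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    phantom = make_phantom(pcfg, constants=constants)
    cohort, cohort_truth = make_cohort(ccfg)

    vd = phantom.voxel_dims
    write_volume(phantom.dwi, outdir / "dwi.nii.gz", voxel_dims=vd)
    write_bval_bvec(phantom.scheme, outdir / "dwi.bval", outdir / "dwi.bvec")
    write_volume(phantom.asl_control, outdir / "asl_control.nii.gz", voxel_dims=vd)
    write_volume(phantom.asl_label, outdir / "asl_label.nii.gz", voxel_dims=vd)
    write_volume(phantom.s0_ref, outdir / "m0.nii.gz", voxel_dims=vd)
    write_volume(phantom.label_map, outdir / "atlas.nii.gz", voxel_dims=vd)
    atlas_meta = {str(s.label_id): {"name": s.name, "hemisphere": s.hemisphere}
                  for s in phantom.specs}
    (outdir / "atlas.json").write_text(json.dumps(atlas_meta, indent=2))
    cohort.to_csv(outdir / "cohort.csv", index=False)
    truth = {"phantom": phantom.truth, "cohort": cohort_truth}
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))

    manifest = {"files": {}}
    for f in sorted(outdir.iterdir()):
        if f.name == "simulate_report.json":
            continue
        manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    _report(outdir, "simulate_report.json",
            {"stage": "simulate", "manifest": manifest,
             "seeds": {"phantom": pcfg.seed, "cohort": ccfg.seed}}, config)
    log.info("simulated dataset in %s (%d files)", outdir, len(manifest["files"]))
    return manifest


def run_fit(config: RunConfig, outdir: str | Path, dwi_path, bval_path,
            bvec_path, asl_control=None, asl_label=None, m0=None,
            mask_path=None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for p in (dwi_path, bval_path, bvec_path):
        if not Path(p).exists():
            raise DataError(f"missing input file: {p}")
    try:
        scheme = read_bval_bvec(bval_path, bvec_path)
    except ValueError as exc:
        raise DataError(f"invalid gradient table: {exc}") from exc
    dwi, affine = read_volume(dwi_path)
    if dwi.ndim != 4:
        raise DataError(f"DWI must be 4-D, got shape {dwi.shape}")
    if dwi.shape[3] != scheme.n_volumes:
        raise DataError(
            f"DWI has {dwi.shape[3]} volumes but gradient table has "
            f"{scheme.n_volumes}")
    if mask_path is not None:
        mask, _ = read_volume(mask_path)
        mask = mask > 0
        if mask.shape != dwi.shape[:3]:
            raise DataError("mask grid does not match the DWI grid")
    else:
        # in-brain voxels: positive signal on every volume
        mask = np.all(dwi > 0, axis=3)
    vd = tuple(np.abs(np.diag(affine))[:3])
    options = config.fit_options()
    maps, summary = fit_dki_volume(dwi, mask, scheme, options)
    sidecar = {"fit_options": asdict(options), **summary}
    for name in ("MK", "FA", "MD"):
        write_map(maps[name], name, outdir / f"{name.lower()}.nii.gz",
                  voxel_dims=vd, sidecar=sidecar)
    log.info("DKI fit: %s", summary)

    report = {"stage": "fit", "dki_summary": summary}
    if asl_control is not None and asl_label is not None and m0 is not None:
        control, _ = read_volume(asl_control)
        label_img, _ = read_volume(asl_label)
        s0_ref, _ = read_volume(m0)
        if control.shape != label_img.shape or control.shape != s0_ref.shape:
            raise DataError("ASL control/label/M0 grids do not match")
        constants = config.asl_constants()
        delta = difference_signal(control, label_img)
        cbf = quantify_cbf(delta, s0_ref, constants)
        cbf = np.where(mask, cbf, np.nan)
        write_map(cbf, "CBF", outdir / "cbf.nii.gz", voxel_dims=vd,
                  sidecar={"asl_constants": asdict(constants)})
        report["asl_constants"] = asdict(constants)
    return _report(outdir, "fit_report.json", report, config)


def _load_atlas(atlas_path) -> tuple[np.ndarray, list]:
    from .roi import ROISpec

    label_map, _ = read_volume(atlas_path)
    label_map = np.rint(label_map).astype(int)
    sidecar = Path(str(atlas_path)).with_suffix("").with_suffix("")
    sidecar = Path(str(sidecar) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        specs = [ROISpec(int(k), v["name"], v["hemisphere"])
                 for k, v in meta.items()]
    else:
        specs = default_atlas_specs()
    return label_map, specs


def _jittered_mean(param_map, label_map, spec, shift) -> float:
    sel = label_map == spec.label_id
    if shift != (0, 0):
        sel = np.roll(np.roll(sel, shift[0], axis=0), shift[1], axis=1)
    vals = param_map[sel]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else np.nan


def run_roi(config: RunConfig, outdir: str | Path, maps_dir, atlas_path,
            subject_id: str = "phantom") -> dict:
    """ROI measurement stage: two raters x three replicates per region.

    Rater re-placement of a manual ROI is emulated by re-extracting each
    region under a small seeded in-plane translation of its mask; with
    rater_jitter 0 (default) all replicates coincide and the ICC of every
    metric is exactly 1.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    maps_dir = Path(maps_dir)
    label_map, specs = _load_atlas(atlas_path)
    jitter = int(config.roi.get("rater_jitter", 0))
    n_rep = int(config.roi.get("n_replicates", 3))
    form = config.roi.get("icc_form", "consistency")
    seed = int(config.roi.get("seed", config.seed))
    rng = np.random.default_rng(seed)

    records = []
    for metric, fname in (("MK", "mk.nii.gz"), ("FA", "fa.nii.gz"),
                          ("MD", "md.nii.gz"), ("CBF", "cbf.nii.gz")):
        fpath = maps_dir / fname
        if not fpath.exists():
            continue
        pmap, _ = read_volume(fpath)
        if pmap.shape != label_map.shape:
            raise DataError(
                f"map {fname} grid {pmap.shape} != atlas grid {label_map.shape}")
        for spec in specs:
            for rater in (1, 2):
                for rep in range(1, n_rep + 1):
                    shift = (0, 0) if jitter == 0 else tuple(
                        rng.integers(-jitter, jitter + 1, size=2))
                    records.append({
                        "subject_id": subject_id, "region": spec.name,
                        "hemisphere": spec.hemisphere, "metric": metric,
                        "rater": rater, "replicate": rep,
                        "value": _jittered_mean(pmap, label_map, spec, shift),
                    })
    if not records:
        raise DataError(f"no parameter maps found in {maps_dir}")
    table = pd.DataFrame(records)
    table.to_csv(outdir / "measurements.csv", index=False)
    combined, per_rater = average_replicates(table)
    combined.to_csv(outdir / "roi_means.csv", index=False)

    # single-subject mode: ICC per metric across the regions as targets
    icc_rows = []
    for metric, grp in per_rater.groupby("metric"):
        wide = grp.pivot_table(index=["region", "hemisphere"], columns="rater",
                               values="value")
        try:
            icc, good = icc_two_rater(wide[1].to_numpy(), wide[2].to_numpy(),
                                      form=form)
        except ValueError:
            icc, good = np.nan, False
        icc_rows.append({"metric": metric, "icc": icc, "good": good,
                         "flagged_low": (not good)})
    icc_table = pd.DataFrame(icc_rows)
    icc_table.to_csv(outdir / "icc_report.csv", index=False)
    low = icc_table.loc[icc_table["flagged_low"], "metric"].tolist()
    if low:
        log.warning("ICC <= 0.75 for metrics: %s", low)
    report = {"stage": "roi", "n_regions": len(specs),
              "icc": icc_table.to_dict(orient="records"),
              "seeds": {"roi": seed}}
    return _report(outdir, "roi_report.json", report, config)


def run_stats(config: RunConfig, outdir: str | Path, cohort_path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(cohort_path)
    if "group" not in cohort.columns:
        raise DataError("cohort table lacks a 'group' column")
    q = float(config.stats.get("q", 0.05))
    corr_group = config.stats.get("correlation_group", "SCDplus")

    frames = []
    for metric in ("MK", "FA", "MD", "CBF"):
        for hemi in ("left", "right"):
            col = metric_column(metric, hemi, REGION_NAMES[0])
            if col not in cohort.columns:
                continue
            try:
                frames.append(regionwise_group_analysis(cohort, metric, hemi, q=q))
            except ValueError as exc:
                raise DataError(str(exc)) from exc
    if not frames:
        raise DataError("cohort table carries no recognizable metric columns")
    results = pd.concat(frames, ignore_index=True)
    results.to_csv(outdir / "group_comparisons.csv", index=False)

    # covariate-adjusted correlations within the configured group
    sub = cohort[cohort["group"] == corr_group]
    sex01 = (sub["sex"] == "F").astype(float)  # M=0, F=1
    covs = np.column_stack([sub["age"], sex01, sub["education"]])
    correlations = []
    for score, metric, hemi, region in DEFAULT_CORRELATIONS:
        col = metric_column(metric, hemi, region)
        if score not in sub.columns or col not in sub.columns:
            continue
        r, p = partial_pearson(sub[col], sub[score], covs)
        correlations.append({"score": score, "metric": metric,
                             "hemisphere": hemi, "region": region,
                             "group": corr_group, "r": r, "p": p})

    # single and combined ROC per configured contrast
    rocs = []
    for contrast in DEFAULT_ROC_CONTRASTS:
        metric = contrast["metric"]
        pos, ref = contrast["positive"], contrast["reference"]
        pair = cohort[cohort["group"].isin([pos, ref])]
        cols = [metric_column(metric, h, r) for h, r in contrast["features"]]
        if any(c not in pair.columns for c in cols):
            continue
        labels = pair["group"].to_numpy()
        singles = {}
        for c in cols:
            res = roc_auc(pair[c], labels, positive_class=pos)
            singles[c] = {"auc": res.auc, "ci": [res.ci_low, res.ci_high]}
        comb = combined_auc(pair[cols], labels, positive_class=pos)
        rocs.append({
            "metric": metric, "positive": pos, "reference": ref,
            "features": cols, "single": singles,
            "combined": {"auc": comb.auc, "ci": [comb.ci_low, comb.ci_high],
                         "weights": comb.weights,
                         "ridge_fallback": comb.ridge_fallback},
        })

    report = {
        "stage": "stats", "q": q,
        "n_comparisons": int(len(results)),
        "n_fdr_rejections": int(results["reject_fdr"].sum()),
        "correlations": correlations,
        "roc": rocs,
        "seeds": {"stats": config.stats.get("seed", config.seed)},
    }
    report = _report(outdir, "stats_report.json", report, config)
    log.info("stats: %d families, %d FDR rejections", len(frames),
             report["n_fdr_rejections"])
    return report
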