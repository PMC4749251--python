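"""End-to-end orchestration: simulate -> denoise/segment -> QC -> ETDRS ->
intensity -> cohort statistics, with a single config and reproducible seeds.

The config is one YAML/JSON document with blocks
``{seed, simulate | inputs, segment, etdrs, stats}``; all defaults are
embedded (see :func:`default_config`). Given the same config the pipeline is
deterministic: every per-subject random stream is derived from the root seed.

Outputs written to the output directory:

* ``intensity_<subject>.csv`` — per-volume (layer, sector) table
* ``cohort.csv`` — covariates plus measured per-layer means
* ``sector_means.csv`` — cohort mean/SD per (layer, sector)
* ``age_groups.csv`` — per-decade per-layer mean +/- SD
* ``correlations.csv`` — covariate x layer univariate screen
* ``stepwise.csv`` — stepwise regression per layer (standardized betas)
* ``group_tests.csv`` — sex comparison and paired nasal-vs-temporal tests
* ``icc.csv`` — per-layer two-operator ICC (when rescan pairs are simulated)
* ``qc_log.json`` — per-volume QC outcome; excluded volumes and reasons
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as oio
from .cohort import COVARIATES, CohortModel, generate_cohort, phantom_spec_for_subject
from .etdrs import build_etdrs_masks, locate_fovea
from .layers import LAYER_NAMES
from .metrics import layer_sector_intensity, layer_means
from .phantom import PhantomSpec, RescanJitter, generate_phantom, generate_rescan_pair
from .segmentation import QCThresholds, SegmentationConfig, SegmentationError, \
    qc_surfaces, segment_retina
from .stats import age_group_summary, compare_groups, correlation_screen, \
    icc_two_operator, stepwise_ols, univariate_screen


class PipelineError(RuntimeError):
    pass


def default_config() -> dict:
    return {
        "seed": 1,
        "simulate": {
            "n_subjects": 20,
            "shape": [128, 32, 256],
            "rescan_subjects": 0,
        },
        "segment": {"dx": 2, "dy": 6, "band_margin": 8,
                    "cad_iterations": 3, "cad_conductance": 2.0, "cad_time_step": 0.0625},
        "etdrs": {"presmooth": [5, 3]},
        "stats": {"alpha_in": 0.05, "alpha_out": 0.10},
    }


def _merge(base: dict, override: Optional[dict]) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return _merge(default_config(), cfg or {})


def _child_seed(root: int, tag: int) -> int:
    return int(np.random.SeedSequence([root, tag]).generate_state(1)[0] % (2**31))


def measure_volume(vol, seg_cfg: SegmentationConfig, presmooth=(5, 3),
                   qc: Optional[QCThresholds] = None):
    """Segment, QC, map the ETDRS grid and measure one volume.

    Returns (intensity table, surfaces, grid, qc report). Raises
    :class:`SegmentationError` on unrecoverable failures.
    """
    surfaces = segment_retina(vol, seg_cfg)
    report = qc_surfaces(surfaces, vol, qc)
    center = locate_fovea(surfaces.z[0], presmooth=tuple(presmooth))
    grid = build_etdrs_masks(center, vol.laterality, surfaces.z[0].shape,
                             (vol.dx_mm, vol.dy_mm))
    table = layer_sector_intensity(vol, surfaces, grid, subject_id=vol.subject_id)
    return table, surfaces, grid, report


def cohort_statistics(cohort: pd.DataFrame, alpha_in: float = 0.05,
                      alpha_out: float = 0.10) -> dict:
    """The full statistical battery over a cohort with measured layer means."""
    out = {}
    out["correlations"] = correlation_screen(cohort, method="pearson")
    out["correlations_spearman"] = correlation_screen(cohort, method="spearman")

    rows = []
    for layer in LAYER_NAMES:
        cands = univariate_screen(cohort, layer, COVARIATES, alpha=alpha_in)
        if cands and len(cohort) <= len(cands) + 10:
            rows.append((layer, "(cohort too small for stepwise)", np.nan, np.nan, np.nan))
        elif cands:
            res = stepwise_ols(cohort, layer, cands, alpha_in=alpha_in, alpha_out=alpha_out)
            for term in res.selected:
                rows.append((layer, term, res.beta_std[term], res.p_values[term],
                             res.r_squared))
            if not res.selected:
                rows.append((layer, "(none)", np.nan, np.nan, 0.0))
        else:
            rows.append((layer, "(none)", np.nan, np.nan, 0.0))
    out["stepwise"] = pd.DataFrame(
        rows, columns=["layer", "predictor", "beta_std", "p", "r_squared"])

    table, trends = age_group_summary(cohort)
    out["age_groups"] = table
    out["age_trends"] = pd.DataFrame(
        [(layer, r, p) for layer, (r, p) in trends.items()],
        columns=["layer", "spearman_r", "p"])

    grows = []
    men = cohort[cohort["sex"] == "M"]
    women = cohort[cohort["sex"] == "F"]
    for layer in LAYER_NAMES:
        if len(men) >= 2 and len(women) >= 2:
            t = compare_groups(men[layer], women[layer], mode="independent")
            grows.append((layer, "sex_M_vs_F", t.t, t.p))
        for a, b in (("nasal", "temporal"),):
            ca, cb = f"{a}_{layer}", f"{b}_{layer}"
            if ca in cohort.columns and cb in cohort.columns:
                t = compare_groups(cohort[ca], cohort[cb], mode="paired")
                grows.append((layer, "nasal_vs_temporal_paired", t.t, t.p))
    out["group_tests"] = pd.DataFrame(grows, columns=["layer", "test", "t", "p"])
    return out


def run_pipeline(config, outdir) -> dict:
    """Run the configured workflow; returns a summary dict (also JSON-logged)."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        config = _merge(default_config(), config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    seg_block = dict(config["segment"])
    seg_cfg = SegmentationConfig(**seg_block)
    presmooth = config["etdrs"]["presmooth"]

    qc_log = []
    volumes = []
    encoded = None
    if "inputs" in config:
        indir = Path(config["inputs"]["dir"])
        paths = sorted(indir.glob("*.tif")) + sorted(indir.glob("*.tiff")) \
            + sorted(indir.glob("*.nii")) + sorted(indir.glob("*.nii.gz"))
        if not paths:
            raise PipelineError(f"no input volumes found in {indir}")
        cohort = None
        for p in paths:
            volumes.append((p.stem, oio.read_volume(p)))
    else:
        sim = config["simulate"]
        model = CohortModel()
        cohort = generate_cohort(model, int(sim["n_subjects"]), seed=_child_seed(seed, 0))
        base_spec = PhantomSpec(shape=tuple(sim["shape"]))
        for i, row in cohort.iterrows():
            spec = phantom_spec_for_subject(base_spec, row)
            vol, _truth = generate_phantom(spec, seed=_child_seed(seed, 100 + i),
                                           subject_id=row["subject_id"])
            volumes.append((row["subject_id"], vol))

    measured_rows = []
    for name, vol in volumes:
        try:
            table, surfaces, grid, report = measure_volume(
                vol, seg_cfg, presmooth=presmooth)
        except (SegmentationError, ValueError) as err:
            qc_log.append({"volume": name, "ok": False, "stage": "segmentation",
                           "reason": str(err)})
            continue
        if not report.ok:
            qc_log.append({"volume": name, "ok": False, "stage": "qc",
                           **report.to_dict()})
            continue
        qc_log.append({"volume": name, "ok": True})
        oio.write_table(table, outdir / f"intensity_{name}.csv")
        means = layer_means(table)
        row = {"subject_id": name}
        row.update({layer: means[layer] for layer in LAYER_NAMES})
        # per-subject pooled nasal / temporal means per layer (paired tests)
        for layer in LAYER_NAMES:
            for side, secs in (("nasal", ("Nin", "Nout")), ("temporal", ("Tin", "Tout"))):
                sub = table[(table["layer"] == layer) & table["sector"].isin(secs)]
                n = sub["n_voxels"].sum()
                row[f"{side}_{layer}"] = float(
                    (sub["mean_au"] * sub["n_voxels"]).sum() / n) if n else np.nan
        measured_rows.append(row)

    if not measured_rows:
        raise PipelineError("every volume failed segmentation or QC")
    measured = pd.DataFrame(measured_rows)
    if cohort is not None:
        merged = cohort.drop(columns=LAYER_NAMES).merge(measured, on="subject_id")
    else:
        merged = measured
    oio.write_table(merged, outdir / "cohort.csv")

    # cohort-level sector summary
    tables = [oio.read_table(outdir / f"intensity_{r['subject_id']}.csv")
              for r in measured_rows]
    allt = pd.concat(tables, ignore_index=True)
    sector_means = (allt.groupby(["layer", "sector"], sort=False)["mean_au"]
                    .agg(["mean", "std", "count"]).reset_index()
                    .rename(columns={"mean": "mean_au", "std": "sd_au", "count": "n_subjects"}))
    oio.write_table(sector_means, outdir / "sector_means.csv")

    summary = {"n_volumes": len(volumes), "n_included": len(measured_rows),
               "n_excluded": len(volumes) - len(measured_rows)}

    if cohort is not None and len(merged) >= 10:
        stats = cohort_statistics(merged, **config["stats"])
        for key in ("correlations", "correlations_spearman", "stepwise",
                    "age_groups", "age_trends", "group_tests"):
            oio.write_table(stats[key], outdir / f"{key}.csv")

        nres = int(config.get("simulate", {}).get("rescan_subjects", 0))
        if nres >= 5:
            icc_rows = []
            model = CohortModel()
            base_spec = PhantomSpec(shape=tuple(config["simulate"]["shape"]))
            jit = RescanJitter()
            pairs = {layer: [] for layer in LAYER_NAMES}
            for i in range(nres):
                row = cohort.iloc[i]
                spec = phantom_spec_for_subject(base_spec, row)
                va, vb = generate_rescan_pair(spec, jit, seed=_child_seed(seed, 5000 + i))
                for vol in (va, vb):
                    t, *_ = measure_volume(vol, seg_cfg, presmooth=presmooth)
                    m = layer_means(t)
                    for layer in LAYER_NAMES:
                        pairs[layer].append(m[layer])
            for layer in LAYER_NAMES:
                arr = np.asarray(pairs[layer]).reshape(nres, 2)
                r = icc_two_operator(arr)
                icc_rows.append((layer, arr[:, 0].mean(), arr[:, 1].mean(),
                                 r.icc2, r.icc3, r.p_value))
            oio.write_table(pd.DataFrame(
                icc_rows, columns=["layer", "mean_operator_A", "mean_operator_B",
                                   "icc2_1", "icc3_1", "p"]),
                outdir / "icc.csv")

    with open(outdir / "qc_log.json", "w") as fh:
        json.dump(qc_log, fh, indent=1)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
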