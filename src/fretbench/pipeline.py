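"""Config-driven end-to-end orchestration of the simulation + analysis run.

A run executes, as configured: simulate (cohort phantoms + rendered data)
-> unmix (spectral separation) -> index (ratiometric FRET index) -> abfret
(efficiency + distance) -> morpho (axis ratio, body length) -> densitometry
(gel phantom quantification) -> report (group statistics and the joined
cross-level summary). Every file created is listed in a manifest with its
SHA-256; the effective config is serialized next to the outputs so a rerun
with the same config and seed is bit-identical for deterministic stages.

One global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence`` spawning, so enabling or disabling one stage
never perturbs another stage's randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import abfret, densitometry, fretindex, morphometry, phantom, report, spectral
from .io import save_config, sha256_of, write_lambda_stack

logger = logging.getLogger("fretbench")

ALL_STAGES = ("simulate", "unmix", "index", "abfret", "morpho", "densitometry", "report")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


def _plain(obj):
    """Recursively convert tuples to lists for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str = "fretbench_run"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    n_embryos: int = 8
    shape: tuple[int, int] = (128, 128)
    lambda_min: float = 462.0
    lambda_max: float = 572.0
    lambda_step: float = 5.0
    donor_window: tuple[float, float] = spectral.DONOR_WINDOW_NM
    acceptor_window: tuple[float, float] = spectral.ACCEPTOR_WINDOW_NM
    r0_nm: float = abfret.R0_DEFAULT_NM
    e_class_threshold: float = abfret.E_CLASS_THRESHOLD_PERCENT
    donor_floor: float | None = None
    alpha: float = 0.05
    write_stacks: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineError(
                f"unknown stage(s) {sorted(unknown)}; valid stages: {ALL_STAGES}"
            )
        if self.n_embryos < 1:
            raise PipelineError("n_embryos must be >= 1")
        if not self.lambda_max > self.lambda_min > 0:
            raise PipelineError("need lambda_max > lambda_min > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("stages", "shape", "donor_window", "acceptor_window"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the manifest dict."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "files": {}, "seed": config.seed}

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        manifest["files"][name] = sha256_of(path)

    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {s: int(c.generate_state(1)[0] % 2**31) for s, c in
                   zip(ALL_STAGES, ss.spawn(len(ALL_STAGES)))}

    members: list[phantom.CohortMember] = []
    acq = phantom.Acquisition(config.lambda_min, config.lambda_max, config.lambda_step)

    if "simulate" in config.stages:
        logger.info("stage simulate: cohort of 4 groups x %d embryos", config.n_embryos)
        try:
            cohort_cfg = phantom.default_cohort_config(
                seed=stage_seeds["simulate"],
                n_embryos=config.n_embryos,
                shape=config.shape,
                acquisition=acq,
            )
            members = phantom.make_cohort(cohort_cfg)
            emit(phantom.cohort_truth_table(members), "cohort_truth.csv")
            if config.write_stacks:
                for m in members:
                    p = out / f"stack_{m.embryo_id}.ome.tif"
                    write_lambda_stack(m.lambda_stack, p)
                    manifest["files"][p.name] = sha256_of(p)
        except Exception as exc:
            raise PipelineError(f"stage 'simulate' failed: {exc}") from exc

    pairs: dict[str, spectral.ChannelPair] = {}
    if "unmix" in config.stages and members:
        try:
            for m in members:
                pairs[m.embryo_id] = spectral.band_window_separation(
                    m.lambda_stack, config.donor_window, config.acceptor_window
                )
        except Exception as exc:
            raise PipelineError(f"stage 'unmix' failed: {exc}") from exc

    index_df = pd.DataFrame()
    if "index" in config.stages and pairs:
        try:
            measurements = []
            for m in members:
                roi = fretindex.ROI("margin", m.margin_roi)
                measurements.append(
                    fretindex.fret_index(
                        pairs[m.embryo_id], roi, config.donor_floor,
                        embryo_id=m.embryo_id, group=m.group,
                    )
                )
            index_df = fretindex.measurements_frame(measurements)
            fcs = []
            control = members[0].group
            for g in sorted({m.group for m in members} - {control}):
                fc, _ = fretindex.fold_change(measurements, g, control)
                fcs.append({"treated": g, "control": control, "fold_change": fc})
            emit(index_df, "fret_index.csv")
            emit(pd.DataFrame(fcs), "fold_changes.csv")
        except Exception as exc:
            raise PipelineError(f"stage 'index' failed: {exc}") from exc

    ab_df = pd.DataFrame()
    if "abfret" in config.stages and members:
        try:
            records = []
            fc = abfret.ForsterConfig(config.r0_nm)
            for m in members:
                roi = fretindex.ROI("margin", m.margin_roi)
                records += abfret.run_abfret(
                    m.bleach_series, [roi], fc, embryo_id=m.embryo_id, group=m.group
                )
            ab_df = abfret.measurements_frame(records)
            emit(ab_df, "abfret.csv")
            cls_rows = [
                {"group": g, **abfret.classify_by_threshold(
                    sub["E_percent"].dropna(), config.e_class_threshold)}
                for g, sub in ab_df.groupby("group")
            ]
            emit(pd.DataFrame(cls_rows), "abfret_classification.csv")
        except Exception as exc:
            raise PipelineError(f"stage 'abfret' failed: {exc}") from exc

    morpho_df = pd.DataFrame()
    if "morpho" in config.stages:
        try:
            rng = np.random.default_rng(stage_seeds["morpho"])
            # morphology phantoms encode the rescue logic: the mutant
            # elongates the 11 hpf oval; MEK inhibition restores it
            truth_ratio = {"Shp2WT": 1.30, "Shp2D61G": 1.60,
                           "Shp2D61G+0.25uMPD": 1.45, "Shp2D61G+1uMPD": 1.32}
            rows = []
            results_by_group: dict[str, list] = {}
            for group, ratio in truth_ratio.items():
                results_by_group[group] = []
                for i in range(config.n_embryos):
                    r = ratio * rng.normal(1.0, 0.03)
                    minor = 80.0
                    mask = phantom.make_morphology_phantom(
                        r * minor, minor, rotation_deg=rng.uniform(0, 180),
                        shape=(256, 256),
                    )
                    res = morphometry.measure_mask(mask, f"{group}_{i:02d}", group)
                    results_by_group[group].append(res)
                    rows.append(vars(res))
            morpho_df = pd.DataFrame(rows)
            emit(morpho_df, "morphometry.csv")
            emit(morphometry.oval_assay(results_by_group).drop(columns="values"),
                 "oval_assay.csv")
        except Exception as exc:
            raise PipelineError(f"stage 'morpho' failed: {exc}") from exc

    if "densitometry" in config.stages:
        try:
            lanes = [
                {"pERK": 150.0, "tERK": 100.0, "GAPDH": 60.0},   # WT
                {"pERK": 300.0, "tERK": 100.0, "GAPDH": 60.0},   # D61G
            ]
            gel, truth = phantom.make_gel_phantom(
                lanes, background_level=10.0,
                noise=phantom.NoiseModel(photon_budget=1.0, read_noise_sd=0.5),
                seed=stage_seeds["densitometry"],
            )
            quants = []
            for lane_idx, sub in truth.groupby("lane"):
                rois = {
                    r.target: densitometry.RectROI(r.y0, r.y1, r.x0, r.x1)
                    for r in sub.itertuples()
                }
                lq = densitometry.quantify_lane(gel, rois, sample_id=f"lane{lane_idx}")
                quants.append({**vars(lq), "norm_ratio": lq.norm_ratio})
            emit(pd.DataFrame(quants), "densitometry.csv")
        except Exception as exc:
            raise PipelineError(f"stage 'densitometry' failed: {exc}") from exc

    if "report" in config.stages and not ab_df.empty:
        try:
            mol = ab_df.rename(columns={"roi": "roi_label"})[
                ["embryo_id", "group", "E_percent", "R_DA_nm"]
            ]
            if not index_df.empty:
                mol = mol.merge(
                    index_df[["embryo_id", "group", "index"]],
                    on=["embryo_id", "group"], how="left",
                ).rename(columns={"index": "fret_index"})
            morph = None
            if not morpho_df.empty:
                morph = morpho_df[["embryo_id", "group", "axis_ratio", "body_length"]].copy()
            per_embryo, per_group = report.summary_matrix(mol, morph)
            emit(per_embryo, "summary_per_embryo.csv")
            emit(per_group.reset_index(), "summary_per_group.csv")
            groups = {g: sub["E_percent"].dropna().to_numpy()
                      for g, sub in ab_df.groupby("group")}
            if len(groups) >= 3:
                res = report.compare_groups(
                    groups,
                    report.Design("anova_dunnett", alternative="two-sided",
                                  control="Shp2WT" if "Shp2WT" in groups else None),
                )
                emit(res.posthoc.assign(omnibus_p=res.p_value), "comparisons.csv")
        except Exception as exc:
            raise PipelineError(f"stage 'report' failed: {exc}") from exc

    save_config(_plain(asdict(config)), out / "run_config.yaml")
    manifest["files"]["run_config.yaml"] = sha256_of(out / "run_config.yaml")
    manifest_path = out / "manifest.yaml"
    save_config(_plain(manifest), manifest_path)
    logger.info("run complete: %d files in %s", len(manifest["files"]), out)
    return manifest
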