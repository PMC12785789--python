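"""End-to-end orchestration: simulate inputs, run every analysis stage, write reports.

The pipeline mirrors the study's stage structure so individual stages can
be rerun selectively: DPV → ECI → kinetic fit → phase segmentation →
texture → feature matrix → PCA / Spearman / ANOVA.  All randomness flows
from the single configured seed; per-level/per-stage seeds are derived
deterministically from it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__, reference as ref
from .kinetics import (
    ECISeries, fit_model, params_to_dict, read_eci_csv, segment_phases,
    write_eci_csv,
)
from .multivariate import one_way_anova, run_pca, spearman_matrix, standardize
from .synthetic import (
    KineticScenario, TextureScenario, assemble_feature_matrix, gen_dpv_day_series,
    gen_eci_series, gen_texture_image,
)
from .texture import heterogeneity_map, texture_profile
from .voltammetry import write_voltammogram_csv

log = logging.getLogger("ecikin")

ALL_STAGES = ("eci", "fit", "phases", "texture", "multivariate")


class ConfigError(ValueError):
    """Invalid run configuration (detected before any output is written)."""


@dataclass
class RunConfig:
    """Configuration of a simulate/analyze run."""

    outdir: str = "ecikin_out"
    seed: int = 0
    toast_levels: tuple[str, ...] = ref.TOAST_LEVELS
    days: tuple[float, ...] = tuple(range(91))
    replicates_per_day: int = 1
    noise_sd: float = 0.02
    late_slope: float = 0.002
    late_onset: float = 60.0
    fit_window: tuple[float, float] = (0.0, 90.0)
    texture_size: int = 128
    dpv_days: tuple[float, ...] = (7.0,)
    stages: tuple[str, ...] = ALL_STAGES
    kinetic_overrides: dict = field(default_factory=dict)   # level -> param dict

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be ≥ 0")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        for level in self.toast_levels:
            if level not in ref.KINETIC_REFERENCE and level not in self.kinetic_overrides:
                raise ConfigError(f"no kinetic parameters for toast level {level!r}")
        for level, over in self.kinetic_overrides.items():
            for key in ("k1", "k2"):
                if key in over and over[key] <= 0:
                    raise ConfigError(f"{level}: {key} must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        names = {f.name for f in dataclasses.fields(cls)}
        if unknown := set(data) - names:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("toast_levels", "days", "fit_window", "dpv_days", "stages"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=1, default=list))


def _scenario(config: RunConfig, level: str, idx: int) -> KineticScenario:
    base = dict(ref.KINETIC_REFERENCE.get(level, {}))
    base.pop("r2", None)
    base.update(config.kinetic_overrides.get(level, {}))
    return KineticScenario(
        **base,
        late_slope=config.late_slope,
        late_onset=config.late_onset,
        noise_sd=config.noise_sd,
        seed=config.seed * 1000 + idx,
    )


def cmd_simulate(config: RunConfig) -> dict[str, list[str]]:
    """Generate ECI series CSVs, example DPV CSVs and texture PNGs per toast level."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[str]] = {"eci": [], "dpv": [], "texture": []}
    for idx, level in enumerate(config.toast_levels):
        t0 = time.perf_counter()
        sc = _scenario(config, level, idx)
        log.info("simulate %s: seed=%d noise_sd=%g", level, sc.seed, sc.noise_sd)
        series = gen_eci_series(sc, np.asarray(config.days), config.replicates_per_day)
        series.toast_level = level
        p = out / f"eci_{level}.csv"
        write_eci_csv(series, p)
        written["eci"].append(str(p))

        for d in config.dpv_days:
            vs = gen_dpv_day_series(sc, [d], toast_level=level)
            p = out / f"dpv_{level}_day{int(d)}.csv"
            write_voltammogram_csv(vs[0], p)
            written["dpv"].append(str(p))

        tsc = TextureScenario.preset(level, image_size=config.texture_size,
                                     seed=config.seed * 1000 + 500 + idx)
        img = gen_texture_image(tsc)
        p = out / f"stave_{level}.png"
        iio.imwrite(p, img)
        written["texture"].append(str(p))
        log.info("simulate %s done in %.2fs", level, time.perf_counter() - t0)
    (out / "simulate_manifest.json").write_text(json.dumps(written, indent=1))
    return written


def cmd_analyze(config: RunConfig) -> dict[str, str]:
    """Run the selected analysis stages on simulated (or user-supplied) inputs.

    Expects per-level ``eci_<level>.csv`` and ``stave_<level>.png`` files in
    ``config.outdir`` (as produced by :func:`cmd_simulate`).  Emits a
    parameter-table CSV, a phases JSON, a texture-metrics CSV, the feature
    matrix, PCA loadings/scores CSVs with a JSON summary, a Spearman
    matrix CSV and an ANOVA JSON, plus a run log of versions and seeds.
    """
    config.validate()
    out = Path(config.outdir)
    outputs: dict[str, str] = {}
    stages = config.stages

    series: dict[str, ECISeries] = {}
    if {"eci", "fit", "phases", "multivariate"} & set(stages):
        for level in config.toast_levels:
            p = out / f"eci_{level}.csv"
            if not p.exists():
                raise FileNotFoundError(f"missing input: {p}")
            series[level] = read_eci_csv(p)[0]

    fits = {}
    if "fit" in stages:
        t0 = time.perf_counter()
        rows = []
        for level, s in series.items():
            fits[level] = fit_model(s, t_window=config.fit_window)
            rows.append({"toast_level": level, **params_to_dict(fits[level])})
        df = pd.DataFrame(rows)
        p = out / "kinetic_params.csv"
        df.to_csv(p, index=False)
        outputs["kinetic_params"] = str(p)
        log.info("fit stage done in %.2fs", time.perf_counter() - t0)

    if "phases" in stages:
        res = {}
        for level, s in series.items():
            seg = segment_phases(s)
            res[level] = {
                "breakpoints": list(seg.breakpoints),
                "slopes": list(seg.slopes),
                "sse": seg.sse,
                "pattern_ok": seg.pattern_ok,
                "no_phase_structure": seg.no_phase_structure,
            }
        p = out / "phases.json"
        p.write_text(json.dumps(res, indent=1))
        outputs["phases"] = str(p)

    tex = {}
    if "texture" in stages:
        rows = []
        for level in config.toast_levels:
            img_path = out / f"stave_{level}.png"
            if not img_path.exists():
                raise FileNotFoundError(f"missing input: {img_path}")
            img = iio.imread(img_path)
            m = texture_profile(img)
            tex[level] = m
            rows.append({"toast_level": level, **dataclasses.asdict(m)})
            hmap = heterogeneity_map(img.astype(float))
            rng = hmap.max() - hmap.min()
            scaled = (hmap - hmap.min()) / (rng if rng > 0 else 1.0)
            iio.imwrite(out / f"heterogeneity_{level}.png",
                        np.rint(scaled * 255).astype(np.uint8))
        p = out / "texture_metrics.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        outputs["texture_metrics"] = str(p)

    if "multivariate" in stages:
        levels = list(config.toast_levels)
        kin = None
        if fits:
            kin = pd.DataFrame({
                "a1": [fits[l].a1_mag for l in levels],
                "a2": [fits[l].a2_mag for l in levels],
                "k1": [fits[l].k1 for l in levels],
                "k2": [fits[l].k2 for l in levels],
                "eci_eq": [fits[l].eci_eq for l in levels],
            }, index=levels)
        desc = None
        if tex and set(levels) <= set(ref.RAMAN_G):
            desc = pd.DataFrame({
                "ftir_oh": [ref.FTIR_OH_PLACEHOLDER[l] for l in levels],
                "ftir_co": [ref.FTIR_CO_PLACEHOLDER[l] for l in levels],
                "raman_g": [ref.RAMAN_G[l] for l in levels],
                "contrast": [tex[l].contrast for l in levels],
                "entropy": [tex[l].entropy for l in levels],
                "homogeneity": [tex[l].homogeneity for l in levels],
            }, index=levels)
        fm = assemble_feature_matrix(kinetics=kin, descriptors=desc)
        p = out / "feature_matrix.csv"
        fm.rename_axis("toast_level").to_csv(p)
        outputs["feature_matrix"] = str(p)

        z = standardize(fm)
        pca = run_pca(z)
        pca.loadings.rename_axis("variable").to_csv(out / "pca_loadings.csv")
        pca.scores.rename_axis("toast_level").to_csv(out / "pca_scores.csv")
        (out / "pca_summary.json").write_text(json.dumps({
            "explained_pct": list(pca.explained_pct),
            "n_components": len(pca.explained_pct),
        }, indent=1))
        outputs["pca_loadings"] = str(out / "pca_loadings.csv")
        outputs["pca_scores"] = str(out / "pca_scores.csv")
        outputs["pca_summary"] = str(out / "pca_summary.json")

        spearman_matrix(fm).rename_axis("variable").to_csv(out / "spearman.csv")
        outputs["spearman"] = str(out / "spearman.csv")

        anova = one_way_anova([series[l].values for l in levels])
        (out / "anova.json").write_text(json.dumps(dataclasses.asdict(anova), indent=1))
        outputs["anova"] = str(out / "anova.json")

    (out / "run_log.json").write_text(json.dumps({
        "ecikin_version": __version__,
        "seed": config.seed,
        "stages": list(stages),
        "fit_window": list(config.fit_window),
        "outputs": outputs,
    }, indent=1))
    outputs["run_log"] = str(out / "run_log.json")
    return outputs


def cmd_report(config: RunConfig) -> str:
    """Merge per-stage outputs in the run directory into one report JSON."""
    out = Path(config.outdir)
    report: dict = {"ecikin_version": __version__}
    for name in ("kinetic_params", "texture_metrics", "feature_matrix",
                 "pca_loadings", "pca_scores", "spearman"):
        p = out / f"{name}.csv"
        if p.exists():
            report[name] = pd.read_csv(p).to_dict(orient="records")
    for name in ("phases", "pca_summary", "anova", "run_log"):
        p = out / f"{name}.json"
        if p.exists():
            report[name] = json.loads(p.read_text())
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=1))
    return str(path)
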