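"""End-to-end pipeline: simulate -> extract -> fit -> biomark -> stats.

Each stage reads and writes plain-text artifacts (TSV tables, JSON
reports, TIFF + JSON recordings) so stages can be run separately or
chained; ``run_all`` executes the full chain and returns a manifest with
checksums of every output.  Two simulation fidelities are supported:

* ``analytic`` — skip image rendering; evaluate the true waveforms on the
  acquisition time grid, add Gaussian amplitude noise and fit directly.
  Fast; used for statistics-heavy work.
* ``imaging`` — render line-scan images, run the full extraction, then
  fit.  This is the end-to-end validation path.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarker import composite_twitch_time, roc_auc
from .linescan import extract_trace
from .stats import (
    BlockDesignData,
    dunn_posthoc,
    gore_test,
    ks_two_sample,
    rank_sum_test,
    skillings_mack_test,
)
from .synthetic import (
    CohortSpec,
    ImageConfig,
    StagePreset,
    calibrate_preset,
    make_cohort,
    render_linescan,
)
from .twitch import TwitchFitError, TwitchParameters, fit_twitch

logger = logging.getLogger("twitchscope")

__all__ = ["PipelineConfig", "RunManifest", "run_all", "StageFailure",
           "simulate_stage", "fit_stage", "biomark_stage", "stats_stage"]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Fully serializable configuration of one pipeline run."""

    n_mice: dict[str, int] = field(default_factory=lambda: {"WT": 5, "ALS": 6})
    timepoints: tuple[int, ...] = (12, 15, 17, 19, 21, 23)
    #: target composite twitch time (ms) per group per week; WT flat at the
    #: healthy value, disease rising toward the late-stage value
    ctt_targets: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "WT": {w: 21.0 for w in (12, 15, 17, 19, 21, 23)},
            "ALS": {12: 27.0, 15: 28.0, 17: 29.0, 19: 31.0, 21: 41.0, 23: 44.0},
        }
    )
    units_per_mouse: tuple[int, int] | None = None
    fidelity: str = "imaging"  # or "analytic"
    image: ImageConfig = field(default_factory=ImageConfig)
    analytic_noise_sd: float = 0.1  # px, for fidelity="analytic"
    qc_snr_threshold: float = 3.0
    master_seed: int = 0
    outdir: str = "twitchscope_out"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["timepoints"] = list(self.timepoints)
        d["ctt_targets"] = {
            g: {int(w): v for w, v in m.items()} for g, m in self.ctt_targets.items()
        }
        if self.units_per_mouse is not None:
            d["units_per_mouse"] = list(self.units_per_mouse)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "image" in d and isinstance(d["image"], dict):
            d["image"] = ImageConfig(**d["image"])
        if "timepoints" in d:
            d["timepoints"] = tuple(d["timepoints"])
        if d.get("units_per_mouse") is not None:
            d["units_per_mouse"] = tuple(d["units_per_mouse"])
        if "ctt_targets" in d:
            d["ctt_targets"] = {
                g: {int(w): float(v) for w, v in m.items()}
                for g, m in d["ctt_targets"].items()
            }
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d["timepoints"] = list(self.timepoints)
        d.pop("outdir", None)  # where the run lands is not what it computes
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seeds: dict[str, int]
    outputs: dict[str, str]  # relative path -> sha256

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True))
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_cohort_spec(cfg: PipelineConfig) -> CohortSpec:
    schedule: dict[tuple[str, int], StagePreset] = {}
    cache: dict[float, StagePreset] = {}
    # with a fixed per-mouse unit count, calibrate to the per-mouse
    # estimand (the group mean over mice is a mean of small-sample CTTs)
    upm = None
    if cfg.units_per_mouse and cfg.units_per_mouse[0] == cfg.units_per_mouse[1]:
        upm = int(cfg.units_per_mouse[0])
    for g, per_week in cfg.ctt_targets.items():
        for w, target in per_week.items():
            if target not in cache:
                cache[target] = calibrate_preset(
                    target, label=f"ctt{target:g}", units_per_mouse=upm
                )
            schedule[(g, int(w))] = cache[target]
    return CohortSpec(
        n_mice=cfg.n_mice,
        timepoints=cfg.timepoints,
        schedule=schedule,
        units_per_mouse=cfg.units_per_mouse,
        master_seed=cfg.master_seed,
    )


def simulate_stage(cfg: PipelineConfig, outdir: Path) -> tuple[Path, Path]:
    """Generate the cohort's ground-truth unit table and per-mouse ledger."""
    spec = _build_cohort_spec(cfg)
    units, ledger = make_cohort(spec)
    units_path = outdir / "units_truth.tsv"
    ledger_path = outdir / "ledger.tsv"
    units.to_csv(units_path, sep="\t", index=False)
    ledger.to_csv(ledger_path, sep="\t", index=False)
    logger.info("simulate: %d units, %d mouse-timepoints, seed %d",
                len(units), len(ledger), cfg.master_seed)
    return units_path, ledger_path


def measure_units(cfg: PipelineConfig, units: pd.DataFrame) -> pd.DataFrame:
    """Recover each unit's time constants at the configured fidelity.

    ``imaging``: render a line-scan recording per unit, average, extract
    the displacement trace, apply QC and fit.  ``analytic``: evaluate the
    true waveform on the acquisition grid, add Gaussian noise, fit.
    Units failing QC or fitting are marked and excluded downstream.
    """
    rows = []
    root = np.random.SeedSequence(cfg.master_seed + 1)
    n = len(units)
    children = root.spawn(n)
    for (_, u), child in zip(units.iterrows(), children):
        params = TwitchParameters(
            T_c=u.T_c, T_hr=u.T_hr, F_max=u.F_max, delay=u.delay
        )
        rng = np.random.default_rng(child)
        rec = {
            "mouse_id": u.mouse_id, "genotype": u.genotype,
            "age_weeks": u.age_weeks, "unit_index": u.unit_index,
            "qc_pass": False, "fit_ok": False,
            "t_r": np.nan, "t_hr": np.nan, "sse": np.nan,
        }
        try:
            if cfg.fidelity == "imaging":
                recording = render_linescan(params, cfg.image, rng)
                trace = extract_trace(
                    recording, snr_threshold=cfg.qc_snr_threshold
                )
                if not trace.qc_pass:
                    rows.append(rec)
                    logger.warning("unit %s/%s excluded by QC (snr %.2f)",
                                   u.mouse_id, u.unit_index, trace.peak_snr)
                    continue
                t, d = trace.t, trace.d
            elif cfg.fidelity == "analytic":
                from .twitch import evaluate_twitch

                line_ms = 1000.0 / cfg.image.line_rate
                t = np.arange(-50.0, 450.0, line_ms)
                d = evaluate_twitch(params, t) + rng.normal(
                    0.0, cfg.analytic_noise_sd, t.size
                )
                d = d - np.median(d[t < 0])
            else:
                raise StageFailure("fit", f"unknown fidelity {cfg.fidelity!r}")
            fit = fit_twitch(t, d)
            tt = fit.times()
            rec.update(
                qc_pass=True, fit_ok=True, t_r=tt.t_r, t_hr=tt.t_hr, sse=fit.sse
            )
        except TwitchFitError as e:
            logger.warning("unit %s/%s fit failed: %s", u.mouse_id, u.unit_index, e)
        rows.append(rec)
    return pd.DataFrame(rows)


def fit_stage(cfg: PipelineConfig, units_path: Path, outdir: Path) -> Path:
    units = pd.read_csv(units_path, sep="\t")
    if units.empty:
        fits = pd.DataFrame(
            columns=["mouse_id", "genotype", "age_weeks", "unit_index",
                     "qc_pass", "fit_ok", "t_r", "t_hr", "sse"]
        )
    else:
        fits = measure_units(cfg, units)
    path = outdir / "unit_fits.tsv"
    fits.to_csv(path, sep="\t", index=False)
    n_ok = int(fits["fit_ok"].sum()) if len(fits) else 0
    logger.info("fit: %d/%d units fitted", n_ok, len(fits))
    return path


def biomark_stage(cfg: PipelineConfig, fits_path: Path, outdir: Path) -> tuple[Path, Path]:
    fits = pd.read_csv(fits_path, sep="\t")
    ok = fits[fits.get("fit_ok", pd.Series(dtype=bool)) == True]  # noqa: E712
    records = []
    for (mouse, geno, week), grp in ok.groupby(
        ["mouse_id", "genotype", "age_weeks"]
    ):
        rec = composite_twitch_time(
            grp["t_r"].to_numpy(), grp["t_hr"].to_numpy(),
            mouse_id=str(mouse), genotype=str(geno), age_weeks=float(week),
        )
        records.append(
            {
                "mouse_id": rec.mouse_id, "genotype": rec.genotype,
                "age_weeks": rec.age_weeks, "n_units": rec.n_units,
                "harmonic_mean_t_r": rec.harmonic_mean_t_r,
                "median_t_hr": rec.median_t_hr, "ctt": rec.ctt,
            }
        )
    metrics = pd.DataFrame(records)
    metrics_path = outdir / "mouse_metrics.tsv"
    metrics.to_csv(metrics_path, sep="\t", index=False)

    roc_report: dict = {}
    groups = sorted(metrics["genotype"].unique()) if len(metrics) else []
    if len(groups) == 2:
        ctrl_name, dis_name = (
            ("WT", [g for g in groups if g != "WT"][0])
            if "WT" in groups
            else (groups[0], groups[1])
        )
        dis = metrics.loc[metrics.genotype == dis_name, "ctt"].to_numpy()
        ctl = metrics.loc[metrics.genotype == ctrl_name, "ctt"].to_numpy()
        roc = roc_auc(dis, ctl, seed=cfg.master_seed + 2)
        roc_report = {
            "disease_group": dis_name, "control_group": ctrl_name,
            "auc": roc.auc, "auc_ci": list(roc.auc_ci),
            "n_bootstrap": roc.n_bootstrap,
            "fpr": roc.fpr.tolist(), "tpr": roc.tpr.tolist(),
        }
    roc_path = outdir / "roc_report.json"
    roc_path.write_text(json.dumps(roc_report, indent=1))
    logger.info("biomark: %d mouse-timepoint metrics", len(metrics))
    return metrics_path, roc_path


def stats_stage(cfg: PipelineConfig, metrics_path: Path, fits_path: Path,
                outdir: Path) -> Path:
    metrics = pd.read_csv(metrics_path, sep="\t")
    fits = pd.read_csv(fits_path, sep="\t")
    ok = fits[fits["fit_ok"] == True]  # noqa: E712
    report: dict = {}

    def as_result(res):
        return {"statistic": res.statistic, "p_value": res.p_value,
                "df": res.df, "method": res.method, "n": res.n}

    groups = sorted(metrics["genotype"].unique()) if len(metrics) else []
    disease = [g for g in groups if g != "WT"]
    if "WT" in groups and disease:
        dis = disease[0]
        # per-timepoint rank-sum on CTT
        per_week = {}
        for w, grp in metrics.groupby("age_weeks"):
            a = grp.loc[grp.genotype == dis, "ctt"].to_numpy()
            b = grp.loc[grp.genotype == "WT", "ctt"].to_numpy()
            if a.size and b.size:
                per_week[str(int(w))] = as_result(rank_sum_test(a, b))
        report["ctt_rank_sum_by_week"] = per_week
        # pooled distribution comparison of unit time constants
        for col in ("t_r", "t_hr"):
            a = ok.loc[ok.genotype == dis, col].dropna().to_numpy()
            b = ok.loc[ok.genotype == "WT", col].dropna().to_numpy()
            if a.size and b.size:
                report[f"ks_{col}"] = as_result(ks_two_sample(a, b))
        # within-disease time-course tests
        dsub = ok[ok.genotype == dis].dropna(subset=["t_r"])
        try:
            data = BlockDesignData(
                dsub["mouse_id"].to_numpy(), dsub["age_weeks"].to_numpy(),
                dsub["t_r"].to_numpy(),
            )
            report["gore_t_r_over_weeks"] = as_result(gore_test(data))
        except Exception as e:  # small configs may not satisfy the design
            report["gore_t_r_over_weeks"] = {"error": str(e)}
        dctt = metrics[metrics.genotype == dis]
        try:
            data = BlockDesignData(
                dctt["mouse_id"].to_numpy(), dctt["age_weeks"].to_numpy(),
                dctt["ctt"].to_numpy(),
            )
            report["skillings_mack_ctt"] = as_result(skillings_mack_test(data))
        except Exception as e:
            report["skillings_mack_ctt"] = {"error": str(e)}
        try:
            weeks = sorted(dctt["age_weeks"].unique())
            if len(weeks) >= 3:
                samples = [
                    dctt.loc[dctt.age_weeks == w, "ctt"].to_numpy() for w in weeks
                ]
                dunn = dunn_posthoc(samples, labels=[str(int(w)) for w in weeks])
                report["dunn_ctt_pairs"] = {
                    f"{a}v{b}": as_result(r) for (a, b), r in dunn.items()
                }
        except Exception as e:
            report["dunn_ctt_pairs"] = {"error": str(e)}
    path = outdir / "stats_report.json"
    path.write_text(json.dumps(report, indent=1, sort_keys=True))
    logger.info("stats: %d entries", len(report))
    return path


def run_all(cfg: PipelineConfig) -> RunManifest:
    """Execute simulate -> fit -> biomark -> stats and write a manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    try:
        units_path, ledger_path = simulate_stage(cfg, outdir)
        outputs += [units_path, ledger_path]
        fits_path = fit_stage(cfg, units_path, outdir)
        outputs.append(fits_path)
        metrics_path, roc_path = biomark_stage(cfg, fits_path, outdir)
        outputs += [metrics_path, roc_path]
        stats_path = stats_stage(cfg, metrics_path, fits_path, outdir)
        outputs.append(stats_path)
    except StageFailure:
        raise
    except Exception as e:
        raise StageFailure("pipeline", str(e)) from e
    cfg_path = cfg.to_yaml(outdir / "config.yaml")
    outputs.append(cfg_path)
    manifest = RunManifest(
        config_hash=cfg.config_hash(),
        version=__version__,
        seeds={"master_seed": cfg.master_seed},
        outputs={p.name: _sha256(p) for p in outputs},
    )
    manifest.write(outdir / "manifest.json")
    return manifest
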