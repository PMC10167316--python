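"""End-to-end orchestration: simulate -> preprocess -> features -> stats ->
select -> classify -> report.

A :class:`PipelineConfig` (one YAML file) drives every stage; the global
seed propagates to cohort generation, optimizers and classifiers.  Each run
writes its outputs plus a ``manifest.json`` with the config echo, stage
timings and a checksumed file inventory, so two runs with the same config
are bit-identical and verifiable.

For the per-channel topographies of pair-wise connectivity measures, a
channel's value is the mean of that measure over all pairs containing the
channel (its connectivity *strength*), which reduces each pair family to
one value per electrode before the channel-wise test.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ModelSpec, SplitSpec, WindowedDataset, benchmark, concat_windows, window_sequences
from .containers import write_events
from .features import CHANNEL_MEASURES, PAIR_MEASURES, FeatureTable, band_filter, extract_feature_table
from .featselect import OptimizerConfig, run_selection
from .groupstats import channelwise_group_test, export_topography, ttest_independent
from .montage import build_montage
from .preprocess import preprocess_recording, rest_to_epochs
from .synth import AmplitudeEffect, CohortSpec, CouplingEffect, EffectSpec, generate_cohort, generate_sart_events

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "report"]


@dataclass
class PipelineConfig:
    # cohort
    n_high: int = 20
    n_low: int = 20
    rest_duration_s: float = 60.0
    fs: float = 512.0
    amplitude_effects: list = field(default_factory=lambda: [["O2", "delta", 1.5]])
    coupling_effects: list = field(default_factory=list)  # [chA, chB, band, lag_rad, mix_high, mix_low]
    # task
    n_blocks: int = 2
    trials_per_block: int = 30
    probe_rate: float = 0.1
    # preprocessing
    filter_band: tuple[float, float] = (0.5, 40.0)
    segment_window: tuple[float, float] = (-0.5, 1.3)
    final_window: tuple[float, float] = (-0.2, 1.3)
    ptp_threshold_uv: float = 150.0
    rest_epoch_s: float = 2.0
    # features / stats
    measures: list = field(default_factory=lambda: ["log_power", "correlation", "plv", "pli", "coherence_mag", "hfd"])
    bands: list = field(default_factory=lambda: ["raw", "delta", "alpha"])
    stats_q: float = 0.05
    # selection
    optimizers: list = field(default_factory=lambda: ["gwo", "ga", "pso"])
    select_population: int = 10
    select_iterations: int = 20
    select_tree_depth: int = 40
    # classification
    model_families: list = field(default_factory=lambda: ["dt", "mlp"])
    window: int = 32
    windows_per_subject: int = 60
    split_mode: str = "sample_level"
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    classify_bands: list = field(default_factory=lambda: ["raw", "delta"])
    lstm_hidden: int = 16
    conv_filters: tuple[int, ...] = (8, 16)
    max_epochs: int = 10
    # bookkeeping
    out_dir: str = "eegvuln_run"
    seed: int = 0

    def validate(self) -> None:
        CohortSpec(n_high=self.n_high, n_low=self.n_low, rest_duration_s=self.rest_duration_s,
                   fs=self.fs, seed=self.seed)  # raises on bad cohort numbers
        known = set(CHANNEL_MEASURES) | set(PAIR_MEASURES) | {"alpha_asymmetry"}
        for m in self.measures:
            if m not in known:
                raise ValueError(f"unknown measure {m!r}")
        for fam in self.model_families:
            ModelSpec(family=fam)
        for alg in self.optimizers:
            OptimizerConfig(algorithm=alg)
        if not 0 < self.stats_q < 1:
            raise ValueError("stats_q must be in (0, 1)")

    def effect_spec(self) -> EffectSpec:
        amps = tuple(AmplitudeEffect(c, b, float(f)) for c, b, f in self.amplitude_effects)
        coups = tuple(
            CouplingEffect((a, b), band, float(lag), float(mh), float(ml))
            for a, b, band, lag, mh, ml in self.coupling_effects
        )
        return EffectSpec(amplitude_effects=amps, coupling_effects=coups)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_high=self.n_high, n_low=self.n_low, rest_duration_s=self.rest_duration_s,
            fs=self.fs, effect=self.effect_spec(), seed=self.seed,
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = PipelineConfig(**{k: tuple(v) if isinstance(getattr(PipelineConfig(), k), tuple) else v
                                for k, v in raw.items()})
        return cfg


@dataclass
class RunManifest:
    config: dict
    stage_seconds: dict
    files: dict  # relative path -> sha256
    version: str = __version__

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path

    @staticmethod
    def from_json(path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return RunManifest(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _questionnaire_stats(quest: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for col in ("PTQ", "RRS", "CESD", "intensity", "frequency"):
        hi = quest.loc[quest["group"] == "high", col].dropna()
        lo = quest.loc[quest["group"] == "low", col].dropna()
        r = ttest_independent(hi, lo)
        rows.append(
            {
                "score": col,
                "mean_high": hi.mean(), "sd_high": hi.std(ddof=1), "n_high": len(hi),
                "mean_low": lo.mean(), "sd_low": lo.std(ddof=1), "n_low": len(lo),
                "t": r.t, "df": r.df, "p": r.p,
            }
        )
    return pd.DataFrame(rows)


def _channel_strength_table(ft: FeatureTable, measure: str, band: str, channels: Sequence[str]) -> FeatureTable:
    """Reduce pair columns of one (measure, band) family to per-channel means."""
    prefix = f"{measure}|{band}|"
    cols = [c for c in ft.descriptors if c.startswith(prefix)]
    data = {}
    for ch in channels:
        sel = [c for c in cols if ch in c.rsplit("|", 1)[-1].split("-")]
        if sel:
            data[f"{measure}|{band}|{ch}"] = ft.values[sel].mean(axis=1)
    return FeatureTable(pd.DataFrame(data, index=ft.values.index), ft.groups.copy())


def _subsample_windows(ds: WindowedDataset, per_subject: int, seed: int) -> WindowedDataset:
    rng = np.random.default_rng([seed % (2**31), 0xC5])
    keep = []
    for sid in pd.unique(ds.subject_ids):
        idx = np.flatnonzero(ds.subject_ids == sid)
        if len(idx) > per_subject:
            idx = np.sort(rng.choice(idx, size=per_subject, replace=False))
        keep.append(idx)
    return ds.subset(np.concatenate(keep))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages on synthetic rest and task cohorts; return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = build_montage()
    timings: dict[str, float] = {}
    spec = config.cohort_spec()

    # --- simulate -----------------------------------------------------------
    t0 = time.perf_counter()
    events = generate_sart_events(config.n_blocks, config.trials_per_block, config.probe_rate, seed=config.seed)
    write_events(events, out / "events.tsv")
    rest_recs, quest = generate_cohort(spec, events=(), montage=montage)
    task_recs, _ = generate_cohort(spec, events=events, montage=montage)
    quest.to_csv(out / "questionnaires.tsv", sep="\t", index=False)
    timings["simulate"] = time.perf_counter() - t0

    # --- questionnaire statistics ------------------------------------------
    t0 = time.perf_counter()
    qstats = _questionnaire_stats(quest)
    qstats.to_csv(out / "questionnaire_stats.tsv", sep="\t", index=False)
    timings["questionnaire_stats"] = time.perf_counter() - t0

    # --- preprocess ---------------------------------------------------------
    t0 = time.perf_counter()
    rest_eps = [rest_to_epochs(r, config.rest_epoch_s) for r in rest_recs]
    task_eps = []
    rejections = []
    for rec in task_recs:
        ep, rep = preprocess_recording(
            rec, events, montage,
            band=tuple(config.filter_band),
            segment_window=tuple(config.segment_window),
            ptp_threshold_uv=config.ptp_threshold_uv,
            final_window=tuple(config.final_window),
        )
        task_eps.append(ep)
        rejections.append({"subject_id": rec.subject_id, "group": rec.group,
                           "n_total": rep.n_total, "n_rejected": rep.n_rejected,
                           "proportion": rep.proportion_rejected})
    pd.DataFrame(rejections).to_csv(out / "rejection_report.tsv", sep="\t", index=False)
    timings["preprocess"] = time.perf_counter() - t0

    # --- features -----------------------------------------------------------
    t0 = time.perf_counter()
    tables = {}
    for kind, eps in (("rest", rest_eps), ("task", task_eps)):
        ft = extract_feature_table(eps, config.measures, config.bands, granularity="subject")
        ft.to_tsv(out / f"features_{kind}.tsv")
        tables[kind] = ft
    timings["features"] = time.perf_counter() - t0

    # --- channel-wise statistics -------------------------------------------
    t0 = time.perf_counter()
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    sig_counts = []
    for kind, ft in tables.items():
        for measure in config.measures:
            if measure == "alpha_asymmetry":
                continue
            for band in config.bands:
                if measure in ("plv", "pli") and band == "raw":
                    continue
                if measure in PAIR_MEASURES:
                    fam = _channel_strength_table(ft, measure, band, montage.channel_names)
                else:
                    prefix = f"{measure}|{band}|"
                    cols = [c for c in ft.descriptors if c.startswith(prefix)]
                    if not cols:
                        continue
                    fam = ft.select(cols)
                if not fam.descriptors:
                    continue
                gsr = channelwise_group_test(fam, q=config.stats_q)
                export_topography(gsr, montage, stats_dir / f"topo_{kind}_{measure}_{band}.tsv")
                sig_counts.append({"data": kind, "measure": measure, "band": band,
                                   "n_significant": gsr.fdr.n_rejected,
                                   "p_threshold": gsr.fdr.p_threshold})
    pd.DataFrame(sig_counts).to_csv(out / "significant_counts.tsv", sep="\t", index=False)
    timings["stats"] = time.perf_counter() - t0

    # --- feature-subset selection (rest biomarkers) -------------------------
    t0 = time.perf_counter()
    sel_rows = []
    for alg in config.optimizers:
        oc = OptimizerConfig(algorithm=alg, population=config.select_population,
                             iterations=config.select_iterations, seed=config.seed,
                             tree_depth=config.select_tree_depth)
        res = run_selection(tables["rest"], oc)
        res.to_text(out / f"selection_{alg}.txt")
        sel_rows.append({"algorithm": alg, "best_fitness": res.best_fitness,
                         "n_selected": res.n_selected, "selected": ";".join(res.selected)})
    pd.DataFrame(sel_rows).to_csv(out / "selection_summary.tsv", sep="\t", index=False)
    timings["select"] = time.perf_counter() - t0

    # --- classification -----------------------------------------------------
    t0 = time.perf_counter()
    datasets = []
    for kind, eps in (("rest", rest_eps), ("task", task_eps)):
        for band in config.classify_bands:
            parts = []
            for ep in eps:
                epb = band_filter(ep, band)
                parts.append(window_sequences(epb, window=config.window, band=band, kind=kind))
            ds = concat_windows(parts)
            datasets.append(_subsample_windows(ds, config.windows_per_subject, config.seed))
    models = [
        ModelSpec(family=fam, lstm_hidden=config.lstm_hidden,
                  conv_filters=tuple(config.conv_filters), max_epochs=config.max_epochs)
        for fam in config.model_families
    ]
    split = SplitSpec(mode=config.split_mode, ratios=tuple(config.split_ratios), seed=config.seed)
    results = benchmark(datasets, models, split)
    results.to_csv(out / "classification_results.tsv", sep="\t", index=False)
    timings["classify"] = time.perf_counter() - t0

    # --- manifest -----------------------------------------------------------
    files = {str(p.relative_to(out)): _sha256(p) for p in sorted(out.rglob("*")) if p.is_file()
             and p.name not in ("manifest.json", "report.md")}
    manifest = RunManifest(config=dataclasses.asdict(config),
                           stage_seconds={k: round(v, 3) for k, v in timings.items()},
                           files=files)
    manifest.to_json(out / "manifest.json")
    return manifest


def report(manifest: RunManifest) -> str:
    """Render a human-readable summary of a finished run; returns the markdown text."""
    out = Path(manifest.config["out_dir"])
    needed = ["questionnaire_stats.tsv", "significant_counts.tsv",
              "selection_summary.tsv", "classification_results.tsv"]
    missing = [f for f in needed if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing run outputs: {missing}")
    qstats = pd.read_csv(out / "questionnaire_stats.tsv", sep="\t")
    sig = pd.read_csv(out / "significant_counts.tsv", sep="\t")
    sel = pd.read_csv(out / "selection_summary.tsv", sep="\t")
    cls = pd.read_csv(out / "classification_results.tsv", sep="\t")
    lines = ["# eegvuln run report", ""]
    lines += ["## Questionnaire group differences", "", qstats.to_string(index=False), ""]
    lines += ["## Significant channels per measure and band (BH-FDR)", "",
              sig.to_string(index=False), ""]
    lines += ["## Feature-subset selection", "", sel.to_string(index=False), ""]
    lines += ["## Classification", "", cls.to_string(index=False), ""]
    text = "\n".join(lines)
    (out / "report.md").write_text(text)
    return text
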