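"""End-to-end orchestration: simulate -> preprocess -> features -> JM ->
LOSO train/diagnose -> evaluation report.

A :class:`RunConfig` captures every stage's settings and serialises to
YAML; ``run_pipeline`` executes the selected stages into a run directory
(manifest, feature tables, JM report, per-subject diagnoses, metrics
report, comodulogram plots), stamping the resolved configuration next to
the results so any run is reproducible from its own output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from .features.classic import classic_features
from .features.pac import pac_feature_table
from .features.wavelet import wavelet_feature_table
from .io import write_csv_recording, write_manifest
from .model import LOSOClassifier, feature_columns
from .nn import FNNSpec
from .preprocess import FilterSpec, preprocess, segment
from .separability import featureset_jm
from .simulate import SimConfig, generate_cohort

log = logging.getLogger("emgpac")

__all__ = ["RunConfig", "run_pipeline"]

FEATURE_SETS = ("classic", "wavelet", "pac")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    fnn: FNNSpec = field(default_factory=FNNSpec)
    feature_set: str = "all"          # classic | wavelet | pac | all
    phase_freqs: list = field(default_factory=lambda: np.arange(2.0, 31.0, 2.0).tolist())
    amp_freqs: list = field(default_factory=lambda: np.arange(30.0, 351.0, 10.0).tolist())
    pac_window_s: float = 4.0
    prevalences: list = field(default_factory=lambda: [0.03, 0.01])
    ci_level: float = 0.95
    seed: int = 0
    write_recordings: bool = False
    stages: list = field(default_factory=lambda: ["simulate", "features", "jm",
                                                  "loso", "evaluate"])

    def selected_sets(self):
        return list(FEATURE_SETS) if self.feature_set == "all" else [self.feature_set]

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("sim", "filter_spec", "fnn"):
            d[key] = {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in d[key].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        for k in ("muscles", "band", "coupled_muscles"):
            if k in sim and isinstance(sim[k], list):
                sim[k] = tuple(sim[k])
        filt = d.pop("filter_spec", {})
        if "band" in filt and isinstance(filt["band"], list):
            filt["band"] = tuple(filt["band"])
        fnn = d.pop("fnn", {})
        return cls(sim=SimConfig(**sim), filter_spec=FilterSpec(**filt),
                   fnn=FNNSpec(**fnn), **d)

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def extract_features(recordings, cfg: RunConfig) -> dict:
    """Per-set feature tables (rows aligned across sets)."""
    tables = {}
    sets = cfg.selected_sets()
    prepped = [preprocess(rec, cfg.filter_spec) for rec in recordings]
    if "classic" in sets or "wavelet" in sets:
        epoch_sets = [segment(rec) for rec in prepped]
    if "classic" in sets:
        tables["classic"] = pd.concat(
            [classic_features(es) for es in epoch_sets], ignore_index=True)
        log.info("classic features: %d rows", len(tables["classic"]))
    if "wavelet" in sets:
        tables["wavelet"] = pd.concat(
            [wavelet_feature_table(es) for es in epoch_sets], ignore_index=True)
        log.info("wavelet features: %d rows", len(tables["wavelet"]))
    if "pac" in sets:
        tables["pac"] = pd.concat(
            [pac_feature_table(rec, window_s=cfg.pac_window_s,
                               phase_freqs=cfg.phase_freqs,
                               amp_freqs=cfg.amp_freqs)
             for rec in prepped], ignore_index=True)
        log.info("pac features: %d rows", len(tables["pac"]))
    return tables


def _dropping_constant(table, features):
    keep = []
    for f in features:
        by_class = table.groupby("group")[f].var(ddof=1)
        if (by_class > 0).all():
            keep.append(f)
    dropped = sorted(set(features) - set(keep))
    if dropped:
        warnings.warn(f"dropping zero-variance features from JM: {dropped}")
    return keep


def jm_report(tables: dict, seed: int = 0) -> pd.DataFrame:
    """Mean JM per feature set on the training rows of each LOSO dataset
    (one row per held-out subject, one column per feature set)."""
    from .model import make_loso_datasets
    first = next(iter(tables.values()))
    subjects = first["subject_id"].unique()
    out = pd.DataFrame(index=pd.Index(subjects, name="held_out_subject"))
    for set_name, table in tables.items():
        feats = feature_columns(table)
        datasets = make_loso_datasets(table, feats, seed)
        vals = []
        for ds in datasets:
            train = table.loc[ds.train_rows]
            usable = _dropping_constant(train, feats)
            vals.append(featureset_jm(train, usable)["mean"])
        out[set_name] = vals
    return out


def jm_statistics(jm_table: pd.DataFrame) -> dict:
    """Friedman omnibus + one-sided Wilcoxon post hocs (Bonferroni x3)."""
    cols = list(jm_table.columns)
    out = {"friedman": ev.friedman(jm_table.to_numpy())}
    posthoc = {}
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            try:
                res = ev.wilcoxon_one_sided(jm_table[a].to_numpy(),
                                            jm_table[b].to_numpy())
            except ValueError as exc:
                res = {"p": None, "rank_biserial": None, "note": str(exc)}
            if res["p"] is not None:
                res["adj_p"] = ev.bonferroni(res["p"], 3)
            posthoc[f"{a}_vs_{b}"] = res
    out["posthoc_one_sided"] = posthoc
    return out


def evaluation_report(results_by_set: dict, cfg: RunConfig) -> dict:
    """Cohort metrics, DOR and prevalence-adjusted PPV per feature set,
    plus pairwise McNemar comparisons (Bonferroni x3)."""
    report = {}
    for name, res in results_by_set.items():
        m = res.metrics(cfg.ci_level)
        se = m["Se"] / 100 if m["Se"] is not None else None
        sp = m["Sp"] / 100 if m["Sp"] is not None else None
        entry = dict(m)
        if se is not None and sp is not None:
            d = ev.dor(se, sp)
            entry["DOR"] = "inf" if d["infinite"] else round(d["value"], 2)
            entry["unbiased_PPV_percent"] = {
                str(p): round(100 * ev.unbiased_ppv(se, sp, ev.PrevalenceSpec(p)), 2)
                for p in cfg.prevalences}
        report[name] = entry
    names = list(results_by_set)
    mcnemar_out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ca = [d.correct for d in results_by_set[a].diagnoses]
            cb = [d.correct for d in results_by_set[b].diagnoses]
            res = ev.mcnemar(ca, cb)
            res["adj_p"] = ev.bonferroni(res["p"], 3)
            mcnemar_out[f"{a}_vs_{b}"] = res
    if mcnemar_out:
        report["mcnemar"] = mcnemar_out
    return report


def plot_comodulogram(c, path, title="comodulogram"):
    """Fig-3-style PAC heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.pcolormesh(c.phase_freqs, c.amp_freqs, c.values.T,
                       shading="nearest", vmin=0, vmax=1, cmap="viridis")
    ax.set_xlabel("phase frequency (Hz)")
    ax.set_ylabel("amplitude frequency (Hz)")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="coherence")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute the configured stages into ``outdir``.

    Returns a dict with the main artifacts (manifest, feature tables, JM
    table, LOSO results, evaluation report).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.save(outdir / "config.yaml")
    artifacts = {}

    log.info("stage: simulate (%d+%d subjects, seed %d)",
             cfg.sim.n_cases, cfg.sim.n_controls, cfg.sim.seed)
    recordings, manifest = generate_cohort(cfg.sim)
    write_manifest(manifest, outdir / "manifest.json")
    artifacts["manifest"] = manifest
    if cfg.write_recordings:
        rec_dir = outdir / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for rec in recordings:
            write_csv_recording(rec, rec_dir / f"{rec.subject_id}.csv")

    if "features" not in cfg.stages:
        return artifacts
    tables = extract_features(recordings, cfg)
    for name, table in tables.items():
        table.to_csv(outdir / f"features_{name}.csv", index=False)
    artifacts["tables"] = tables

    if "jm" in cfg.stages:
        log.info("stage: jm")
        jm_table = jm_report(tables, cfg.seed)
        jm_table.to_csv(outdir / "jm_report.csv")
        artifacts["jm"] = jm_table
        if jm_table.shape[1] >= 2:
            stats = jm_statistics(jm_table)
            (outdir / "jm_statistics.json").write_text(json.dumps(stats, indent=1))
            artifacts["jm_statistics"] = stats

    if "loso" in cfg.stages:
        results_by_set = {}
        for name, table in tables.items():
            log.info("stage: loso (%s features)", name)
            model = LOSOClassifier(table, spec=cfg.fnn)
            res = model.fit(seed=cfg.seed)
            res.to_frame().to_csv(outdir / f"diagnoses_{name}.csv", index=False)
            (outdir / f"summary_{name}.txt").write_text(res.summary() + "\n")
            results_by_set[name] = res
        artifacts["loso"] = results_by_set

        if "evaluate" in cfg.stages:
            log.info("stage: evaluate")
            report = evaluation_report(results_by_set, cfg)
            (outdir / "metrics_report.json").write_text(
                json.dumps(report, indent=1, default=str))
            artifacts["report"] = report

    if "pac" in tables and len(recordings) >= 2:
        from .features.pac import comodulogram
        for rec, tag in ((recordings[0], "case"),
                         (recordings[-1], "control")):
            sig = preprocess(rec, cfg.filter_spec).samples[0]
            n = min(sig.size, int(4.0 * rec.fs))
            try:
                c = comodulogram(sig[:n], rec.fs, cfg.phase_freqs, cfg.amp_freqs)
                plot_comodulogram(c, outdir / f"comodulogram_{tag}.png",
                                  f"{rec.subject_id} ({tag})")
            except ValueError:
                log.warning("comodulogram plot skipped (%s): signal too short", tag)
    return artifacts
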