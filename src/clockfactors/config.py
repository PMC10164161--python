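"""Run configuration and the end-to-end pipeline.

One YAML file describes a full run: cohort generation, preprocessing,
RF-VAE training, latent analysis, and classification.  A single master
seed fans out to per-stage streams so rerunning one stage never
perturbs the others.  ``run_pipeline`` executes the five stages in
order, skips stages whose outputs already match the config hash, and
writes a machine-readable summary plus a manifest with content hashes.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, classify, preprocess, rfvae, synthetic

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config",
           "run_pipeline", "STAGES"]

STAGES = ("generate", "preprocess", "train", "analyze", "classify")


class ConfigError(ValueError):
    """Invalid, unknown or out-of-range configuration."""


@dataclass
class CohortSection:
    n_train: int = 400
    n_finetune_dem: int = 84
    n_finetune_ctl: int = 263
    n_test_dem: int = 28
    n_test_ctl: int = 87
    canvas_px: int = 256
    stroke_px: int = 3
    effect_shift: dict = field(
        default_factory=lambda: dict(synthetic.DEFAULT_EFFECT_SHIFT))


@dataclass
class PreprocessSection:
    min_area_fraction: float = 1e-4


@dataclass
class TrainSection:
    latent_dim: int = 10
    epochs: int = 100
    learning_rate: float = 1e-4
    batch_size: int = 64
    tc_weight: float = 6.4
    relevance_sparsity: float = 0.2
    kl_relevance_coupling: float = 1.0
    tc_estimator: str = "discriminator"


@dataclass
class AnalyzeSection:
    fdr_q: float = 0.01
    atypical_k: float = 2.0
    corr_threshold: float = 0.2
    match_ratio: int = 2
    traversal_lo: float = -3.0
    traversal_hi: float = 3.0
    traversal_steps: int = 7


@dataclass
class ClassifySection:
    epochs: int = 20
    learning_rate: float = 0.0075
    positive_class_weight: float = 3.125
    latent_hidden: tuple = (7, 4)
    latent_batch_size: int = 32
    demo_hidden: tuple = (512, 256, 128)
    demo_batch_size: int = 8
    bootstrap_B: int = 100
    threshold: float = 0.5


@dataclass
class RunConfig:
    """Validated, round-trippable configuration of a full pipeline run."""

    cohort: CohortSection = field(default_factory=CohortSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    train: TrainSection = field(default_factory=TrainSection)
    analyze: AnalyzeSection = field(default_factory=AnalyzeSection)
    classify: ClassifySection = field(default_factory=ClassifySection)
    seed: int = 0
    out_dir: str = "runs/run0"
    verbosity: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classify"]["latent_hidden"] = list(d["classify"]["latent_hidden"])
        d["classify"]["demo_hidden"] = list(d["classify"]["demo_hidden"])
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Derived per-stage seed (below 2**31), stable in the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


_SECTIONS = {
    "cohort": CohortSection, "preprocess": PreprocessSection,
    "train": TrainSection, "analyze": AnalyzeSection,
    "classify": ClassifySection,
}
_TOP_KEYS = set(_SECTIONS) | {"seed", "out_dir", "verbosity"}


def _reject_unknown(given: set, allowed: set, where: str) -> None:
    for key in sorted(given - allowed):
        hint = difflib.get_close_matches(key, allowed, n=1)
        suggest = f"; did you mean {hint[0]!r}?" if hint else ""
        raise ConfigError(f"unknown key {key!r} in {where}{suggest}")


def _coerce_section(cls, raw: dict, where: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    _reject_unknown(set(raw), set(fields), where)
    kwargs = {}
    for name, value in raw.items():
        if name in ("latent_hidden", "demo_hidden") and isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def _validate(cfg: RunConfig) -> RunConfig:
    checks = [
        (cfg.train.latent_dim > 0, "train.latent_dim must be positive"),
        (cfg.train.epochs > 0, "train.epochs must be positive"),
        (cfg.train.learning_rate > 0, "train.learning_rate must be positive"),
        (cfg.train.batch_size > 0, "train.batch_size must be positive"),
        (0 < cfg.analyze.fdr_q < 1, "analyze.fdr_q must be in (0, 1)"),
        (cfg.analyze.corr_threshold >= 0,
         "analyze.corr_threshold must be non-negative"),
        (cfg.classify.bootstrap_B >= 2, "classify.bootstrap_B must be >= 2"),
        (cfg.cohort.canvas_px >= 64, "cohort.canvas_px must be >= 64"),
        (all(getattr(cfg.cohort, k) >= 0 for k in
             ("n_train", "n_finetune_dem", "n_finetune_ctl",
              "n_test_dem", "n_test_ctl")),
         "cohort counts must be >= 0"),
    ]
    for ok, msg in checks:
        if not ok:
            raise ConfigError(f"out-of-range value: {msg}")
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Absent keys take their documented defaults (latent D = 10,
    FDR q = 0.01, bootstrap B = 100, ...); unknown keys are rejected
    with a nearest-name suggestion.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {path}: {e}") from e
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    _reject_unknown(set(raw), _TOP_KEYS, "top level")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            section = raw[name] or {}
            if not isinstance(section, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            kwargs[name] = _coerce_section(cls, section, f"section {name!r}")
    for name in ("seed", "out_dir", "verbosity"):
        if name in raw:
            kwargs[name] = raw[name]
    return _validate(RunConfig(**kwargs))


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


# --- pipeline ------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_done(out: Path, stage: str, cfg_hash: str) -> bool:
    marker = out / f".{stage}.done.json"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text())["config_hash"] == cfg_hash
    except (json.JSONDecodeError, KeyError):
        return False


def _mark_done(out: Path, stage: str, cfg_hash: str, seed: int,
               artifacts: list[Path], t0: float) -> dict:
    entry = {
        "stage": stage, "status": "done", "seed": seed,
        "duration_s": round(time.time() - t0, 3),
        "config_hash": cfg_hash,
        "artifacts": {str(p.relative_to(out)): _sha256(p)
                      for p in artifacts if p.exists()},
    }
    (out / f".{stage}.done.json").write_text(json.dumps(entry, indent=2))
    return entry


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute generate → preprocess → train → analyze → classify.

    Stages whose outputs already exist under the same config hash are
    skipped.  Returns the run summary (also written to ``summary.json``)
    listing every stage with status, seed, duration and artifact hashes.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.content_hash()
    save_config(cfg, out / "config.yaml")
    summary: list[dict] = []

    def log(msg: str) -> None:
        if cfg.verbosity:
            print(f"[clockfactors] {msg}")

    # -- generate --
    stage = "generate"
    t0 = time.time()
    if _stage_done(out, stage, cfg_hash):
        log("generate: cached, skipping")
        summary.append({"stage": stage, "status": "skipped"})
    else:
        seed = cfg.stage_seed(stage)
        cc = synthetic.CohortConfig(
            n_train=cfg.cohort.n_train,
            n_finetune_dem=cfg.cohort.n_finetune_dem,
            n_finetune_ctl=cfg.cohort.n_finetune_ctl,
            n_test_dem=cfg.cohort.n_test_dem,
            n_test_ctl=cfg.cohort.n_test_ctl,
            effect_shift=dict(cfg.cohort.effect_shift),
            seed=seed, canvas_px=cfg.cohort.canvas_px,
            stroke_px=cfg.cohort.stroke_px)
        subjects, images, truth = synthetic.generate_cohort(cc)
        synthetic.write_cohort(out / "cohort", subjects, images, truth)
        arts = [out / "cohort" / "subjects.csv", out / "cohort" / "truth.csv",
                out / "cohort" / "train_manifest.csv"]
        summary.append(_mark_done(out, stage, cfg_hash, seed, arts, t0))
        log(f"generate: {len(subjects)} clocks")

    # -- preprocess --
    stage = "preprocess"
    t0 = time.time()
    if _stage_done(out, stage, cfg_hash):
        log("preprocess: cached, skipping")
        summary.append({"stage": stage, "status": "skipped"})
    else:
        subjects = pd.read_csv(out / "cohort" / "subjects.csv")
        from PIL import Image
        rows, stack = [], []
        (out / "preprocessed").mkdir(exist_ok=True)
        for sid in subjects["id"]:
            page = np.asarray(
                Image.open(out / "cohort" / "images" / f"{sid}.png"),
                dtype=np.float64) / 255.0
            ci = preprocess.preprocess_page(
                page, source_id=sid,
                min_area_fraction=cfg.preprocess.min_area_fraction)
            stack.append(ci.pixels)
            x, y, w, h = ci.original_bbox
            rows.append({"id": sid, "x": x, "y": y, "w": w, "h": h})
        np.save(out / "preprocessed" / "images64.npy",
                np.asarray(stack, dtype=np.float32))
        pd.DataFrame(rows).to_csv(out / "preprocessed" / "manifest.csv",
                                  index=False)
        arts = [out / "preprocessed" / "manifest.csv"]
        summary.append(_mark_done(out, stage, cfg_hash,
                                  cfg.stage_seed(stage), arts, t0))
        log(f"preprocess: {len(rows)} images standardized")

    # -- train --
    stage = "train"
    t0 = time.time()
    model_path = out / "model" / "rfvae"
    if _stage_done(out, stage, cfg_hash):
        log("train: cached, skipping")
        summary.append({"stage": stage, "status": "skipped"})
        model = rfvae.load_model(model_path)
    else:
        seed = cfg.stage_seed(stage)
        subjects = pd.read_csv(out / "cohort" / "subjects.csv")
        images = np.load(out / "preprocessed" / "images64.npy").astype(np.float64)
        train_mask = (subjects["split"] == "train").to_numpy()
        tc = rfvae.TrainConfig(
            epochs=cfg.train.epochs, learning_rate=cfg.train.learning_rate,
            batch_size=cfg.train.batch_size, tc_weight=cfg.train.tc_weight,
            relevance_sparsity=cfg.train.relevance_sparsity,
            kl_relevance_coupling=cfg.train.kl_relevance_coupling,
            tc_estimator=cfg.train.tc_estimator, seed=seed)
        model, history = rfvae.train(images[train_mask], tc,
                                     latent_dim=cfg.train.latent_dim)
        rfvae.save_model(model, model_path, config=tc,
                         epoch=cfg.train.epochs,
                         losses=history.iloc[-1][["recon", "kl_total",
                                                  "tc", "total"]].to_dict())
        history.to_csv(out / "model" / "training_log.csv", index=False)
        arts = [out / "model" / "training_log.csv",
                model_path.with_suffix(".json")]
        summary.append(_mark_done(out, stage, cfg_hash, seed, arts, t0))
        log(f"train: {cfg.train.epochs} epochs, final recon "
            f"{history['recon'].iloc[-1]:.1f}")

    # -- analyze --
    stage = "analyze"
    t0 = time.time()
    rep = out / "reports"
    if _stage_done(out, stage, cfg_hash):
        log("analyze: cached, skipping")
        summary.append({"stage": stage, "status": "skipped"})
    else:
        rep.mkdir(exist_ok=True)
        subjects = pd.read_csv(out / "cohort" / "subjects.csv")
        images = np.load(out / "preprocessed" / "images64.npy").astype(np.float64)
        an = cfg.analyze
        # traversal montage
        montage = analysis.traversal_montage(model, steps=an.traversal_steps,
                                             lo=an.traversal_lo,
                                             hi=an.traversal_hi)
        from PIL import Image
        Image.fromarray((montage * 255).round().astype(np.uint8)).save(
            rep / "traversals.png")
        # latent stats on the labeled (classification) clocks
        labeled = subjects[subjects["label"] != "unlabeled"]
        if not labeled.empty:
            idx = labeled.index.to_numpy()
            Z = model.latent_means(images[idx])
            y = (labeled["label"] == "dementia").to_numpy()
            match = analysis.propensity_match(labeled, ratio=an.match_ratio)
            pos = {sid: i for i, sid in enumerate(labeled["id"])}
            midx = np.array([pos[s] for s in match.matched["id"]])
            my = (match.matched["label"] == "dementia").to_numpy()
            comp = analysis.compare_groups(Z[midx], my, q=an.fdr_q)
            comp.table.to_csv(rep / "group_comparison.csv", index=False)
            mu_c, sd_c = Z[~y].mean(axis=0), Z[~y].std(axis=0, ddof=1)
            counts = analysis.count_atypical(Z[y], mu_c, sd_c, k=an.atypical_k)
            pd.DataFrame({"dimension": [f"z{d}" for d in range(Z.shape[1])],
                          "atypical_count": counts}).to_csv(
                rep / "atypical_counts.csv", index=False)
            net = analysis.correlation_network(Z, y.astype(int),
                                               threshold=an.corr_threshold)
            net.corr.to_csv(rep / "correlation_matrix.csv")
            net.edges.to_csv(rep / "network_edges.csv", index=False)
            import networkx as nx
            nx.write_graphml(net.graph(), rep / "network.graphml")
        arts = sorted(rep.glob("*.csv")) + [rep / "traversals.png"]
        summary.append(_mark_done(out, stage, cfg_hash,
                                  cfg.stage_seed(stage), arts, t0))
        log("analyze: reports written")

    # -- classify --
    stage = "classify"
    t0 = time.time()
    if _stage_done(out, stage, cfg_hash):
        log("classify: cached, skipping")
        summary.append({"stage": stage, "status": "skipped"})
    else:
        seed = cfg.stage_seed(stage)
        rep.mkdir(exist_ok=True)
        subjects = pd.read_csv(out / "cohort" / "subjects.csv")
        images = np.load(out / "preprocessed" / "images64.npy").astype(np.float64)
        cl = cfg.classify

        def pack(split: str) -> classify.LabeledData:
            part = subjects[subjects["split"] == split]
            idx = part.index.to_numpy()
            return classify.LabeledData(
                images=images[idx],
                labels=(part["label"] == "dementia").to_numpy(int),
                demographics=part[["age", "sex", "race",
                                   "education"]].reset_index(drop=True),
                ids=part["id"].tolist())

        ft, te = pack("finetune"), pack("test")
        results = {}
        modes = {"latent": classify.HeadConfig(
                     hidden_sizes=tuple(cl.latent_hidden),
                     batch_size=cl.latent_batch_size, epochs=cl.epochs,
                     learning_rate=cl.learning_rate,
                     positive_class_weight=cl.positive_class_weight,
                     seed=seed),
                 "latent+demo": classify.HeadConfig(
                     hidden_sizes=tuple(cl.demo_hidden),
                     batch_size=cl.demo_batch_size, epochs=cl.epochs,
                     learning_rate=cl.learning_rate,
                     positive_class_weight=cl.positive_class_weight,
                     seed=seed + 1),
                 "demo": classify.HeadConfig(
                     hidden_sizes=tuple(cl.demo_hidden),
                     batch_size=cl.demo_batch_size, epochs=cl.epochs,
                     learning_rate=cl.learning_rate,
                     positive_class_weight=cl.positive_class_weight,
                     seed=seed + 2)}
        rows = []
        for mode, hc in modes.items():
            clf, _ = classify.finetune(
                None if mode == "demo" else model, hc, ft, mode=mode)
            report = classify.bootstrap_ci(
                clf, te, B=cl.bootstrap_B,
                rng=np.random.default_rng(cfg.stage_seed(f"boot:{mode}")),
                threshold=cl.threshold)
            results[mode] = report
            for m, (med, lo, hi) in report.metrics.items():
                rows.append({"features": mode, "metric": m, "median": med,
                             "ci_lo": lo, "ci_hi": hi,
                             "point": report.point[m]})
            scores = clf.predict_proba(te)
            pd.DataFrame({"id": te.ids, "score": scores,
                          "label": te.labels}).to_csv(
                rep / f"predictions_{mode.replace('+', '_')}.csv", index=False)
        pd.DataFrame(rows).to_csv(rep / "classifier_metrics.csv", index=False)
        (rep / "classifier_metrics.json").write_text(json.dumps(
            {mode: {m: {"median": v[0], "ci_lo": v[1], "ci_hi": v[2]}
                    for m, v in r.metrics.items()}
             for mode, r in results.items()}, indent=2))
        arts = [rep / "classifier_metrics.csv",
                rep / "classifier_metrics.json"]
        summary.append(_mark_done(out, stage, cfg_hash, seed, arts, t0))
        log("classify: metrics written")

    run_summary = {"config_hash": cfg_hash, "seed": cfg.seed,
                   "stages": summary}
    (out / "summary.json").write_text(json.dumps(run_summary, indent=2))
    return run_summary
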