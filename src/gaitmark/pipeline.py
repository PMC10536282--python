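"""Config-driven orchestration of the full analysis workflow.

``run_pipeline`` executes simulate -> preprocess -> label -> featurize ->
evaluate -> similarity (any contiguous subset), writing every artifact under
a run directory together with a manifest recording the config hash and
seeds. Re-running with the same config and seed reproduces byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .classify import DESIGNS, ForestParams, SplitSpec, run_design
from .core import ConfigurationError, GaitmarkError, read_recording, write_recording
from .corpus import Corpus, prepare_corpus
from .events import AugmentParams
from .features import FeatureParams
from .preprocess import PreprocessParams
from .similarity import SimilarityParams, TABLE_PAIRS, similarity_matrix
from .simulate import SimConfig, simulate_cohort

__all__ = ["RunConfig", "validate_config", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger("gaitmark")

ALL_STAGES = ("simulate", "preprocess", "label", "featurize", "evaluate", "similarity")


@dataclasses.dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    out_dir: str = "gaitmark_run"
    data_dir: str | None = None
    stages: tuple = ALL_STAGES
    designs: tuple = ("A",)
    seed: int = 0
    cv_folds: int | None = None
    log_level: str = "INFO"
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    preprocess: PreprocessParams = dataclasses.field(default_factory=PreprocessParams)
    central_duration_s: float | None = None
    augment: AugmentParams = dataclasses.field(default_factory=AugmentParams)
    features: FeatureParams = dataclasses.field(default_factory=FeatureParams)
    forest: ForestParams = dataclasses.field(default_factory=ForestParams)
    split: SplitSpec = dataclasses.field(default_factory=SplitSpec)
    similarity: SimilarityParams = dataclasses.field(default_factory=SimilarityParams)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return {
            f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


_SECTION_TYPES = {
    "sim": SimConfig,
    "preprocess": PreprocessParams,
    "augment": AugmentParams,
    "features": FeatureParams,
    "forest": ForestParams,
    "split": SplitSpec,
    "similarity": SimilarityParams,
}


def _build_config(raw: dict, errors: list[str]) -> RunConfig:
    cfg = RunConfig()
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key: {key!r}")
    for key, cls in _SECTION_TYPES.items():
        section = raw.get(key, {})
        if not isinstance(section, dict):
            errors.append(f"{key}: expected a mapping")
            continue
        valid_fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in section.items():
            if k not in valid_fields:
                errors.append(f"{key}.{k}: unknown field")
            else:
                kwargs[k] = tuple(v) if isinstance(v, list) else v
        try:
            setattr(cfg, key, cls(**kwargs))
        except (GaitmarkError, TypeError, ValueError) as exc:
            errors.append(f"{key}: {exc}")
    for key in ("out_dir", "data_dir", "log_level"):
        if key in raw:
            setattr(cfg, key, raw[key])
    for key in ("seed", "cv_folds"):
        if key in raw and raw[key] is not None:
            try:
                setattr(cfg, key, int(raw[key]))
            except (TypeError, ValueError):
                errors.append(f"{key}: expected an integer, got {raw[key]!r}")
    if "stages" in raw:
        stages = tuple(raw["stages"])
        bad = [s for s in stages if s not in ALL_STAGES]
        if bad:
            errors.append(f"stages: unknown stage(s) {bad}; valid: {ALL_STAGES}")
        cfg.stages = stages
    if "designs" in raw:
        designs = tuple(raw["designs"])
        bad = [d for d in designs if d not in DESIGNS]
        if bad:
            errors.append(f"designs: unknown design(s) {bad}")
        cfg.designs = designs
    # cross-field checks
    if cfg.sim.fs < cfg.preprocess.target_fs:
        errors.append(
            "sim.fs / preprocess.target_fs: simulated rate "
            f"({cfg.sim.fs} Hz) below the resampling target "
            f"({cfg.preprocess.target_fs} Hz)"
        )
    return cfg


def validate_config(path) -> RunConfig:
    """Load, default-fill and validate a YAML/JSON config file.

    Raises :class:`ConfigurationError` listing every problem found; an
    empty file yields the fully-defaulted config.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    errors: list[str] = []
    cfg = _build_config(raw, errors)
    if errors:
        raise ConfigurationError(
            "invalid configuration:\n  - " + "\n  - ".join(errors)
        )
    return cfg


# ---------------------------------------------------------------------------
# pipeline execution
# ---------------------------------------------------------------------------


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump_json(payload: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _load_recordings(data_dir: Path):
    recs = []
    for csv_path in sorted(data_dir.glob("*.csv")):
        for ext in (".json", ".yaml", ".yml"):
            meta = csv_path.with_suffix(ext)
            if meta.exists():
                recs.append(read_recording(csv_path, meta))
                break
    if not recs:
        raise ConfigurationError(f"no recording CSV/metadata pairs in {data_dir}")
    return recs


def _write_events_csv(corpus: Corpus, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("subject,condition,speed,event_type,sample_index,time_s\n")
        for rid in sorted(corpus.events):
            rec = corpus.recordings[rid]
            ev = corpus.events[rid]
            rows = [(int(i), "IC") for i in ev.ic] + [(int(j), "FO") for j in ev.fo]
            for idx, kind in sorted(rows):
                fh.write(
                    f"{rec.subject_id},{rec.support},{rec.speed:g},"
                    f"{kind},{idx},{idx / corpus.fs!r}\n"
                )


def run_pipeline(config: RunConfig, out_dir=None) -> Path:
    """Execute the configured stages and write all artifacts under the run
    directory. Returns the run directory path."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": list(config.stages),
        "outputs": [],
    }

    def record(stage: str, path: Path):
        manifest["outputs"].append({"stage": stage, "path": str(path.relative_to(out))})

    try:
        log.info("run config hash %s, seed %d", config.config_hash(), config.seed)
        # --- simulate or load -----------------------------------------
        if "simulate" in config.stages:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            pairs = simulate_cohort(sim)
            recordings = [rec for rec, _ in pairs]
            rec_dir = out / "recordings"
            rec_dir.mkdir(exist_ok=True)
            for rec, _ in pairs:
                stem = rec.recording_id.replace("|", "_").replace("/", "-")
                write_recording(rec, rec_dir / f"{stem}.csv", rec_dir / f"{stem}.json")
                record("simulate", rec_dir / f"{stem}.csv")
                record("simulate", rec_dir / f"{stem}.json")
            truth_path = out / "ground_truth_events.csv"
            with open(truth_path, "w", encoding="utf-8") as fh:
                fh.write("subject,condition,speed,event_type,sample_index\n")
                for rec, ev in pairs:
                    rows = [(int(i), "IC") for i in ev.ic] + [
                        (int(j), "FO") for j in ev.fo
                    ]
                    for idx, kind in sorted(rows):
                        fh.write(
                            f"{rec.subject_id},{rec.support},{rec.speed:g},{kind},{idx}\n"
                        )
            record("simulate", truth_path)
        elif config.data_dir:
            recordings = _load_recordings(Path(config.data_dir))
        else:
            raise ConfigurationError(
                "no input: enable the simulate stage or set data_dir"
            )
        log.info("%d recordings", len(recordings))

        remaining = [s for s in config.stages if s != "simulate"]
        if not remaining:
            return out

        # --- preprocess + label + featurize ---------------------------
        corpus = prepare_corpus(
            recordings,
            pre=config.preprocess,
            augment=config.augment,
            feat=config.features,
            central_duration_s=config.central_duration_s,
        )
        log.info("corpus: %d samples, %d cycles", len(corpus), corpus.n_cycles)
        if "preprocess" in config.stages:
            pp_dir = out / "preprocessed"
            pp_dir.mkdir(exist_ok=True)
            for rid in sorted(corpus.recordings):
                rec = corpus.recordings[rid]
                stem = rid.replace("|", "_").replace("/", "-")
                write_recording(rec, pp_dir / f"{stem}.csv", pp_dir / f"{stem}.json")
                record("preprocess", pp_dir / f"{stem}.csv")
                record("preprocess", pp_dir / f"{stem}.json")
        if "label" in config.stages:
            ev_path = out / "events.csv"
            _write_events_csv(corpus, ev_path)
            record("label", ev_path)
        if "featurize" in config.stages:
            feat_path = out / "features.csv"
            corpus.frames.to_csv(feat_path, index=False)
            record("featurize", feat_path)

        # --- evaluate -------------------------------------------------
        if "evaluate" in config.stages:
            rep_dir = out / "reports"
            rep_dir.mkdir(exist_ok=True)
            for design in config.designs:
                try:
                    result = run_design(
                        corpus,
                        design,
                        split_seed=config.split.seed,
                        forest_seed=config.forest.seed,
                        held_out_subjects=config.split.held_out_subjects,
                        cv_folds=config.cv_folds,
                    )
                except GaitmarkError as exc:
                    raise GaitmarkError(f"[evaluate/design {design}] {exc}") from exc
                payload = result.to_dict()
                payload["seeds"] = {
                    "root": config.seed,
                    "split": config.split.seed,
                    "forest": config.forest.seed,
                }
                path = rep_dir / f"design_{design}.json"
                _dump_json(payload, path)
                record("evaluate", path)
                log.info("design %s accuracy %.3f", design, result.report.accuracy)

        # --- similarity -----------------------------------------------
        if "similarity" in config.stages:
            supports = {r.support for r in corpus.recordings.values()}
            pairs = tuple(
                p for p in TABLE_PAIRS if p[0] in supports and p[1] in supports
            )
            if pairs:
                table = similarity_matrix(corpus, pairs, params=config.similarity)
                sim_path = out / "similarity.csv"
                table.to_csv(sim_path, float_format="%.6f")
                record("similarity", sim_path)
    except GaitmarkError as exc:
        log.error("pipeline failed: %s", exc)
        raise
    finally:
        _dump_json(manifest, out / "manifest.json")
        log.removeHandler(handler)
        handler.close()
    return out
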