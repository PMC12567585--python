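"""Readers, writers, run configuration and the end-to-end pipeline driver.

CSV dialect everywhere: comma-separated, UTF-8, header row required.
Accelerometer timestamps may be epoch seconds or ISO-8601; both are
normalised to seconds internally. GAF frames are written as 8-bit grayscale
PNG (value = round(255 * pixel)) with a manifest CSV; a lossless NPZ option
exists for numeric round-trips.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from pydantic import BaseModel, ConfigDict, Field

from .clinical import SNAP_ITEM_COLUMNS, DEFAULT_FEATURE_COLUMNS
from .gaf import ImageSequence, TriaxialSeries, WindowingConfig
from .model import FUSION_KINDS

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_COLUMN_MAP", "read_accelerometer_csv", "write_accelerometer_csv",
    "read_clinical_csv", "write_clinical_csv", "write_data_dictionary",
    "write_gaf_pngs", "read_gaf_pngs", "save_sequences_npz", "load_sequences_npz",
    "save_checkpoint", "load_checkpoint", "write_metrics_json",
    "RunConfig", "RunManifest", "load_config", "run_pipeline",
]

#: Assumed SensorLog-style export columns; override via the config column map.
DEFAULT_COLUMN_MAP = {
    "timestamp": "loggingTime",
    "x": "accelerometerAccelerationX",
    "y": "accelerometerAccelerationY",
    "z": "accelerometerAccelerationZ",
}


# --------------------------------------------------------------------- readers
def _parse_timestamps(col: pd.Series) -> np.ndarray:
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().all():
        return numeric.to_numpy(dtype=np.float64)
    parsed = pd.to_datetime(col, errors="coerce", format="ISO8601", utc=True)
    return parsed.astype("int64").to_numpy() / 1e9


def read_accelerometer_csv(path, column_map=None, rate_hz: float = 100.0,
                           strict: bool = False) -> TriaxialSeries:
    """Read a SensorLog-style CSV into a validated :class:`TriaxialSeries`.

    Unparsable rows are dropped and counted; in strict mode more than 1%
    dropped rows is an error, otherwise a warning. The sampling rate estimated
    from the timestamps must agree with `rate_hz` within 5%.
    """
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in cmap.values() if c not in frame.columns]
    if missing:
        raise ValueError(
            f"missing mapped columns {missing}; file has {list(frame.columns)}")
    ts = _parse_timestamps(frame[cmap["timestamp"]])
    axes = {k: pd.to_numeric(frame[cmap[k]], errors="coerce").to_numpy(dtype=np.float64)
            for k in ("x", "y", "z")}
    ok = np.isfinite(ts)
    for a in axes.values():
        ok &= np.isfinite(a)
    dropped = int((~ok).sum())
    if dropped:
        frac = dropped / len(frame)
        msg = f"dropped {dropped}/{len(frame)} unparsable rows from {path}"
        if strict and frac > 0.01:
            raise ValueError(msg + " (> 1% in strict mode)")
        logger.warning(msg)
    series = TriaxialSeries(timestamps=ts[ok], x=axes["x"][ok], y=axes["y"][ok],
                            z=axes["z"][ok], rate_hz=rate_hz)
    # median inter-sample gap is robust to isolated dropped rows
    est = 1.0 / float(np.median(np.diff(series.timestamps)))
    if abs(est - rate_hz) / rate_hz > 0.05:
        raise ValueError(
            f"estimated rate {est:.2f} Hz deviates > 5% from declared {rate_hz} Hz")
    return series


def write_accelerometer_csv(series: TriaxialSeries, path, column_map=None):
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    frame = pd.DataFrame({
        cmap["timestamp"]: series.timestamps, cmap["x"]: series.x,
        cmap["y"]: series.y, cmap["z"]: series.z,
    })
    frame.to_csv(path, index=False)  # default float repr round-trips exactly


def read_clinical_csv(path) -> pd.DataFrame:
    """One row per subject; missing values are empty cells."""
    frame = pd.read_csv(path)
    if "subject_id" not in frame.columns:
        raise ValueError("clinical CSV needs a 'subject_id' column")
    return frame


def write_clinical_csv(frame: pd.DataFrame, path):
    frame.to_csv(path, index=False)


def write_data_dictionary(path):
    """Document the clinical encodings next to any exported clinical table."""
    lines = [
        "column,encoding",
        "subject_id,unique key",
        "sex,male=0 female=1",
        "age,years",
        "bmi,kg/m^2",
        "grade,school grade (1-7)",
        "health_state,ordinal 1=poor 2=good 3=very good",
        "diet_state,ordinal 1=poor 2=good 3=very good",
        "parental_education,ordinal 1=poor 2=moderate 3=good",
    ] + [f"{c},SNAP-IV item rating 0-3" for c in SNAP_ITEM_COLUMNS]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ----------------------------------------------------------------- GAF images
def write_gaf_pngs(sequences, out_dir) -> pd.DataFrame:
    """Write each frame's first channel as 8-bit grayscale PNG + manifest CSV.

    Row index 0 of the matrix (earliest window time) is the top image row.
    Returns the manifest frame (also written to ``out_dir/manifest.csv``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for si, seq in enumerate(sequences):
        for fi in range(seq.frames.shape[0]):
            img = np.rint(255.0 * seq.frames[fi, 0]).astype(np.uint8)
            name = f"{seq.subject_id or 'subject'}_seq{si:04d}_frame{fi}.png"
            Image.fromarray(img, mode="L").save(out_dir / name)
            start, end = seq.windows[fi] if seq.windows else (-1, -1)
            rows.append({"subject_id": seq.subject_id, "sequence": si, "frame": fi,
                         "window_start": start, "window_end": end, "path": name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_gaf_pngs(out_dir):
    """Rebuild (quantised) image sequences from a PNG directory + manifest."""
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / "manifest.csv")
    sequences = []
    for (sid, si), group in manifest.groupby(["subject_id", "sequence"], sort=True):
        group = group.sort_values("frame")
        mats = [np.asarray(Image.open(out_dir / p), dtype=np.float64) / 255.0
                for p in group["path"]]
        frames = np.stack([np.repeat(m[None], 3, axis=0) for m in mats])
        windows = list(zip(group["window_start"], group["window_end"]))
        sequences.append(ImageSequence(frames=frames, subject_id=str(sid), windows=windows))
    return sequences


def save_sequences_npz(sequences, path):
    """Lossless float archive of image sequences (exact round-trip)."""
    arrays, meta = {}, []
    for i, seq in enumerate(sequences):
        arrays[f"frames_{i}"] = seq.frames
        meta.append({"subject_id": seq.subject_id, "windows": list(map(list, seq.windows))})
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_sequences_npz(path):
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    return [ImageSequence(frames=data[f"frames_{i}"], subject_id=m["subject_id"],
                          windows=[tuple(w) for w in m["windows"]])
            for i, m in enumerate(meta)]


# --------------------------------------------------------------- model state
def save_checkpoint(model, path):
    """NPZ checkpoint: every parameter plus the embedded model configuration."""
    cfg = {"vit": asdict(model.vit_cfg), "bilstm": asdict(model.lstm_cfg),
           "fusion": asdict(model.fusion_cfg), "tabular_dim": model.tabular_dim,
           "seed": model.seed}
    state = {k.replace(".", "/"): v for k, v in model.state_dict().items()}
    np.savez(path, __config__=json.dumps(cfg), **state)


def load_checkpoint(path):
    from .model import BiLstmConfig, FusionConfig, MultimodalNet, ViTConfig
    data = np.load(path)
    cfg = json.loads(str(data["__config__"]))
    model = MultimodalNet(ViTConfig(**cfg["vit"]), BiLstmConfig(**cfg["bilstm"]),
                          FusionConfig(**cfg["fusion"]), cfg["tabular_dim"],
                          seed=cfg["seed"])
    model.load_state_dict({k.replace("/", "."): data[k] for k in data.files
                           if k != "__config__"})
    model.eval()
    return model


def write_metrics_json(metrics: dict, path):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    _atomic_write_text(Path(path), json.dumps(metrics, indent=2, default=default))


def _atomic_write_text(path: Path, text: str):
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


# -------------------------------------------------------------- configuration
class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WindowingSection(_Section):
    window_seconds: float = 10.0
    image_size: int = 224
    frames_per_sequence: int = 5
    channel_mode: str = "replicate"
    clip_negative_enmo: bool = False


class ClinicalSection(_Section):
    column_map: dict = Field(default_factory=dict)
    feature_columns: list = Field(default_factory=lambda: list(DEFAULT_FEATURE_COLUMNS))
    t_score_ddof: int = 1


class CohortSection(_Section):
    n_subjects: int = 50
    prevalence: float = 0.26
    minutes_per_subject: float = 2.0
    rate_hz: float = 100.0
    effect_size: float = 2.0
    snap_shift: float = 0.8


class VitSection(_Section):
    image_size: int = 224
    patch_size: int = 16
    depth: int = 12
    heads: int = 12
    embed_dim: int = 768
    pretrained: bool = False
    weights_path: str | None = None


class BiLstmSection(_Section):
    hidden: int = 128
    layers: int = 2


class FusionSection(_Section):
    kind: str = "cross_attention"
    d_k: int = 128
    heads: int = 4
    dropout: float = 0.5
    single_token: bool = False


class TrainSection(_Section):
    epochs: int = 20
    learning_rate: float = 1e-4
    batch_size: int = 8
    weight_decay: float = 1e-5
    dropout: float = 0.5
    focal_gamma: float = 2.0
    class_weight_mode: str = "inverse"
    split_fractions: tuple = (0.55, 0.15, 0.30)
    cv_folds: int = 10


class RunConfig(_Section):
    """Validated top-level run configuration (unknown keys rejected)."""

    seed: int = 42
    output_dir: str = "runs/latest"
    windowing: WindowingSection = Field(default_factory=WindowingSection)
    clinical: ClinicalSection = Field(default_factory=ClinicalSection)
    cohort: CohortSection = Field(default_factory=CohortSection)
    vit: VitSection = Field(default_factory=VitSection)
    bilstm: BiLstmSection = Field(default_factory=BiLstmSection)
    fusion: FusionSection = Field(default_factory=FusionSection)
    train: TrainSection = Field(default_factory=TrainSection)

    def tiny(self) -> "RunConfig":
        """CPU-scale preset overriding the study-scale model sizes."""
        cfg = self.model_copy(deep=True)
        cfg.windowing.image_size = 32
        cfg.vit = VitSection(image_size=32, patch_size=8, depth=2, heads=4, embed_dim=64)
        cfg.bilstm = BiLstmSection(hidden=32, layers=1)
        cfg.fusion.d_k = 32
        cfg.fusion.heads = 2
        cfg.train.epochs = 30
        cfg.train.learning_rate = 3e-3
        return cfg

    def windowing_config(self) -> WindowingConfig:
        return WindowingConfig(**self.windowing.model_dump())


def load_config(path=None, tiny: bool = False, seed: int = None) -> RunConfig:
    if path is None:
        cfg = RunConfig()
    else:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = RunConfig.model_validate(raw)
    if tiny:
        cfg = cfg.tiny()
    if seed is not None:
        cfg.seed = seed
    return cfg


# ------------------------------------------------------------------- pipeline
@dataclass
class RunManifest:
    """Everything needed to re-execute and audit a run."""

    config: dict
    seed: int
    input_hashes: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    failed_stage: str = None

    def write(self, path):
        _atomic_write_text(Path(path), json.dumps(asdict(self), indent=2))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """simulate -> encode -> preprocess -> train -> evaluate, with a manifest.

    Runs on a synthetic cohort drawn from ``cfg.cohort``; every artifact path,
    stage timing and the full config snapshot are recorded. Deterministic
    given (config, seed).
    """
    from .dataset import build_dataset
    from .model import BiLstmConfig, FusionConfig, MultimodalNet, ViTConfig
    from .synthetic import CohortSpec, generate_cohort
    from .training import TrainConfig, evaluate, subject_split, train as train_loop

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg.model_dump(), seed=cfg.seed)
    stage = "simulate"
    try:
        t0 = time.time()
        spec = CohortSpec(seed=cfg.seed, **cfg.cohort.model_dump())
        subjects, clinical = generate_cohort(spec)
        clinical_path = out / "clinical.csv"
        write_clinical_csv(clinical, clinical_path)
        write_data_dictionary(out / "data_dictionary.csv")
        manifest.input_hashes["clinical.csv"] = _sha256(clinical_path)
        manifest.artifacts["clinical"] = str(clinical_path)
        manifest.timings[stage] = time.time() - t0

        stage = "split"
        t0 = time.time()
        from .clinical import build_cohort_table
        table = build_cohort_table(clinical)
        plan = subject_split(list(table.subject_ids), table.labels,
                             fractions=tuple(cfg.train.split_fractions), seed=cfg.seed)
        manifest.timings[stage] = time.time() - t0

        stage = "encode"
        t0 = time.time()
        data = build_dataset(subjects, clinical, windowing=cfg.windowing_config(),
                             train_ids=plan.train,
                             feature_columns=cfg.clinical.feature_columns)
        manifest.timings[stage] = time.time() - t0

        stage = "train"
        t0 = time.time()
        pos = {sid: i for i, sid in enumerate(data.subject_ids)}
        tr = data.select_subjects([pos[s] for s in plan.train])
        va = data.select_subjects([pos[s] for s in plan.val])
        te = data.select_subjects([pos[s] for s in plan.test])
        model = MultimodalNet(
            ViTConfig(**cfg.vit.model_dump()),
            BiLstmConfig(input_dim=cfg.vit.embed_dim, **cfg.bilstm.model_dump()),
            FusionConfig(**cfg.fusion.model_dump()),
            tabular_dim=data.tabular.shape[1], seed=cfg.seed)
        tcfg = TrainConfig(seed=cfg.seed,
                           **{k: v for k, v in cfg.train.model_dump().items()
                              if k not in ("split_fractions", "cv_folds")})
        history = train_loop(model, data, tr, va, tcfg)
        ckpt = out / "model.npz"
        save_checkpoint(model, ckpt)
        manifest.artifacts["checkpoint"] = str(ckpt)
        manifest.timings[stage] = time.time() - t0

        stage = "evaluate"
        t0 = time.time()
        results = {
            "subject_level": evaluate(model, data, te, subject_level=True),
            "sequence_level": evaluate(model, data, te, subject_level=False),
            "history": {"train_loss": history.train_loss, "val_loss": history.val_loss,
                        "best_epoch": history.best_epoch},
            "split": {"train": plan.train, "val": plan.val, "test": plan.test},
        }
        metrics_path = out / "metrics.json"
        write_metrics_json(results, metrics_path)
        manifest.artifacts["metrics"] = str(metrics_path)
        manifest.timings[stage] = time.time() - t0
    except Exception:
        manifest.failed_stage = stage
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return manifest
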