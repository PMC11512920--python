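"""Configuration, file I/O and end-to-end orchestration.

``run_pipeline`` chains the stages -- simulate (or read) recordings, extract
band phases, compute CFS matrices, render image sequences, cross-validate
the classifier and explain the correctly classified subjects -- writing
metrics, explanation tables, figures and a provenance record (configuration
hash, seeds, package versions, per-stage timings) to the output directory.

Segment and frame indices are 0-based in memory and 1-based in written
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bands import CANONICAL_BANDS, BandDefinition, extract_phases
from .cfs import DEFAULT_PAIRS, SegmentationSpec, cfs_matrix
from .classifier import (CNNConfig, CVResults, LSTMConfig, TrainConfig,
                         cross_validate)
from .explain import explain_sequence, plot_relevance_frames, top_superpixels
from .imaging import (CFSImageSequence, build_feature_mask, project_montage,
                      stack_frames)
from .montage import Montage, default_montage, read_sfp
from .recording import Recording
from .synthetic import (ClassTemplate, default_templates, make_cohort,
                        read_matrix, write_manifest)

logger = logging.getLogger("cfsimage")

__all__ = ["PipelineConfig", "read_eeg", "transform_recording",
           "transform_cohort", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Referentially complete parameter set for one pipeline run."""

    # data source: generated cohort (default) or a directory of recordings
    n_control: int = 33
    n_dyslexic: int = 15
    duration_s: float = 150.0
    sfreq: float = 500.0
    data_dir: str | None = None  # read .tsv/.edf/.vhdr recordings instead
    stimulus_label: str = "4.8Hz"

    # transform
    bands: tuple[dict, ...] = field(default_factory=lambda: tuple(
        {"name": b.name, "f_low": b.f_low, "f_high": b.f_high}
        for b in CANONICAL_BANDS))
    band_pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    window_s: float = 5.0
    overlap_s: float = 0.0
    mesh: int = 32
    montage_file: str | None = None  # .sfp path; default idealised montage

    # classification
    folds: int = 5
    cnn_filters: tuple[int, int] = (8, 16)
    cnn_kernel: int = 3
    cnn_strides: tuple[int, int] = (1, 2)
    lstm_hidden: int = 20
    lstm_layers: int = 2
    dropout: float = 0.5
    lr: float = 1e-3
    epochs: int = 200
    patience: int = 20

    # explanation
    lime_samples: int = 10_000
    lasso_penalty: float = 1e-3

    seed: int = 0
    output_dir: str = "cfsimage-output"
    save_sequences: bool = False

    # -- derived objects ---------------------------------------------------
    def band_definitions(self) -> tuple[BandDefinition, ...]:
        return tuple(BandDefinition(**b) for b in self.bands)

    def segmentation(self) -> SegmentationSpec:
        return SegmentationSpec(self.window_s, self.overlap_s)

    def montage(self) -> Montage:
        return (read_sfp(self.montage_file) if self.montage_file
                else default_montage())

    def cnn_config(self) -> CNNConfig:
        return CNNConfig(filters=tuple(self.cnn_filters),
                         kernel=self.cnn_kernel,
                         strides=tuple(self.cnn_strides))

    def lstm_config(self) -> LSTMConfig:
        return LSTMConfig(layers=self.lstm_layers, hidden=self.lstm_hidden,
                          dropout=self.dropout)

    def train_config(self) -> TrainConfig:
        return TrainConfig(lr=self.lr, epochs=self.epochs,
                           patience=self.patience)

    def validate(self) -> None:
        self.band_definitions()
        self.segmentation()
        if len(self.band_pairs) != 3:
            raise ValueError("band_pairs must name exactly three pairs")
        if self.data_dir is None and self.folds > min(self.n_control,
                                                      self.n_dyslexic):
            raise ValueError(
                f"folds={self.folds} exceeds the smaller class count")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**d)
        # normalise list-vs-tuple so round-trips are stable
        cfg.bands = tuple(dict(b) for b in cfg.bands)
        cfg.band_pairs = tuple(tuple(p) for p in cfg.band_pairs)
        cfg.cnn_filters = tuple(cfg.cnn_filters)
        cfg.cnn_strides = tuple(cfg.cnn_strides)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_eeg(path, fmt: str | None = None, montage: Montage | None = None,
             zscore: bool = True) -> Recording:
    """Read a recording from BrainVision, EDF or matrix+sidecar files.

    Channels are reordered to the montage's channel order when a montage is
    given (the reference, if present in the file, is dropped).  By default
    each channel is z-scored, mirroring standard preprocessing; pass
    ``zscore=False`` for data already normalised.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".vhdr": "brainvision", ".edf": "edf",
               ".tsv": "matrix", ".json": "matrix"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format of {path.name}; "
                             "pass fmt='brainvision'|'edf'|'matrix'")
    if fmt == "matrix":
        rec = read_matrix(path.with_suffix(""))
    elif fmt in ("brainvision", "edf"):
        import mne

        reader = (mne.io.read_raw_brainvision if fmt == "brainvision"
                  else mne.io.read_raw_edf)
        raw = reader(path, preload=True, verbose="error")
        rec = Recording(data=raw.get_data() * 1e6, sfreq=raw.info["sfreq"],
                        channel_names=tuple(raw.ch_names),
                        subject_id=path.stem)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if montage is not None:
        missing = [ch for ch in montage.channels
                   if ch not in rec.channel_names]
        if missing:
            raise ValueError(f"{path.name}: montage channels missing from "
                             f"file: {missing}")
        order = [rec.channel_names.index(ch) for ch in montage.channels]
        rec = Recording(data=rec.data[order], sfreq=rec.sfreq,
                        channel_names=montage.channels,
                        subject_id=rec.subject_id, label=rec.label)
    return rec.standardized() if zscore else rec


def transform_recording(recording: Recording, config: PipelineConfig,
                        projected=None) -> CFSImageSequence:
    """Recording -> band phases -> CFS matrix -> image sequence."""
    phases = extract_phases(recording, config.band_definitions())
    pairs = tuple(dict.fromkeys(tuple(p) for p in config.band_pairs))
    matrix = cfs_matrix(phases, pairs, config.segmentation())
    projected = projected or project_montage(config.montage())
    return stack_frames(matrix, tuple(tuple(p) for p in config.band_pairs),
                        projected, mesh=config.mesh)


def transform_cohort(recordings: list[Recording], config: PipelineConfig
                     ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Image-sequence tensor (subjects, frames, mesh, mesh, 3) + labels."""
    projected = project_montage(config.montage())
    sequences, labels, ids = [], [], []
    for rec in recordings:
        seq = transform_recording(rec, config, projected)
        sequences.append(seq.frames)
        labels.append(1 if rec.label == "dyslexic" else 0)
        ids.append(rec.subject_id)
    return np.stack(sequences), np.array(labels), ids


def _load_data_dir(config: PipelineConfig) -> list[Recording]:
    import pandas as pd

    data_dir = Path(config.data_dir)
    manifest = data_dir / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"{manifest} not found (subject ids + labels)")
    table = pd.read_csv(manifest)
    montage = config.montage()
    recordings = []
    for _, row in table.iterrows():
        stem = data_dir / str(row["subject_id"])
        for ext in (".vhdr", ".edf", ".tsv"):
            if stem.with_suffix(ext).exists():
                rec = read_eeg(stem.with_suffix(ext), montage=montage)
                break
        else:
            raise FileNotFoundError(f"no recording found for {stem}")
        rec.subject_id = str(row["subject_id"])
        rec.label = str(row["label"])
        recordings.append(rec)
    return recordings


def run_pipeline(config: PipelineConfig,
                 templates: tuple[ClassTemplate, ClassTemplate] | None = None
                 ) -> dict:
    """Execute the full pipeline and write all artefacts.

    Returns a dictionary with the cohort ids, the :class:`CVResults`, the
    aggregated explanation map and the paths written.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    timings: dict[str, float] = {}
    logging.basicConfig(level=logging.INFO)

    def stage(name):
        logger.info("stage %s (config %s)", name, chash)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    stage("data")
    if config.data_dir is not None:
        recordings = _load_data_dir(config)
    else:
        recordings = make_cohort(config.n_control, config.n_dyslexic,
                                 templates=templates, seed=config.seed,
                                 duration_s=config.duration_s,
                                 sfreq=config.sfreq,
                                 montage=config.montage())
    write_manifest(recordings, out / "manifest.csv")
    done("data")

    stage("transform")
    X, y, ids = transform_cohort(recordings, config)
    if config.save_sequences:
        np.savez_compressed(out / "sequences.npz", frames=X, labels=y,
                            subject_ids=np.array(ids))
    done("transform")

    stage("train")
    cv = cross_validate(X, y, k=config.folds, seed=config.seed,
                        cnn=config.cnn_config(), lstm=config.lstm_config(),
                        train=config.train_config())
    metrics_path = out / "metrics.csv"
    frame = cv.to_frame()
    frame.loc["mean"] = frame.mean()
    frame.loc["sd"] = frame.std(ddof=0)
    frame.to_csv(metrics_path)
    (out / "summary.txt").write_text(
        f"stimulus {config.stimulus_label}\n{cv.summary()}\n")
    for i, model in enumerate(cv.models):
        model.save(out / f"model-fold{i + 1}.npz")
    done("train")

    stage("explain")
    projected = project_montage(config.montage())
    mask = build_feature_mask(projected, mesh=config.mesh)
    maps = []
    for subj in np.flatnonzero(cv.correct):
        fold = next(i for i, te in enumerate(cv.test_indices) if subj in te)
        maps.append(explain_sequence(
            cv.models[fold], X[subj], mask,
            n_samples=config.lime_samples,
            lasso_penalty=config.lasso_penalty,
            seed=config.seed + 100 * subj, subject_id=ids[subj]))
    explanations = None
    if maps:
        import pandas as pd

        pd.concat([m.to_dataframe() for m in maps]).to_csv(
            out / "explanations.csv", index=False)
        mean_map, rankings = top_superpixels(maps, k=5)
        explanations = (mean_map, rankings)
        show = np.unique(np.linspace(0, mean_map.shape[0] - 1, 7).astype(int))
        plot_relevance_frames(mask, mean_map, show, k=5,
                              path=out / "top-superpixels.png")
    done("explain")

    provenance = {
        "config_hash": chash,
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "numpy": np.__version__,
        "timings_s": timings,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=list)
    config.to_yaml(out / "config.yaml")

    return {"subject_ids": ids, "labels": y, "cv": cv,
            "explanations": explanations, "output_dir": str(out),
            "config_hash": chash}
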