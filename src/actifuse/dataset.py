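"""Assembly of model-ready datasets from cohorts (signals + clinical table)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clinical import build_cohort_table
from .gaf import WindowingConfig, compute_enmo, window_to_sequence

__all__ = ["SequenceDataset", "build_dataset"]


@dataclass
class SequenceDataset:
    """Flat per-sequence arrays with the subject bookkeeping CV needs.

    frames: (N, F, 3, H, W) image sequences; tabular: (N, d) standardised
    clinical vectors (replicated across a subject's sequences); y: per-sequence
    labels; subject_index: position of each sequence's subject in `subject_ids`.
    """

    frames: np.ndarray
    tabular: np.ndarray
    y: np.ndarray
    subject_index: np.ndarray
    subject_ids: np.ndarray
    subject_labels: np.ndarray
    feature_columns: list

    def __len__(self):
        return len(self.y)

    def select_subjects(self, subject_positions) -> np.ndarray:
        """Sequence indices belonging to the given subject positions."""
        wanted = set(int(p) for p in subject_positions)
        return np.flatnonzero([int(s) in wanted for s in self.subject_index])

    def subject_probabilities(self, seq_probs: np.ndarray):
        """Aggregate per-sequence positive probabilities to subject level
        (mean over each subject's sequences). Returns (positions, probs)."""
        seq_probs = np.asarray(seq_probs, dtype=np.float64)
        positions = np.unique(self.subject_index)
        agg = np.array([seq_probs[self.subject_index == p].mean() for p in positions])
        return positions, agg


def build_dataset(subjects, clinical_frame, windowing: WindowingConfig = None,
                  train_ids=None, feature_columns=None) -> SequenceDataset:
    """Encode every subject's signal and pair it with standardised clinical
    features and the T-score-derived label.

    `subjects` are objects with ``series``/``record`` attributes (e.g. the
    synthetic generator's output); labels come from the real scoring pipeline
    applied to `clinical_frame`, never from generator ground truth.
    """
    windowing = windowing or WindowingConfig()
    table = build_cohort_table(clinical_frame, train_ids=train_ids,
                               feature_columns=feature_columns)
    ids = list(table.subject_ids)
    id_pos = {sid: i for i, sid in enumerate(ids)}

    frames, tab, y, subj_idx = [], [], [], []
    for subject in subjects:
        sid = subject.record.subject_id
        pos = id_pos[sid]
        enmo = compute_enmo(subject.series, clip_negative=windowing.clip_negative_enmo)
        axes = ((subject.series.x, subject.series.y, subject.series.z)
                if windowing.channel_mode == "per_axis" else None)
        for seq in window_to_sequence(enmo, windowing, subject_id=sid, axes=axes):
            frames.append(seq.frames)
            tab.append(table.feature_matrix[pos])
            y.append(table.labels[pos])
            subj_idx.append(pos)
    if not frames:
        raise ValueError("no image sequences produced; recordings too short for the windowing")
    return SequenceDataset(
        frames=np.stack(frames), tabular=np.stack(tab),
        y=np.asarray(y, dtype=np.int64), subject_index=np.asarray(subj_idx, dtype=np.int64),
        subject_ids=np.asarray(ids), subject_labels=table.labels,
        feature_columns=table.feature_columns,
    )
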