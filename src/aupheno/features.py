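"""Duration-independent AU summary features and the classifier matrix.

Because recording lengths differ across participants, every feature is a
proportion or a per-frame moment rather than a raw count: mean and
population SD of the binary presence channel and of the 0-5 intensity
channel, plus the two derived headline quantities —

* **presence metric** (``presence_gt1``): proportion of valid frames with
  intensity strictly greater than 1;
* **variation metric**: number of active/inactive flips between
  consecutive retained frames divided by the number of valid frames.

Together with the mean-intensity metric these feed both the classifier
(six features per dual-channel AU) and the clinical-validation
correlations.  AU28 has no intensity channel: its matrix columns are the
presence-channel statistics, the variation metric, and an ``activity``
column (presence-channel mean) standing in for the intensity>1
proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import catalog
from .ingest import AUSequence, QCReport


class UnavailableChannelError(ValueError):
    """Requested a channel (e.g. AU28 intensity) the dialect does not carry."""


def _presence_values(seq: AUSequence, au: int) -> np.ndarray:
    return seq.frames[catalog.presence_column(au)].to_numpy(float)


def _intensity_values(seq: AUSequence, au: int) -> np.ndarray:
    if not catalog.has_intensity(au):
        raise UnavailableChannelError(f"{catalog.au_label(au)} has no intensity channel")
    return seq.frames[catalog.intensity_column(au)].to_numpy(float)


def compute_presence_stats(seq: AUSequence, au: int) -> tuple[float, float]:
    """Mean and population SD of the binary presence channel."""
    v = _presence_values(seq, au)
    if len(v) == 0:
        raise ValueError(f"{seq.participant_id}: no valid frames for presence stats")
    return float(v.mean()), float(v.std(ddof=0))


def compute_intensity_stats(seq: AUSequence, au: int) -> tuple[float, float]:
    """Mean and population SD of the 0-5 intensity channel."""
    v = _intensity_values(seq, au)
    if len(v) == 0:
        raise ValueError(f"{seq.participant_id}: no valid frames for intensity stats")
    return float(v.mean()), float(v.std(ddof=0))


def compute_presence_metric(seq: AUSequence, au: int, threshold: float = 1.0) -> float:
    """Proportion of valid frames with intensity strictly above ``threshold``."""
    v = _intensity_values(seq, au)
    if len(v) == 0:
        raise ValueError(f"{seq.participant_id}: no valid frames")
    return float((v > threshold).mean())


def compute_variation_metric(seq: AUSequence, au: int) -> float:
    """Active/inactive flips between consecutive valid frames / #valid frames.

    Flips across a gap left by removed frames count as one comparison
    between the surviving neighbours.  Always in [0, 1) since N frames
    have N-1 adjacent pairs.
    """
    v = _presence_values(seq, au)
    if len(v) < 2:
        raise ValueError(f"{seq.participant_id}: need >=2 valid frames for variation metric")
    flips = int(np.count_nonzero(np.diff(v) != 0))
    return flips / len(v)


@dataclass
class FeatureMatrix:
    """Participants x features table with group labels.

    ``X`` is indexed by participant id with the deterministic catalog
    column order; ``labels`` holds case/control aligned to ``X``.
    """

    X: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing cells")
        if not self.X.index.is_unique:
            raise ValueError("duplicate participant ids")
        self.labels = self.labels.reindex(self.X.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.X)

    def to_csv(self, path) -> None:
        out = self.X.copy()
        out.insert(0, "group", self.labels)
        out.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="id")
        labels = df.pop("group")
        return cls(X=df, labels=labels)


def compute_feature_row(seq: AUSequence) -> dict[str, float]:
    """All catalog features for one filtered sequence."""
    row: dict[str, float] = {}
    for au in catalog.AU_IDS:
        lab = catalog.au_label(au)
        pm, psd = compute_presence_stats(seq, au)
        row[f"{lab}_presence_mean"] = pm
        row[f"{lab}_presence_sd"] = psd
        if catalog.has_intensity(au):
            im, isd = compute_intensity_stats(seq, au)
            row[f"{lab}_intensity_mean"] = im
            row[f"{lab}_intensity_sd"] = isd
            row[f"{lab}_presence_gt1"] = compute_presence_metric(seq, au)
        else:
            # AU28: presence-channel mean stands in for the intensity>1 proportion
            row[f"{lab}_activity"] = pm
        row[f"{lab}_variation"] = compute_variation_metric(seq, au)
    return row


def build_feature_matrix(
    sequences: list[AUSequence],
    qc: QCReport,
    labels: dict[str, str] | pd.Series,
) -> FeatureMatrix:
    """Assemble the classifier matrix over QC-included participants.

    Column order is deterministic (AU ascending, fixed feature order);
    any undefined feature raises naming the participant and feature.
    """
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    included = set(qc.included_ids())
    rows, ids = [], []
    for seq in sequences:
        if seq.participant_id not in included:
            continue
        try:
            rows.append(compute_feature_row(seq))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"participant {seq.participant_id}: {exc}") from exc
        ids.append(seq.participant_id)
    if len(ids) < 2:
        raise ValueError("need at least 2 included participants")
    X = pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=catalog.feature_columns())
    lab = pd.Series({i: labels[i] for i in ids}, name="group")
    if lab.nunique() < 2:
        raise ValueError("feature matrix must span both labels")
    return FeatureMatrix(X=X, labels=lab)
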