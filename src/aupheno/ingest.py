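"""Reading OpenFace 2.0 per-frame CSVs and frame/participant quality control.

The dialect consumed here is the one OpenFace writes for a single-face
video: one header row, then one row per frame with ``frame, face_id,
timestamp, confidence, success``, head-pose angles ``pose_Rx/Ry/Rz``
(radians), 17 intensity channels ``AU**_r`` on 0-5 and 18 presence
channels ``AU**_c`` in {0,1}.  Header whitespace is tolerated; extra
columns are ignored; rows for secondary faces (``face_id != 0``) are
dropped with a warning.

Quality control follows the study protocol for brief video recordings:
frames with tracking confidence below 80% (or a failed fit) are removed,
and participants retaining fewer than 90% valid frames are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import catalog

#: Frame-level confidence threshold: frames with confidence < 0.80 removed.
DEFAULT_FRAME_CONFIDENCE = 0.80
#: Participant-level threshold: < 90% valid frames excluded.
DEFAULT_VALID_FRACTION = 0.90

POSE_COLUMNS = ("pose_Rx", "pose_Ry", "pose_Rz")
META_COLUMNS = ("frame", "face_id", "timestamp", "confidence", "success")


def openface_columns() -> list[str]:
    """Full dialect header, in OpenFace order."""
    cols = list(META_COLUMNS) + list(POSE_COLUMNS)
    cols += [catalog.intensity_column(a) for a in catalog.INTENSITY_AU_IDS]
    cols += [catalog.presence_column(a) for a in catalog.AU_IDS]
    return cols


@dataclass(frozen=True)
class FrameRecord:
    """One video frame's tracked values."""

    frame_index: int
    timestamp: float
    confidence: float
    success: int
    pose: tuple[float, float, float]
    au_intensity: dict[int, float]
    au_presence: dict[int, int]


@dataclass
class AUSequence:
    """One participant's ordered frame stream plus QC provenance.

    ``frames`` is a DataFrame in the dialect's column layout; ``n_raw`` is
    the number of frames as recorded, ``n_valid`` the number surviving the
    confidence filter (None before filtering).
    """

    participant_id: str
    frames: pd.DataFrame
    n_raw: int
    n_valid: int | None = None

    def __post_init__(self) -> None:
        fr = self.frames["frame"].to_numpy()
        if len(fr) > 1 and not np.all(np.diff(fr) > 0):
            raise ValueError(f"{self.participant_id}: frame indices not strictly increasing")

    @property
    def valid_fraction(self) -> float:
        if self.n_valid is None:
            raise ValueError("sequence not yet filtered")
        return self.n_valid / self.n_raw if self.n_raw else 0.0

    def __len__(self) -> int:
        return len(self.frames)

    def record(self, i: int) -> FrameRecord:
        row = self.frames.iloc[i]
        return FrameRecord(
            frame_index=int(row["frame"]),
            timestamp=float(row["timestamp"]),
            confidence=float(row["confidence"]),
            success=int(row["success"]),
            pose=tuple(float(row[c]) for c in POSE_COLUMNS),
            au_intensity={
                a: float(row[catalog.intensity_column(a)]) for a in catalog.INTENSITY_AU_IDS
            },
            au_presence={a: int(row[catalog.presence_column(a)]) for a in catalog.AU_IDS},
        )


@dataclass
class QCEntry:
    participant_id: str
    n_raw: int
    n_removed_low_confidence: int
    valid_fraction: float
    included: bool | None = None


@dataclass
class QCReport:
    """Cohort-level QC outcome: per-participant entries plus exclusion list."""

    entries: list[QCEntry]
    participant_threshold: float
    excluded: list[str] = field(default_factory=list)

    def included_ids(self) -> list[str]:
        return [e.participant_id for e in self.entries if e.included]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [e.participant_id for e in self.entries],
                "n_raw": [e.n_raw for e in self.entries],
                "n_removed_low_confidence": [e.n_removed_low_confidence for e in self.entries],
                "valid_fraction": [e.valid_fraction for e in self.entries],
                "included": [e.included for e in self.entries],
            }
        )


class MissingChannelError(ValueError):
    """An expected AU channel column is absent from the header."""

    def __init__(self, missing: list[str]):
        self.missing = missing
        super().__init__("missing AU channels: " + ", ".join(missing))


def read_openface_csv(path, participant_id: str | None = None) -> AUSequence:
    """Parse one OpenFace-dialect CSV into an :class:`AUSequence`.

    Leading/trailing whitespace in header names is stripped; percent-style
    confidence (values > 1) is normalized to a fraction; rows with
    ``face_id != 0`` are dropped with a warning; missing catalog columns
    raise :class:`MissingChannelError` naming every absent channel.
    """
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]

    missing_meta = [c for c in (*META_COLUMNS, *POSE_COLUMNS) if c not in df.columns and c != "face_id"]
    if missing_meta:
        raise ValueError(f"{path}: missing required columns: {', '.join(missing_meta)}")
    missing: list[str] = []
    for a in catalog.AU_IDS:
        if catalog.has_intensity(a) and catalog.intensity_column(a) not in df.columns:
            missing.append(f"{catalog.au_label(a)} intensity")
        if catalog.presence_column(a) not in df.columns:
            missing.append(f"{catalog.au_label(a)} presence")
    if missing:
        raise MissingChannelError(missing)

    if "face_id" in df.columns:
        other = df["face_id"] != 0
        if other.any():
            warnings.warn(
                f"{path}: dropping {int(other.sum())} rows with face_id != 0", stacklevel=2
            )
            df = df.loc[~other].reset_index(drop=True)
    else:
        df = df.copy()
        df.insert(1, "face_id", 0)

    keep = openface_columns()
    df = df[[c for c in keep if c in df.columns]]

    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: malformed row(s) at line(s) {[int(i) + 2 for i in bad[:5]]}")

    if (df["confidence"] > 1.0).any():  # percent-style dialect
        df["confidence"] = df["confidence"] / 100.0
    df["confidence"] = df["confidence"].clip(0.0, 1.0)

    pid = participant_id
    if pid is None:
        import os

        pid = os.path.splitext(os.path.basename(str(path)))[0]
    return AUSequence(participant_id=pid, frames=df, n_raw=len(df))


def filter_low_confidence(
    seq: AUSequence, frame_threshold: float = DEFAULT_FRAME_CONFIDENCE
) -> tuple[AUSequence, QCEntry]:
    """Drop frames with confidence below threshold or a failed fit.

    A valid frame has ``confidence >= frame_threshold`` *and*
    ``success == 1``.  Ordering is preserved; counts are recorded in the
    returned :class:`QCEntry`.  Filtering is idempotent.
    """
    if not 0.0 < frame_threshold <= 1.0:
        raise ValueError("frame_threshold must be in (0, 1]")
    if seq.n_raw == 0 or len(seq.frames) == 0 and seq.n_valid is None:
        raise ValueError(f"{seq.participant_id}: empty input sequence")
    ok = (seq.frames["confidence"].to_numpy() >= frame_threshold) & (
        seq.frames["success"].to_numpy() == 1
    )
    kept = seq.frames.loc[ok].reset_index(drop=True)
    n_valid = int(ok.sum())
    filtered = replace(seq, frames=kept, n_valid=n_valid)
    entry = QCEntry(
        participant_id=seq.participant_id,
        n_raw=seq.n_raw,
        # removed in THIS pass (so refiltering a filtered sequence removes 0)
        n_removed_low_confidence=len(seq.frames) - n_valid,
        valid_fraction=n_valid / seq.n_raw,
    )
    return filtered, entry


def assess_validity(
    entries: list[QCEntry], participant_threshold: float = DEFAULT_VALID_FRACTION
) -> QCReport:
    """Mark participants with ``valid_fraction >= threshold`` as included.

    The boundary is inclusive: exactly 90% valid frames is kept, matching
    a literal reading of "<90% excluded".
    """
    if not entries:
        raise ValueError("no QC entries")
    out = []
    for e in entries:
        out.append(replace_included(e, e.valid_fraction >= participant_threshold))
    excluded = sorted(e.participant_id for e in out if not e.included)
    return QCReport(entries=out, participant_threshold=participant_threshold, excluded=excluded)


def replace_included(entry: QCEntry, included: bool) -> QCEntry:
    return QCEntry(
        participant_id=entry.participant_id,
        n_raw=entry.n_raw,
        n_removed_low_confidence=entry.n_removed_low_confidence,
        valid_fraction=entry.valid_fraction,
        included=included,
    )


def pose_nuisance_correlations(
    sequences: list[AUSequence], flag_threshold: float = 0.2
) -> pd.DataFrame:
    """Pearson r between each pose axis and each AU channel on pooled frames.

    All (filtered) frames are pooled across participants.  Zero-variance
    channels yield an undefined correlation, reported as NaN with
    ``undefined=True`` rather than 0.  ``flagged`` marks |r| above the
    non-negligible bound.
    """
    pooled = pd.concat([s.frames for s in sequences], ignore_index=True)
    if len(pooled) < 3:
        raise ValueError("need at least 3 pooled valid frames")
    channels = [catalog.intensity_column(a) for a in catalog.INTENSITY_AU_IDS] + [
        catalog.presence_column(a) for a in catalog.AU_IDS
    ]
    rows = []
    for axis in POSE_COLUMNS:
        x = pooled[axis].to_numpy(float)
        xs = x.std()
        for ch in channels:
            y = pooled[ch].to_numpy(float)
            ys = y.std()
            if xs == 0.0 or ys == 0.0:
                r, undefined = np.nan, True
            else:
                r = float(np.corrcoef(x, y)[0, 1])
                undefined = False
            rows.append(
                {
                    "pose_axis": axis,
                    "channel": ch,
                    "r": r,
                    "undefined": undefined,
                    "flagged": (not undefined) and abs(r) > flag_threshold,
                }
            )
    return pd.DataFrame(rows)
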