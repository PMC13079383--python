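"""Catalog of the 18 FACS action units tracked by the pipeline.

OpenFace 2.0 reports 18 AUs: an intensity channel (``AU**_r``, continuous
0-5) and a presence channel (``AU**_c``, binary).  AU28 (lip suck) is the
one unit for which OpenFace provides no intensity regressor, so every
intensity-derived quantity is unavailable for it.
"""

from __future__ import annotations

AU_IDS: tuple[int, ...] = (1, 2, 4, 5, 6, 7, 9, 10, 12, 14, 15, 17, 20, 23, 25, 26, 28, 45)

#: AUs with an intensity (``_r``) channel; AU28 is presence-only.
INTENSITY_AU_IDS: tuple[int, ...] = tuple(a for a in AU_IDS if a != 28)

#: Per-sequence features computed for every dual-channel AU, in column order.
FEATURE_KINDS: tuple[str, ...] = (
    "presence_mean",
    "presence_sd",
    "intensity_mean",
    "intensity_sd",
    "presence_gt1",
    "variation",
)

#: The three headline metrics used for clinical validation.
METRICS: tuple[str, ...] = ("presence", "intensity", "variation")


def au_label(au: int) -> str:
    """``7 -> 'AU07'``, ``45 -> 'AU45'`` (zero-padded to two digits)."""
    if au not in AU_IDS:
        raise ValueError(f"unknown action unit: {au}")
    return f"AU{au:02d}"


def intensity_column(au: int) -> str:
    return f"{au_label(au)}_r"


def presence_column(au: int) -> str:
    return f"{au_label(au)}_c"


def has_intensity(au: int) -> bool:
    return au in INTENSITY_AU_IDS


def feature_columns() -> list[str]:
    """Deterministic classifier-matrix column order.

    Dual-channel AUs contribute all six features; AU28 contributes its
    presence-channel statistics, variation, and an ``activity`` column
    (presence-channel mean standing in for the intensity>1 proportion).
    """
    cols: list[str] = []
    for au in AU_IDS:
        lab = au_label(au)
        if has_intensity(au):
            cols.extend(f"{lab}_{kind}" for kind in FEATURE_KINDS)
        else:
            cols.extend(
                [f"{lab}_presence_mean", f"{lab}_presence_sd", f"{lab}_activity", f"{lab}_variation"]
            )
    return cols


def metric_column(au: int, metric: str) -> str:
    """Column holding the headline metric for one AU.

    presence -> intensity>1 proportion (AU28: presence-channel activity);
    intensity -> mean intensity (undefined for AU28);
    variation -> switch proportion.
    """
    lab = au_label(au)
    if metric == "presence":
        return f"{lab}_activity" if not has_intensity(au) else f"{lab}_presence_gt1"
    if metric == "intensity":
        if not has_intensity(au):
            raise ValueError(f"{lab} has no intensity channel")
        return f"{lab}_intensity_mean"
    if metric == "variation":
        return f"{lab}_variation"
    raise ValueError(f"unknown metric: {metric}")


def metric_variables() -> list[tuple[str, int, str]]:
    """The (metric, au, column) triples of the clinical-validation family.

    Three metrics for 18 AUs minus the undefined AU28 intensity: 53 tests.
    """
    out = []
    for metric in METRICS:
        for au in AU_IDS:
            if metric == "intensity" and not has_intensity(au):
                continue
            out.append((metric, au, metric_column(au, metric)))
    return out
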