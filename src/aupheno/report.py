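"""Report assembly: a human-readable document plus a machine summary.

The report mirrors the analysis surfaces a reader expects: QC counts,
cross-validated classifier metrics with the permutation p-values,
feature-selection frequencies, and the metric x AU correlation matrices
with significance markers.  The JSON twin is schema-validated (pydantic)
so downstream tooling can rely on its shape.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import catalog


class QCSummary(BaseModel):
    n_participants: int
    n_excluded: int
    excluded_ids: list[str]
    frame_confidence_threshold: float
    valid_fraction_threshold: float


class CVSection(BaseModel):
    model_family: str
    n_folds: int
    mean: dict[str, float]
    sd: dict[str, float]


class PermutationSection(BaseModel):
    n_permutations: int
    observed: dict[str, float]
    p_values: dict[str, float]


class SelectionEntry(BaseModel):
    feature: str
    count: int
    always_selected: bool


class CorrelationSection(BaseModel):
    outcome: str
    family_size: int
    bonferroni_alpha: float
    n_fdr_significant: int
    n_bonferroni_significant: int


class ReportSummary(BaseModel):
    """Machine-readable pipeline summary; round-trips through validation."""

    qc: QCSummary | None = None
    cv: CVSection | None = None
    permutation: PermutationSection | None = None
    selection: list[SelectionEntry] | None = None
    correlations: list[CorrelationSection] | None = None
    missing_artifacts: list[str] = []


def validate_summary(payload: dict) -> ReportSummary:
    """Schema check; raises pydantic.ValidationError on malformed input."""
    return ReportSummary.model_validate(payload)


def _corr_markers(results: pd.DataFrame) -> pd.DataFrame:
    """Wide AU x metric table of 'r{**}' strings, starred by significance."""
    def fmt(row):
        star = "**" if row["bonferroni_significant"] else ("*" if row["q"] < 0.05 else "")
        return f"{row['r']:+.3f}{star}"

    tab = results.assign(cell=results.apply(fmt, axis=1)).pivot(
        index="au", columns="metric", values="cell"
    )
    order = [catalog.au_label(a) for a in catalog.AU_IDS]
    return tab.reindex(order)[[m for m in catalog.METRICS if m in tab.columns]]


def plot_correlation_heatmap(results: pd.DataFrame, path, title: str = "") -> None:
    """Metric x AU heatmap; r annotated only where q < 0.05."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide_r = results.pivot(index="metric", columns="au", values="r")
    wide_q = results.pivot(index="metric", columns="au", values="q")
    order = [catalog.au_label(a) for a in catalog.AU_IDS]
    cols = [a for a in order if a in wide_r.columns]
    wide_r, wide_q = wide_r[cols], wide_q[cols]
    fig, ax = plt.subplots(figsize=(12, 2.6))
    im = ax.imshow(wide_r.to_numpy(), cmap="RdBu_r", vmin=-0.6, vmax=0.6, aspect="auto")
    ax.set_xticks(range(len(cols)), cols, rotation=90)
    ax.set_yticks(range(len(wide_r)), wide_r.index)
    for i in range(wide_r.shape[0]):
        for j in range(wide_r.shape[1]):
            r, q = wide_r.iat[i, j], wide_q.iat[i, j]
            if np.isfinite(q) and q < 0.05:
                ax.text(j, i, f"{r:.2f}", ha="center", va="center", fontsize=6)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(artifacts: dict, out_dir) -> tuple[str, dict]:
    """Assemble report.md and the validated report.json payload.

    ``artifacts`` maps section names to in-memory objects (``qc``,
    ``cv_results``, ``validation``); missing ones are listed and the
    report is still produced with gaps marked.
    """
    missing: list[str] = []
    lines = ["# Facial action-unit expressivity report", ""]
    payload: dict = {"missing_artifacts": missing}

    qc = artifacts.get("qc")
    lines.append("## Quality control")
    if qc is None:
        missing.append("qc")
        lines.append("_missing_")
    else:
        rep, fthr = qc["report"], qc["frame_threshold"]
        lines += [
            f"- participants: {len(rep.entries)}",
            f"- excluded (<{rep.participant_threshold:.0%} valid frames): "
            f"{len(rep.excluded)} {rep.excluded}",
            f"- frame confidence threshold: {fthr:.2f}",
        ]
        payload["qc"] = {
            "n_participants": len(rep.entries),
            "n_excluded": len(rep.excluded),
            "excluded_ids": rep.excluded,
            "frame_confidence_threshold": fthr,
            "valid_fraction_threshold": rep.participant_threshold,
        }

    res = artifacts.get("cv_results")
    lines += ["", "## Classifier performance (repeated nested CV)"]
    if res is None:
        missing.append("cv_results")
        lines.append("_missing_")
    else:
        mean, sd = res.mean_metrics, res.sd_metrics
        lines.append("| metric | mean | SD |")
        lines.append("|---|---|---|")
        for m in mean:
            lines.append(f"| {m} | {mean[m]:.3f} | {sd[m]:.3f} |")
        payload["cv"] = {
            "model_family": res.config.model_family,
            "n_folds": len(res.fold_results),
            "mean": mean,
            "sd": sd,
        }

    lines += ["", "## Permutation test"]
    if res is None or res.permutation is None:
        missing.append("permutation")
        lines.append("_missing_")
    else:
        perm = res.permutation
        for k, p in perm.p_values.items():
            lines.append(f"- {k}: observed {perm.observed[k]:.3f}, p = {p:.4f}")
        payload["permutation"] = {
            "n_permutations": perm.n_permutations,
            "observed": perm.observed,
            "p_values": perm.p_values,
        }

    lines += ["", "## Feature-selection frequency"]
    if res is None:
        missing.append("selection")
        lines.append("_missing_")
    else:
        freq = res.selection_frequencies()
        top = freq.head(10)
        lines.append("| feature | count | always selected |")
        lines.append("|---|---|---|")
        for name, row in top.iterrows():
            lines.append(f"| {name} | {int(row['count'])} | {bool(row['always_selected'])} |")
        payload["selection"] = [
            {"feature": name, "count": int(row["count"]), "always_selected": bool(row["always_selected"])}
            for name, row in freq.iterrows()
        ]

    val = artifacts.get("validation")
    lines += ["", "## Clinical validation"]
    if val is None:
        missing.append("validation")
        lines.append("_missing_")
    else:
        sections = []
        fams = [("primary: " + "hisoc_item1", val.primary)] + [
            (f"exploratory: {k}", v) for k, v in val.exploratory.items()
        ]
        for title, fam in fams:
            sections.append(
                {
                    "outcome": title.split(": ")[1],
                    "family_size": int(fam.attrs["family_size"]),
                    "bonferroni_alpha": float(fam.attrs["bonferroni_alpha"]),
                    "n_fdr_significant": int((fam["q"] < 0.05).sum()),
                    "n_bonferroni_significant": int(fam["bonferroni_significant"].sum()),
                }
            )
        payload["correlations"] = sections
        lines.append(
            f"Primary family: {val.primary.attrs['family_size']} tests, "
            f"Bonferroni alpha {val.primary.attrs['bonferroni_alpha']:.6f} "
            "(** Bonferroni, * FDR q<0.05)"
        )
        lines.append("")
        tab = _corr_markers(val.primary)
        lines.append("| AU | " + " | ".join(tab.columns) + " |")
        lines.append("|" + "---|" * (len(tab.columns) + 1))
        for au, row in tab.iterrows():
            lines.append(f"| {au} | " + " | ".join(row.astype(str)) + " |")

    summary = validate_summary(payload)
    doc = "\n".join(lines) + "\n"
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "report.md"), "w") as fh:
        fh.write(doc)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(summary.model_dump(), fh, indent=2, sort_keys=True)
    return doc, summary.model_dump()
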