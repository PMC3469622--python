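"""Heatmap rendering and table export for trajectory matrices.

Color semantics follow the field's two-channel convention: in the label-free
heatmap black is the peptide's time-course average and yellow/blue are above/
below it; in the SILAC heatmap black is no change and green/red are elevated/
reduced in the deficient channel.  Values beyond the display cap (100-fold
label-free, 50-fold SILAC) render as the cap color.  Blank cells (no defined
SIC peak in any replicate) are drawn as empty (white); white dots mark cells
with q < 0.02; a CV color bar (black = 0% to orange) is appended.

TSV exports are the canonical, bit-exact record; figures are views and never
alter the exported values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from phosquant.stats import RatioMatrix

CV_SATURATION = 100.0  # CV (%) that renders fully orange


@dataclass(frozen=True)
class HeatmapSpec:
    kind: str                  # "label-free" | "silac"
    cap_fold: float            # 100 label-free, 50 SILAC
    q_threshold: float = 0.02

    def __post_init__(self) -> None:
        if self.cap_fold <= 1:
            raise ValueError("cap fold must be > 1")
        if self.kind not in ("label-free", "silac"):
            raise ValueError(f"unknown heatmap kind {self.kind!r}")


LABELFREE_SPEC = HeatmapSpec("label-free", 100.0)
SILAC_SPEC = HeatmapSpec("silac", 50.0)


def value_to_rgb(value: float, spec: HeatmapSpec) -> tuple[float, float, float]:
    """Symmetric diverging color of one capped log10 value; 0 maps to black.

    Label-free: positive -> yellow, negative -> blue.  SILAC: positive
    (elevated in deficient) -> green, negative -> red.  The intensity is
    |value| / log10(cap), so v and -v are equally bright on opposite hues and
    anything at or beyond the cap saturates.
    """
    if not np.isfinite(value):
        return (1.0, 1.0, 1.0)  # blank
    lim = np.log10(spec.cap_fold)
    frac = float(min(abs(value) / lim, 1.0))
    if spec.kind == "label-free":
        return (frac, frac, 0.0) if value > 0 else (0.0, 0.0, frac)
    return (0.0, frac, 0.0) if value > 0 else (frac, 0.0, 0.0)


def cv_to_rgb(cv: float) -> tuple[float, float, float]:
    """CV bar color: black at 0%, increasingly orange with larger CV."""
    if not np.isfinite(cv):
        return (1.0, 1.0, 1.0)
    frac = float(min(max(cv, 0.0) / CV_SATURATION, 1.0))
    return (frac, 0.65 * frac, 0.0)


def matrix_to_rgb(matrix: RatioMatrix, spec: HeatmapSpec) -> np.ndarray:
    """(rows, cols, 3) RGB array of the capped display values."""
    capped = matrix.capped.to_numpy(dtype=float)
    blank = matrix.blank.to_numpy(dtype=bool)
    rgb = np.empty(capped.shape + (3,))
    for i in range(capped.shape[0]):
        for j in range(capped.shape[1]):
            v = np.nan if blank[i, j] else capped[i, j]
            rgb[i, j] = value_to_rgb(v, spec)
    return rgb


def build_heatmap(
    matrix: RatioMatrix,
    spec: HeatmapSpec,
    out_path: str | Path | None = None,
    row_annotations: dict[str, str] | None = None,
) -> plt.Figure:
    """Render the trajectory heatmap with significance dots and CV bar."""
    if matrix.kind != spec.kind:
        raise ValueError(
            f"matrix kind {matrix.kind!r} does not match spec kind {spec.kind!r}"
        )
    if len(matrix.values) < 1:
        raise ValueError("matrix must have at least one row")
    rgb = matrix_to_rgb(matrix, spec)
    mean_cv = matrix.cv.mean(axis=0, skipna=True).to_numpy(dtype=float)
    cv_row = np.array([[cv_to_rgb(c) for c in mean_cv]])

    n_rows, n_cols = rgb.shape[:2]
    fig, (ax, ax_cv) = plt.subplots(
        2, 1, figsize=(max(4, 0.5 * n_cols), max(3, 0.22 * n_rows + 0.6)),
        gridspec_kw={"height_ratios": [n_rows, 1]},
    )
    ax.imshow(rgb, aspect="auto", interpolation="nearest")
    sig = matrix.significant.to_numpy(dtype=bool)
    ys, xs = np.nonzero(sig)
    ax.scatter(xs, ys, s=12, c="white", edgecolors="none", zorder=3)
    labels = [
        f"{pid} {row_annotations.get(pid, '')}".rstrip() if row_annotations else str(pid)
        for pid in matrix.values.index
    ]
    ax.set_yticks(range(n_rows), labels, fontsize=6)
    ax.set_xticks(range(n_cols), [str(c) for c in matrix.values.columns])
    ax.set_title(f"{matrix.kind} heatmap (cap {spec.cap_fold:g}-fold, dot: q < {spec.q_threshold:g})")
    ax_cv.imshow(cv_row, aspect="auto", interpolation="nearest")
    ax_cv.set_yticks([0], ["CV"])
    ax_cv.set_xticks([])
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig


def export_tables(
    out_dir: str | Path,
    stage_tables: dict[str, pd.DataFrame],
    manifest_extra: dict | None = None,
) -> Path:
    """Write all stage tables as TSV with a run manifest; returns manifest path.

    Column order is as given; floats are written with repr precision so two
    runs with the same seed/config produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = {}
    for name, df in stage_tables.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        counts[name] = int(len(df))
    manifest = {
        "tables": counts,
        **(manifest_extra or {}),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path


def matrix_tables(matrix: RatioMatrix, prefix: str) -> dict[str, pd.DataFrame]:
    """Flatten a RatioMatrix into exportable long-format tables."""
    long = []
    for pep in matrix.values.index:
        for tp in matrix.values.columns:
            long.append(dict(
                peptide_id=pep, timepoint=tp,
                value=matrix.values.at[pep, tp],
                capped=matrix.capped.at[pep, tp],
                cv_percent=matrix.cv.at[pep, tp],
                p=matrix.p.at[pep, tp],
                q=matrix.q.at[pep, tp],
                significant=bool(matrix.significant.at[pep, tp]),
                blank=bool(matrix.blank.at[pep, tp]),
            ))
    return {f"{prefix}_heatmap": pd.DataFrame(long)}
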