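"""Fold-change matrices, per-timepoint tests and Storey pFDR control.

Label-free trajectories are log10 ratios of spike-normalized peak area to the
geometric mean across observed timepoints (so the centered values sum to 0);
SILAC trajectories are log10 heavy/light ratios.  Display values are capped
at 100-fold (label-free) or 50-fold (SILAC).  Per timepoint, the label-free
track is tested against the minimal-mean timepoint with an unpaired
two-sided Student t-test and the SILAC track with a paired two-sided t-test
across replicates; both tests run on log10-transformed areas, which the
multiplicative replicate noise makes approximately normal.  Multiple testing
is controlled per matrix with a from-scratch implementation of Storey's
positive false discovery rate: q-values with the smoother pi0 estimator, and
a strict q < 0.02 significance flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

Q_SIGNIFICANCE = 0.02
REPRO_RANGE = 0.6  # log2 window of the ratio-of-ratios reproducibility check


def labelfree_centered_logfc(areas: np.ndarray) -> np.ndarray:
    """log10(area / geometric mean over defined timepoints); NaN propagates.

    The returned values sum to zero over the defined timepoints (before any
    display capping).
    """
    a = np.asarray(areas, dtype=float)
    if np.all(~np.isfinite(a)):
        return np.full_like(a, np.nan)
    if np.nanmin(a[np.isfinite(a)]) <= 0:
        raise ValueError("areas must be > 0 where defined")
    logs = np.full_like(a, np.nan)
    mask = np.isfinite(a) & (a > 0)
    logs[mask] = np.log10(a[mask])
    return logs - np.nanmean(logs)


def cap_display(log_values: np.ndarray | float, cap_fold: float) -> np.ndarray | float:
    """Clip log10 values to +/- log10(cap_fold); idempotent."""
    if cap_fold <= 1:
        raise ValueError(f"cap fold must be > 1, got {cap_fold}")
    lim = math.log10(cap_fold)
    return np.clip(log_values, -lim, lim)


def cv_percent(values: np.ndarray) -> float:
    """Coefficient of variation, 100 * sample SD / mean, over defined values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        return float("nan")
    mean = v.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / mean)


def _student_t_p(x: np.ndarray, y: np.ndarray, welch: bool) -> tuple[float | None, bool]:
    """Two-sided two-sample t; degenerate (None, True) when variance vanishes."""
    if len(x) < 2 or len(y) < 2:
        return None, False
    if np.allclose(x.var(ddof=1), 0) and np.allclose(y.var(ddof=1), 0):
        if math.isclose(float(x.mean()), float(y.mean())):
            return 1.0, False
        return None, True
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return float(res.pvalue), False


def unpaired_t_vs_min(
    values: np.ndarray, welch: bool = False
) -> tuple[np.ndarray, int, np.ndarray]:
    """Per-timepoint unpaired two-sided t against the minimal-mean timepoint.

    ``values`` is (timepoints x replicates) with NaN for missing replicates;
    the reference is the timepoint with the lowest mean (ties: earliest) and
    gets p = 1.  Returns (p-values, reference index, degenerate flags); p is
    NaN where replicates are insufficient or the variance is degenerate.
    """
    v = np.asarray(values, dtype=float)
    counts = np.sum(np.isfinite(v), axis=1)
    sums = np.nansum(np.where(np.isfinite(v), v, 0.0), axis=1)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if np.all(~np.isfinite(means)):
        return np.full(v.shape[0], np.nan), -1, np.zeros(v.shape[0], dtype=bool)
    ref = int(np.nanargmin(means))  # nanargmin takes the first minimum: earliest wins
    ref_vals = v[ref][np.isfinite(v[ref])]
    p = np.full(v.shape[0], np.nan)
    degenerate = np.zeros(v.shape[0], dtype=bool)
    for tp in range(v.shape[0]):
        if tp == ref:
            p[tp] = 1.0 if len(ref_vals) else np.nan
            continue
        x = v[tp][np.isfinite(v[tp])]
        pv, degen = _student_t_p(x, ref_vals, welch)
        degenerate[tp] = degen
        if pv is not None:
            p[tp] = pv
    return p, ref, degenerate


def paired_t_silac(
    heavy: np.ndarray, light: np.ndarray
) -> tuple[float | None, bool]:
    """Paired two-sided t on log10(heavy) - log10(light) across replicates.

    Pairs with a missing side are dropped.  All-zero log differences give
    p = 1 (no change); a constant nonzero difference with zero spread is
    degenerate and returns (None, True) rather than a spurious p = 0.
    """
    h = np.asarray(heavy, dtype=float)
    l = np.asarray(light, dtype=float)
    ok = np.isfinite(h) & np.isfinite(l) & (h > 0) & (l > 0)
    if ok.sum() < 2:
        return None, False
    d = np.log10(h[ok]) - np.log10(l[ok])
    if np.allclose(d, 0.0):
        return 1.0, False
    if np.allclose(d.std(ddof=1), 0.0):
        return None, True
    res = sps.ttest_rel(np.log10(h[ok]), np.log10(l[ok]))
    return float(res.pvalue), False


DEFAULT_LAMBDAS = np.round(np.arange(0.05, 0.96, 0.05), 2)


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray = DEFAULT_LAMBDAS) -> float:
    """Smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) on the lambda grid, then
    a cubic polynomial smoother evaluated at the largest lambda.  Falls back
    to 1 for small samples (< 100 p-values) or out-of-range estimates.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m < 100:
        return 1.0
    pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, 3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    if not 0.0 < pi0 <= 1.0:
        return 1.0
    return pi0


def storey_qvalues(
    p: np.ndarray,
    pi0: float | None = None,
    lambdas: np.ndarray = DEFAULT_LAMBDAS,
) -> np.ndarray:
    """q-values: the minimum positive FDR at which each test is significant.

    q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j), clipped to 1;
    monotone non-decreasing in p by construction.  Pass ``pi0`` explicitly to
    bypass the smoother estimator (pi0 = 1 gives Benjamini-Hochberg-style
    step-up values).
    """
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p, lambdas)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def flag_significant(q: np.ndarray, threshold: float = Q_SIGNIFICANCE) -> np.ndarray:
    """Strict q < threshold; NaN (blank) q-values are never flagged."""
    q = np.asarray(q, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.isfinite(q) & (q < threshold)


def reproducibility_stats(ratios: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Replicate agreement of SILAC ratios via pairwise log2 ratio-of-ratios.

    ``ratios`` holds one row per peptide with three replicate ratio columns
    (R1, R2, R3).  For each pair (R2/R1, R3/R1, R3/R2) the log2 ratios are
    summarized by mean, SD and the fraction falling within [-0.6, +0.6]
    (about 1.5-fold agreement).
    """
    arr = np.asarray(ratios, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected an (n_peptides, 3) ratio table")
    ok = np.all(np.isfinite(arr) & (arr > 0), axis=1)
    arr = arr[ok]
    if len(arr) == 0:
        raise ValueError("no peptide with all three replicate ratios defined")
    rows = []
    for name, (i, j) in (("R2/R1", (1, 0)), ("R3/R1", (2, 0)), ("R3/R2", (2, 1))):
        lr = np.log2(arr[:, i] / arr[:, j])
        rows.append(dict(
            pair=name,
            mean=float(lr.mean()),
            sd=float(lr.std(ddof=1)) if len(lr) > 1 else 0.0,
            frac_in_range=float(np.mean(np.abs(lr) <= REPRO_RANGE)),
            n=int(len(lr)),
        ))
    return pd.DataFrame(rows).set_index("pair")


@dataclass
class RatioMatrix:
    """Peptides x timepoints trajectory matrix with per-cell statistics.

    ``values`` are uncapped log10 magnitudes, ``capped`` the display-clipped
    copy; ``cv`` is in percent; ``p``/``q`` follow the matrix's test family
    and ``significant`` flags q < 0.02; ``blank`` marks cells without a
    defined SIC peak in any replicate.
    """

    kind: str                 # "label-free" | "silac"
    cap_fold: float
    values: pd.DataFrame
    capped: pd.DataFrame
    cv: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    significant: pd.DataFrame
    blank: pd.DataFrame


def _family_qvalues(p_df: pd.DataFrame) -> pd.DataFrame:
    """q-values over the whole matrix's defined p-values (one family)."""
    flat = p_df.to_numpy(dtype=float).ravel()
    mask = np.isfinite(flat)
    q = np.full_like(flat, np.nan)
    if mask.sum() > 0:
        q[mask] = storey_qvalues(flat[mask])
    return pd.DataFrame(
        q.reshape(p_df.shape), index=p_df.index, columns=p_df.columns
    )


def build_labelfree_matrix(
    quant: pd.DataFrame,
    n_timepoints: int,
    cap_fold: float = 100.0,
    welch: bool = False,
    q_threshold: float = Q_SIGNIFICANCE,
) -> RatioMatrix:
    """Label-free trajectory matrix from spike-normalized light-channel areas.

    ``quant`` needs columns peptide_id, channel, timepoint, replicate,
    norm_area (NaN when the floor or the spike was undefined).  Cell value:
    mean over replicates of log10 normalized area, centered on the peptide's
    mean over defined timepoints.
    """
    light = quant[quant["channel"] == "light"]
    peptides = sorted(light["peptide_id"].unique())
    cols = list(range(n_timepoints))
    shape = (len(peptides), n_timepoints)
    vals = np.full(shape, np.nan)
    cv = np.full(shape, np.nan)
    pmat = np.full(shape, np.nan)
    blank = np.ones(shape, dtype=bool)
    for pi, pep in enumerate(peptides):
        sub = light[light["peptide_id"] == pep]
        area = np.full((n_timepoints, int(quant["replicate"].max()) + 1), np.nan)
        for _, r in sub.iterrows():
            if np.isfinite(r["norm_area"]):
                area[int(r["timepoint"]), int(r["replicate"])] = r["norm_area"]
        with np.errstate(divide="ignore", invalid="ignore"):
            log_area = np.where(area > 0, np.log10(np.where(area > 0, area, 1.0)), np.nan)
        cell_log = np.array([
            np.nanmean(log_area[tp]) if np.any(np.isfinite(log_area[tp])) else np.nan
            for tp in range(n_timepoints)
        ])
        if np.any(np.isfinite(cell_log)):
            vals[pi] = cell_log - np.nanmean(cell_log)
        blank[pi] = ~np.isfinite(cell_log)
        for tp in range(n_timepoints):
            cv[pi, tp] = cv_percent(area[tp])
        pvec, _ref, _deg = unpaired_t_vs_min(log_area, welch=welch)
        pmat[pi] = np.where(blank[pi], np.nan, pvec)
    idx = pd.Index(peptides, name="peptide_id")
    as_df = lambda a: pd.DataFrame(a, index=idx, columns=cols)
    p_df = as_df(pmat)
    q_df = _family_qvalues(p_df)
    sig = pd.DataFrame(
        flag_significant(q_df.to_numpy(), q_threshold), index=idx, columns=cols
    )
    return RatioMatrix(
        "label-free", cap_fold, as_df(vals),
        as_df(cap_display(vals, cap_fold)), as_df(cv), p_df, q_df, sig,
        as_df(blank).astype(bool),
    )


def build_silac_matrix(
    quant: pd.DataFrame,
    n_timepoints: int,
    cap_fold: float = 50.0,
    q_threshold: float = Q_SIGNIFICANCE,
) -> RatioMatrix:
    """SILAC heavy/light trajectory matrix on raw (floor-cleared) areas.

    Per replicate the ratio is heavy/light raw area; the cell value is the
    mean of log10 ratios over defined replicates, the p-value a paired t-test
    across replicates.
    """
    peptides = sorted(quant["peptide_id"].unique())
    cols = list(range(n_timepoints))
    n_rep = int(quant["replicate"].max()) + 1
    shape = (len(peptides), n_timepoints)
    vals = np.full(shape, np.nan)
    cv = np.full(shape, np.nan)
    pmat = np.full(shape, np.nan)
    blank = np.ones(shape, dtype=bool)
    pivot = quant.set_index(["peptide_id", "channel", "timepoint", "replicate"])["raw_area"]
    for pi, pep in enumerate(peptides):
        for tp in range(n_timepoints):
            h = np.full(n_rep, np.nan)
            l = np.full(n_rep, np.nan)
            for rep in range(n_rep):
                h[rep] = pivot.get((pep, "heavy", tp, rep), np.nan)
                l[rep] = pivot.get((pep, "light", tp, rep), np.nan)
            ok = np.isfinite(h) & np.isfinite(l) & (l > 0)
            if not np.any(ok):
                continue
            ratios = h[ok] / l[ok]
            blank[pi, tp] = False
            vals[pi, tp] = float(np.mean(np.log10(ratios)))
            cv[pi, tp] = cv_percent(ratios)
            pv, _deg = paired_t_silac(h, l)
            if pv is not None:
                pmat[pi, tp] = pv
    idx = pd.Index(peptides, name="peptide_id")
    as_df = lambda a: pd.DataFrame(a, index=idx, columns=cols)
    p_df = as_df(pmat)
    q_df = _family_qvalues(p_df)
    sig = pd.DataFrame(
        flag_significant(q_df.to_numpy(), q_threshold), index=idx, columns=cols
    )
    return RatioMatrix(
        "silac", cap_fold, as_df(vals), as_df(cap_display(vals, cap_fold)),
        as_df(cv), p_df, q_df, sig, as_df(blank).astype(bool),
    )
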