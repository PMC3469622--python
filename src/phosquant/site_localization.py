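"""Binomial phosphosite localization from site-determining fragment ions.

Given an MS/MS peak list and candidate phosphoacceptor positions, each
candidate isoform is scored by how many of its site-determining singly
charged b/y ions (those whose m/z differ between the top two isoforms) are
matched, within a fragment tolerance, among the top-k most intense peaks per
100-m/z window.  Matches are scored against a binomial null — a random peak
matches a given ion with probability p = k * (2 * tolerance) / 100 — and the
localization score is the difference of the two best candidates'
-10*log10(binomial tail) values, maximized over peak depths k = 1..10.

This is a simplified variant of the Ascore family of localizers: it uses
b/y ions only, a fixed depth range, and no neutral-loss ions; its numeric
scores are not comparable with any vendor implementation, only the top-site
prediction and relative confidence are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from phosquant.mass_chem import (
    PHOSPHO_DELTA,
    PROTON,
    STD_AA_MASS,
    WATER,
    Mod,
    ModifiedPeptide,
)

FRAGMENT_TOL_DA = 0.5
MAX_DEPTH = 10
_WINDOW = 100.0


def by_ion_mz(pep: ModifiedPeptide, series: str, length: int) -> float:
    """m/z of a singly charged b- or y-ion of the given fragment length."""
    n = len(pep.sequence)
    if not 1 <= length < n:
        raise ValueError(f"fragment length {length} out of range for {pep.sequence}")
    if series == "b":
        residues = range(0, length)
        base = 0.0
    elif series == "y":
        residues = range(n - length, n)
        base = WATER
    else:
        raise ValueError(f"unknown ion series {series!r}")
    mass = base + sum(STD_AA_MASS[pep.sequence[i]] for i in residues)
    mass += sum(m.delta for m in pep.mods if m.position in residues)
    return mass + PROTON


def _isoform(pep: ModifiedPeptide, position: int) -> ModifiedPeptide:
    """Move the (single) phospho group to ``position``, keeping other mods."""
    kept = tuple(m for m in pep.mods if m.kind != "phospho")
    return replace(pep, mods=kept + (Mod(position, PHOSPHO_DELTA, "phospho"),))


def _all_by_ions(pep: ModifiedPeptide) -> np.ndarray:
    n = len(pep.sequence)
    return np.array(
        [by_ion_mz(pep, s, i) for s in ("b", "y") for i in range(1, n)]
    )


def _top_k_peaks(mz: np.ndarray, intensity: np.ndarray, k: int) -> np.ndarray:
    """Peaks that are among the k most intense within their 100-m/z window."""
    keep = []
    lo = np.floor(mz.min() / _WINDOW) * _WINDOW if len(mz) else 0.0
    hi = mz.max() if len(mz) else 0.0
    edges = np.arange(lo, hi + _WINDOW, _WINDOW)
    for a, b in zip(edges[:-1], edges[1:]):
        in_win = np.flatnonzero((mz >= a) & (mz < b))
        if len(in_win) == 0:
            continue
        # tie-break equal intensities by m/z so the selection is independent
        # of peak-list order
        order = np.lexsort((mz[in_win], -intensity[in_win]))
        keep.extend(in_win[order[:k]].tolist())
    return mz[np.sort(np.asarray(keep, dtype=int))] if keep else np.empty(0)


def _count_matches(ions: np.ndarray, peaks: np.ndarray, tol: float) -> int:
    if len(peaks) == 0 or len(ions) == 0:
        return 0
    diffs = np.abs(ions[:, None] - peaks[None, :])
    return int(np.sum(diffs.min(axis=1) <= tol))


def binomial_tail_score(k_matched: int, n_trials: int, p: float) -> float:
    """-10*log10 P(X >= k | n, p) for a Binomial(n, p) null; 0 when k = 0."""
    if k_matched <= 0:
        return 0.0
    tail = float(sps.binom.sf(k_matched - 1, n_trials, p))
    tail = max(tail, 1e-300)
    return -10.0 * np.log10(tail)


@dataclass(frozen=True)
class SiteLocalizationResult:
    best_position: int          # 0-based residue index
    score: float                # difference of top-two binomial tail scores
    ambiguous: bool
    match_counts: dict[int, int]  # candidate position -> matched ions at best depth
    depth: int                  # peak depth at which the score was taken


def localize(
    peaks: tuple[np.ndarray, np.ndarray] | list[tuple[float, float]],
    pep: ModifiedPeptide,
    candidate_positions: list[int],
    tol: float = FRAGMENT_TOL_DA,
) -> SiteLocalizationResult:
    """Pick the best-supported phosphosite among candidate positions.

    ``peaks`` is an (m/z array, intensity array) pair or a list of (m/z,
    intensity) tuples.  With a single candidate the score is that isoform's
    own binomial tail score over all its b/y ions (forced localization).
    Ties in matched-ion counts give score 0, the lowest-index position, and
    the ambiguous flag.
    """
    if not candidate_positions:
        raise ValueError("at least one candidate position required")
    if isinstance(peaks, (list, tuple)) and len(peaks) == 2 and np.ndim(peaks[0]) == 1:
        mz = np.asarray(peaks[0], dtype=float)
        intensity = np.asarray(peaks[1], dtype=float)
    else:
        arr = np.asarray(peaks, dtype=float)
        mz, intensity = arr[:, 0], arr[:, 1]
    if len(mz) == 0:
        raise ValueError("peak list is empty")
    for pos in candidate_positions:
        if pep.sequence[pos] not in "STY":
            raise ValueError(f"candidate position {pos} is not S/T/Y")

    candidates = sorted(candidate_positions)
    isoforms = {pos: _isoform(pep, pos) for pos in candidates}

    if len(candidates) == 1:
        pos = candidates[0]
        ions = _all_by_ions(isoforms[pos])
        best = (0.0, 1, 0)
        for depth in range(1, MAX_DEPTH + 1):
            sel = _top_k_peaks(mz, intensity, depth)
            k = _count_matches(ions, sel, tol)
            p = min(depth * 2.0 * tol / _WINDOW, 1.0)
            s = binomial_tail_score(k, len(ions), p)
            if s > best[0]:
                best = (s, depth, k)
        return SiteLocalizationResult(pos, best[0], False, {pos: best[2]}, best[1])

    best_overall: tuple[float, int, dict[int, int], list[int]] | None = None
    for depth in range(1, MAX_DEPTH + 1):
        sel = _top_k_peaks(mz, intensity, depth)
        p = min(depth * 2.0 * tol / _WINDOW, 1.0)
        # rank candidates by matched site-determining ions against the
        # current leader; use per-pair site-determining ions for the top two
        counts: dict[int, int] = {}
        scores: dict[int, float] = {}
        all_ions = {pos: _all_by_ions(isoforms[pos]) for pos in candidates}
        for pos in candidates:
            k = _count_matches(all_ions[pos], sel, tol)
            counts[pos] = k
            scores[pos] = binomial_tail_score(k, len(all_ions[pos]), p)
        order = sorted(candidates, key=lambda q: (-scores[q], q))
        top, second = order[0], order[1]
        # site-determining ions: b/y ions differing between the two isoforms
        ions_top = all_ions[top]
        ions_second = all_ions[second]
        sd_top = np.array([m for m in ions_top if np.abs(ions_second - m).min() > 1e-6])
        sd_second = np.array([m for m in ions_second if np.abs(ions_top - m).min() > 1e-6])
        k_top = _count_matches(sd_top, sel, tol)
        k_second = _count_matches(sd_second, sel, tol)
        n_sd = max(len(sd_top), len(sd_second), 1)
        s_top = binomial_tail_score(k_top, n_sd, p)
        s_second = binomial_tail_score(k_second, n_sd, p)
        diff = s_top - s_second
        counts_sd = dict(counts)
        counts_sd[top] = k_top
        counts_sd[second] = k_second
        if best_overall is None or diff > best_overall[0]:
            best_overall = (diff, depth, counts_sd, [top, second, k_top, k_second])

    assert best_overall is not None
    diff, depth, counts_sd, (top, second, k_top, k_second) = (
        best_overall[0], best_overall[1], best_overall[2], best_overall[3],
    )
    if k_top == k_second:
        return SiteLocalizationResult(
            min(top, second), 0.0, True, counts_sd, depth
        )
    return SiteLocalizationResult(top, max(diff, 0.0), False, counts_sd, depth)
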