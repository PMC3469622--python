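"""PSM filtering, target-decoy FDR control and non-redundant assembly.

Score gates follow the original search criteria: Xcorr-like engine A needs
strictly more than 1.5 / 2.0 / 2.5 at charge +1 / +2 / +3, Mowse-like engine
B strictly more than 10, and the absolute precursor mass error must be under
20 ppm.  FDR is estimated with the concatenated target-decoy convention
(50% forward, 50% reversed database): FDR = 2*D / (T + D), clamped to [0, 1].
The operating point targets 0.5% FDR on the assembled list, and peptides must
be observed in at least 4 of the 8 timepoints to be quantified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from phosquant.mass_chem import mass_error_ppm

PSM_COLUMNS = [
    "psm_id", "sequence", "mods", "charge", "engine", "score",
    "obs_mass", "theo_mass", "decoy", "timepoint", "replicate", "channel",
]


@dataclass(frozen=True)
class FilterPolicy:
    """Score, mass-accuracy, FDR and observation-count acceptance rules."""

    xcorr_min: Mapping[int, float] = field(
        default_factory=lambda: {1: 1.5, 2: 2.0, 3: 2.5}
    )
    mowse_min: float = 10.0
    max_abs_ppm: float = 20.0
    fdr_target: float = 0.005
    min_timepoints_observed: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.fdr_target < 1:
            raise ValueError(f"fdr_target must be in (0,1), got {self.fdr_target}")
        if self.max_abs_ppm <= 0 or self.mowse_min <= 0:
            raise ValueError("thresholds must be positive")


def passes_score_filters(psm: Mapping, policy: FilterPolicy = FilterPolicy()) -> bool:
    """Engine-appropriate score strictly above threshold AND |ppm| < 20.

    ``psm`` is any mapping (dict, pandas row) with charge, engine, score,
    theo_mass, obs_mass.  Charges outside +1..+3 are rejected, mirroring the
    acquisition's charge-state screening.
    """
    charge = int(psm["charge"])
    if charge not in (1, 2, 3):
        return False
    ppm = mass_error_ppm(float(psm["theo_mass"]), float(psm["obs_mass"]))
    if abs(ppm) >= policy.max_abs_ppm:
        return False
    engine = psm["engine"]
    score = float(psm["score"])
    if engine == "A":
        return score > policy.xcorr_min[charge]
    if engine == "B":
        return score > policy.mowse_min
    raise ValueError(f"unknown engine {engine!r}")


def estimate_decoy_fdr(n_target_accepted: int, n_decoy_accepted: int) -> float:
    """Concatenated target-decoy FDR estimate 2*D/(T+D), clamped to [0, 1]."""
    if n_target_accepted < 0 or n_decoy_accepted < 0:
        raise ValueError("counts must be >= 0")
    if n_target_accepted + n_decoy_accepted == 0:
        return 0.0
    fdr = 2.0 * n_decoy_accepted / (n_target_accepted + n_decoy_accepted)
    return min(fdr, 1.0)


def threshold_for_fdr(
    psms: pd.DataFrame, policy: FilterPolicy = FilterPolicy()
) -> dict[str, float]:
    """Per-engine score cutoff reaching the FDR target.

    For each engine the unique observed scores are scanned from high to low;
    the returned threshold is the smallest cutoff whose acceptance set
    (score >= cutoff, ties accepted) still has an estimated FDR at or below
    ``policy.fdr_target``.  ``+inf`` (empty acceptance) when no cutoff
    achieves the target.  Lowering the target can only raise the threshold.
    """
    out: dict[str, float] = {}
    for engine, grp in psms.groupby("engine"):
        scores = grp["score"].to_numpy(dtype=float)
        decoy = grp["decoy"].to_numpy(dtype=bool)
        best = math.inf
        # the estimate is not monotone in the cutoff, so scan every unique
        # score rather than stopping at the first infeasible one
        for cutoff in np.unique(scores)[::-1]:
            accepted = scores >= cutoff
            d = int(np.sum(decoy & accepted))
            t = int(np.sum(~decoy & accepted))
            if estimate_decoy_fdr(t, d) <= policy.fdr_target:
                best = float(cutoff)
        out[str(engine)] = best
    return out


def filter_psms(psms: pd.DataFrame, policy: FilterPolicy = FilterPolicy()) -> pd.DataFrame:
    """Apply score/ppm gates, then per-engine decoy-FDR thresholds.

    Returns accepted target PSMs (decoys are used for thresholding and then
    removed).
    """
    mask = psms.apply(lambda r: passes_score_filters(r, policy), axis=1)
    gated = psms[mask.to_numpy(dtype=bool)]
    if gated.empty:
        return gated
    thresholds = threshold_for_fdr(gated, policy)
    keep = gated["score"] >= gated["engine"].map(thresholds).astype(float)
    accepted = gated[keep.to_numpy(dtype=bool)]
    return accepted[~accepted["decoy"].astype(bool)].reset_index(drop=True)


def _phospho_key(mods: str) -> frozenset[int]:
    positions = []
    for part in str(mods).split(";"):
        if not part:
            continue
        pos, _delta, kind = part.split(":")
        if kind == "phospho":
            positions.append(int(pos))
    return frozenset(positions)


def assemble_nonredundant(accepted: pd.DataFrame) -> pd.DataFrame:
    """Collapse accepted PSMs to unique (sequence, phosphosite-set) entries.

    Retains the best score per engine and the set of (timepoint, replicate)
    observations; the union over engines counts a peptide once.  Idempotent
    in the sense that re-running on its own expansion changes nothing.
    """
    if accepted.empty:
        return pd.DataFrame(columns=[
            "sequence", "phospho_positions", "peptide_id",
            "best_score_A", "best_score_B", "observed_timepoints", "n_observations",
        ])
    work = accepted.copy()
    work["_key"] = [
        (seq, _phospho_key(mods)) for seq, mods in zip(work["sequence"], work["mods"])
    ]
    rows = []
    for (seq, sites), grp in work.groupby("_key", sort=True):
        scores_a = grp.loc[grp["engine"] == "A", "score"]
        scores_b = grp.loc[grp["engine"] == "B", "score"]
        rows.append(dict(
            sequence=seq,
            phospho_positions=",".join(str(p) for p in sorted(sites)),
            peptide_id=grp["peptide_id"].iloc[0] if "peptide_id" in grp else seq,
            best_score_A=float(scores_a.max()) if len(scores_a) else float("nan"),
            best_score_B=float(scores_b.max()) if len(scores_b) else float("nan"),
            observed_timepoints=",".join(
                str(t) for t in sorted(set(int(t) for t in grp["timepoint"]))
            ),
            n_observations=int(len(grp)),
        ))
    return pd.DataFrame(rows)


def apply_observation_rule(
    entry: Mapping | Iterable[int], policy: FilterPolicy = FilterPolicy()
) -> bool:
    """True iff observed in at least ``min_timepoints_observed`` timepoints."""
    if isinstance(entry, Mapping) or isinstance(entry, pd.Series):
        raw = entry["observed_timepoints"]
        tps = set() if raw in ("", None) else {int(t) for t in str(raw).split(",")}
    else:
        tps = set(int(t) for t in entry)
    return len(tps) >= policy.min_timepoints_observed
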