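"""Seeded ground-truth generator for two-channel SILAC time-course experiments.

Emulates the statistical structure of a phosphotyrosine time course comparing
a reconstituted (light) and deficient (heavy) cell line: 8 stimulation
timepoints, 3 replicates, Gaussian elution peaks over a baseline-noise floor,
a constant 10-pmol spike-in peptide (LIEDAEpYTAK) per timepoint, target and
decoy identifications with separated score distributions, per-replicate
multiplicative log-normal noise, per-(timepoint, replicate) injection scale
factors, and missing observations.

Trajectory classes
------------------
``null``                     flat light abundance, heavy/light ratio 1.
``induced``                  light abundance rises to an ~18-fold maximum
                             over the time course; ratio 1.
``early_up_late_down``       ratio elevated (~2x) early, reduced late —
                             the kinase-activation-loop pattern.
``constitutively_reduced``   ratio constant at 0.25 across all timepoints.

Seven of the eight timepoints correspond to the stated stimulation times
0, 1, 1.5, 2, 3, 5 and 10 min; the grid is kept as ordered labels because
downstream rules (the 4-of-8 observation rule, per-timepoint tests) depend
only on the ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from phosquant.mass_chem import (
    HEAVY_SCHEME,
    LIGHT_SCHEME,
    ModifiedPeptide,
    monoisotopic_mass,
    parse_peptide,
)
from phosquant.quantitation import Chromatogram, gaussian_chromatogram
from phosquant.site_localization import by_ion_mz

SPIKE_SEQUENCE = "LIEDAEpYTAK"
TRAJECTORY_CLASSES = ("null", "induced", "early_up_late_down", "constitutively_reduced")

DEFAULT_CLASS_PROPORTIONS: Mapping[str, float] = {
    "null": 0.40,
    "induced": 0.25,
    "early_up_late_down": 0.20,
    "constitutively_reduced": 0.15,
}

# Light-channel abundance profiles (relative to the peptide's base area) and
# heavy/light ratio profiles, one value per timepoint.
DEFAULT_LIGHT_PROFILES: Mapping[str, tuple[float, ...]] = {
    "null": (1, 1, 1, 1, 1, 1, 1, 1),
    "induced": (1, 2, 5, 10, 18, 14, 8, 4),
    "early_up_late_down": (1, 1, 1, 1, 1, 1, 1, 1),
    "constitutively_reduced": (1, 1, 1, 1, 1, 1, 1, 1),
}
DEFAULT_RATIO_PROFILES: Mapping[str, tuple[float, ...]] = {
    "null": (1, 1, 1, 1, 1, 1, 1, 1),
    "induced": (1, 1, 1, 1, 1, 1, 1, 1),
    "early_up_late_down": (2.0, 2.0, 2.0, 1.5, 1.0, 0.6, 0.4, 0.3),
    "constitutively_reduced": (0.25,) * 8,
}

_RESIDUES = "ACDEFGHILMNPQSTVW"  # K/R reserved for the tryptic terminus


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of the time-course experiment.

    ``timepoints`` are ordered labels; the default eight-point grid covers
    stimulation times 0–10 min.  ``spike_amount`` is the nominal constant
    spike-in quantity per timepoint (pmol) and ``spike_area_per_pmol``
    converts it to a nominal SIC area for simulation.
    """

    timepoints: tuple[str, ...] = ("t0", "t1", "t2", "t3", "t4", "t5", "t6", "t7")
    n_replicates: int = 3
    channels: tuple[str, str] = ("light", "heavy")
    spike_amount: float = 10.0
    spike_area_per_pmol: float = 5e4

    def __post_init__(self) -> None:
        if len(self.timepoints) < 2:
            raise ValueError("need at least 2 timepoints")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates for any statistical test")
        if self.spike_amount <= 0:
            raise ValueError("spike amount must be > 0")

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    @property
    def spike_base_area(self) -> float:
        return self.spike_amount * self.spike_area_per_pmol


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic components layered onto the true signal.

    ``replicate_sigma`` is the SD of natural-log multiplicative noise on peak
    areas (0.2 reproduces the replicate CV scale of the assay); the additive
    chromatogram baseline is half-normal per scan with SD ``baseline_sd``
    counts, whose typical integrated area over a trace is of the order of the
    500-count spectral noise floor; ``ppm_sd`` disperses observed precursor
    masses; ``missing_rate`` drops whole (peptide, timepoint) cells.

    ``incorrect_rate`` is the probability that a target PSM is a spurious
    match: it then draws its scores from the decoy distributions and is
    flagged ``true_match = False`` in the hidden ground-truth column.  Under
    the concatenated-database convention spurious matches land on target and
    decoy sequences with equal probability, which is what makes the decoy
    count an estimator of the number of false target matches.
    """

    replicate_sigma: float = 0.2
    baseline_sd: float = 10.0
    ppm_sd: float = 4.0
    missing_rate: float = 0.10
    incorrect_rate: float = 0.02
    injection_range: tuple[float, float] = (0.5, 2.0)
    target_scores_a: tuple[float, float] = (3.2, 0.5)
    decoy_scores_a: tuple[float, float] = (1.55, 0.45)
    target_scores_b: tuple[float, float] = (45.0, 12.0)
    decoy_scores_b: tuple[float, float] = (11.0, 5.0)
    score_correlation: float = 0.7


@dataclass
class GroundTruth:
    """True generative state of a synthetic experiment."""

    peptides: pd.DataFrame          # peptide_id, sequence, site, traj_class, base_area
    true_light: np.ndarray          # (n_peptides, n_timepoints) relative light abundance
    true_ratio: np.ndarray          # (n_peptides, n_timepoints) heavy/light
    injection: np.ndarray           # (n_timepoints, n_replicates) scale factors, > 0
    missing: np.ndarray             # (n_peptides, n_timepoints) bool
    replicate_sigma: float = 0.2


@dataclass
class SyntheticRun:
    """Observable output of a synthetic experiment: PSMs + chromatograms."""

    design: ExperimentDesign
    psms: pd.DataFrame
    chromatograms: dict[tuple[str, str, int, int], Chromatogram]
    spike_chromatograms: dict[tuple[int, int], Chromatogram]
    peak_lists: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def _random_peptide(rng: np.random.Generator) -> tuple[str, int]:
    """Tryptic-like sequence with one internal Y (the true site), K/R terminus."""
    length = int(rng.integers(9, 15))
    chars = [str(c) for c in rng.choice(list(_RESIDUES), size=length - 1)]
    site = int(rng.integers(1, length - 2))
    chars[site] = "Y"
    chars.append("K" if rng.random() < 0.5 else "R")
    return "".join(chars), site


def _correlated_scores(
    rng: np.random.Generator, n: int, params_a: tuple[float, float],
    params_b: tuple[float, float], rho: float,
) -> tuple[np.ndarray, np.ndarray]:
    u = rng.standard_normal(n)
    ea = rng.standard_normal(n)
    eb = rng.standard_normal(n)
    za = rho * u + math.sqrt(1 - rho**2) * ea
    zb = rho * u + math.sqrt(1 - rho**2) * eb
    a = np.clip(params_a[0] + params_a[1] * za, 0.05, None)
    b = np.clip(params_b[0] + params_b[1] * zb, 0.5, None)
    return a, b


def _spectrum_for(pep: ModifiedPeptide, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Fragment peak list: true-site b/y ions plus uniform noise peaks."""
    mzs, intens = [], []
    n = len(pep.sequence)
    for i in range(1, n):
        mzs.append(by_ion_mz(pep, "b", i))
        mzs.append(by_ion_mz(pep, "y", n - i))
        intens.extend(rng.uniform(200.0, 1000.0, size=2))
    n_noise = 30
    mzs.extend(rng.uniform(150.0, 1500.0, size=n_noise))
    intens.extend(rng.uniform(20.0, 150.0, size=n_noise))
    mz = np.asarray(mzs)
    order = np.argsort(mz)
    return mz[order], np.asarray(intens)[order]


def simulate_experiment(
    design: ExperimentDesign = ExperimentDesign(),
    n_peptides: int = 60,
    class_proportions: Mapping[str, float] | None = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    ratio_profiles: Mapping[str, tuple[float, ...]] | None = None,
    light_profiles: Mapping[str, tuple[float, ...]] | None = None,
    decoy_share: float = 0.5,
    with_spectra: bool = False,
) -> tuple[GroundTruth, SyntheticRun]:
    """Generate a complete ground-truth experiment, deterministic in ``seed``.

    ``class_proportions`` assigns peptides to trajectory classes (must sum to
    1); ``ratio_profiles`` / ``light_profiles`` may override or extend the
    built-in per-class profiles (values are recycled/truncated to the design's
    timepoint count).  ``decoy_share`` is the fraction of spurious matches
    that land on reversed (decoy) sequences — 0.5 under the 50/50
    concatenated-database convention.  ``with_spectra`` additionally emits one
    fragment peak list per target peptide for site-localization testing.
    """
    if n_peptides < 1:
        raise ValueError(f"n_peptides must be >= 1, got {n_peptides}")
    props = dict(class_proportions or DEFAULT_CLASS_PROPORTIONS)
    total = sum(props.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"class proportions must sum to 1, got {total}")
    if any(v < 0 for v in props.values()):
        raise ValueError("class proportions must be non-negative")

    rprof = {**DEFAULT_RATIO_PROFILES, **(ratio_profiles or {})}
    lprof = {**DEFAULT_LIGHT_PROFILES, **(light_profiles or {})}
    for cls in props:
        if cls not in rprof or cls not in lprof:
            raise ValueError(f"no abundance/ratio profile for class {cls!r}")

    rng = np.random.default_rng(seed)
    n_tp, n_rep = design.n_timepoints, design.n_replicates

    def profile(table: Mapping[str, tuple[float, ...]], cls: str) -> np.ndarray:
        base = np.asarray(table[cls], dtype=float)
        reps = int(np.ceil(n_tp / len(base)))
        return np.tile(base, reps)[:n_tp]

    # --- peptide roster -----------------------------------------------------
    classes = list(props)
    counts = rng.multinomial(n_peptides, [props[c] for c in classes])
    rows, true_light, true_ratio = [], [], []
    for cls, cnt in zip(classes, counts):
        for _ in range(cnt):
            seq, site = _random_peptide(rng)
            pep_id = f"pep{len(rows):04d}"
            base_area = float(10 ** rng.uniform(4.0, 5.5))
            rows.append((pep_id, seq, site, cls, base_area))
            true_light.append(profile(lprof, cls))
            true_ratio.append(profile(rprof, cls))
    peptides = pd.DataFrame(
        rows, columns=["peptide_id", "sequence", "site", "traj_class", "base_area"]
    )
    true_light_arr = np.asarray(true_light).reshape(len(rows), n_tp)
    true_ratio_arr = np.asarray(true_ratio).reshape(len(rows), n_tp)

    injection = rng.uniform(*noise.injection_range, size=(n_tp, n_rep))
    missing = rng.random((len(rows), n_tp)) < noise.missing_rate

    truth = GroundTruth(
        peptides, true_light_arr, true_ratio_arr, injection, missing,
        replicate_sigma=noise.replicate_sigma,
    )

    # --- chromatograms ------------------------------------------------------
    chroms: dict[tuple[str, str, int, int], Chromatogram] = {}
    for i, row in peptides.iterrows():
        for tp in range(n_tp):
            if missing[i, tp]:
                continue
            for rep in range(n_rep):
                light_area = (
                    row.base_area * true_light_arr[i, tp] * injection[tp, rep]
                    * math.exp(noise.replicate_sigma * rng.standard_normal())
                )
                heavy_area = (
                    row.base_area * true_light_arr[i, tp] * true_ratio_arr[i, tp]
                    * injection[tp, rep]
                    * math.exp(noise.replicate_sigma * rng.standard_normal())
                )
                for channel, area in (("light", light_area), ("heavy", heavy_area)):
                    baseline = np.abs(rng.normal(0.0, noise.baseline_sd, size=61))
                    chroms[(row.peptide_id, channel, tp, rep)] = gaussian_chromatogram(
                        area, apex_time=30.0 + rng.normal(0, 2.0), baseline=baseline
                    )

    spike_chroms: dict[tuple[int, int], Chromatogram] = {}
    for tp in range(n_tp):
        for rep in range(n_rep):
            # spike area scales exactly with the injection factor: the basis
            # of the normalization invariance checks
            spike_chroms[(tp, rep)] = gaussian_chromatogram(
                design.spike_base_area * injection[tp, rep], apex_time=30.0
            )

    # --- PSMs ---------------------------------------------------------------
    psm_rows: list[dict] = []

    def add_psms(pep_id, seq, site, decoy, cells, rng):
        mods = f"{site}:79.9663:phospho"
        light = parse_peptide(
            seq[:site] + "p" + seq[site:], charge=2, scheme=LIGHT_SCHEME
        )
        theo = monoisotopic_mass(light)
        n_cells = len(cells)
        # spurious matches land on target and decoy sequences evenly, so the
        # per-target spurious probability is half the overall incorrect rate
        true_match = (
            np.zeros(n_cells, dtype=bool)
            if decoy else rng.random(n_cells) >= noise.incorrect_rate / 2.0
        )
        a_t, b_t = _correlated_scores(
            rng, n_cells, noise.target_scores_a, noise.target_scores_b,
            noise.score_correlation,
        )
        a_d, b_d = _correlated_scores(
            rng, n_cells, noise.decoy_scores_a, noise.decoy_scores_b,
            noise.score_correlation,
        )
        a = np.where(true_match, a_t, a_d)
        b = np.where(true_match, b_t, b_d)
        for j, (tp, rep) in enumerate(cells):
            obs = theo * (1.0 + 1e-6 * rng.normal(0.0, noise.ppm_sd))
            for engine, score in (("A", a[j]), ("B", b[j])):
                psm_rows.append(dict(
                    psm_id=f"psm{len(psm_rows):06d}", peptide_id=pep_id,
                    sequence=seq, mods=mods, charge=2, engine=engine,
                    score=float(score), obs_mass=obs, theo_mass=theo,
                    decoy=decoy, timepoint=tp, replicate=rep, channel="light",
                    true_match=bool(true_match[j]),
                ))

    total_cells = 0
    for i, row in peptides.iterrows():
        cells = [
            (tp, rep)
            for tp in range(n_tp) if not missing[i, tp]
            for rep in range(n_rep) if rng.random() < 0.85
        ]
        total_cells += len(cells)
        add_psms(row.peptide_id, row.sequence, int(row.site), False, cells, rng)

    # reversed-database decoys: the other half of the spurious matches
    n_decoy_cells = int(rng.binomial(total_cells, decoy_share * noise.incorrect_rate))
    for d in range(n_decoy_cells):
        seq, site = _random_peptide(rng)
        cell = (int(rng.integers(0, n_tp)), int(rng.integers(0, n_rep)))
        add_psms(f"dec{d:04d}", seq, site, True, [cell], rng)

    psms = pd.DataFrame(psm_rows)

    peak_lists: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if with_spectra:
        for _, row in peptides.iterrows():
            pep = parse_peptide(
                row.sequence[: row.site] + "p" + row.sequence[row.site :], charge=2
            )
            peak_lists[row.peptide_id] = _spectrum_for(pep, rng)

    run = SyntheticRun(design, psms, chroms, spike_chroms, peak_lists)
    return truth, run


def simulate_null_pvalue_study(
    design: ExperimentDesign = ExperimentDesign(),
    n_peptides: int = 300,
    seed: int = 0,
    sigma: float = 0.2,
) -> np.ndarray:
    """Paired-t p-values from data with no true heavy/light difference.

    Calibration harness for the per-timepoint paired test: heavy and light
    areas share the same mean with independent log-normal replicate noise, so
    the p-value distribution should be uniform on [0, 1].
    """
    if design.n_replicates < 2:
        raise ValueError("need at least 2 replicates for a paired test")
    from phosquant.stats import paired_t_silac

    rng = np.random.default_rng(seed)
    n_tp, n_rep = design.n_timepoints, design.n_replicates
    pvals = []
    for _ in range(n_peptides):
        base = 10 ** rng.uniform(4.0, 5.5)
        for _tp in range(n_tp):
            light = base * np.exp(sigma * rng.standard_normal(n_rep))
            heavy = base * np.exp(sigma * rng.standard_normal(n_rep))
            p, _degenerate = paired_t_silac(heavy, light)
            if p is not None:
                pvals.append(p)
    return np.asarray(pvals)
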