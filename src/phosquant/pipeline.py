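"""End-to-end orchestration: simulate -> identify -> localize -> quantify ->
stats -> report, with file-based stage boundaries for the CLI.

Every stage reads and writes plain TSV in the run directory, so the shell
subcommands compose, and the whole pipeline is deterministic given (config,
seed).  Stage failures abort with a stage-tagged error and leave no partial
outputs for that stage.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from phosquant import identification as ident
from phosquant import reporting, stats
from phosquant.identification import FilterPolicy
from phosquant.quantitation import (
    Chromatogram,
    IntegrationParams,
    apply_area_floor,
    integrate_peak,
    normalize_to_spike,
)
from phosquant.site_localization import localize
from phosquant.synthetic import (
    ExperimentDesign,
    NoiseModel,
    SyntheticRun,
    simulate_experiment,
)

log = logging.getLogger("phosquant")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All knobs of a pipeline run; every printed threshold is a default here."""

    out_dir: str = "phosquant_run"
    seed: int = 0
    n_peptides: int = 60
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    noise: NoiseModel = field(default_factory=NoiseModel)
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    integration: IntegrationParams = field(default_factory=IntegrationParams)
    welch: bool = False
    labelfree_cap: float = 100.0
    silac_cap: float = 50.0
    q_threshold: float = 0.02
    make_figures: bool = True

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        kwargs: dict = {}
        for key in ("out_dir", "seed", "n_peptides", "welch", "labelfree_cap",
                    "silac_cap", "q_threshold", "make_figures"):
            if key in raw:
                kwargs[key] = raw[key]
        if "design" in raw:
            d = dict(raw["design"])
            if "timepoints" in d:
                d["timepoints"] = tuple(d["timepoints"])
            kwargs["design"] = ExperimentDesign(**d)
        if "noise" in raw:
            kwargs["noise"] = NoiseModel(**raw["noise"])
        if "policy" in raw:
            p = dict(raw["policy"])
            if "xcorr_min" in p:
                p["xcorr_min"] = {int(k): float(v) for k, v in p["xcorr_min"].items()}
            kwargs["policy"] = FilterPolicy(**p)
        if "integration" in raw:
            kwargs["integration"] = IntegrationParams(**raw["integration"])
        return cls(**kwargs)


# ---------------------------------------------------------------- simulate --

def write_run(run: SyntheticRun, out_dir: str | Path) -> None:
    """Serialize a synthetic run to the TSV formats the stages read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run.psms.to_csv(out / "psms.tsv", sep="\t", index=False)
    chrom_rows = []
    for (pep, channel, tp, rep), c in run.chromatograms.items():
        for t, y in zip(c.times, c.intensities):
            chrom_rows.append((pep, channel, tp, rep, t, y))
    pd.DataFrame(
        chrom_rows,
        columns=["peptide_id", "channel", "timepoint", "replicate", "scan_time", "intensity"],
    ).to_csv(out / "chromatograms.tsv", sep="\t", index=False)
    spike_rows = []
    for (tp, rep), c in run.spike_chromatograms.items():
        for t, y in zip(c.times, c.intensities):
            spike_rows.append((tp, rep, t, y))
    pd.DataFrame(
        spike_rows, columns=["timepoint", "replicate", "scan_time", "intensity"]
    ).to_csv(out / "spike_chromatograms.tsv", sep="\t", index=False)
    if run.peak_lists:
        rows = [
            (pep, mz, inten)
            for pep, (mzs, intens) in run.peak_lists.items()
            for mz, inten in zip(mzs, intens)
        ]
        pd.DataFrame(rows, columns=["peptide_id", "mz", "intensity"]).to_csv(
            out / "peak_lists.tsv", sep="\t", index=False
        )


def read_chromatograms(path: str | Path, keyed_by_peptide: bool = True) -> dict:
    df = pd.read_csv(path, sep="\t")
    chroms: dict = {}
    keys = (
        ["peptide_id", "channel", "timepoint", "replicate"]
        if keyed_by_peptide else ["timepoint", "replicate"]
    )
    for key, grp in df.groupby(keys, sort=True):
        chroms[key if len(keys) > 2 else tuple(key)] = Chromatogram(
            grp["scan_time"].to_numpy(), grp["intensity"].to_numpy()
        )
    return chroms


# ---------------------------------------------------------------- quantify --

def quantify_run(
    run: SyntheticRun,
    params: IntegrationParams = IntegrationParams(),
    peptide_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Integrate every chromatogram, apply the area floor, spike-normalize.

    Returns one row per (peptide, channel, timepoint, replicate):
    ``raw_area`` is NaN when no peak was found or the area is below the
    500-count floor; ``norm_area`` additionally requires a defined spike
    area for that (timepoint, replicate).
    """
    spike_area: dict[tuple[int, int], float] = {}
    for key, chrom in run.spike_chromatograms.items():
        res = integrate_peak(chrom, params)
        area = res[0] if res else None
        spike_area[key] = area if apply_area_floor(area, params) else np.nan
    rows = []
    for (pep, channel, tp, rep), chrom in run.chromatograms.items():
        if peptide_ids is not None and pep not in peptide_ids:
            continue
        res = integrate_peak(chrom, params)
        area = res[0] if res else None
        raw = area if apply_area_floor(area, params) else np.nan
        spike = spike_area.get((tp, rep), np.nan)
        norm = (
            normalize_to_spike(raw, spike)
            if np.isfinite(raw) and np.isfinite(spike) else np.nan
        )
        rows.append(dict(
            peptide_id=pep, channel=channel, timepoint=tp, replicate=rep,
            raw_area=raw if raw is not None else np.nan,
            spike_area=spike, norm_area=norm,
        ))
    return pd.DataFrame(rows).sort_values(
        ["peptide_id", "channel", "timepoint", "replicate"]
    ).reset_index(drop=True)


# ------------------------------------------------------------ run_pipeline --

def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns a summary dict of stage outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"out_dir": str(out)}

    try:
        truth, run = simulate_experiment(
            config.design, config.n_peptides, None, config.noise,
            seed=config.seed, with_spectra=True,
        )
        write_run(run, out)
        truth.peptides.to_csv(out / "ground_truth_peptides.tsv", sep="\t", index=False)
        summary["n_psms"] = len(run.psms)
        log.info("simulate: %d PSMs, %d peptides", len(run.psms), config.n_peptides)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - stage tagging contract
        raise PipelineError("simulate", str(e)) from e

    try:
        accepted = ident.filter_psms(run.psms, config.policy)
        nonredundant = ident.assemble_nonredundant(accepted)
        keep = nonredundant.apply(
            lambda r: ident.apply_observation_rule(r, config.policy), axis=1
        )
        peptide_list = nonredundant[keep.to_numpy(dtype=bool)].reset_index(drop=True)
        peptide_list.to_csv(out / "accepted_peptides.tsv", sep="\t", index=False)
        summary["n_accepted_psms"] = len(accepted)
        summary["n_nonredundant"] = len(nonredundant)
        summary["n_quantifiable"] = len(peptide_list)
        log.info("identify: %d PSMs accepted, %d nonredundant, %d pass 4-of-%d",
                 len(accepted), len(nonredundant), len(peptide_list),
                 config.design.n_timepoints)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("identify", str(e)) from e

    try:
        site_rows = []
        for _, row in peptide_list.iterrows():
            pep_id = row["peptide_id"]
            if pep_id not in run.peak_lists:
                continue
            seq = row["sequence"]
            candidates = [i for i, r in enumerate(seq) if r == "Y"]
            from phosquant.mass_chem import parse_peptide
            claimed = int(str(row["phospho_positions"]).split(",")[0])
            pep = parse_peptide(seq[:claimed] + "p" + seq[claimed:], charge=2)
            res = localize(run.peak_lists[pep_id], pep, candidates)
            site_rows.append(dict(
                peptide_id=pep_id, sequence=seq,
                site=res.best_position,
                site_label=f"{seq[res.best_position]}{res.best_position + 1}",
                score=res.score, ambiguous=res.ambiguous,
            ))
        sites = pd.DataFrame(site_rows)
        sites.to_csv(out / "site_localization.tsv", sep="\t", index=False)
        summary["n_localized"] = len(sites)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("localize", str(e)) from e

    try:
        quant = quantify_run(
            run, config.integration,
            peptide_ids=list(peptide_list["peptide_id"]),
        )
        quant.to_csv(out / "quant.tsv", sep="\t", index=False)
        summary["n_quant_records"] = len(quant)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("quantify", str(e)) from e

    try:
        n_tp = config.design.n_timepoints
        lf = stats.build_labelfree_matrix(
            quant, n_tp, config.labelfree_cap, config.welch, config.q_threshold
        )
        sil = stats.build_silac_matrix(quant, n_tp, config.silac_cap, config.q_threshold)
        summary["labelfree"] = lf
        summary["silac"] = sil
    except Exception as e:  # noqa: BLE001
        raise PipelineError("stats", str(e)) from e

    try:
        tables = {
            "accepted_peptides": peptide_list,
            "site_localization": sites,
            "quant": quant,
            **reporting.matrix_tables(lf, "labelfree"),
            **reporting.matrix_tables(sil, "silac"),
        }
        manifest_extra = {
            "seed": config.seed,
            "n_peptides": config.n_peptides,
            "config": {
                k: v for k, v in dataclasses.asdict(config).items()
                if isinstance(v, (int, float, str, bool))
            },
        }
        reporting.export_tables(out, tables, manifest_extra)
        if config.make_figures and len(lf.values) and len(sil.values):
            reporting.build_heatmap(lf, reporting.LABELFREE_SPEC, out / "labelfree_heatmap.png")
            reporting.build_heatmap(sil, reporting.SILAC_SPEC, out / "silac_heatmap.png")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("report", str(e)) from e

    return summary
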