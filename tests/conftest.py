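import numpy as np
import pandas as pd
import pytest

from phosquant.synthetic import ExperimentDesign, NoiseModel, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """One modest synthetic run shared by read-only tests."""
    return simulate_experiment(
        ExperimentDesign(), n_peptides=25, seed=11, with_spectra=True
    )


@pytest.fixture()
def psm_fixture_12row() -> pd.DataFrame:
    """Hand-built 12-row PSM table for exhaustive FDR-threshold checks.

    Engine A only; scores descending with decoys interleaved so the
    threshold scan has a non-trivial optimum.
    """
    rows = []
    scores = [9.0, 8.5, 8.0, 7.5, 7.0, 6.5, 6.0, 5.5, 5.0, 4.5, 4.0, 3.5]
    decoys = [False, False, False, False, False, False, False, True, False, False, True, True]
    for i, (s, d) in enumerate(zip(scores, decoys)):
        rows.append(dict(
            psm_id=f"f{i:02d}", peptide_id=f"f{i:02d}", sequence="AAAYK",
            mods="3:79.9663:phospho", charge=2, engine="A", score=s,
            obs_mass=600.0, theo_mass=600.0, decoy=d, timepoint=0,
            replicate=0, channel="light", true_match=not d,
        ))
    return pd.DataFrame(rows)
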