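import numpy as np
import pandas as pd
import pytest

import decaykit as dk
from decaykit.io_formats import COND_COL, REP_COL, TIME_COL, sample_name

LN2 = np.log(2.0)
TIMES = [0.0, 120.0, 240.0, 480.0]


def make_design(conditions=("P", "CI7"), n_replicates=2, times=TIMES) -> pd.DataFrame:
    rows = [
        (sample_name(c, r, t), t, c, r)
        for c in conditions
        for r in range(1, n_replicates + 1)
        for t in times
    ]
    return pd.DataFrame(rows, columns=["sample", TIME_COL, COND_COL, REP_COL]).set_index(
        "sample"
    )


def make_dataset(halflives: dict[str, tuple[float, float]], a0=1000.0) -> dk.TimeCourseDataset:
    """Noiseless dataset from per-gene (halflife_P, halflife_CI7) in minutes.

    A half-life of np.inf means a flat (non-decaying) profile.
    """
    design = make_design()
    cols = {}
    for s in design.index:
        t = design.loc[s, TIME_COL]
        cond = design.loc[s, COND_COL]
        vals = []
        for g, (hl_p, hl_c) in halflives.items():
            hl = hl_p if cond == "P" else hl_c
            k = 0.0 if np.isinf(hl) else LN2 / hl
            vals.append(a0 * np.exp(-k * t))
        cols[s] = vals
    mat = pd.DataFrame(cols, index=pd.Index(list(halflives), name="gene"))
    return dk.TimeCourseDataset(mat, design)


@pytest.fixture(scope="session")
def null_sim():
    """2000 all-exponential genes, no differential decay: the null condition."""
    cfg = dk.SimulationConfig(
        n_genes=2000, frac_differential=0.0, frac_nonexponential=0.0,
        noise_sd=0.2, replicate_effect_sd=0.1, seed=7,
    )
    ds, truth = dk.simulate_timecourse(cfg)
    fits, summary = dk.fit_all(ds)
    fits = dk.test_differential(fits)
    return ds, truth, fits, summary


@pytest.fixture(scope="session")
def planted_sim():
    """2000 genes with a sign-balanced 10% differential subpopulation."""
    cfg = dk.SimulationConfig(
        n_genes=2000, frac_differential=0.1, differential_log2_effect=1.0,
        frac_nonexponential=0.0, noise_sd=0.2, replicate_effect_sd=0.1, seed=7,
    )
    ds, truth = dk.simulate_timecourse(cfg)
    fits, summary = dk.fit_all(ds)
    fits = dk.test_differential(fits)
    return ds, truth, fits, summary


@pytest.fixture(scope="session")
def clustering_sim():
    """A second planted draw at the same study conditions, used for the
    profile-clustering recovery checks."""
    cfg = dk.SimulationConfig(
        n_genes=2000, frac_differential=0.1, differential_log2_effect=1.0,
        frac_nonexponential=0.0, noise_sd=0.2, replicate_effect_sd=0.1, seed=1,
    )
    ds, truth = dk.simulate_timecourse(cfg)
    fits, _ = dk.fit_all(ds)
    fits = dk.test_differential(fits)
    return ds, truth, fits


@pytest.fixture(scope="session")
def planted_metric(planted_sim):
    _, truth, fits, _ = planted_sim
    return truth, dk.compute_metric(fits)
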