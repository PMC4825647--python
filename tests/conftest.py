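import pandas as pd
import pytest

import stresstraj as st


@pytest.fixture
def small_design():
    """A fast 300-gene version of the default study design."""
    return st.SyntheticDesign(n_genes=300, seed=1)


@pytest.fixture
def noiseless_design():
    return st.SyntheticDesign(n_genes=300, noise_sd_log2=0.0, seed=1)


@pytest.fixture
def null_design():
    """No planted signal of any kind: every gene flat at ratio 1."""
    return st.SyntheticDesign(
        n_genes=300,
        noise_sd_log2=0.05,
        de_fraction=0.0,
        baseline_log2_sd=0.0,
        pattern_weights={"NcNcNc": 1.0},
        nc_jitter=0.0,
        seed=1,
    )


@pytest.fixture
def toy_array():
    """Hand-written 10-probe array: 5 genes x 2 probes."""
    probes = pd.DataFrame(
        {
            "probe_id": [f"g{i}_p{j}" for i in range(1, 6) for j in (1, 2)],
            "gene_id": [f"g{i}" for i in range(1, 6) for _ in (1, 2)],
            "channelA": [4.0, 16.0, 100.0, 100.0, 2.0, 8.0, 50.0, 200.0, 0.5, 2.0],
            "channelB": [8.0, 8.0, 300.0, 300.0, 4.0, 4.0, 100.0, 100.0, 1.0, 1.0],
        }
    )
    return st.TwoChannelArray(
        array_id="toy", timepoint="pre", replicate=1, dye_swapped=False, probes=probes
    )


def make_ratio_table(trajectories: dict, timepoints=("t0", "t1", "t2", "t3")):
    """RatioTable from a dict gene -> tuple of linear ratios."""
    df = pd.DataFrame.from_dict(trajectories, orient="index", columns=list(timepoints))
    df.index.name = "gene_id"
    return st.RatioTable(ratios=df)


def normalize_all(arrays, **kwargs):
    kwargs.setdefault("loess", "off")
    return [st.normalize_array(a, **kwargs) for a in arrays]
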