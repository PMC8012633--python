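import numpy as np
import pandas as pd
import pytest

import tmtde


@pytest.fixture
def tiny_quant_file(tmp_path):
    """3 proteins x 4 samples MaxQuant-dialect TSV, one reverse-flagged row."""
    path = tmp_path / "proteinGroups.txt"
    rows = [
        "Protein IDs\tGene names\tReverse\tPotential contaminant\t"
        "Reporter intensity corrected 1\tReporter intensity corrected 2\t"
        "Reporter intensity corrected 3\tReporter intensity corrected 4",
        "P00001\tGeneA\t\t\t100.5\t200\t0\t150",
        "P00002\tGeneB\t\t\t50\t\t75.25\t80",
        "P00003\tGeneC\t\t\t10\t20\t30\t40",
        "REV_P9\tDecoy\t+\t\t1\t1\t1\t1",
    ]
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def design_16(tmp_path):
    """16 samples over the four reference groups of four."""
    path = tmp_path / "design.tsv"
    lines = [
        f"{g}_{r}\t{g}"
        for g in ("naive_sed", "naive_ex", "lpc_sed", "lpc_ex")
        for r in range(1, 5)
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "setA\tfirst set\tG1\tG2\tG3\n"
        "setB\tsecond set\tG4\tG5\tG6\tG7\tG8\n"
    )
    return path


def make_table(values, samples=None, ids=None, scale="linear"):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"P{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return tmtde.QuantTable(
        pd.DataFrame(values, index=ids, columns=samples), scale=scale
    )


def make_design(groups, reps):
    return tmtde.StudyDesign(
        {f"{g}_{r}": g for g in groups for r in range(1, reps + 1)}
    )


@pytest.fixture(scope="session")
def default_sim():
    """One simulated dataset at default study conditions (seed 42)."""
    cfg = tmtde.SimConfig(seed=42)
    table, design, truth = tmtde.simulate_dataset(cfg)
    return cfg, table, design, truth


@pytest.fixture(scope="session")
def default_pipeline_result(default_sim):
    """Filter -> log2 -> cyclic LOESS -> linear, shared by the slower tests."""
    _, table, design, truth = default_sim
    filtered, freport = tmtde.filter_low_observation(table, design)
    logt = tmtde.to_log2(filtered)
    normalized, nreport = tmtde.cyclic_loess_normalize(logt)
    linear = tmtde.back_to_linear(normalized)
    return {
        "design": design,
        "truth": truth,
        "filtered": filtered,
        "filter_report": freport,
        "log2_pre": logt,
        "log2_post": normalized,
        "norm_report": nreport,
        "linear_post": linear,
    }
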