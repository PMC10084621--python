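import numpy as np
import pandas as pd
import pytest

from candigene import synth


@pytest.fixture
def toy_phenotypes(tmp_path):
    """Three-individual phenotype CSV covering both levels of each factor."""
    path = tmp_path / "pheno.csv"
    pd.DataFrame({
        "individual_id": ["i1", "i2", "i3"],
        "pond_id": ["H1", "C1", "C1"],
        "maternal_line": ["H1_F01", "C1_F01", "C1_F02"],
        "latitude": ["high", "central", "Central"],
        "temperature": [20, 24, 24],
        "predator": ["absent", "present", "1"],
        "mass": [5.0, 6.0, 4.5],
        "head_width": [1.0, 1.2, 0.9],
        "wing_pad": [2.0, 2.2, 1.8],
        "dev_time": [20, 18, 25],
    }).to_csv(path, index=False)
    return path


@pytest.fixture
def toy_counts(tmp_path):
    """featureCounts-style TSV: 2 genes x 3 samples, with a comment line."""
    path = tmp_path / "counts.tsv"
    with open(path, "w") as fh:
        fh.write("# Program:featureCounts v2.0.3\n")
        fh.write("Geneid\tChr\tStart\tEnd\tStrand\tLength\ti1\ti2\ti3\n")
        fh.write("g1\t1\t100\t600\t+\t500\t10\t0\t3\n")
        fh.write("g2\tX\t700\t1200\t-\t500\t5\t8\t2\n")
    return path


@pytest.fixture
def chain_obo(tmp_path):
    """Five-term is_a chain a <- b <- c <- d <- e in biological_process."""
    path = tmp_path / "chain.obo"
    lines = ["format-version: 1.2\n"]
    ids = [f"GO:000000{i}" for i in range(1, 6)]
    for i, tid in enumerate(ids):
        lines.append(f"\n[Term]\nid: {tid}\nname: term{i}\nnamespace: biological_process\n")
        if i > 0:
            lines.append(f"is_a: {ids[i - 1]} ! term{i - 1}\n")
    path.write_text("".join(lines))
    return path, ids


@pytest.fixture
def design272():
    return synth.generate_design(synth.DesignConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
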