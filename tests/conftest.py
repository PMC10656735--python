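import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from mdmscan.pairwise import ReferenceDB
from mdmscan.seqio import read_fasta, read_lineages
from mdmscan.synthdata import SynthConfig, generate_dataset, make_reference_db


@pytest.fixture(scope="session")
def synth_dir(tmp_path_factory) -> Path:
    """The default synthetic community (seed 42), generated once per session."""
    out = tmp_path_factory.mktemp("synth") / "data"
    generate_dataset(SynthConfig(seed=42), out)
    return out


@pytest.fixture(scope="session")
def synth_truth(synth_dir) -> pd.DataFrame:
    return pd.read_csv(synth_dir / "truth" / "otus.tsv", sep="\t")


@pytest.fixture(scope="session")
def synth_db(synth_dir) -> ReferenceDB:
    return ReferenceDB(
        records=read_fasta(synth_dir / "refs.fasta"),
        lineages=read_lineages(synth_dir / "refs_lineage.tsv"),
    )


@pytest.fixture(scope="session")
def small_db() -> ReferenceDB:
    """A cheap 12-reference database for unit tests (2 phyla deep hierarchy)."""
    cfg = SynthConfig(seed=7, n_phyla=2, classes_per_phylum=1, orders_per_class=1,
                      families_per_order=3, genera_per_family=2)
    rng = np.random.default_rng(7)
    db, _ = make_reference_db(cfg, rng)
    return db
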