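import numpy as np
import pandas as pd
import pytest

from pbmgrn.pbm import EnrichmentTable, PBMExperiment, ProbeRecord


def make_table(es: dict, n_foreground: dict | None = None, threshold: float = 0.40) -> EnrichmentTable:
    """EnrichmentTable from {tf: {pattern: es}} (patterns assumed canonical)."""
    es_df = pd.DataFrame(es)
    nf_df = pd.DataFrame(n_foreground) if n_foreground is not None else None
    return EnrichmentTable(es_df, n_foreground=nf_df, threshold=threshold)


def make_experiment(seqs, intensities, tf_id="TF_X", replicate=1) -> PBMExperiment:
    probes = [
        ProbeRecord(f"p{i}", s, float(v), replicate)
        for i, (s, v) in enumerate(zip(seqs, intensities))
    ]
    return PBMExperiment(tf_id=tf_id, probes=probes, n_replicates=1)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
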