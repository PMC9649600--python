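import numpy as np
import pandas as pd
import pytest

import scnoise as sn


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic experiment, shared across tests."""
    return sn.simulate_experiment(sn.SimulationDesign(), seed=1)


@pytest.fixture(scope="session")
def default_bundle(default_sim):
    """QC'd counts, metadata, size factors and normalized matrix."""
    sim = default_sim
    meta = sn.qc_filter(sim.counts, sim.meta)
    passing = meta.loc[meta["qc_pass"], "cell_id"].tolist()
    counts = sim.counts.subset_cells(passing)
    meta = meta[meta["qc_pass"]].reset_index(drop=True)
    sf = sn.size_factors(counts)
    norm = sn.normalize_log2(counts, sf)
    return {"sim": sim, "counts": counts, "meta": meta, "sf": sf, "norm": norm}


@pytest.fixture()
def tiny_counts():
    """3 genes x 2 cells with one spike-in row."""
    values = np.array([[10, 20], [4, 4], [6, 18]])
    return sn.CountMatrix(values, ["geneA", "geneB", "ERCC-00002"], ["c1", "c2"])


def make_norm(values, feature_ids, cell_ids, pseudocount=1.0):
    """Construct a NormalizedMatrix directly from log2-space values."""
    values = np.asarray(values, dtype=float)
    is_spike = np.array([str(f).startswith("ERCC-") for f in feature_ids])
    return sn.NormalizedMatrix(
        values,
        np.asarray(feature_ids, dtype=object),
        np.asarray(cell_ids, dtype=object),
        is_spike,
        pseudocount,
    )
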