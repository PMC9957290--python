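import logging

import pytest

from ibparch import pipeline as pl
from ibparch import synthetic_data as sd

logging.getLogger("ibparch").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """Default-condition simulated dataset with its ground truth."""
    out = tmp_path_factory.mktemp("default_ds")
    truth = sd.simulate(sd.SimConfig(seed=1234), out)
    return out, truth


@pytest.fixture(scope="session")
def default_ctx(default_dataset, tmp_path_factory):
    """Pipeline results computed once over the default dataset."""
    ds, truth = default_dataset
    cfg = pl.RunConfig(
        dataset_dir=str(ds),
        out_dir=str(tmp_path_factory.mktemp("default_out")),
        n_permutations=199,
    )
    return pl.compute_all(cfg), truth


@pytest.fixture(scope="session")
def recovery_dataset(tmp_path_factory):
    """Fixed-size simulation: 50 contigs, exactly 500 genes, 5 samples."""
    out = tmp_path_factory.mktemp("recovery_ds")
    cfg = sd.SimConfig(
        seed=7,
        n_samples={
            "interior_ice": 2, "sea_ice_interface": 1,
            "epipelagic": 1, "meso_bathypelagic": 1,
        },
        n_contigs_per_sample=(10, 10),
        genes_per_contig=(10, 10),
        eukaryote_contig_fraction=0.0,
        short_contig_fraction=0.0,
    )
    truth = sd.simulate(cfg, out)
    return out, truth
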