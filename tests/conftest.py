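import numpy as np
import pytest

import rloopgram as rg


@pytest.fixture(scope="session")
def tiny_plasmid():
    """20 nt gene region inside a 28 nt plasmid, known sequence."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=28))
    return rg.PlasmidSequence(name="tiny", seq=seq, gene_region=(5, 24))


@pytest.fixture(scope="session")
def small_sample():
    """Small synthetic plasmid + footprints for integration-style tests."""
    spec = rg.SyntheticSpec(
        name="small",
        gene_length=400,
        flank=60,
        n_rloops=150,
        mean_length=80,
        cluster_means=(0.3, 0.65),
        cluster_sd=40.0,
        planted_span=80.0,
        seed=7,
    )
    plasmid, ds = rg.generate_sample(spec)
    return spec, plasmid, ds


@pytest.fixture(scope="session")
def small_model(small_sample):
    """Dictionary + model trained on the small synthetic sample."""
    _, plasmid, ds = small_sample
    dic, model = rg.train_one_model(
        {plasmid.name: ds}, {plasmid.name: plasmid}, k=4, p=7,
        rng=np.random.default_rng(0),
    )
    return plasmid, dic, model


def homogeneous_dictionary(k, outside="sigH", inside="tauH", p=0):
    """Dictionary mapping every k-mer to one fixed symbol pair."""
    import itertools

    kmers = ["".join(t) for t in itertools.product("ACGT", repeat=k)]
    return rg.SymbolDictionary(
        k=k, p=p,
        outside={s: outside for s in kmers},
        inside={s: inside for s in kmers},
        provenance="test:homogeneous",
    )
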