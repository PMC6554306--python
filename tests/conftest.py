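import numpy as np
import pytest

import tgindel as tg


@pytest.fixture(scope="session")
def toy_result():
    """One shared small end-to-end run: 5-copy array with a switch."""
    fx = tg.build_toy_fixture(7, n_copies=5, switch_index=2, coverage=30,
                              error_rate=0.001)
    return tg.run_pipeline(fx)


@pytest.fixture(scope="session")
def plain_genome_paired():
    """Mapping of an error-free simulation of a non-transgenic genome."""
    rng = np.random.default_rng(11)
    ref = {"chrA": tg._seq.random_dna(40000, rng), "chrB": tg._seq.random_dna(15000, rng)}
    monomer = tg.build_monomer(seed=5)
    haps = {"hap1": ref, "hap2": ref}
    params = tg.ReadSimParams(coverage=20, substitution_error_rate=0.0, seed=3)
    r1, r2, meta = tg.simulate_read_arrays(haps, params)
    index = tg.build_index({**ref, "transgene_monomer": monomer.sequence}, k=31)
    paired = tg.map_pairs(r1, r2, index)
    return paired, meta, params


@pytest.fixture(scope="session")
def tiny_monomer():
    return tg.build_monomer(
        segment_spec=[("prom", 150), ("shared", 400), ("orf", 250), ("polyA", 100)],
        shared_segment="shared",
        marker_count=4,
        marker_spacing=60,
        seed=2,
    )
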