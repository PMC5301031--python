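import numpy as np
import pytest

from clonarch import (
    SimulationConfig,
    build_default_architecture,
    load_germline_v_references,
)


@pytest.fixture(scope="session")
def config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def tree(config):
    return build_default_architecture(config)


@pytest.fixture(scope="session")
def germline_refs():
    return load_germline_v_references()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_pileup_sites(rng, n):
    """Random pileup sites concentrated around the screening boundaries."""
    from clonarch import Effect, PileupSite

    sites = []
    for i in range(n):
        # mix tiny and large depths so every rule gets exercised
        depth = int(rng.choice([rng.integers(1, 25), rng.integers(25, 500)]))
        alt = int(rng.integers(0, depth + 1))
        alt_fwd = int(rng.integers(0, alt + 1))
        depth_fwd = alt_fwd + int(rng.integers(0, depth - alt + 1))
        sites.append(
            PileupSite(
                sample="s",
                contig="c",
                pos=i + 1,
                ref="A",
                alt="T",
                alt_fwd=alt_fwd,
                alt_rev=alt - alt_fwd,
                depth_fwd=depth_fwd,
                depth_rev=depth - depth_fwd,
                effect=Effect.synonymous if rng.random() < 0.2 else Effect.nonsynonymous,
                known_snp=bool(rng.random() < 0.2),
            )
        )
    return sites
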