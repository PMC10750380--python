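import numpy as np
import pytest

import diplochrom as dc


@pytest.fixture(scope="session")
def sizes():
    return {"chr1": 600_000, "chr2": 400_000}


@pytest.fixture(scope="session")
def model(sizes):
    """Small diploid model: 4 chains (30+30+20+20 beads) at 20 kbp."""
    return dc.GenomeModel.from_chrom_sizes(sizes, 20_000)


@pytest.fixture(scope="session")
def haploid_model(sizes):
    return dc.GenomeModel.from_chrom_sizes(sizes, 20_000, ploidy=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def recovery_fixture():
    """Haploid 3-chain mixed globule with dense unambiguous contacts.

    Session-scoped: several tests reuse the same ground truth and its
    derived contact list.
    """
    spec = dc.FixtureSpec(
        chrom_lengths={"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000},
        kind="confined_walk",
        ploidy=1,
        ambiguity=0.0,
        seed=5,
    )
    return dc.make_fixture(spec)


@pytest.fixture(scope="session")
def recovered_structure(recovery_fixture):
    """Lowest-energy reconstruction of the recovery fixture (3 runs)."""
    fix = recovery_fixture
    pairs = dc.build_bead_contacts(fix.records, fix.model).pair_array()
    results = [
        dc.minimize(fix.model, pairs, dc.make_schedule(), seed=s)
        for s in (7, 8, 9)
    ]
    best = min(results, key=lambda r: r.traces[-1].final_energy)
    return best, pairs
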