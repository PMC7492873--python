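import pytest

import plastcomp as pc


@pytest.fixture(scope="session")
def truth():
    """One synthetic plastome with planted structure, SSRs and genes."""
    return pc.generate_plastome(seed=7)


@pytest.fixture(scope="session")
def mutated_pair(truth):
    """Derived genome with 50 substitutions, a 6 bp in-frame CDS deletion and
    eight single-base intergenic deletions (14 gap columns in total)."""
    return pc.mutate_genome(
        truth, n_snp=50, indel_events=[(6, True)] + [(1, False)] * 8, seed=11
    )
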