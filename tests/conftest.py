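import pytest

from mybscope import domains, simulate


@pytest.fixture(scope="session")
def template():
    return simulate.CanonicalDomainTemplate()


@pytest.fixture(scope="session")
def profile(template):
    return domains.profile_from_template(template)


@pytest.fixture(scope="session")
def clean_family(template):
    """Zero-mutation family: 10 true members + 4 decoys of each kind."""
    spec = simulate.FamilySimSpec(n_true_r2r3=10, n_decoys_per_kind=4,
                                  mutation_rate=0.0, seed=42)
    return simulate.simulate_family(spec, template)


@pytest.fixture(scope="session")
def noisy_family(template):
    """100 true members + decoys at 5% substitution outside constraints."""
    spec = simulate.FamilySimSpec(n_true_r2r3=100, n_decoys_per_kind=10,
                                  mutation_rate=0.05, seed=7)
    return simulate.simulate_family(spec, template)


@pytest.fixture(scope="session")
def noisy_annotations(noisy_family, profile, template):
    seqs, _ = noisy_family
    return domains.annotate_all(seqs, profile, template)
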