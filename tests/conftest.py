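import pytest

import ty1kit as tk


@pytest.fixture(scope="session")
def small_genome():
    """2 identical full copies + 3 solo LTRs on one small chromosome."""
    model, seqs = tk.build_toy_genome(
        n_full=2, n_solo=3, element_len=5000, ltr_len=334, seed=1
    )
    return model, seqs


@pytest.fixture(scope="session")
def family_genome():
    """8 full copies + 6 solo LTRs; the scale used for profiling checks."""
    model, _ = tk.build_toy_genome(n_full=8, n_solo=6, seed=11)
    return model


@pytest.fixture(scope="session")
def family_control_track(family_genome):
    """Shared untagged-control pileup (100k uniform fragments) on family_genome."""
    ctrl = tk.simulate_control(family_genome, 100_000, seed=77)
    track, _ = tk.process_fragments(ctrl, family_genome, seed=78)
    return track
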