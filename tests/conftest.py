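import pytest

from spongeflow.pipeline import matched_desk_configs, run_case


@pytest.fixture(scope="session")
def desk_cases():
    """The matched desk-scale trio: isolated, in-line λ=D, side-by-side λ=D.

    One shared solve per layout at Re=100 in a common domain (identical
    blockage, body-1 position and outlet distance); every cross-run
    comparison test draws on these converged cases.
    """
    cfgs = matched_desk_configs(Re=100.0, seed=1)
    return {mode: run_case(cfg) for mode, cfg in cfgs.items()}
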