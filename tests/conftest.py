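import pytest

from replast import ModelParams, solve

GRID_PRIORS = (0.5, 0.7, 0.9)
GRID_RELIABILITIES = (0.55, 0.75, 0.95)


@pytest.fixture(scope="session")
def solved_cache():
    """Session-wide cache of solved policies keyed by ModelParams."""
    cache = {}

    def get(**kwargs):
        params = ModelParams.make(**kwargs)
        if params not in cache:
            cache[params] = solve(params)
        return cache[params]

    return get
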