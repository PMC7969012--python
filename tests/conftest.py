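import numpy as np
import pytest

from axiscorr.correlation import ScaledFragment, scale_series
from axiscorr.pipeline import scale_cohort
from axiscorr.simulate import generate_cohort


def make_scaled(values_s, values_r=None, **ids) -> ScaledFragment:
    """Scale raw vectors into a ScaledFragment (r defaults to s)."""
    s = scale_series(np.asarray(values_s, dtype=float))
    r = s if values_r is None else scale_series(np.asarray(values_r, dtype=float))
    return ScaledFragment(s=s, r=r, **ids)


def random_scaled_fragments(rng, n, min_len=3, max_len=12):
    """Random non-degenerate scaled fragments for oracle comparisons."""
    frags = []
    while len(frags) < n:
        L = int(rng.integers(min_len, max_len + 1))
        s = rng.normal(size=L)
        r = rng.normal(size=L)
        if s.std(ddof=1) == 0 or r.std(ddof=1) == 0:
            continue
        frags.append(
            ScaledFragment(s=scale_series(s), r=scale_series(r), fragment_id=f"f{len(frags)}")
        )
    return frags


def scaled_cohort(params, seed, n=500):
    """Generate and scale a synthetic cohort with one call."""
    profiles, _ = generate_cohort(params.replace(seed=seed), n)
    return scale_cohort(profiles, "platform", "focus")


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
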