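import numpy as np
import pytest

from npascore.contrasts import MatchedInput
from npascore.synthetic import SyntheticSpec, generate_contrast, generate_hyp, generate_universe


def matched(s, beta, sd=None, df=None, p=None, fdr=None, treated=None, control=None):
    """Build a MatchedInput from plain sequences (test helper)."""
    s = np.asarray(s, dtype=int)
    n = len(s)
    arr = lambda v: None if v is None else np.asarray(v, dtype=float)
    fdr = arr(fdr)
    return MatchedInput(
        genes=np.asarray([f"g{i}" for i in range(n)], dtype=object),
        s=s,
        beta=np.asarray(beta, dtype=float),
        sd=arr(sd),
        df=arr(df),
        p=arr(p),
        fdr=fdr,
        fndr=None if fdr is None else 1.0 - fdr,
        treated=arr(treated),
        control=arr(control),
    )


@pytest.fixture(scope="session")
def small_study():
    """A seeded synthetic study: universe, controller counts, HYP, contrast."""
    spec = SyntheticSpec(n_background=600, n_downstream=40, amplitude=1.0,
                         noise_sd=0.5, seed=11)
    universe, counts = generate_universe(spec)
    h = generate_hyp(spec, universe)
    c = generate_contrast(h, universe, spec)
    return spec, universe, counts, h, c
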