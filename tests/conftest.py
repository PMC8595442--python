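import numpy as np
import pytest

from nlcc.features import FeatureSet
from nlcc.trials import TrialTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gaussian_feature_world(
    rng, dim=5, n=50_000, ds=0.2, eps=0.0, s0=0.0
):
    """Linear-in-features Gaussian world with known signal and noise.

    Features R | s ~ N((s - s0) F', Gamma) at two stimulus levels
    s0 +/- ds/2, with an optional information-limiting component
    eps * F'F'^T folded into Gamma. Returns (Gamma0, Gamma, F', table,
    features).
    """
    A = rng.standard_normal((dim, dim))
    gamma0 = A @ A.T + 0.3 * np.eye(dim)
    fp = rng.standard_normal(dim)
    gamma = gamma0 + eps * np.outer(fp, fp)
    s = rng.choice([s0 - ds / 2, s0 + ds / 2], size=n)
    R = np.outer(s - s0, fp) + rng.multivariate_normal(
        np.zeros(dim), gamma, size=n
    )
    table = TrialTable(s=s, r=np.zeros((n, 1)))
    feats = FeatureSet(terms=[(i,) for i in range(dim)], values=R)
    return gamma0, gamma, fp, table, feats
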