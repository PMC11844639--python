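import numpy as np
import pandas as pd
import pytest

from crossprot.pqtl import CredibleSet


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_credible_set(members, lead, lead_p, probe="probe1", platform="A",
                      signal_index=0, kind="cis", betas=None):
    """Minimal valid credible set for unit tests."""
    pips = {m: 1.0 / len(members) for m in members}
    betas = betas or {m: 0.5 for m in members}
    return CredibleSet(
        probe_id=probe, platform=platform, signal_index=signal_index, kind=kind,
        members=list(members), pips=pips, lead=lead,
        lead_beta=betas[lead], lead_se=0.1, lead_p=lead_p, significant=True,
        member_betas=betas, member_ps={m: lead_p for m in members},
    )


@pytest.fixture()
def small_genotypes():
    """Five variants with controlled LD: v1~v2 highly correlated, rest independent."""
    rng = np.random.default_rng(7)
    n = 400
    g1 = rng.binomial(2, 0.3, n).astype(float)
    noise = rng.binomial(2, 0.3, n).astype(float)
    g2 = np.where(rng.uniform(size=n) < 0.9, g1, noise)  # r^2 ~ 0.8 with g1
    g3 = rng.binomial(2, 0.4, n).astype(float)
    g4 = rng.binomial(2, 0.25, n).astype(float)
    g5 = rng.binomial(2, 0.5, n).astype(float)
    return pd.DataFrame({"v1": g1, "v2": g2, "v3": g3, "v4": g4, "v5": g5})
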