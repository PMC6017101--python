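import numpy as np
import pytest

from combindex import MedianEffectResults

# Published single-agent median-effect parameters (Dm mg/mL, m, SE of m)
# for the phospholipase-A2 inhibition panel; used as generator truths and
# as inputs to worked examples.
REFERENCE_PARAMS = {
    "bromelain": (0.0723, 0.6767, 0.0450),
    "amenthoflavone": (0.1079, 0.4480, 0.0489),
    "asiaticoside": (0.3143, 0.5258, 0.0381),
    "diosgenin": (0.9659, 0.7018, 0.0229),
}


def ref_fit(agent: str) -> MedianEffectResults:
    """A MedianEffectResults carrying the published (Dm, m) for an agent."""
    dm, m, m_se = REFERENCE_PARAMS[agent]
    return MedianEffectResults(
        agent_id=agent, dm=dm, m=m, r=1.0, m_se=m_se,
        intercept=-m * np.log10(dm), intercept_se=0.0, n_used=5)


@pytest.fixture
def bromelain_fit() -> MedianEffectResults:
    return ref_fit("bromelain")


@pytest.fixture
def amenthoflavone_fit() -> MedianEffectResults:
    return ref_fit("amenthoflavone")


@pytest.fixture
def asiaticoside_fit() -> MedianEffectResults:
    return ref_fit("asiaticoside")
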