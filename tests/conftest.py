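import pytest
from hypothesis import HealthCheck, settings

import fapindex as fx

settings.register_profile(
    "derandomized",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def lib():
    return fx.builtin_library()


@pytest.fixture(scope="session")
def profiles():
    return fx.builtin_profiles()


@pytest.fixture(scope="session")
def ref_anchors():
    return fx.FAPAnchorSet(fx.reference_anchor_times())


@pytest.fixture(scope="session")
def four_oils(lib, profiles):
    """Noise-free synthetic runs of the four oils with annotations (shared)."""
    out = {}
    for oil, prof in profiles.items():
        chrom, truth = fx.generate_run(prof, noise=0.0, seed=11)
        anchors = fx.extract_fap_anchors(chrom)
        annotations = fx.annotate_run(chrom, anchors, lib)
        out[oil] = {"profile": prof, "chrom": chrom, "truth": truth,
                    "anchors": anchors, "annotations": annotations}
    return out
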