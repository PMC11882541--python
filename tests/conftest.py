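import numpy as np
import pytest

from crmscreen import motif_scan as ms
from crmscreen import mutagenesis as mut
from crmscreen.synthetic_data import (
    ETS_SYN_COUNTS,
    TCF_SYN_COUNTS,
    LocusConfig,
    synth_locus,
)


@pytest.fixture(scope="session")
def ets_pwm():
    return ms.pwm_from_counts(ETS_SYN_COUNTS, name="ETS_SYN")


@pytest.fixture(scope="session")
def tcf_pwm():
    return ms.pwm_from_counts(TCF_SYN_COUNTS, name="TCF_SYN")


@pytest.fixture(scope="session")
def pwm_set(ets_pwm, tcf_pwm):
    return [ets_pwm, tcf_pwm]


@pytest.fixture(scope="session")
def enzymes():
    return [
        mut.RestrictionEnzyme(n, r)
        for n, r in [
            ("EcoRI", "GAATTC"),
            ("BamHI", "GGATCC"),
            ("HindIII", "AAGCTT"),
            ("XhoI", "CTCGAG"),
            ("NotI", "GCGGCCGC"),
        ]
    ]


@pytest.fixture(scope="session")
def locus1():
    """Default synthetic locus, seed 1 (in-memory)."""
    return synth_locus(LocusConfig(), seed=1)


@pytest.fixture(scope="session")
def locus1_dir(tmp_path_factory):
    """Default synthetic locus, seed 1, written to disk with its manifest."""
    d = tmp_path_factory.mktemp("locus1")
    synth_locus(LocusConfig(), seed=1, outdir=d)
    return d


def random_pwm(rng: np.random.Generator, length: int, uniform_bg: bool = True) -> ms.PWM:
    counts = rng.integers(0, 30, size=(4, length))
    counts[rng.integers(0, 4), counts.sum(axis=0) == 0] = 1  # no all-zero column
    if uniform_bg:
        bg = np.full(4, 0.25)
    else:
        bg = rng.dirichlet(np.full(4, 5.0))
    return ms.pwm_from_counts(counts, background=bg, name=f"rand{length}")
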