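import numpy as np
import pytest
from hypothesis import settings

from twinchol.core import Individual, PhenotypeSchema, TwinPairRecord, Zygosity

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_individual(pid, fid, zyg, phenotypes=None, onsets=None):
    phenotypes = dict(phenotypes or {})
    onsets = dict(onsets or {})
    for k in phenotypes:
        onsets.setdefault(k, None)
    return Individual(
        person_id=pid,
        family_id=fid,
        zygosity=zyg,
        phenotypes=phenotypes,
        onset_ages=onsets,
    )


def make_pair(fid, zyg, phen1, phen2=None, onsets1=None, onsets2=None):
    t1 = make_individual(f"{fid}_1", fid, zyg, phen1, onsets1)
    t2 = None
    if phen2 is not None:
        t2 = make_individual(f"{fid}_2", fid, zyg, phen2, onsets2)
    return TwinPairRecord(fid, zyg, t1, t2)


@pytest.fixture
def binary_schema():
    return [PhenotypeSchema("affected", "binary")]


@pytest.fixture
def small_cohort():
    """Two families: one complete MZ pair, one DZ singleton."""
    return [
        make_pair("F1", Zygosity.MZ, {"affected": 1}, {"affected": 0},
                  onsets1={"affected": 18}),
        make_pair("F2", Zygosity.DZ, {"affected": 1}, None,
                  onsets1={"affected": None}),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
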