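import numpy as np
import pytest

from cryptobee import simulate_specimens
from cryptobee.morphometrics import HairProfile, SpecimenRecord


def make_record(rid="B1", mr1=1.4, mr3=1.8, mrl=0.9, species="unknown",
                caste="worker", region="Midwest", **kw):
    """Build a record whose computed ratios equal (mr1, mr3, mrl) exactly
    by anchoring malar width at one reticle unit."""
    return SpecimenRecord(
        id=rid, species_dna=species, caste=caste, region=region,
        malar_length=mrl, malar_width=1.0,
        flag1_length=mrl / mr1, flag3_length=mrl / mr3, **kw,
    )


def gaussian_class_records(rng, n_a, n_b, mean_a, mean_b, sd_a, sd_b,
                           measurement="mrl", caste="worker"):
    """Two-class 1-D fixture on one ratio; other ratios held constant."""
    out = []
    for label, n, mu, sd in (("sandersoni", n_a, mean_a, sd_a),
                             ("vagans", n_b, mean_b, sd_b)):
        for i, v in enumerate(rng.normal(mu, sd, size=n)):
            kw = {"mr1": 1.4, "mr3": 1.8, "mrl": 0.9, measurement: float(abs(v))}
            out.append(make_record(rid=f"{label[:1]}{i:03d}", species=label,
                                   caste=caste, **kw))
    return out


@pytest.fixture(scope="session")
def default_records():
    return simulate_specimens(seed=0)


@pytest.fixture(scope="session")
def worker_pair(default_records):
    return [r for r in default_records
            if r.caste == "worker" and r.species_dna in ("sandersoni", "vagans")]


@pytest.fixture(scope="session")
def queen_pair(default_records):
    return [r for r in default_records
            if r.caste == "queen" and r.species_dna in ("sandersoni", "vagans")]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
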