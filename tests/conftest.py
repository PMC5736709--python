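import numpy as np
import pytest

from sbs.msa import Alignment
from sbs.hmm import build_profile
from sbs.phylo.ratemodel import default_model
from sbs.simulate import gen_families, gen_family


@pytest.fixture(scope="session")
def wag():
    return default_model()


@pytest.fixture(scope="session")
def family_sim():
    """Two divergent domain families (canonical-like / Vibrio-like)."""
    return gen_families(
        n_per_family=8, n_columns=200, within_identity=0.45,
        between_identity=0.17, seed=1,
    )


@pytest.fixture(scope="session")
def seed_families(family_sim):
    fams = dict(family_sim.families)
    fams["gh33"] = gen_family("gh33", n_seqs=8, n_columns=180, seed=11)
    fams["decoy"] = gen_family("decoy", n_seqs=8, n_columns=160, seed=12)
    return fams


@pytest.fixture(scope="session")
def models(seed_families, family_sim):
    out = {
        kind: build_profile(Alignment(recs), name=kind)
        for kind, recs in seed_families.items()
    }
    out["combined"] = build_profile(Alignment(family_sim.pooled), name="combined")
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
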