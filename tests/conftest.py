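import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bvf.formats_io import AnnotatedVariant
from bvf.simbulk import SimScenario, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Compact scenario for tests that only need a valid experiment, not the
#: default problem size: 200 kb genome, 20 genes, 60 background variants.
SMALL = dict(
    genome_length=200_000,
    n_genes=20,
    n_background_variants=60,
    causal_gene_index=10,
)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(SimScenario(seed=11, **SMALL))


@pytest.fixture(scope="session")
def default_sim():
    return simulate(SimScenario(seed=7))


def make_variant(
    chrom="Chr01",
    pos=100,
    ref="A",
    alt="T",
    qd=30.0,
    gq=99,
    dp=30,
    ad_ref=0,
    ad_alt=30,
    effects=(("missense_variant", "GENE1", "GENE1.1"),),
):
    return AnnotatedVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, qd=qd, gq=gq, dp=dp,
        ad_ref=ad_ref, ad_alt=ad_alt, effects=tuple(effects),
    )


def random_variants(n, seed, with_missing_fields=True):
    """Randomized variant fixture with occasional absent quality fields."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        dp = int(rng.integers(0, 60))
        ad_alt = int(rng.integers(0, dp + 1))
        v = make_variant(
            pos=int(10 + i * 13 + rng.integers(0, 5)),
            qd=None if with_missing_fields and rng.random() < 0.1
            else float(rng.uniform(0, 40)),
            gq=None if with_missing_fields and rng.random() < 0.1
            else int(rng.integers(0, 100)),
            dp=dp,
            ad_ref=dp - ad_alt,
            ad_alt=ad_alt,
        )
        out.append(v)
    return out
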