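import numpy as np
import pandas as pd
import pytest

from vcgh.core import GenomeAnnotation
from vcgh.simulate import ChromSpec, CohortConfig, Hotspot, generate


@pytest.fixture
def ann10() -> GenomeAnnotation:
    """10 probes: chr1 has 6 (bands p1, q1), chr2 has 4 (bands p1, q1)."""
    rows = []
    for chrom, n in (("chr1", 6), ("chr2", 4)):
        for i in range(n):
            rows.append({
                "probe_id": f"{chrom}_g{i}",
                "chrom": chrom,
                "start": i * 1000,
                "end": i * 1000 + 500,
                "cytoband": "p1" if i < n // 2 else "q1",
            })
    return GenomeAnnotation(pd.DataFrame(rows))


def small_config(seed: int = 7, **overrides) -> CohortConfig:
    """A compact two-chromosome cohort for fast unit tests."""
    kwargs = dict(
        n_samples=30,
        chromosomes=[ChromSpec("chr1", 100, 20), ChromSpec("chr2", 100, 20)],
        hotspots=[Hotspot("chr1", "+", 1, 2, 0.3),
                  Hotspot("chr2", "-", 2, 3, 0.3)],
        segment_jitter_probes=5,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return generate(small_config())


def random_params(rng: np.random.Generator, chrom: str = "chrT"):
    """Random strictly positive HMM parameters (Dirichlet rows)."""
    from vcgh.hmm import HmmParams, N_STATES
    return HmmParams(
        chrom=chrom,
        initial=rng.dirichlet(np.ones(N_STATES)),
        transition=rng.dirichlet(np.ones(N_STATES), size=N_STATES),
    )
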