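import numpy as np
import pytest

from ipscnv.probes import ProbeMap
from ipscnv.simulate import (ControlLocusSpec, HotspotSpec, PolymorphicSpec,
                             SimConfig)


def small_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """A desk-scale cohort (fast to generate) with the same planted structure
    as the default study layout."""
    cfg = SimConfig(
        seed=seed,
        genome=(("chr1", 20_000_000, 5000), ("chr2", 20_000_000, 5000),
                ("chrX", 10_000_000, 5000)),
        n_donors=24,
        clones_per_donor=1,
        female_donors=12,
        n_controls=150,
        female_controls=75,
        inherited_rate=1.0,
        de_novo_rate=1.0,
        hotspots=(
            HotspotSpec("chr1", 2_000_000, 2_200_000, 0.45),
            HotspotSpec("chr2", 5_000_000, 5_300_000, 0.40),
            HotspotSpec("chrX", 3_000_000, 3_200_000, 0.50, restrict_sex="female"),
        ),
        polymorphic=(
            PolymorphicSpec("chr1", 8_000_000, 8_250_000, 0.25, 0.25),
            PolymorphicSpec("chr2", 12_000_000, 12_200_000, 0.25, 0.25),
        ),
        control_loci=(
            ControlLocusSpec("chr1", 15_000_000, 15_200_000, 0.05),
            ControlLocusSpec("chr2", 2_000_000, 2_150_000, 0.04),
        ),
    )
    for k, v in overrides.items():
        object.__setattr__(cfg, k, v) if False else setattr(cfg, k, v)
    return cfg


@pytest.fixture
def small_config():
    return small_sim_config()


def uniform_probe_map(n_probes: int = 200, spacing: int = 10_000,
                      chroms=("chr1",)) -> ProbeMap:
    ids = {}
    pos = {}
    for chrom in chroms:
        p = np.arange(spacing, (n_probes + 1) * spacing, spacing, dtype=np.int64)
        pos[chrom] = p
        ids[chrom] = np.array([f"{chrom}_{i}" for i in range(n_probes)],
                              dtype=object)
    return ProbeMap(list(chroms), ids, pos)
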