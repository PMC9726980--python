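import numpy as np
import pytest

from cloneweave.simulate import SimulationConfig, simulate_patient
from cloneweave.variants import MutationRecord, RegionSample


@pytest.fixture
def three_regions():
    return [
        RegionSample("P1", "oesophagus", f"P1_R{i}", purity=p, carcinoma_content=c)
        for i, (p, c) in enumerate(
            [(0.6, 0.7), (0.5, 0.55), (0.8, 0.9)], start=1
        )
    ]


@pytest.fixture
def small_records(three_regions):
    """Three hand-written mutations with simple per-region support."""
    rids = [r.region_id for r in three_regions]

    def rec(pos, ref, alt, fclass, counts, channel=None):
        return MutationRecord(
            patient_id="P1",
            chrom="1",
            pos=pos,
            ref=ref,
            alt=alt,
            gene=f"G{pos}",
            functional_class=fclass,
            channel96=channel,
            per_region=dict(zip(rids, counts)),
        )

    return [
        rec(100, "C", "A", "nonsynonymous", [(30, 60), (25, 50), (40, 80)], channel=5),
        rec(200, "T", "G", "synonymous", [(10, 70), (0, 66), (0, 71)], channel=95),
        rec(300, "AT", "A", "frameshift_indel", [(0, 80), (12, 60), (15, 75)]),
    ]


@pytest.fixture(scope="session")
def sim_patient():
    """One deterministic simulated multi-region tumour (shared across tests)."""
    cfg = SimulationConfig(depth_mean=150, seed=0)
    return cfg, simulate_patient(cfg, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
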