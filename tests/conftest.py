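import numpy as np
import pandas as pd
import pytest

from popeqtl.simulate import PlantedEQTL, SimulationConfig


@pytest.fixture
def small_config():
    """Tiny two-population cohort with one planted eQTL."""
    return SimulationConfig(
        populations={"P1": 30, "P2": 20},
        n_genes=10,
        n_snps=8,
        planted_eqtls=[PlantedEQTL("rs_planted", "geneX", 0.5, {"P1": 0.9, "P2": 0.3})],
        seed=7,
    )


def make_samples(rows):
    """Metadata frame from (sample_id, population, age, stage[, subtype]) tuples."""
    recs = []
    for r in rows:
        rec = dict(sample_id=r[0], population=r[1], age=r[2], stage=r[3])
        rec["subtype"] = r[4] if len(r) > 4 else "LA"
        rec["condition"] = "tumor"
        recs.append(rec)
    return pd.DataFrame(recs)
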