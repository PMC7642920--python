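import numpy as np
import pandas as pd
import pytest

from seedqtl.simdata import (
    HotspotSpec,
    SimConfig,
    simulate_expression,
    simulate_marker_map,
    simulate_ril_genotypes,
)


@pytest.fixture(scope="session")
def small_study():
    """One subpopulation with planted local eQTLs and one hotspot regulator."""
    cfg = SimConfig(
        n_lines=40, n_genes=200, n_markers=150, local_fraction=0.2,
        local_r2=0.4, seed=42,
        hotspot_spec=(HotspotSpec("5", 24_500_000, 30, target_effect=1.3),),
    )
    rng = np.random.default_rng(cfg.seed)
    mmap = simulate_marker_map(cfg, rng)
    geno = simulate_ril_genotypes(mmap, cfg, rng)
    expr, genes, truth = simulate_expression(geno, mmap, cfg, rng)
    return {"cfg": cfg, "marker_map": mmap, "genotypes": geno,
            "expression": expr, "genes": genes, "truth": truth}


@pytest.fixture()
def toy_scan_inputs():
    """Four lines, one marker with a clean A/A/B/B split."""
    expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g1"],
                        columns=["l1", "l2", "l3", "l4"])
    geno = pd.DataFrame({"m1": ["A", "A", "B", "B"]},
                        index=["l1", "l2", "l3", "l4"])
    mmap = pd.DataFrame({"chromosome": ["1"], "position_bp": [500_000]},
                        index=pd.Index(["m1"], name="marker"))
    return expr, geno, mmap
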