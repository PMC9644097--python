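import numpy as np
import pandas as pd
import pytest

import evcargo as ev


@pytest.fixture(scope="session")
def small_cohort():
    """Compact no-effect cohort shared by read-only tests."""
    cfg = ev.SimulationConfig(
        n_hc=6, n_responders=4, n_nonresponders=6,
        library_size_mean=5e4,
        n_features_per_biotype={b: 30 for b in ev.BIOTYPES},
        seed=11,
    )
    return ev.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def marker_cohort():
    """Study-shaped cohort with six planted non-responder markers."""
    markers = [
        ev.PlantedMarker(f"mk{i}", "miRNA", carrier_groups=("NR",),
                         carrier_fraction=0.3,
                         active_timepoints=("Dg", "NAC"))
        for i in range(6)
    ]
    cfg = ev.SimulationConfig(library_size_mean=2e5, seed=5,
                              planted_markers=markers)
    return ev.simulate_cohort(cfg)


@pytest.fixture
def toy_catalog():
    """Overlapping features exercising the priority hierarchy."""
    feats = [
        ev.Feature("mir1", "miRNA", "chr1", 100, 122, "+"),
        ev.Feature("lnc1", "lncRNA", "chr1", 50, 550, "+"),
        ev.Feature("sno1", "snoRNA", "chr1", 600, 700, "+"),
        ev.Feature("pir1", "piRNA", "chr1", 620, 650, "+"),
        ev.Feature("mir2", "miRNA", "chr2", 0, 22, "-"),
    ]
    return ev.FeatureCatalog(feats)
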