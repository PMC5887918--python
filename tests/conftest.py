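import numpy as np
import pandas as pd
import pytest

import dietlink as dl


@pytest.fixture(scope="session")
def small_db() -> dl.BarcodeDB:
    """Six prey taxa + two predators + one contaminant, two haplotypes each."""
    return dl.generate_reference_db(
        6, haplotypes_per_taxon=2, between_taxon_divergence=0.10, within_taxon_divergence=0.01, seed=1
    )


@pytest.fixture(scope="session")
def abundance_row() -> pd.Series:
    return pd.Series({f"prey{i + 1:02d}": float(c) for i, c in enumerate([120, 80, 60, 150, 40, 90])})


@pytest.fixture(scope="session")
def error_free_run(small_db, abundance_row):
    """Guts + error-free reads + processed detections, shared across tests."""
    guts_a = dl.simulate_guts(abundance_row, "predatorA", 12, seed=21, site_id="site01")
    guts_b = dl.simulate_guts(abundance_row, "predatorB", 12, seed=22, site_id="site01")
    guts = guts_a + guts_b
    batch = dl.simulate_reads(guts, small_db, reads_per_gut=80, seed=23)
    detections, t_opt, diagnostics = dl.process_reads(batch, small_db)
    return {"guts": guts, "batch": batch, "detections": detections, "t_opt": t_opt, "diagnostics": diagnostics}


@pytest.fixture(scope="session")
def diet_matrix(error_free_run, small_db) -> dl.DietMatrix:
    guts = error_free_run["guts"]
    meta = pd.DataFrame(
        {
            "predator_species": [g.predator_species for g in guts],
            "site_id": [g.site_id for g in guts],
            "season": [g.season for g in guts],
        },
        index=[g.individual_id for g in guts],
    )
    rank_map = {t: t for t in small_db.taxa}
    return dl.build_diet_matrix(error_free_run["detections"], rank_map, meta)
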