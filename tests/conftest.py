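"""Shared fixtures: small simulated panels reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import growthgwas as gg


@pytest.fixture(scope="session")
def small_panel():
    """150-genotype, 440-marker panel with 3 pools and default LD contrast."""
    cfg = gg.SimConfig(n_genotypes=150, n_snp=400, n_cnv=40, seed=1)
    panel, truth = gg.simulate_genotypes(cfg)
    return panel, truth, cfg


@pytest.fixture(scope="session")
def filtered_panel(small_panel):
    panel, truth, cfg = small_panel
    filt, log = gg.filter_markers(panel)
    imputed, zero_var = gg.impute_for_scan(filt)
    pcs = gg.compute_pcs(imputed, k=10)
    return filt, imputed, zero_var, pcs


@pytest.fixture(scope="session")
def biomass_mta():
    return gg.examples.load_biomass_mta()


@pytest.fixture(scope="session")
def candidate_regions():
    return gg.examples.load_candidate_regions()


def make_series(values_by_day: dict, genotypes: list[str],
                experiment: str = "E0") -> pd.DataFrame:
    """Small long-format phenotype series builder for hand-crafted tests."""
    rows = []
    for day, values in values_by_day.items():
        for g, v in zip(genotypes, values):
            rows.append({
                "genotype": g, "experiment": experiment, "carrier": f"{experiment}-{g}",
                "day": day,
                "timestamp": pd.Timestamp("2014-03-01") + pd.Timedelta(days=day, hours=8),
                "trait": "trait", "value": v, "is_check": False, "position": "P1",
            })
    return pd.DataFrame(rows)
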