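"""Bundled worked-example data.

Two small published-results tables from a canola (Brassica napus) early-growth
association study ship with the package: the end-point biomass marker-trait
associations (22 records for fresh and dry weight) and the five candidate
regions around markers with temporally dynamic associations. They drive the
worked examples and the cross-trait / interval arithmetic checks.

The dosage panels returned by :func:`flank_region_panel` and
:func:`ld_block_region_panel` are synthetic stand-ins: the focal marker ids,
focal positions and interval endpoints are the published values, while the
dosage vectors and the intermediate block-member positions (not published)
are constructed so the printed LD-block topology is reproduced exactly.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .markerqc import MarkerPanel


def _load(name: str) -> pd.DataFrame:
    with resources.files("growthgwas.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_biomass_mta() -> pd.DataFrame:
    """End-point biomass MTA table (fresh and dry weight, FDR <= 0.1)."""
    return _load("endpoint_biomass_mta.tsv")


def load_candidate_regions() -> pd.DataFrame:
    """Candidate-region table (five intervals around dynamic markers)."""
    return _load("candidate_regions.tsv")


def _panel(marker_ids, positions, chromosome, dosages) -> MarkerPanel:
    markers = pd.DataFrame({
        "marker_id": marker_ids,
        "chromosome": chromosome,
        "position": positions,
        "marker_class": "SNP",
    })
    dosages = np.asarray(dosages, dtype=float)
    genotypes = [f"G{i:02d}" for i in range(dosages.shape[1])]
    return MarkerPanel(markers=markers, dosages=dosages,
                       genotypes=genotypes).with_stats()


def flank_region_panel() -> tuple[MarkerPanel, str]:
    """Synthetic panel around the A04 focal marker with no LD block.

    The focal marker sits at A04:2,103,821; both neighbours are uncorrelated
    (r^2 < 0.6), so the candidate interval falls back to the 100-kb flank
    rule: [2,003,821, 2,203,821], 200,000 bp.
    """
    rng = np.random.default_rng(11)
    n = 24
    focal = rng.integers(0, 3, n).astype(float)
    left = rng.permutation(focal)
    right = rng.integers(0, 3, n).astype(float)
    panel = _panel(
        ["neigh-left", "Bn-A04-p2218115", "neigh-right"],
        [1_900_000, 2_103_821, 2_300_000],
        "A04",
        np.vstack([left, focal, right]),
    )
    return panel, "Bn-A04-p2218115"


def ld_block_region_panel() -> tuple[MarkerPanel, str]:
    """Synthetic panel around the C08 focal marker with a five-member block.

    The focal marker at C08:40,120,568 forms an LD block (r^2 >= 0.6 with the
    focal marker) with four neighbours; the nearest unrelated markers sit at
    39,843,456 and 40,211,817, so the block interval spans 368,361 bp.
    """
    rng = np.random.default_rng(7)
    n = 48
    focal = np.tile([0.0, 1.0, 2.0], n // 3)

    def correlated(x, n_flips):
        y = x.copy()
        idx = rng.choice(len(x), size=n_flips, replace=False)
        y[idx] = rng.integers(0, 3, n_flips)
        return y

    members = [correlated(focal, 6) for _ in range(4)]
    unrelated = [rng.permutation(focal), rng.permutation(focal)]
    ids = ["unrel-left", "blk-1", "blk-2", "Bn-scaff_16361_1-p2350469",
           "blk-3", "blk-4", "unrel-right"]
    positions = [39_843_456, 40_090_000, 40_105_000, 40_120_568,
                 40_150_000, 40_190_000, 40_211_817]
    dosages = np.vstack([unrelated[0], members[0], members[1], focal,
                         members[2], members[3], unrelated[1]])
    panel = _panel(ids, positions, "C08", dosages)
    return panel, "Bn-scaff_16361_1-p2350469"
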