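"""Pairwise LD, subgenome decay fits, candidate intervals and gene overlap.

LD between two markers is the squared Pearson correlation of their dosage
vectors over genotypes non-missing at both (composite LD on unphased
dosages). Decay with physical distance is fitted per subgenome with the
Hill-Weir expectation for r^2 under drift-recombination equilibrium,

    E[r^2] = (10 + C) / ((2 + C)(11 + C))
             * (1 + (3 + C)(12 + 12C + C^2) / (n (2 + C)(11 + C))),

with C = rho * distance and n the sample size; the half-decay distance is
where the fitted curve reaches half its value at distance zero.

The candidate interval around a significant focal marker is the LD block —
the maximal contiguous run of markers containing the focal marker whose
members all have r^2 >= 0.6 with it — extended to the nearest flanking
markers outside the block; if no block exists (block of size one), a fixed
100-kb flank on either side is used instead. Genes overlapping the interval
by >= 1 bp (1-based inclusive coordinates) are the candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .markerqc import MarkerPanel


@dataclass
class LdMatrix:
    chromosome: str
    marker_ids: list[str]
    positions: np.ndarray
    r2: np.ndarray  # symmetric, diagonal 1, NaN for untestable pairs


@dataclass
class LdDecayFit:
    subgenome: str
    rho: float  # per-bp recombination-scale parameter (C = rho * distance)
    n: int  # sample size used in the expectation
    half_decay_bp: float
    converged: bool = True
    binned: pd.DataFrame | None = None


@dataclass
class CandidateInterval:
    focal_marker: str
    chromosome: str
    start: int
    stop: int
    method: str  # "LD-block" or "flank"
    block_members: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.stop - self.start


# ---------------------------------------------------------------------------
# pairwise LD
# ---------------------------------------------------------------------------

def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over entries non-missing in both vectors."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return np.nan
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_matrix(panel: MarkerPanel, chromosome: str) -> LdMatrix:
    """Symmetric r^2 matrix for all markers on one chromosome.

    Monomorphic pairs get NaN; the diagonal of polymorphic markers is 1.
    """
    mask = panel.markers["chromosome"] == chromosome
    if mask.sum() < 2:
        raise ValueError(f"need >= 2 markers on {chromosome}")
    sub = panel.markers.loc[mask]
    D = panel.dosages[mask.to_numpy()]
    m = D.shape[0]

    if not np.isnan(D).any():
        sd = D.std(axis=1)
        poly = sd > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.corrcoef(D) ** 2
        r2[~poly, :] = np.nan
        r2[:, ~poly] = np.nan
    else:
        r2 = np.full((m, m), np.nan)
        for i in range(m):
            r2[i, i] = pairwise_r2(D[i], D[i])
            for j in range(i + 1, m):
                r2[i, j] = r2[j, i] = pairwise_r2(D[i], D[j])
    np.fill_diagonal(r2, np.where(np.isnan(np.diag(r2)), np.nan, 1.0))
    return LdMatrix(chromosome, sub["marker_id"].tolist(),
                    sub["position"].to_numpy(), r2)


# ---------------------------------------------------------------------------
# decay fitting
# ---------------------------------------------------------------------------

def hill_weir_expectation(distance: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Expected r^2 at a physical distance for sample size n."""
    C = rho * np.asarray(distance, dtype=float)
    lead = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    corr = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
    return lead * corr


def _subgenome_pairs(panel: MarkerPanel, subgenome: str,
                     max_distance: float) -> tuple[np.ndarray, np.ndarray]:
    """Pool (distance, r^2) pairs over all chromosomes of a subgenome."""
    chroms = [c for c in pd.unique(panel.markers["chromosome"])
              if str(c).startswith(subgenome)]
    dists, r2s = [], []
    for chrom in chroms:
        if (panel.markers["chromosome"] == chrom).sum() < 2:
            continue
        ld = ld_matrix(panel, chrom)
        iu = np.triu_indices(len(ld.marker_ids), k=1)
        d = np.abs(ld.positions[iu[0]] - ld.positions[iu[1]]).astype(float)
        r2 = ld.r2[iu]
        ok = ~np.isnan(r2) & (d <= max_distance)
        dists.append(d[ok])
        r2s.append(r2[ok])
    if not dists:
        raise ValueError(f"no marker pairs for subgenome {subgenome!r}")
    return np.concatenate(dists), np.concatenate(r2s)


def fit_ld_decay(panel: MarkerPanel, subgenome: str,
                 max_distance: float = 2.5e7,
                 n: int | None = None) -> LdDecayFit:
    """Nonlinear least-squares Hill-Weir fit of r^2 decay for one subgenome."""
    dist, r2 = _subgenome_pairs(panel, subgenome, max_distance)
    if n is None:
        n = panel.n_genotypes

    if np.ptp(dist) == 0:  # degenerate: a single distance observed
        return LdDecayFit(subgenome, rho=0.0, n=n, half_decay_bp=np.inf,
                          converged=False,
                          binned=pd.DataFrame({"distance": [dist[0]],
                                               "mean_r2": [r2.mean()]}))

    def model(d, log_rho):
        return hill_weir_expectation(d, np.exp(log_rho), n)

    try:
        popt, _ = optimize.curve_fit(model, dist, r2, p0=[np.log(2.0 / dist.mean())],
                                     maxfev=10000)
        rho = float(np.exp(popt[0]))
        converged = True
    except RuntimeError:
        warnings.warn(f"Hill-Weir fit did not converge for subgenome {subgenome}; "
                      "reporting empirical binned decay")
        rho, converged = np.nan, False

    bins = np.quantile(dist, np.linspace(0, 1, 21))
    idx = np.clip(np.searchsorted(bins, dist, side="right") - 1, 0, 19)
    binned = pd.DataFrame({"distance": [dist[idx == b].mean() for b in range(20)],
                           "mean_r2": [r2[idx == b].mean() for b in range(20)]})
    if not converged:
        return LdDecayFit(subgenome, rho, n, np.nan, converged, binned)

    r2_at_zero = hill_weir_expectation(np.array([0.0]), rho, n)[0]
    target = r2_at_zero / 2.0

    def gap(d):
        return hill_weir_expectation(np.array([d]), rho, n)[0] - target

    upper = 1e12
    half = float(optimize.brentq(gap, 1e-6, upper))
    return LdDecayFit(subgenome, rho, n, half, converged, binned)


# ---------------------------------------------------------------------------
# candidate intervals
# ---------------------------------------------------------------------------

def define_interval(focal_marker: str, panel: MarkerPanel,
                    ld: LdMatrix | None = None, r2_threshold: float = 0.6,
                    flank: int = 100_000) -> CandidateInterval:
    """Candidate interval around a significant focal marker.

    The LD block is the maximal contiguous marker run containing the focal
    marker in which every member has r^2 >= ``r2_threshold`` with the focal
    marker. With >= 2 members the interval runs from the nearest marker
    immediately left of the block to the nearest marker immediately right of
    it (the flanking "unrelated" markers), truncated to block edge +/- flank
    at chromosome ends; otherwise the interval is the +/- ``flank`` window
    around the focal position, clamped at 1.
    """
    rows = panel.markers.index[panel.markers["marker_id"] == focal_marker]
    if not len(rows):
        raise KeyError(f"marker {focal_marker!r} not in panel")
    chrom = panel.markers.loc[rows[0], "chromosome"]
    if ld is None:
        ld = ld_matrix(panel, chrom)
    fi = ld.marker_ids.index(focal_marker)
    r2_focal = ld.r2[fi]
    if np.isnan(r2_focal[fi]):
        raise ValueError(f"focal marker {focal_marker!r} is monomorphic")

    in_block = np.nan_to_num(r2_focal, nan=-1.0) >= r2_threshold
    left = fi
    while left - 1 >= 0 and in_block[left - 1]:
        left -= 1
    right = fi
    while right + 1 < len(in_block) and in_block[right + 1]:
        right += 1

    pos = ld.positions
    if right > left:  # a real block: extend to nearest unrelated markers
        start = int(pos[left - 1]) if left - 1 >= 0 else max(1, int(pos[left]) - flank)
        stop = (int(pos[right + 1]) if right + 1 < len(pos)
                else int(pos[right]) + flank)
        return CandidateInterval(
            focal_marker, str(chrom), start, stop, method="LD-block",
            block_members=[ld.marker_ids[j] for j in range(left, right + 1)])
    focal_pos = int(pos[fi])
    return CandidateInterval(focal_marker, str(chrom),
                             max(1, focal_pos - flank), focal_pos + flank,
                             method="flank")


# ---------------------------------------------------------------------------
# gene annotation and overlap
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["gene_id", "chromosome", "start", "stop", "function"]


def read_annotation(path) -> pd.DataFrame:
    """Gene annotation from GFF3 (gene features) or tabular TSV.

    The TSV dialect has columns chromosome, start, stop, gene_id[, function].
    """
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                rows.append((attrs.get("ID", f"{f[0]}:{f[3]}"), f[0],
                             int(f[3]), int(f[4]), attrs.get("Note", "")))
        return pd.DataFrame(rows, columns=GENE_COLUMNS)
    tab = pd.read_csv(path, sep="\t")
    if "function" not in tab.columns:
        tab["function"] = ""
    return tab[["gene_id", "chromosome", "start", "stop", "function"]]


def genes_in_interval(interval: CandidateInterval,
                      annotation: pd.DataFrame) -> pd.DataFrame:
    """Genes overlapping [start, stop] by >= 1 bp, 1-based inclusive, by start.

    A gene ending exactly at the interval start (or starting at the stop) is
    included. Returns an empty frame with a warning if the annotation has no
    genes on the interval's chromosome.
    """
    on_chrom = annotation[annotation["chromosome"] == interval.chromosome]
    if annotation.shape[0] and on_chrom.empty:
        warnings.warn(f"annotation has no genes on {interval.chromosome}")
    hits = on_chrom[(on_chrom["stop"] >= interval.start)
                    & (on_chrom["start"] <= interval.stop)]
    return hits.sort_values("start").reset_index(drop=True)


def interval_table(intervals: list[CandidateInterval]) -> pd.DataFrame:
    """Flatten candidate intervals for TSV export."""
    return pd.DataFrame([{
        "marker_id": iv.focal_marker, "chromosome": iv.chromosome,
        "ld_block": "yes" if iv.method == "LD-block" else "no",
        "interval_start": iv.start, "interval_stop": iv.stop,
        "interval_size": iv.size, "n_genes": len(iv.genes),
        "genes": ";".join(iv.genes),
    } for iv in intervals])
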