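"""Marker encoding, quality control, imputation and population covariates.

Genotype calls from a diploid SNP+CNV panel are encoded to numeric dosages
(SNP: 0 = AA, 1 = AB, 2 = BB; CNV: 0 = normal, 2 = declared event, reciprocal
event = missing), filtered on minor-allele frequency, missingness and
heterozygosity, imputed for association scanning (missing -> heterozygous),
and summarised by principal components and per-group allele frequencies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: valid SNP call states (string calls) -> dosage of the B allele
SNP_CODES = {"AA": 0.0, "AB": 1.0, "BA": 1.0, "BB": 2.0}

#: valid CNV call states
CNV_STATES = {"normal", "deletion", "duplication"}

MAP_COLUMNS = ["marker_id", "chromosome", "position", "marker_class"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MarkerPanel:
    """A marker map plus a markers x genotypes dosage matrix.

    ``dosages`` is a float array with entries in {0, 1, 2} and ``nan`` for
    missing calls. ``markers`` carries one row per matrix row with columns
    ``marker_id, chromosome, position, marker_class`` plus per-marker QC
    statistics (``maf``, ``missing_frac``, ``het_frac``) added lazily.
    """

    markers: pd.DataFrame
    dosages: np.ndarray
    genotypes: list[str]
    pools: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.markers) != self.dosages.shape[0]:
            raise ValueError("marker map and dosage matrix row counts differ")
        if len(self.genotypes) != self.dosages.shape[1]:
            raise ValueError("genotype ids and dosage matrix column counts differ")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_genotypes(self) -> int:
        return self.dosages.shape[1]

    def with_stats(self) -> "MarkerPanel":
        """Return a copy whose marker table carries MAF/missing/het columns."""
        stats = marker_stats(self.dosages, self.markers["marker_class"].to_numpy())
        markers = self.markers.drop(columns=[c for c in stats if c in self.markers])
        markers = pd.concat([markers, stats], axis=1)
        return replace(self, markers=markers)

    def subset(self, row_index: np.ndarray) -> "MarkerPanel":
        return replace(
            self,
            markers=self.markers.iloc[row_index].reset_index(drop=True),
            dosages=self.dosages[row_index],
        )


@dataclass
class PcScores:
    """Principal-component scores of the centred dosage matrix."""

    scores: np.ndarray  # genotypes x k
    explained_variance_ratio: np.ndarray
    degenerate: bool = False

    @property
    def k(self) -> int:
        return self.scores.shape[1]


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def encode_markers(snp_calls: pd.DataFrame, cnv_calls: pd.DataFrame | None = None) -> MarkerPanel:
    """Encode string SNP and CNV calls into a numeric :class:`MarkerPanel`.

    Parameters
    ----------
    snp_calls
        One row per SNP with columns ``marker_id, chromosome, position`` and
        one column per genotype holding ``AA/AB/BB`` or missing (NaN/"NA").
    cnv_calls
        Same layout, plus a ``marker_class`` column with the declared event
        type (``DEL`` or ``DUP``); per-genotype states are
        ``normal/deletion/duplication`` or missing. The declared event is
        coded 2, normal 0, and the reciprocal event is treated as a missing
        value. CNV positions are shifted by +1 bp (or -1 bp if +1 collides
        with an occupied position) so all (chromosome, position) pairs are
        unique.
    """
    geno_cols = [c for c in snp_calls.columns if c not in MAP_COLUMNS]
    rows = []
    dose_rows = []

    def _snp_dose(val):
        if pd.isna(val) or val == "NA":
            return np.nan
        try:
            return SNP_CODES[val]
        except KeyError:
            raise ValueError(f"unknown SNP call state: {val!r}")

    for _, rec in snp_calls.iterrows():
        rows.append((rec["marker_id"], rec["chromosome"], int(rec["position"]), "SNP"))
        dose_rows.append([_snp_dose(rec[c]) for c in geno_cols])

    occupied = {(r[1], r[2]) for r in rows}

    if cnv_calls is not None and len(cnv_calls):
        cnv_geno_cols = [c for c in cnv_calls.columns if c not in MAP_COLUMNS]
        if cnv_geno_cols != geno_cols:
            raise ValueError("SNP and CNV call tables list different genotypes")
        for _, rec in cnv_calls.iterrows():
            mclass = rec["marker_class"]
            if mclass not in ("DEL", "DUP"):
                raise ValueError(f"unknown CNV marker class: {mclass!r}")
            event = "deletion" if mclass == "DEL" else "duplication"
            reciprocal = "duplication" if mclass == "DEL" else "deletion"

            pos = int(rec["position"]) + 1
            if (rec["chromosome"], pos) in occupied:
                pos = int(rec["position"]) - 1
            if (rec["chromosome"], pos) in occupied:
                raise ValueError(
                    f"cannot place CNV {rec['marker_id']}: positions "
                    f"{int(rec['position']) - 1} and {int(rec['position']) + 1} occupied"
                )
            occupied.add((rec["chromosome"], pos))

            doses = []
            for c in cnv_geno_cols:
                val = rec[c]
                if pd.isna(val) or val == "NA":
                    doses.append(np.nan)
                elif val == event:
                    doses.append(2.0)
                elif val == "normal":
                    doses.append(0.0)
                elif val == reciprocal:
                    doses.append(np.nan)
                else:
                    raise ValueError(f"unknown CNV call state: {val!r}")
            rows.append((rec["marker_id"], rec["chromosome"], pos, mclass))
            dose_rows.append(doses)

    markers = pd.DataFrame(rows, columns=MAP_COLUMNS)
    dosages = np.asarray(dose_rows, dtype=float)

    # sort by chromosome then position; positions must be unique within chrom
    order = np.lexsort((markers["position"].to_numpy(), markers["chromosome"].to_numpy()))
    markers = markers.iloc[order].reset_index(drop=True)
    dosages = dosages[order]
    dup = markers.duplicated(subset=["chromosome", "position"])
    if dup.any():
        raise ValueError("duplicate (chromosome, position) after CNV shifting")

    return MarkerPanel(markers=markers, dosages=dosages, genotypes=list(geno_cols)).with_stats()


def marker_stats(dosages: np.ndarray, marker_class: np.ndarray) -> pd.DataFrame:
    """Per-marker MAF, missing fraction and heterozygous fraction.

    MAF of a SNP is the folded B-allele frequency (mean dosage / 2, folded at
    0.5). For 0/2-coded CNV markers the event frequency is folded the same
    way so the joint MAF filter applies to every marker class. The
    heterozygous fraction is computed over non-missing calls.
    """
    n_geno = dosages.shape[1]
    missing = np.isnan(dosages)
    n_obs = n_geno - missing.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nansum(dosages, axis=1) / np.maximum(2 * n_obs, 1)
    freq[n_obs == 0] = np.nan
    maf = np.minimum(freq, 1.0 - freq)
    het = (dosages == 1).sum(axis=1) / np.maximum(n_obs, 1)
    return pd.DataFrame(
        {
            "maf": maf,
            "missing_frac": missing.sum(axis=1) / n_geno,
            "het_frac": het,
        }
    )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_markers(
    panel: MarkerPanel,
    maf_min: float = 0.01,
    max_missing: float = 0.10,
    max_het: float = 0.25,
) -> tuple[MarkerPanel, pd.DataFrame]:
    """Remove markers failing the MAF / missingness / heterozygosity rules.

    A marker is removed iff MAF < ``maf_min`` OR missing fraction >
    ``max_missing`` OR heterozygous fraction > ``max_het``; boundary values
    are retained. Returns the filtered panel and a removal log listing each
    removed marker with the rule(s) it violated.
    """
    panel = panel.with_stats()
    m = panel.markers
    bad_maf = (m["maf"] < maf_min) | m["maf"].isna()
    bad_miss = m["missing_frac"] > max_missing
    bad_het = m["het_frac"] > max_het
    removed = bad_maf | bad_miss | bad_het

    reasons = []
    for i in np.flatnonzero(removed.to_numpy()):
        r = []
        if bad_maf.iloc[i]:
            r.append("maf")
        if bad_miss.iloc[i]:
            r.append("missing")
        if bad_het.iloc[i]:
            r.append("het")
        reasons.append(";".join(r))
    log = m.loc[removed, MAP_COLUMNS + ["maf", "missing_frac", "het_frac"]].copy()
    log["rules"] = reasons

    keep_idx = np.flatnonzero(~removed.to_numpy())
    if keep_idx.size == 0:
        raise ValueError("no markers survive filtering: degenerate input panel")
    return panel.subset(keep_idx), log.reset_index(drop=True)


def impute_for_scan(panel: MarkerPanel) -> tuple[np.ndarray, np.ndarray]:
    """Replace missing dosages by the heterozygous code 1.

    Returns the imputed matrix and a boolean mask of markers that are
    zero-variance after imputation (untestable in a scan; excluded there but
    kept in the panel).
    """
    imputed = panel.dosages.copy()
    imputed[np.isnan(imputed)] = 1.0
    zero_var = imputed.var(axis=1) == 0.0
    if zero_var.any():
        logger.info("%d zero-variance markers after imputation (excluded from scans)",
                    int(zero_var.sum()))
    return imputed, zero_var


# ---------------------------------------------------------------------------
# covariates and group frequencies
# ---------------------------------------------------------------------------

def compute_pcs(dosages: np.ndarray, k: int = 10) -> PcScores:
    """Principal components of the column-centred genotype matrix.

    ``dosages`` is markers x genotypes and must be complete (impute first).
    Scores are genotypes x k; the explained-variance fractions are
    non-increasing.
    """
    X = np.asarray(dosages, dtype=float).T  # genotypes x markers
    if np.isnan(X).any():
        raise ValueError("compute_pcs requires a complete dosage matrix; impute first")
    Xc = X - X.mean(axis=0)
    total_var = (Xc**2).sum()
    if total_var == 0.0:
        warnings.warn("all genotypes identical: zero total variance, returning zeros")
        return PcScores(np.zeros((X.shape[0], 0)), np.zeros(0), degenerate=True)

    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum())
    if k > rank:
        warnings.warn(f"requested {k} components but rank is {rank}; returning {rank}")
        k = rank
    scores = U[:, :k] * s[:k]
    evr = (s**2) / (s**2).sum()
    return PcScores(scores, evr[:k])


def allele_freq_by_group(panel: MarkerPanel, groups: np.ndarray | list) -> pd.DataFrame:
    """Per-marker alternate-allele (or event) frequency per group.

    Frequency = mean dosage / 2 over non-missing entries in the group; a
    group with zero non-missing calls at a marker gets NaN.
    """
    groups = np.asarray(groups)
    if groups.shape[0] != panel.n_genotypes:
        raise ValueError("group label length does not match genotype count")
    out = {}
    for g in pd.unique(groups):
        sub = panel.dosages[:, groups == g]
        n_obs = (~np.isnan(sub)).sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(sub, axis=1) / 2.0
        freq[n_obs == 0] = np.nan
        out[str(g)] = freq
    res = pd.DataFrame(out)
    res.insert(0, "marker_id", panel.markers["marker_id"].to_numpy())
    return res


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_panel_tsv(panel: MarkerPanel, genotype_path, map_path) -> None:
    """Write the dosage matrix and marker map in the plain TSV dialect."""
    geno = pd.DataFrame(panel.dosages, columns=panel.genotypes)
    geno.insert(0, "marker_id", panel.markers["marker_id"].to_numpy())
    geno.to_csv(genotype_path, sep="\t", index=False, na_rep="NA", float_format="%.0f")
    panel.markers[MAP_COLUMNS].to_csv(map_path, sep="\t", index=False)


def read_panel_tsv(genotype_path, map_path) -> MarkerPanel:
    """Read a panel written by :func:`write_panel_tsv`."""
    geno = pd.read_csv(genotype_path, sep="\t", na_values="NA")
    mmap = pd.read_csv(map_path, sep="\t")
    merged = mmap.merge(geno, on="marker_id", how="left", validate="one_to_one")
    geno_cols = [c for c in geno.columns if c != "marker_id"]
    dosages = merged[geno_cols].to_numpy(dtype=float)
    return MarkerPanel(markers=mmap[MAP_COLUMNS], dosages=dosages,
                       genotypes=list(geno_cols)).with_stats()


def read_panel_vcf(path) -> MarkerPanel:
    """Read a biallelic VCF into a panel (GT field -> B-allele dosage).

    Non-biallelic records are rejected. Requires :mod:`cyvcf2`.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    genotypes = list(vcf.samples)
    rows, dose_rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"non-biallelic record at {var.CHROM}:{var.POS}")
        rows.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS, "SNP"))
        doses = []
        for gt in var.genotypes:
            alleles = [a for a in gt[:-1] if a >= 0]
            doses.append(float(sum(alleles)) if len(alleles) == 2 else np.nan)
        dose_rows.append(doses)
    markers = pd.DataFrame(rows, columns=MAP_COLUMNS)
    return MarkerPanel(markers=markers, dosages=np.array(dose_rows, dtype=float),
                       genotypes=genotypes).with_stats()
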