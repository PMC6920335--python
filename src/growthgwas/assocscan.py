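"""Iterative pseudo-QTN marker-trait association scans with FDR and PVE.

For each trait at each time label the scan regresses genotype BLUEs on each
marker's dosage with principal-component covariates (fixed-effects model),
then promotes the strongest markers to pseudo-QTNs — markers provisionally
treated as known causal loci and added as covariates — and repeats until the
pseudo-QTN set stabilises:

1. fixed-effects scan: per marker, least squares of the response on dosage +
   PC covariates + current pseudo-QTN dosages (a marker is never its own
   covariate); a t-test gives the per-marker P-value;
2. candidate pseudo-QTNs are markers below the eligibility threshold,
   deduplicated per genomic bin (best P per bin); the bin size is chosen
   among the configured sizes by maximising the restricted likelihood of a
   variance-component model whose kinship is built from the candidate
   pseudo-QTN dosages;
3. iterate until the set is unchanged or the loop cap is reached.

Final P-values come from the last fixed-effects scan. With a single
iteration and no eligible pseudo-QTNs this reduces exactly to the
covariate-adjusted single-marker OLS test. P-values are adjusted per scan by
Benjamini-Hochberg, significance is called at adjusted P <= 0.1, and the
variance explained by each significant marker (PVE%) is the sequential
(type-I) sum of squares of a joint linear model with markers entered in
decreasing P order:

    PVE% = SS_marker / (sum SS_significant + SS_residual) * 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .markerqc import MarkerPanel, PcScores, impute_for_scan

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanParams:
    n_pcs: int = 4
    qtn_threshold: float = 1e-5
    max_loop: int = 100
    bin_sizes: tuple[float, ...] = (5e5, 5e6, 5e7)
    fdr_level: float = 0.1
    report_level: float = 0.05

    def __post_init__(self):
        if not (0 < self.qtn_threshold < 1) or not (0 < self.fdr_level < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.max_loop < 1:
            raise ValueError("max_loop must be >= 1")


RECORD_COLUMNS = ["trait", "time_label", "marker_id", "chromosome", "position",
                  "maf", "effect", "se", "p_value"]


# ---------------------------------------------------------------------------
# fixed-effects scan
# ---------------------------------------------------------------------------

def _ols_scan(y: np.ndarray, cov: np.ndarray, X: np.ndarray,
              testable: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column OLS of y on [cov, x_j]; returns (beta, se, p) per column.

    Uses the Frisch-Waugh-Lovell projection: residualise y and every marker
    column against the covariates once, then run simple regressions.
    """
    n, p = cov.shape
    Q, _ = np.linalg.qr(cov)
    y_r = y - Q @ (Q.T @ y)
    X_r = X - Q @ (Q.T @ X)
    ss = np.einsum("ij,ij->j", X_r, X_r)
    ok = testable & (ss > 1e-10)

    beta = np.full(X.shape[1], np.nan)
    se = np.full(X.shape[1], np.nan)
    pval = np.full(X.shape[1], np.nan)
    df = n - p - 1
    if df <= 0:
        raise ValueError("fewer genotypes than covariates + 2: scan aborted")

    b = (X_r[:, ok].T @ y_r) / ss[ok]
    rss = (y_r @ y_r) - b**2 * ss[ok]
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    s = np.sqrt(sigma2 / ss[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(s > 0, b / s, np.inf * np.sign(b))
    beta[ok] = b
    se[ok] = s
    pval[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, pval


def _scan_with_pseudo(y, cov0, X, pseudo: list[int], testable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed scan with pseudo-QTN covariates; a marker never conditions on itself."""
    if not pseudo:
        return _ols_scan(y, cov0, X, testable)
    cov = np.column_stack([cov0, X[:, pseudo]])
    beta, se, pval = _ols_scan(y, cov, X, testable)
    # re-test each pseudo-QTN without itself in the covariate set
    for j in pseudo:
        others = [k for k in pseudo if k != j]
        cov_j = np.column_stack([cov0, X[:, others]]) if others else cov0
        bj, sj, pj = _ols_scan(y, cov_j, X[:, [j]], np.array([testable[j]]))
        beta[j], se[j], pval[j] = bj[0], sj[0], pj[0]
    return beta, se, pval


# ---------------------------------------------------------------------------
# pseudo-QTN selection
# ---------------------------------------------------------------------------

def _reml_kinship_score(y: np.ndarray, cov: np.ndarray, Z: np.ndarray) -> float:
    """Restricted log-likelihood of y ~ cov + u, u ~ N(0, s2g * K),
    K the cross-product similarity of the centred pseudo-QTN dosages Z,
    profiled over the variance ratio."""
    n, p = cov.shape
    Zc = Z - Z.mean(axis=0)
    K = (Zc @ Zc.T) / max(Z.shape[1], 1)
    s_eig, U = np.linalg.eigh(K)
    s_eig = np.maximum(s_eig, 0.0)
    y_t = U.T @ y
    X_t = U.T @ cov

    def neg_rll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = lam * s_eig + 1.0
        Xw = X_t / w[:, None]
        XtViX = X_t.T @ Xw
        XtViy = X_t.T @ (y_t / w)
        try:
            bhat = np.linalg.solve(XtViX, XtViy)
            sign, logdet_x = np.linalg.slogdet(XtViX)
            if sign <= 0:
                return np.inf
        except np.linalg.LinAlgError:
            return np.inf
        r = y_t - X_t @ bhat
        ypy = float(r @ (r / w))
        if ypy <= 0:
            return np.inf
        sig2 = ypy / (n - p)
        return 0.5 * ((n - p) * np.log(sig2) + np.log(w).sum() + logdet_x + (n - p))

    res = optimize.minimize_scalar(neg_rll, bounds=(-10.0, 10.0), method="bounded",
                                   options={"xatol": 1e-4})
    return -float(res.fun)


def _bin_best(cand: np.ndarray, pvals: np.ndarray, chrom: np.ndarray,
              pos: np.ndarray, bin_size: float) -> list[int]:
    """Best-P candidate per (chromosome, bin) with deterministic tie-breaks."""
    best: dict[tuple, int] = {}
    order = cand[np.lexsort((pos[cand], chrom[cand], pvals[cand]))]
    for j in order:
        key = (chrom[j], int(pos[j] // bin_size))
        if key not in best:
            best[key] = int(j)
    return sorted(best.values())


def _select_pseudo_qtns(y, cov0, X, pvals, markers: pd.DataFrame,
                        params: ScanParams) -> list[int]:
    with np.errstate(invalid="ignore"):
        cand = np.flatnonzero(np.nan_to_num(pvals, nan=1.0) < params.qtn_threshold)
    if cand.size == 0:
        return []
    chrom = markers["chromosome"].to_numpy()
    pos = markers["position"].to_numpy()
    best_set, best_score = [], -np.inf
    for bsize in params.bin_sizes:
        sel = _bin_best(cand, pvals, chrom, pos, bsize)
        score = _reml_kinship_score(y, cov0, X[:, sel])
        if score > best_score + 1e-9:
            best_set, best_score = sel, score
    return best_set


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _align(blues: pd.Series, panel: MarkerPanel,
           pcs: PcScores | None) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Intersect BLUE genotypes with panel genotypes; return y, X, pc scores."""
    common = [g for g in panel.genotypes if g in blues.index and pd.notna(blues.get(g))]
    if len(common) < 3:
        raise ValueError("fewer than 3 genotypes shared between BLUEs and panel")
    col_idx = [panel.genotypes.index(g) for g in common]
    imputed, zero_var = impute_for_scan(panel)
    X = imputed[:, col_idx].T  # genotypes x markers
    y = blues.reindex(common).to_numpy(dtype=float)
    pc = pcs.scores[col_idx] if pcs is not None and pcs.k else np.empty((len(common), 0))
    return y, X, ~zero_var, common, pc


def scan_trait(blues: pd.Series, panel: MarkerPanel, pcs: PcScores | None,
               params: ScanParams = ScanParams(), trait: str = "",
               time_label: object = None) -> pd.DataFrame:
    """Run the iterative pseudo-QTN scan for one trait x time label.

    ``blues`` is a genotype-indexed response (one BLUE per genotype).
    Returns one record per testable marker with effect (per-dosage-unit,
    B-allele oriented), standard error and raw P-value. Zero-variance markers
    get missing P. Deterministic given its inputs.
    """
    y, X, testable, common, pc = _align(blues, panel, pcs)
    n = len(y)
    cov0 = np.column_stack([np.ones(n), pc[:, : params.n_pcs]])
    if n < cov0.shape[1] + 2:
        raise ValueError("fewer genotypes than covariates + 2: scan aborted")

    pseudo: list[int] = []
    beta = se = pvals = None
    for loop in range(params.max_loop):
        beta, se, pvals = _scan_with_pseudo(y, cov0, X, pseudo, testable)
        new_pseudo = _select_pseudo_qtns(y, cov0, X, pvals, panel.markers, params)
        if new_pseudo == pseudo:
            break
        if loop == params.max_loop - 1:
            logger.info("pseudo-QTN set did not stabilise within %d loops",
                        params.max_loop)
            break
        pseudo = new_pseudo

    m = panel.with_stats().markers
    return pd.DataFrame({
        "trait": trait, "time_label": time_label,
        "marker_id": m["marker_id"], "chromosome": m["chromosome"],
        "position": m["position"], "maf": m["maf"],
        "effect": beta, "se": se, "p_value": pvals,
    })


def adjust_fdr(records: pd.DataFrame, level: float = 0.1) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjustment across one scan's markers.

    Missing P-values are excluded from the number of tests (logged).
    Adds ``p_value_fdr`` and a ``significant`` flag at adjusted P <= level.
    """
    from statsmodels.stats.multitest import multipletests

    out = records.copy()
    p = out["p_value"].to_numpy(dtype=float)
    ok = ~np.isnan(p)
    if (~ok).any():
        logger.info("excluding %d missing P-values from FDR adjustment", int((~ok).sum()))
    adj = np.full(len(p), np.nan)
    if ok.any():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    out["p_value_fdr"] = adj
    out["significant"] = np.nan_to_num(adj, nan=1.0) <= level
    return out


def estimate_pve(blues: pd.Series, significant: pd.DataFrame,
                 panel: MarkerPanel) -> pd.DataFrame:
    """Sequential-ANOVA variance decomposition over the significant markers.

    Significant-marker dosages enter a single linear model in decreasing
    raw-P order; each marker's sequential (type-I) SS divided by the total
    (sum of marker SS plus residual SS) gives its PVE%. Collinear markers
    receive only the residual contribution of their entry step (flagged).
    """
    if significant.empty:
        return pd.DataFrame(columns=["marker_id", "ss", "pve_pct", "collinear"])
    order = significant.sort_values("p_value", ascending=False, kind="mergesort")
    marker_rows = [panel.markers.index[panel.markers["marker_id"] == mid][0]
                   for mid in order["marker_id"]]
    y, X, _, common, _ = _align(blues, panel, None)

    design = np.ones((len(y), 1))
    rss_prev = float(((y - y.mean()) ** 2).sum())
    total = rss_prev  # SS around the intercept = sum of marker SS + residual
    ss_list, collinear = [], []
    for ridx in marker_rows:
        design = np.column_stack([design, X[:, ridx]])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(((y - design @ coef) ** 2).sum())
        ss = max(rss_prev - rss, 0.0)
        collinear.append(ss < 1e-10 and design.shape[1] > 2)
        ss_list.append(ss)
        rss_prev = rss

    pve = [100.0 * ss / total if total > 0 else 0.0 for ss in ss_list]
    return pd.DataFrame({
        "marker_id": order["marker_id"].to_numpy(),
        "ss": ss_list, "residual_ss": rss_prev,
        "pve_pct": pve, "collinear": collinear,
    })


def scan_with_fdr(blues: pd.Series, panel: MarkerPanel, pcs: PcScores | None,
                  params: ScanParams = ScanParams(), trait: str = "",
                  time_label: object = None) -> pd.DataFrame:
    """Scan + BH adjustment + PVE% for the significant markers."""
    rec = scan_trait(blues, panel, pcs, params, trait=trait, time_label=time_label)
    rec = adjust_fdr(rec, level=params.fdr_level)
    sig = rec[rec["significant"]]
    rec["pve_pct"] = np.nan
    if len(sig):
        pve = estimate_pve(blues, sig, panel)
        rec = rec.merge(pve[["marker_id", "pve_pct"]], on="marker_id",
                        how="left", suffixes=("_drop", ""))
        rec = rec.drop(columns=[c for c in rec.columns if c.endswith("_drop")])
    return rec
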