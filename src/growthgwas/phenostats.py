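"""Phenotype cleaning, per-day mixed-model BLUEs, heritability and rates.

Raw observations are long-format rows (genotype, experiment, carrier, day,
timestamp, trait, value, is_check, position). For each trait and day a linear
mixed model is fitted with genotype as a fixed effect and design factors as
random effects:

    image traits:     Y = G + E + GxE + C + CxE + e
    end-point traits: Y = G + E + P + GxE + C + CxE + PxE + e

where E is the experiment, C the check-line identity (checks also enter G),
P the pot-position code, and e the residual. Variance components are
estimated by REML; the BLUE of a genotype is its estimated marginal mean.
Broad-sense heritability uses the same model with genotype random:

    H^2 = sigma_G^2 / (sigma_G^2 + sigma_e^2 / n0)

with n0 the number of experiments (image traits) or plant replicates
(end-point biomass). Relative growth rates and absolute change rates between
two time points are computed from imaging timestamps at minute precision:

    RGR = (ln W2 - ln W1) / (t2 - t1),   ACR = (W2 - W1) / (t2 - t1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["genotype", "experiment", "carrier", "day", "trait"]


@dataclass(frozen=True)
class MixedModelSpec:
    """Fixed genotype effect plus a set of random design terms."""

    random_terms: tuple[str, ...]

    def __post_init__(self):
        allowed = {"E", "GxE", "C", "CxE", "P", "PxE"}
        bad = set(self.random_terms) - allowed
        if bad:
            raise ValueError(f"unknown random terms: {sorted(bad)}")


#: per-day image-trait model
EQ1 = MixedModelSpec(("E", "GxE", "C", "CxE"))
#: end-point biomass model (adds pot position)
EQ2 = MixedModelSpec(("E", "P", "GxE", "C", "CxE", "PxE"))


@dataclass
class BlueTable:
    trait: str
    day: object  # int day or interval label
    blues: pd.Series  # genotype -> BLUE
    diagnostics: dict = field(default_factory=dict)


@dataclass
class HeritabilityEstimate:
    trait: str
    day: object
    sigma_g2: float
    sigma_e2: float
    n0: float
    h2: float
    flagged: bool = False


# ---------------------------------------------------------------------------
# outlier filtering
# ---------------------------------------------------------------------------

def filter_outliers(series: pd.DataFrame,
                    manual_exclusions: list | None = None,
                    n_sd: float = 3.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Threshold filtering: median +/- ``n_sd`` SD per experiment, day, trait.

    Carriers in ``manual_exclusions`` are removed first. Values outside the
    closed interval [median - n_sd*SD, median + n_sd*SD] of their stratum are
    removed; strata with fewer than 3 observations are left untouched (with a
    warning). Returns the filtered series and a removal log.
    """
    series = series.copy()
    logs = []
    if manual_exclusions:
        manual = series["carrier"].isin(set(manual_exclusions))
        log = series.loc[manual].copy()
        log["reason"] = "manual"
        logs.append(log)
        series = series.loc[~manual]

    small = 0
    keep_mask = np.ones(len(series), dtype=bool)
    values = series["value"].to_numpy()
    grouped = series.groupby(["experiment", "day", "trait"], sort=False, observed=True)
    for _, idx in grouped.indices.items():
        if len(idx) < 3:
            small += 1
            continue
        v = values[idx]
        med, sd = np.median(v), np.std(v, ddof=1)
        if sd == 0:
            continue
        out = np.abs(v - med) > n_sd * sd
        keep_mask[idx[out]] = False
    if small:
        warnings.warn(f"{small} strata with < 3 observations left unfiltered")

    log = series.loc[~keep_mask].copy()
    if len(log):
        log["reason"] = "threshold"
        logs.append(log)
    removal_log = (pd.concat(logs, ignore_index=True)
                   if logs else series.iloc[0:0].assign(reason=pd.Series(dtype=str)))
    return series.loc[keep_mask].reset_index(drop=True), removal_log


# ---------------------------------------------------------------------------
# mixed-model machinery
# ---------------------------------------------------------------------------

def _random_design(df: pd.DataFrame, term: str) -> np.ndarray | None:
    """Dummy design matrix for one random term; None if degenerate.

    Check terms (C, CxE) have all-zero rows for non-check observations.
    A term is dropped when it has fewer than 2 levels or when every level
    holds at most one observation (confounded with the residual).
    """
    # interactions with the experiment factor are meaningless (and confounded
    # with their main effect) when only one experiment is present
    single_experiment = df["experiment"].nunique() < 2
    if term == "E":
        codes = df["experiment"]
    elif term == "GxE":
        if single_experiment:
            return None
        codes = df["genotype"].astype(str) + ":" + df["experiment"].astype(str)
    elif term == "C":
        codes = df["genotype"].where(df["is_check"], other=np.nan)
    elif term == "CxE":
        if single_experiment:
            return None
        codes = (df["genotype"].astype(str) + ":" + df["experiment"].astype(str)
                 ).where(df["is_check"], other=np.nan)
    elif term == "P":
        codes = df["position"]
    elif term == "PxE":
        if single_experiment:
            return None
        codes = df["position"].astype(str) + ":" + df["experiment"].astype(str)
    else:  # pragma: no cover
        raise ValueError(term)

    valid = codes.notna()
    levels = pd.unique(codes[valid])
    if len(levels) < 2:
        return None
    counts = codes.value_counts()
    if counts.max() <= 1:
        return None
    mat = np.zeros((len(df), len(levels)))
    lut = {lv: j for j, lv in enumerate(levels)}
    rows = np.flatnonzero(valid.to_numpy())
    mat[rows, [lut[c] for c in codes[valid]]] = 1.0
    return mat


def _fit_vc_model(df: pd.DataFrame, exog: np.ndarray, vc_terms: dict[str, np.ndarray]):
    """REML fit of endog ~ exog with variance-component random terms."""
    from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

    names = sorted(vc_terms)
    spec = VCSpec(
        names,
        [[[f"{nm}[{j}]" for j in range(vc_terms[nm].shape[1])]] for nm in names],
        [[vc_terms[nm]] for nm in names],
    )
    groups = np.zeros(len(df))
    model = MixedLM(df["value"].to_numpy(), exog, groups=groups, exog_vc=spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True, method="lbfgs", maxiter=200)
    return result, names


def fit_blues(series: pd.DataFrame, spec: MixedModelSpec = EQ1,
              trait: str | None = None, day: object | None = None) -> BlueTable:
    """Estimate per-genotype BLUEs for one trait at one time label.

    Genotype is fixed, the model's remaining terms random with non-negative
    REML variance components. The BLUE is the estimated marginal genotype
    mean. If no random term is estimable the model degenerates to ordinary
    least squares, i.e. plain genotype means; non-convergence falls back to
    genotype means with a warning flag.
    """
    df = _subset(series, trait, day)
    genos = pd.unique(df["genotype"])
    if len(genos) < 2:
        raise ValueError("need at least two genotypes to fit BLUEs")

    n_exp = df.groupby("genotype", observed=True)["experiment"].nunique()
    singletons = n_exp.index[n_exp == 1].tolist() if n_exp.max() > 1 else []

    lut = {g: j for j, g in enumerate(genos)}
    exog = np.zeros((len(df), len(genos)))
    exog[np.arange(len(df)), [lut[g] for g in df["genotype"]]] = 1.0

    vc_terms = {}
    dropped = []
    for term in spec.random_terms:
        mat = _random_design(df, term)
        if mat is None:
            dropped.append(term)
        else:
            vc_terms[term] = mat

    diagnostics = {"dropped_terms": dropped, "fallback": False, "converged": True,
                   "single_experiment_genotypes": singletons}
    if not vc_terms:
        blues = df.groupby("genotype", sort=False, observed=True)["value"].mean()
        diagnostics["method"] = "ols_means"
        return BlueTable(trait or "", day, blues.reindex(genos), diagnostics)

    try:
        result, names = _fit_vc_model(df, exog, vc_terms)
        converged = bool(getattr(result, "converged", True))
    except Exception as exc:  # numerical failure -> genotype means
        warnings.warn(f"mixed model failed ({exc}); falling back to genotype means")
        blues = df.groupby("genotype", sort=False, observed=True)["value"].mean()
        diagnostics.update(method="fallback_means", fallback=True, converged=False)
        return BlueTable(trait or "", day, blues.reindex(genos), diagnostics)

    if not converged:
        warnings.warn("mixed model did not converge; falling back to genotype means")
        blues = df.groupby("genotype", sort=False, observed=True)["value"].mean()
        diagnostics.update(method="fallback_means", fallback=True, converged=False)
        return BlueTable(trait or "", day, blues.reindex(genos), diagnostics)

    diagnostics.update(
        method="reml",
        variance_components={nm: float(v) for nm, v in zip(names, result.vcomp)},
        residual_variance=float(result.scale),
    )
    blues = pd.Series(result.fe_params[: len(genos)], index=genos)
    return BlueTable(trait or "", day, blues, diagnostics)


def estimate_h2(series: pd.DataFrame, spec: MixedModelSpec = EQ1,
                trait: str | None = None, day: object | None = None,
                n0_rule: str = "experiments") -> HeritabilityEstimate:
    """Broad-sense heritability with all effects random.

    ``n0_rule`` is ``"experiments"`` (image traits: number of experiments) or
    ``"plant_reps"`` (end-point biomass: replicates per genotype). A genotype
    variance estimated at the zero boundary yields H^2 = 0 with a flag.
    """
    df = _subset(series, trait, day)
    vc_terms = {"G": _random_design_genotype(df)}
    for term in spec.random_terms:
        mat = _random_design(df, term)
        if mat is not None:
            vc_terms[term] = mat

    exog = np.ones((len(df), 1))
    result, names = _fit_vc_model(df, exog, vc_terms)
    sigma_g2 = float(result.vcomp[names.index("G")])
    sigma_e2 = float(result.scale)

    if n0_rule == "experiments":
        n0 = float(df["experiment"].nunique())
    elif n0_rule == "plant_reps":
        n0 = float(df.loc[~df["is_check"]].groupby("genotype", observed=True)
                   .size().mean())
    else:
        raise ValueError(f"unknown n0 rule {n0_rule!r}")

    flagged = sigma_g2 <= 1e-10
    h2 = 0.0 if flagged else sigma_g2 / (sigma_g2 + sigma_e2 / n0)
    if sigma_e2 <= 1e-12 and not flagged:
        h2 = 1.0
    return HeritabilityEstimate(trait or "", day, sigma_g2, sigma_e2, n0, h2, flagged)


def _random_design_genotype(df: pd.DataFrame) -> np.ndarray:
    genos = pd.unique(df["genotype"])
    lut = {g: j for j, g in enumerate(genos)}
    mat = np.zeros((len(df), len(genos)))
    mat[np.arange(len(df)), [lut[g] for g in df["genotype"]]] = 1.0
    return mat


def _subset(series: pd.DataFrame, trait, day) -> pd.DataFrame:
    df = series
    if trait is not None:
        df = df[df["trait"] == trait]
    if day is not None:
        df = df[df["day"] == day]
    if df.empty:
        raise ValueError(f"no observations for trait={trait!r}, day={day!r}")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# growth rates
# ---------------------------------------------------------------------------

def default_windows(days: list[int] | np.ndarray, span: int = 3) -> list[tuple[int, int]]:
    """Non-overlapping windows anchored at measured days, ``span`` steps wide."""
    days = sorted(set(int(d) for d in days))
    return [(days[i], days[i + span]) for i in range(0, len(days) - span, span)]


def compute_rates(series: pd.DataFrame, kind: str = "RGR",
                  windows: list[tuple[int, int]] | None = None,
                  traits: list[str] | None = None) -> pd.DataFrame:
    """Relative growth rates or absolute change rates over day windows.

    The denominator is the timestamp difference in days at minute resolution.
    RGR records with a non-positive endpoint value are skipped with a log
    message. The result is itself a long-format phenotype series whose trait
    is ``<trait>_<kind>`` and whose ``day`` is the interval label
    ``"<d1>-<d2>"``, ready for :func:`fit_blues`.
    """
    if kind not in ("RGR", "ACR"):
        raise ValueError("kind must be 'RGR' or 'ACR'")
    if traits is None:
        traits = [t for t in pd.unique(series["trait"])]
    if windows is None:
        windows = default_windows(series["day"].unique())

    keys = ["genotype", "experiment", "carrier", "trait"]
    out = []
    skipped = 0
    for d1, d2 in windows:
        a = series[series["day"] == d1]
        b = series[series["day"] == d2]
        m = a.merge(b, on=keys, suffixes=("_1", "_2"))
        m = m[m["trait"].isin(traits)]
        if m.empty:
            continue
        dt = (pd.to_datetime(m["timestamp_2"]) - pd.to_datetime(m["timestamp_1"])
              ) / pd.Timedelta(days=1)
        w1 = m["value_1"].to_numpy()
        w2 = m["value_2"].to_numpy()
        if kind == "RGR":
            ok = (w1 > 0) & (w2 > 0)
            skipped += int((~ok).sum())
            rate = np.full(len(m), np.nan)
            rate[ok] = (np.log(w2[ok]) - np.log(w1[ok])) / dt[ok]
        else:
            ok = np.ones(len(m), dtype=bool)
            rate = (w2 - w1) / dt

        res = pd.DataFrame({
            "genotype": m["genotype"], "experiment": m["experiment"],
            "carrier": m["carrier"], "day": f"{d1}-{d2}",
            "timestamp": m["timestamp_1"],
            "trait": m["trait"].astype(str) + "_" + kind,
            "value": rate, "is_check": m["is_check_1"],
            "position": m["position_1"],
            "t1": m["timestamp_1"], "t2": m["timestamp_2"],
            "w1": w1, "w2": w2, "kind": kind,
        })
        out.append(res)
    if skipped:
        logger.info("skipped %d rate records with non-positive endpoint values", skipped)
    if not out:
        return pd.DataFrame(columns=["genotype", "experiment", "carrier", "day",
                                     "timestamp", "trait", "value", "is_check",
                                     "position", "t1", "t2", "w1", "w2", "kind"])
    rates = pd.concat(out, ignore_index=True)
    return rates[rates["value"].notna()].reset_index(drop=True)


# ---------------------------------------------------------------------------
# table assembly / I/O
# ---------------------------------------------------------------------------

def blue_matrix(tables: list[BlueTable]) -> pd.DataFrame:
    """Stack BLUE tables for one trait into a genotypes x time-label frame."""
    cols = {t.day: t.blues for t in tables}
    return pd.DataFrame(cols)


def write_blues_tsv(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", index=True, index_label="genotype")
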