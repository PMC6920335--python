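"""Dynamic QTL calls from per-day / per-interval association tables.

A marker becomes a dynamic QTL when it is significant at a minimum number of
*consecutive* measured time labels (default 3 for time-point traits, 2 for
rate intervals). Adjacency follows the ordered list of measured labels, so
days 13 and 15 are adjacent when day 14 was never measured. For retained
markers the module estimates per-label allele-effect trajectories with a
simple covariate-adjusted single-marker model (comparable across labels,
unlike the iterative scan whose covariate set varies per scan), detects
sign reversals of the allele effect over time, and tabulates markers shared
between traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assocscan import _ols_scan
from .markerqc import MarkerPanel, PcScores, impute_for_scan


@dataclass
class DynamicQtl:
    marker_id: str
    trait: str
    significant_labels: list
    run_start: object
    run_end: object
    run_length: int
    trajectory: pd.DataFrame | None = None  # time_label, effect, se, significant
    reversal: bool = False
    switch_points: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# consecutive-significance filtering
# ---------------------------------------------------------------------------

def _max_run(flags: np.ndarray) -> tuple[int, int, int]:
    """Longest run of True; returns (length, start_idx, end_idx)."""
    best = (0, -1, -1)
    run = 0
    for i, f in enumerate(flags):
        run = run + 1 if f else 0
        if run > best[0]:
            best = (run, i - run + 1, i)
    return best


def filter_consecutive(assoc_tables: dict | pd.DataFrame, k: int = 3,
                       labels: list | None = None,
                       level: float | None = None) -> list[DynamicQtl]:
    """Retain markers significant at >= k successive measured time labels.

    ``assoc_tables`` is either a dict label -> association table or a single
    stacked table with a ``time_label`` column; tables must carry
    ``significant`` flags (or ``p_value_fdr`` with ``level`` given). ``labels``
    fixes the measured-label order; by default the union of observed labels in
    sorted order. A label with no scan is excluded from the adjacency chain
    with a warning, so labels on either side of it become adjacent.
    """
    if isinstance(assoc_tables, pd.DataFrame):
        stacked = assoc_tables
    else:
        stacked = pd.concat(
            [t.assign(time_label=lbl) for lbl, t in assoc_tables.items()],
            ignore_index=True)

    if "significant" not in stacked.columns:
        if level is None:
            raise ValueError("need 'significant' flags or an explicit level")
        stacked = stacked.assign(significant=stacked["p_value_fdr"] <= level)

    present = list(pd.unique(stacked["time_label"]))
    if labels is None:
        labels = sorted(present)
    else:
        missing = [lbl for lbl in labels if lbl not in present]
        if missing:
            warnings.warn(f"no scan for labels {missing}; excluded from adjacency")
        labels = [lbl for lbl in labels if lbl in present]

    out: list[DynamicQtl] = []
    for (trait, marker), grp in stacked.groupby(["trait", "marker_id"], sort=True):
        sig_by_label = grp.set_index("time_label")["significant"]
        flags = np.array([bool(sig_by_label.get(lbl, False)) for lbl in labels])
        length, s, e = _max_run(flags)
        if length >= k:
            out.append(DynamicQtl(
                marker_id=marker, trait=trait,
                significant_labels=[lbl for lbl, f in zip(labels, flags) if f],
                run_start=labels[s], run_end=labels[e], run_length=length,
            ))
    return out


# ---------------------------------------------------------------------------
# effect trajectories and reversals
# ---------------------------------------------------------------------------

def effect_trajectory(marker_id: str, blues_by_label: dict,
                      panel: MarkerPanel, pcs: PcScores | None,
                      n_pcs: int = 4) -> pd.DataFrame:
    """Covariate-adjusted single-marker effect at every time label.

    ``blues_by_label`` maps time label -> genotype-indexed BLUE series. Uses
    the same PC covariates as the scan but no pseudo-QTNs, so estimates are
    comparable across labels. A zero-variance marker yields an empty frame.
    """
    rows = panel.markers.index[panel.markers["marker_id"] == marker_id]
    if not len(rows):
        raise KeyError(f"marker {marker_id!r} not in panel")
    ridx = int(rows[0])
    imputed, zero_var = impute_for_scan(panel)
    if zero_var[ridx]:
        return pd.DataFrame(columns=["time_label", "effect", "se", "p_value"])

    out = []
    for lbl, blues in blues_by_label.items():
        common = [g for g in panel.genotypes if g in blues.index and pd.notna(blues.get(g))]
        cols = [panel.genotypes.index(g) for g in common]
        y = blues.reindex(common).to_numpy(dtype=float)
        x = imputed[ridx, cols][:, None]
        pc = (pcs.scores[cols][:, :n_pcs] if pcs is not None and pcs.k
              else np.empty((len(common), 0)))
        cov = np.column_stack([np.ones(len(common)), pc])
        beta, se, pval = _ols_scan(y, cov, x, np.array([True]))
        out.append({"time_label": lbl, "effect": beta[0], "se": se[0],
                    "p_value": pval[0]})
    return pd.DataFrame(out)


def detect_reversals(trajectory: pd.DataFrame,
                     se_factor: float = 1.0) -> tuple[bool, list]:
    """Flag allele-effect sign reversal along a trajectory.

    A reversal requires two labels whose effect estimates have opposite sign
    and each exceeds ``se_factor`` times its standard error in magnitude (a
    noise guard against sign flips of near-zero estimates). Returns the flag
    and the list of (label_negative_side, label_positive_side) switch pairs
    between successive guarded estimates.
    """
    if trajectory is None or len(trajectory) < 2:
        return False, []
    eff = trajectory["effect"].to_numpy(dtype=float)
    se = trajectory["se"].to_numpy(dtype=float)
    labels = trajectory["time_label"].tolist()
    strong = np.abs(eff) > se_factor * se
    signs = np.sign(eff)

    strong_idx = [i for i in range(len(eff)) if strong[i] and signs[i] != 0]
    flag = len({int(signs[i]) for i in strong_idx}) == 2
    switches = []
    for a, b in zip(strong_idx, strong_idx[1:]):
        if signs[a] != signs[b]:
            switches.append((labels[a], labels[b]))
    return flag, switches


# ---------------------------------------------------------------------------
# cross-trait sharing
# ---------------------------------------------------------------------------

def shared_markers(*tables: pd.DataFrame) -> pd.DataFrame:
    """Markers associated with more than one trait, with labels per trait.

    Each input table needs columns ``marker_id``, ``trait`` and optionally
    ``time_label``. Returns one row per marker shared by >= 2 distinct traits
    with the sorted trait list, trait count and per-trait time labels.
    """
    frames = []
    for t in tables:
        cols = ["marker_id", "trait"] + (["time_label"] if "time_label" in t.columns else [])
        frames.append(t[cols])
    stacked = pd.concat(frames, ignore_index=True)
    if "time_label" not in stacked.columns:
        stacked["time_label"] = None

    rows = []
    for marker, grp in stacked.groupby("marker_id", sort=True):
        traits = sorted(grp["trait"].unique())
        if len(traits) < 2:
            continue
        labels = {tr: sorted(g["time_label"].dropna().unique().tolist())
                  for tr, g in grp.groupby("trait")}
        rows.append({"marker_id": marker, "traits": traits,
                     "n_traits": len(traits), "labels_by_trait": labels})
    return pd.DataFrame(rows, columns=["marker_id", "traits", "n_traits",
                                       "labels_by_trait"])


def dynamic_qtl_table(qtls: list[DynamicQtl]) -> pd.DataFrame:
    """Flatten dynamic QTL calls for TSV export."""
    return pd.DataFrame([{
        "marker_id": q.marker_id, "trait": q.trait,
        "run_start": q.run_start, "run_end": q.run_end,
        "run_length": q.run_length,
        "significant_labels": ";".join(str(l) for l in q.significant_labels),
        "reversal": q.reversal,
    } for q in qtls])
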