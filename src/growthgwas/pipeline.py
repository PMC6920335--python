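"""End-to-end orchestration: simulate/load -> QC -> BLUEs -> rates -> scans
-> dynamics -> candidate intervals, with a reproducible output manifest.

Every stage reads its inputs from the run directory and persists its outputs
there, so any single stage can be re-run from the persisted state of the
previous one. The manifest records, per stage, the files written with their
SHA-256 hashes, the parameters used and row counts; identical configuration
and seed give byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assocscan, ldcandidates, markerqc, phenostats, qtldynamics, simulate
from .simulate import ChromosomeSpec, QtlSpec, SimConfig, TraitSpec

logger = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "blues", "rates", "scan", "dynamics", "candidates"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "growthgwas_run"
    seed: int = 0
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    genotypes_path: str | None = None
    marker_map_path: str | None = None
    phenotypes_path: str | None = None
    annotation_path: str | None = None
    maf_min: float = 0.01
    max_missing: float = 0.10
    max_het: float = 0.25
    n_pcs_computed: int = 10
    scan: assocscan.ScanParams = field(default_factory=assocscan.ScanParams)
    k_timepoint: int = 3
    k_rate: int = 2
    rate_span: int = 3
    r2_threshold: float = 0.6
    flank: int = 100_000
    log_level: str = "INFO"

    def __post_init__(self):
        if not self.simulate:
            for p in (self.genotypes_path, self.marker_map_path, self.phenotypes_path):
                if p is None:
                    raise ValueError("non-simulated runs need genotype, map and "
                                     "phenotype paths")
                if not Path(p).exists():
                    raise FileNotFoundError(f"input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw:
            sim_raw = raw.pop("sim")
            if "chromosomes" in sim_raw:
                sim_raw["chromosomes"] = [ChromosomeSpec(*c)
                                          for c in sim_raw["chromosomes"]]
            if "traits" in sim_raw:
                sim_raw["traits"] = [TraitSpec(**t) for t in sim_raw["traits"]]
            if "qtl" in sim_raw:
                sim_raw["qtl"] = [QtlSpec(**{**q, "window": tuple(q["window"])})
                                  for q in sim_raw["qtl"]]
            if "days" in sim_raw:
                sim_raw["days"] = tuple(sim_raw["days"])
            raw["sim"] = SimConfig(**sim_raw)
        if "scan" in raw:
            sp = dict(raw.pop("scan"))
            if "bin_sizes" in sp:
                sp["bin_sizes"] = tuple(sp["bin_sizes"])
            raw["scan"] = assocscan.ScanParams(**sp)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.path = outdir / "manifest.json"
        self.data: dict = {"stages": {}}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def record(self, stage: str, files: list[Path], params: dict,
               counts: dict) -> None:
        self.data["stages"][stage] = {
            "files": {f.name: _sha256(f) for f in sorted(files)},
            "params": params,
            "row_counts": counts,
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True,
                                        default=str))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path, manifest: Manifest):
    sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
    panel, obs, truth = simulate.simulate_study(sim_cfg)
    g, m = outdir / "genotypes.tsv", outdir / "marker_map.tsv"
    p, t = outdir / "phenotypes.csv", outdir / "truth.json"
    markerqc.write_panel_tsv(panel, g, m)
    simulate.write_phenotypes_csv(obs, p)
    simulate.write_truth_json(truth, t)
    np.savetxt(outdir / "pools.tsv", truth.pools, fmt="%d")
    manifest.record("simulate", [g, m, p, t], {"seed": cfg.seed,
                    "n_genotypes": sim_cfg.n_genotypes,
                    "n_markers": sim_cfg.n_snp + sim_cfg.n_cnv},
                    {"phenotype_rows": len(obs), "markers": panel.n_markers})
    return panel, obs, truth


def stage_qc(cfg: RunConfig, outdir: Path, manifest: Manifest):
    panel = markerqc.read_panel_tsv(outdir / "genotypes.tsv",
                                    outdir / "marker_map.tsv")
    filtered, log = markerqc.filter_markers(panel, cfg.maf_min,
                                            cfg.max_missing, cfg.max_het)
    imputed, zero_var = markerqc.impute_for_scan(filtered)
    pcs = markerqc.compute_pcs(imputed, k=min(cfg.n_pcs_computed,
                                              filtered.n_genotypes - 1))
    g, m = outdir / "genotypes_filtered.tsv", outdir / "marker_map_filtered.tsv"
    markerqc.write_panel_tsv(filtered, g, m)
    log_path = outdir / "marker_removal_log.tsv"
    log.to_csv(log_path, sep="\t", index=False)
    pc_path = outdir / "pc_scores.tsv"
    pc_df = pd.DataFrame(pcs.scores, index=filtered.genotypes,
                         columns=[f"PC{i+1}" for i in range(pcs.k)])
    pc_df.to_csv(pc_path, sep="\t", index_label="genotype")
    manifest.record("qc", [g, m, log_path, pc_path],
                    {"maf_min": cfg.maf_min, "max_missing": cfg.max_missing,
                     "max_het": cfg.max_het},
                    {"kept": filtered.n_markers, "removed": len(log)})
    return filtered, pcs


def _image_traits(obs: pd.DataFrame) -> list[str]:
    return [t for t in pd.unique(obs["trait"])
            if t not in ("fresh_weight", "dry_weight")]


def stage_blues(cfg: RunConfig, outdir: Path, manifest: Manifest):
    obs = simulate.read_phenotypes_csv(outdir / "phenotypes.csv")
    obs, removal = phenostats.filter_outliers(obs)
    removal_path = outdir / "phenotype_removal_log.tsv"
    removal.to_csv(removal_path, sep="\t", index=False)

    files = [removal_path]
    h2_rows = []
    for trait in pd.unique(obs["trait"]):
        endpoint = trait in ("fresh_weight", "dry_weight")
        spec = phenostats.EQ2 if endpoint else phenostats.EQ1
        n0_rule = "plant_reps" if endpoint else "experiments"
        tables = []
        for day in sorted(obs.loc[obs["trait"] == trait, "day"].unique()):
            tbl = phenostats.fit_blues(obs, spec, trait=trait, day=day)
            tbl.blues = tbl.blues[~tbl.blues.index.str.startswith("CHK")]
            tables.append(tbl)
            try:
                h2 = phenostats.estimate_h2(obs, spec, trait=trait, day=day,
                                            n0_rule=n0_rule)
                h2_rows.append({"trait": trait, "day": day, "sigma_g2": h2.sigma_g2,
                                "sigma_e2": h2.sigma_e2, "n0": h2.n0, "h2": h2.h2})
            except Exception as exc:
                logger.warning("H2 fit failed for %s day %s: %s", trait, day, exc)
        mat = phenostats.blue_matrix(tables)
        path = outdir / f"blues_{trait}.tsv"
        phenostats.write_blues_tsv(mat, path)
        files.append(path)
    h2_path = outdir / "heritability.tsv"
    pd.DataFrame(h2_rows).to_csv(h2_path, sep="\t", index=False)
    files.append(h2_path)
    manifest.record("blues", files, {"model": "eq1/eq2"},
                    {"h2_fits": len(h2_rows)})


def stage_rates(cfg: RunConfig, outdir: Path, manifest: Manifest):
    obs = simulate.read_phenotypes_csv(outdir / "phenotypes.csv")
    obs, _ = phenostats.filter_outliers(obs)
    image = obs[~obs["trait"].isin(["fresh_weight", "dry_weight"])]
    days = sorted(image["day"].unique())
    windows = phenostats.default_windows(days, span=cfg.rate_span)
    growth = [t for t in _image_traits(obs) if t != "color_uniformity"]
    rates = phenostats.compute_rates(image, kind="RGR", windows=windows,
                                     traits=growth)
    if "color_uniformity" in _image_traits(obs):
        acr = phenostats.compute_rates(image, kind="ACR", windows=windows,
                                       traits=["color_uniformity"])
        rates = pd.concat([rates, acr], ignore_index=True)
    rates_path = outdir / "rates.csv"
    out = rates.copy()
    for c in ("timestamp", "t1", "t2"):
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%dT%H:%M")
    out.to_csv(rates_path, index=False)

    files = [rates_path]
    for trait in pd.unique(rates["trait"]):
        tables = []
        for label in pd.unique(rates.loc[rates["trait"] == trait, "day"]):
            tbl = phenostats.fit_blues(rates, phenostats.EQ1, trait=trait, day=label)
            tbl.blues = tbl.blues[~tbl.blues.index.str.startswith("CHK")]
            tables.append(tbl)
        mat = phenostats.blue_matrix(tables)
        path = outdir / f"blues_{trait}.tsv"
        phenostats.write_blues_tsv(mat, path)
        files.append(path)
    manifest.record("rates", files, {"windows": windows},
                    {"rate_records": len(rates)})


def _scan_blue_file(cfg, outdir, panel, pcs, trait, path, files, records):
    mat = pd.read_csv(path, sep="\t", index_col="genotype")
    for label in mat.columns:
        rec = assocscan.scan_with_fdr(mat[label], panel, pcs, cfg.scan,
                                      trait=trait, time_label=label)
        records.append(rec)


def stage_scan(cfg: RunConfig, outdir: Path, manifest: Manifest):
    panel = markerqc.read_panel_tsv(outdir / "genotypes_filtered.tsv",
                                    outdir / "marker_map_filtered.tsv")
    pc_df = pd.read_csv(outdir / "pc_scores.tsv", sep="\t", index_col="genotype")
    pcs = markerqc.PcScores(pc_df.to_numpy(), np.zeros(pc_df.shape[1]))

    records = []
    for path in sorted(outdir.glob("blues_*.tsv")):
        trait = path.stem.removeprefix("blues_")
        _scan_blue_file(cfg, outdir, panel, pcs, trait, path, [], records)
    assoc = pd.concat(records, ignore_index=True)
    assoc_path = outdir / "associations.tsv"
    assoc.to_csv(assoc_path, sep="\t", index=False)
    sig_path = outdir / "associations_significant.tsv"
    assoc[assoc["significant"]].to_csv(sig_path, sep="\t", index=False)
    manifest.record("scan", [assoc_path, sig_path],
                    dataclasses.asdict(cfg.scan),
                    {"scans": sum(1 for _ in assoc.groupby(["trait", "time_label"])),
                     "significant": int(assoc["significant"].sum())})


def stage_dynamics(cfg: RunConfig, outdir: Path, manifest: Manifest):
    assoc = pd.read_csv(outdir / "associations.tsv", sep="\t")
    panel = markerqc.read_panel_tsv(outdir / "genotypes_filtered.tsv",
                                    outdir / "marker_map_filtered.tsv")
    pc_df = pd.read_csv(outdir / "pc_scores.tsv", sep="\t", index_col="genotype")
    pcs = markerqc.PcScores(pc_df.to_numpy(), np.zeros(pc_df.shape[1]))

    is_rate = assoc["trait"].str.endswith(("_RGR", "_ACR"))
    qtls = []
    for sub, k, label_sort in ((assoc[~is_rate], cfg.k_timepoint, int),
                               (assoc[is_rate], cfg.k_rate,
                                lambda s: int(str(s).split("-")[0]))):
        if sub.empty:
            continue
        for trait, grp in sub.groupby("trait"):
            labels = sorted(grp["time_label"].unique(), key=label_sort)
            qtls.extend(qtldynamics.filter_consecutive(grp, k=k, labels=labels))

    blue_cache: dict[str, dict] = {}
    for q in qtls:
        if q.trait not in blue_cache:
            mat = pd.read_csv(outdir / f"blues_{q.trait}.tsv", sep="\t",
                              index_col="genotype")
            blue_cache[q.trait] = {lbl: mat[lbl] for lbl in mat.columns}
        traj = qtldynamics.effect_trajectory(q.marker_id, blue_cache[q.trait],
                                             panel, pcs, n_pcs=cfg.scan.n_pcs)
        q.trajectory = traj
        q.reversal, q.switch_points = qtldynamics.detect_reversals(traj)

    dyn = qtldynamics.dynamic_qtl_table(qtls)
    dyn_path = outdir / "dynamic_qtl.tsv"
    dyn.to_csv(dyn_path, sep="\t", index=False)
    shared = qtldynamics.shared_markers(dyn) if len(dyn) else pd.DataFrame()
    shared_path = outdir / "shared_markers.tsv"
    shared.to_csv(shared_path, sep="\t", index=False)
    manifest.record("dynamics", [dyn_path, shared_path],
                    {"k_timepoint": cfg.k_timepoint, "k_rate": cfg.k_rate},
                    {"dynamic_qtl": len(dyn), "shared": len(shared)})
    return qtls


def stage_candidates(cfg: RunConfig, outdir: Path, manifest: Manifest):
    panel = markerqc.read_panel_tsv(outdir / "genotypes_filtered.tsv",
                                    outdir / "marker_map_filtered.tsv")
    dyn = pd.read_csv(outdir / "dynamic_qtl.tsv", sep="\t")
    annotation = (ldcandidates.read_annotation(cfg.annotation_path)
                  if cfg.annotation_path else pd.DataFrame(
                      columns=ldcandidates.GENE_COLUMNS))

    intervals = []
    for marker in pd.unique(dyn["marker_id"]) if len(dyn) else []:
        try:
            iv = ldcandidates.define_interval(marker, panel,
                                              r2_threshold=cfg.r2_threshold,
                                              flank=cfg.flank)
        except (KeyError, ValueError) as exc:
            logger.warning("no interval for %s: %s", marker, exc)
            continue
        genes = ldcandidates.genes_in_interval(iv, annotation)
        iv.genes = genes["gene_id"].tolist()
        intervals.append(iv)

    # subgenome-wise decay summary
    decay = {}
    for sub in ("A", "C"):
        try:
            fit = ldcandidates.fit_ld_decay(panel, sub)
            decay[sub] = {"rho": fit.rho, "half_decay_bp": fit.half_decay_bp,
                          "converged": fit.converged}
        except ValueError:
            pass
    decay_path = outdir / "ld_decay.json"
    decay_path.write_text(json.dumps(decay, indent=2))

    iv_path = outdir / "candidate_intervals.tsv"
    ldcandidates.interval_table(intervals).to_csv(iv_path, sep="\t", index=False)
    manifest.record("candidates", [iv_path, decay_path],
                    {"r2_threshold": cfg.r2_threshold, "flank": cfg.flank},
                    {"intervals": len(intervals)})
    return intervals


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "blues": stage_blues,
    "rates": stage_rates,
    "scan": stage_scan,
    "dynamics": stage_dynamics,
    "candidates": stage_candidates,
}


def run_all(cfg: RunConfig, stages: list[str] | None = None) -> Path:
    """Execute the pipeline stages in order; returns the run directory.

    On a stage failure the error is logged with the stage name and re-raised;
    outputs of completed stages remain on disk.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(asctime)s %(levelname)s [%(name)s] %(message)s")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir)
    todo = stages or STAGES
    if not cfg.simulate and "simulate" in todo:
        # copy external inputs into the run directory under the canonical names
        import shutil

        shutil.copy(cfg.genotypes_path, outdir / "genotypes.tsv")
        shutil.copy(cfg.marker_map_path, outdir / "marker_map.tsv")
        shutil.copy(cfg.phenotypes_path, outdir / "phenotypes.csv")
        todo = [s for s in todo if s != "simulate"]

    for stage in todo:
        logger.info("stage %s: start", stage)
        try:
            STAGE_FUNCS[stage](cfg, outdir, manifest)
        except Exception:
            logger.exception("stage %s: FAILED", stage)
            raise
        logger.info("stage %s: done", stage)
    return outdir
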