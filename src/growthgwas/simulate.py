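"""Synthetic genotype panels and replicated growth-phenotype time series.

The generator emulates a diverse allotetraploid (AACC) canola breeding panel
phenotyped daily through early vegetative growth:

* ~hundreds of genotypes drawn from a small number of admixed breeding pools
  (Dirichlet admixture over pool-specific allele frequencies),
* 19 chromosomes (A01-A10, C01-C09) with along-chromosome linkage
  disequilibrium generated by an autoregressive latent-haplotype process whose
  correlation decays as exp(-rho * distance); the A subgenome decays faster
  than the C subgenome,
* biallelic SNP markers plus deletion/duplication CNV calls,
* four image-derived traits measured on 21 days (6-13 and 15-27 DAS; day 14
  is structurally missing) — exponential biovolume and projected leaf area,
  linear early plant height, and a noisy, flat colour-uniformity trait —
  plus end-point fresh/dry weight derived from final biovolume,
* several glasshouse experiments with replicated check lines and imaging
  timestamps at minute precision,
* a known QTL architecture in which marker effects are restricted to short
  developmental windows and may reverse sign over time.

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .markerqc import MarkerPanel, encode_markers

#: measured days-after-sowing; day 14 is missing by design (plants sampled)
DEFAULT_DAYS: tuple[int, ...] = tuple(range(6, 14)) + tuple(range(15, 28))

#: time of day imaging starts
IMAGING_START_MINUTE = 8 * 60

SOWING_DATE = pd.Timestamp("2014-03-01 00:00")

PHENOTYPE_COLUMNS = [
    "genotype", "experiment", "carrier", "day", "timestamp",
    "trait", "value", "is_check", "position",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length_bp: int
    subgenome: str  # "A" or "C"


@dataclass(frozen=True)
class TraitSpec:
    """One measured trait and its growth law.

    ``growth_law`` is ``exponential`` (genetic and residual effects act on the
    log scale, residuals Gaussian on the log scale), ``linear`` or ``flat``
    (additive on the natural scale). ``rate`` is the per-day log-slope
    (exponential) or natural slope (linear); ignored for ``flat``.
    ``genetic_sd`` is the polygenic genotype-effect SD on the additive scale,
    ``noise_sd`` the residual SD, ``experiment_sd``/``gxe_sd`` the experiment
    main-effect and genotype-by-experiment SDs.
    """

    name: str
    growth_law: str
    baseline: float
    rate: float = 0.0
    genetic_sd: float = 0.1
    noise_sd: float = 0.1
    experiment_sd: float = 0.05
    gxe_sd: float = 0.03


@dataclass(frozen=True)
class QtlSpec:
    """A planted QTL: a marker with a trait effect inside an active window.

    ``effect`` may be a per-dosage-unit constant, a callable day -> effect
    (allowing sign change), or None, in which case the effect size is derived
    from ``variance_fraction`` (the target fraction of genotype-mean
    phenotypic variance explained while active). ``reversal_day`` is a
    convenience: the constant effect flips sign from that day on.
    ``marker_index`` may be None; a polymorphic marker (MAF > 0.2) is then
    chosen deterministically from the panel, with equal ``marker_key`` values
    mapping to the same marker across specs (shared-marker architecture).
    """

    trait: str
    window: tuple[int, int]
    variance_fraction: float = 0.05
    effect: float | Callable[[float], float] | None = None
    reversal_day: int | None = None
    marker_index: int | None = None
    marker_key: str | None = None

    def __post_init__(self):
        if not (0 <= self.variance_fraction < 1):
            raise ValueError("variance_fraction must be in [0, 1)")
        if self.window[0] > self.window[1]:
            raise ValueError("QTL window start must not exceed end")


def default_chromosomes() -> list[ChromosomeSpec]:
    chroms = [ChromosomeSpec(f"A{i:02d}", 25_000_000, "A") for i in range(1, 11)]
    chroms += [ChromosomeSpec(f"C{i:02d}", 45_000_000, "C") for i in range(1, 10)]
    return chroms


def default_traits() -> list[TraitSpec]:
    return [
        TraitSpec("biovolume", "exponential", baseline=2000.0, rate=0.18,
                  genetic_sd=0.12, noise_sd=0.10, experiment_sd=0.05, gxe_sd=0.03),
        TraitSpec("leaf_area", "exponential", baseline=1500.0, rate=0.15,
                  genetic_sd=0.11, noise_sd=0.10, experiment_sd=0.05, gxe_sd=0.03),
        TraitSpec("plant_height", "linear", baseline=20.0, rate=6.0,
                  genetic_sd=5.0, noise_sd=4.0, experiment_sd=2.0, gxe_sd=1.0),
        TraitSpec("color_uniformity", "flat", baseline=10.0,
                  genetic_sd=0.5, noise_sd=0.8, experiment_sd=0.3, gxe_sd=0.1),
    ]


def default_qtl() -> list[QtlSpec]:
    """Window-restricted QTL, including a shared marker and a sign reversal."""
    return [
        QtlSpec("biovolume", (9, 13), variance_fraction=0.08),
        QtlSpec("biovolume", (20, 25), variance_fraction=0.06),
        QtlSpec("biovolume", (16, 21), variance_fraction=0.10, marker_key="shared"),
        QtlSpec("leaf_area", (16, 21), variance_fraction=0.10, marker_key="shared"),
        QtlSpec("plant_height", (8, 24), variance_fraction=0.08, reversal_day=16),
    ]


@dataclass
class SimConfig:
    """Full specification of one synthetic study."""

    n_genotypes: int = 400
    n_pools: int = 3
    admixture_alpha: float = 0.3
    pool_divergence: float = 0.15  # Balding-Nichols F between pools
    chromosomes: list[ChromosomeSpec] = field(default_factory=default_chromosomes)
    n_snp: int = 1800
    n_cnv: int = 200
    cnv_dup_fraction: float = 0.02
    # per-bp latent-correlation decay; calibrated so the fitted r^2 half-decay
    # is ~400 kb on A and ~3.9 Mb on C (rho = ln 2 / (2 * half-decay))
    ld_rho_A: float = 8.7e-7
    ld_rho_C: float = 8.9e-8
    missing_rate: float = 0.02
    cnv_reciprocal_rate: float = 0.01
    inbreeding: float = 0.95  # fraction of genotypes that are fully homozygous lines
    n_experiments: int = 3
    replicates_per_experiment: int = 1
    days: tuple[int, ...] = DEFAULT_DAYS
    traits: list[TraitSpec] = field(default_factory=default_traits)
    qtl: list[QtlSpec] = field(default_factory=default_qtl)
    n_checks: int = 2
    check_replicates: int = 4
    check_sd: float = 0.05
    n_positions: int = 4
    position_sd: float = 0.02
    outlier_fraction: float = 0.0
    fw_scale: float = 2.0e-4
    fw_noise_sd: float = 0.05
    dw_ratio: float = 0.09
    seed: int = 0

    def __post_init__(self):
        if self.n_genotypes <= 0 or self.n_snp <= 0 or self.n_cnv < 0:
            raise ValueError("counts must be positive")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if list(self.days) != sorted(set(self.days)):
            raise ValueError("days must be strictly increasing")
        trait_names = {t.name for t in self.traits}
        for q in self.qtl:
            if q.trait not in trait_names:
                raise ValueError(f"QTL trait {q.trait!r} absent from trait list")
            if not (self.days[0] <= q.window[0] and q.window[1] <= self.days[-1]):
                raise ValueError(f"QTL window {q.window} outside measured days")

    @property
    def trait_map(self) -> dict[str, TraitSpec]:
        return {t.name: t for t in self.traits}

    @property
    def n_plant_reps(self) -> int:
        return self.n_experiments * self.replicates_per_experiment


@dataclass
class TruthRecord:
    """Ground truth of one simulation, reproducible from (config, seed)."""

    pools: np.ndarray
    genotype_ids: list[str]
    genetic_values: dict[str, pd.DataFrame] = field(default_factory=dict)
    qtl: pd.DataFrame | None = None
    qtl_effects: list[dict] = field(default_factory=list)
    realized_qtl_variance: pd.DataFrame | None = None
    outliers: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _marker_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay markers on chromosomes proportional to length, sorted positions."""
    total = config.n_snp + config.n_cnv
    lengths = np.array([c.length_bp for c in config.chromosomes], dtype=float)
    ideal = total * lengths / lengths.sum()
    counts = np.floor(ideal).astype(int)
    # largest-remainder allocation of the leftover markers
    leftover = total - counts.sum()
    counts[np.argsort(-(ideal - counts))[:leftover]] += 1

    rows = []
    for chrom, k in zip(config.chromosomes, counts):
        pos = np.sort(rng.choice(np.arange(1, chrom.length_bp, 100), size=k, replace=False))
        for p in pos:
            rows.append((chrom.name, int(p), chrom.subgenome))
    mmap = pd.DataFrame(rows, columns=["chromosome", "position", "subgenome"])
    is_cnv = np.zeros(len(mmap), dtype=bool)
    is_cnv[rng.choice(len(mmap), size=config.n_cnv, replace=False)] = True
    n_dup = int(round(config.cnv_dup_fraction * config.n_cnv))
    cls = np.where(is_cnv, "DEL", "SNP").astype(object)
    cnv_idx = np.flatnonzero(is_cnv)
    if n_dup and len(cnv_idx):
        cls[rng.choice(cnv_idx, size=min(n_dup, len(cnv_idx)), replace=False)] = "DUP"
    mmap["marker_class"] = cls
    mmap["marker_id"] = [
        f"sim-{c}-p{p}" + ("" if k == "SNP" else ("_del" if k == "DEL" else "_dup"))
        for c, p, k in zip(mmap.chromosome, mmap.position, mmap.marker_class)
    ]
    return mmap


def simulate_genotypes(config: SimConfig) -> tuple[MarkerPanel, TruthRecord]:
    """Simulate an admixed SNP+CNV panel with subgenome-specific LD.

    Each genotype carries two latent haplotypes per chromosome. A haplotype is
    a stationary Gaussian AR process with correlation exp(-rho * distance)
    between adjacent markers; the allele at a marker is the indicator that the
    Gaussian quantile falls below the genotype's admixed allele frequency, so
    allele frequencies follow the pool structure while r^2 decays with
    distance at the subgenome rate. CNV markers are emitted as
    deletion/duplication calls (with occasional reciprocal events) and encoded
    through :func:`growthgwas.markerqc.encode_markers`.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[0])
    mmap = _marker_map(config, rng)
    n, n_pools = config.n_genotypes, config.n_pools

    # pool structure: Balding-Nichols pool frequencies + Dirichlet admixture
    f = config.pool_divergence
    p0 = rng.uniform(0.08, 0.92, size=len(mmap))
    shape = (1.0 - f) / f
    pool_freq = rng.beta(p0 * shape, (1.0 - p0) * shape, size=(n_pools, len(mmap)))
    pool_freq = np.clip(pool_freq, 0.01, 0.99)

    pools = rng.integers(0, n_pools, size=n)
    alpha = np.full((n, n_pools), config.admixture_alpha)
    alpha[np.arange(n), pools] += 1.0
    # per-genotype Dirichlet with its own concentration vector
    gam = rng.gamma(alpha)
    q = gam / gam.sum(axis=1, keepdims=True)
    indiv_freq = q @ pool_freq  # n x markers

    from scipy.stats import norm

    # breeding lines are largely homozygous: an inbred genotype carries two
    # copies of the same haplotype
    inbred = rng.random(n) < config.inbreeding

    rho_by_sub = {"A": config.ld_rho_A, "C": config.ld_rho_C}
    dosage = np.empty((len(mmap), n))
    for chrom, sub in mmap.groupby("chromosome", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["position"].to_numpy()
        rho = rho_by_sub[sub["subgenome"].iloc[0]]
        z = np.empty((2 * n, len(idx)))
        z[:, 0] = rng.standard_normal(2 * n)
        for j in range(1, len(idx)):
            phi = np.exp(-rho * (pos[j] - pos[j - 1]))
            z[:, j] = phi * z[:, j - 1] + np.sqrt(1 - phi**2) * rng.standard_normal(2 * n)
        u = norm.cdf(z)  # 2n x markers
        thr = indiv_freq[:, idx]  # n x markers
        alleles = (u.reshape(n, 2, len(idx)) < thr[:, None, :])
        hap = np.where(inbred[:, None], 2 * alleles[:, 0, :], alleles.sum(axis=1))
        dosage[idx] = hap.T

    genotype_ids = [f"G{i:04d}" for i in range(n)]

    # emit raw call tables and encode them (exercises the coding rules)
    miss = rng.random((len(mmap), n)) < config.missing_rate
    snp_rows = mmap["marker_class"].to_numpy() == "SNP"
    snp_calls = mmap.loc[snp_rows, ["marker_id", "chromosome", "position"]].copy()
    snp_str = np.array(["AA", "AB", "BB"], dtype=object)[
        dosage[snp_rows].astype(int)
    ].astype(object)
    snp_str[miss[snp_rows]] = np.nan
    snp_calls = pd.concat(
        [snp_calls, pd.DataFrame(snp_str, index=snp_calls.index, columns=genotype_ids)],
        axis=1)

    cnv_rows = ~snp_rows
    cnv_calls = mmap.loc[cnv_rows, ["marker_id", "chromosome", "position", "marker_class"]].copy()
    if cnv_rows.any():
        event = np.where(
            (mmap.loc[cnv_rows, "marker_class"] == "DEL").to_numpy()[:, None],
            "deletion", "duplication",
        ).astype(object)
        recip = np.where(event == "deletion", "duplication", "deletion")
        state = np.where(dosage[cnv_rows] >= 1, event, "normal").astype(object)
        flip = rng.random(state.shape) < config.cnv_reciprocal_rate
        state[flip] = np.broadcast_to(recip, state.shape)[flip]
        state[miss[cnv_rows]] = np.nan
        cnv_calls = pd.concat(
            [cnv_calls, pd.DataFrame(state, index=cnv_calls.index, columns=genotype_ids)],
            axis=1)

    panel = encode_markers(snp_calls, cnv_calls if cnv_rows.any() else None)
    panel.pools = pools
    truth = TruthRecord(pools=pools, genotype_ids=genotype_ids)
    return panel, truth


# ---------------------------------------------------------------------------
# QTL resolution and genetic values
# ---------------------------------------------------------------------------

def _resolve_qtl(config: SimConfig, panel: MarkerPanel,
                 rng: np.random.Generator) -> list[dict]:
    """Assign markers and per-day effect functions to every QtlSpec."""
    stats = panel.with_stats().markers
    eligible = np.flatnonzero(
        (stats["maf"].to_numpy() > 0.2) & (stats["missing_frac"].to_numpy() < 0.05)
    )
    eligible = rng.permutation(eligible)
    key_map: dict[str, int] = {}
    used: set[int] = set()
    cursor = 0
    resolved = []
    for spec in config.qtl:
        if spec.marker_index is not None:
            midx = spec.marker_index
            if not (0 <= midx < panel.n_markers):
                raise ValueError(f"QTL marker index {midx} out of range")
        elif spec.marker_key is not None and spec.marker_key in key_map:
            midx = key_map[spec.marker_key]
        else:
            while cursor < len(eligible) and int(eligible[cursor]) in used:
                cursor += 1
            if cursor >= len(eligible):
                raise ValueError("not enough polymorphic markers to place QTL")
            midx = int(eligible[cursor])
            cursor += 1
        used.add(midx)
        if spec.marker_key is not None:
            key_map[spec.marker_key] = midx

        x = panel.dosages[midx].copy()
        x[np.isnan(x)] = np.nanmean(x)
        xc = x - x.mean()
        var_x = xc.var()
        tspec = config.trait_map[spec.trait]
        v_base = tspec.genetic_sd**2 + tspec.noise_sd**2 / config.n_plant_reps
        if spec.effect is None:
            fr = spec.variance_fraction
            b = np.sqrt(fr / (1.0 - fr) * v_base / max(var_x, 1e-12))
        else:
            b = spec.effect

        if callable(b):
            eff_fun = b
        elif spec.reversal_day is not None:
            rd, bb = spec.reversal_day, float(b)
            eff_fun = (lambda d, rd=rd, bb=bb: bb if d < rd else -bb)
        else:
            bb = float(b)
            eff_fun = (lambda d, bb=bb: bb)

        resolved.append({
            "spec": spec,
            "marker_index": midx,
            "marker_id": stats["marker_id"].iloc[midx],
            "dosage_centred": xc,
            "effect_fun": eff_fun,
        })
    return resolved


def _genetic_values(config: SimConfig, resolved: list[dict],
                    rng: np.random.Generator) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Per-trait genotype x day genetic values (polygenic + active QTL)."""
    n = config.n_genotypes
    days = np.asarray(config.days)
    values: dict[str, np.ndarray] = {}
    var_rows = []
    for tspec in config.traits:
        poly = rng.normal(0.0, tspec.genetic_sd, size=n)
        g = np.tile(poly[:, None], (1, len(days)))
        values[tspec.name] = g
    for qi, item in enumerate(resolved):
        spec: QtlSpec = item["spec"]
        g = values[spec.trait]
        tspec = config.trait_map[spec.trait]
        v_base = tspec.genetic_sd**2 + tspec.noise_sd**2 / config.n_plant_reps
        for j, d in enumerate(days):
            if spec.window[0] <= d <= spec.window[1]:
                b = item["effect_fun"](float(d))
                contrib = b * item["dosage_centred"]
                g[:, j] += contrib
                var_rows.append({
                    "qtl": qi, "marker_id": item["marker_id"], "trait": spec.trait,
                    "day": int(d), "effect": float(b),
                    "realized_fraction": float(contrib.var() / (contrib.var() + v_base)),
                    "target_fraction": spec.variance_fraction,
                })
    return values, pd.DataFrame(var_rows)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(panel: MarkerPanel, truth: TruthRecord,
                        config: SimConfig) -> pd.DataFrame:
    """Simulate the replicated long-format phenotype series (plus biomass).

    Each observation is growth-law mean + genotype genetic value (sum of
    active QTL effects plus a polygenic term) + experiment effect + genotype x
    experiment effect + check effect where flagged + residual noise; for
    exponential traits all effects act on the log scale (residuals Gaussian on
    the log scale). Timestamps carry minute precision with a per-day imaging
    stagger. End-point fresh/dry weight is a noisy monotone transform of
    final-day biovolume. Updates ``truth`` in place with genetic values,
    the QTL table and planted outliers; returns the observation table.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[1])

    resolved = _resolve_qtl(config, panel, rng)
    gvals, var_table = _genetic_values(config, resolved, rng)
    days = np.asarray(config.days)
    n = config.n_genotypes
    geno_ids = truth.genotype_ids

    truth.qtl = pd.DataFrame([
        {
            "marker_index": it["marker_index"], "marker_id": it["marker_id"],
            "trait": it["spec"].trait, "start_day": it["spec"].window[0],
            "end_day": it["spec"].window[1],
            "target_fraction": it["spec"].variance_fraction,
            "reversal_day": it["spec"].reversal_day,
        }
        for it in resolved
    ])
    truth.qtl_effects = [
        {"marker_index": it["marker_index"], "trait": it["spec"].trait,
         "effect_fun": it["effect_fun"]} for it in resolved
    ]
    truth.realized_qtl_variance = var_table
    truth.genetic_values = {
        t: pd.DataFrame(gvals[t], index=geno_ids, columns=days) for t in gvals
    }

    # design layout ------------------------------------------------------
    reps = config.replicates_per_experiment
    check_ids = [f"CHK{i}" for i in range(config.n_checks)]
    entries = []  # (genotype_label, geno_index or -1-check_index, is_check, carrier)
    for e in range(config.n_experiments):
        slot = 0
        for i in range(n):
            for r in range(reps):
                entries.append((geno_ids[i], i, False, e, f"E{e}C{slot:04d}"))
                slot += 1
        for ci, cid in enumerate(check_ids):
            for r in range(config.check_replicates):
                entries.append((cid, -(ci + 1), True, e, f"E{e}C{slot:04d}"))
                slot += 1
    layout = pd.DataFrame(entries, columns=["genotype", "gidx", "is_check", "exp", "carrier"])
    n_rows = len(layout)
    layout["position"] = [f"P{p+1}" for p in rng.integers(0, config.n_positions, n_rows)]

    # imaging schedule: per-day offset + per-carrier slot, minute precision
    day_offset = rng.integers(0, 90, size=len(days))
    carrier_slot = {c: (i * 3) % 420 for i, c in enumerate(pd.unique(layout["carrier"]))}

    gidx = layout["gidx"].to_numpy()
    expn = layout["exp"].to_numpy()
    is_check = layout["is_check"].to_numpy()

    frames = []
    for tspec in config.traits:
        g = gvals[tspec.name]  # n x days
        e_eff = rng.normal(0, tspec.experiment_sd, size=config.n_experiments)
        ge_eff = rng.normal(0, tspec.gxe_sd, size=(n, config.n_experiments))
        # size floor of 1 keeps the indexing in np.where valid when no checks
        chk_eff = rng.normal(0, config.check_sd, size=max(config.n_checks, 1))
        chk_exp_eff = rng.normal(0, config.check_sd / 2,
                                 size=(max(config.n_checks, 1), config.n_experiments))
        pos_eff = rng.normal(0, config.position_sd, size=config.n_positions)
        pos_codes = layout["position"].str[1:].astype(int).to_numpy() - 1

        for j, d in enumerate(days):
            minutes = IMAGING_START_MINUTE + day_offset[j] + np.array(
                [carrier_slot[c] for c in layout["carrier"]]
            )
            ts = (SOWING_DATE + pd.to_timedelta(int(d), unit="D")
                  + pd.to_timedelta(minutes, unit="m"))
            t_frac = int(d) + minutes / 1440.0

            add = np.where(is_check, 0.0, np.where(gidx >= 0, g[np.maximum(gidx, 0), j], 0.0))
            add = add + e_eff[expn] + np.where(
                is_check,
                chk_eff[np.maximum(-gidx - 1, 0)] + chk_exp_eff[np.maximum(-gidx - 1, 0), expn],
                ge_eff[np.maximum(gidx, 0), expn],
            )
            add = add + pos_eff[pos_codes]
            eps = rng.normal(0, tspec.noise_sd, size=n_rows)

            if tspec.growth_law == "exponential":
                value = tspec.baseline * np.exp(tspec.rate * (t_frac - days[0]) + add + eps)
            elif tspec.growth_law == "linear":
                value = tspec.baseline + tspec.rate * (t_frac - days[0]) + add + eps
            elif tspec.growth_law == "flat":
                value = tspec.baseline + add + eps
            else:
                raise ValueError(f"unknown growth law {tspec.growth_law!r}")

            frames.append(pd.DataFrame({
                "genotype": layout["genotype"], "experiment": [f"E{e}" for e in expn],
                "carrier": layout["carrier"], "day": int(d), "timestamp": ts,
                "trait": tspec.name, "value": value,
                "is_check": is_check, "position": layout["position"],
            }))

    obs = pd.concat(frames, ignore_index=True)

    # end-point biomass from final-day biovolume -------------------------
    if "biovolume" in gvals:
        bio = config.trait_map["biovolume"]
        final_log = bio.rate * (days[-1] + 1 - days[0]) + np.where(
            gidx >= 0, gvals["biovolume"][np.maximum(gidx, 0), -1], 0.0
        )
        e_eff = rng.normal(0, config.fw_noise_sd / 2, size=config.n_experiments)
        bday = int(days[-1] + 1)
        ts = SOWING_DATE + pd.to_timedelta(bday, unit="D") + pd.to_timedelta(9 * 60, unit="m")
        fw = (config.fw_scale * bio.baseline
              * np.exp(final_log + e_eff[expn] + rng.normal(0, config.fw_noise_sd, n_rows)))
        dw = (config.dw_ratio * config.fw_scale * bio.baseline
              * np.exp(final_log + e_eff[expn] + rng.normal(0, config.fw_noise_sd, n_rows)))
        for tname, vals in (("fresh_weight", fw), ("dry_weight", dw)):
            frames_bm = pd.DataFrame({
                "genotype": layout["genotype"], "experiment": [f"E{e}" for e in expn],
                "carrier": layout["carrier"], "day": bday, "timestamp": ts,
                "trait": tname, "value": vals,
                "is_check": is_check, "position": layout["position"],
            })
            obs = pd.concat([obs, frames_bm], ignore_index=True)

    # planted outliers ----------------------------------------------------
    if config.outlier_fraction > 0:
        k = int(round(config.outlier_fraction * len(obs)))
        pick = rng.choice(len(obs), size=k, replace=False)
        sd = obs.groupby(["experiment", "day", "trait"])["value"].transform("std")
        obs.loc[pick, "value"] += 10.0 * sd.iloc[pick].fillna(1.0)
        truth.outliers = obs.iloc[pick][["genotype", "experiment", "carrier",
                                         "day", "trait"]].reset_index(drop=True)
    else:
        truth.outliers = pd.DataFrame(
            columns=["genotype", "experiment", "carrier", "day", "trait"])

    return obs


def simulate_study(config: SimConfig) -> tuple[MarkerPanel, pd.DataFrame, TruthRecord]:
    """Convenience wrapper: genotypes then phenotypes for one config."""
    panel, truth = simulate_genotypes(config)
    obs = simulate_phenotypes(panel, truth, config)
    return panel, obs, truth


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_phenotypes_csv(obs: pd.DataFrame, path) -> None:
    out = obs.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M")
    out.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    obs = pd.read_csv(path, parse_dates=["timestamp"])
    obs["is_check"] = obs["is_check"].astype(bool)
    return obs


def write_truth_json(truth: TruthRecord, path) -> None:
    payload = {
        "pools": truth.pools.tolist(),
        "genotype_ids": truth.genotype_ids,
        "qtl": truth.qtl.to_dict(orient="records") if truth.qtl is not None else [],
        "realized_qtl_variance": (
            truth.realized_qtl_variance.to_dict(orient="records")
            if truth.realized_qtl_variance is not None else []),
        "outliers": truth.outliers.to_dict(orient="records") if truth.outliers is not None else [],
        "genetic_values": {
            t: {"index": list(df.index), "columns": [int(c) for c in df.columns],
                "data": df.to_numpy().tolist()}
            for t, df in truth.genetic_values.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def config_to_yaml(config: SimConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["chromosomes"] = [list(dataclasses.astuple(c)) for c in config.chromosomes]
    d["traits"] = [dataclasses.asdict(t) for t in config.traits]
    d["qtl"] = [
        {k: v for k, v in dataclasses.asdict(q).items() if not callable(v)}
        for q in config.qtl
    ]
    d["days"] = list(config.days)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def config_from_yaml(path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["chromosomes"] = [ChromosomeSpec(*c) for c in d["chromosomes"]]
    d["traits"] = [TraitSpec(**t) for t in d["traits"]]
    d["qtl"] = [QtlSpec(**{**q, "window": tuple(q["window"])}) for q in d["qtl"]]
    d["days"] = tuple(d["days"])
    return SimConfig(**d)
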