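"""Synthetic developmental-transcriptome generator with planted structure.

Emulates a BrainSpan-like cohort — ~42 donors aged 8 post-conception
weeks to 40 years, up to 16 grey-matter structures each (one
cerebellar), log-normal RPKM baselines with many near-zero genes — and
plants the structure the pipeline is meant to recover:

* a target gene whose cerebellar-relative population z-score rises
  linearly through foetal life and the first postnatal year, then
  declines linearly to adulthood;
* positively and negatively correlated gene modules that load on the
  target's whole log-expression deviation field (cerebellar effect and
  regional noise alike, the textbook co-expression structure), with the
  loading calibrated so their realized z-profiles have a requested
  population correlation with the target's;
* a configured fraction of never-expressed (all-zero) genes;
* per-(donor, structure) sampling dropout, with a subset of sparse
  donors destined to fail the specimen-inclusion rule.

Generative model: gene g in donor d, region r has
log RPKM = mu_g + b_{gd} + sigma * eps, with mu_g ~ N(log_mean_mu,
log_mean_sd^2), donor effect b ~ N(0, donor_effect_sd^2) and
region-exchangeable noise eps ~ N(0,1).  Because the z-score is
invariant to positive per-specimen scaling, mu and b cancel from every
z, so the planted cerebellar log-effect

    delta(zeta) = (sigma^2 - tau^2)/2 + log(1 + zeta * sqrt(e^{sigma^2} - 1))

gives the cerebellar sample (whose own noise SD is tau = ``noise_sd``)
a population z-score of exactly ``zeta``.  Requests that would need a
non-positive cerebellar mean (zeta below -1/sqrt(e^{sigma^2}-1)) are
infeasible and raise.  A module gene with loading a in (-1, 1) has
deviation field a * (target's deviations) + sqrt(1 - a^2) * (its own
independent noises), so a -> +/-1 drives the module-to-target z-profile
correlation to +/-1 while a = 0 recovers an unrelated null gene.
Module loadings and trajectory slopes targeting a given population
correlation are solved numerically on a seeded Monte-Carlo estimate
(common random numbers + Brent's method).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .ages import BIRTH_DAYS, DAYS_PER_MONTH, DAYS_PER_YEAR, AgePoint, parse_age
from .enrichment import AnnotationCollection, write_gmt
from .io import ExpressionDataset, SpecimenRecord, StructureLabel, write_brainspan

#: BrainSpan-style structure acronyms; CBC is the cerebellar one.
DEFAULT_REGIONS = (
    "CBC", "DFC", "VFC", "MFC", "OFC", "M1C", "S1C", "IPC",
    "A1C", "STC", "ITC", "V1C", "HIP", "AMY", "STR", "MD",
)


class InfeasibleCalibrationError(ValueError):
    """Requested planted effect cannot be realised under the noise model."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 42 donors, 16 regions, tens of thousands of
    genes, ~3.6% never expressed, a rise-then-fall target trajectory and
    +/-0.8 modules."""

    n_donors: int = 42
    age_min_days: float = 56.0          # 8 pcw
    age_max_days: float = 14890.0       # 40 yrs
    regions: tuple[str, ...] = DEFAULT_REGIONS
    cerebellar_region: str = "CBC"
    n_whole_cerebellum_donors: int = 3  # youngest donors carry 'CB' instead of 'CBC'
    region_dropout: float = 0.10
    n_sparse_donors: int = 12
    sparse_dropout: float = 0.70
    n_null_genes: int = 20_000
    n_positive_module: int = 60
    n_negative_module: int = 60
    fraction_never_expressed: float = 0.036
    #: RPKM below this is recorded as 0 (sequencing detection floor);
    #: all-zero profiles of low-baseline genes arise organically from it
    detection_floor: float = 0.01
    target_gene: str = "ATM"
    z_start: float = 0.0                # planted population z at age_min
    phase1_slope: float = 2.5           # z units per year up to peak_age_days
    phase2_slope: float = -0.065        # z units per year after the peak
    peak_age_days: float = BIRTH_DAYS + DAYS_PER_YEAR
    noise_sd: float = 0.05              # log-SD of planted genes' cerebellar sample
    r_mod: float = 0.8                  # requested module-to-target population corr
    region_noise_sd: float = 0.25       # log-SD of region-exchangeable noise
    log_mean_mu: float = -1.0
    log_mean_sd: float = 2.0
    # target/module genes are well-expressed (an ATM-like baseline),
    # so planted structure is not destroyed by the low-expression filter
    planted_log_mean_mu: float = 1.0
    planted_log_mean_sd: float = 0.5
    donor_effect_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_donors", "n_null_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_positive_module", "n_negative_module", "n_sparse_donors",
                     "n_whole_cerebellum_donors"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("region_dropout", "sparse_dropout", "fraction_never_expressed"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1.0 < self.r_mod < 1.0:
            raise ValueError("r_mod must lie in (-1, 1)")
        if not 0 < self.age_min_days < self.age_max_days:
            raise ValueError("invalid age range")
        if self.cerebellar_region not in self.regions:
            raise ValueError("cerebellar_region must be among regions")
        if self.n_sparse_donors > self.n_donors:
            raise ValueError("more sparse donors than donors")


@dataclass
class PlantedEffects:
    """Resolved calibration: module loadings on the target's deviations."""

    loading_positive: float
    loading_negative: float


@dataclass
class GroundTruth:
    config: SimulationConfig
    effects: PlantedEffects
    ages: dict[str, AgePoint]
    positive_module: tuple[str, ...]
    negative_module: tuple[str, ...]
    never_expressed: tuple[str, ...]
    target_zeta: dict[str, float]       # donor -> planted population z
    sparse_donors: tuple[str, ...]


def target_z_trajectory(age_days: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Planted population z of the target gene: linear rise to the peak
    age, then linear decline (slopes in z units per year)."""
    age = np.asarray(age_days, dtype=float)
    years_up = (np.minimum(age, cfg.peak_age_days) - cfg.age_min_days) / DAYS_PER_YEAR
    years_down = np.maximum(age - cfg.peak_age_days, 0.0) / DAYS_PER_YEAR
    return cfg.z_start + cfg.phase1_slope * years_up + cfg.phase2_slope * years_down


def cerebellar_log_effect(zeta: np.ndarray, sigma: float, tau: float) -> np.ndarray:
    """Log-scale additive cerebellar effect whose population z is ``zeta``."""
    zeta = np.asarray(zeta, dtype=float)
    cv = math.sqrt(math.expm1(sigma * sigma))
    arg = 1.0 + zeta * cv
    if np.any(arg <= 0):
        raise InfeasibleCalibrationError(
            f"planted z of {zeta[arg <= 0].min():.3f} requires a negative cerebellar "
            f"mean (floor is {-1.0 / cv:.3f} at region noise SD {sigma})"
        )
    return (sigma * sigma - tau * tau) / 2.0 + np.log(arg)


def _quantize_age_label(days: float) -> str:
    """Nearest dialect age label ('<n> pcw' / '<n> mos' / '<n> yrs')."""
    if days < BIRTH_DAYS:
        pcw = int(round(days / 7.0))
        pcw = min(max(pcw, 1), 39)
        return f"{pcw} pcw"
    months = (days - BIRTH_DAYS) / DAYS_PER_MONTH
    if months < 23.5:
        return f"{max(int(round(months)), 1)} mos"
    years = (days - BIRTH_DAYS) / DAYS_PER_YEAR
    return f"{max(int(round(years)), 2)} yrs"


def _sample_ages(cfg: SimulationConfig, rng: np.random.Generator) -> list[AgePoint]:
    """Log-uniform ages (dense prenatal coverage), quantized to labels."""
    raw = np.exp(
        rng.uniform(math.log(cfg.age_min_days), math.log(cfg.age_max_days), cfg.n_donors)
    )
    return [parse_age(_quantize_age_label(d)) for d in np.sort(raw)]


def _simulate_zhat_pairs(
    loading: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    n_mc: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo draws of (target zhat, module zhat) over random specimens.

    The module gene's deviations are ``loading`` times the target's plus
    sqrt(1 - loading^2) times independent noise of the same scales,
    mirroring the generator's co-expression structure.
    """
    sigma, tau = cfg.region_noise_sd, cfg.noise_sd
    a = loading
    b = math.sqrt(1.0 - a * a)
    ages = np.exp(
        rng.uniform(math.log(cfg.age_min_days), math.log(cfg.age_max_days), n_mc)
    )
    k = rng.binomial(len(cfg.regions) - 1, 1.0 - cfg.region_dropout, n_mc)
    k = np.maximum(k, 2)
    kmax = k.max()
    zeta_t = target_z_trajectory(ages, cfg)
    delta_t = cerebellar_log_effect(zeta_t, sigma, tau)
    dev_cb_t = delta_t + tau * rng.standard_normal(n_mc)
    dev_reg_t = sigma * rng.standard_normal((n_mc, kmax))
    dev_cb_g = a * dev_cb_t + b * tau * rng.standard_normal(n_mc)
    dev_reg_g = a * dev_reg_t + b * sigma * rng.standard_normal((n_mc, kmax))
    mask = np.arange(kmax)[None, :] < k[:, None]
    out = []
    for dev_cb, dev_reg in ((dev_cb_t, dev_reg_t), (dev_cb_g, dev_reg_g)):
        c = np.exp(dev_cb)
        x = np.where(mask, np.exp(dev_reg), np.nan)
        out.append((c - np.nanmean(x, axis=1)) / np.nanstd(x, axis=1, ddof=1))
    return out[0], out[1]


def module_profile_correlation(
    loading: float, cfg: SimulationConfig, n_mc: int = 20_000, seed: int = 7_654_321
) -> float:
    """Population correlation between a module gene's realized z profile
    and the target's, estimated by seeded Monte-Carlo (deterministic in
    ``loading`` via common random numbers)."""
    rng = np.random.default_rng(seed)
    zt, zg = _simulate_zhat_pairs(loading, cfg, rng, n_mc)
    return float(np.corrcoef(zt, zg)[0, 1])


def calibrate_module_loading(
    cfg: SimulationConfig, r_target: float, n_mc: int = 20_000
) -> float:
    """Solve for the loading whose realized z-profile correlation with
    the target equals ``r_target``.  Raises
    :class:`InfeasibleCalibrationError` when no loading in (-1, 1)
    reaches the request under the configured noise."""
    if r_target == 0.0:
        return 0.0
    lo, hi = (0.0, 1.0 - 1e-9) if r_target > 0 else (-1.0 + 1e-9, 0.0)
    f = lambda a: module_profile_correlation(a, cfg, n_mc) - r_target
    fl, fh = f(lo), f(hi)
    if not (min(fl, fh) <= 0.0 <= max(fl, fh)):
        reachable = fl + r_target if abs(fl) > abs(fh) else fh + r_target
        raise InfeasibleCalibrationError(
            f"module correlation {r_target:+.2f} unreachable (extreme feasible "
            f"correlation about {reachable:+.2f} under this noise model)"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-4))


def calibrate_effects(cfg: SimulationConfig, n_mc: int = 20_000) -> PlantedEffects:
    """Resolve both module loadings for a config (reusable across seeds)."""
    a_pos = (
        calibrate_module_loading(cfg, cfg.r_mod, n_mc) if cfg.n_positive_module else 0.0
    )
    a_neg = (
        calibrate_module_loading(cfg, -cfg.r_mod, n_mc) if cfg.n_negative_module else 0.0
    )
    return PlantedEffects(a_pos, a_neg)


def calibrate_phase1_slope(
    cfg: SimulationConfig, r_target: float, n_mc: int = 20_000, seed: int = 31_337
) -> float:
    """Phase-1 slope (z/year) whose realized age-vs-z population Pearson
    correlation, over ages sampled within phase 1, equals ``r_target``."""
    if not -1.0 < r_target < 1.0 or r_target == 0.0:
        raise ValueError("r_target must be in (-1, 1) and non-zero")
    phase_cfg = dataclasses.replace(
        cfg, age_max_days=min(cfg.age_max_days, cfg.peak_age_days)
    )

    def corr_for_slope(slope: float) -> float:
        c = dataclasses.replace(phase_cfg, phase1_slope=slope)
        rng = np.random.default_rng(seed)
        ages = np.exp(
            rng.uniform(math.log(c.age_min_days), math.log(c.age_max_days), n_mc)
        )
        k = rng.binomial(len(c.regions) - 1, 1.0 - c.region_dropout, n_mc)
        k = np.maximum(k, 2)
        zeta = target_z_trajectory(ages, c)
        delta = cerebellar_log_effect(zeta, c.region_noise_sd, c.noise_sd)
        cb = np.exp(delta + c.noise_sd * rng.standard_normal(n_mc))
        kmax = k.max()
        x = np.exp(c.region_noise_sd * rng.standard_normal((n_mc, kmax)))
        x = np.where(np.arange(kmax)[None, :] < k[:, None], x, np.nan)
        zhat = (cb - np.nanmean(x, axis=1)) / np.nanstd(x, axis=1, ddof=1)
        return float(np.corrcoef(ages, zhat)[0, 1])

    cv = math.sqrt(math.expm1(cfg.region_noise_sd ** 2))
    span_years = (phase_cfg.age_max_days - phase_cfg.age_min_days) / DAYS_PER_YEAR
    if r_target > 0:
        lo, hi = 0.0, 50.0
    else:
        # declining trajectories are floored by RPKM non-negativity
        lo, hi = -0.999 * (1.0 / cv + cfg.z_start) / span_years, 0.0
    f = lambda s: corr_for_slope(s) - r_target
    fl, fh = f(lo), f(hi)
    if not (min(fl, fh) <= 0.0 <= max(fl, fh)):
        raise InfeasibleCalibrationError(
            f"population age-z correlation {r_target:+.2f} unreachable in phase 1"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-3))


def _gene_names(cfg: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    pos = [f"POS{i + 1:04d}" for i in range(cfg.n_positive_module)]
    neg = [f"NEG{i + 1:04d}" for i in range(cfg.n_negative_module)]
    null = [f"GENE{i + 1:06d}" for i in range(cfg.n_null_genes)]
    return pos, neg, null


def simulate(
    cfg: SimulationConfig, effects: PlantedEffects | None = None
) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one synthetic cohort.

    ``effects`` (module calibration) depends only on the config, not the
    seed; pass a precomputed :class:`PlantedEffects` to amortise the
    calibration across replicates.
    """
    if effects is None:
        effects = calibrate_effects(cfg)
    rng = np.random.default_rng(cfg.seed)
    sigma, tau = cfg.region_noise_sd, cfg.noise_sd

    ages = _sample_ages(cfg, rng)
    donors = [f"D{i + 1:03d}" for i in range(cfg.n_donors)]
    sparse = tuple(
        sorted(rng.choice(donors, size=cfg.n_sparse_donors, replace=False))
    ) if cfg.n_sparse_donors else ()

    # per-donor structure realisation (dropout); youngest donors carry a
    # whole-cerebellum 'CB' sample instead of cerebellar cortex
    specimens: list[SpecimenRecord] = []
    columns: list[tuple[str, str]] = []
    cb_col_idx: dict[str, int] = {}
    for i, (donor, age) in enumerate(zip(donors, ages)):
        p_drop = cfg.sparse_dropout if donor in sparse else cfg.region_dropout
        kept = rng.random(len(cfg.regions)) >= p_drop
        labels = []
        for region, keep in zip(cfg.regions, kept):
            if not keep:
                continue
            is_cb = region == cfg.cerebellar_region
            acronym = region
            if is_cb and i < cfg.n_whole_cerebellum_donors:
                acronym = "CB"
            labels.append(StructureLabel(acronym, is_cb))
            if is_cb:
                cb_col_idx[donor] = len(columns)
            columns.append((donor, acronym))
        specimens.append(SpecimenRecord(donor, age, tuple(labels)))

    pos, neg, null = _gene_names(cfg)
    genes = [cfg.target_gene] + pos + neg + null
    G, C, D = len(genes), len(columns), len(donors)
    donor_of_col = np.array([donors.index(d) for d, _ in columns])

    mu = rng.normal(cfg.log_mean_mu, cfg.log_mean_sd, G)
    mu[: 1 + len(pos) + len(neg)] = rng.normal(
        cfg.planted_log_mean_mu, cfg.planted_log_mean_sd, 1 + len(pos) + len(neg)
    )
    donor_eff = rng.normal(0.0, cfg.donor_effect_sd, (G, D))
    dev = sigma * rng.standard_normal((G, C))

    # planted genes (target + modules): cerebellar samples carry their
    # own noise scale tau, and the target's carries the age effect
    age_days = np.array([a.days_post_conception for a in ages])
    zeta_t = target_z_trajectory(age_days, cfg)
    delta_t = cerebellar_log_effect(zeta_t, sigma, tau)
    n_planted = 1 + len(pos) + len(neg)
    cb_cols = np.array([cb_col_idx[d] for d in donors if d in cb_col_idx], dtype=int)
    cb_donors = np.array(
        [i for i, d in enumerate(donors) if d in cb_col_idx], dtype=int
    )
    if cb_cols.size:
        dev[:n_planted, cb_cols] = tau * rng.standard_normal((n_planted, cb_cols.size))
        dev[0, cb_cols] += delta_t[cb_donors]

    # module genes load on the target's whole deviation field
    for rows, loading in (
        (slice(1, 1 + len(pos)), effects.loading_positive),
        (slice(1 + len(pos), n_planted), effects.loading_negative),
    ):
        dev[rows] = loading * dev[0][None, :] + math.sqrt(1 - loading ** 2) * dev[rows]

    values = np.exp(mu[:, None] + donor_eff[:, donor_of_col] + dev)
    values[values < cfg.detection_floor] = 0.0

    if cfg.fraction_never_expressed > 0:
        n_never = int(round(cfg.fraction_never_expressed * cfg.n_null_genes))
        pick = rng.choice(len(null), size=n_never, replace=False)
        offset = 1 + len(pos) + len(neg)
        values[offset + np.sort(pick), :] = 0.0
    # bookkeeping: every all-zero row (planted or organic via the floor)
    never = sorted(np.asarray(genes)[~(values > 0).any(axis=1)])

    df = pd.DataFrame(
        values,
        index=pd.Index(genes, name="gene"),
        columns=pd.MultiIndex.from_tuples(columns, names=["donor_id", "structure"]),
    )
    ds = ExpressionDataset(df, specimens)
    gt = GroundTruth(
        config=cfg,
        effects=effects,
        ages={d: a for d, a in zip(donors, ages)},
        positive_module=tuple(pos),
        negative_module=tuple(neg),
        never_expressed=tuple(never),
        target_zeta={d: float(z) for d, z in zip(donors, zeta_t)},
        sparse_donors=sparse,
    )
    return ds, gt


def write_simulation(
    ds: ExpressionDataset, gt: GroundTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write the BrainSpan-dialect triplet plus a ground-truth sidecar."""
    out_dir = Path(out_dir)
    paths = write_brainspan(ds, out_dir)
    gt_path = out_dir / "ground_truth.txt"
    with open(gt_path, "w") as fh:
        fh.write(f"target_gene={gt.config.target_gene}\n")
        fh.write(f"seed={gt.config.seed}\n")
        fh.write(f"loading_positive={gt.effects.loading_positive!r}\n")
        fh.write(f"loading_negative={gt.effects.loading_negative!r}\n")
        fh.write("positive_module=" + ",".join(gt.positive_module) + "\n")
        fh.write("negative_module=" + ",".join(gt.negative_module) + "\n")
        fh.write("never_expressed=" + ",".join(gt.never_expressed) + "\n")
        fh.write("sparse_donors=" + ",".join(gt.sparse_donors) + "\n")
        for donor, zeta in gt.target_zeta.items():
            fh.write(f"target_zeta.{donor}={zeta!r}\n")
    paths["ground_truth"] = gt_path
    return paths


def simulate_gmt(
    universe: list[str],
    query: list[str],
    planted_term_fold: float,
    seed: int,
    n_random_terms: int = 50,
    term_size: int = 50,
    planted_term_id: str = "PLANTED",
) -> tuple[AnnotationCollection, str]:
    """Random annotation terms plus one term with a planted expected fold.

    Random terms are uniform draws from the universe; the planted term
    contains round(fold * K * n / N) designated-query members (the exact
    expected count under the fold definition) and random non-query
    members for the remainder.
    """
    if planted_term_fold < 1.0:
        raise ValueError("planted_term_fold must be >= 1")
    rng = np.random.default_rng(seed)
    universe = sorted(set(universe))
    query_in = sorted(set(query) & set(universe))
    N, n, K = len(universe), len(query_in), term_size
    if K > N:
        raise InfeasibleCalibrationError("term size exceeds universe")
    k = int(round(planted_term_fold * K * n / N))
    if k > min(K, n) or (K - k) > (N - n):
        raise InfeasibleCalibrationError(
            f"fold {planted_term_fold} infeasible for K={K}, n={n}, N={N} (k={k})"
        )
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(n_random_terms):
        members = frozenset(rng.choice(universe, size=term_size, replace=False))
        terms[f"T{i + 1:04d}"] = (f"random term {i + 1}", members)
    non_query = sorted(set(universe) - set(query_in))
    planted = frozenset(
        list(rng.choice(query_in, size=k, replace=False))
        + list(rng.choice(non_query, size=K - k, replace=False))
    )
    terms[planted_term_id] = (f"planted fold {planted_term_fold:g}", planted)
    return AnnotationCollection(terms, frozenset(universe)), planted_term_id
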