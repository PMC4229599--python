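"""Seeded synthetic study generator.

Emulates the structure of a combinatorial fermentation experiment on
*Lactococcus lactis*: a small design over four process factors (salt,
starting pH, temperature, aeration), logistic growth curves whose rate and
carrying capacity depend on temperature and pH, latent stress-robustness
phenotypes (log10 survival) with condition- and time-point-level noise,
plate-count CFU observations with Poisson noise at the counted-colony scale,
and two-channel microarray probe intensities with an intensity-dependent dye
bias and a planted set of genes whose expression tracks robustness.

The latent robustness for fermentation *f*, stress *s* and time point *t* is

    R[f, s, t] = base_s + effect_s(f) + L[f, s] + eps[f, s, t]

where ``effect_s`` is the stress-specific systematic factor effect (aeration
for heat, temperature for oxidative stress), ``L`` is a shared condition
component (so the 30- and 60-minute phenotypes correlate) and ``eps`` is
time-point noise.  Planted genes respond linearly to the shared part
``base + effect + L``, which is what makes them recoverable at both time
points by the downstream signature selection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import FACTOR_COLUMNS, load_fermentation_table

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "SimulatedStudy",
    "generate_design",
    "generate_truth",
    "simulate_growth_curves",
    "simulate_robustness_counts",
    "simulate_probe_intensities",
    "simulate_study",
    "write_study",
]

STRESSES = ("heat", "oxidative")
STRESS_TIMES = (30, 60)

# substream tags so each stage draws from an independent, call-order-free stream
_STAGE_DESIGN, _STAGE_TRUTH, _STAGE_GROWTH, _STAGE_CFU, _STAGE_PROBES = range(5)


def _default_factor_levels() -> dict[str, tuple]:
    return {
        "nacl_mM": (0, 100),
        "start_pH": (6.0, 6.5),
        "temperature_C": (27, 30, 35),
        "aeration": ("+", "-"),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with defaults matching the emulated
    experiment: 13 fermentations (one condition duplicated), 2369 genes,
    1-5 probes per gene, 10 planted robustness-responsive genes per stress.

    Robustness units are log10(Nt/N0); expression units are log2 ratios.
    """

    n_fermentations: int = 13
    factor_levels: dict[str, tuple] = field(default_factory=_default_factor_levels)
    n_genes: int = 2369
    probes_per_gene: tuple[int, int] = (1, 5)
    n_planted_per_stress: int = 10
    planted_slope: float = 1.0          # max |slope|, log2 per log10 robustness
    planted_slope_min: float = 0.5
    planted_frac_positive: float = 0.7
    n_effect_genes: int = 0             # genes with factor main effects, per factor
    effect_size_log2: float = 1.0
    dye_bias_amplitude: float = 0.8     # M units
    cfu_baseline: float = 1e8           # CFU/ml before stress
    n_replicates: int = 2
    noise_sd_expression: float = 0.2    # per-channel log2 noise
    noise_sd_growth: float = 0.03       # multiplicative OD noise (log scale)
    # latent robustness model (log10 units)
    heat_base: float = -2.7
    heat_aeration_effect: float = 1.5
    oxidative_base: float = -2.8
    oxidative_temp_effect: float = 1.5  # total shift from 27 to 35 degC
    latent_cross_sd: float = 0.35       # condition noise shared across stresses
    latent_stress_sd: float = 0.35      # condition noise per stress (30/60 shared)
    time_sd_30: float = 0.5             # 30-min time-point noise
    time_sd_60: float = 0.2             # 60-min time-point noise (more repeatable)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_per_stress * len(STRESSES) > self.n_genes:
            raise ValueError("n_planted_per_stress exceeds available genes")
        for name, levels in self.factor_levels.items():
            if len(levels) == 0:
                raise ValueError(f"factor {name!r} has an empty level set")
        if self.probes_per_gene[0] < 1 or self.probes_per_gene[0] > self.probes_per_gene[1]:
            raise ValueError("probes_per_gene must be a (lo, hi) range with lo >= 1")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class PlantedTruth:
    """Ground truth of a simulated study.

    ``planted`` maps stress -> DataFrame(gene_id, slope); ``shared`` holds the
    time-point-free robustness component per fermentation x stress that planted
    genes respond to; ``latent`` holds the realized per-time-point robustness.
    """

    planted: dict[str, pd.DataFrame]
    shared: pd.DataFrame   # fermentation_id, stress, shared
    latent: pd.DataFrame   # fermentation_id, stress, time_min, robustness
    effect_genes: pd.DataFrame  # gene_id, factor, effect_log2

    def planted_ids(self, stress: str) -> set[str]:
        return set(self.planted[stress]["gene_id"])


def generate_design(config: SimulationConfig) -> pd.DataFrame:
    """Build the combinatorial fermentation design.

    With the default 13-fermentation request and default factor levels the
    study's own design is returned (rows 1-12 distinct, row 13 duplicating
    row 6).  A request for the full factorial size returns every combination
    once.  Other sizes are sampled (seeded) from the factorial subject to a
    coverage requirement: every level of every factor present in at least two
    rows (one row when fewer than 12 fermentations are requested).
    """
    levels = config.factor_levels
    n = config.n_fermentations
    if n < 1:
        raise ValueError("n_fermentations must be positive")
    if levels == _default_factor_levels() and n == 13:
        return load_fermentation_table()[["fermentation_id"] + FACTOR_COLUMNS].copy()

    names = list(levels)
    combos = list(itertools.product(*(levels[k] for k in names)))
    min_per_level = 2 if n >= 12 else 1
    max_levels = max(len(v) for v in levels.values())
    if n < max_levels * min_per_level:
        raise ValueError(
            f"{n} fermentations cannot cover every factor level "
            f"{min_per_level} time(s)"
        )
    if n == len(combos):
        chosen = combos
    else:
        rng = config.rng(_STAGE_DESIGN)
        for _ in range(1000):
            if n <= len(combos):
                idx = rng.choice(len(combos), size=n, replace=False)
            else:
                idx = np.concatenate(
                    [np.arange(len(combos))] * (n // len(combos))
                    + [rng.choice(len(combos), size=n % len(combos), replace=False)]
                )
            candidate = [combos[i] for i in idx]
            cols = list(zip(*candidate))
            ok = all(
                sum(v == lev for v in cols[j]) >= min_per_level
                for j, name in enumerate(names)
                for lev in levels[name]
            )
            if ok:
                chosen = candidate
                break
        else:
            raise ValueError("could not satisfy level coverage; too few fermentations")
    df = pd.DataFrame(chosen, columns=names)
    df.insert(0, "fermentation_id", np.arange(1, n + 1))
    return df


def _shared_robustness(design: pd.DataFrame, config: SimulationConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for _, r in design.iterrows():
        aer = 1.0 if r["aeration"] == "+" else 0.0
        temp = float(r["temperature_C"])
        sys_eff = {
            "heat": config.heat_base + config.heat_aeration_effect * aer,
            "oxidative": config.oxidative_base
            + config.oxidative_temp_effect * (temp - 27.0) / 8.0,
        }
        # condition-level noise split into a component common to both stresses
        # (heat and oxidative survival co-vary across fermentations) and a
        # stress-specific one; both are shared by the 30- and 60-min assays
        common = rng.normal(0.0, config.latent_cross_sd)
        for stress in STRESSES:
            rows.append((r["fermentation_id"], stress,
                         sys_eff[stress] + common
                         + rng.normal(0.0, config.latent_stress_sd)))
    return pd.DataFrame(rows, columns=["fermentation_id", "stress", "shared"])


def generate_truth(design: pd.DataFrame, config: SimulationConfig) -> PlantedTruth:
    """Draw the latent robustness surface and the planted gene sets."""
    rng = config.rng(_STAGE_TRUTH)
    shared = _shared_robustness(design, config, rng)
    time_sd = {30: config.time_sd_30, 60: config.time_sd_60}
    lat_rows = []
    for _, r in shared.iterrows():
        for t in STRESS_TIMES:
            lat_rows.append((r["fermentation_id"], r["stress"], t,
                             r["shared"] + rng.normal(0.0, time_sd[t])))
    latent = pd.DataFrame(
        lat_rows, columns=["fermentation_id", "stress", "time_min", "robustness"]
    )

    gene_ids = np.array([f"gene_{i:04d}" for i in range(config.n_genes)])
    picked = rng.choice(config.n_genes,
                        size=config.n_planted_per_stress * len(STRESSES),
                        replace=False)
    planted = {}
    for k, stress in enumerate(STRESSES):
        idx = picked[k * config.n_planted_per_stress:(k + 1) * config.n_planted_per_stress]
        mag = rng.uniform(config.planted_slope_min, config.planted_slope, size=len(idx))
        sign = np.where(rng.random(len(idx)) < config.planted_frac_positive, 1.0, -1.0)
        planted[stress] = pd.DataFrame(
            {"gene_id": gene_ids[idx], "slope": mag * sign}
        )

    taken = set(picked)
    free = np.array([i for i in range(config.n_genes) if i not in taken])
    eff_rows = []
    if config.n_effect_genes > 0:
        for factor in config.factor_levels:
            sel = rng.choice(free, size=config.n_effect_genes, replace=False)
            free = np.setdiff1d(free, sel)
            for i in sel:
                eff_rows.append((gene_ids[i], factor,
                                 config.effect_size_log2 * rng.choice([-1.0, 1.0])))
    effect_genes = pd.DataFrame(eff_rows, columns=["gene_id", "factor", "effect_log2"])
    return PlantedTruth(planted=planted, shared=shared, latent=latent,
                        effect_genes=effect_genes)


# growth-rate and carrying-capacity anchors per factor level (h^-1 / OD units)
_GROWTH_RATE_BY_TEMP = {27: 0.81, 30: 0.97, 35: 1.07}
_CAPACITY_BY_PH = {6.0: 2.06, 6.5: 2.96}


def simulate_growth_curves(design: pd.DataFrame, config: SimulationConfig,
                           t_end: float = 10.0, dt: float = 0.5) -> pd.DataFrame:
    """Logistic OD600 trajectories, one per fermentation.

    The intrinsic rate depends on temperature (slower at 27 degC) and the
    carrying capacity on starting pH (higher at 6.5); duplicated conditions
    share parameters and differ only by multiplicative observation noise.
    """
    if design.empty:
        raise ValueError("design is empty")
    rng = config.rng(_STAGE_GROWTH)
    times = np.arange(0.0, t_end + 1e-9, dt)
    od0 = 0.05
    out = []
    for _, row in design.iterrows():
        r = _GROWTH_RATE_BY_TEMP[int(row["temperature_C"])]
        k = _CAPACITY_BY_PH[float(row["start_pH"])]
        od = k / (1.0 + (k - od0) / od0 * np.exp(-r * times))
        od = od * np.exp(rng.normal(0.0, config.noise_sd_growth, size=times.size))
        out.append(pd.DataFrame({
            "fermentation_id": row["fermentation_id"],
            "time_h": times,
            "od600": od,
        }))
    return pd.concat(out, ignore_index=True)


_MAX_COLONIES = 300  # largest countable expectation per plated spot


def simulate_robustness_counts(design: pd.DataFrame, truth: PlantedTruth,
                               config: SimulationConfig) -> pd.DataFrame:
    """CFU observations before/after stress with serial-dilution Poisson noise.

    Counts are drawn at the plated-colony scale (expectation capped at
    ~300 colonies) and rescaled by the power-of-ten dilution, mirroring
    spot plating of serial dilutions.
    """
    rng = config.rng(_STAGE_CFU)
    lat = truth.latent.set_index(["fermentation_id", "stress", "time_min"])["robustness"]
    rows = []
    for _, row in design.iterrows():
        fid = row["fermentation_id"]
        for stress in STRESSES:
            for t in (0,) + STRESS_TIMES:
                rob = 0.0 if t == 0 else float(lat.loc[(fid, stress, t)])
                for rep in range(1, config.n_replicates + 1):
                    n0 = config.cfu_baseline * np.exp(rng.normal(0.0, 0.1))
                    expected = n0 * 10.0 ** rob
                    if expected <= 0:
                        nt = 0.0
                    else:
                        dil = max(0, int(np.ceil(np.log10(max(expected, 1.0) / _MAX_COLONIES))))
                        nt = float(rng.poisson(expected / 10.0 ** dil)) * 10.0 ** dil
                    rows.append((fid, stress, t, rep, n0, nt))
    return pd.DataFrame(
        rows,
        columns=["fermentation_id", "stress", "time_min", "replicate",
                 "n0_cfu_per_ml", "nt_cfu_per_ml"],
    )


def _dye_bias(a: np.ndarray, amplitude: float) -> np.ndarray:
    # single smooth bow over the occupied intensity range (classic two-color
    # banana shape), centered at A ~ 10
    return amplitude * np.sin(0.5 * (a - 10.0))


def simulate_probe_intensities(design: pd.DataFrame, truth: PlantedTruth,
                               config: SimulationConfig) -> pd.DataFrame:
    """Two-channel probe intensities for every fermentation (one array each).

    The reference channel reflects a fixed per-gene baseline; the sample
    channel additionally carries the planted robustness response (slope times
    the shared robustness component) and any factor main effects.  Both
    channels are distorted by a smooth intensity-dependent dye bias applied
    symmetrically, so M is shifted while A is preserved.
    """
    rng = config.rng(_STAGE_PROBES)
    n_genes = config.n_genes
    gene_ids = np.array([f"gene_{i:04d}" for i in range(n_genes)])
    baseline = rng.normal(10.0, 1.5, size=n_genes)
    lo, hi = config.probes_per_gene
    n_probes_per_gene = rng.integers(lo, hi + 1, size=n_genes)
    gene_idx = np.repeat(np.arange(n_genes), n_probes_per_gene)
    n_probes = gene_idx.size
    probe_affinity = rng.normal(0.0, 0.5, size=n_probes)
    probe_ids = np.array([
        f"{gene_ids[g]}_p{j}"
        for g, j in zip(gene_idx, _within_gene_counter(gene_idx))
    ])

    # per-gene expression offsets per fermentation (log2)
    shared = truth.shared.set_index(["fermentation_id", "stress"])["shared"]
    slope_by_gene = {s: dict(zip(df["gene_id"], df["slope"]))
                     for s, df in truth.planted.items()}
    expr = np.zeros((n_genes, len(design)))
    id_to_row = {g: i for i, g in enumerate(gene_ids)}
    for f_col, (_, drow) in enumerate(design.iterrows()):
        fid = drow["fermentation_id"]
        for stress in STRESSES:
            x = float(shared.loc[(fid, stress)])
            for g, sl in slope_by_gene.get(stress, {}).items():
                expr[id_to_row[g], f_col] += sl * x
        for _, erow in truth.effect_genes.iterrows():
            levels = config.factor_levels[erow["factor"]]
            on = drow[erow["factor"]] == levels[-1]
            if on:
                expr[id_to_row[erow["gene_id"]], f_col] += erow["effect_log2"]

    frames = []
    for f_col, (_, drow) in enumerate(design.iterrows()):
        fid = drow["fermentation_id"]
        ref = (baseline[gene_idx] + probe_affinity
               + rng.normal(0.0, config.noise_sd_expression, size=n_probes))
        sam = (baseline[gene_idx] + probe_affinity + expr[gene_idx, f_col]
               + rng.normal(0.0, config.noise_sd_expression, size=n_probes))
        a0 = 0.5 * (ref + sam)
        bias = _dye_bias(a0, config.dye_bias_amplitude)
        sam = sam + bias / 2.0
        ref = ref - bias / 2.0
        frames.append(pd.DataFrame({
            "array_id": fid,
            "probe_id": probe_ids,
            "orf_id": gene_ids[gene_idx],
            "channel_sample": 2.0 ** sam,
            "channel_reference": 2.0 ** ref,
        }))
    return pd.concat(frames, ignore_index=True)


def _within_gene_counter(gene_idx: np.ndarray) -> np.ndarray:
    out = np.zeros_like(gene_idx)
    counter: dict[int, int] = {}
    for i, g in enumerate(gene_idx):
        counter[g] = counter.get(g, 0) + 1
        out[i] = counter[g]
    return out


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    design: pd.DataFrame
    truth: PlantedTruth
    growth: pd.DataFrame
    cfu: pd.DataFrame
    probes: pd.DataFrame


def simulate_study(config: SimulationConfig, seed: int | None = None) -> SimulatedStudy:
    """Generate every synthetic input of the study under one seed."""
    if seed is not None:
        config = replace(config, seed=seed)
    design = generate_design(config)
    truth = generate_truth(design, config)
    return SimulatedStudy(
        config=config,
        design=design,
        truth=truth,
        growth=simulate_growth_curves(design, config),
        cfu=simulate_robustness_counts(design, truth, config),
        probes=simulate_probe_intensities(design, truth, config),
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every table of a simulated study as TSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "design": outdir / "design.tsv",
        "growth": outdir / "growth_curves.tsv",
        "cfu": outdir / "cfu_counts.tsv",
        "probes": outdir / "probe_intensities.tsv",
        "truth_planted": outdir / "truth_planted.tsv",
        "truth_latent": outdir / "truth_latent.tsv",
    }
    study.design.to_csv(paths["design"], sep="\t", index=False)
    study.growth.to_csv(paths["growth"], sep="\t", index=False)
    study.cfu.to_csv(paths["cfu"], sep="\t", index=False)
    study.probes.to_csv(paths["probes"], sep="\t", index=False)
    planted = pd.concat(
        [df.assign(stress=s) for s, df in study.truth.planted.items()],
        ignore_index=True,
    )
    planted.to_csv(paths["truth_planted"], sep="\t", index=False)
    study.truth.latent.to_csv(paths["truth_latent"], sep="\t", index=False)
    return paths
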