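"""Desk-scale synthetic developmental transcriptome generator.

Generates gene x timepoint log2-CPM trajectories drawn from k module mean
curves parameterised on the orthogonal cubic basis, plus Gaussian noise on
the log scale, together with module-dependent gene annotations: chromosome
(with per-module enrichment multipliers), arm/center domain, operon
membership, gamete expression class, early-embryo category, ortholog
presence and lognormal K_A. The default scenario echoes the qualitative
structure of the C. elegans ontogeny: one early-embryo module whose
expression declines through development (fast-evolving, oogenic- and
arm-enriched), hump-shaped late-embryogenesis modules, spermatogenic
adult-peak modules, and constitutive modules differing mainly in overall
level, with the highly expressed ones operon-rich and slow-evolving.

All randomness flows from a single seed through named SeedSequence
substreams, so each draw family (modules, noise, K_A, categories, counts)
is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .molevo import stage_map
from .preprocess import CountTable, ExpressionMatrix
from .shape_metrics import build_basis

#: Genome-wide baseline rates the per-module odds multipliers act on.
BASE_CHROM_FRACS = {"I": 0.15, "II": 0.17, "III": 0.13, "IV": 0.16, "V": 0.20, "X": 0.19}
BASE_ARM_FRAC = 0.37
BASE_OPERON_FRAC = 0.205
BASE_GAMETE = {"spermatogenic": 0.15, "oogenic": 0.20, "sex-neutral": 0.55, "NA": 0.10}
BASE_EMBRYO = {"maternal": 0.45, "embryonic": 0.25, "transient": 0.15, "degradation": 0.15}

_SUBSTREAMS = ("module", "noise", "ka", "ortholog", "chromosome", "domain",
               "operon", "gamete", "embryo", "counts")


@dataclass
class ModuleProfile:
    """Generating parameters of one coexpression module."""

    name: str
    weight: float
    coeffs: tuple  # (alpha, beta1, beta2, beta3) on the cubic basis
    ka_median: float
    ortholog_fraction: float = 0.65
    chromosome_multipliers: dict = field(default_factory=dict)
    arm_odds: float = 1.0
    operon_odds: float = 1.0
    gamete_multipliers: dict = field(default_factory=dict)
    embryo_multipliers: dict = field(default_factory=dict)


@dataclass
class SyntheticConfig:
    modules: list
    n_genes: int = 3000
    T: int = 30
    noise_sd: float = 0.5
    ka_log_sd: float = 0.8           # sd of natural-log K_A within a module
    embryo_annotated_fraction: float = 0.34
    replicate_sd: float = 0.1        # between-replicate sd for timepoints 26..30
    library_size: int = 20_000_000
    seed: int = 1

    @property
    def k_true(self) -> int:
        return len(self.modules)

    def validate(self) -> None:
        w = np.array([m.weight for m in self.modules])
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("module weights must sum to 1")
        if (w <= 0).any():
            raise ValueError("module weights must be positive")
        if self.noise_sd < 0 or self.replicate_sd < 0 or self.ka_log_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if any(m.ka_median <= 0 for m in self.modules):
            raise ValueError("K_A medians must be > 0")
        if self.T < 4 or self.n_genes < 1:
            raise ValueError("invalid problem size")


def _rngs(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_SUBSTREAMS, children)}


def _odds_prob(base: float, odds_multiplier: float) -> float:
    odds = base / (1.0 - base) * odds_multiplier
    return odds / (1.0 + odds)


def _categorical(rng, base: dict, multipliers: dict, size: int) -> np.ndarray:
    cats = list(base)
    p = np.array([base[c] * multipliers.get(c, 1.0) for c in cats], dtype=float)
    p /= p.sum()
    return rng.choice(cats, size=size, p=p)


def generate(cfg: SyntheticConfig, as_counts: bool = False):
    """Generate (ExpressionMatrix | CountTable, annotation frame, truth frame).

    Trajectories are basis @ module coefficients + N(0, noise_sd^2) per
    timepoint. With ``as_counts`` the log-CPM values are inverted at the
    configured library size with Poisson sampling to produce an approximate
    count table (timepoints 26..30 duplicated with replicate noise),
    exercising the preprocessing stage.
    """
    cfg.validate()
    rng = _rngs(cfg.seed)
    k = cfg.k_true
    basis = build_basis(cfg.T)
    gene_ids = pd.Index([f"g{i:05d}" for i in range(cfg.n_genes)], name="gene_id")

    weights = np.array([m.weight for m in cfg.modules])
    module_idx = rng["module"].choice(k, size=cfg.n_genes, p=weights)
    coeffs = np.array([m.coeffs for m in cfg.modules])
    traj = coeffs[module_idx] @ basis.columns.T
    traj = traj + rng["noise"].normal(0.0, cfg.noise_sd, size=traj.shape)

    has_orth = np.empty(cfg.n_genes, dtype=bool)
    ka = np.full(cfg.n_genes, np.nan)
    ks = np.full(cfg.n_genes, np.nan)
    chrom = np.empty(cfg.n_genes, dtype=object)
    domain = np.empty(cfg.n_genes, dtype=object)
    operon = np.empty(cfg.n_genes, dtype=bool)
    gamete = np.empty(cfg.n_genes, dtype=object)
    embryo = np.full(cfg.n_genes, pd.NA, dtype=object)

    z_ka = rng["ka"].normal(0.0, 1.0, cfg.n_genes)
    u_orth = rng["ortholog"].random(cfg.n_genes)
    u_arm = rng["domain"].random(cfg.n_genes)
    u_op = rng["operon"].random(cfg.n_genes)
    u_emb = rng["embryo"].random(cfg.n_genes)
    for j, mod in enumerate(cfg.modules):
        idx = np.flatnonzero(module_idx == j)
        has_orth[idx] = u_orth[idx] < mod.ortholog_fraction
        ka_j = mod.ka_median * np.exp(cfg.ka_log_sd * z_ka[idx])
        ka[idx] = np.where(has_orth[idx], ka_j, np.nan)
        ks[idx] = np.where(has_orth[idx], 2.33 * np.exp(0.3 * z_ka[idx]), np.nan)
        chrom[idx] = _categorical(rng["chromosome"], BASE_CHROM_FRACS,
                                  mod.chromosome_multipliers, len(idx))
        domain[idx] = np.where(u_arm[idx] < _odds_prob(BASE_ARM_FRAC, mod.arm_odds),
                               "arm", "center")
        operon[idx] = u_op[idx] < _odds_prob(BASE_OPERON_FRAC, mod.operon_odds)
        gamete[idx] = _categorical(rng["gamete"], BASE_GAMETE,
                                   mod.gamete_multipliers, len(idx))
        annotated = idx[u_emb[idx] < cfg.embryo_annotated_fraction]
        embryo[annotated] = _categorical(rng["embryo"], BASE_EMBRYO,
                                         mod.embryo_multipliers, len(annotated))

    ann = pd.DataFrame({
        "chromosome": chrom,
        "domain": domain,
        "operon": operon,
        "gamete_class": np.where(gamete == "NA", pd.NA, gamete),
        "embryo_category": embryo,
        "has_ortholog": has_orth,
        "ka": ka,
        "ks": ks,
    }, index=gene_ids)

    truth = pd.DataFrame({
        "module": module_idx + 1,
        "module_name": [cfg.modules[j].name for j in module_idx],
        "alpha": coeffs[module_idx, 0],
        "beta1": coeffs[module_idx, 1],
        "beta2": coeffs[module_idx, 2],
        "beta3": coeffs[module_idx, 3],
        "ka": ka,
    }, index=gene_ids)

    tp_meta = stage_map(cfg.T) if cfg.T == 30 else pd.DataFrame(
        {"minutes": np.nan, "stage": "NA"}, index=pd.RangeIndex(1, cfg.T + 1, name="timepoint"))

    if not as_counts:
        em = ExpressionMatrix(
            values=pd.DataFrame(traj, index=gene_ids, columns=tp_meta.index),
            timepoints=tp_meta.assign(n_replicates=1),
            replicates_averaged=True,
        )
        return em, ann, truth

    # count-space export: duplicate the postembryonic timepoints 26..T
    dup_from = max(cfg.T - 4, 1)
    samples, sample_tp, sample_rep = [], [], []
    for t in range(1, cfg.T + 1):
        reps = 2 if t >= dup_from else 1
        for r in range(1, reps + 1):
            samples.append(f"t{t:02d}r{r}")
            sample_tp.append(t)
            sample_rep.append(r)
    log_expr = traj[:, np.array(sample_tp) - 1]
    log_expr = log_expr + rng["counts"].normal(0.0, cfg.replicate_sd, size=log_expr.shape)
    lam = 2.0**log_expr / 1e6 * cfg.library_size
    counts = rng["counts"].poisson(lam)
    meta = pd.DataFrame({
        "timepoint": sample_tp,
        "minutes": [tp_meta.loc[t, "minutes"] for t in sample_tp],
        "stage": [tp_meta.loc[t, "stage"] for t in sample_tp],
        "replicate": sample_rep,
    }, index=pd.Index(samples, name="sample_id"))
    ct = CountTable(counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
                    sample_meta=meta)
    return ct, ann, truth


def default_scenario(seed: int = 1) -> SyntheticConfig:
    """Eight-module scenario echoing the ontogenetic archetypes.

    3,000 genes, 30 timepoints, log-scale noise sd 0.5. Module separations in
    the (alpha, beta) space are wide enough that the full pipeline recovers
    the generating partition with ARI >= 0.9.
    """
    modules = [
        ModuleProfile(
            name="early_decline", weight=0.10, coeffs=(6.0, -3.0, 1.0, -0.5),
            ka_median=0.40, ortholog_fraction=0.30,
            chromosome_multipliers={"II": 2.0}, arm_odds=3.0, operon_odds=0.5,
            gamete_multipliers={"oogenic": 3.0},
            embryo_multipliers={"transient": 3.0, "maternal": 0.4},
        ),
        ModuleProfile(
            name="late_embryo_a", weight=0.14, coeffs=(5.0, 2.5, -2.0, -1.0),
            ka_median=0.10, ortholog_fraction=0.65,
            chromosome_multipliers={"X": 2.0},
        ),
        ModuleProfile(
            name="late_embryo_b", weight=0.12, coeffs=(3.0, 1.2, -2.5, -0.5),
            ka_median=0.08, ortholog_fraction=0.65,
            chromosome_multipliers={"X": 2.0},
        ),
        ModuleProfile(
            name="adult_peak_a", weight=0.10, coeffs=(4.0, 3.0, 2.0, 1.0),
            ka_median=0.26, ortholog_fraction=0.55,
            chromosome_multipliers={"V": 1.5}, operon_odds=0.1,
            gamete_multipliers={"spermatogenic": 3.0, "oogenic": 0.2},
        ),
        ModuleProfile(
            name="adult_peak_b", weight=0.10, coeffs=(2.0, 1.8, 1.5, 0.8),
            ka_median=0.19, ortholog_fraction=0.55,
            chromosome_multipliers={"IV": 1.5}, operon_odds=0.1,
            gamete_multipliers={"spermatogenic": 3.0, "oogenic": 0.2},
        ),
        ModuleProfile(
            name="constitutive_high", weight=0.12, coeffs=(9.0, 0.0, 0.0, 0.0),
            ka_median=0.033, ortholog_fraction=0.92, operon_odds=3.0,
            embryo_multipliers={"maternal": 2.0, "transient": 0.5},
        ),
        ModuleProfile(
            name="constitutive_mid", weight=0.16, coeffs=(6.8, 0.3, 0.0, 0.0),
            ka_median=0.06, ortholog_fraction=0.80, operon_odds=2.0,
        ),
        ModuleProfile(
            name="constitutive_low", weight=0.16, coeffs=(1.0, 0.0, 0.3, 0.0),
            ka_median=0.15, ortholog_fraction=0.60, arm_odds=2.0,
        ),
    ]
    return SyntheticConfig(modules=modules, seed=seed)
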