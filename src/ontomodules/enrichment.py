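"""Contingency-table enrichment of coexpression modules.

Each module is tested against genomic and functional categories with 2x2
Pearson chi-square tests (1 df, no continuity correction by default):
module membership x chromosome (mitochondrial genes excluded), module x
arm/center recombination domain within each chromosome, and module x
cross-referenced gene sets (operon membership, gamete expression class,
early-embryo category). Chromosome and domain families are adjusted by
Holm-Bonferroni; cross-referenced gene-set families use plain Bonferroni.
Genes lacking the tested annotation are excluded from that test's universe
rather than counted as negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

CHROMOSOMES = ("I", "II", "III", "IV", "V", "X")
RESULT_COLS = ("module", "category", "observed", "expected", "obs_exp_ratio",
               "chi2", "df", "p_raw", "p_adjusted", "significant")


@dataclass
class Chi2Result:
    chi2: float
    df: int
    p: float
    degenerate: bool = False


def chi2_2x2(table, yates: bool = False) -> Chi2Result:
    """Pearson chi-square on a 2x2 table, 1 df.

    No continuity correction unless ``yates``. A zero row or column margin
    makes the test undefined; such tables return chi2=0, p=1 flagged
    degenerate.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    if t.sum() <= 0:
        raise ValueError("empty table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return Chi2Result(0.0, 1, 1.0, degenerate=True)
    chi2, p, df, _ = stats.chi2_contingency(t, correction=yates)
    return Chi2Result(float(chi2), int(df), float(p), degenerate=False)


def holm_bonferroni(p) -> np.ndarray:
    """Step-down Holm adjustment, monotone and capped at 1."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def bonferroni(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="bonferroni")[1]


def _tests_to_frame(rows, adjust, alpha) -> pd.DataFrame:
    out = pd.DataFrame(rows, columns=list(RESULT_COLS[:-2]))
    if len(out):
        out["p_adjusted"] = adjust(out["p_raw"].to_numpy())
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["p_adjusted"] = []
        out["significant"] = []
    return out


def _universe(labels: pd.Series, ann: pd.DataFrame) -> pd.Index:
    common = labels.index.intersection(ann.index)
    dropped = len(labels) - len(common)
    if dropped:
        log.info("dropping %d assigned genes without annotation", dropped)
    return common


def module_by_chromosome(labels: pd.Series, ann: pd.DataFrame,
                         alpha: float = 0.05, yates: bool = False) -> pd.DataFrame:
    """One 2x2 test per (module, chromosome) pair; Holm across the family.

    The universe is the assigned, annotated genes on the six nuclear
    chromosomes (MtDNA excluded). obs_exp_ratio is
    observed / (module size x chromosome fraction of the universe).
    """
    genes = _universe(labels, ann)
    ann = ann.loc[genes]
    keep = ann["chromosome"].isin(CHROMOSOMES)
    if (~keep).sum():
        log.info("excluding %d MtDNA/unplaced genes", int((~keep).sum()))
    genes = genes[keep]
    lab = labels.loc[genes].to_numpy()
    chrom = ann.loc[genes, "chromosome"].to_numpy()
    n = len(genes)
    rows = []
    for m in sorted(np.unique(lab)):
        in_m = lab == m
        if not in_m.any():
            continue
        for c in CHROMOSOMES:
            if (chrom == c).sum() == 0:
                continue
            on_c = chrom == c
            obs = int((in_m & on_c).sum())
            expected = in_m.sum() * on_c.sum() / n
            table = [[obs, in_m.sum() - obs],
                     [on_c.sum() - obs, n - in_m.sum() - on_c.sum() + obs]]
            r = chi2_2x2(table, yates=yates)
            rows.append((m, c, obs, expected,
                         obs / expected if expected > 0 else np.nan,
                         r.chi2, r.df, r.p))
    return _tests_to_frame(rows, holm_bonferroni, alpha)


def module_by_domain(labels: pd.Series, ann: pd.DataFrame,
                     alpha: float = 0.05, yates: bool = False) -> pd.DataFrame:
    """Arm vs center 2x2 test per (module, chromosome); Holm across the family.

    Restricted to genes with an assigned recombination domain. ``observed``
    is the module's arm count on that chromosome and ``expected`` scales the
    chromosome's arm fraction to the module's gene count there.
    """
    genes = _universe(labels, ann)
    ann = ann.loc[genes]
    keep = ann["chromosome"].isin(CHROMOSOMES) & ann["domain"].isin(["arm", "center"])
    genes = genes[keep]
    lab = labels.loc[genes].to_numpy()
    chrom = ann.loc[genes, "chromosome"].to_numpy()
    arm = (ann.loc[genes, "domain"] == "arm").to_numpy()
    rows = []
    for m in sorted(np.unique(lab)):
        for c in CHROMOSOMES:
            on_c = chrom == c
            if on_c.sum() == 0:
                continue
            in_m = lab == m
            a = int((in_m & on_c & arm).sum())
            b = int((in_m & on_c & ~arm).sum())
            cc = int((~in_m & on_c & arm).sum())
            d = int((~in_m & on_c & ~arm).sum())
            if a + b == 0:
                continue
            expected = (a + b) * (a + cc) / on_c.sum()
            r = chi2_2x2([[a, b], [cc, d]], yates=yates)
            rows.append((m, f"{c}:arm", a, expected,
                         a / expected if expected > 0 else np.nan,
                         r.chi2, r.df, r.p))
    return _tests_to_frame(rows, holm_bonferroni, alpha)


def module_arm_fractions(labels: pd.Series, ann: pd.DataFrame) -> pd.DataFrame:
    """Pooled autosomal arm fraction per module, with the genome-wide fraction."""
    genes = _universe(labels, ann)
    ann = ann.loc[genes]
    keep = (ann["chromosome"].isin(CHROMOSOMES) & (ann["chromosome"] != "X")
            & ann["domain"].isin(["arm", "center"]))
    genes = genes[keep]
    lab = labels.loc[genes]
    arm = (ann.loc[genes, "domain"] == "arm")
    out = arm.groupby(lab.to_numpy()).agg(["mean", "size"])
    out.columns = ["arm_fraction", "n_genes"]
    out.index.name = "module"
    out["genome_arm_fraction"] = arm.mean()
    return out


def _geneset_categories(ann: pd.DataFrame, which: str):
    """Return (universe mask, {category: membership bool series})."""
    if which == "operon":
        col = ann["operon"]
        mask = col.notna()
        return mask, {"operon": col.fillna(False).astype(bool)}
    if which == "gamete_class":
        col = ann["gamete_class"]
        mask = col.notna() & (col != "NA")
        cats = sorted(col[mask].unique())
        return mask, {c: col == c for c in cats}
    if which == "embryo_category":
        col = ann["embryo_category"]
        mask = col.notna() & (col != "NA")
        sets = col[mask].astype(str).str.split("|")
        cats = sorted({c for s in sets for c in s})
        member = {c: pd.Series(False, index=ann.index) for c in cats}
        for c in cats:
            member[c].loc[sets.index] = sets.apply(lambda s: c in s)
        return mask, member
    raise ValueError(f"unknown gene-set attribute {which!r}")


def module_by_geneset(labels: pd.Series, ann: pd.DataFrame, which: str,
                      alpha: float = 0.05, yates: bool = False) -> pd.DataFrame:
    """2x2 module x category tests on the annotated-gene universe; Bonferroni.

    ``which`` selects the annotation family: ``operon`` (boolean), a
    ``gamete_class`` (spermatogenic / oogenic / sex-neutral), or
    ``embryo_category`` ( '|'-separated, not mutually exclusive). Only genes
    annotated for the selected attribute form the test universe.
    """
    genes = _universe(labels, ann)
    ann = ann.loc[genes]
    mask, member = _geneset_categories(ann, which)
    genes = genes[mask.loc[genes]]
    if len(genes) == 0:
        raise ValueError(f"no genes annotated for {which!r}")
    lab = labels.loc[genes].to_numpy()
    n = len(genes)
    rows = []
    for m in sorted(np.unique(lab)):
        in_m = lab == m
        for cat, memb in member.items():
            in_c = memb.loc[genes].to_numpy()
            if in_c.sum() == 0:
                continue
            obs = int((in_m & in_c).sum())
            expected = in_m.sum() * in_c.sum() / n
            table = [[obs, in_m.sum() - obs],
                     [in_c.sum() - obs, n - in_m.sum() - in_c.sum() + obs]]
            r = chi2_2x2(table, yates=yates)
            rows.append((m, cat, obs, expected,
                         obs / expected if expected > 0 else np.nan,
                         r.chi2, r.df, r.p))
    return _tests_to_frame(rows, bonferroni, alpha)


def read_breakpoints(path) -> pd.DataFrame:
    """BED-like TSV of 1-based inclusive (chrom, start, end, domain) intervals."""
    bp = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "domain"],
                     header=None, comment="#")
    if not bp["domain"].isin(["arm", "center"]).all():
        raise ValueError("domain column must be 'arm' or 'center'")
    return bp.sort_values(["chrom", "start"]).reset_index(drop=True)


def assign_domains(positions: pd.DataFrame, breakpoints: pd.DataFrame) -> pd.Series:
    """Map gene (chromosome, position) to arm/center domain.

    Intervals are 1-based inclusive; a position on a shared boundary belongs
    to the interval that *starts* there. Genes outside every interval get NA.
    """
    out = pd.Series(pd.NA, index=positions.index, dtype=object)
    for gid, row in positions.iterrows():
        cand = breakpoints[(breakpoints["chrom"] == row["chromosome"])
                           & (breakpoints["start"] <= row["position"])
                           & (breakpoints["end"] >= row["position"])]
        if len(cand):
            out.loc[gid] = cand.loc[cand["start"].idxmax(), "domain"]
    n_na = int(out.isna().sum())
    if n_na:
        log.info("%d genes fall outside every domain interval", n_na)
    return out
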