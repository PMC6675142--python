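"""Count-table ingestion and log-CPM normalisation for developmental time series.

The pipeline starts from a featureCounts-style gene x sample count table plus
a sample sheet mapping each sample column to a developmental timepoint and
replicate. Counts are normalised to log2 counts-per-million with a 0.5 prior
count, replicates are averaged on the log scale, and weakly expressed genes
(below a plain-CPM threshold at every timepoint) are removed, after which
log-CPM is recomputed on the filtered counts to account for the library-size
change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: featureCounts annotation columns that are ignored when reading a count TSV.
FEATURECOUNTS_ANNOT_COLS = frozenset(
    {"Chr", "Start", "End", "Strand", "Length", "chr", "start", "end", "strand", "length"}
)

SAMPLE_SHEET_COLS = ("sample_id", "timepoint", "minutes", "stage", "replicate")


@dataclass
class CountTable:
    """Gene x sample raw counts with per-sample timepoint metadata.

    ``counts`` is indexed by unique gene id; ``sample_meta`` is indexed by
    sample id and carries at least ``timepoint`` (1..T), ``minutes``,
    ``stage`` and ``replicate`` columns.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if not self.counts.columns.equals(self.sample_meta.index):
            missing = set(self.counts.columns) ^ set(self.sample_meta.index)
            raise ValueError(f"sample columns and sample sheet disagree: {sorted(missing)}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.sample_meta["timepoint"].isna().any():
            raise ValueError("every sample must map to a timepoint")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def library_size(self) -> pd.Series:
        """Per-sample total counts (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def n_timepoints(self) -> int:
        return self.sample_meta["timepoint"].nunique()


@dataclass
class ExpressionMatrix:
    """Gene x column log2-CPM values.

    Columns are samples until :func:`average_replicates` collapses them to one
    column per timepoint (ordered by developmental time). ``timepoints``
    carries the per-column metadata; ``replicate_r`` records the per-timepoint
    Pearson correlation between replicates observed during averaging.
    """

    values: pd.DataFrame
    timepoints: pd.DataFrame
    replicates_averaged: bool = False
    refiltered: bool = False
    replicate_r: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index


def read_counts(
    counts_path,
    sample_sheet_path,
    exclude_genes=None,
    gene_type_col: str | None = None,
    exclude_types=("transposable element", "pseudogene"),
) -> CountTable:
    """Read a featureCounts-style TSV and its sample sheet into a CountTable.

    Leading annotation columns (Chr/Start/End/Strand/Length) are ignored by
    name. ``exclude_genes`` drops an explicit id list (e.g. transposon or
    pseudogene entries); alternatively ``gene_type_col`` names a column in the
    counts TSV whose values are matched against ``exclude_types``.
    """
    df = pd.read_csv(counts_path, sep="\t", comment="#")
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    df.index.name = "gene_id"

    type_series = None
    if gene_type_col is not None:
        if gene_type_col not in df.columns:
            raise ValueError(f"gene type column {gene_type_col!r} not in counts table")
        type_series = df[gene_type_col]
        df = df.drop(columns=[gene_type_col])
    df = df.drop(columns=[c for c in df.columns if c in FEATURECOUNTS_ANNOT_COLS])

    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    for col in ("sample_id", "timepoint", "replicate"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet lacks required column {col!r}")
    for col in ("minutes", "stage"):
        if col not in sheet.columns:
            sheet[col] = np.nan
    sheet = sheet.set_index("sample_id")

    missing = [c for c in df.columns if c not in sheet.index]
    if missing:
        raise ValueError(f"sample columns missing from sample sheet: {missing}")
    sheet = sheet.loc[df.columns]

    bad = df.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        raise ValueError("non-numeric count values")
    df = bad

    if type_series is not None:
        drop = type_series.isin(exclude_types)
        log.info("excluding %d genes by annotation type", int(drop.sum()))
        df = df.loc[~drop]
    if exclude_genes is not None:
        df = df.drop(index=[g for g in exclude_genes if g in df.index])

    return CountTable(counts=df, sample_meta=sheet)


def log_cpm(ct: CountTable) -> ExpressionMatrix:
    """log2 counts-per-million with a 0.5 prior count and library size + 1.

    value = log2( (count + 0.5) / (library_size + 1) * 1e6 ), per sample.
    """
    lib = ct.library_size.to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    vals = np.log2((ct.counts.to_numpy(dtype=float) + 0.5) / (lib + 1.0) * 1e6)
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=ct.counts.index, columns=ct.counts.columns),
        timepoints=ct.sample_meta.copy(),
    )


def average_replicates(em: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicate samples per timepoint on the log scale.

    Single-replicate timepoints pass through unchanged. For duplicated
    timepoints the Pearson correlation between the replicate profiles is
    recorded in ``replicate_r`` (identical replicates are reported as r=1).
    """
    meta = em.timepoints
    tps = sorted(meta["timepoint"].unique())
    cols, rows, rvals = {}, [], {}
    for t in tps:
        samples = meta.index[meta["timepoint"] == t]
        block = em.values[samples]
        cols[t] = block.mean(axis=1)
        first = meta.loc[samples[0]]
        rows.append({"timepoint": t, "minutes": first.get("minutes"), "stage": first.get("stage"),
                     "n_replicates": len(samples)})
        if len(samples) >= 2:
            rs = []
            for i in range(len(samples)):
                for j in range(i + 1, len(samples)):
                    a, b = block.iloc[:, i], block.iloc[:, j]
                    if a.equals(b):
                        rs.append(1.0)
                    else:
                        rs.append(float(a.corr(b)))
            rvals[int(t)] = float(np.mean(rs))
    out = pd.DataFrame(cols)
    out.columns.name = "timepoint"
    tp_meta = pd.DataFrame(rows).set_index("timepoint")
    return ExpressionMatrix(values=out, timepoints=tp_meta, replicates_averaged=True,
                            refiltered=em.refiltered, replicate_r=rvals)


def filter_min_cpm(
    ct: CountTable,
    threshold_cpm: float = 1.0,
    min_timepoints: int = 1,
    per_timepoint: bool = True,
) -> tuple[CountTable, ExpressionMatrix]:
    """Drop genes below ``threshold_cpm`` plain CPM everywhere, then renormalise.

    The filter is evaluated on plain CPM (count / library_size * 1e6, no
    prior). With ``per_timepoint`` (default) CPM is first averaged across
    replicates of a timepoint; otherwise each sample counts separately. The
    threshold is inclusive (CPM equal to the threshold is retained). After
    filtering, log-CPM is recomputed from the *filtered* counts so library
    sizes reflect the removed genes, and replicates are re-averaged.
    """
    if threshold_cpm <= 0:
        raise ValueError("threshold_cpm must be > 0")
    lib = ct.library_size.to_numpy(dtype=float)
    cpm = pd.DataFrame(ct.counts.to_numpy(dtype=float) / lib * 1e6,
                       index=ct.counts.index, columns=ct.counts.columns)
    if per_timepoint:
        cpm = cpm.T.groupby(ct.sample_meta["timepoint"]).mean().T
    keep = (cpm >= threshold_cpm).sum(axis=1) >= min_timepoints
    if not keep.any():
        raise ValueError("all genes removed by CPM filter")
    log.info("CPM filter retained %d of %d genes", int(keep.sum()), len(keep))
    ct2 = CountTable(counts=ct.counts.loc[keep], sample_meta=ct.sample_meta)
    em2 = average_replicates(log_cpm(ct2))
    em2.refiltered = True
    return ct2, em2
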