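"""Count-table containers, featureCounts-dialect I/O, TMM/CPM normalization
and replicate-concordance QC."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "QCReport",
    "read_counts_table",
    "read_samples_table",
    "tmm_factors",
    "cpm_normalize",
    "replicate_qc",
]

_META_COLUMNS = ["Chr", "Start", "End", "Strand", "Length"]


class SchemaError(ValueError):
    """Input table violates the expected layout or metadata contract."""


class DataError(ValueError):
    """Input table has invalid values (negative, non-integer, NaN counts)."""


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with sample (and optional gene) metadata."""

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene ids: {dups[:5]}")
        if c.columns.has_duplicates:
            raise DataError("duplicate sample ids")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if np.isnan(arr).any() or (arr != np.floor(arr)).any():
                raise DataError("counts must be non-negative integers")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise DataError("negative counts")
        missing = [s for s in c.columns if s not in self.sample_meta.index]
        if missing:
            raise SchemaError(f"sample columns without metadata: {missing}")
        # keep metadata aligned and restricted to present samples
        self.sample_meta = self.sample_meta.loc[c.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[list(sample_ids)],
            sample_meta=self.sample_meta.loc[list(sample_ids)],
            gene_meta=self.gene_meta,
        )


@dataclass
class NormalizedMatrix:
    """TMM-scaled CPM values with the factors and library sizes that produced them."""

    values: pd.DataFrame
    norm_factors: pd.Series
    lib_sizes: pd.Series
    sample_meta: pd.DataFrame

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def group_means(self, sample_ids) -> pd.Series:
        """Mean CPM per gene over the given samples."""
        return self.values[list(sample_ids)].mean(axis=1)


def read_samples_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "species", "tissue", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"samples table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise SchemaError("duplicate sample ids in samples table")
    return df.set_index("sample_id")


def read_counts_table(path, samples_path) -> CountMatrix:
    """Parse a featureCounts-style TSV plus its sample-metadata table.

    The first column must be ``Geneid``; the optional positional columns
    Chr/Start/End/Strand/Length are split into ``gene_meta``; everything
    else must be an integer sample column announced in the samples table.
    """
    sample_meta = read_samples_table(samples_path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "Geneid":
        raise SchemaError(f"first column must be 'Geneid', got {df.columns[0]!r}")
    df = df.set_index("Geneid")
    df.index.name = "gene_id"
    meta_cols = [c for c in _META_COLUMNS if c in df.columns]
    gene_meta = df[meta_cols] if meta_cols else None
    counts = df.drop(columns=meta_cols)
    unknown = [c for c in counts.columns if c not in sample_meta.index]
    if unknown:
        raise SchemaError(f"count columns not present in samples table: {unknown}")
    if counts.isna().any().any():
        raise DataError("NaN counts in table")
    return CountMatrix(counts=counts, sample_meta=sample_meta, gene_meta=gene_meta)


def tmm_factors(cm: CountMatrix, trim_m: float = 0.3, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    Reference sample: the one whose 75th count-fraction percentile is
    closest to the mean across samples.  For each sample, genes expressed in
    both it and the reference contribute an M (log2 ratio of count
    fractions) and an A (average log2 abundance); M-values are doubly
    trimmed (``trim_m`` of each M tail, ``trim_a`` of each A tail) and
    averaged with inverse-delta-method precision weights.  Factors are
    rescaled to geometric mean 1.
    """
    counts = cm.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    zero = lib == 0
    if zero.any():
        raise ValueError(f"all-zero sample(s): {list(cm.sample_ids[zero])}")
    frac = counts / lib
    f75 = np.quantile(frac, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(
            counts[:, j], counts[:, ref], lib[j], lib[ref], trim_m, trim_a
        )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.sample_ids, name="norm_factor")


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a) -> float:
    """log2 TMM factor of one sample against the reference."""
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 0.0
    obs, ref = obs[ok], ref[ok]
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method variance of M; smaller variance -> larger weight
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:  # identical composition: factor 1
        return 0.0
    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 0.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return 0.0 if not np.isfinite(f) else float(f)


def cpm_normalize(cm: CountMatrix, factors: pd.Series | None = None) -> NormalizedMatrix:
    """Counts per million over the effective library size (lib size x factor)."""
    if factors is None:
        factors = tmm_factors(cm)
    factors = factors.reindex(cm.sample_ids)
    if factors.isna().any():
        raise ValueError("factors not aligned to samples")
    lib = cm.lib_sizes()
    eff = lib * factors
    if (eff <= 0).any():
        bad = list(eff.index[eff <= 0])
        raise ValueError(f"zero effective library size for sample(s): {bad}")
    values = cm.counts / eff * 1e6
    return NormalizedMatrix(
        values=values,
        norm_factors=factors,
        lib_sizes=lib,
        sample_meta=cm.sample_meta,
    )


@dataclass
class QCReport:
    """Pairwise replicate correlations within species x tissue groups."""

    pairs: pd.DataFrame  # species, tissue, sample_1, sample_2, r, flagged
    group_summary: pd.DataFrame  # species, tissue, n_pairs, min_r, max_r
    min_r: float
    skipped_groups: list = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return int(self.pairs["flagged"].sum())


def replicate_qc(nm: NormalizedMatrix, min_r: float = 0.9, log_scale: bool = True) -> QCReport:
    """All within-group pairwise Pearson correlations of normalized expression.

    Correlations are computed on log2(CPM + 1) by default: on the linear
    scale multiplicative (overdispersion-driven) noise caps attainable
    replicate correlation at 1/(1 + phi) regardless of how concordant
    replicates are, so log-scale correlation is the informative concordance
    measure.  Pairs below ``min_r`` are flagged, never dropped.
    """
    vals = np.log2(nm.values + 1.0) if log_scale else nm.values
    rows = []
    summaries = []
    skipped = []
    for (species, tissue), meta in nm.sample_meta.groupby(["species", "tissue"], sort=True):
        samples = list(meta.index)
        if len(samples) < 2:
            warnings.warn(f"group {species}/{tissue} has <2 replicates; skipped")
            skipped.append((species, tissue))
            continue
        sub = vals[samples].to_numpy().T
        r = np.corrcoef(sub)
        group_rs = []
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                rij = float(r[i, j])
                rows.append((species, tissue, samples[i], samples[j], rij, rij < min_r))
                group_rs.append(rij)
        summaries.append((species, tissue, len(group_rs), min(group_rs), max(group_rs)))
    pairs = pd.DataFrame(
        rows, columns=["species", "tissue", "sample_1", "sample_2", "r", "flagged"]
    )
    group_summary = pd.DataFrame(
        summaries, columns=["species", "tissue", "n_pairs", "min_r", "max_r"]
    )
    overall = float(pairs["r"].min()) if len(pairs) else float("nan")
    return QCReport(pairs=pairs, group_summary=group_summary, min_r=overall, skipped_groups=skipped)
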