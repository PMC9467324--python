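"""GO-term expression analysis.

The central statistic is the *average GO expression*: for term k with
member genes i present in the expression matrix,

    expr_k = sum_i CPM_ik / count(ik),

the arithmetic mean of the member genes' mean CPM within a sample group.
Terms are then compared between two groups by a negative-binomial log-linear
model over the stacked member-gene expression values of both groups, between
species by a Welch test on the members' root-vs-shoot log fold changes, and
DEG sets are tested for term over-representation with a hypergeometric test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import _nbglm
from .counts import NormalizedMatrix
from .de import adjust_pvalues

__all__ = [
    "read_go_table",
    "aggregate_go_expression",
    "go_glm_test",
    "select_candidate_go",
    "cross_species_go_compare",
    "go_enrichment_hypergeometric",
]

LFC_PSEUDOCOUNT = 0.5


def read_go_table(path) -> pd.DataFrame:
    """Read a gene_id <TAB> go_id (optionally namespace) annotation table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns or "go_id" not in df.columns:
        raise ValueError("GO table needs columns gene_id and go_id")
    return df


def _members_present(ann: pd.DataFrame, gene_ids) -> pd.Series:
    present = ann[ann["gene_id"].isin(set(gene_ids))]
    return present.groupby("go_id")["gene_id"].apply(lambda g: sorted(set(g)))


def aggregate_go_expression(nm: NormalizedMatrix, ann: pd.DataFrame, group_samples) -> pd.DataFrame:
    """Average GO expression per term within one sample group.

    Genes absent from the matrix are dropped from the member count; terms
    with no present member are omitted.  Returns a frame indexed by go_id
    with ``expr`` and ``gene_count``.
    """
    members = _members_present(ann, nm.gene_ids)
    if members.empty:
        raise ValueError("no annotated gene is present in the expression matrix")
    gene_means = nm.group_means(group_samples)
    rows = {
        go_id: (gene_means.loc[genes].mean(), len(genes))
        for go_id, genes in members.items()
    }
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["expr", "gene_count"])
    out.index.name = "go_id"
    out["gene_count"] = out["gene_count"].astype(int)
    return out.sort_index()


def _pooled_mom_dispersion(samples_a: list[np.ndarray], samples_b: list[np.ndarray]) -> float:
    """Common NB dispersion over GO-level observations, pooled method of moments."""
    num = den = 0.0
    for vals in (*samples_a, *samples_b):
        if len(vals) < 2:
            continue
        m = vals.mean()
        if m <= 0:
            continue
        v = vals.var(ddof=1)
        num += v - m
        den += m * m
    if den <= 0:
        return 1e-6
    return float(np.clip(num / den, 1e-6, 10.0))


def go_glm_test(
    nm: NormalizedMatrix,
    ann: pd.DataFrame,
    group_a,
    group_b,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Two-group NB test of average GO expression, per term.

    Observations for term k are the member genes' mean CPM in group A and in
    group B (2 * count(ik) rows, gene pairing deliberately ignored), rounded
    to the nearest integer for the NB likelihood.  The group effect is
    tested by LRT at a common dispersion (pooled method-of-moments across
    terms unless given), and BH adjustment runs across terms.
    """
    members = _members_present(ann, nm.gene_ids)
    if members.empty:
        raise ValueError("no annotated gene is present in the expression matrix")
    means_a = nm.group_means(group_a)
    means_b = nm.group_means(group_b)

    obs_a = [np.round(means_a.loc[g].to_numpy(dtype=float)) for g in members]
    obs_b = [np.round(means_b.loc[g].to_numpy(dtype=float)) for g in members]
    if dispersion is None:
        dispersion = _pooled_mom_dispersion(obs_a, obs_b)

    rows = []
    for go_id, ya, yb in zip(members.index, obs_a, obs_b):
        k = len(ya)
        y = np.concatenate([ya, yb])[None, :]
        groups = np.array([0] * k + [1] * k)
        p, _, _ = _nbglm.lrt_two_group(y, np.ones(2 * k), groups, dispersion)
        expr_a = float(means_a.loc[members[go_id]].mean())
        expr_b = float(means_b.loc[members[go_id]].mean())
        log_fc = float(np.log2((expr_a + LFC_PSEUDOCOUNT) / (expr_b + LFC_PSEUDOCOUNT)))
        rows.append((go_id, k, expr_a, expr_b, log_fc, float(p[0])))
    out = pd.DataFrame(
        rows, columns=["go_id", "gene_count", "expr_a", "expr_b", "log_fc", "p_value"]
    ).set_index("go_id")
    out["fdr"] = adjust_pvalues(out["p_value"].to_numpy(), "fdr")
    out.attrs["dispersion"] = dispersion
    return out


def select_candidate_go(
    records: pd.DataFrame,
    fdr_max: float = 0.01,
    lfc_min: float = 3.0,
    min_genes: int = 5,
) -> pd.DataFrame:
    """Candidate terms: fdr < fdr_max, |log_fc| > lfc_min, gene_count >= min_genes."""
    mask = (
        (records["fdr"] < fdr_max)
        & (records["log_fc"].abs() > lfc_min)
        & (records["gene_count"] >= min_genes)
    )
    return records.loc[mask]


def cross_species_go_compare(
    de_sp1: pd.DataFrame,
    de_sp2: pd.DataFrame,
    ann_sp1: pd.DataFrame,
    ann_sp2: pd.DataFrame,
    fdr_max: float = 0.05,
    min_count: int = 2,
) -> pd.DataFrame:
    """Compare each GO term's tissue log-fold-change distribution between species.

    Inputs are per-gene tissue DE tables (``log_fc`` column, ``tested``
    flag) for each species with that species' annotation.  For every term
    shared by both annotations the members' LFC samples are compared by
    Welch's t-test; BH runs across terms; a term is selected when
    fdr < fdr_max and its gene count exceeds ``min_count`` in *both*
    species.  Terms with fewer than 2 usable members on either side are
    skipped (no defined test).
    """
    lfc1 = de_sp1.loc[de_sp1["tested"], "log_fc"]
    lfc2 = de_sp2.loc[de_sp2["tested"], "log_fc"]
    mem1 = _members_present(ann_sp1, lfc1.index)
    mem2 = _members_present(ann_sp2, lfc2.index)
    shared = sorted(set(mem1.index) & set(mem2.index))
    skipped = []
    rows = []
    for go_id in shared:
        a = lfc1.loc[mem1[go_id]].to_numpy()
        b = lfc2.loc[mem2[go_id]].to_numpy()
        if len(a) < 2 or len(b) < 2:
            skipped.append(go_id)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            t = stats.ttest_ind(a, b, equal_var=False)
        p = float(t.pvalue)
        if not np.isfinite(p):  # zero variance on both sides
            p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        rows.append((go_id, len(a), len(b), a.mean(), b.mean(), p))
    out = pd.DataFrame(
        rows,
        columns=[
            "go_id",
            "n_genes_species1",
            "n_genes_species2",
            "mean_lfc_species1",
            "mean_lfc_species2",
            "p_value",
        ],
    ).set_index("go_id")
    if len(out):
        out["fdr"] = adjust_pvalues(out["p_value"].to_numpy(), "fdr")
    else:
        out["fdr"] = pd.Series(dtype=float)
    out["selected"] = (
        (out["fdr"] < fdr_max)
        & (out["n_genes_species1"] > min_count)
        & (out["n_genes_species2"] > min_count)
    )
    out.attrs["skipped_terms"] = skipped
    return out


def go_enrichment_hypergeometric(deg, background, ann: pd.DataFrame) -> pd.DataFrame:
    """One-sided (upper tail) hypergeometric DEG over-representation per term.

    For a term with n members in a background of size M and a DEG list of
    size N overlapping the term in k genes, p = P(X >= k) under
    X ~ Hypergeom(M, n, N).  BH adjustment across terms; fold enrichment is
    (k/N)/(n/M).
    """
    deg = set(deg)
    background = set(background)
    if not deg <= background:
        raise ValueError("DEG set must be a subset of the background")
    if not deg:
        warnings.warn("empty DEG set; enrichment table is empty")
        return pd.DataFrame(
            columns=["n_term", "n_deg", "overlap", "fold_enrichment", "p_value", "fdr"]
        )
    members = _members_present(ann, background)
    M, N = len(background), len(deg)
    rows = []
    for go_id, genes in members.items():
        n = len(genes)
        k = len(deg & set(genes))
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        fold = (k / N) / (n / M) if n else float("nan")
        rows.append((go_id, n, N, k, fold, p))
    out = pd.DataFrame(
        rows, columns=["go_id", "n_term", "n_deg", "overlap", "fold_enrichment", "p_value"]
    ).set_index("go_id")
    out["fdr"] = adjust_pvalues(out["p_value"].to_numpy(), "fdr")
    return out.sort_values("p_value")
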