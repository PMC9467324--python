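"""Two-group negative-binomial differential expression.

The same machinery serves the root-vs-shoot contrast within a species and
the species-vs-species contrast within a tissue.  Replicates are treated as
i.i.d. NB observations in a fixed-effects log-linear model with a common
dispersion and an effective-library-size offset; the group effect is tested
by a likelihood-ratio test.  Log fold changes are reported descriptively as
log2 of pseudocounted group mean CPMs, so they stay finite for genes that
vanish in one group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import _nbglm
from .counts import CountMatrix, NormalizedMatrix, cpm_normalize, tmm_factors

__all__ = [
    "estimate_dispersion",
    "nb_two_group_test",
    "adjust_pvalues",
    "classify_presence",
    "select_deg",
    "split_groups",
]

LFC_PSEUDOCOUNT = 0.5


def split_groups(sample_meta: pd.DataFrame, column: str, levels=None):
    """Sample-id lists (group_a, group_b) for a two-level metadata column."""
    values = sample_meta[column]
    found = sorted(values.unique())
    if levels is None:
        levels = found
    if len(levels) != 2:
        raise ValueError(f"column {column!r} must have exactly 2 levels, got {found}")
    a = list(values.index[values == levels[0]])
    b = list(values.index[values == levels[1]])
    if not a or not b:
        raise ValueError(f"empty group among levels {levels}")
    return a, b


def estimate_dispersion(cm: CountMatrix, group_a, group_b, factors: pd.Series | None = None) -> float:
    """Common NB dispersion for a two-group contrast (Cox-Reid APL maximizer).

    Clamped to [1e-6, 10]; constant/degenerate data hit the lower clamp.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples to estimate dispersion")
    samples = list(group_a) + list(group_b)
    y = cm.counts[samples].to_numpy(dtype=float)
    lib = cm.lib_sizes()[samples].to_numpy(dtype=float)
    if factors is not None:
        lib = lib * factors.reindex(samples).to_numpy()
    offsets = lib / lib.mean()
    groups = np.array([0] * len(group_a) + [1] * len(group_b))
    return _nbglm.estimate_common_dispersion_apl(y, offsets, groups)


def nb_two_group_test(
    cm: CountMatrix,
    group_a,
    group_b,
    nm: NormalizedMatrix | None = None,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-gene NB LRT of group A vs group B.

    Returns a frame indexed by gene id with columns ``mean_a``/``mean_b``
    (CPM group means), ``log_fc`` (log2, positive = higher in A),
    ``p_value``, ``fdr``, ``bonferroni`` and ``tested``.  Genes with zero
    counts across the contrast are reported untested with p = 1 and are not
    counted in the adjustment denominator.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    samples = list(group_a) + list(group_b)
    sub = cm.subset_samples(samples)
    if nm is None:
        nm = cpm_normalize(sub, tmm_factors(sub))
    if dispersion is None:
        dispersion = _nbglm.estimate_common_dispersion_apl(
            sub.counts.to_numpy(dtype=float),
            (sub.lib_sizes() * nm.norm_factors.reindex(samples)).to_numpy() ,
            np.array([0] * len(group_a) + [1] * len(group_b)),
        )

    y = sub.counts.to_numpy(dtype=float)
    eff = (sub.lib_sizes() * nm.norm_factors.reindex(samples)).to_numpy(dtype=float)
    offsets = eff / eff.mean()
    groups = np.array([0] * len(group_a) + [1] * len(group_b))
    p, _, _ = _nbglm.lrt_two_group(y, offsets, groups, dispersion)

    mean_a = nm.group_means(group_a).reindex(cm.gene_ids)
    mean_b = nm.group_means(group_b).reindex(cm.gene_ids)
    log_fc = np.log2((mean_a + LFC_PSEUDOCOUNT) / (mean_b + LFC_PSEUDOCOUNT))
    tested = y.sum(axis=1) > 0
    p = np.where(tested, p, 1.0)
    log_fc = np.where(tested, log_fc, 0.0)

    fdr = np.ones_like(p)
    bonf = np.ones_like(p)
    if tested.any():
        fdr[tested] = adjust_pvalues(p[tested], "fdr")
        bonf[tested] = adjust_pvalues(p[tested], "bonferroni")
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log_fc": log_fc,
            "p_value": p,
            "fdr": fdr,
            "bonferroni": bonf,
            "tested": tested,
        },
        index=cm.gene_ids,
    )


def adjust_pvalues(p, method: str = "fdr") -> np.ndarray:
    """Benjamini-Hochberg step-up (``"fdr"``) or Bonferroni adjustment."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "fdr":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    raise ValueError(f"unknown method {method!r}")


def classify_presence(
    nm: NormalizedMatrix,
    group_a,
    group_b,
    threshold_cpm: float = 1.0,
    labels: tuple[str, str] = ("a", "b"),
):
    """Partition genes into both / A-only / B-only / neither by mean CPM.

    A gene counts as expressed in a group when its mean CPM across the
    group's replicates is at or above ``threshold_cpm``.  Returns
    ``(per_gene_frame, summary_dict)``; the summary carries counts and
    percentages of the full annotated gene set.
    """
    in_a = nm.group_means(group_a) >= threshold_cpm
    in_b = nm.group_means(group_b) >= threshold_cpm
    la, lb = labels
    cls = np.select(
        [in_a & in_b, in_a & ~in_b, ~in_a & in_b],
        ["both", f"{la}_only", f"{lb}_only"],
        default="neither",
    )
    frame = pd.DataFrame({"presence": cls}, index=nm.gene_ids)
    total = len(frame)
    summary = {}
    for name in ["both", f"{la}_only", f"{lb}_only", "neither"]:
        n = int((cls == name).sum())
        summary[name] = n
        summary[f"{name}_pct"] = round(100.0 * n / total, 1) if total else float("nan")
    summary["total"] = total
    return frame, summary


def select_deg(results: pd.DataFrame, fdr_max: float = 0.01, lfc_min: float = 3.0) -> pd.DataFrame:
    """DEG selection rule: fdr < fdr_max and |log_fc| > lfc_min, split by sign.

    Returns the passing rows with a ``direction`` column (``up_in_a`` /
    ``up_in_b``).
    """
    mask = (results["fdr"] < fdr_max) & (results["log_fc"].abs() > lfc_min)
    out = results.loc[mask].copy()
    out["direction"] = np.where(out["log_fc"] > 0, "up_in_a", "up_in_b")
    return out
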