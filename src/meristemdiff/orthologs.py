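"""1:1 orthologue expression comparison across species.

Orthologue pairs are joined at the raw-count level, renormalized as their
own dataset (TMM factors over the joined samples), tested species-vs-species
per tissue with the shared NB machinery, and classified into DEG
(expression divergence), EEG (equally expressed) or neither.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .counts import CountMatrix, cpm_normalize, tmm_factors
from .de import nb_two_group_test, split_groups

__all__ = [
    "read_ortholog_map",
    "match_orthologs",
    "cross_species_de",
    "classify_deg_eeg",
    "pca_expression",
]

logger = logging.getLogger(__name__)

PAIR_SEP = "|"


def read_ortholog_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"species_a_gene", "species_b_gene"}
    if not need <= set(df.columns):
        raise ValueError(f"ortholog map needs columns {sorted(need)}")
    _check_one_to_one(df)
    return df


def _check_one_to_one(mapping: pd.DataFrame) -> None:
    for col in ("species_a_gene", "species_b_gene"):
        if mapping[col].duplicated().any():
            dup = mapping.loc[mapping[col].duplicated(), col].iloc[0]
            raise ValueError(f"gene {dup!r} occurs in more than one pair; map must be 1:1")


def match_orthologs(mapping: pd.DataFrame, cm_a: CountMatrix, cm_b: CountMatrix) -> CountMatrix:
    """Join the two species' counts on orthologue pairs.

    Rows are pair ids ``geneA|geneB``; columns are the union of both
    species' samples.  Pairs with either member absent from its count
    matrix are dropped with a log entry.
    """
    _check_one_to_one(mapping)
    in_a = mapping["species_a_gene"].isin(cm_a.gene_ids)
    in_b = mapping["species_b_gene"].isin(cm_b.gene_ids)
    kept = mapping[in_a & in_b]
    n_dropped = len(mapping) - len(kept)
    if n_dropped:
        logger.warning("dropped %d ortholog pair(s) with a missing gene", n_dropped)
    pair_ids = kept["species_a_gene"] + PAIR_SEP + kept["species_b_gene"]
    left = cm_a.counts.loc[kept["species_a_gene"]].set_axis(pair_ids, axis=0)
    right = cm_b.counts.loc[kept["species_b_gene"]].set_axis(pair_ids, axis=0)
    joined = pd.concat([left, right], axis=1)
    joined.index.name = "pair_id"
    sample_meta = pd.concat([cm_a.sample_meta, cm_b.sample_meta])
    out = CountMatrix(counts=joined, sample_meta=sample_meta)
    out.counts.attrs["n_dropped_pairs"] = n_dropped
    return out


def cross_species_de(joined: CountMatrix, tissue: str, dispersion: float | None = None) -> pd.DataFrame:
    """Species-vs-species NB test over orthologue pairs within one tissue.

    The tissue subset is renormalized with its own TMM factors before
    testing; ``mean_a``/``mean_b`` are per-species mean CPM over the joined
    library, ``log_fc`` is log2(species A / species B).
    """
    meta = joined.sample_meta
    samples = list(meta.index[meta["tissue"] == tissue])
    if not samples:
        raise ValueError(f"no samples for tissue {tissue!r}")
    sub = joined.subset_samples(samples)
    group_a, group_b = split_groups(sub.sample_meta, "species")
    nm = cpm_normalize(sub, tmm_factors(sub))
    res = nb_two_group_test(sub, group_a, group_b, nm=nm, dispersion=dispersion)
    res["tissue"] = tissue
    return res


def classify_deg_eeg(
    results: pd.DataFrame,
    deg_fdr: float = 0.05,
    deg_lfc: float = 3.0,
    deg_min_expr: float = 5.0,
    eeg_fdr: float = 0.2,
    eeg_min_mean: float = 5.0,
) -> tuple[pd.DataFrame, dict]:
    """Label orthologue pairs DEG / EEG / neither.

    DEG: fdr < deg_fdr, |log_fc| > deg_lfc and mean CPM above
    ``deg_min_expr`` in *both* species.  EEG: fdr > eeg_fdr and the
    across-species mean CPM above ``eeg_min_mean``.  The relaxed DEG
    variant requires expression above the floor in *either* species and is
    reported in the summary alongside the strict count.
    """
    fdr = results["fdr"]
    lfc = results["log_fc"].abs()
    ea, eb = results["mean_a"], results["mean_b"]
    sig = (fdr < deg_fdr) & (lfc > deg_lfc)
    deg_strict = sig & (ea > deg_min_expr) & (eb > deg_min_expr)
    deg_relaxed = sig & ((ea > deg_min_expr) | (eb > deg_min_expr))
    eeg = (fdr > eeg_fdr) & ((ea + eb) / 2.0 > eeg_min_mean) & ~deg_strict
    out = results.copy()
    out["class"] = np.select([deg_strict, eeg], ["DEG", "EEG"], default="neither")
    out["deg_relaxed"] = deg_relaxed
    counts = {
        "DEG": int(deg_strict.sum()),
        "DEG_relaxed": int(deg_relaxed.sum()),
        "EEG": int(eeg.sum()),
        "neither": int((~deg_strict & ~eeg).sum()),
    }
    return out, counts


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fractions: np.ndarray


def pca_expression(matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Column-centered PCA of a samples x features expression matrix.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making scores reproducible across SVD backends.
    A constant matrix yields zero variance fractions and a warning from the
    zero-variance check.
    """
    X = matrix.to_numpy(dtype=float)
    n_components = min(n_components, min(X.shape) - 0 if min(X.shape) else 0, X.shape[0] - 1, X.shape[1])
    n_components = max(n_components, 1)
    if np.allclose(X.var(axis=0), 0.0):
        import warnings

        warnings.warn("constant matrix: no variance to decompose")
        scores = pd.DataFrame(0.0, index=matrix.index, columns=[f"PC{i+1}" for i in range(n_components)])
        loadings = pd.DataFrame(0.0, index=matrix.columns, columns=scores.columns)
        return PCAResult(scores, loadings, np.zeros(n_components))
    pca = PCA(n_components=n_components, svd_solver="full")
    s = pca.fit_transform(X)
    comps = pca.components_
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1.0
            s[:, i] *= -1.0
    cols = [f"PC{i+1}" for i in range(comps.shape[0])]
    return PCAResult(
        scores=pd.DataFrame(s, index=matrix.index, columns=cols),
        loadings=pd.DataFrame(comps.T, index=matrix.columns, columns=cols),
        variance_fractions=pca.explained_variance_ratio_,
    )
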