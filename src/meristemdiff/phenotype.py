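"""Group statistics for the chlorophyll-content validation experiment.

Relative chlorophyll content (arbitrary MultispeQ-style units) is compared
with Welch's unequal-variance t-test between photoperiods within each
species and between species within each photoperiod.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["welch_t_test", "compare_photoperiods", "read_phenotype_table"]


def read_phenotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"species", "photoperiod", "replicate", "value"}
    if not need <= set(df.columns):
        raise ValueError(f"phenotype table needs columns {sorted(need)}")
    if not np.isfinite(df["value"]).all():
        raise ValueError("non-finite phenotype values")
    return df


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float


def welch_t_test(group_a, group_b) -> WelchResult:
    """Welch's two-sided t-test with Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0, a.mean(), b.mean())
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue), a.mean(), b.mean())


def compare_photoperiods(table: pd.DataFrame, replicate_column: str = "replicate") -> pd.DataFrame:
    """The four planned contrasts on a species x photoperiod design.

    Within species: 8h vs 16h; within photoperiod: species vs species.
    Repeated measurements of the same replicate (e.g. per-leaf, per-day
    readings) are averaged per replicate before testing.  The report gives
    group means, t, df, p and the relative change of group B over group A.
    """
    df = table.groupby(["species", "photoperiod", replicate_column], as_index=False)["value"].mean()
    species = sorted(df["species"].unique())
    photoperiods = sorted(df["photoperiod"].unique(), key=lambda s: (len(s), s))
    if len(species) != 2 or len(photoperiods) != 2:
        raise ValueError("need exactly two species and two photoperiods")

    def values(sp, ph):
        v = df.loc[(df["species"] == sp) & (df["photoperiod"] == ph), "value"].to_numpy()
        if len(v) == 0:
            raise ValueError(f"missing group: {sp}/{ph}")
        return v

    contrasts = [
        (f"{species[0]}_{photoperiods[0]}_vs_{photoperiods[1]}", values(species[0], photoperiods[0]), values(species[0], photoperiods[1])),
        (f"{species[1]}_{photoperiods[0]}_vs_{photoperiods[1]}", values(species[1], photoperiods[0]), values(species[1], photoperiods[1])),
        (f"{photoperiods[0]}_{species[0]}_vs_{species[1]}", values(species[0], photoperiods[0]), values(species[1], photoperiods[0])),
        (f"{photoperiods[1]}_{species[0]}_vs_{species[1]}", values(species[0], photoperiods[1]), values(species[1], photoperiods[1])),
    ]
    rows = []
    for name, a, b in contrasts:
        r = welch_t_test(a, b)
        rel = (r.mean_b - r.mean_a) / r.mean_a if r.mean_a != 0 else float("nan")
        rows.append((name, r.mean_a, r.mean_b, rel, r.t, r.df, r.p))
    return pd.DataFrame(
        rows,
        columns=["contrast", "mean_a", "mean_b", "relative_change", "t", "df", "p_value"],
    ).set_index("contrast")
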