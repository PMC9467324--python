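"""MACE-like two-species count simulator with known ground truth.

Emulates the input side of a barley/tomato root-vs-shoot meristem profiling
experiment: two species with disjoint gene catalogs, two tissues with three
biological replicates each, 3'-tag counts (one NB-distributed count per gene,
no transcript-length bias), a shared GO vocabulary, and a strict 1:1
orthologue subset whose members have conserved baseline expression so that
cross-species "equally expressed" calls are meaningful.

Effects are planted at three levels and recorded in a :class:`GroundTruth`:

* individual genes with a tissue effect (``frac_de_genes`` of expressed,
  non-orthologue genes get a ``2**gene_lfc_effect`` multiplier in one tissue),
* whole GO terms with a coherent tissue shift applied to every expressed
  member gene,
* orthologue pairs with a species effect in one tissue (expression
  divergence); all other pairs keep identical means in both species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .counts import CountMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "generate_gene_catalog",
    "assign_ground_truth",
    "simulate_counts",
    "simulate_phenotypes",
    "simulate_dataset",
    "write_fixture",
]

TISSUES = ("root", "shoot")

#: chromosome counts used for positional annotation (barley-like / tomato-like)
_N_CHROMS = {0: 7, 1: 12}


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated two-species experiment.

    ``mean_log_expression``/``sd_log_expression`` are on the natural-log
    scale; per-gene baseline means are drawn log-normally and then rescaled
    per sample so each library has an expected depth of ``library_size``.
    ``nb_dispersion`` is the quadratic overdispersion phi in
    Var = mu + phi*mu**2 (0 gives Poisson counts).  ``frac_unexpressed`` may
    be a single fraction or a per-species mapping (the route to asymmetric
    expressed-gene catalogs).  Effect sizes are in log2 units.
    """

    seed: int = 0
    species: tuple[str, str] = ("barley", "tomato")
    n_genes_per_species: int = 12000
    n_go_terms: int = 300
    go_size_range: tuple[int, int] = (1, 500)
    n_ortholog_pairs: int = 500
    n_replicates: int = 3
    mean_log_expression: float = math.log(50.0)
    sd_log_expression: float = 1.5
    nb_dispersion: float = 0.05
    library_size: int = 5_000_000
    frac_de_genes: float = 0.05
    gene_lfc_effect: float = 4.0
    n_de_go_terms: int = 10
    de_go_min_genes: int = 30
    frac_unexpressed: float | Mapping[str, float] = 0.3
    n_divergent_orthologs: int = 50
    ortholog_lfc_effect: float = 5.0

    def validate(self) -> None:
        lo, hi = self.go_size_range
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"go_size_range must satisfy 1 <= min <= max, got {self.go_size_range}")
        if self.n_ortholog_pairs > self.n_genes_per_species:
            raise ConfigurationError(
                f"n_ortholog_pairs={self.n_ortholog_pairs} exceeds catalog size {self.n_genes_per_species}"
            )
        if self.n_divergent_orthologs > self.n_ortholog_pairs:
            raise ConfigurationError("n_divergent_orthologs exceeds n_ortholog_pairs")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if not 0.0 <= self.frac_de_genes <= 1.0:
            raise ConfigurationError("frac_de_genes must be in [0, 1]")
        for sp in self.species:
            f = self.frac_unexpressed_for(sp)
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError("frac_unexpressed must be in [0, 1]")
        if len(set(self.species)) != 2:
            raise ConfigurationError("exactly two distinct species labels required")

    def frac_unexpressed_for(self, species: str) -> float:
        if isinstance(self.frac_unexpressed, Mapping):
            return float(self.frac_unexpressed[species])
        return float(self.frac_unexpressed)

    def prefix(self, species: str) -> str:
        return species[:3].upper() + "_"

    def _rngs(self):
        """Three independent child streams: catalog, truth, counts."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(np.random.default_rng(c) for c in children)


@dataclass
class GroundTruth:
    """Planted effects, keyed the same way the analysis reports them.

    ``de_genes``: species, gene_id, tissue, lfc (log2, up in ``tissue``).
    ``de_go``: species, go_id, tissue, lfc — coherent whole-term shifts.
    ``divergent_orthologs``: gene_a, gene_b, tissue, lfc (positive = species
    B overexpressed in that tissue).
    """

    de_genes: pd.DataFrame
    de_go: pd.DataFrame
    divergent_orthologs: pd.DataFrame
    species_of_gene: dict[str, str] = field(default_factory=dict)

    def de_gene_ids(self, species: str) -> set[str]:
        df = self.de_genes
        return set(df.loc[df["species"] == species, "gene_id"])

    def de_go_ids(self, species: str) -> set[str]:
        df = self.de_go
        return set(df.loc[df["species"] == species, "go_id"])


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    catalogs: dict[str, pd.DataFrame]
    go: pd.DataFrame
    orthologs: pd.DataFrame
    truth: GroundTruth
    counts: dict[str, CountMatrix]
    samples: pd.DataFrame


def generate_gene_catalog(config: SimulationConfig):
    """Build per-species gene tables, a shared GO annotation, and a 1:1 ortholog map.

    Each gene table carries positional metadata plus the simulation-facing
    columns ``baseline_mean`` (log-normal, pre-scaling) and ``expressed``
    (False marks a structural zero).  Orthologue partners inherit the
    species-A baseline and expression status, modelling conserved expression.
    """
    config.validate()
    rng, _, _ = config._rngs()
    catalogs: dict[str, pd.DataFrame] = {}
    for si, sp in enumerate(config.species):
        n = config.n_genes_per_species
        ids = [f"{config.prefix(sp)}{i:05d}" for i in range(1, n + 1)]
        n_chrom = _N_CHROMS[si]
        chrom = rng.integers(1, n_chrom + 1, size=n)
        length = rng.integers(200, 10000, size=n)
        start = rng.integers(1, 100_000_000, size=n)
        strand = rng.choice(["+", "-"], size=n)
        baseline = np.exp(rng.normal(config.mean_log_expression, config.sd_log_expression, size=n))
        expressed = rng.random(n) >= config.frac_unexpressed_for(sp)
        catalogs[sp] = pd.DataFrame(
            {
                "gene_id": ids,
                "chrom": [f"chr{c}{'H' if si == 0 else ''}" for c in chrom],
                "start": start,
                "end": start + length - 1,
                "strand": strand,
                "length": length,
                "baseline_mean": baseline,
                "expressed": expressed,
            }
        )

    # shared GO vocabulary annotating both species' genes
    lo, hi = config.go_size_range
    records = []
    namespaces = ["biological_process", "molecular_function", "cellular_component"]
    for t in range(1, config.n_go_terms + 1):
        go_id = f"GO:{t:07d}"
        size = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi + 1)))))
        size = int(np.clip(size, lo, hi))
        ns = namespaces[int(rng.integers(0, 3))]
        for sp in config.species:
            members = rng.choice(catalogs[sp]["gene_id"].to_numpy(), size=size, replace=False)
            records.extend((g, go_id, ns) for g in members)
    go = pd.DataFrame(records, columns=["gene_id", "go_id", "namespace"])

    # strict 1:1 ortholog map; partner inherits baseline & expression status
    sp_a, sp_b = config.species
    if config.n_ortholog_pairs > 0:
        idx_a = rng.choice(config.n_genes_per_species, size=config.n_ortholog_pairs, replace=False)
        idx_b = rng.choice(config.n_genes_per_species, size=config.n_ortholog_pairs, replace=False)
        cat_b = catalogs[sp_b]
        cat_b.loc[idx_b, "baseline_mean"] = catalogs[sp_a]["baseline_mean"].to_numpy()[idx_a]
        cat_b.loc[idx_b, "expressed"] = catalogs[sp_a]["expressed"].to_numpy()[idx_a]
        orthologs = pd.DataFrame(
            {
                "species_a_gene": catalogs[sp_a]["gene_id"].to_numpy()[idx_a],
                "species_b_gene": cat_b["gene_id"].to_numpy()[idx_b],
            }
        )
    else:
        orthologs = pd.DataFrame(columns=["species_a_gene", "species_b_gene"])
    return catalogs, go, orthologs


def assign_ground_truth(config: SimulationConfig, catalogs, go: pd.DataFrame, orthologs: pd.DataFrame) -> GroundTruth:
    """Plant tissue and species effects; see module docstring for the scheme.

    Coherent GO shifts are restricted to terms with at least
    ``de_go_min_genes`` expressed member genes and mutually disjoint member
    sets, so that each planted term is an unambiguous, detectable unit.
    Orthologue-paired genes are excluded from gene/GO-level tissue effects;
    their only planted signal is the species effect on designated divergent
    pairs.
    """
    _, rng, _ = config._rngs()
    sp_a, sp_b = config.species
    ortho_genes = set(orthologs["species_a_gene"]) | set(orthologs["species_b_gene"])

    de_gene_rows = []
    de_go_rows = []
    species_of_gene: dict[str, str] = {}
    for sp in config.species:
        cat = catalogs[sp]
        species_of_gene.update({g: sp for g in cat["gene_id"]})
        expressed = set(cat.loc[cat["expressed"], "gene_id"])

        # coherent GO terms first: their members are reserved
        claimed: set[str] = set()
        go_sp = go[go["gene_id"].isin(expressed - ortho_genes)]
        members_by_term = go_sp.groupby("go_id")["gene_id"].apply(set)
        eligible = [t for t, m in members_by_term.items() if len(m) >= config.de_go_min_genes]
        rng.shuffle(eligible)
        chosen_terms = eligible[: config.n_de_go_terms]
        if len(chosen_terms) < config.n_de_go_terms:
            raise ConfigurationError(
                f"only {len(chosen_terms)} GO terms with >= {config.de_go_min_genes} "
                f"expressed non-orthologue genes available for species {sp}"
            )
        # overlapping chosen terms must shift the same way, otherwise the
        # shared genes would dilute each other's coherent signal: assign one
        # direction per connected component of the term-overlap graph
        component = {t: i for i, t in enumerate(chosen_terms)}
        for i, t1 in enumerate(chosen_terms):
            for t2 in chosen_terms[:i]:
                if members_by_term[t1] & members_by_term[t2]:
                    old, new = component[t1], component[t2]
                    for t in component:
                        if component[t] == old:
                            component[t] = new
        direction = {c: TISSUES[int(rng.integers(0, 2))] for c in sorted(set(component.values()))}
        for t in chosen_terms:
            tissue = direction[component[t]]
            de_go_rows.append((sp, t, tissue, config.gene_lfc_effect))
            for g in sorted(members_by_term[t] - claimed):
                de_gene_rows.append((sp, g, tissue, config.gene_lfc_effect, "go"))
            claimed |= members_by_term[t]

        # individual DE genes among the remaining expressed, non-ortholog genes
        pool = np.array(sorted(expressed - ortho_genes - claimed))
        n_de = int(round(config.frac_de_genes * config.n_genes_per_species))
        n_de = min(n_de, len(pool))
        picks = rng.choice(pool, size=n_de, replace=False)
        tissues = rng.integers(0, 2, size=n_de)
        for g, ti in zip(picks, tissues):
            de_gene_rows.append((sp, g, TISSUES[ti], config.gene_lfc_effect, "gene"))

    # divergent orthologs: species-B member over/under-expressed in one tissue
    div_rows = []
    if config.n_divergent_orthologs > 0:
        a = orthologs["species_a_gene"].to_numpy()
        b = orthologs["species_b_gene"].to_numpy()
        expressed_b = set(catalogs[sp_b].loc[catalogs[sp_b]["expressed"], "gene_id"])
        ok = np.array([g in expressed_b for g in b])
        idx = rng.choice(np.flatnonzero(ok), size=config.n_divergent_orthologs, replace=False)
        for i in idx:
            tissue = TISSUES[int(rng.integers(0, 2))]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            div_rows.append((a[i], b[i], tissue, sign * config.ortholog_lfc_effect))

    de_genes = pd.DataFrame(de_gene_rows, columns=["species", "gene_id", "tissue", "lfc", "source"])
    de_go = pd.DataFrame(de_go_rows, columns=["species", "go_id", "tissue", "lfc"])
    divergent = pd.DataFrame(div_rows, columns=["gene_a", "gene_b", "tissue", "lfc"])
    return GroundTruth(de_genes, de_go, divergent, species_of_gene)


def simulate_counts(config: SimulationConfig, catalogs, truth: GroundTruth) -> dict[str, CountMatrix]:
    """Draw NB counts per species: gene baseline x 2^(tissue effect), scaled per sample.

    Per tissue the gene mean vector is rescaled so its sum equals
    ``library_size`` (expected sequencing depth); replicates are i.i.d.
    ``nb_dispersion == 0`` produces Poisson counts.  Structural zeros stay
    exactly zero.
    """
    _, _, rng = config._rngs()
    sp_a, sp_b = config.species
    phi = config.nb_dispersion
    out: dict[str, CountMatrix] = {}
    div_by_gene_b = {
        (r.gene_b, r.tissue): r.lfc for r in truth.divergent_orthologs.itertuples()
    }
    for sp in config.species:
        cat = catalogs[sp]
        genes = cat["gene_id"].to_numpy()
        base = cat["baseline_mean"].to_numpy() * cat["expressed"].to_numpy(dtype=float)
        mult = {t: np.ones(len(genes)) for t in TISSUES}
        de = truth.de_genes[truth.de_genes["species"] == sp]
        gene_pos = {g: i for i, g in enumerate(genes)}
        for r in de.itertuples():
            mult[r.tissue][gene_pos[r.gene_id]] *= 2.0 ** r.lfc
        if sp == sp_b:
            for (g, tissue), lfc in div_by_gene_b.items():
                if g in gene_pos:
                    mult[tissue][gene_pos[g]] *= 2.0 ** lfc

        cols = {}
        meta_rows = []
        for tissue in TISSUES:
            mu = base * mult[tissue]
            tot = mu.sum()
            mu = mu * (config.library_size / tot) if tot > 0 else mu
            for rep in range(1, config.n_replicates + 1):
                if phi > 0:
                    # NB via gamma-Poisson mixture: shape 1/phi, scale phi*mu
                    lam = rng.gamma(1.0 / phi, phi * mu)
                    y = rng.poisson(lam)
                else:
                    y = rng.poisson(mu)
                sample_id = f"{sp}_{tissue}_r{rep}"
                cols[sample_id] = y
                meta_rows.append((sample_id, sp, tissue, rep))
        counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
        sample_meta = pd.DataFrame(
            meta_rows, columns=["sample_id", "species", "tissue", "replicate"]
        ).set_index("sample_id")
        gene_meta = cat.set_index("gene_id")[["chrom", "start", "end", "strand", "length"]]
        out[sp] = CountMatrix(counts=counts, sample_meta=sample_meta, gene_meta=gene_meta)
    return out


def simulate_dataset(config: SimulationConfig | None = None, **overrides) -> SimulatedDataset:
    """One-call generation of a complete dataset (catalog -> truth -> counts)."""
    if config is None:
        config = SimulationConfig()
    if overrides:
        config = replace(config, **overrides)
    catalogs, go, orthologs = generate_gene_catalog(config)
    truth = assign_ground_truth(config, catalogs, go, orthologs)
    counts = simulate_counts(config, catalogs, truth)
    samples = pd.concat([cm.sample_meta for cm in counts.values()])
    return SimulatedDataset(config, catalogs, go, orthologs, truth, counts, samples)


#: group means reported for the chlorophyll validation experiment
DEFAULT_CHLOROPHYLL_MEANS = {
    "barley_8h": 25.53,
    "barley_16h": 35.95,
    "tomato_8h": 30.13,
    "tomato_16h": 31.37,
}


def simulate_phenotypes(
    group_means: Mapping[str, float] | None = None,
    group_sd: float = 2.0,
    n_per_group: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian per-plant chlorophyll readings; keys are ``"<species>_<photoperiod>"``."""
    if group_means is None:
        group_means = DEFAULT_CHLOROPHYLL_MEANS
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not group_sd > 0:
        raise ValueError("group_sd must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for key, mean in group_means.items():
        species, photoperiod = key.rsplit("_", 1)
        values = rng.normal(mean, group_sd, size=n_per_group)
        rows.extend(
            (species, photoperiod, rep + 1, v) for rep, v in enumerate(values)
        )
    return pd.DataFrame(rows, columns=["species", "photoperiod", "replicate", "value"])


def write_fixture(dataset: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Write the dataset as the plain-TSV file set the readers consume.

    Counts go out in featureCounts dialect (Geneid/Chr/Start/End/Strand/
    Length then one column per sample).  The truth table lists planted gene,
    GO and orthologue effects with their tissue and signed log2 size.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sp, cm in dataset.counts.items():
        tbl = cm.gene_meta.rename(
            columns={"chrom": "Chr", "start": "Start", "end": "End", "strand": "Strand", "length": "Length"}
        ).join(cm.counts)
        tbl.index.name = "Geneid"
        p = out / f"counts_{sp}.tsv"
        tbl.to_csv(p, sep="\t")
        paths[f"counts_{sp}"] = p

    p = out / "samples.tsv"
    samples = dataset.samples.copy()
    samples.index.name = "sample_id"
    samples.to_csv(p, sep="\t")
    paths["samples"] = p

    p = out / "go.tsv"
    dataset.go.to_csv(p, sep="\t", index=False)
    paths["go"] = p

    p = out / "orthologs.tsv"
    dataset.orthologs.to_csv(p, sep="\t", index=False)
    paths["orthologs"] = p

    t = dataset.truth
    rows = [
        (r.gene_id, "gene", r.species, r.tissue, r.lfc) for r in t.de_genes.itertuples()
    ]
    rows += [(r.go_id, "go", r.species, r.tissue, r.lfc) for r in t.de_go.itertuples()]
    rows += [
        (f"{r.gene_a}|{r.gene_b}", "ortholog", dataset.config.species[1], r.tissue, r.lfc)
        for r in t.divergent_orthologs.itertuples()
    ]
    truth_df = pd.DataFrame(
        rows, columns=["element_id", "element_type", "species", "tissue", "tissue_effect_log2"]
    )
    p = out / "truth.tsv"
    truth_df.to_csv(p, sep="\t", index=False)
    paths["truth"] = p
    return paths
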