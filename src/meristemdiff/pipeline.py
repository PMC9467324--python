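"""End-to-end orchestration: normalize -> DE -> GO -> cross-species -> orthologs.

One :class:`PipelineConfig` drives the full analysis.  Every stage writes
its table under the output directory (restartable, inspectable), and a
machine-readable summary collects the headline counts; the summary is
cross-checked against recounts of the stage files before it is written, so
a summary/stage inconsistency is a hard error rather than a silent drift.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import go as go_mod
from . import orthologs as ortho_mod
from .counts import cpm_normalize, read_counts_table, replicate_qc, tmm_factors
from .de import classify_presence, nb_two_group_test, select_deg, split_groups
from .phenotype import compare_photoperiods, read_phenotype_table
from .report import ratio

__all__ = ["PipelineConfig", "run_full_analysis", "write_summary"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    counts_a: str
    counts_b: str
    samples: str
    go: str
    orthologs: str
    out_dir: str
    phenotype: str | None = None
    deg_fdr: float = 0.01
    deg_lfc: float = 3.0
    go_fdr: float = 0.01
    go_lfc: float = 3.0
    go_min_genes: int = 5
    cross_fdr: float = 0.05
    cross_min_count: int = 2
    ortho_deg_fdr: float = 0.05
    ortho_deg_lfc: float = 3.0
    ortho_deg_min_expr: float = 5.0
    ortho_eeg_fdr: float = 0.2
    ortho_eeg_min_mean: float = 5.0
    presence_cpm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deg_fdr", "go_fdr", "cross_fdr", "ortho_deg_fdr", "ortho_eeg_fdr"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("deg_lfc", "go_lfc", "ortho_deg_lfc", "presence_cpm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.go_min_genes < 1 or self.cross_min_count < 0:
            raise ValueError("invalid count thresholds")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name):
    """Wrap stage execution so failures carry the stage name."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)

    return _Ctx()


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run all stages in dependency order; returns the summary dict.

    Stage tables land in ``config.out_dir``; the summary is written as
    ``summary.json`` and a flat ``summary.tsv``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    with _stage("read"):
        cm_a = read_counts_table(config.counts_a, config.samples)
        cm_b = read_counts_table(config.counts_b, config.samples)
        sp_a = cm_a.sample_meta["species"].iloc[0]
        sp_b = cm_b.sample_meta["species"].iloc[0]
        ann = go_mod.read_go_table(config.go)
        species = {sp_a: cm_a, sp_b: cm_b}

    norm = {}
    with _stage("normalize"):
        for sp, cm in species.items():
            factors = tmm_factors(cm)
            nm = cpm_normalize(cm, factors)
            norm[sp] = nm
            nm.values.to_csv(out / f"norm_{sp}.tsv", sep="\t", float_format=_FLOAT_FMT)
            factors.to_frame().to_csv(out / f"norm_factors_{sp}.tsv", sep="\t", float_format=_FLOAT_FMT)

    with _stage("replicate_qc"):
        qc_section = {}
        for sp, nm in norm.items():
            qc = replicate_qc(nm)
            qc.pairs.to_csv(out / f"qc_{sp}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
            qc_section[sp] = {
                "min_r": round(qc.min_r, 4),
                "n_flagged": qc.n_flagged,
            }
        summary["replicate_qc"] = qc_section

    with _stage("presence"):
        presence_section = {}
        for sp, nm in norm.items():
            root, shoot = split_groups(nm.sample_meta, "tissue", levels=("root", "shoot"))
            frame, counts = classify_presence(
                nm, root, shoot, threshold_cpm=config.presence_cpm, labels=("root", "shoot")
            )
            frame.to_csv(out / f"presence_{sp}.tsv", sep="\t")
            presence_section[sp] = counts
        summary["presence"] = presence_section

    de_tables = {}
    with _stage("gene_de"):
        deg_section = {}
        for sp, cm in species.items():
            root, shoot = split_groups(cm.sample_meta, "tissue", levels=("root", "shoot"))
            res = nb_two_group_test(cm, root, shoot, nm=norm[sp])
            de_tables[sp] = res
            deg = select_deg(res, fdr_max=config.deg_fdr, lfc_min=config.deg_lfc)
            res_out = res.copy()
            res_out["deg_flag"] = res.index.isin(deg.index)
            res_out["direction"] = deg["direction"].reindex(res.index).fillna("")
            res_out.to_csv(out / f"de_{sp}.tsv", sep="\t", float_format=_FLOAT_FMT)
            deg_section[sp] = {
                "n_deg": int(len(deg)),
                "up_in_root": int((deg["direction"] == "up_in_a").sum()),
                "up_in_shoot": int((deg["direction"] == "up_in_b").sum()),
                "n_tested": int(res["tested"].sum()),
            }
        summary["deg"] = deg_section

    with _stage("go_expression"):
        go_section = {}
        for sp, nm in norm.items():
            root, shoot = split_groups(nm.sample_meta, "tissue", levels=("root", "shoot"))
            rec = go_mod.go_glm_test(nm, ann, root, shoot)
            rec.to_csv(out / f"go_{sp}.tsv", sep="\t", float_format=_FLOAT_FMT)
            cand = go_mod.select_candidate_go(
                rec, fdr_max=config.go_fdr, lfc_min=config.go_lfc, min_genes=config.go_min_genes
            )
            go_section[sp] = {"n_terms": int(len(rec)), "n_candidates": int(len(cand))}
        summary["candidate_go"] = go_section

    with _stage("go_enrichment"):
        for sp, res in de_tables.items():
            deg = select_deg(res, fdr_max=config.deg_fdr, lfc_min=config.deg_lfc)
            background = res.index[res["tested"]]
            if len(deg):
                enr = go_mod.go_enrichment_hypergeometric(set(deg.index), set(background), ann)
                enr.to_csv(out / f"enrichment_{sp}.tsv", sep="\t", float_format=_FLOAT_FMT)

    with _stage("cross_species_go"):
        cross = go_mod.cross_species_go_compare(
            de_tables[sp_a],
            de_tables[sp_b],
            ann,
            ann,
            fdr_max=config.cross_fdr,
            min_count=config.cross_min_count,
        )
        cross.to_csv(out / "go_cross.tsv", sep="\t", float_format=_FLOAT_FMT)
        summary["cross_species_go"] = {
            "n_terms": int(len(cross)),
            "n_selected": int(cross["selected"].sum()),
        }

    with _stage("orthologs"):
        mapping = ortho_mod.read_ortholog_map(config.orthologs)
        ortho_section = {"n_pairs": int(len(mapping))}
        if len(mapping):
            joined = ortho_mod.match_orthologs(mapping, species[sp_a], species[sp_b])
            for tissue in ("root", "shoot"):
                res = ortho_mod.cross_species_de(joined, tissue)
                labelled, counts = ortho_mod.classify_deg_eeg(
                    res,
                    deg_fdr=config.ortho_deg_fdr,
                    deg_lfc=config.ortho_deg_lfc,
                    deg_min_expr=config.ortho_deg_min_expr,
                    eeg_fdr=config.ortho_eeg_fdr,
                    eeg_min_mean=config.ortho_eeg_min_mean,
                )
                labelled.to_csv(out / f"ortho_{tissue}.tsv", sep="\t", float_format=_FLOAT_FMT)
                ortho_section[tissue] = counts
        summary["orthologs"] = ortho_section

    with _stage("phenotype"):
        if config.phenotype:
            table = read_phenotype_table(config.phenotype)
            report = compare_photoperiods(table)
            report.to_csv(out / "phenotype.tsv", sep="\t", float_format=_FLOAT_FMT)
            summary["phenotype"] = {
                c: {"p_value": float(f"{r.p_value:.6g}"), "mean_a": round(r.mean_a, 3), "mean_b": round(r.mean_b, 3)}
                for c, r in report.iterrows()
            }
        else:
            summary["phenotype"] = {}

    with _stage("summary"):
        n_a = summary["candidate_go"][sp_a]["n_candidates"]
        n_b = summary["candidate_go"][sp_b]["n_candidates"]
        summary["derived"] = {
            f"{sp_b}_to_{sp_a}_candidate_go_ratio": (ratio(n_b, n_a) if n_a else None)
        }
        write_summary(summary, out, species_order=(sp_a, sp_b))
    return summary


def _recount_checks(summary: dict, out: Path, species_order) -> None:
    """Verify summary counts against independent recounts of the stage files."""
    for sp in species_order:
        de = pd.read_csv(out / f"de_{sp}.tsv", sep="\t", index_col=0)
        if int(de["deg_flag"].sum()) != summary["deg"][sp]["n_deg"]:
            raise RuntimeError(f"summary/stage mismatch: DEG count for {sp}")
        pres = pd.read_csv(out / f"presence_{sp}.tsv", sep="\t", index_col=0)
        if int((pres["presence"] == "both").sum()) != summary["presence"][sp]["both"]:
            raise RuntimeError(f"summary/stage mismatch: presence count for {sp}")
    cross = pd.read_csv(out / "go_cross.tsv", sep="\t", index_col=0)
    if int(cross["selected"].sum()) != summary["cross_species_go"]["n_selected"]:
        raise RuntimeError("summary/stage mismatch: cross-species GO count")


def write_summary(summary: dict, out_dir, species_order) -> None:
    """Write summary.json and a flat summary.tsv with stable key order."""
    out = Path(out_dir)
    _recount_checks(summary, out, species_order)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=False)
        fh.write("\n")
    rows = []

    def flatten(prefix, obj):
        if isinstance(obj, dict):
            for k in obj:
                flatten(f"{prefix}.{k}" if prefix else str(k), obj[k])
        else:
            rows.append((prefix, obj))

    flatten("", summary)
    pd.DataFrame(rows, columns=["key", "value"]).to_csv(out / "summary.tsv", sep="\t", index=False)
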