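"""End-to-end orchestration: genetics chain and expression chain.

``run_genetics`` chains co-segregation filtering -> population-absence
filtering -> meiosis classification -> two-point LOD -> ACMG classification
for every variant that survives the filters. ``run_expression`` chains
dispersion estimation -> exact test -> BH -> DE filtering -> top-N selection
-> enrichment. Both are deterministic given their inputs and return plain
dictionaries of tables and records that the CLI serialises.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import acmg, lod, rnaseq, segregation
from .errors import ValidationError
from .pedigree import read_ped

log = logging.getLogger("famseg")


@dataclass
class RunConfig:
    """Paths and model parameters for a full run; YAML-loadable."""

    vcf: str | None = None
    ped: str | None = None
    ped_meta: str | None = None
    annotations: str | None = None
    counts: str | None = None
    groups: str | None = None
    gmt: str | None = None
    out_dir: str = "famseg_out"

    max_af: float = 0.0
    panels: tuple[str, ...] = segregation.DEFAULT_PANELS
    require_het: bool = False
    strict_missing: bool = False
    grid_step: float = 0.001
    pp1_thresholds: Mapping[str, float] = dc_field(
        default_factory=lambda: dict(acmg.DEFAULT_PP1_THRESHOLDS))
    #: evidence codes asserted from outside the pipeline (e.g. PS3 when an
    #: in vitro functional study supports a damaging effect)
    asserted_evidence: tuple[str, ...] = ()
    alpha: float = 0.05
    lfc_min: float = 1.0
    top_n: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ValidationError(f"alpha must be in [0,1], got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def run_genetics(cfg: RunConfig) -> dict[str, Any]:
    """Filter -> LOD -> classify on a multi-sample VCF and pedigree.

    Returns a report with each stage's table: all verdicts, the variants
    passing both filters, and per passing variant the meiosis counts, the LOD
    curve maximum and the ACMG classification (PP1 from the LOD, PM2 from
    population absence, plus any asserted evidence codes).
    """
    if cfg.vcf is None or cfg.ped is None:
        raise ValidationError("run_genetics requires vcf and ped paths")
    ped = read_ped(cfg.ped, meta=cfg.ped_meta)
    gm = segregation.read_vcf(cfg.vcf, annotations=cfg.annotations)
    report: dict[str, Any] = {"n_variants": len(gm), "stages": {}}
    if len(gm) == 0:
        warnings.warn("empty VCF: nothing to analyse", stacklevel=2)
        report["passing"] = []
        return report

    verdicts = segregation.dominant_filter(
        gm, ped, require_het=cfg.require_het, strict_missing=cfg.strict_missing)
    segregating = [v for v in verdicts if v.segregates]
    report["stages"]["dominant_filter"] = {
        "n_tested": len(verdicts), "n_segregating": len(segregating)}
    log.info("dominant filter: %d/%d variants segregate",
             len(segregating), len(verdicts))

    passing = segregation.population_absence_filter(
        segregating, max_af=cfg.max_af, require_panels=cfg.panels)
    report["stages"]["population_filter"] = {
        "max_af": cfg.max_af, "n_passing": len(passing)}

    results = []
    for verdict in passing:
        variant = verdict.variant
        counts = lod.classify_meioses(ped, gm, variant)
        lr = lod.max_lod(counts, grid_step=cfg.grid_step)
        items = []
        pp1 = acmg.pp1_strength(lr.lod_max, thresholds=cfg.pp1_thresholds)
        if pp1 is not None:
            items.append(pp1)
        if all(variant.pop_af.get(p, 0.0) <= cfg.max_af for p in cfg.panels):
            items.append(acmg.evidence("PM2", note="absent from population panels"))
        for code in cfg.asserted_evidence:
            items.append(acmg.evidence(code, note="asserted input"))
        cls = acmg.combine(items)
        results.append({
            "variant": str(variant),
            "gene": variant.gene,
            "hgvs_c": variant.hgvs_c,
            "n_informative": counts.n,
            "non_recombinant": counts.non_recombinant,
            "recombinant": counts.recombinant,
            "lod_max": lr.lod_max,
            "lod_max_1dp": round(lr.lod_max, 1),
            "theta_max": lr.theta_max,
            "evidence": [f"{e.code}_{e.strength}" for e in items],
            "verdict": cls.verdict,
            "fired_rule": cls.fired_rule,
        })
    report["passing"] = results
    return report


def run_expression(cfg: RunConfig,
                   truth: pd.DataFrame | None = None) -> dict[str, Any]:
    """DE -> top-N -> enrichment on a count matrix.

    If a planted-truth table is supplied (columns gene_id, sign) the report
    additionally carries sensitivity and observed false-discovery proportion
    of the recovered DE sets against that truth.
    """
    if cfg.counts is None or cfg.groups is None:
        raise ValidationError("run_expression requires counts and groups paths")
    cm = rnaseq.CountMatrix.from_tsv(cfg.counts, cfg.groups)
    res = rnaseq.de_analysis(cm, alpha=cfg.alpha, lfc_min=cfg.lfc_min)
    up, down = rnaseq.de_filter(res, alpha=cfg.alpha, lfc_min=cfg.lfc_min)
    top_up, top_down = rnaseq.top_n_by_direction(
        res, n=cfg.top_n, alpha=cfg.alpha, lfc_min=cfg.lfc_min)
    report: dict[str, Any] = {
        "de_table": res,
        "n_de": len(up) + len(down),
        "n_up": len(up),
        "n_down": len(down),
        "up": up,
        "down": down,
        "top_up": top_up,
        "top_down": top_down,
        "dispersion": float(res["dispersion"].iloc[0]) if len(res) else None,
    }
    if cfg.gmt is not None:
        gsc = rnaseq.read_gmt(cfg.gmt)
        universe = rnaseq.expression_universe(cm)
        enr = rnaseq.enrich(up + down, gsc, alpha=cfg.alpha, universe=universe)
        report["enrichment"] = enr
        report["enrichment_top20"] = enr.head(20)
    if truth is not None:
        called = set(up) | set(down)
        true_set = set(truth["gene_id"])
        tp = len(called & true_set)
        report["recovery"] = {
            "sensitivity": tp / len(true_set) if true_set else float("nan"),
            "observed_fdr": (len(called) - tp) / len(called) if called else 0.0,
            "n_called": len(called),
        }
    return report


def write_expression_report(report: dict[str, Any], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report["de_table"].to_csv(out / "de_table.tsv", sep="\t")
    pd.Series(report["top_up"]).to_csv(out / "top_up.txt", index=False, header=False)
    pd.Series(report["top_down"]).to_csv(out / "top_down.txt", index=False, header=False)
    if "enrichment" in report:
        report["enrichment"].to_csv(out / "enrichment.tsv", sep="\t", index=False)
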