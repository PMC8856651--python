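"""Synthetic inputs with known planted truth for every pipeline stage.

Three generators emulate the study's data structures so the whole analysis
chain is testable offline:

* :func:`simulate_family` — a multi-sample genotype matrix over the
  four-generation family template: one causal dominant variant plus a
  background of independent rare variants (founder allele frequencies drawn
  from a rare-skewed Beta, Mendelian gene-dropping to descendants), with
  optional genotyping-error and missingness processes. With penetrance 1 the
  causal genotypes are conditioned on the template's affection pattern,
  reproducing the study family (13 affected including the deceased founder,
  23 genotyped members) deterministically; with penetrance < 1 the allele is
  gene-dropped from the affected founder and affection drawn per carrier.
* :func:`simulate_counts` — a genes x samples NB count matrix (2 patients vs
  4 controls by default) with log-normal baseline means, common dispersion
  and a planted two-fold-plus DE signature of known sign.
* :func:`simulate_ct` — qPCR Ct tables for the four treatment groups with a
  constant reference gene: Ct = base - log2(expression) + Gaussian noise.

All generators are deterministic given (config, seed), and each returns a
truth manifest sufficient for downstream recovery checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pedigree import Affection, Individual, Pedigree, load_family_fixture, write_ped
from .rnaseq import CountMatrix
from .segregation import (
    GenotypeMatrix,
    HET,
    MISSING,
    VariantRecord,
    write_vcf,
)

DEFAULT_PANELS = ("ExAC", "1000G", "gnomAD")

#: Synthetic analogue of the study's causal allele. The gene symbol and HGVS
#: name mirror the reported variant; chromosome-7 coordinates are placeholder
#: values (this is simulated data, not a clinical annotation).
DEFAULT_CAUSAL = VariantRecord(
    chrom="7", pos=149_520_000, ref="G", alt="A",
    gene="ZNF862", region_class="exon", hgvs_c="c.2812G>A",
    pop_af={p: 0.0 for p in DEFAULT_PANELS},
)


@dataclass
class FamilySimConfig:
    penetrance: float = 1.0
    n_background_variants: int = 5000
    background_af_beta: tuple[float, float] = (0.2, 5.0)  # rare-skewed
    genotype_missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("penetrance", "genotype_missing_rate", "genotype_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")


def _topological_order(ped: Pedigree) -> list[Individual]:
    placed: set[str] = set()
    out: list[Individual] = []
    pending = list(ped)
    while pending:
        rest = []
        for ind in pending:
            if ind.is_founder or (ind.father_id in placed and ind.mother_id in placed):
                out.append(ind)
                placed.add(ind.id)
            else:
                rest.append(ind)
        if len(rest) == len(pending):  # pragma: no cover - Pedigree is acyclic
            raise ValidationError("pedigree ordering failed")
        pending = rest
    return out


def _gene_drop(ped: Pedigree, founder_allele_p: np.ndarray,
               rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Drop independent biallelic variants through the pedigree.

    Returns per-individual allele matrices of shape (2, n_variants).
    """
    n_var = len(founder_allele_p)
    alleles: dict[str, np.ndarray] = {}
    for ind in _topological_order(ped):
        if ind.is_founder:
            alleles[ind.id] = (rng.random((2, n_var)) < founder_allele_p).astype(np.int8)
        else:
            pick_f = rng.integers(0, 2, n_var)
            pick_m = rng.integers(0, 2, n_var)
            cols = np.arange(n_var)
            alleles[ind.id] = np.stack([
                alleles[ind.father_id][pick_f, cols],
                alleles[ind.mother_id][pick_m, cols],
            ])
    return alleles


def simulate_family(
    cfg: FamilySimConfig | None = None,
    pedigree: Pedigree | None = None,
    causal: VariantRecord = DEFAULT_CAUSAL,
) -> tuple[GenotypeMatrix, Pedigree, dict]:
    """Simulate the family genotype matrix; see module docstring.

    Returns ``(genotype_matrix, pedigree, truth)`` where the genotype matrix
    covers the genotyped pedigree members and ``truth`` records the causal
    variant, the true (pre-error) causal genotypes, and which background
    variants co-segregate with the phenotype by chance.
    """
    cfg = cfg or FamilySimConfig()
    ped = pedigree or load_family_fixture()
    rng = np.random.default_rng(cfg.seed)

    # -- causal variant ----------------------------------------------------
    if cfg.penetrance == 1.0:
        # condition on the template phenotype: het in affected, hom-ref otherwise
        carrier = {i.id: i.affected is Affection.AFFECTED for i in ped}
        realized = ped
    else:
        founder = next(i for i in ped.founders()
                       if i.affected is Affection.AFFECTED)
        one_var = np.zeros(1)
        alleles = _gene_drop(ped, one_var, rng)
        alleles[founder.id][0, 0] = 1
        # re-drop descendants now the founder carries the allele
        for ind in _topological_order(ped):
            if ind.is_founder:
                continue
            pf, pm = rng.integers(0, 2), rng.integers(0, 2)
            alleles[ind.id][0, 0] = alleles[ind.father_id][pf, 0]
            alleles[ind.id][1, 0] = alleles[ind.mother_id][pm, 0]
        carrier = {i.id: bool(alleles[i.id][:, 0].sum() > 0) for i in ped}
        realized = Pedigree(
            [Individual(
                id=i.id, father_id=i.father_id, mother_id=i.mother_id,
                sex=i.sex,
                affected=(Affection.AFFECTED
                          if carrier[i.id] and rng.random() < cfg.penetrance
                          else Affection.UNAFFECTED),
                alive=i.alive, genotyped=i.genotyped, generation=i.generation,
            ) for i in ped],
            name=ped.name,
        )

    samples = [i.id for i in realized if i.genotyped]

    # -- background variants ----------------------------------------------
    a, b = cfg.background_af_beta
    afs = rng.beta(a, b, cfg.n_background_variants)
    alleles_bg = _gene_drop(realized, afs, rng)
    bg_calls = np.stack([alleles_bg[s].sum(axis=0) for s in samples], axis=1)

    causal_calls = np.array([[HET if carrier[s] else 0 for s in samples]],
                            dtype=np.int8)
    calls = np.vstack([causal_calls, bg_calls]).astype(np.int8)

    variants = [causal]
    for j in range(cfg.n_background_variants):
        variants.append(VariantRecord(
            chrom=str(1 + j % 22), pos=1_000_000 + j, ref="A", alt="G",
            gene=f"BG{j:05d}", region_class="exon",
            pop_af={p: round(float(afs[j]), 6) for p in DEFAULT_PANELS},
        ))

    # truth: which background variants truly co-segregate (pre error/missing)
    aff_mask = np.array(
        [realized.get(s).affected is Affection.AFFECTED for s in samples])
    unaff_mask = np.array(
        [realized.get(s).affected is Affection.UNAFFECTED for s in samples])
    coseg = ((bg_calls[:, aff_mask] >= 1).all(axis=1)
             & (bg_calls[:, unaff_mask] == 0).all(axis=1))
    truth = {
        "causal": str(causal),
        "causal_genotypes": {s: int(c) for s, c in zip(samples, causal_calls[0])},
        "background_cosegregating": [str(variants[1 + j])
                                     for j in np.flatnonzero(coseg)],
        "n_affected": int(len(realized.affected_ids())),
        "n_genotyped": len(samples),
        "seed": cfg.seed,
    }

    # -- error and missingness processes ----------------------------------
    if cfg.genotype_error_rate > 0:
        err = rng.random(calls.shape) < cfg.genotype_error_rate
        shift = rng.integers(1, 3, calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if cfg.genotype_missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < cfg.genotype_missing_rate,
                         MISSING, calls).astype(np.int8)

    return GenotypeMatrix(variants, samples, calls), realized, truth


def simulate_family_vcf(
    cfg: FamilySimConfig | None = None,
    out_dir: str | Path = ".",
    pedigree: Pedigree | None = None,
    causal: VariantRecord = DEFAULT_CAUSAL,
) -> dict[str, Path]:
    """File-based wrapper around :func:`simulate_family`.

    Writes ``family.vcf``, ``family.ped``, ``annotations.tsv`` and
    ``truth.json`` into ``out_dir`` and returns their paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gm, ped, truth = simulate_family(cfg, pedigree=pedigree, causal=causal)

    paths = {
        "vcf": out_dir / "family.vcf",
        "ped": out_dir / "family.ped",
        "ped_meta": out_dir / "family_meta.tsv",
        "annotations": out_dir / "annotations.tsv",
        "truth": out_dir / "truth.json",
    }
    write_vcf(gm, paths["vcf"])
    write_ped(ped, paths["ped"])
    pd.DataFrame({
        "id": [i.id for i in ped],
        "generation": [i.generation if i.generation is not None else ""
                       for i in ped],
        "alive": [int(i.alive) for i in ped],
        "genotyped": [int(i.genotyped) for i in ped],
    }).to_csv(paths["ped_meta"], sep="\t", index=False)
    rows = []
    for v in gm.variants:
        row = {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
               "gene": v.gene, "region_class": v.region_class, "hgvs_c": v.hgvs_c}
        for p in DEFAULT_PANELS:
            row[p] = v.pop_af.get(p, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(paths["annotations"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

@dataclass
class CountSimConfig:
    n_genes: int = 5000
    n_patients: int = 2
    n_controls: int = 4
    #: natural-log mean/sd of the log-normal baseline. The default gives a
    #: mean of ~2.3k counts per gene — the per-gene coverage of a 45M-read
    #: library spread over ~20k expressed genes, matching deep bulk RNA-seq
    #: of cultured fibroblasts.
    baseline_mean_log_params: tuple[float, float] = (6.6, 1.5)
    dispersion: float = 0.15
    de_fraction: float = 0.014   # 70 of 5000 genes
    de_up_share: float = 4 / 7   # mirrors a 40-up / 30-down planted split
    de_log2fc: float = 2.0
    library_sizes: tuple[float, ...] | None = None
    gene_length_range: tuple[int, int] = (300, 10_000)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValidationError("both groups need >=1 sample")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValidationError("de_fraction must be in [0,1]")


def simulate_counts(cfg: CountSimConfig | None = None) -> tuple[CountMatrix, pd.DataFrame]:
    """NB count matrix with a planted DE signature.

    Returns ``(count_matrix, truth)``; truth has one row per planted DE gene
    with its sign and log2 effect. Patient-group means are shifted by
    2^(+-de_log2fc) for planted genes.
    """
    cfg = cfg or CountSimConfig()
    rng = np.random.default_rng(cfg.seed)
    mu_log, sd_log = cfg.baseline_mean_log_params
    baseline = rng.lognormal(mu_log, sd_log, cfg.n_genes)
    lengths = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1],
                           cfg.n_genes)

    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    n_up = int(round(cfg.de_up_share * n_de))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    signs = np.array([1] * n_up + [-1] * (n_de - n_up))
    effect = np.zeros(cfg.n_genes)
    effect[de_idx] = signs * cfg.de_log2fc

    n_samples = cfg.n_patients + cfg.n_controls
    sample_ids = ([f"patient_{i+1}" for i in range(cfg.n_patients)]
                  + [f"control_{i+1}" for i in range(cfg.n_controls)])
    group = {s: ("patient" if s.startswith("patient") else "control")
             for s in sample_ids}

    means = np.tile(baseline[:, None], (1, n_samples))
    means[:, :cfg.n_patients] *= 2.0 ** effect[:, None]
    if cfg.library_sizes is not None:
        if len(cfg.library_sizes) != n_samples:
            raise ValidationError("library_sizes length must equal sample count")
        scale = np.asarray(cfg.library_sizes) / means.sum(axis=0)
        means = means * scale

    if cfg.dispersion == 0:
        counts = rng.poisson(means)
    else:
        r = 1.0 / cfg.dispersion
        p = r / (r + means)
        counts = rng.negative_binomial(r, p)

    cm = CountMatrix([f"G{i:05d}" for i in range(cfg.n_genes)], lengths,
                     sample_ids, group, counts)
    truth = pd.DataFrame({
        "gene_id": [cm.gene_ids[i] for i in de_idx],
        "sign": np.where(signs > 0, "up", "down"),
        "log2fc": signs * cfg.de_log2fc,
    })
    return cm, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def simulate_ct(
    target_fold_changes: dict[str, float] | None = None,
    noise_sd: float = 0.2,
    n_per_group: int = 3,
    n_replicates: int = 3,
    target: str = "COL1A1",
    reference: str = "18srRNA",
    base_ct: float = 24.0,
    reference_ct: float = 15.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a Ct table for the four treatment groups.

    ``target_fold_changes`` maps group name to expression fold relative to
    the control group (default: untreated and scrambled at 1.0, two knockdown
    constructs at 4- and 3-fold up-regulation of the target). Target Ct is
    ``base_ct - log2(fold) + N(0, noise_sd)`` per replicate; the reference
    gene is constant across groups.
    """
    folds = target_fold_changes or {"Un": 1.0, "Sc": 1.0, "S1": 4.0, "S2": 3.0}
    if any(f <= 0 for f in folds.values()):
        raise ValidationError("fold changes must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for grp, fold in folds.items():
        for i in range(n_per_group):
            sid = f"{grp}_{i+1}"
            for rep in range(1, n_replicates + 1):
                ct = base_ct - np.log2(fold) + rng.normal(0.0, noise_sd)
                rows.append({"sample_id": sid, "group": grp, "gene": target,
                             "replicate": rep, "ct": float(ct)})
            for rep in range(1, n_replicates + 1):
                rows.append({"sample_id": sid, "group": grp, "gene": reference,
                             "replicate": rep, "ct": float(reference_ct)})
    return pd.DataFrame(rows)
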