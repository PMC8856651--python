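"""Co-segregation filtering of multi-sample variant calls.

Reproduces the triage logic used to nominate a causal variant in a fully
penetrant autosomal-dominant family: a variant *segregates* when every
genotyped affected member carries at least one alternate allele and every
genotyped unaffected member is homozygous reference. A second filter removes
variants observed in population control panels (ExAC, 1000 Genomes, gnomAD);
absence from every panel at frequency 0 is the PM2-style evidence consumed by
the classification stage.

Genotype calls are held in a dense variants x samples int8 matrix with codes
``0`` hom-ref, ``1`` het, ``2`` hom-alt, ``-1`` missing. Multi-allelic sites
are decomposed on read into one record per alternate allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .pedigree import Affection, Pedigree

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

REGION_CLASSES = ("promoter", "exon", "splice_site", "intron", "utr", "intergenic")

#: Population panels recognised by default.
DEFAULT_PANELS = ("ExAC", "1000G", "gnomAD")


@dataclass(frozen=True)
class VariantRecord:
    """A single (decomposed) alternate allele with optional annotation."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    gene: str | None = None
    region_class: str | None = None
    hgvs_c: str | None = None
    pop_af: Mapping[str, float] = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self):
        if self.pos < 1:
            raise DataError(f"variant position must be >=1, got {self.pos}")
        if self.ref == self.alt:
            raise DataError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        for panel, af in self.pop_af.items():
            if not 0.0 <= af <= 1.0:
                raise DataError(f"allele frequency {af} for panel {panel} outside [0,1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


class GenotypeMatrix:
    """Diploid calls for an ordered set of variants over an ordered set of samples."""

    def __init__(self, variants: Sequence[VariantRecord], sample_ids: Sequence[str],
                 calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(variants), len(sample_ids)):
            raise DataError(
                f"call matrix shape {calls.shape} does not match "
                f"{len(variants)} variants x {len(sample_ids)} samples"
            )
        self.variants = list(variants)
        self.sample_ids = list(sample_ids)
        self.calls = calls
        self._vindex = {v.key: i for i, v in enumerate(self.variants)}

    def __len__(self) -> int:
        return len(self.variants)

    def variant_index(self, variant: VariantRecord) -> int:
        try:
            return self._vindex[variant.key]
        except KeyError:
            raise DataError(f"variant {variant} not present in matrix") from None

    def calls_for(self, variant: VariantRecord) -> dict[str, int]:
        row = self.calls[self.variant_index(variant)]
        return dict(zip(self.sample_ids, (int(c) for c in row)))

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return GenotypeMatrix(self.variants, list(sample_ids), self.calls[:, idx])


@dataclass
class SegregationVerdict:
    """Outcome of the dominant-model filter for one variant."""

    variant: VariantRecord
    segregates: bool
    n_affected_carrier: int
    n_unaffected_noncarrier: int
    n_missing: int
    violations: list[tuple[str, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# VCF / annotation I/O
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> dict[tuple[str, int, str, str], dict]:
    """Annotation sidecar TSV keyed by (chrom, pos, ref, alt).

    Fixed columns ``chrom pos ref alt gene region_class hgvs_c``; every other
    column is interpreted as a population panel frequency.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    fixed = {"chrom", "pos", "ref", "alt", "gene", "region_class", "hgvs_c"}
    panels = [c for c in df.columns if c not in fixed]
    out: dict[tuple[str, int, str, str], dict] = {}
    for d in df.to_dict(orient="records"):
        key = (str(d["chrom"]), int(d["pos"]), str(d["ref"]), str(d["alt"]))
        out[key] = {
            "gene": None if pd.isna(d.get("gene")) else str(d["gene"]),
            "region_class": None if pd.isna(d.get("region_class")) else str(d["region_class"]),
            "hgvs_c": None if pd.isna(d.get("hgvs_c")) else str(d["hgvs_c"]),
            "pop_af": {p: float(d[p]) for p in panels if not pd.isna(d[p])},
        }
    return out


def read_vcf(path: str | Path, annotations: str | Path | None = None) -> GenotypeMatrix:
    """Read a multi-sample VCF 4.x into a :class:`GenotypeMatrix`.

    Multi-allelic sites are decomposed into one record per alternate allele;
    for alternate allele *k* the per-sample call is the number of *k* alleles
    in the genotype (other alternate alleles count as reference for that
    record). Any missing allele yields a missing call.
    """
    from cyvcf2 import VCF

    ann = read_annotations(annotations) if annotations is not None else {}
    path = str(path)
    if not Path(path).exists():
        raise DataError(f"VCF file not found: {path}")
    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    for v in vcf:
        if len(sample_ids):
            # cyvcf2 genotype entries are [allele_a, allele_b, phased]
            gts = np.array([g[:2] for g in v.genotypes], dtype=int)
        else:
            gts = np.empty((0, 2), int)
        for k, alt in enumerate(v.ALT, start=1):
            key = (str(v.CHROM), int(v.POS), str(v.REF), str(alt))
            extra = ann.get(key, {})
            variants.append(VariantRecord(
                chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                gene=extra.get("gene"), region_class=extra.get("region_class"),
                hgvs_c=extra.get("hgvs_c"), pop_af=extra.get("pop_af", {}),
            ))
            calls = (gts == k).sum(axis=1).astype(np.int8)
            calls[(gts < 0).any(axis=1)] = MISSING
            rows.append(calls)
    calls = np.vstack(rows) if rows else np.empty((0, len(sample_ids)), dtype=np.int8)
    return GenotypeMatrix(variants, sample_ids, calls)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF 4.2 (inverse of :func:`read_vcf` for
    biallelic records)."""
    gt_out = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    contigs = sorted({v.chrom for v in gm.variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=famseg\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for i, v in enumerate(gm.variants):
            gts = "\t".join(gt_out[int(c)] for c in gm.calls[i])
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def dominant_filter(
    gm: GenotypeMatrix,
    ped: Pedigree,
    require_het: bool = False,
    strict_missing: bool = False,
) -> list[SegregationVerdict]:
    """Retain variants compatible with a fully penetrant dominant model.

    A variant segregates iff every genotyped affected sample carries >=1
    alternate allele (exactly het if ``require_het``) and every genotyped
    unaffected sample is hom-ref. Missing calls are compatible but counted
    (and, with ``strict_missing``, rejected). Hom-alt calls in affected
    members pass but are flagged as atypical for a rare dominant variant.
    """
    sample_set = set(gm.sample_ids)
    aff_ids = [i.id for i in ped
               if i.affected is Affection.AFFECTED and i.id in sample_set]
    unaff_ids = [i.id for i in ped
                 if i.affected is Affection.UNAFFECTED and i.id in sample_set]
    if not aff_ids and not unaff_ids:
        raise ConfigurationError(
            "no overlap between pedigree members and VCF sample ids"
        )
    col = {s: j for j, s in enumerate(gm.sample_ids)}
    aff_idx = np.array([col[s] for s in aff_ids], dtype=int)
    unaff_idx = np.array([col[s] for s in unaff_ids], dtype=int)

    A = gm.calls[:, aff_idx] if aff_idx.size else np.empty((len(gm), 0), np.int8)
    U = gm.calls[:, unaff_idx] if unaff_idx.size else np.empty((len(gm), 0), np.int8)

    a_missing = A == MISSING
    u_missing = U == MISSING
    a_carrier = (A == HET) if require_het else (A >= HET)
    a_bad = ~a_carrier & ~a_missing
    u_bad = (U != HOM_REF) & ~u_missing

    n_missing = a_missing.sum(axis=1) + u_missing.sum(axis=1)
    seg = ~a_bad.any(axis=1) & ~u_bad.any(axis=1)
    if strict_missing:
        seg &= n_missing == 0

    verdicts: list[SegregationVerdict] = []
    for i, variant in enumerate(gm.variants):
        violations: list[tuple[str, str]] = []
        notes: list[str] = []
        if a_bad[i].any() or u_bad[i].any() or (strict_missing and n_missing[i] > 0):
            for j in np.flatnonzero(a_bad[i]):
                reason = ("affected not heterozygous" if require_het
                          else "affected without alt allele")
                violations.append((aff_ids[j], reason))
            for j in np.flatnonzero(u_bad[i]):
                violations.append((unaff_ids[j], "unaffected carries alt allele"))
            if strict_missing:
                for j in np.flatnonzero(a_missing[i]):
                    violations.append((aff_ids[j], "missing call (strict mode)"))
                for j in np.flatnonzero(u_missing[i]):
                    violations.append((unaff_ids[j], "missing call (strict mode)"))
        if not require_het and (A[i] == HOM_ALT).any():
            notes.append("hom-alt call in affected member (atypical for rare dominant)")
        if n_missing[i] > 0 and not strict_missing:
            notes.append(f"{int(n_missing[i])} missing call(s) treated as compatible")
        verdicts.append(SegregationVerdict(
            variant=variant,
            segregates=bool(seg[i]) and not violations,
            n_affected_carrier=int((a_carrier[i]).sum()),
            n_unaffected_noncarrier=int((U[i] == HOM_REF).sum()),
            n_missing=int(n_missing[i]),
            violations=violations,
            notes=notes,
        ))
    return verdicts


def population_absence_filter(
    verdicts: Iterable[SegregationVerdict],
    max_af: float = 0.0,
    require_panels: Sequence[str] = DEFAULT_PANELS,
) -> list[SegregationVerdict]:
    """Keep verdicts whose variant frequency is <= ``max_af`` in every panel.

    A variant with no entry for a panel is treated as unobserved there
    (frequency 0) and flagged. Panel names are validated against the panels
    declared anywhere in the input plus the default panel set.
    """
    if not 0.0 <= max_af <= 1.0:
        raise ConfigurationError(f"max_af must be in [0,1], got {max_af}")
    verdicts = list(verdicts)
    known = set(DEFAULT_PANELS)
    for v in verdicts:
        known.update(v.variant.pop_af)
    unknown = [p for p in require_panels if p not in known]
    if unknown:
        raise ConfigurationError(f"unknown population panel(s): {unknown}")

    kept: list[SegregationVerdict] = []
    for v in verdicts:
        afs = v.variant.pop_af
        if all(afs.get(p, 0.0) <= max_af for p in require_panels):
            unobserved = [p for p in require_panels if p not in afs]
            if unobserved:
                v.notes.append("unobserved in panel(s): " + ",".join(unobserved))
            kept.append(v)
    return kept


@dataclass
class ConcordanceReport:
    n_concordant: int
    n_discordant: int
    discordant_ids: list[str]
    full_family_segregates: bool


def validation_concordance(
    gm_wes: GenotypeMatrix,
    gm_validation: GenotypeMatrix,
    variant: VariantRecord,
    ped: Pedigree,
) -> ConcordanceReport:
    """Compare exome and validation (e.g. Sanger) calls for one variant.

    Per-sample calls are compared on the shared samples; the dominant filter
    is then evaluated on the union of samples (validation calls taking
    precedence on conflicts) to decide whether the variant co-segregates in
    the full family.
    """
    wes = gm_wes.calls_for(variant)
    val = gm_validation.calls_for(variant)
    shared = [s for s in wes if s in val]
    discordant = [s for s in shared if wes[s] != val[s]]

    merged = dict(wes)
    merged.update(val)  # validation takes precedence
    samples = list(merged)
    calls = np.array([[merged[s] for s in samples]], dtype=np.int8)
    union_gm = GenotypeMatrix([variant], samples, calls)
    verdict = dominant_filter(union_gm, ped)[0]
    return ConcordanceReport(
        n_concordant=len(shared) - len(discordant),
        n_discordant=len(discordant),
        discordant_ids=discordant,
        full_family_segregates=verdict.segregates,
    )
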