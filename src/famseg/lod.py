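"""Two-point linkage LOD scores from phase-known meiosis counts.

Model: fully penetrant autosomal-dominant trait, zero phenocopy rate and a
vanishingly rare disease allele. Under these assumptions each informative
meiosis is scored recombinant (R) or non-recombinant (NR) by comparing the
child's carrier status with its affection status, and the two-point LOD at
recombination fraction theta is

    LOD(theta) = log10[ (1-theta)^NR * theta^R / 0.5^(NR+R) ]

so complete co-segregation over n meioses gives LOD(0) = n * log10(2).
With R > 0 the likelihood vanishes at theta = 0; that point is represented by
``-inf`` and excluded from grid maximization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .pedigree import (
    Affection,
    MeiosisSet,
    Pedigree,
    informative_meioses,
    obligate_carriers,
)
from .segregation import GenotypeMatrix, HET, MISSING, VariantRecord


@dataclass
class MeiosisCounts:
    """Recombinant / non-recombinant tallies over a set of informative meioses."""

    non_recombinant: int = 0
    recombinant: int = 0
    #: meioses that could not be scored (e.g. child affection unknown), as
    #: (parent_id, child_id, reason)
    excluded: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.non_recombinant + self.recombinant

    def __add__(self, other: "MeiosisCounts") -> "MeiosisCounts":
        return MeiosisCounts(
            self.non_recombinant + other.non_recombinant,
            self.recombinant + other.recombinant,
            self.excluded + other.excluded,
        )


@dataclass
class LodResult:
    counts: MeiosisCounts
    theta_grid: np.ndarray
    lods: np.ndarray
    theta_max: float
    lod_max: float

    @property
    def lod_at(self) -> dict[float, float]:
        return dict(zip(self.theta_grid.tolist(), self.lods.tolist()))


def carriers_from_genotypes(gm: GenotypeMatrix, variant: VariantRecord) -> dict[str, bool]:
    """Carrier map (>=1 alt allele) for samples with a non-missing call."""
    return {s: c >= HET for s, c in gm.calls_for(variant).items() if c != MISSING}


def classify_meioses(
    ped: Pedigree,
    gm: GenotypeMatrix,
    variant: VariantRecord,
    use_affection_proxy: bool = True,
) -> MeiosisCounts:
    """Score each informative meiosis as recombinant or non-recombinant.

    Carrier statuses are read from the genotype matrix, obligate carriers are
    resolved for ungenotyped members, and each informative meiosis is
    non-recombinant when the child's carrier status matches its affection
    status under the dominant model. Children with unknown affection cannot be
    scored and are reported in ``excluded``.
    """
    carriers = {s: v for s, v in carriers_from_genotypes(gm, variant).items() if s in ped}
    inferred = obligate_carriers(ped, carriers, use_affection_proxy=use_affection_proxy)
    full = dict(carriers)
    for iid in inferred:
        full[iid] = True
    if use_affection_proxy:
        # non-carrier side of the proxy, for ungenotyped unaffected founders
        for ind in ped:
            if ind.id not in full and not ind.genotyped \
                    and ind.affected is Affection.UNAFFECTED:
                full[ind.id] = False

    meioses: MeiosisSet = informative_meioses(ped, full)
    counts = MeiosisCounts()
    for parent_id, child_id in meioses.meioses:
        child = ped.get(child_id)
        if child.affected is Affection.UNKNOWN:
            counts.excluded.append((parent_id, child_id, "child affection unknown"))
            continue
        carrier = full[child_id]
        affected = child.affected is Affection.AFFECTED
        if carrier == affected:
            counts.non_recombinant += 1
        else:
            counts.recombinant += 1
    return counts


def lod_at_theta(counts: MeiosisCounts, theta: float) -> float:
    """Phase-known two-point LOD at a single recombination fraction."""
    if not 0.0 <= theta <= 0.5:
        raise ValidationError(f"theta must be in [0, 0.5], got {theta}")
    nr, r = counts.non_recombinant, counts.recombinant
    if theta == 0.5 or (nr == 0 and r == 0):
        return 0.0
    if theta == 0.0:
        return float("-inf") if r > 0 else nr * math.log10(2.0)
    n = nr + r
    return nr * math.log10(1.0 - theta) + r * math.log10(theta) + n * math.log10(2.0)


def max_lod(counts: MeiosisCounts, grid_step: float = 0.001) -> LodResult:
    """Maximize the LOD over a regular theta grid on [0, 0.5].

    Ties break toward smaller theta; ``-inf`` (theta = 0 with R > 0) is
    excluded from the maximization but kept in the curve.
    """
    if grid_step <= 0:
        raise ValidationError(f"grid_step must be > 0, got {grid_step}")
    n_points = int(round(0.5 / grid_step)) + 1
    grid = np.linspace(0.0, 0.5, n_points)
    lods = np.array([lod_at_theta(counts, float(t)) for t in grid])
    finite = np.where(np.isfinite(lods), lods, -np.inf)
    imax = int(np.argmax(finite))  # argmax returns the first (smallest theta) on ties
    return LodResult(
        counts=counts,
        theta_grid=grid,
        lods=lods,
        theta_max=float(grid[imax]),
        lod_max=float(lods[imax]),
    )
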