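"""Model-free co-segregation filtering.

A variant co-segregates with disease when every genotyped affected family
member carries it and no genotyped unaffected member does.  No inheritance
model is fitted; instead the filter is run under both a dominant carrier
definition (dosage >= 1) and a recessive homozygote definition
(dosage == 2), and reported separately.

Missing genotypes are handled by an explicit policy:

* ``strict`` (default, conservative) — a missing genotype among the
  affected makes the variant *ambiguous*, never segregating.
* ``permissive`` — missing individuals are simply ignored.

Individuals with ``affection='excluded'`` or ``'unknown'`` never enter the
carrier counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from famseg.pedio import MISSING, GenotypeMatrix, Pedigree

__all__ = [
    "SegregationResult",
    "FunnelCounts",
    "classify_carriers",
    "segregation_filter",
    "segregation_funnel_report",
]

Model = Literal["dominant_carrier", "recessive_homozygote"]
MissingPolicy = Literal["strict", "permissive"]

CARRIER, NONCARRIER, MISSING_CALL = "carrier", "noncarrier", "missing"


@dataclass(frozen=True)
class SegregationResult:
    """Carrier-pattern classification of one variant."""

    variant_index: int
    model: str
    affected_carriers: int
    affected_noncarriers: int
    unaffected_carriers: int
    unaffected_noncarriers: int
    n_missing_affected: int
    n_missing_unaffected: int
    status: str  # segregating | non_segregating | ambiguous

    def __post_init__(self) -> None:
        if self.status == "segregating":
            assert self.affected_noncarriers == 0
            assert self.unaffected_carriers == 0


@dataclass(frozen=True)
class FunnelCounts:
    """Variant counts through the segregation funnel."""

    n_total: int
    n_segregating_dominant: int
    n_segregating_recessive: int
    n_ambiguous: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def classify_carriers(dosages: Sequence[int] | np.ndarray, model: Model
                      ) -> list[str]:
    """Classify each dosage as carrier / noncarrier / missing under a model.

    ``dominant_carrier``: carrier iff dosage >= 1.
    ``recessive_homozygote``: carrier iff dosage == 2.
    """
    d = np.asarray(dosages)
    if model == "dominant_carrier":
        carrier = d >= 1
    elif model == "recessive_homozygote":
        carrier = d == 2
    else:
        raise ValueError(f"unknown model {model!r}")
    out = []
    for di, ci in zip(d, carrier):
        if di == MISSING:
            out.append(MISSING_CALL)
        else:
            out.append(CARRIER if ci else NONCARRIER)
    return out


def _status_groups(pedigree: Pedigree, matrix: GenotypeMatrix
                   ) -> tuple[list[int], list[int]]:
    """Matrix column indices of genotyped affected / unaffected members."""
    cols = {s: j for j, s in enumerate(matrix.sample_ids)}
    affected, unaffected = [], []
    for ind in pedigree.individuals:
        j = cols.get(ind.id)
        if j is None:
            continue
        if ind.affection == "affected":
            affected.append(j)
        elif ind.affection == "unaffected":
            unaffected.append(j)
        # unknown / excluded: never counted
    return affected, unaffected


def segregation_filter(matrix: GenotypeMatrix, pedigree: Pedigree,
                       model: Model = "dominant_carrier",
                       missing_policy: MissingPolicy = "strict",
                       ) -> list[SegregationResult]:
    """Classify every variant's co-segregation status; the segregating
    subset is ``[r for r in results if r.status == 'segregating']``.

    A variant is segregating iff every genotyped affected is a carrier AND
    every genotyped unaffected is a noncarrier.  Under the ``strict``
    policy a missing genotype among the affected renders the variant
    ambiguous instead.
    """
    if missing_policy not in ("strict", "permissive"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    aff_cols, unaff_cols = _status_groups(pedigree, matrix)
    if not aff_cols:
        raise ValueError("no genotyped affected individuals in pedigree")

    G = matrix.genotypes
    A = G[:, aff_cols] if aff_cols else np.empty((matrix.n_variants, 0), np.int8)
    U = G[:, unaff_cols] if unaff_cols else np.empty((matrix.n_variants, 0), np.int8)

    def carrier_mask(block: np.ndarray) -> np.ndarray:
        if model == "dominant_carrier":
            return block >= 1
        if model == "recessive_homozygote":
            return block == 2
        raise ValueError(f"unknown model {model!r}")

    a_missing = A == MISSING
    u_missing = U == MISSING
    a_carrier = carrier_mask(A) & ~a_missing
    u_carrier = carrier_mask(U) & ~u_missing
    a_noncarrier = ~carrier_mask(A) & ~a_missing
    u_noncarrier = ~carrier_mask(U) & ~u_missing

    results: list[SegregationResult] = []
    for i in range(matrix.n_variants):
        n_ac = int(a_carrier[i].sum())
        n_an = int(a_noncarrier[i].sum())
        n_uc = int(u_carrier[i].sum())
        n_un = int(u_noncarrier[i].sum())
        n_ma = int(a_missing[i].sum())
        n_mu = int(u_missing[i].sum())
        if missing_policy == "strict" and n_ma > 0:
            status = "ambiguous"
        elif n_an == 0 and n_uc == 0 and n_ac > 0:
            status = "segregating"
        else:
            status = "non_segregating"
        results.append(SegregationResult(
            variant_index=i, model=model,
            affected_carriers=n_ac, affected_noncarriers=n_an,
            unaffected_carriers=n_uc, unaffected_noncarriers=n_un,
            n_missing_affected=n_ma, n_missing_unaffected=n_mu,
            status=status))
    return results


def segregation_funnel_report(matrix: GenotypeMatrix, pedigree: Pedigree,
                              missing_policy: MissingPolicy = "strict",
                              ) -> FunnelCounts:
    """Run both allele models and summarise the funnel.

    ``n_ambiguous`` counts variants with a missing genotype among the
    affected (strict policy); it is model-independent.
    """
    if matrix.n_variants == 0:
        return FunnelCounts(0, 0, 0, 0)
    dom = segregation_filter(matrix, pedigree, "dominant_carrier", missing_policy)
    rec = segregation_filter(matrix, pedigree, "recessive_homozygote", missing_policy)
    return FunnelCounts(
        n_total=matrix.n_variants,
        n_segregating_dominant=sum(r.status == "segregating" for r in dom),
        n_segregating_recessive=sum(r.status == "segregating" for r in rec),
        n_ambiguous=sum(r.status == "ambiguous" for r in dom),
    )


def results_to_frame(results: Sequence[SegregationResult],
                     matrix: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Serialise segregation results (optionally annotated with variant
    coordinates) in deterministic (chrom, pos, alt) order."""
    rows = [r.__dict__ for r in results]
    df = pd.DataFrame(rows)
    if matrix is not None and len(df):
        df["chrom"] = [matrix.variants[i].chrom for i in df["variant_index"]]
        df["pos"] = [matrix.variants[i].pos for i in df["variant_index"]]
        df["alt"] = [matrix.variants[i].alt_allele for i in df["variant_index"]]
        df["rsid"] = [matrix.variants[i].rsid for i in df["variant_index"]]
        df = df.sort_values(["chrom", "pos", "alt"], kind="mergesort",
                            ignore_index=True)
    return df
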