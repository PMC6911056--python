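"""Prioritization of co-segregating variants.

Variants that survive the segregation filter are ranked by three labels:

* **deleteriousness** — a consensus vote over up to five in-silico
  predictors (SIFT, PolyPhen-2, CADD, GERP, MutationTaster), each at its
  conventional damaging threshold; missing scores shrink the denominator
  rather than counting as benign.
* **novelty** — the gene is absent from a supplied known-disease-gene list.
* **population MAF class** — rare / common / unknown.  MAF is a *label*,
  not a filter: a common deleterious variant in a novel gene stays in
  tier 1 (an optional ``max_maf`` cut exists but defaults to off).

Tiers: 1 = deleterious AND novel gene; 2 = deleterious, known gene;
3 = not deleterious, novel gene; 4 = neither.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from famseg.pedio import GenotypeMatrix, PredictionScores
from famseg.segregation import SegregationResult

__all__ = ["PriorityRules", "PriorityCall", "deleterious_votes",
           "prioritize_variants"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PriorityRules:
    """Thresholds for the deleteriousness consensus and MAF classing.

    Defaults are each predictor's conventional damaging cut-off; the
    combination rule is a configurable vote count.
    """

    sift_max: float = 0.05          # damaging if sift < sift_max
    polyphen_min: float = 0.85      # damaging if polyphen > polyphen_min
    cadd_min: float = 15.0          # damaging if cadd_phred >= cadd_min
    gerp_min: float = 2.0           # damaging if gerp > gerp_min
    min_votes: int = 2              # deleterious if votes >= min_votes ...
    min_present: int = 2            # ... among >= min_present present scores
    rare_maf: float = 0.01          # rare if population_maf < rare_maf
    max_maf: float | None = None    # optional hard MAF filter (off)


@dataclass(frozen=True)
class PriorityCall:
    """Prioritization labels for one segregating variant."""

    variant_index: int
    votes_deleterious: int
    n_scores_present: int
    deleterious: bool
    novel_gene: bool
    maf_class: str  # rare | common | unknown
    tier: int

    def __post_init__(self) -> None:
        assert self.votes_deleterious <= self.n_scores_present
        assert (self.tier == 1) == (self.deleterious and self.novel_gene)


def deleterious_votes(scores: PredictionScores,
                      rules: PriorityRules = PriorityRules()
                      ) -> tuple[int, int]:
    """Count damaging votes among present predictor scores.

    Returns ``(votes, n_present)``; all-absent scores give ``(0, 0)``.
    """
    votes = 0
    present = 0
    if scores.sift is not None:
        present += 1
        votes += scores.sift < rules.sift_max
    if scores.polyphen is not None:
        present += 1
        votes += scores.polyphen > rules.polyphen_min
    if scores.cadd_phred is not None:
        present += 1
        votes += scores.cadd_phred >= rules.cadd_min
    if scores.gerp is not None:
        present += 1
        votes += scores.gerp > rules.gerp_min
    if scores.mutation_taster is not None:
        present += 1
        votes += scores.mutation_taster == "disease_causing"
    return votes, present


def _maf_class(pmaf: float | None, rules: PriorityRules) -> str:
    if pmaf is None:
        return "unknown"
    return "rare" if pmaf < rules.rare_maf else "common"


def prioritize_variants(segregating: Sequence[SegregationResult],
                        matrix: GenotypeMatrix,
                        known_genes: Iterable[str],
                        rules: PriorityRules = PriorityRules()
                        ) -> list[PriorityCall]:
    """Label and rank segregating variants.

    The output is a pure relabelling of the input set (no silent drops,
    unless the optional ``rules.max_maf`` filter is enabled), sorted by
    (tier, descending votes, ascending population MAF with unknown last).
    A variant without a gene symbol is conservatively treated as
    not-novel and logged.
    """
    known = set(known_genes)
    calls: list[PriorityCall] = []
    for res in segregating:
        v = matrix.variants[res.variant_index]
        votes, present = deleterious_votes(v.predictions, rules)
        deleterious = (present >= rules.min_present
                       and votes >= rules.min_votes)
        if v.gene is None:
            log.warning("variant %s:%d has no gene symbol; treating as "
                        "not novel", v.chrom, v.pos)
            novel = False
        else:
            novel = v.gene not in known
        mclass = _maf_class(v.population_maf, rules)
        if rules.max_maf is not None and v.population_maf is not None \
                and v.population_maf > rules.max_maf:
            continue
        tier = (1 if deleterious and novel else
                2 if deleterious else
                3 if novel else 4)
        calls.append(PriorityCall(
            variant_index=res.variant_index,
            votes_deleterious=votes, n_scores_present=present,
            deleterious=deleterious, novel_gene=novel,
            maf_class=mclass, tier=tier))

    def sort_key(c: PriorityCall):
        pmaf = matrix.variants[c.variant_index].population_maf
        v = matrix.variants[c.variant_index]
        return (c.tier, -c.votes_deleterious,
                pmaf if pmaf is not None else float("inf"),
                v.chrom, v.pos, v.alt_allele)

    calls.sort(key=sort_key)
    return calls


def calls_to_frame(calls: Sequence[PriorityCall],
                   matrix: GenotypeMatrix) -> pd.DataFrame:
    rows = []
    for c in calls:
        v = matrix.variants[c.variant_index]
        rows.append({**c.__dict__, "chrom": v.chrom, "pos": v.pos,
                     "rsid": v.rsid, "gene": v.gene,
                     "population_maf": v.population_maf})
    return pd.DataFrame(rows)
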