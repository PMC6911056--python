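"""Gene-dropping simulator for family and cohort study designs.

Generates every input the analysis pipeline consumes:

* a four-generation pedigree template (~32 members, one first-cousin
  consanguineous mating) with genotypes gene-dropped from founder
  haplotypes through each meiosis, under per-interval recombination
  fractions, symmetric genotyping error and missingness;
* affection statuses drawn from a penetrance model (carrier risk ``f1``,
  phenocopy rate ``f0``) at a planted causal variant;
* a case-control cohort genotyped at one biallelic SNP with specified
  control risk-allele frequency and true allelic odds ratio;
* genotype-stratified phenotype tables with configurable per-group
  moments and optional linear covariate effects.

Everything is driven by a single integer seed through
``numpy.random.default_rng`` and writes the same plain-text formats the
readers in :mod:`famseg.pedio` consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from famseg.pedio import (MISSING, GenotypeMatrix, Individual, Pedigree,
                          PredictionScores, VariantRecord, write_ped,
                          write_vcf)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "four_generation_template",
    "gene_drop",
    "assign_affection",
    "simulate_family",
    "simulate_cohort",
    "simulate_phenotypes",
    "make_fixture",
    "study_config",
    "COHORT_PHENOTYPE_MODEL",
    "COHORT_GROUP_SIZES",
]


@dataclass
class SimulationConfig:
    """All knobs of the simulator.

    ``founder_freqs`` may be a scalar (shared by all variants) or an array
    of per-variant founder alt-allele frequencies; ``recombination`` is a
    scalar or per-adjacent-interval array of recombination fractions in
    [0, 0.5].  The causal variant is planted as ``causal_founder_copies``
    alt copies in ``causal_founder``, optionally extended over a
    contiguous ``risk_segment`` of variants carried on the same founder
    haplotype(s).
    """

    n_variants: int = 2001
    founder_freqs: float | np.ndarray = 0.3
    recombination: float | np.ndarray = 0.01
    penetrance_f0: float = 0.05   # phenocopy rate
    penetrance_f1: float = 0.9    # carrier risk
    inheritance_model: str = "dominant_carrier"
    genotype_error_rate: float = 0.0
    genotype_missing_rate: float = 0.0
    causal_index: int | None = None
    causal_founder: str = "I-1"
    causal_founder_copies: int = 2
    risk_segment: tuple[int, int] | None = None
    n_cases: int = 141
    n_controls: int = 130
    control_risk_freq: float = 0.38
    true_or: float = 1.579
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("penetrance_f0", "penetrance_f1",
                     "genotype_error_rate", "genotype_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.penetrance_f1 < self.penetrance_f0:
            raise ValueError("risk model requires f1 >= f0")
        r = np.atleast_1d(np.asarray(self.recombination, dtype=float))
        if ((r < 0) | (r > 0.5)).any():
            raise ValueError("recombination fractions must lie in [0, 0.5]")
        if not 0 < self.control_risk_freq < 1:
            raise ValueError("control_risk_freq must be in (0, 1)")
        if self.true_or <= 0:
            raise ValueError("true_or must be > 0")


@dataclass
class TruthRecord:
    """Simulator ground truth: phased diplotypes, masks, causal index."""

    sample_ids: list[str]
    paternal_haplotypes: np.ndarray  # (n_variants, n_samples) 0/1
    maternal_haplotypes: np.ndarray
    causal_index: int | None
    error_mask: np.ndarray           # True where an allele was flipped
    missing_mask: np.ndarray         # True where the call was dropped
    affection_mechanism: dict[str, str] = dc_field(default_factory=dict)

    def true_dosage(self) -> np.ndarray:
        return (self.paternal_haplotypes + self.maternal_haplotypes
                ).astype(np.int8)


def four_generation_template() -> Pedigree:
    """A fixed four-generation family of 32 with one first-cousin loop.

    Individuals are labelled ``<generation>-<index>`` (I-1 ... IV-10);
    III-2 x III-6 is the consanguineous (first cousin) mating.  Affection
    statuses are all 'unknown' until assigned by the penetrance model.
    """
    P: list[Individual] = []

    def add(iid, father=None, mother=None, sex="unknown"):
        P.append(Individual(id=iid, father_id=father, mother_id=mother,
                            sex=sex, generation_label=iid.replace("-", ":")))

    add("I-1", sex="male")
    add("I-2", sex="female")
    # generation II: four children of I-1 x I-2 plus married-in spouses
    add("II-1", "I-1", "I-2", "male")
    add("II-2", "I-1", "I-2", "male")
    add("II-3", "I-1", "I-2", "female")
    add("II-4", "I-1", "I-2", "female")
    add("II-5", sex="female")   # spouse of II-1
    add("II-6", sex="female")   # spouse of II-2
    add("II-7", sex="male")     # spouse of II-3
    add("II-8", sex="male")     # spouse of II-4
    # generation III
    add("III-1", "II-1", "II-5", "male")
    add("III-2", "II-1", "II-5", "male")
    add("III-3", "II-1", "II-5", "female")
    add("III-4", "II-2", "II-6", "male")
    add("III-5", "II-2", "II-6", "female")
    add("III-6", "II-7", "II-3", "female")
    add("III-7", "II-7", "II-3", "male")
    add("III-8", "II-8", "II-4", "male")
    add("III-9", "II-8", "II-4", "female")
    add("III-10", sex="female")  # spouse of III-1
    add("III-11", sex="male")    # spouse of III-5
    add("III-12", sex="female")  # spouse of III-8
    # generation IV; III-2 x III-6 are first cousins (consanguineous)
    add("IV-1", "III-1", "III-10", "male")
    add("IV-2", "III-1", "III-10", "female")
    add("IV-3", "III-1", "III-10", "male")
    add("IV-4", "III-2", "III-6", "female")
    add("IV-5", "III-2", "III-6", "male")
    add("IV-6", "III-2", "III-6", "female")
    add("IV-7", "III-11", "III-5", "male")
    add("IV-8", "III-11", "III-5", "female")
    add("IV-9", "III-8", "III-12", "male")
    add("IV-10", "III-8", "III-12", "female")
    return Pedigree(P, family_id="FAM4G")


#: Members of the template treated as genotyped (array subset, n=20).
TEMPLATE_GENOTYPED = [
    "II-1", "II-2", "II-3", "II-5", "II-6", "II-7",
    "III-1", "III-2", "III-4", "III-5", "III-6", "III-8", "III-10",
    "IV-1", "IV-2", "IV-4", "IV-5", "IV-6", "IV-7", "IV-9",
]


def _topological_order(pedigree: Pedigree) -> list[Individual]:
    placed: set[str] = set()
    order: list[Individual] = []
    pending = list(pedigree.individuals)
    while pending:
        progressed = False
        rest = []
        for ind in pending:
            if ind.is_founder or (ind.father_id in placed
                                  and ind.mother_id in placed):
                order.append(ind)
                placed.add(ind.id)
                progressed = True
            else:
                rest.append(ind)
        if not progressed:  # unreachable: Pedigree is validated acyclic
            raise RuntimeError("could not order pedigree")
        pending = rest
    return order


def _meiosis(h0: np.ndarray, h1: np.ndarray, recomb: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a parent's haplotype pair."""
    n = len(h0)
    switches = rng.random(n - 1) < recomb
    state = np.empty(n, dtype=np.int8)
    state[0] = rng.integers(0, 2)
    state[1:] = switches
    state = np.cumsum(state) % 2
    return np.where(state == 0, h0, h1).astype(np.int8)


def _default_variants(n: int, rng: np.random.Generator,
                      freqs: np.ndarray,
                      causal_index: int | None) -> list[VariantRecord]:
    bases = ("A", "C", "G", "T")
    variants = []
    for i in range(n):
        ref, alt = rng.choice(4, size=2, replace=False)
        scores = PredictionScores(
            sift=float(np.round(rng.random(), 3)) if rng.random() < 0.85 else None,
            polyphen=float(np.round(rng.random(), 3)) if rng.random() < 0.85 else None,
            cadd_phred=float(np.round(rng.random() * 30, 2)) if rng.random() < 0.85 else None,
            gerp=float(np.round(rng.random() * 11 - 5, 2)) if rng.random() < 0.85 else None,
            mutation_taster=("disease_causing" if rng.random() < 0.1
                             else "polymorphism") if rng.random() < 0.85 else None,
        )
        variants.append(VariantRecord(
            chrom="11", pos=1_000_000 + 1000 * i,
            ref_allele=bases[ref], alt_allele=bases[alt],
            rsid=f"rs{900000 + i}", gene=f"GENE{i // 5:04d}",
            consequence="missense_variant",
            predictions=scores,
            population_maf=float(np.round(min(freqs[i], 1 - freqs[i]), 4)),
        ))
    if causal_index is not None:
        v = variants[causal_index]
        variants[causal_index] = VariantRecord(
            chrom=v.chrom, pos=v.pos, ref_allele="G", alt_allele="C",
            rsid="rs10839616", gene="OR2AG2", consequence="missense_variant",
            predictions=PredictionScores(sift=0.01, polyphen=0.97,
                                         cadd_phred=24.0, gerp=4.2,
                                         mutation_taster="disease_causing"),
            population_maf=0.42)
    return variants


def gene_drop(config: SimulationConfig,
              pedigree: Pedigree | None = None,
              rng: np.random.Generator | None = None,
              variants: Sequence[VariantRecord] | None = None,
              sample_ids: Sequence[str] | None = None,
              ) -> tuple[GenotypeMatrix, TruthRecord]:
    """Drop founder haplotypes through the pedigree.

    Founder haplotypes are independent Bernoulli draws at the founder
    frequencies (the causal founder's planted copies override these over
    the risk segment); every meiosis transmits one recombinant gamete.
    Observed genotypes are the true dosages after symmetric single-allele
    flip errors and a missingness mask.  ``sample_ids`` restricts the
    emitted matrix to the genotyped subset (truth keeps everyone).
    """
    if pedigree is None:
        pedigree = four_generation_template()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_variants
    freqs = np.broadcast_to(np.asarray(config.founder_freqs, dtype=float),
                            (n,)).copy()
    recomb = np.broadcast_to(np.asarray(config.recombination, dtype=float),
                             (max(n - 1, 0),)).copy()
    order = _topological_order(pedigree)
    all_ids = [i.id for i in pedigree.individuals]
    col = {s: j for j, s in enumerate(all_ids)}
    pat = np.zeros((n, len(all_ids)), dtype=np.int8)
    mat = np.zeros((n, len(all_ids)), dtype=np.int8)

    seg = config.risk_segment
    if seg is None and config.causal_index is not None:
        seg = (config.causal_index, config.causal_index)
    if config.causal_index is not None:
        # the risk allele is private to the causal founder: it enters the
        # family exactly once and spreads identically by descent
        freqs[config.causal_index] = 0.0

    for ind in order:
        j = col[ind.id]
        if ind.is_founder:
            h0 = (rng.random(n) < freqs).astype(np.int8)
            h1 = (rng.random(n) < freqs).astype(np.int8)
            if ind.id == config.causal_founder and seg is not None:
                lo, hi = seg
                h0[lo:hi + 1] = 1
                if config.causal_founder_copies >= 2:
                    h1[lo:hi + 1] = 1
            pat[:, j], mat[:, j] = h0, h1
        else:
            fj, mj = col[ind.father_id], col[ind.mother_id]
            pat[:, j] = _meiosis(pat[:, fj], mat[:, fj], recomb, rng)
            mat[:, j] = _meiosis(pat[:, mj], mat[:, mj], recomb, rng)

    true_dosage = (pat + mat).astype(np.int8)
    observed = true_dosage.copy()
    error_mask = rng.random(observed.shape) < config.genotype_error_rate
    if error_mask.any():
        flip_up = rng.integers(0, 2, size=observed.shape).astype(np.int8)
        at = observed[error_mask]
        up = flip_up[error_mask]
        # symmetric single-allele flip: 0->1, 2->1, 1->0 or 2
        flipped = np.where(at == 0, 1, np.where(at == 2, 1,
                           np.where(up == 1, 2, 0))).astype(np.int8)
        observed[error_mask] = flipped
    missing_mask = rng.random(observed.shape) < config.genotype_missing_rate
    observed[missing_mask] = MISSING

    if variants is None:
        variants = _default_variants(n, rng, freqs, config.causal_index)
    truth = TruthRecord(sample_ids=all_ids, paternal_haplotypes=pat,
                        maternal_haplotypes=mat,
                        causal_index=config.causal_index,
                        error_mask=error_mask, missing_mask=missing_mask)
    if sample_ids is not None:
        cols = [col[s] for s in sample_ids]
        matrix = GenotypeMatrix(variants, list(sample_ids),
                                observed[:, cols])
    else:
        matrix = GenotypeMatrix(variants, all_ids, observed)
    return matrix, truth


def assign_affection(truth: TruthRecord, penetrance: tuple[float, float],
                     causal_index: int, model: str = "dominant_carrier",
                     rng: np.random.Generator | None = None,
                     seed: int | None = None) -> dict[str, str]:
    """Draw affected/unaffected per individual under a penetrance model.

    ``penetrance`` is ``(f0, f1)``: carriers at the causal variant (under
    the given model) are affected with probability ``f1``, non-carriers
    with the phenocopy rate ``f0``.
    """
    f0, f1 = penetrance
    if rng is None:
        rng = np.random.default_rng(seed)
    dosage = truth.true_dosage()[causal_index]
    out: dict[str, str] = {}
    for j, sid in enumerate(truth.sample_ids):
        if model == "dominant_carrier":
            carrier = dosage[j] >= 1
        elif model == "recessive_homozygote":
            carrier = dosage[j] == 2
        else:
            raise ValueError(f"unknown model {model!r}")
        p = f1 if carrier else f0
        affected = rng.random() < p
        out[sid] = "affected" if affected else "unaffected"
        truth.affection_mechanism[sid] = (
            f"{'carrier' if carrier else 'noncarrier'}:p={p:g}")
    return out


def simulate_family(config: SimulationConfig,
                    pedigree: Pedigree | None = None,
                    genotyped_ids: Sequence[str] | None = None,
                    ) -> tuple[Pedigree, GenotypeMatrix, TruthRecord]:
    """Gene-drop a family and assign affection in one seeded pass.

    Returns the pedigree with affection statuses filled in, the observed
    genotype matrix restricted to ``genotyped_ids`` (default: the
    20-member template subset) and the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    if pedigree is None:
        pedigree = four_generation_template()
        if genotyped_ids is None:
            genotyped_ids = TEMPLATE_GENOTYPED
    if genotyped_ids is None:
        genotyped_ids = pedigree.ids()
    causal = (config.causal_index if config.causal_index is not None
              else config.n_variants // 2)
    config = _with_causal(config, causal)
    matrix, truth = gene_drop(config, pedigree, rng,
                              sample_ids=list(genotyped_ids))
    affection = assign_affection(
        truth, (config.penetrance_f0, config.penetrance_f1),
        causal, config.inheritance_model, rng=rng)
    individuals = [Individual(
        id=i.id, father_id=i.father_id, mother_id=i.mother_id, sex=i.sex,
        affection=affection[i.id], generation_label=i.generation_label)
        for i in pedigree.individuals]
    return Pedigree(individuals, pedigree.family_id), matrix, truth


def _with_causal(config: SimulationConfig, causal: int) -> SimulationConfig:
    from dataclasses import replace
    return replace(config, causal_index=causal)


def simulate_cohort(config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[np.ndarray, list[str]]:
    """Case-control dosages at one biallelic SNP under HWE within group.

    Controls have risk-allele frequency ``p0``; the case frequency is the
    odds transform p1 = theta*p0 / (1 - p0 + theta*p0) implied by the true
    allelic odds ratio ``theta``.  Returns (dosages, status labels).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p0 = config.control_risk_freq
    theta = config.true_or
    p1 = theta * p0 / (1 - p0 + theta * p0)
    cases = rng.binomial(2, p1, size=config.n_cases)
    controls = rng.binomial(2, p0, size=config.n_controls)
    dosages = np.concatenate([cases, controls]).astype(np.int8)
    status = ["case"] * config.n_cases + ["control"] * config.n_controls
    return dosages, status


#: Per-genotype-group phenotype moments of the pediatric cohort
#: (mean, SD per GG / GC / CC group).
COHORT_PHENOTYPE_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    "age_months": {"GG": (106.88, 42.09), "GC": (101.36, 38.20), "CC": (106.50, 38.36)},
    "feno_ppb": {"GG": (24.65, 19.66), "GC": (18.89, 11.95), "CC": (16.77, 9.56)},
    "fev1_pct": {"GG": (89.2, 18.76), "GC": (83.28, 19.02), "CC": (83.33, 17.70)},
    "fvc_pct": {"GG": (86.96, 15.99), "GC": (81.93, 16.34), "CC": (82.10, 17.48)},
    "mef25_pct": {"GG": (79.43, 48.19), "GC": (77.86, 40.62), "CC": (89.57, 48.24)},
    "mef75_pct": {"GG": (91.58, 29.69), "GC": (84.32, 30.25), "CC": (84.67, 29.83)},
    "pefr_pct": {"GG": (74.48, 20.65), "GC": (67.43, 24.14), "CC": (69.05, 20.07)},
    "exacerbation_freq": {"GG": (0.13, 0.14), "GC": (0.20, 0.22), "CC": (0.16, 0.12)},
    "odor_score_pea": {"GG": (8.4, 3.09), "GC": (7.04, 3.39), "CC": (6.48, 3.63)},
}

#: Genotype-group sizes of the genotyped pediatric cases.
COHORT_GROUP_SIZES: dict[str, int] = {"GG": 57, "GC": 58, "CC": 26}


def simulate_phenotypes(subjects: pd.DataFrame | None = None,
                        phenotype_model: Mapping[str, Mapping[str, tuple[float, float]]]
                        = COHORT_PHENOTYPE_MODEL,
                        seed: int = 0,
                        n_followups: int = 1,
                        covariate_effects: Mapping[str, Mapping[str, float]] | None = None,
                        rng: np.random.Generator | None = None,
                        ) -> pd.DataFrame:
    """Draw a phenotype table with per-group normal moments.

    ``subjects`` needs columns ``subject_id`` and ``genotype_group``
    (default: the genotyped-case group sizes above); covariates age (yr),
    sex and height (cm) are generated, optional linear ``covariate_effects``
    (phenotype -> covariate -> beta) are added before the noise draw.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if subjects is None:
        rows = []
        i = 0
        for grp, n in COHORT_GROUP_SIZES.items():
            for _ in range(n):
                rows.append({"subject_id": f"S{i:04d}", "genotype_group": grp})
                i += 1
        subjects = pd.DataFrame(rows)
    out_rows = []
    for _, subj in subjects.iterrows():
        age = float(np.clip(rng.normal(8.8, 3.3), 4, 17))
        sex = "male" if rng.random() < 0.6 else "female"
        height = float(np.clip(rng.normal(115 + 4.5 * age, 7), 90, 185))
        for fu in range(n_followups):
            row = {"subject_id": subj["subject_id"],
                   "genotype_group": subj["genotype_group"],
                   "followup_index": fu,
                   "age": round(age + fu * 0.25, 2), "sex": sex,
                   "height": round(height + fu * 1.2, 1)}
            for pheno, groups in phenotype_model.items():
                mean, sd = groups[subj["genotype_group"]]
                if sd < 0:
                    raise ValueError(f"negative SD for {pheno}")
                val = mean
                if covariate_effects and pheno in covariate_effects:
                    for cov, beta in covariate_effects[pheno].items():
                        cov_val = {"age": row["age"], "height": row["height"],
                                   "sex": 1.0 if sex == "female" else 0.0}[cov]
                        val += beta * cov_val
                val += rng.normal(0.0, sd)
                row[pheno] = round(float(val), 4)
            out_rows.append(row)
    return pd.DataFrame(out_rows)


def study_config(seed: int = 42, n_variants: int = 5001,
                     genotype_error_rate: float = 0.0,
                     genotype_missing_rate: float = 0.0) -> SimulationConfig:
    """The bundled study-shaped preset.

    A four-generation family with 20 genotyped members; an exome-scale
    variant table (5001 variants, one planted fully-annotated causal
    variant at the centre of a 15-variant founder risk segment); a
    141-case / 130-control cohort with control risk-allele frequency 0.38
    and true allelic OR 1.579.
    """
    causal = n_variants // 2
    return SimulationConfig(
        n_variants=n_variants,
        founder_freqs=0.2,
        recombination=0.01,
        penetrance_f0=0.05,
        penetrance_f1=0.9,
        genotype_error_rate=genotype_error_rate,
        genotype_missing_rate=genotype_missing_rate,
        causal_index=causal,
        risk_segment=(causal - 7, causal + 7),
        n_cases=141, n_controls=130,
        control_risk_freq=0.38, true_or=1.579,
        seed=seed)


def exome_subset(pedigree: Pedigree, matrix: GenotypeMatrix,
                 n_affected: int = 5, n_unaffected: int = 3) -> list[str]:
    """Deterministic choice of the sequenced subset: the first
    ``n_affected`` affected and ``n_unaffected`` unaffected genotyped
    members in pedigree order."""
    aff = [i.id for i in pedigree.individuals
           if i.affection == "affected" and i.id in matrix._col]
    unaff = [i.id for i in pedigree.individuals
             if i.affection == "unaffected" and i.id in matrix._col]
    return aff[:n_affected] + unaff[:n_unaffected]


def make_fixture(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete input bundle for the pipeline.

    Emits family VCF + PED, cohort VCF + status CSV, a phenotype CSV, a
    known-genes list (which never contains the planted causal gene) and a
    truth JSON.  Byte-identical across runs at equal seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pedigree, matrix, truth = simulate_family(config)
    paths = {
        "family_vcf": out / "family.vcf",
        "family_ped": out / "family.ped",
        "cohort_vcf": out / "cohort.vcf",
        "status_csv": out / "status.csv",
        "phenotypes_csv": out / "phenotypes.csv",
        "known_genes": out / "known_genes.txt",
        "truth_json": out / "truth.json",
    }
    write_vcf(matrix, paths["family_vcf"])
    write_ped(pedigree, paths["family_ped"])

    rng = np.random.default_rng(config.seed + 1)
    dosages, status = simulate_cohort(config, rng)
    causal = truth.causal_index if truth.causal_index is not None else 0
    cohort_ids = [f"C{i:04d}" for i in range(len(dosages))]
    cohort_variant = matrix.variants[causal]
    cohort_matrix = GenotypeMatrix([cohort_variant], cohort_ids,
                                   dosages.reshape(1, -1))
    write_vcf(cohort_matrix, paths["cohort_vcf"])
    pd.DataFrame({"sample_id": cohort_ids, "status": status}
                 ).to_csv(paths["status_csv"], index=False)

    pheno = simulate_phenotypes(seed=config.seed + 2)
    pheno.to_csv(paths["phenotypes_csv"], index=False)

    causal_gene = matrix.variants[causal].gene
    genes = sorted({v.gene for v in matrix.variants
                    if v.gene and v.gene != causal_gene})
    known = [g for i, g in enumerate(genes) if i % 3 == 0]  # deterministic subset
    paths["known_genes"].write_text("\n".join(known) + "\n")

    truth_doc = {
        "schema_version": 1,
        "seed": config.seed,
        "causal_index": truth.causal_index,
        "causal_rsid": cohort_variant.rsid,
        "causal_gene": causal_gene,
        "risk_segment": list(config.risk_segment) if config.risk_segment else None,
        "affection_mechanism": truth.affection_mechanism,
        "n_errors": int(truth.error_mask.sum()),
        "n_missing": int(truth.missing_mask.sum()),
    }
    paths["truth_json"].write_text(json.dumps(truth_doc, indent=2,
                                              sort_keys=True) + "\n")
    return paths
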