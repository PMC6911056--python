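"""Pedigree, VCF and phenotype I/O with structural validation.

Formats supported:

* PED — PLINK-style 6-column whitespace-delimited pedigree files
  (family, individual, father, mother, sex, affection).  Sex is coded
  1=male / 2=female / 0=unknown.  Affection is coded 2=affected,
  1=unaffected, 0 or -9 = unknown, and 3 = excluded (a dialect extension
  for subjects deliberately removed from segregation analysis, e.g.
  atopy-without-asthma relatives, while keeping the pedigree structure
  intact).
* VCF 4.2 — biallelic SNVs with per-sample GT and in-silico prediction
  scores / population frequencies carried in INFO keys (configurable map).
* Phenotype CSV — one row per subject x follow-up with a header row.
* Gene lists — one symbol per line, ``#`` comments allowed.

All genotype calls are stored as alt-allele dosage 0/1/2 with ``MISSING``
(-1) for no-calls.  Coordinates are 1-based inclusive as in VCF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "Individual",
    "Pedigree",
    "PredictionScores",
    "VariantRecord",
    "GenotypeMatrix",
    "Violation",
    "PedigreeError",
    "VcfFormatError",
    "read_ped",
    "write_ped",
    "read_vcf",
    "write_vcf",
    "read_gene_list",
    "read_phenotypes",
    "validate_mendelian",
]

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

SEXES = ("male", "female", "unknown")
AFFECTIONS = ("affected", "unaffected", "unknown", "excluded")

_SEX_FROM_CODE = {"1": "male", "2": "female", "0": "unknown"}
_SEX_TO_CODE = {"male": "1", "female": "2", "unknown": "0"}
_AFF_FROM_CODE = {"2": "affected", "1": "unaffected", "0": "unknown",
                  "-9": "unknown", "3": "excluded"}
_AFF_TO_CODE = {"affected": "2", "unaffected": "1", "unknown": "0",
                "excluded": "3"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (unresolved parent, cycle, ...)."""


class VcfFormatError(ValueError):
    """Malformed or unsupported VCF content."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    Founders have both parent ids absent; non-founders have both present.
    ``affection='excluded'`` marks subjects removed from segregation
    analysis (distinct from phenotype-unknown).
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    affection: str = "unknown"
    generation_label: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"invalid sex {self.sex!r} for {self.id}")
        if self.affection not in AFFECTIONS:
            raise ValueError(f"invalid affection {self.affection!r} for {self.id}")
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.id!r} has exactly one parent recorded; "
                "founders must have none, non-founders both"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


@dataclass
class Pedigree:
    """An ordered collection of individuals forming one family.

    Validated on construction: parent references resolve, parent sexes are
    consistent (father male, mother female, unless unknown), the parentage
    graph is acyclic and at least one founder exists.
    """

    individuals: list[Individual]
    family_id: str = "FAM"

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate individual id(s): {dup}")
        self._index = {ind.id: ind for ind in self.individuals}
        if not self.individuals:
            raise PedigreeError("empty pedigree")
        for ind in self.individuals:
            for role, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
                if pid is None:
                    continue
                if pid == ind.id:
                    raise PedigreeError(
                        f"individual {ind.id!r} lists itself as {role}"
                    )
                parent = self._index.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"individual {ind.id!r} references unknown {role} {pid!r}"
                    )
                want = "male" if role == "father" else "female"
                if parent.sex not in (want, "unknown"):
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.id!r} has sex {parent.sex!r}"
                    )
        cycle = self._find_cycle()
        if cycle:
            raise PedigreeError(
                "pedigree contains an ancestry cycle: " + " -> ".join(cycle)
            )
        if not any(ind.is_founder for ind in self.individuals):
            raise PedigreeError("pedigree has no founder")

    def _find_cycle(self) -> list[str] | None:
        # iterative DFS over child -> parent edges; grey set spots back-edges
        WHITE, GREY, BLACK = 0, 1, 2
        color = {i: WHITE for i in self._index}
        for start in self._index:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            path = [start]
            color[start] = GREY
            while stack:
                node, pi = stack[-1]
                parents = [p for p in (self._index[node].father_id,
                                       self._index[node].mother_id) if p]
                if pi < len(parents):
                    stack[-1] = (node, pi + 1)
                    nxt = parents[pi]
                    if color[nxt] == GREY:
                        return path[path.index(nxt):] + [nxt]
                    if color[nxt] == WHITE:
                        color[nxt] = GREY
                        stack.append((nxt, 0))
                        path.append(nxt)
                else:
                    color[node] = BLACK
                    stack.pop()
                    path.pop()
        return None

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._index

    def __getitem__(self, sample_id: str) -> Individual:
        return self._index[sample_id]

    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    def members(self, affection: str | None = None) -> list[Individual]:
        if affection is None:
            return list(self.individuals)
        return [i for i in self.individuals if i.affection == affection]

    def ids(self) -> list[str]:
        return [i.id for i in self.individuals]


@dataclass(frozen=True)
class PredictionScores:
    """In-silico deleteriousness annotations for one variant.

    ``sift`` in [0, 1] (low = damaging), ``polyphen`` in [0, 1] (high =
    damaging), ``cadd_phred`` >= 0, ``gerp`` unbounded conservation score,
    ``mutation_taster`` in {'disease_causing', 'polymorphism'}.  Absent
    scores are ``None``.
    """

    sift: float | None = None
    polyphen: float | None = None
    cadd_phred: float | None = None
    gerp: float | None = None
    mutation_taster: str | None = None

    def __post_init__(self) -> None:
        if self.sift is not None and not 0.0 <= self.sift <= 1.0:
            raise ValueError(f"SIFT score {self.sift} outside [0,1]")
        if self.polyphen is not None and not 0.0 <= self.polyphen <= 1.0:
            raise ValueError(f"PolyPhen score {self.polyphen} outside [0,1]")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"CADD phred {self.cadd_phred} negative")
        if self.mutation_taster is not None and self.mutation_taster not in (
            "disease_causing", "polymorphism"
        ):
            raise ValueError(f"bad MutationTaster call {self.mutation_taster!r}")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant with annotations."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    rsid: str | None = None
    gene: str | None = None
    consequence: str | None = None
    predictions: PredictionScores = field(default_factory=PredictionScores)
    population_maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position {self.pos} must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt ({self.ref_allele!r}) at "
                             f"{self.chrom}:{self.pos}")
        if self.population_maf is not None and not 0 <= self.population_maf <= 1:
            raise ValueError(f"population MAF {self.population_maf} outside [0,1]")


class GenotypeMatrix:
    """Variants x samples alt-allele dosage matrix.

    ``genotypes[i, j]`` is the dosage (0/1/2) of variant ``i`` in sample
    ``j``, or ``MISSING`` (-1).
    """

    def __init__(self, variants: Sequence[VariantRecord],
                 sample_ids: Sequence[str], genotypes: np.ndarray) -> None:
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.shape != (len(variants), len(sample_ids)):
            raise ValueError(
                f"genotype matrix shape {genotypes.shape} != "
                f"({len(variants)}, {len(sample_ids)})"
            )
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        bad = ~np.isin(genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0/1/2 or MISSING")
        self.variants = list(variants)
        self.sample_ids = list(sample_ids)
        self.genotypes = genotypes
        self._col = {s: j for j, s in enumerate(self.sample_ids)}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        return self._col[sample_id]

    def dosages(self, sample_id: str) -> np.ndarray:
        """All dosages for one sample (length n_variants)."""
        return self.genotypes[:, self._col[sample_id]]

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        cols = [self._col[s] for s in sample_ids]
        return GenotypeMatrix(self.variants, list(sample_ids),
                              self.genotypes[:, cols])

    def sorted_by_position(self) -> "GenotypeMatrix":
        """Deterministic (chrom, pos, alt) ordering of variants."""
        def key(i: int):
            v = self.variants[i]
            c = v.chrom.removeprefix("chr")
            return (not c.isdigit(), int(c) if c.isdigit() else 0, c,
                    v.pos, v.alt_allele)
        order = sorted(range(self.n_variants), key=key)
        return GenotypeMatrix([self.variants[i] for i in order],
                              self.sample_ids, self.genotypes[order, :])


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_ped(path: str | Path) -> Pedigree:
    """Read a PLINK-style 6-column PED file into a validated :class:`Pedigree`.

    Raises :class:`PedigreeError` naming the offending individual on
    unresolved parent references or ancestry cycles.
    """
    path = Path(path)
    rows: list[tuple[str, ...]] = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise PedigreeError(f"{path}:{ln}: expected >=6 columns, got {len(parts)}")
        rows.append(tuple(parts[:6]))
    if not rows:
        raise PedigreeError(f"{path}: no pedigree rows")
    family_id = rows[0][0]
    individuals = []
    for fam, iid, fid, mid, sex, aff in rows:
        individuals.append(Individual(
            id=iid,
            father_id=None if fid in ("0", "") else fid,
            mother_id=None if mid in ("0", "") else mid,
            sex=_SEX_FROM_CODE.get(sex, "unknown"),
            affection=_AFF_FROM_CODE.get(aff, "unknown"),
        ))
    return Pedigree(individuals, family_id=family_id)


def write_ped(pedigree: Pedigree, path: str | Path) -> None:
    """Write a pedigree back to the 6-column PED dialect of :func:`read_ped`."""
    lines = []
    for ind in pedigree.individuals:
        lines.append("\t".join([
            pedigree.family_id, ind.id,
            ind.father_id or "0", ind.mother_id or "0",
            _SEX_TO_CODE[ind.sex], _AFF_TO_CODE[ind.affection],
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

#: Default mapping from PredictionScores / VariantRecord fields to INFO keys.
DEFAULT_ANNOTATION_FIELDS: dict[str, str] = {
    "sift": "SIFT",
    "polyphen": "POLYPHEN2",
    "cadd_phred": "CADD",
    "gerp": "GERP",
    "mutation_taster": "MUTATIONTASTER",
    "population_maf": "MAF",
    "gene": "GENE",
    "consequence": "CSQ",
}

_MT_FROM_INFO = {"disease_causing": "disease_causing", "D": "disease_causing",
                 "polymorphism": "polymorphism", "P": "polymorphism",
                 "N": "polymorphism", "A": "disease_causing"}


def read_vcf(path: str | Path,
             annotation_field_map: Mapping[str, str] | None = None,
             split_multiallelic: bool = False) -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    GT fields map to alt dosage 0/1/2 with ``./.`` as missing; phased
    separators are accepted but phase is ignored.  Prediction scores and
    population MAF are pulled from INFO via ``annotation_field_map``
    (field name -> INFO key; see :data:`DEFAULT_ANNOTATION_FIELDS`).

    Multiallelic records are rejected by default; ``split_multiallelic``
    splits them naively, counting each alt separately with other alts
    treated as ref.
    """
    from cyvcf2 import VCF  # deferred: import cost and optional at runtime

    fmap = dict(DEFAULT_ANNOTATION_FIELDS)
    if annotation_field_map:
        fmap.update(annotation_field_map)

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        alts = rec.ALT
        if len(alts) == 0:
            continue
        if len(alts) > 1 and not split_multiallelic:
            raise VcfFormatError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={','.join(alts)}); pass split_multiallelic=True to split"
            )
        gt_types = rec.gt_types  # gts012: 0/1/2 dosage, 3 = unknown
        dosage = np.where(gt_types == 3, MISSING, gt_types).astype(np.int8)

        def info_get(field_name: str):
            key = fmap.get(field_name)
            return rec.INFO.get(key) if key else None

        mt_raw = info_get("mutation_taster")
        mt = _MT_FROM_INFO.get(str(mt_raw)) if mt_raw is not None else None
        if mt_raw is not None and mt is None:
            warnings.warn(f"unrecognised MutationTaster value {mt_raw!r} at "
                          f"{rec.CHROM}:{rec.POS}; treating as absent")
        try:
            scores = PredictionScores(
                sift=_maybe_float(info_get("sift")),
                polyphen=_maybe_float(info_get("polyphen")),
                cadd_phred=_maybe_float(info_get("cadd_phred")),
                gerp=_maybe_float(info_get("gerp")),
                mutation_taster=mt,
            )
        except ValueError as exc:
            raise VcfFormatError(f"{rec.CHROM}:{rec.POS}: {exc}") from exc
        gene = info_get("gene")
        csq = info_get("consequence")
        pmaf = _maybe_float(info_get("population_maf"))
        for ai, alt in enumerate(alts):
            variants.append(VariantRecord(
                chrom=rec.CHROM, pos=rec.POS,
                ref_allele=rec.REF, alt_allele=alt,
                rsid=rec.ID if rec.ID not in (None, ".") else None,
                gene=str(gene) if gene is not None else None,
                consequence=str(csq) if csq is not None else None,
                predictions=scores, population_maf=pmaf,
            ))
            if len(alts) == 1:
                rows.append(dosage)
            else:
                # naive split: count copies of this alt from the raw GT
                rows.append(_alt_dosage_from_genotypes(rec.genotypes, ai + 1))
    vcf.close()
    geno = (np.vstack(rows) if rows
            else np.empty((0, len(sample_ids)), dtype=np.int8))
    return GenotypeMatrix(variants, sample_ids, geno)


def _alt_dosage_from_genotypes(genotypes, allele_index: int) -> np.ndarray:
    out = np.zeros(len(genotypes), dtype=np.int8)
    for j, g in enumerate(genotypes):
        alleles = g[:-1]  # last element is the phased flag
        if any(a < 0 for a in alleles):
            out[j] = MISSING
        else:
            out[j] = sum(1 for a in alleles if a == allele_index)
    return out


def _maybe_float(x) -> float | None:
    if x is None:
        return None
    return float(x)


_MT_TO_INFO = {"disease_causing": "disease_causing",
               "polymorphism": "polymorphism"}

_VCF_INFO_HEADER = [
    ('SIFT', 'Float', 'SIFT score (low = damaging)'),
    ('POLYPHEN2', 'Float', 'PolyPhen-2 probability (high = damaging)'),
    ('CADD', 'Float', 'CADD phred-scaled score'),
    ('GERP', 'Float', 'GERP++ conservation score'),
    ('MUTATIONTASTER', 'String', 'MutationTaster call'),
    ('MAF', 'Float', 'Population minor allele frequency'),
    ('GENE', 'String', 'Gene symbol'),
    ('CSQ', 'String', 'Consequence'),
]


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as an unphased VCF 4.2 text file."""
    lines = ["##fileformat=VCFv4.2", "##source=famseg"]
    for chrom in dict.fromkeys(v.chrom for v in matrix.variants):
        lines.append(f"##contig=<ID={chrom}>")
    for key, typ, desc in _VCF_INFO_HEADER:
        lines.append(f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids))
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for i, v in enumerate(matrix.variants):
        info_parts = []
        p = v.predictions
        for val, key in ((p.sift, "SIFT"), (p.polyphen, "POLYPHEN2"),
                         (p.cadd_phred, "CADD"), (p.gerp, "GERP")):
            if val is not None:
                info_parts.append(f"{key}={val:g}")
        if p.mutation_taster is not None:
            info_parts.append(f"MUTATIONTASTER={_MT_TO_INFO[p.mutation_taster]}")
        if v.population_maf is not None:
            info_parts.append(f"MAF={v.population_maf:g}")
        if v.gene is not None:
            info_parts.append(f"GENE={v.gene}")
        if v.consequence is not None:
            info_parts.append(f"CSQ={v.consequence}")
        info = ";".join(info_parts) if info_parts else "."
        gts = "\t".join(gt_str[int(d)] for d in matrix.genotypes[i])
        lines.append(f"{v.chrom}\t{v.pos}\t{v.rsid or '.'}\t{v.ref_allele}\t"
                     f"{v.alt_allele}\t.\tPASS\t{info}\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Gene lists & phenotypes
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> set[str]:
    """Read a known-gene list, one symbol per line (# comments allowed)."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if sym and not sym.startswith("#"):
            genes.add(sym)
    return genes


PHENOTYPE_COLUMNS = ("fev1_pct", "fvc_pct", "mef25_pct", "mef75_pct",
                     "pefr_pct", "feno_ppb", "exacerbation_freq",
                     "odor_score_pea", "age_months")
GENOTYPE_GROUPS = ("GG", "GC", "CC")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype CSV: one row per subject x follow-up.

    Requires ``subject_id`` and ``followup_index``; validates genotype
    groups against {GG, GC, CC} and that present phenotype values are
    finite.
    """
    df = pd.read_csv(path)
    for col in ("subject_id", "followup_index"):
        if col not in df.columns:
            raise ValueError(f"phenotype table missing required column {col!r}")
    if (df["followup_index"] < 0).any():
        raise ValueError("followup_index must be >= 0")
    if df.duplicated(subset=["subject_id", "followup_index"]).any():
        raise ValueError("duplicate (subject_id, followup_index) rows")
    if "genotype_group" in df.columns:
        bad = set(df["genotype_group"].dropna()) - set(GENOTYPE_GROUPS)
        if bad:
            raise ValueError(f"unknown genotype group(s): {sorted(bad)}")
    numeric = [c for c in df.columns
               if c in PHENOTYPE_COLUMNS or c in ("age", "height")]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        if np.isinf(vals.dropna()).any():
            raise ValueError(f"non-finite values in column {col!r}")
        df[col] = vals
    return df


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One impossible parent->child transmission."""

    variant_index: int
    child: str
    reason: str


def _duo_possible(parent: int, child: int) -> bool:
    # autosomal: a homozygous parent must transmit its allele
    if parent == 0:
        return child <= 1
    if parent == 2:
        return child >= 1
    return True


def _trio_possible(father: int, mother: int, child: int) -> bool:
    paternal = {0: (0,), 1: (0, 1), 2: (1,)}[father]
    maternal = {0: (0,), 1: (0, 1), 2: (1,)}[mother]
    return any(p + m == child for p in paternal for m in maternal)


def validate_mendelian(pedigree: Pedigree, matrix: GenotypeMatrix
                       ) -> list[Violation]:
    """Report every (variant, child) whose dosage is impossible given the
    genotyped parents, treating all variants as autosomal.

    Missing genotypes are never flagged; with a single genotyped parent
    only the homozygous-parent constraints apply.  An empty list means the
    data are Mendelian-consistent.
    """
    cols = {s: j for j, s in enumerate(matrix.sample_ids)}
    violations: list[Violation] = []
    trios = []
    for ind in pedigree.individuals:
        if ind.is_founder or ind.id not in cols:
            continue
        fj = cols.get(ind.father_id)
        mj = cols.get(ind.mother_id)
        if fj is None and mj is None:
            continue
        trios.append((ind.id, cols[ind.id], fj, mj))
    G = matrix.genotypes
    for child_id, cj, fj, mj in trios:
        child = G[:, cj]
        father = G[:, fj] if fj is not None else None
        mother = G[:, mj] if mj is not None else None
        for i in np.nonzero(child != MISSING)[0]:
            c = int(child[i])
            f = int(father[i]) if father is not None else MISSING
            m = int(mother[i]) if mother is not None else MISSING
            if f != MISSING and m != MISSING:
                if not _trio_possible(f, m, c):
                    violations.append(Violation(
                        int(i), child_id,
                        f"child dosage {c} impossible for parents {f},{m}"))
            elif f != MISSING:
                if not _duo_possible(f, c):
                    violations.append(Violation(
                        int(i), child_id,
                        f"child dosage {c} impossible for father dosage {f}"))
            elif m != MISSING:
                if not _duo_possible(m, c):
                    violations.append(Violation(
                        int(i), child_id,
                        f"child dosage {c} impossible for mother dosage {m}"))
    return violations
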