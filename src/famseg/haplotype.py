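"""Pedigree haplotype analysis.

Three pieces:

* :func:`mendelian_phase` — rule-based phasing within a pedigree.  A
  genotype is phased whenever transmission is forced: homozygotes are
  trivially phased, and a heterozygous child with a homozygous genotyped
  parent has the allele from that parent determined.  Triple-heterozygote
  trios stay unresolved.  This deliberately replaces population-coalescent
  phasing with exact Mendelian logic, which resolves most genotypes inside
  a deep pedigree and is exactly testable.
* :func:`shared_risk_haplotype` — greedy bidirectional extension from a
  seed variant of the maximal interval over which all affected members can
  carry the risk allele on one consistent haplotype (identity-by-descent
  style co-segregation of a risk haplotype).
* :func:`em_haplotype_freqs` — maximum-likelihood two-locus haplotype
  frequencies by EM over the double-heterozygote ambiguity, with the
  derived linkage-disequilibrium measures D, D' and r².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from famseg.pedio import (MISSING, GenotypeMatrix, Pedigree,
                          _trio_possible, _duo_possible)

__all__ = [
    "PhaseAssignment",
    "PhaseResult",
    "SharedInterval",
    "LDStats",
    "mendelian_phase",
    "shared_risk_haplotype",
    "em_haplotype_freqs",
]

# allele codes in phase arrays
REF, ALT, UNKNOWN = 0, 1, -1
_ALLELE_NAME = {REF: "ref", ALT: "alt", UNKNOWN: "unknown"}


@dataclass(frozen=True)
class PhaseAssignment:
    """Phase call for one (sample, variant): which allele sits on the
    paternally vs maternally inherited chromosome."""

    sample_id: str
    variant_index: int
    paternal_allele: str  # ref | alt | unknown
    maternal_allele: str
    resolved: bool


@dataclass
class PhaseResult:
    """Dense phase arrays for a pedigree.

    ``paternal[i, j]`` / ``maternal[i, j]`` hold the allele (0=ref, 1=alt,
    -1=unknown) on the paternally / maternally inherited chromosome of
    sample ``j`` at variant ``i``.  ``skipped`` lists (variant_index,
    sample_id) pairs dropped for Mendelian inconsistency.
    """

    sample_ids: list[str]
    paternal: np.ndarray
    maternal: np.ndarray
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def is_resolved(self, variant_index: int, sample_id: str) -> bool:
        j = self.sample_ids.index(sample_id)
        return (self.paternal[variant_index, j] != UNKNOWN
                and self.maternal[variant_index, j] != UNKNOWN)

    def assignments(self) -> list[PhaseAssignment]:
        out = []
        n_var = self.paternal.shape[0]
        for j, sid in enumerate(self.sample_ids):
            for i in range(n_var):
                p, m = int(self.paternal[i, j]), int(self.maternal[i, j])
                out.append(PhaseAssignment(
                    sample_id=sid, variant_index=i,
                    paternal_allele=_ALLELE_NAME[p],
                    maternal_allele=_ALLELE_NAME[m],
                    resolved=(p != UNKNOWN and m != UNKNOWN)))
        return out


def mendelian_phase(pedigree: Pedigree, matrix: GenotypeMatrix) -> PhaseResult:
    """Phase a pedigree's genotypes by forced Mendelian transmission.

    For each individual and autosomal biallelic variant:

    * dosage 0 or 2 → both alleles known;
    * heterozygote with a genotyped homozygous parent → the allele
      received from that parent is forced, the other follows;
    * otherwise unresolved.

    Mendelian-inconsistent (variant, child) combinations are skipped and
    reported in ``PhaseResult.skipped``; no assignment ever contradicts the
    observed dosage.
    """
    cols = {s: j for j, s in enumerate(matrix.sample_ids)}
    n_var, n_samp = matrix.n_variants, matrix.n_samples
    pat = np.full((n_var, n_samp), UNKNOWN, dtype=np.int8)
    mat = np.full((n_var, n_samp), UNKNOWN, dtype=np.int8)
    skipped: list[tuple[int, str]] = []
    G = matrix.genotypes

    for sid, j in cols.items():
        ind = pedigree[sid] if sid in pedigree else None
        fj = cols.get(ind.father_id) if ind is not None and ind.father_id else None
        mj = cols.get(ind.mother_id) if ind is not None and ind.mother_id else None
        for i in range(n_var):
            c = int(G[i, j])
            if c == MISSING:
                continue
            f = int(G[i, fj]) if fj is not None else MISSING
            m = int(G[i, mj]) if mj is not None else MISSING
            # consistency gate first
            ok = True
            if f != MISSING and m != MISSING:
                ok = _trio_possible(f, m, c)
            elif f != MISSING:
                ok = _duo_possible(f, c)
            elif m != MISSING:
                ok = _duo_possible(m, c)
            if not ok:
                skipped.append((i, sid))
                continue
            if c == 0:
                pat[i, j], mat[i, j] = REF, REF
            elif c == 2:
                pat[i, j], mat[i, j] = ALT, ALT
            else:  # heterozygote: a homozygous parent forces its side
                if f in (0, 2):
                    pat[i, j] = REF if f == 0 else ALT
                    mat[i, j] = ALT - pat[i, j] + REF  # the complementary allele
                elif m in (0, 2):
                    mat[i, j] = REF if m == 0 else ALT
                    pat[i, j] = ALT - mat[i, j] + REF
                # both parents het or unknown: unresolved
    return PhaseResult(sample_ids=list(matrix.sample_ids),
                       paternal=pat, maternal=mat, skipped=skipped)


@dataclass
class SharedInterval:
    """Maximal variant-index interval over which all affected can share
    the risk haplotype (indices inclusive, into the ordered variant list)."""

    chrom: str
    start_index: int
    end_index: int
    carrier_side_per_affected: dict[str, str]  # paternal | maternal | either

    @property
    def n_variants(self) -> int:
        return self.end_index - self.start_index + 1


def _allele_code(risk_allele: str) -> int:
    if risk_allele in ("alt", "ALT", "1"):
        return ALT
    if risk_allele in ("ref", "REF", "0"):
        return REF
    raise ValueError(f"risk_allele must be 'ref' or 'alt', got {risk_allele!r}")


def _carries(dosage: int, allele: int) -> bool:
    """Does a genotype include at least one copy of ``allele``?"""
    if dosage == MISSING:
        return True  # unknown: compatible
    return dosage >= 1 if allele == ALT else dosage <= 1


def shared_risk_haplotype(phased: PhaseResult, matrix: GenotypeMatrix,
                          affected_ids: Sequence[str],
                          seed_variant_index: int,
                          risk_allele: str = "alt",
                          mode: Literal["permissive", "strict"] = "permissive",
                          ) -> SharedInterval:
    """Greedy bidirectional extension of the haplotype interval shared by
    all affected around a seed variant.

    For each affected, the set of chromosome sides (paternal/maternal) that
    could carry the risk haplotype is tracked.  At each neighbouring
    variant the interval extends while some allele exists that every
    affected can carry on one of its still-compatible sides — in
    ``permissive`` mode an unresolved phase counts as compatible with
    either allele (subject to the observed dosage); in ``strict`` mode only
    resolved phases extend.  The returned interval is maximal under this
    rule and the side sets surviving the scan are reported.

    Raises ``ValueError`` naming the sample if any affected lacks the risk
    allele at the seed.
    """
    risk = _allele_code(risk_allele)
    n_var = matrix.n_variants
    if not 0 <= seed_variant_index < n_var:
        raise IndexError("seed variant index out of range")
    cols = {s: j for j, s in enumerate(matrix.sample_ids)}
    for sid in affected_ids:
        d = int(matrix.genotypes[seed_variant_index, cols[sid]])
        if d != MISSING and not _carries(d, risk):
            raise ValueError(
                f"affected sample {sid!r} does not carry the risk allele "
                f"at the seed variant")

    def side_alleles(i: int, sid: str) -> dict[str, int]:
        j = cols[sid]
        return {"paternal": int(phased.paternal[i, j]),
                "maternal": int(phased.maternal[i, j])}

    def compatible_sides(i: int, sid: str, allele: int,
                         current: set[str]) -> set[str]:
        """Sides in ``current`` on which sample ``sid`` could carry
        ``allele`` at variant ``i``."""
        d = int(matrix.genotypes[i, cols[sid]])
        alleles = side_alleles(i, sid)
        out = set()
        for side in current:
            a = alleles[side]
            if a == allele:
                out.add(side)
            elif a == UNKNOWN:
                if mode == "strict":
                    continue
                if _carries(d, allele):
                    out.add(side)
        return out

    # initial side sets at the seed
    sides: dict[str, set[str]] = {}
    for sid in affected_ids:
        s = compatible_sides(seed_variant_index, sid, risk,
                             {"paternal", "maternal"})
        if not s:
            raise ValueError(
                f"affected sample {sid!r} cannot carry the risk allele on "
                f"any haplotype at the seed variant")
        sides[sid] = s

    def try_extend(i: int, sides: dict[str, set[str]]
                   ) -> dict[str, set[str]] | None:
        best: dict[str, set[str]] | None = None
        for allele in (ALT, REF):
            cand = {sid: compatible_sides(i, sid, allele, sides[sid])
                    for sid in sides}
            if all(cand.values()):
                if best is None or (sum(map(len, cand.values()))
                                    > sum(map(len, best.values()))):
                    best = cand
        return best

    start = end = seed_variant_index
    chrom = matrix.variants[seed_variant_index].chrom
    # extend right
    i = seed_variant_index + 1
    while i < n_var and matrix.variants[i].chrom == chrom:
        nxt = try_extend(i, sides)
        if nxt is None:
            break
        sides, end, i = nxt, i, i + 1
    # extend left
    i = seed_variant_index - 1
    while i >= 0 and matrix.variants[i].chrom == chrom:
        nxt = try_extend(i, sides)
        if nxt is None:
            break
        sides, start, i = nxt, i, i - 1

    side_label = {sid: ("either" if len(s) == 2 else next(iter(s)))
                  for sid, s in sides.items()}
    return SharedInterval(chrom=chrom, start_index=start, end_index=end,
                          carrier_side_per_affected=side_label)


# ---------------------------------------------------------------------------
# Two-locus EM haplotype frequencies and LD
# ---------------------------------------------------------------------------

@dataclass
class LDStats:
    """Two-locus haplotype frequencies and LD summary.

    Haplotypes are labelled by alt-allele content: ``f_AB`` carries alt at
    both loci, ``f_Ab`` alt/ref, ``f_aB`` ref/alt, ``f_ab`` ref/ref, so
    ``p_A``/``p_B`` are the alt frequencies and D = f_AB - p_A p_B.
    """

    p_A: float
    p_B: float
    hap_freqs: tuple[float, float, float, float]  # (f_AB, f_Ab, f_aB, f_ab)
    D: float
    D_prime: float
    r2: float
    n_iterations: int
    loglik: float
    degenerate: bool = False


def _two_locus_loglik(freqs: np.ndarray, counts: dict) -> float:
    """Multinomial log-likelihood of the nine two-locus genotype classes."""
    f_AB, f_Ab, f_aB, f_ab = freqs
    probs = {
        (2, 2): f_AB ** 2,
        (2, 1): 2 * f_AB * f_Ab,
        (2, 0): f_Ab ** 2,
        (1, 2): 2 * f_AB * f_aB,
        (1, 1): 2 * f_AB * f_ab + 2 * f_Ab * f_aB,
        (1, 0): 2 * f_Ab * f_ab,
        (0, 2): f_aB ** 2,
        (0, 1): 2 * f_aB * f_ab,
        (0, 0): f_ab ** 2,
    }
    ll = 0.0
    for g, n in counts.items():
        if n == 0:
            continue
        p = probs[g]
        if p <= 0:
            return -np.inf
        ll += n * np.log(p)
    return ll


def em_haplotype_freqs(two_locus_genotypes: np.ndarray | Sequence[Sequence[int]],
                       tol: float = 1e-10, max_iter: int = 1000) -> LDStats:
    """MLE two-locus haplotype frequencies by EM, plus D, D' and r².

    ``two_locus_genotypes`` is an (n, 2) array of alt dosages for n
    unrelated samples; rows with a missing dosage are dropped pairwise.
    Only double heterozygotes are phase-ambiguous; the EM starts at
    linkage equilibrium and iterates until the largest haplotype-frequency
    change is below ``tol``.  A monomorphic locus makes LD undefined:
    D = 0 is returned with ``degenerate=True``.
    """
    g = np.asarray(two_locus_genotypes, dtype=float)
    if g.ndim != 2 or g.shape[1] != 2:
        raise ValueError("expected an (n, 2) genotype array")
    keep = ~np.any((g == MISSING) | np.isnan(g), axis=1)
    g = g[keep].astype(int)
    n = len(g)
    if n < 2:
        raise ValueError("need at least 2 samples with complete genotypes")

    p_A = g[:, 0].mean() / 2.0
    p_B = g[:, 1].mean() / 2.0
    counts: dict[tuple[int, int], int] = {}
    for ga, gb in g:
        counts[(int(ga), int(gb))] = counts.get((int(ga), int(gb)), 0) + 1

    if p_A in (0.0, 1.0) or p_B in (0.0, 1.0):
        f = (p_A * p_B, p_A * (1 - p_B), (1 - p_A) * p_B,
             (1 - p_A) * (1 - p_B))
        return LDStats(p_A=p_A, p_B=p_B, hap_freqs=f, D=0.0, D_prime=0.0,
                       r2=0.0, n_iterations=0,
                       loglik=_two_locus_loglik(np.array(f), counts),
                       degenerate=True)

    # unambiguous gamete contributions; only (1,1) is latent
    base = np.zeros(4)  # AB, Ab, aB, ab
    n_dh = counts.get((1, 1), 0)
    for (ga, gb), cnt in counts.items():
        if (ga, gb) == (1, 1):
            continue
        # at most one locus het: the two gametes are determined up to
        # labelling, so pairing alt-first at each locus enumerates them
        a_hap = {0: (0, 0), 1: (1, 0), 2: (1, 1)}[ga]
        b_hap = {0: (0, 0), 1: (1, 0), 2: (1, 1)}[gb]
        for k in (0, 1):
            a, b = a_hap[k], b_hap[k]
            base[_hap_index(a, b)] += cnt
    freqs = np.array([p_A * p_B, p_A * (1 - p_B),
                      (1 - p_A) * p_B, (1 - p_A) * (1 - p_B)])
    total_gametes = 2.0 * n
    ll_prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        f_AB, f_Ab, f_aB, f_ab = freqs
        denom = f_AB * f_ab + f_Ab * f_aB
        p_coupling = (f_AB * f_ab / denom) if denom > 0 else 0.5
        expected = base.copy()
        expected[0] += n_dh * p_coupling        # AB
        expected[3] += n_dh * p_coupling        # ab
        expected[1] += n_dh * (1 - p_coupling)  # Ab
        expected[2] += n_dh * (1 - p_coupling)  # aB
        new = expected / total_gametes
        ll = _two_locus_loglik(new, counts)
        assert ll >= ll_prev - 1e-9, "EM log-likelihood decreased"
        delta = np.max(np.abs(new - freqs))
        freqs, ll_prev = new, ll
        if delta < tol:
            break

    f_AB, f_Ab, f_aB, f_ab = freqs
    p_A_hat = f_AB + f_Ab
    p_B_hat = f_AB + f_aB
    D = f_AB - p_A_hat * p_B_hat
    if D >= 0:
        d_max = min(p_A_hat * (1 - p_B_hat), (1 - p_A_hat) * p_B_hat)
    else:
        d_max = min(p_A_hat * p_B_hat, (1 - p_A_hat) * (1 - p_B_hat))
    D_prime = abs(D) / d_max if d_max > 0 else 0.0
    denom_r2 = p_A_hat * (1 - p_A_hat) * p_B_hat * (1 - p_B_hat)
    r2 = D * D / denom_r2 if denom_r2 > 0 else 0.0
    return LDStats(p_A=float(p_A_hat), p_B=float(p_B_hat),
                   hap_freqs=tuple(float(x) for x in freqs),
                   D=float(D), D_prime=float(min(D_prime, 1.0)),
                   r2=float(min(r2, 1.0)), n_iterations=it,
                   loglik=float(ll_prev))


def _hap_index(a: int, b: int) -> int:
    # (alt?, alt?) -> index into (AB, Ab, aB, ab)
    return {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(a, b)]
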