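import numpy as np
import pytest

from famseg.pedio import (GenotypeMatrix, Individual, Pedigree,
                          PredictionScores, VariantRecord)


def make_variants(n, chrom="1", start=1000, spacing=1000):
    bases = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    out = []
    for i in range(n):
        ref, alt = bases[i % 4]
        out.append(VariantRecord(chrom=chrom, pos=start + i * spacing,
                                 ref_allele=ref, alt_allele=alt,
                                 rsid=f"rs{i}", gene=f"G{i}",
                                 predictions=PredictionScores()))
    return out


def make_matrix(genotypes, sample_ids=None, **variant_kwargs):
    """GenotypeMatrix from a (n_variants, n_samples) dosage array."""
    g = np.asarray(genotypes, dtype=np.int8)
    if g.ndim == 1:
        g = g.reshape(1, -1)
    if sample_ids is None:
        sample_ids = [f"S{j}" for j in range(g.shape[1])]
    return GenotypeMatrix(make_variants(g.shape[0], **variant_kwargs),
                          sample_ids, g)


@pytest.fixture
def trio_pedigree():
    return Pedigree([
        Individual(id="dad", sex="male", affection="unaffected"),
        Individual(id="mom", sex="female", affection="unaffected"),
        Individual(id="kid", father_id="dad", mother_id="mom",
                   sex="male", affection="affected"),
    ], family_id="TRIO")


def nuclear_pedigree(n_affected, n_unaffected):
    """Two founder parents plus n_affected + n_unaffected children."""
    inds = [Individual(id="F", sex="male", affection="unknown"),
            Individual(id="M", sex="female", affection="unknown")]
    for i in range(n_affected):
        inds.append(Individual(id=f"A{i}", father_id="F", mother_id="M",
                               sex="male", affection="affected"))
    for i in range(n_unaffected):
        inds.append(Individual(id=f"U{i}", father_id="F", mother_id="M",
                               sex="female", affection="unaffected"))
    return Pedigree(inds, family_id="NUC")
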