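import importlib.resources as ir
from fractions import Fraction
import math

import pytest

from sdmaf import genotype_io, read_count_table
from sdmaf.genotype_io import SexStratifiedCounts


@pytest.fixture(scope="session")
def top_snp_records():
    """Packaged gnomAD-style count-table records keyed by (SNP, population)."""
    path = ir.files("sdmaf") / "data" / "gnomad_top_snps.tsv"
    return {(r.id, r.population): r for r in read_count_table(path)}


@pytest.fixture
def toy_npr_counts():
    """Female (640, 320, 40), hemizygous male (500 ref, 500 alt)."""
    return SexStratifiedCounts(
        female=(640, 320, 40), male=(500, 500),
        male_layout=genotype_io.HEMIZYGOUS,
    )


# ---------------------------------------------------------------------------
# independent oracles (exact rational arithmetic; no package code paths)

def exact_hwe_oracle(n0, n1, n2):
    """Two-sided conditional exact HWE p-value by full enumeration with
    Fractions."""
    n = n0 + n1 + n2
    nA = 2 * n2 + n1
    nB = 2 * n0 + n1
    n_minor = min(nA, nB)
    if n_minor == 0:
        return Fraction(1)
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        a = (nA - h) // 2
        b = (nB - h) // 2
        if a < 0 or b < 0 or a + b + h != n:
            continue
        weights[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(a) * math.factorial(h) * math.factorial(b),
        )
    obs = weights[n1]
    total = sum(weights.values())
    return sum(w for w in weights.values() if w <= obs) / total


def exact_joint_oracle(female, male):
    """Two-sided joint X-chromosomal exact HWE p-value by full enumeration
    with Fractions (hemizygous males + diploid females)."""
    f0, f1, f2 = female
    m_ref, m_alt = male
    f = f0 + f1 + f2
    m = m_ref + m_alt
    nA = 2 * f2 + f1 + m_alt
    nB = 2 * f0 + f1 + m_ref
    if nA == 0 or nB == 0:
        return Fraction(1)
    weights = {}
    for mA in range(max(0, nA - 2 * f), min(m, nA) + 1):
        fem_A = nA - mA
        for h in range(fem_A % 2, min(f, fem_A) + 1, 2):
            faa = (fem_A - h) // 2
            fbb = f - faa - h
            if fbb < 0:
                continue
            weights[(mA, h)] = (
                math.comb(m, mA)
                * Fraction(math.factorial(f) * 2**h,
                           math.factorial(faa) * math.factorial(h)
                           * math.factorial(fbb))
            )
    obs = weights[(m_alt, f1)]
    total = sum(weights.values())
    return sum(w for w in weights.values() if w <= obs) / total


@pytest.fixture(scope="session")
def exact_oracles():
    return exact_hwe_oracle, exact_joint_oracle
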