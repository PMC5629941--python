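import numpy as np
import pandas as pd
import pytest

from mhcmap.catalog import (
    HLA_4DIGIT,
    SNP,
    DosageMatrix,
    Marker,
    ResidueMap,
)


@pytest.fixture
def b97_map() -> ResidueMap:
    """Residues at HLA-B position 97 for a six-allele catalogue."""
    rows = [
        ("B*44:02", "B", 97, "R"),
        ("B*07:02", "B", 97, "S"),
        ("B*57:01", "B", 97, "T"),
        ("B*51:01", "B", 97, "V"),
        ("B*27:05", "B", 97, "N"),
        ("B*47:01", "B", 97, "W"),
    ]
    return ResidueMap(
        pd.DataFrame(rows, columns=["allele", "gene", "position", "residue"])
    )


def allele_matrix(dosage_by_allele: dict[str, list[float]]) -> DosageMatrix:
    """Build a 4-digit allele DosageMatrix from per-allele dosage lists."""
    alleles = list(dosage_by_allele)
    n = len(next(iter(dosage_by_allele.values())))
    markers = [
        Marker(a, HLA_4DIGIT, f"{a.split('*')[0]}_4digit", a) for a in alleles
    ]
    dosage = np.column_stack([dosage_by_allele[a] for a in alleles])
    return DosageMatrix(
        markers=markers, samples=[f"s{i}" for i in range(n)], dosage=dosage
    )


def snp_matrix(rng: np.random.Generator, n: int, freqs) -> DosageMatrix:
    """Hard-call SNP dosages at given allele frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    dosage = rng.binomial(2, freqs, size=(n, freqs.size)).astype(float)
    markers = [Marker(f"rs{j}", SNP, f"rs{j}", "alt") for j in range(freqs.size)]
    return DosageMatrix(
        markers=markers, samples=[f"s{i}" for i in range(n)], dosage=dosage
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
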