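"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from alleleforge.fixtures import default_specs, generate_reference_db


@pytest.fixture(scope="session")
def synthetic_db():
    """Standard synthetic reference database: 3 loci x 10 alleles + partials."""
    text, db, truth = generate_reference_db(default_specs(10), seed=1)
    return text, db, truth


@pytest.fixture(scope="session")
def full_length_refs(synthetic_db):
    _, db, _ = synthetic_db
    return [a for a in db if a.is_full_length]


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)


def apply_differences(ref_seq: str, differences) -> str:
    """Rebuild the query from the reference and an emitted difference list.

    Uses only the reference coordinates of each record; independent of the
    alignment machinery.
    """
    out = []
    cursor = 1
    for d in differences:
        kind = d.dtype.value
        if kind == "SUB":
            out.append(ref_seq[cursor - 1 : d.ref_pos - 1])
            out.append(d.query_bases)
            cursor = d.ref_pos + 1
        elif kind == "INS":
            out.append(ref_seq[cursor - 1 : d.ref_pos])
            out.append(d.query_bases)
            cursor = d.ref_pos + 1
        else:  # DEL
            out.append(ref_seq[cursor - 1 : d.ref_pos - 1])
            cursor = d.ref_pos + len(d.ref_bases)
    out.append(ref_seq[cursor - 1 :])
    return "".join(out)


def levenshtein_dp(a: str, b: str) -> int:
    """Quadratic-space unit-cost global alignment score (textbook DP),
    vectorised row by row with numpy."""
    m = len(b)
    prev = np.arange(m + 1)
    for i, ca in enumerate(a, start=1):
        sub = prev[:-1] + np.fromiter((ca != cb for cb in b), dtype=int, count=m)
        up = prev[1:] + 1
        t = np.minimum(sub, up)
        # within-row insertion chains: D[j] = j + min_{k<=j}(T[k] - k)
        row = np.empty(m + 1, dtype=int)
        row[0] = i
        best = np.minimum.accumulate(np.concatenate(([i], t)) - np.arange(m + 1))
        row[1:] = np.arange(1, m + 1) + best[1:]
        prev = row
    return int(prev[-1])


CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_table(cds: str) -> str:
    """Direct table translation of complete codons, stops included as '*'."""
    return "".join(
        CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3)
    )
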