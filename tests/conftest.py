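"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately naive (quadratic scans, exhaustive
enumeration) and never share code with the implementation they check.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations

import numpy as np
import pytest

from twobrad.digestion import IUPAC, BCGI

# ---------------------------------------------------------------------------
# Naive digestion oracle

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _matches_at(seq: str, pos: int, motif: str) -> bool:
    if pos < 0 or pos + len(motif) > len(seq):
        return False
    for c, m in zip(seq[pos : pos + len(motif)], motif):
        if c == "N" or c not in IUPAC[m]:
            return False
    return True


def naive_find_sites(seq: str, enzyme=BCGI) -> list[tuple[int, str]]:
    """Quadratic sliding-window site scan over both strands."""
    motif = enzyme.recognition.upper()
    rc_motif = naive_revcomp_motif(motif)
    sites = []
    for i in range(len(seq)):
        if _matches_at(seq, i, motif):
            sites.append((i, "+"))
        if _matches_at(seq, i, rc_motif):
            sites.append((i, "-"))
    sites.sort()
    return sites


_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def naive_revcomp_motif(motif: str) -> str:
    return motif.translate(_IUPAC_COMP)[::-1]


def naive_digest(seq: str, enzyme=BCGI) -> Counter:
    """Hand-sliced tag extraction: the oracle for digest()."""
    out: Counter = Counter()
    for pos, strand in naive_find_sites(seq, enzyme):
        if strand == "+":
            s, e = pos - enzyme.flank5, pos + enzyme.motif_length + enzyme.flank3
            if s < 0 or e > len(seq):
                continue
            tag = seq[s:e]
        else:
            s, e = pos - enzyme.flank3, pos + enzyme.motif_length + enzyme.flank5
            if s < 0 or e > len(seq):
                continue
            tag = naive_revcomp(seq[s:e])
        out[min(tag, naive_revcomp(tag))] += 1
    return out


# ---------------------------------------------------------------------------
# Exhaustive Mann-Whitney permutation oracle


def mwu_enumeration_p(x, y) -> float:
    """Two-sided p by enumerating all C(m+n, m) group assignments.

    Extremeness is |U - mn/2| of the observed split (tie-free inputs only).
    """
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    m, n = len(x), len(y)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    center = m * n / 2.0
    obs = abs(u_stat(x, y) - center)
    total = extreme = 0
    for idx in combinations(range(m + n), m):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(m + n) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - center) >= obs - 1e-12:
            extreme += 1
    return extreme / total


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def small_panel():
    """4-species reference panel: genomes + marker database (session-cached)."""
    from twobrad.study import build_reference_db, reference_genome_specs

    specs = reference_genome_specs(seed=0, n_species=4)
    genomes, db = build_reference_db(specs)
    return specs, genomes, db


@pytest.fixture(scope="session")
def ten_species_panel():
    from twobrad.study import build_reference_db, reference_genome_specs

    specs = reference_genome_specs(seed=2, n_species=10)
    genomes, db = build_reference_db(specs)
    return specs, genomes, db


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
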