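"""In-silico type IIB restriction digestion.

Type IIB enzymes (BcgI and relatives) cut on both sides of their recognition
site, releasing a fragment of uniform length.  Sequencing libraries built on
such fragments ("2bRAD tags") therefore sample a genome at a reproducible,
enzyme-defined set of loci.  This module models the enzyme geometry and
extracts the fixed-length tags from arbitrary DNA.

A tag is reported in *canonical* form -- the lexicographic minimum of the
extracted sequence and its reverse complement -- because sequencing does not
preserve the strand of origin.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterator

from Bio.Seq import reverse_complement as _bio_revcomp

# IUPAC nucleotide codes -> the set of concrete bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware for motifs)."""
    if set(seq) <= set("ACGTN"):
        return _bio_revcomp(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(tag: str) -> str:
    """Strand-collapsed representative: min(tag, revcomp(tag))."""
    rc = revcomp(tag)
    return tag if tag <= rc else rc


@dataclass(frozen=True)
class EnzymeSpec:
    """Geometry of a type IIB restriction enzyme.

    Parameters
    ----------
    name : str
        Enzyme name, e.g. ``"BcgI"``.
    recognition : str
        IUPAC recognition motif, e.g. ``CGANNNNNNTGC`` for BcgI.
    flank5, flank3 : int
        Bases retained upstream/downstream of the motif (in the orientation
        in which the motif matched), so the released tag has length
        ``flank5 + len(recognition) + flank3``.
    """

    name: str
    recognition: str
    flank5: int
    flank3: int

    def __post_init__(self) -> None:
        bad = set(self.recognition.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC codes in recognition motif: {sorted(bad)}")
        if self.flank5 < 0 or self.flank3 < 0:
            raise ValueError("flank lengths must be non-negative")
        if self.tag_length <= len(self.recognition):
            raise ValueError("tag_length must exceed the recognition motif length")

    @property
    def motif_length(self) -> int:
        return len(self.recognition)

    @property
    def tag_length(self) -> int:
        return self.flank5 + len(self.recognition) + self.flank3

    def motif_regex(self) -> re.Pattern:
        return _compile_motif(self.recognition)

    def motif_regex_rc(self) -> re.Pattern:
        return _compile_motif(revcomp(self.recognition))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "recognition": self.recognition,
            "flank5": self.flank5,
            "flank3": self.flank3,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnzymeSpec":
        return cls(d["name"], d["recognition"], int(d["flank5"]), int(d["flank3"]))


def _compile_motif(motif: str) -> re.Pattern:
    # Overlapping matches via lookahead.  Ambiguity classes never include
    # sequence N, so N in the subject matches nothing, as required.
    body = "".join(c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in motif.upper())
    return re.compile(f"(?=({body}))")


#: BcgI: CGA(N6)TGC core with symmetric 10 bp flanks -> 32 bp tags.
BCGI = EnzymeSpec(name="BcgI", recognition="CGANNNNNNTGC", flank5=10, flank3=10)

#: Registry of shipped enzymes; extensible via :func:`load_registry`.
ENZYMES: dict[str, EnzymeSpec] = {"BcgI": BCGI}


def get_enzyme(name: str) -> EnzymeSpec:
    try:
        return ENZYMES[name]
    except KeyError:
        raise KeyError(f"unknown enzyme {name!r}; registered: {sorted(ENZYMES)}") from None


def load_registry(path) -> dict[str, EnzymeSpec]:
    """Load additional enzymes from a JSON file and merge into the registry."""
    with open(path) as fh:
        entries = json.load(fh)
    for d in entries:
        spec = EnzymeSpec.from_dict(d)
        ENZYMES[spec.name] = spec
    return ENZYMES


def find_sites(sequence: str, enzyme: EnzymeSpec) -> list[tuple[int, str]]:
    """All recognition-site matches on either strand.

    Returns ``(offset, strand)`` pairs in ascending offset order, where
    ``offset`` is the 0-based position of the motif window on the forward
    strand and ``strand`` is ``"+"`` when the motif matches the forward
    strand and ``"-"`` when it matches the reverse strand.  A locus matching
    both strands is reported once per strand.
    """
    seq = sequence.upper()
    sites = [(m.start(), "+") for m in enzyme.motif_regex().finditer(seq)]
    sites += [(m.start(), "-") for m in enzyme.motif_regex_rc().finditer(seq)]
    sites.sort(key=lambda s: (s[0], s[1]))
    return sites


def _extract(seq: str, offset: int, strand: str, enzyme: EnzymeSpec) -> str | None:
    """Tag at a site, in site-strand orientation; None if flanks truncated."""
    m = enzyme.motif_length
    if strand == "+":
        start, end = offset - enzyme.flank5, offset + m + enzyme.flank3
        if start < 0 or end > len(seq):
            return None
        return seq[start:end]
    start, end = offset - enzyme.flank3, offset + m + enzyme.flank5
    if start < 0 or end > len(seq):
        return None
    return revcomp(seq[start:end])


def iter_tags(sequence: str, enzyme: EnzymeSpec, circular: bool = False) -> Iterator[str]:
    """Yield canonical tags for every site with full flanks available."""
    seq = sequence.upper()
    n = len(seq)
    if circular:
        # Virtually wrap so sites spanning the origin are recovered once.
        seq = seq + seq[: enzyme.tag_length - 1]
    for offset, strand in find_sites(seq, enzyme):
        if circular and offset >= n:
            continue
        tag = _extract(seq, offset, strand, enzyme)
        if tag is not None:
            yield canonical(tag)


def digest(sequence: str, enzyme: EnzymeSpec, circular: bool = False) -> Counter:
    """Multiset of canonical tags released from a sequence.

    Sites whose flanks run off the sequence end are dropped (their tags could
    never be matched exactly by a read).  Copy number within the sequence is
    preserved in the multiset.
    """
    return Counter(iter_tags(sequence, enzyme, circular=circular))


def digest_records(records, enzyme: EnzymeSpec, circular: bool = False) -> Counter:
    """Digest a genome given as an iterable of Biopython SeqRecords.

    A genome is the union of all its records (contigs); multiplicities add.
    """
    total: Counter = Counter()
    for rec in records:
        total.update(digest(str(rec.seq), enzyme, circular=circular))
    return total
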