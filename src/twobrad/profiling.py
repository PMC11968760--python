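"""Read set -> species profile.

The profiling contract mirrors how 2bRAD data are reduced in practice:

1. QC funnel: *raw* reads -> *enzyme* reads (recognition motif present with
   full flanks) -> *clean* reads (exactly one extraction locus, no N in the
   tag, mean Phred >= 20 over the tag).
2. Each clean tag is looked up exactly (no mismatches) in the marker table.
3. Per species, S = reads assigned to its markers and t = distinct markers
   observed; the G score sqrt(S*t) (or S*t under the product form) must
   reach the threshold (default 5) for the species to be reported -- this is
   the false-positive control for sparse chance hits.
4. Relative abundance of species i = (S_i/T_i) / sum_j (S_j/T_j) over the
   species that passed, where T_i is the theoretical marker count; dividing
   by T_i converts read counts into coverage, cancelling marker-richness
   (genome size) effects.
"""

from __future__ import annotations

import gzip
import math
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .digestion import EnzymeSpec, canonical
from .markers import MarkerDatabase
from .tables import AbundanceMatrix


@dataclass
class ReadQCSummary:
    raw_reads: int = 0
    enzyme_reads: int = 0
    clean_reads: int = 0

    def __post_init__(self) -> None:
        if not self.raw_reads >= self.enzyme_reads >= self.clean_reads >= 0:
            raise ValueError("QC funnel must satisfy raw >= enzyme >= clean >= 0")


@dataclass
class SpeciesHit:
    species: str
    S: int          # reads assigned to the species' markers
    t: int          # distinct markers observed
    T: int          # theoretical marker count
    G: float
    passed: bool

    @property
    def coverage(self) -> float:
        return self.S / self.T


@dataclass
class SampleProfile:
    sample_id: str
    hits: list[SpeciesHit]
    relative_abundance: dict[str, float]
    unassigned_reads: int
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species": h.species, "S": h.S, "t": h.t, "T": h.T, "G": h.G,
                "coverage": h.coverage, "passed": h.passed,
                "relative_abundance": self.relative_abundance.get(h.species, 0.0),
            }
            for h in sorted(self.hits, key=lambda h: (-h.G, h.species))
        ]
        return pd.DataFrame(rows, columns=["species", "S", "t", "T", "G",
                                           "coverage", "passed", "relative_abundance"])


def g_score(S: int, t: int, form: str = "sqrt") -> float:
    """Per-species confidence score combining read count and marker breadth.

    ``sqrt`` (default): G = sqrt(S*t), the geometric-mean form on which the
    conventional threshold of 5 is calibrated.  ``product``: G = S*t.
    """
    if S < 0 or t < 0:
        raise ValueError("S and t must be non-negative")
    if form == "sqrt":
        return math.sqrt(S * t)
    if form == "product":
        return float(S * t)
    raise ValueError("gscore_form must be 'sqrt' or 'product'")


def _candidate_loci(read: str, enzyme: EnzymeSpec) -> list[tuple[int, str]]:
    from .digestion import find_sites

    out = []
    for off, strand in find_sites(read, enzyme):
        up = enzyme.flank5 if strand == "+" else enzyme.flank3
        down = enzyme.flank3 if strand == "+" else enzyme.flank5
        if off - up >= 0 and off + enzyme.motif_length + down <= len(read):
            out.append((off, strand))
    return out


def extract_tag_from_read(read: str, enzyme: EnzymeSpec) -> str | None:
    """Canonical tag carried by a read, or None.

    None when the read carries no full-flank recognition locus, or more than
    one (ambiguous placement).
    """
    loci = _candidate_loci(read.upper(), enzyme)
    if len(loci) != 1:
        return None
    off, strand = loci[0]
    from .digestion import _extract

    tag = _extract(read.upper(), off, strand, enzyme)
    return canonical(tag) if tag is not None else None


def _iter_fastq(path):
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        yield from FastqGeneralIterator(fh)


def profile(
    reads,
    db: MarkerDatabase,
    sample_id: str = "sample",
    threshold: float = 5.0,
    gscore_form: str = "sqrt",
    min_mean_quality: float = 20.0,
) -> tuple[SampleProfile, ReadQCSummary]:
    """Profile a read set against a marker database.

    ``reads`` is an iterable of ``(seq, qual)`` pairs (qual may be None) or
    a FASTQ path.  Returns the per-species profile and the QC funnel counts.
    """
    if not db.markers:
        raise ValueError("marker database is empty")
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        reads = ((seq, qual) for _title, seq, qual in _iter_fastq(reads))

    enzyme = db.enzyme
    raw = clean = enzymatic = unassigned = 0
    S: dict[str, int] = defaultdict(int)
    seen: dict[str, set] = defaultdict(set)

    for item in reads:
        seq, qual = item if isinstance(item, tuple) else (item, None)
        raw += 1
        seq = seq.upper()
        loci = _candidate_loci(seq, enzyme)
        if not loci:
            continue
        enzymatic += 1
        if len(loci) != 1:
            continue  # ambiguous placement
        off, strand = loci[0]
        from .digestion import _extract

        tag = _extract(seq, off, strand, enzyme)
        if tag is None or "N" in tag:
            continue
        if qual is not None:
            up = enzyme.flank5 if strand == "+" else enzyme.flank3
            start = off - up
            window = qual[start : start + enzyme.tag_length]
            mean_q = sum(ord(c) - 33 for c in window) / len(window)
            if mean_q < min_mean_quality:
                continue
        clean += 1
        tag = canonical(tag)
        sp = db.markers.get(tag)
        if sp is None:
            unassigned += 1
            continue
        S[sp] += 1
        seen[sp].add(tag)

    hits: list[SpeciesHit] = []
    for sp in sorted(S):
        g = g_score(S[sp], len(seen[sp]), gscore_form)
        hits.append(SpeciesHit(species=sp, S=S[sp], t=len(seen[sp]),
                               T=db.T[sp], G=g, passed=g >= threshold))

    passed = [h for h in hits if h.passed]
    warnings = []
    if passed:
        cov = {h.species: h.S / h.T for h in passed}
        total = sum(cov.values())
        rel = {sp: c / total for sp, c in cov.items()}
    else:
        rel = {}
        warnings.append("no species passed the G-score threshold")

    prof = SampleProfile(sample_id=sample_id, hits=hits, relative_abundance=rel,
                         unassigned_reads=unassigned, warnings=warnings)
    qc = ReadQCSummary(raw_reads=raw, enzyme_reads=enzymatic, clean_reads=clean)
    return prof, qc


def aggregate(
    profiles: list[SampleProfile],
    groups: dict[str, str],
    lineages: dict[str, dict[str, str]],
    rank: str = "species",
) -> AbundanceMatrix:
    """Merge per-sample profiles into an AbundanceMatrix at a taxonomic rank.

    Species abundances are summed within the chosen rank per sample, so row
    sums are preserved; taxa absent from a sample are filled with 0.
    """
    if rank not in ("phylum", "class", "order", "family", "genus", "species"):
        raise ValueError(f"unknown rank {rank!r}")

    rows = {}
    for p in profiles:
        agg: dict[str, float] = defaultdict(float)
        for sp, a in p.relative_abundance.items():
            if rank == "species":
                label = sp
            else:
                lin = lineages.get(sp)
                if lin is None or rank not in lin:
                    raise KeyError(f"no {rank} lineage for species {sp!r}")
                label = lin[rank]
            agg[label] += a
        rows[p.sample_id] = agg

    values = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    values = values.reindex(sorted(values.columns), axis=1)
    values.index.name = "sample"
    taxon_lineages = {}
    if rank == "species":
        taxon_lineages = {sp: lineages.get(sp, {}) for sp in values.columns}
    gs = pd.Series({p.sample_id: groups[p.sample_id] for p in profiles})
    return AbundanceMatrix(values=values, groups=gs, lineages=taxon_lineages)


def counts_frame(profiles: list[SampleProfile], passed_only: bool = True) -> pd.DataFrame:
    """Samples x species table of assigned read counts S (for alpha diversity)."""
    rows = {
        p.sample_id: {h.species: h.S for h in p.hits if h.passed or not passed_only}
        for p in profiles
    }
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    df.index.name = "sample"
    return df.reindex(sorted(df.columns), axis=1)


def qc_frame(qcs: dict[str, ReadQCSummary]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            sid: {"raw_reads": q.raw_reads, "enzyme_reads": q.enzyme_reads,
                  "clean_reads": q.clean_reads}
            for sid, q in qcs.items()
        }
    ).T
    df.index.name = "sample"
    return df
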