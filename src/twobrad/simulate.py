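"""Synthetic genomes, communities and read sets with known ground truth.

Every downstream stage of the pipeline (digestion, marker database,
profiling, statistics, classification) is exercised against data produced
here, where the true species composition is known exactly.

The read model is deliberately simple: reads are error-free by default
(``error_rate`` exists but planted substitutions simply fail the exact-match
lookup downstream), each community read embeds one enzyme tag from a member
genome, and contamination is modelled by two extra read classes -- *host*
reads carrying tags of a genome absent from the marker database, and *junk*
reads of motif-free random sequence.  Junk and host reads are what make the
quality-control funnel (raw / enzyme / clean reads) and the G-score
false-positive filter testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .digestion import EnzymeSpec, canonical, find_sites, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Recipe for one synthetic genome with a known number of enzyme sites."""

    genome_id: str
    species_label: str
    lineage: dict[str, str] = field(default_factory=dict)  # rank -> name, phylum..species
    length_bp: int = 20_000
    gc_fraction: float = 0.5
    n_planted_sites: int = 20
    seed: int = 0

    def validate(self, enzyme: EnzymeSpec) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.n_planted_sites < 0:
            raise ValueError("n_planted_sites must be non-negative")
        need = self.n_planted_sites * (enzyme.tag_length + 2)
        if self.length_bp < need:
            raise ValueError(
                f"length_bp={self.length_bp} too small for {self.n_planted_sites} "
                f"non-overlapping {enzyme.name} sites (needs >= {need} bp)"
            )


@dataclass(frozen=True)
class CommunitySpec:
    """A two-ingredient read mixture: community members plus contamination."""

    members: list[tuple[str, float]]  # (genome_id, cell proportion)
    n_reads: int
    host_fraction: float = 0.0
    junk_fraction: float = 0.0
    read_length: int = 100  # matches the ~100 bp 2bRAD library band
    error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        props = np.asarray([p for _, p in self.members], dtype=float)
        if len(props) == 0 or (props <= 0).any():
            raise ValueError("member proportions must be positive")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"member proportions must sum to 1 (got {props.sum()!r})")
        if not (0 <= self.host_fraction < 1 and 0 <= self.junk_fraction < 1):
            raise ValueError("host/junk fractions must lie in [0, 1)")
        if self.host_fraction + self.junk_fraction >= 1:
            raise ValueError("host_fraction + junk_fraction must be < 1")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _scrub_motif(arr: np.ndarray, enzyme: EnzymeSpec, rng: np.random.Generator,
                 protected: list[tuple[int, int]] | None = None) -> np.ndarray:
    """Mutate bases until no motif occurrence survives outside protected spans.

    ``protected`` spans are [start, end) windows (planted motifs) that must
    not be touched.
    """
    protected = protected or []

    def is_protected(i: int) -> bool:
        return any(s <= i < e for s, e in protected)

    for _ in range(200):
        seq = arr.tobytes().decode()
        extra = [
            (off, strand)
            for off, strand in find_sites(seq, enzyme)
            if not any(off == s and off + enzyme.motif_length == e for s, e in protected)
        ]
        if not extra:
            return arr
        for off, _strand in extra:
            span = [i for i in range(off, off + enzyme.motif_length) if not is_protected(i)]
            if not span:  # same span as a planted motif on the other strand
                continue
            i = int(rng.choice(span))
            old = arr[i]
            choices = _BASES[_BASES != old]
            arr[i] = rng.choice(choices)
    raise RuntimeError("failed to scrub recognition motif from background sequence")


def _fill_motif(enzyme: EnzymeSpec, rng: np.random.Generator) -> str:
    """A concrete motif instance that does not also match the reverse strand."""
    from .digestion import IUPAC

    for _ in range(100):
        inst = "".join(
            c if len(IUPAC[c]) == 1 else IUPAC[c][rng.integers(len(IUPAC[c]))]
            for c in enzyme.recognition.upper()
        )
        # Avoid instances matching the motif on both strands: they would be
        # double-counted by digestion and break exact site accounting.
        if not enzyme.motif_regex_rc().match(inst):
            return inst
    raise RuntimeError("could not realise a single-strand motif instance")


def generate_genome(spec: SyntheticGenomeSpec, enzyme: EnzymeSpec) -> str:
    """A random genome with *exactly* ``n_planted_sites`` enzyme sites.

    Background sequence is scrubbed of chance motif occurrences on both
    strands, and every planted site has full flank clearance from the ends,
    so digestion of the result yields exactly one tag per planted site.
    Pure function of (spec, seed).
    """
    spec.validate(enzyme)
    rng = np.random.default_rng(spec.seed)
    arr = _random_seq(rng, spec.length_bp, spec.gc_fraction)

    slot = enzyme.tag_length + 2  # non-overlap spacing guaranteed by the invariant
    margin = max(enzyme.flank5, enzyme.flank3)
    n = spec.n_planted_sites
    protected: list[tuple[int, int]] = []
    if n > 0:
        # Spaced sampling: n sorted draws, each shifted to its own slot.
        free = spec.length_bp - n * slot - 2 * margin
        if free < 0:
            raise ValueError("length_bp too small to clear flanks for all planted sites")
        offsets = np.sort(rng.integers(0, free + 1, size=n)) if free > 0 else np.zeros(n, int)
        starts = margin + offsets + np.arange(n) * slot
        for s in starts:
            inst = _fill_motif(enzyme, rng)
            arr[s : s + enzyme.motif_length] = np.frombuffer(inst.encode(), dtype="S1")
            protected.append((int(s), int(s) + enzyme.motif_length))

    arr = _scrub_motif(arr, enzyme, rng, protected)
    return arr.tobytes().decode()


def _random_read_without_motif(rng: np.random.Generator, length: int,
                               enzyme: EnzymeSpec) -> str:
    arr = _random_seq(rng, length)
    return _scrub_motif(arr, enzyme, rng).tobytes().decode()


def _embed_tag(tag: str, read_length: int, enzyme: EnzymeSpec,
               rng: np.random.Generator, error_rate: float) -> str:
    """Place a tag at a random offset/strand in a read of random filler.

    Filler is resampled until the read contains exactly one extraction locus,
    keeping per-tag read accounting exact.
    """
    tl = len(tag)
    for _ in range(50):
        oriented = tag if rng.random() < 0.5 else revcomp(tag)
        off = int(rng.integers(0, read_length - tl + 1))
        left = _random_seq(rng, off).tobytes().decode()
        right = _random_seq(rng, read_length - tl - off).tobytes().decode()
        read = left + oriented + right
        if error_rate > 0:
            arr = np.frombuffer(read.encode(), dtype="S1").copy()
            hits = rng.random(read_length) < error_rate
            for i in np.flatnonzero(hits):
                arr[i] = rng.choice(_BASES[_BASES != arr[i]])
            read = arr.tobytes().decode()
        sites = [
            (o, s) for o, s in find_sites(read, enzyme)
            if o - (enzyme.flank5 if s == "+" else enzyme.flank3) >= 0
            and o + enzyme.motif_length + (enzyme.flank3 if s == "+" else enzyme.flank5)
            <= read_length
        ]
        if error_rate > 0 or len(sites) == 1:
            return read
    raise RuntimeError("failed to embed tag without spurious motif copies")


def simulate_reads(
    community: CommunitySpec,
    genomes: dict[str, str],
    enzyme: EnzymeSpec,
    host_genome: str | None = None,
    weighting: str = "cell",
) -> list[str]:
    """Draw a 2bRAD read set for a community.

    Read classes are drawn multinomially: ``host_fraction`` of reads carry a
    tag from ``host_genome`` (a contaminant absent from any marker database),
    ``junk_fraction`` are motif-free random sequence, and the remainder come
    from member genomes.  Under the default ``weighting="cell"`` a member is
    chosen with probability proportional to (proportion x tag count), i.e.
    proportions are genome-copy (cell) proportions and every tag locus in a
    cell is an equally likely template -- this is what makes marker-count
    normalisation recover cell proportions downstream.  ``weighting="read"``
    instead picks the member genome directly proportional to its proportion.
    """
    community.validate()
    rng = np.random.default_rng(community.seed)

    tag_lists: list[list[str]] = []
    for gid, _p in community.members:
        if gid not in genomes:
            raise KeyError(f"community member {gid!r} not in genome collection")
        from .digestion import digest

        tags = list(digest(genomes[gid], enzyme).elements())
        if not tags:
            raise ValueError(f"member genome {gid!r} has no enzyme tags; "
                             "its abundance would be unrecoverable")
        tag_lists.append(tags)

    if community.host_fraction > 0:
        if host_genome is None:
            host_spec = SyntheticGenomeSpec(
                genome_id="host", species_label="host",
                length_bp=30_000, n_planted_sites=40,
                seed=int(rng.integers(2**31)),
            )
            host_genome = generate_genome(host_spec, enzyme)
        from .digestion import digest

        host_tags = list(digest(host_genome, enzyme).elements())
        if not host_tags:
            raise ValueError("host_genome has no enzyme tags")
    else:
        host_tags = []

    props = np.asarray([p for _, p in community.members], dtype=float)
    if weighting == "cell":
        w = props * np.asarray([len(t) for t in tag_lists], dtype=float)
    elif weighting == "read":
        w = props.copy()
    else:
        raise ValueError("weighting must be 'cell' or 'read'")
    w /= w.sum()

    member_p = (1.0 - community.host_fraction - community.junk_fraction) * w
    p_full = np.concatenate([member_p, [community.host_fraction, community.junk_fraction]])
    counts = rng.multinomial(community.n_reads, p_full)

    reads: list[str] = []
    for i, tags in enumerate(tag_lists):
        for _ in range(counts[i]):
            tag = tags[rng.integers(len(tags))]
            reads.append(_embed_tag(tag, community.read_length, enzyme, rng,
                                    community.error_rate))
    for _ in range(counts[-2]):
        tag = host_tags[rng.integers(len(host_tags))]
        reads.append(_embed_tag(tag, community.read_length, enzyme, rng,
                                community.error_rate))
    for _ in range(counts[-1]):
        reads.append(_random_read_without_motif(rng, community.read_length, enzyme))
    # Shuffle so read order carries no class information.
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


# ---------------------------------------------------------------------------
# On-disk formats


def write_fasta(path, records: dict[str, str]) -> None:
    """Write genomes as FASTA via Biopython."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=gid, description="") for gid, seq in records.items()]
    seqio_write(recs, str(path), "fasta")


def write_fastq(path, reads: list[str], sample_id: str = "sample",
                quality_char: str = "I") -> None:
    # Constant Phred+33 quality (I = Q40); the simulator models no quality decay.
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@{sample_id}.{i}\n{read}\n+\n{quality_char * len(read)}\n")


def write_manifest(path, specs: list[SyntheticGenomeSpec],
                   ranks: tuple[str, ...] = ("phylum", "class", "order",
                                             "family", "genus", "species")) -> None:
    """TSV manifest: genome_id, species_label, semicolon-joined lineage."""
    with open(path, "w") as fh:
        fh.write("genome_id\tspecies_label\tlineage\n")
        for s in specs:
            lineage = ";".join(s.lineage.get(r, "") for r in ranks)
            fh.write(f"{s.genome_id}\t{s.species_label}\t{lineage}\n")
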