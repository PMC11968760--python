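"""Species-specific 2bRAD marker database.

A *marker* is a canonical tag that (a) occurs exactly once within at least
one genome of its species and (b) occurs in no genome -- at any copy
number -- of any other species.  The per-species marker count ``T`` is the
theoretical number of markers, the divisor that turns assigned read counts
into coverage-like abundances.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .digestion import EnzymeSpec, digest_records, get_enzyme

RANKS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass
class GenomeEntry:
    """One labelled, digested genome."""

    genome_id: str
    species_label: str
    lineage: dict[str, str]
    tag_multiset: Counter

    def single_copy_tags(self) -> set[str]:
        """Canonical tags with within-genome multiplicity exactly 1."""
        return {t for t, c in self.tag_multiset.items() if c == 1}


def single_copy_tags(entry: GenomeEntry) -> set[str]:
    return entry.single_copy_tags()


@dataclass
class MarkerDatabase:
    """tag -> species lookup plus per-species theoretical marker counts."""

    enzyme: EnzymeSpec
    markers: dict[str, str]              # canonical tag -> species
    T: dict[str, int]                    # species -> marker count (> 0)
    lineages: dict[str, dict[str, str]]  # species -> rank map
    unprofilable: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def marker_set(self, species: str) -> set[str]:
        return {t for t, s in self.markers.items() if s == species}

    @property
    def species(self) -> list[str]:
        return sorted(self.T)

    def digest_hex(self) -> str:
        """Content hash over the sorted marker table (rebuild determinism)."""
        h = hashlib.sha256()
        for tag in sorted(self.markers):
            h.update(f"{tag}\t{self.markers[tag]}\n".encode())
        return h.hexdigest()

    # -- persistence: sorted flat tables so digests are reproducible --------

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "markers.tsv", "w") as fh:
            fh.write("canonical_tag\tspecies\n")
            for tag in sorted(self.markers):
                fh.write(f"{tag}\t{self.markers[tag]}\n")
        with open(outdir / "species.tsv", "w") as fh:
            fh.write("species\tT\tlineage\n")
            for sp in sorted(self.T):
                lin = ";".join(self.lineages.get(sp, {}).get(r, "") for r in RANKS)
                fh.write(f"{sp}\t{self.T[sp]}\t{lin}\n")
        meta = dict(self.meta)
        meta.update(enzyme=self.enzyme.to_dict(), unprofilable=self.unprofilable,
                    digest=self.digest_hex())
        with open(outdir / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, dbdir) -> "MarkerDatabase":
        dbdir = Path(dbdir)
        with open(dbdir / "meta.json") as fh:
            meta = json.load(fh)
        enzyme = EnzymeSpec.from_dict(meta.pop("enzyme"))
        unprofilable = meta.pop("unprofilable", [])
        meta.pop("digest", None)
        markers: dict[str, str] = {}
        with open(dbdir / "markers.tsv") as fh:
            next(fh)
            for line in fh:
                tag, sp = line.rstrip("\n").split("\t")
                markers[tag] = sp
        T: dict[str, int] = {}
        lineages: dict[str, dict[str, str]] = {}
        with open(dbdir / "species.tsv") as fh:
            next(fh)
            for line in fh:
                sp, t, lin = line.rstrip("\n").split("\t")
                T[sp] = int(t)
                names = lin.split(";")
                lineages[sp] = {r: n for r, n in zip(RANKS, names) if n}
        return cls(enzyme=enzyme, markers=markers, T=T, lineages=lineages,
                   unprofilable=unprofilable, meta=meta)


def build(entries: list[GenomeEntry], enzyme: EnzymeSpec) -> MarkerDatabase:
    """Build the species-specific marker database.

    Per species, candidates are the union over its genomes of single-copy
    tags (a tag duplicated in one conspecific genome but single-copy in
    another is kept -- the single-copy filter is per genome).  A candidate
    becomes a marker iff it appears, at any multiplicity, in no genome of
    any other species.  Output is independent of input order; marker sets
    are pairwise disjoint by construction and re-asserted before returning.
    """
    if not entries:
        raise ValueError("no genome entries supplied")
    ids = [e.genome_id for e in entries]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate genome_id(s): {dup}")

    lineages: dict[str, dict[str, str]] = {}
    for e in entries:
        if not e.species_label:
            raise ValueError(f"genome {e.genome_id!r} lacks a species label")
        prev = lineages.setdefault(e.species_label, e.lineage)
        if prev != e.lineage:
            raise ValueError(f"conflicting lineages for species {e.species_label!r}")

    candidates: dict[str, set[str]] = defaultdict(set)
    occurs_in: dict[str, set[str]] = defaultdict(set)  # tag -> species with any copy
    intra_flagged: dict[str, int] = defaultdict(int)
    for e in entries:
        candidates[e.species_label] |= e.single_copy_tags()
        for tag in e.tag_multiset:
            occurs_in[tag].add(e.species_label)

    markers: dict[str, str] = {}
    T: dict[str, int] = {}
    unprofilable: list[str] = []
    for sp in sorted(candidates):
        kept = {t for t in candidates[sp] if occurs_in[t] == {sp}}
        # report tags kept despite being multi-copy in some conspecific genome
        for e in entries:
            if e.species_label == sp:
                intra_flagged[sp] += sum(
                    1 for t, c in e.tag_multiset.items() if c > 1 and t in kept
                )
        if kept:
            for t in kept:
                markers[t] = sp
            T[sp] = len(kept)
        else:
            unprofilable.append(sp)

    db = MarkerDatabase(
        enzyme=enzyme, markers=markers, T=T,
        lineages={sp: lineages[sp] for sp in T},
        unprofilable=sorted(unprofilable),
        meta={
            "n_genomes": len(entries),
            "n_species": len(candidates),
            "intra_species_multicopy_kept": {k: v for k, v in sorted(intra_flagged.items()) if v},
        },
    )
    _assert_disjoint(db)
    return db


def _assert_disjoint(db: MarkerDatabase) -> None:
    # markers is a dict keyed by tag, so each tag maps to exactly one species;
    # verify the per-species counts are consistent with it.
    counts = Counter(db.markers.values())
    for sp, t in db.T.items():
        if counts[sp] != t:
            raise AssertionError(f"marker bookkeeping broken for species {sp!r}")


def entries_from_fasta(manifest_path, fasta_dir, enzyme_name: str = "BcgI",
                       circular: bool = False) -> tuple[list[GenomeEntry], EnzymeSpec]:
    """Read a TSV manifest (genome_id, species_label, lineage) and digest FASTAs.

    Each genome is the FASTA file ``<fasta_dir>/<genome_id>.fasta`` (all its
    records pooled).
    """
    enzyme = get_enzyme(enzyme_name)
    fasta_dir = Path(fasta_dir)
    entries: list[GenomeEntry] = []
    with open(manifest_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            row = line.rstrip("\n").split("\t")
            gid, sp = row[idx["genome_id"]], row[idx["species_label"]]
            names = row[idx["lineage"]].split(";") if "lineage" in idx else []
            lineage = {r: n for r, n in zip(RANKS, names) if n}
            path = fasta_dir / f"{gid}.fasta"
            tags = digest_records(SeqIO.parse(str(path), "fasta"), enzyme,
                                  circular=circular)
            entries.append(GenomeEntry(gid, sp, lineage, tags))
    return entries, enzyme
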