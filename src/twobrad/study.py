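"""Reference synthetic two-group study.

A fixed, seeded study design used by the analysis drivers, the test suite
and the acceptance script: 12 synthetic species (6 genera, 2 phyla) whose
genomes carry known numbers of BcgI sites, sequenced as a 10 + 10 two-group
cohort (disease group M vs comparison group H) with three planted
between-group effects, host contamination and motif-free junk reads.

All functions are pure in their seeds: the same seed reproduces the same
genomes, reads and tables byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import markers as markers_mod
from .digestion import BCGI, EnzymeSpec, digest
from .markers import GenomeEntry, MarkerDatabase
from .profiling import SampleProfile, ReadQCSummary, aggregate, counts_frame, profile
from .simulate import CommunitySpec, SyntheticGenomeSpec, generate_genome, simulate_reads
from .tables import AbundanceMatrix

_PHYLA = ("Pseudomonadota_syn", "Bacillota_syn")
_GENERA = ("GenusA", "GenusB", "GenusC", "GenusD", "GenusE", "GenusF")


def reference_genome_specs(seed: int = 0, n_species: int = 12,
                           length_bp: int = 12_000) -> list[SyntheticGenomeSpec]:
    """Genome recipes for the reference panel (varying site counts)."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_species):
        genus = _GENERA[i % len(_GENERA)]
        phylum = _PHYLA[0] if i % len(_GENERA) < 3 else _PHYLA[1]
        species = f"{genus}_sp{i + 1:02d}"
        specs.append(SyntheticGenomeSpec(
            genome_id=f"GCF_SYN{i + 1:04d}",
            species_label=species,
            lineage={
                "phylum": phylum,
                "class": f"{phylum}_class",
                "order": f"{genus}_order",
                "family": f"{genus}_family",
                "genus": genus,
                "species": species,
            },
            length_bp=length_bp,
            gc_fraction=0.45 + 0.01 * (i % 5),
            n_planted_sites=int(15 + 5 * (i % 7)),  # 15..45 markers per genome
            seed=seed * 1000 + i,
        ))
    return specs


def build_reference_db(specs: list[SyntheticGenomeSpec],
                       enzyme: EnzymeSpec = BCGI
                       ) -> tuple[dict[str, str], MarkerDatabase]:
    """Generate the genomes and build their marker database."""
    genomes = {s.genome_id: generate_genome(s, enzyme) for s in specs}
    entries = [
        GenomeEntry(s.genome_id, s.species_label, s.lineage,
                    digest(genomes[s.genome_id], enzyme))
        for s in specs
    ]
    return genomes, markers_mod.build(entries, enzyme)


@dataclass
class StudyDesign:
    """Two-group community design with planted effects."""

    specs: list[SyntheticGenomeSpec]
    group_means: dict[str, np.ndarray]          # group -> mean proportions
    concentration: float = 300.0                # Dirichlet concentration
    n_per_group: int = 10
    n_reads: int = 20_000
    host_fraction: float = 0.05
    junk_fraction: float = 0.10
    seed: int = 0
    planted: list[str] = field(default_factory=list)


def reference_design(seed: int = 0, n_per_group: int = 10,
                     n_reads: int = 20_000) -> StudyDesign:
    """The reference design: 12 species, 3 planted between-group effects.

    Species 1 is enriched in group M; species 2 and 3 are enriched in
    group H; the remaining 9 share a common lognormal background.
    """
    specs = reference_genome_specs(seed)
    k = len(specs)
    rng = np.random.default_rng(seed + 17)
    background = np.exp(rng.normal(0.0, 0.6, size=k))
    base = background / background.sum()

    mean_m = base.copy()
    mean_h = base.copy()
    mean_m[0], mean_h[0] = 0.20, 0.03   # planted: enriched in M
    mean_m[1], mean_h[1] = 0.02, 0.12   # planted: enriched in H
    mean_m[2], mean_h[2] = 0.02, 0.10   # planted: enriched in H
    mean_m /= mean_m.sum()
    mean_h /= mean_h.sum()
    return StudyDesign(
        specs=specs,
        group_means={"M": mean_m, "H": mean_h},
        n_per_group=n_per_group,
        n_reads=n_reads,
        seed=seed,
        planted=[specs[i].species_label for i in range(3)],
    )


@dataclass
class StudyResult:
    design: StudyDesign
    genomes: dict[str, str]
    db: MarkerDatabase
    truth: pd.DataFrame                     # samples x species true proportions
    profiles: list[SampleProfile]
    qcs: dict[str, ReadQCSummary]
    matrix: AbundanceMatrix                 # species-level relative abundances
    counts: pd.DataFrame                    # samples x species assigned reads S


def run_study(design: StudyDesign, enzyme: EnzymeSpec = BCGI) -> StudyResult:
    """Simulate the cohort and profile every sample end-to-end."""
    genomes, db = build_reference_db(design.specs, enzyme)
    gids = [s.genome_id for s in design.specs]
    species = [s.species_label for s in design.specs]
    rng = np.random.default_rng(design.seed + 101)

    sample_ids, group_of, profiles, qcs = [], {}, [], {}
    truth_rows = {}
    for group in ("M", "H"):
        mean = design.group_means[group]
        for j in range(design.n_per_group):
            sid = f"{group}{j + 1:02d}"
            props = rng.dirichlet(mean * design.concentration)
            comm = CommunitySpec(
                members=list(zip(gids, props.tolist())),
                n_reads=design.n_reads,
                host_fraction=design.host_fraction,
                junk_fraction=design.junk_fraction,
                seed=int(rng.integers(2**31)),
            )
            reads = simulate_reads(comm, genomes, enzyme)
            prof, qc = profile(((r, None) for r in reads), db, sample_id=sid)
            sample_ids.append(sid)
            group_of[sid] = group
            profiles.append(prof)
            qcs[sid] = qc
            truth_rows[sid] = dict(zip(species, props))

    matrix = aggregate(profiles, group_of, db.lineages, rank="species")
    truth = pd.DataFrame.from_dict(truth_rows, orient="index").reindex(
        index=matrix.sample_ids, columns=sorted(species))
    truth.index.name = "sample"
    return StudyResult(design=design, genomes=genomes, db=db, truth=truth,
                       profiles=profiles, qcs=qcs, matrix=matrix,
                       counts=counts_frame(profiles))


# ---------------------------------------------------------------------------
# Small fixture matrices for the statistics stages (no sequencing involved)


def lefse_fixture(
    n_per_group: int = 10,
    n_features: int = 20,
    planted: bool = True,
    noise_cpm: float = 30.0,
    seed: int = 0,
) -> AbundanceMatrix:
    """A counts-per-million style matrix for effect-size calibration.

    Base composition is lognormal across features with small *absolute*
    per-sample noise (default sd 30 CPM), i.e. a deliberately low-noise
    profile that isolates the behaviour of the Kruskal-Wallis screen and the
    LDA >= 2.0 threshold.  With ``planted=True`` feature 0 has per-million
    class means 1e5 (group M) vs 1e3 (group H).
    """
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(0.0, 1.0, size=n_features))
    base = base / base.sum() * 1e6
    if planted:
        base[0] = 1e3
    rows, groups = {}, {}
    for g in ("M", "H"):
        for j in range(n_per_group):
            sid = f"{g}{j + 1:02d}"
            v = base + rng.normal(0.0, noise_cpm, size=n_features)
            if planted and g == "M":
                v[0] = 1e5 + rng.normal(0.0, noise_cpm)
            rows[sid] = np.clip(v, 0.0, None)
            groups[sid] = g
    values = pd.DataFrame.from_dict(rows, orient="index")
    values.columns = [f"feat{j:02d}" for j in range(n_features)]
    values.index.name = "sample"
    return AbundanceMatrix(values=values, groups=pd.Series(groups))


def noise_matrix(n_per_group: int = 10, n_features: int = 30,
                 seed: int = 0) -> AbundanceMatrix:
    """Pure-noise two-group matrix (classifier null calibration)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    values = pd.DataFrame(
        rng.lognormal(0.0, 1.0, size=(n, n_features)),
        index=[f"M{j + 1:02d}" for j in range(n_per_group)]
        + [f"H{j + 1:02d}" for j in range(n_per_group)],
        columns=[f"feat{j:02d}" for j in range(n_features)],
    )
    values = values.div(values.sum(axis=1), axis=0)
    values.index.name = "sample"
    groups = pd.Series({s: s[0] for s in values.index})
    return AbundanceMatrix(values=values, groups=groups)


def separable_matrix(n_per_group: int = 10, n_features: int = 30,
                     seed: int = 0) -> AbundanceMatrix:
    """Noise matrix plus one perfectly separating feature (feat00)."""
    m = noise_matrix(n_per_group, n_features, seed)
    v = m.values.copy()
    sep = np.where(m.groups.to_numpy() == "M", 0.4, 0.05)
    rng = np.random.default_rng(seed + 1)
    v["feat00"] = sep + rng.uniform(0, 0.01, size=len(v))
    return AbundanceMatrix(values=v, groups=m.groups)
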