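"""Profiling: tag extraction from reads, G score, abundance normalization,
rank aggregation, QC funnel."""

import math

import numpy as np
import pandas as pd
import pytest

from twobrad.digestion import BCGI, canonical, revcomp
from twobrad.markers import MarkerDatabase
from twobrad.profiling import (aggregate, extract_tag_from_read, g_score,
                               profile, SampleProfile)
from twobrad.simulate import CommunitySpec, simulate_reads
from twobrad.tables import AbundanceMatrix


def motif_tag(inner="ACGTAC", left="T" * 10, right="G" * 10) -> str:
    return left + "CGA" + inner + "TGC" + right


class TestExtractTag:
    def test_embedded_tag_recovered(self):
        tag = motif_tag()
        read = "A" * 30 + tag + "C" * 38
        assert extract_tag_from_read(read, BCGI) == canonical(tag)

    def test_reverse_strand_recovered(self):
        tag = motif_tag()
        read = revcomp("A" * 30 + tag + "C" * 38)
        assert extract_tag_from_read(read, BCGI) == canonical(tag)

    def test_no_motif(self):
        assert extract_tag_from_read("A" * 100, BCGI) is None

    def test_two_loci_ambiguous(self):
        tag = motif_tag()
        read = tag + "A" * 6 + tag
        assert extract_tag_from_read(read, BCGI) is None

    def test_truncated_flank_not_extractable(self):
        # motif at position 4: upstream flank incomplete
        read = "T" * 4 + "CGA" + "ACGTAC" + "TGC" + "G" * 60
        assert extract_tag_from_read(read, BCGI) is None

    def test_agrees_with_digestion_of_read(self):
        rng = np.random.default_rng(5)
        from twobrad.digestion import digest

        for _ in range(50):
            read = "".join(rng.choice(list("ACGT"), size=100))
            tags = digest(read, BCGI)
            expected = next(iter(tags)) if sum(tags.values()) == 1 else None
            assert extract_tag_from_read(read, BCGI) == expected


class TestGScore:
    @pytest.mark.parametrize("S,t,expected", [(0, 0, 0.0), (25, 1, 5.0), (4, 4, 4.0)])
    def test_sqrt_form(self, S, t, expected):
        assert g_score(S, t) == pytest.approx(expected)

    def test_threshold_boundary(self):
        assert g_score(25, 1) >= 5.0
        assert g_score(4, 4) < 5.0

    def test_product_form(self):
        assert g_score(25, 1, form="product") == 25.0
        assert g_score(3, 2, form="product") == 6.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            g_score(-1, 0)


def tiny_db(T: dict[str, int], lineages=None) -> MarkerDatabase:
    """A hand-built database with T[sp] distinct markers per species."""
    rng = np.random.default_rng(42)
    markers = {}
    for sp, n in T.items():
        made = 0
        while made < n:
            flank5 = "".join(rng.choice(list("ACGT"), size=10))
            inner = "".join(rng.choice(list("ACGT"), size=6))
            flank3 = "".join(rng.choice(list("ACGT"), size=10))
            t = canonical(flank5 + "CGA" + inner + "TGC" + flank3)
            if t not in markers and extract_tag_from_read("T" * 10 + t + "T" * 10,
                                                          BCGI) == t:
                markers[t] = sp
                made += 1
    return MarkerDatabase(enzyme=BCGI, markers=markers, T=dict(T),
                          lineages=lineages or {sp: {"species": sp} for sp in T})


def reads_for(db: MarkerDatabase, sp: str, n: int, rng) -> list[tuple[str, None]]:
    tags = sorted(t for t, s in db.markers.items() if s == sp)
    out = []
    for i in range(n):
        tag = tags[i % len(tags)]
        off = int(rng.integers(0, 69))
        read = ("".join(rng.choice(list("ACGT"), size=off)) + tag
                + "".join(rng.choice(list("ACGT"), size=68 - off)))
        if extract_tag_from_read(read, BCGI) != tag:
            read = "T" * 34 + tag + "T" * 34  # fallback: clean context
        out.append((read, None))
    return out


class TestProfile:
    def test_coverage_normalized_abundance(self):
        db = tiny_db({"spA": 10, "spB": 20})
        rng = np.random.default_rng(1)
        reads = reads_for(db, "spA", 10, rng) + reads_for(db, "spB", 10, rng)
        prof, qc = profile(reads, db)
        # S/T = 1.0 and 0.5 -> renormalized 2/3, 1/3
        assert prof.relative_abundance["spA"] == pytest.approx(2 / 3)
        assert prof.relative_abundance["spB"] == pytest.approx(1 / 3)
        assert qc.raw_reads == qc.enzyme_reads == qc.clean_reads == 20

    def test_single_passing_species(self):
        db = tiny_db({"spA": 10, "spB": 20})
        rng = np.random.default_rng(2)
        prof, _ = profile(reads_for(db, "spA", 30, rng), db)
        assert prof.relative_abundance == {"spA": pytest.approx(1.0)}

    def test_gscore_threshold_filters_sparse_species(self):
        db = tiny_db({"spA": 10, "spB": 20})
        rng = np.random.default_rng(3)
        # spB: 4 reads over 4 markers -> G = 4 < 5 -> filtered
        reads = reads_for(db, "spA", 30, rng) + reads_for(db, "spB", 4, rng)
        prof, _ = profile(reads, db)
        hits = {h.species: h for h in prof.hits}
        assert not hits["spB"].passed
        assert list(prof.relative_abundance) == ["spA"]

    def test_no_passing_species_warns_not_raises(self):
        db = tiny_db({"spA": 10})
        prof, _ = profile([("A" * 100, None)], db)
        assert prof.relative_abundance == {}
        assert prof.warnings

    def test_low_quality_tag_dropped(self):
        db = tiny_db({"spA": 5})
        tag = sorted(db.markers)[0]
        read = "T" * 34 + tag + "T" * 34
        prof, qc = profile([(read, "#" * 102)], db)  # Phred 2 everywhere
        assert qc.clean_reads == 0
        prof, qc = profile([(read, "I" * 102)], db)
        assert qc.clean_reads == 1

    def test_n_in_tag_rejected_at_clean_step(self):
        db = tiny_db({"spA": 5})
        tag = sorted(db.markers)[0]
        broken = tag[:2] + "N" + tag[3:]  # N in the flank: motif intact, tag dirty
        read = "T" * 34 + broken + "T" * 34
        prof, qc = profile([(read, None)], db)
        assert (qc.enzyme_reads, qc.clean_reads) == (1, 0)

    def test_qc_funnel_monotone(self):
        db = tiny_db({"spA": 5})
        rng = np.random.default_rng(4)
        reads = reads_for(db, "spA", 10, rng) + [("A" * 100, None)] * 5
        _, qc = profile(reads, db)
        assert qc.raw_reads >= qc.enzyme_reads >= qc.clean_reads

    def test_empty_db_rejected(self):
        db = tiny_db({"spA": 1})
        db.markers = {}
        with pytest.raises(ValueError, match="empty"):
            profile([], db)


class TestEndToEndRecovery:
    def test_three_species_recovery(self, small_panel):
        specs, genomes, db = small_panel
        gids = [s.genome_id for s in specs[:3]]
        truth = [0.7, 0.2, 0.1]
        comm = CommunitySpec(members=list(zip(gids, truth)), n_reads=30_000, seed=13)
        reads = simulate_reads(comm, genomes, BCGI)
        prof, _ = profile(((r, None) for r in reads), db)
        for s, p in zip(specs[:3], truth):
            assert prof.relative_abundance[s.species_label] == pytest.approx(p, abs=0.02)

    def test_genome_size_invariance(self, small_panel):
        """Doubling a member's tag count at fixed cell proportion moves its
        estimate by <= 0.02 (the T_i division cancels marker richness)."""
        from twobrad.digestion import digest
        from twobrad.markers import GenomeEntry, build
        from twobrad.simulate import SyntheticGenomeSpec, generate_genome

        def run(n_sites_a):
            sa = SyntheticGenomeSpec("ga", "spa", {"species": "spa"}, length_bp=6000,
                                     n_planted_sites=n_sites_a, seed=21)
            sb = SyntheticGenomeSpec("gb", "spb", {"species": "spb"}, length_bp=6000,
                                     n_planted_sites=25, seed=22)
            genomes = {"ga": generate_genome(sa, BCGI), "gb": generate_genome(sb, BCGI)}
            db = build([GenomeEntry(g, g.replace("g", "sp"), {}, digest(genomes[g], BCGI))
                        for g in genomes], BCGI)
            comm = CommunitySpec(members=[("ga", 0.3), ("gb", 0.7)],
                                 n_reads=30_000, seed=31)
            reads = simulate_reads(comm, genomes, BCGI)
            prof, _ = profile(((r, None) for r in reads), db)
            return prof.relative_abundance["spa"]

        assert abs(run(20) - run(40)) <= 0.02


class TestAggregate:
    def _profiles(self):
        lineages = {
            "spA": {"phylum": "P1", "genus": "G1", "species": "spA"},
            "spB": {"phylum": "P1", "genus": "G1", "species": "spB"},
            "spC": {"phylum": "P2", "genus": "G2", "species": "spC"},
        }
        p1 = SampleProfile("s1", [], {"spA": 0.6, "spB": 0.4}, 0)
        p2 = SampleProfile("s2", [], {"spA": 0.2, "spC": 0.8}, 0)
        return [p1, p2], {"s1": "M", "s2": "H"}, lineages

    def test_genus_rollup(self):
        profiles, groups, lineages = self._profiles()
        m = aggregate(profiles, groups, lineages, rank="genus")
        assert m.values.loc["s1", "G1"] == pytest.approx(1.0)
        assert m.values.loc["s2", "G1"] == pytest.approx(0.2)
        assert m.values.loc["s2", "G2"] == pytest.approx(0.8)

    def test_species_rank_is_identity(self):
        profiles, groups, lineages = self._profiles()
        m = aggregate(profiles, groups, lineages, rank="species")
        assert m.values.loc["s1", "spA"] == pytest.approx(0.6)
        assert m.values.loc["s1", "spC"] == 0.0

    def test_row_sums_preserved(self):
        rng = np.random.default_rng(8)
        lineages = {f"sp{i}": {"phylum": f"P{i % 3}", "genus": f"G{i % 5}",
                               "species": f"sp{i}"} for i in range(12)}
        profiles = []
        groups = {}
        for s in range(10):
            v = rng.dirichlet(np.ones(12))
            profiles.append(SampleProfile(f"s{s}", [],
                                          {f"sp{i}": v[i] for i in range(12)}, 0))
            groups[f"s{s}"] = "M" if s < 5 else "H"
        for rank in ("phylum", "genus", "species"):
            m = aggregate(profiles, groups, lineages, rank=rank)
            np.testing.assert_allclose(m.values.sum(axis=1), 1.0, atol=1e-9)
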