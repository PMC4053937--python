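import numpy as np
import pandas as pd
import pytest

from paremir import hairpin as hp
from paremir import mapping, normalization
from paremir.config import PipelineConfig
from paremir.mapping import GenomeHit, TagHits
from paremir.mirna_pipeline import (
    Rejection,
    assign_names,
    evaluate_candidate,
    filter1_stringent,
    homology_pipeline,
    run_stringent_pipeline,
    MirnaCall,
)
from paremir.sequence_io import GenomeSeq, TagTable, revcomp
from paremir.synthetic_data import SimulationConfig, simulate_dataset


def make_table(tag_counts: dict, totals=None, libs=("l1",)):
    df = pd.DataFrame(
        {lib: [c[i] for c in tag_counts.values()] for i, lib in enumerate(libs)},
        index=list(tag_counts.keys()),
    ).astype("int64")
    df.index.name = "tag"
    t = TagTable(df)
    t.genome_matched_totals = totals or {lib: int(df[lib].sum()) for lib in libs}
    return t


def one_hit(tags):
    return {t: TagHits([GenomeHit("c", 0, "+")]) for t in tags}


class TestFilter1:
    def test_size_abundance_and_hit_clauses(self):
        tags = {
            "A" * 19: (100,),           # too short
            "C" * 10 + "G" * 11: (100,),  # passes everything
            "G" * 10 + "C" * 11: (1,),    # exactly 10 TP2M with this basis
            "T" * 10 + "A" * 11: (0,),    # absent
        }
        table = make_table(tags, totals={"l1": 200_000})
        hits = one_hit(tags)
        kept = filter1_stringent(table, hits)
        assert "A" * 19 not in kept
        assert "C" * 10 + "G" * 11 in kept
        # 1 read * 2e6 / 2e5 = 10 TP2M: the >= comparison keeps it
        assert "G" * 10 + "C" * 11 in kept
        assert "T" * 10 + "A" * 11 not in kept

    def test_hit_count_cap(self):
        tag = "ACGT" * 5 + "A"
        table = make_table({tag: (100,)}, totals={"l1": 1000})
        over = {tag: TagHits([GenomeHit("c", i, "+") for i in range(21)])}
        assert filter1_stringent(table, over) == []
        over[tag].hits.pop()
        assert filter1_stringent(table, over) == [tag]


@pytest.fixture(scope="module")
def pipeline_run(dataset, dataset_hits):
    calls, rejections = run_stringent_pipeline(
        dataset.smallrna, dataset_hits, dataset.genome_map
    )
    return calls, rejections


class TestStringentRoute:
    def test_all_compliant_plants_recovered(self, dataset, pipeline_run):
        calls, _ = pipeline_run
        matures = {p["mature_seq"] for p in dataset.truth.precursors if p["compliant"]}
        assert matures <= {c.mature_seq for c in calls}

    def test_no_calls_outside_planted_loci(self, dataset, pipeline_run):
        calls, _ = pipeline_run
        planted = [(p["start"], p["end"]) for p in dataset.truth.precursors]
        for call in calls:
            for prec in call.precursors:
                assert any(prec.start < e and prec.end > s for s, e in planted)

    def test_sirna_locus_tags_rejected_for_strand_bias(self, dataset, pipeline_run):
        _, rejections = pipeline_run
        sirna = dataset.truth.sirna_loci[0]
        genome = dataset.genome_map["chr1"]
        region_tags = [
            tag for tag in rejections
            if genome.find(tag) != -1 and sirna["start"] <= genome.find(tag) < sirna["end"]
        ]
        assert region_tags, "no evaluated tags from the siRNA locus"
        for tag in region_tags:
            assert any(r.reason == "strand_bias" for r in rejections[tag])

    def test_bulgy_plant_fails_on_bulge_size(self, dataset, dataset_hits):
        bulgy = next(p for p in dataset.truth.precursors if not p["compliant"])
        tag = bulgy["mature_seq"]
        res = evaluate_candidate(
            tag, dataset_hits[tag].hits[0], dataset.genome_map,
            dataset.smallrna, dataset_hits, PipelineConfig(),
        )
        assert isinstance(res, Rejection) and res.reason == "bulge_size"

    def test_duplex_threshold_drives_rejection(self, dataset, dataset_hits):
        """With a zero-defect requirement even the single planted mismatch
        is a duplex rejection; the default threshold admits it."""
        mature = next(p for p in dataset.truth.precursors if p["compliant"])["mature_seq"]
        hit = dataset_hits[mature].hits[0]
        strict = PipelineConfig(max_defects_stringent=0)
        res = evaluate_candidate(
            mature, hit, dataset.genome_map, dataset.smallrna, dataset_hits, strict
        )
        assert isinstance(res, Rejection) and res.reason == "duplex"
        ok = evaluate_candidate(
            mature, hit, dataset.genome_map, dataset.smallrna, dataset_hits,
            PipelineConfig(),
        )
        assert not isinstance(ok, Rejection)

    def test_relaxing_a_threshold_admits_its_rejections(self):
        """Plants failing only the abundance-bias criterion pass once that
        single threshold is relaxed (rejection reasons partition failures)."""
        cfg = SimulationConfig(seed=3, mature_fraction=0.35, star_fraction=0.1,
                               n_jitter_variants=8, n_precursors=2,
                               n_bulgy_precursors=0, phased_locus_specs=())
        ds = simulate_dataset(cfg)
        hits = mapping.map_tags(ds.genome, ds.smallrna.tags, 20)
        normalization.attach_genome_matched_totals(ds.smallrna, hits)
        calls, rejections = run_stringent_pipeline(ds.smallrna, hits, ds.genome_map)
        matures = {p["mature_seq"] for p in ds.truth.precursors}
        assert not matures & {c.mature_seq for c in calls}
        for m in matures:
            assert any(r.reason == "abundance_bias" for r in rejections[m])
        relaxed = PipelineConfig(abundance_bias_min_stringent=0.3)
        calls2, _ = run_stringent_pipeline(ds.smallrna, hits, ds.genome_map, relaxed)
        assert matures <= {c.mature_seq for c in calls2}


class TestHomologyRoute:
    def test_bulgy_plant_recovered_via_homology(self, dataset, dataset_hits):
        bulgy = next(p for p in dataset.truth.precursors if not p["compliant"])
        calls, _ = homology_pipeline(
            dataset.smallrna, dataset_hits, dataset.genome,
            {"fam-x": bulgy["mature_seq"]},
        )
        assert any(c.mature_seq == bulgy["mature_seq"] for c in calls)
        call = next(c for c in calls if c.mature_seq == bulgy["mature_seq"])
        assert call.route == "homology"
        assert call.precursors[0].stats.max_bulge_len == 2

    def test_eight_defect_limit_via_structure_override(self, dataset, dataset_hits):
        """The <= 8 total-defect rule: a hand-built structure with 9 duplex
        defects (6 mismatches + 3 bulges) fails the homology criteria, one
        with 6 (4 mismatches + 2 bulges) passes."""
        bulgy = next(p for p in dataset.truth.precursors if not p["compliant"])
        tag = bulgy["mature_seq"]
        hit = dataset_hits[tag].hits[0]
        L = len(tag)
        lo = hit.start - 10
        m0 = 10

        def build_structure(mm_qs, gap_qs):
            # pair the miRNA across a loop onto a pseudo-star; mm_qs columns
            # are unpaired on both arms (mismatches), gap_qs skip one star
            # base each (1-nt star-arm bulges)
            star0 = m0 + L + 8
            hi = lo + star0 + L + len(gap_qs) + 6
            window = dataset.genome_map["chr1"][lo:hi]
            pair_map = [-1] * len(window)
            cur = star0 + L + len(gap_qs) - 1
            for q in range(L):
                if q in gap_qs:
                    cur -= 1  # extra star base opposite nothing: a bulge
                if q not in mm_qs:  # mismatch: both column bases unpaired
                    pair_map[m0 + q], pair_map[cur] = cur, m0 + q
                cur -= 1
            db = hp.dotbracket_from_pairmap(pair_map)
            return (lo, hi), hp.HairpinStructure(window, db, pair_map)

        cfg = PipelineConfig()
        window, structure = build_structure({5, 7, 9, 11}, {14, 16})
        ok = evaluate_candidate(
            tag, hit, dataset.genome_map, dataset.smallrna, dataset_hits, cfg,
            windows=[window], route="homology", external_structure=structure,
        )
        assert not isinstance(ok, Rejection), getattr(ok, "reason", None)
        assert ok.stats.total_defects == 6
        window, structure = build_structure({4, 6, 8, 10, 12, 14}, {3, 16, 18})
        bad = evaluate_candidate(
            tag, hit, dataset.genome_map, dataset.smallrna, dataset_hits, cfg,
            windows=[window], route="homology", external_structure=structure,
        )
        assert isinstance(bad, Rejection) and bad.reason == "duplex"

    def test_anchors_within_100nt_are_merged(self, rng):
        genome_seq = "".join(rng.choice(list("ACGT"), 800))
        known = genome_seq[200:221]
        # a second copy of the known miRNA 80 nt downstream
        genome_seq = genome_seq[:280] + known + genome_seq[301:]
        genome = [GenomeSeq("g", genome_seq)]
        tag_hi, tag_lo = known, genome_seq[281:302]
        table = make_table({tag_hi: (500,), tag_lo: (50,)}, totals={"l1": 100_000})
        hits = mapping.map_tags(genome, table.tags, 20)
        calls, rejections = homology_pipeline(
            table, hits, genome, {"fam": known}
        )
        # the two anchors 80 nt apart collapse into one evaluated candidate
        assert len(calls) + len(rejections) == 1
        evaluated = {c.mature_seq for c in calls} | set(rejections)
        assert evaluated == {tag_hi}


class TestAssignNames:
    def mk(self, seq, route="stringent"):
        return MirnaCall(name="", mature_seq=seq, route=route)

    def test_exact_and_two_mismatch_matches_take_family_name(self):
        known = {"miR-alpha": "TAGCAGCACGTAAATATTGGC"}
        exact = self.mk("TAGCAGCACGTAAATATTGGC")
        two = self.mk("TAGCAGCACGTAAATATTAAC")
        three = self.mk("TAGCAGCACGTAAATATAAAC")
        assign_names([exact, two, three], known)
        assert exact.name == "miR-alpha" and two.name == "miR-alpha"
        assert three.name.startswith("candidate-miR")

    def test_three_mismatches_only_via_manual_family_route(self):
        known = {"miR-alpha": "TAGCAGCACGTAAATATTGGC"}
        manual = self.mk("TAGCAGCACGTAAATATAAAC", route="manual-family")
        assign_names([manual], known)
        assert manual.name == "miR-alpha"

    def test_conservation_requires_other_species_match(self):
        known = {"miR-alpha": "TAGCAGCACGTAAATATTGGC"}
        other = {"osa-miR-alpha": "TAGCAGCACGTAAATATTGGC"}
        a, b = self.mk("TAGCAGCACGTAAATATTGGC"), self.mk("AAAAAGCACGTAAATATTGGC")
        assign_names([a, b], known, other_species=other)
        assert a.conservation == "conserved"
        assert b.conservation == "non-conserved"
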