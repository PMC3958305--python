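"""Novel-junction enumeration, event classification and abundance fractions."""

from dataclasses import replace

import pandas as pd
import pytest

from minorsplice.annotation import (
    U2,
    U12,
    Exon,
    Gene,
    Transcript,
    build_reference_pairs,
)
from minorsplice.events import (
    classify_event,
    detect_events,
    enumerate_novel_junctions,
    event_fractions,
)
from minorsplice.quantify import JunctionKey, SampleScan
from minorsplice.simulate import (
    CRYPTIC_3P,
    CRYPTIC_5P,
    EXON_SKIP,
    SimulationConfig,
    simulate_cohort,
)

from conftest import naive_junction_counts, parse_sam_text


def make_gene(strand="+"):
    """Four exons; introns (200,400) U2, (500,700) U12, (800,1000) U2."""
    exons = [
        Exon("chr1", 100, 200, strand),
        Exon("chr1", 400, 500, strand),
        Exon("chr1", 700, 800, strand),
        Exon("chr1", 1000, 1100, strand),
    ]
    t = Transcript("t1", "g1", exons)
    t.derive_introns()
    for j, intron in enumerate(t.introns):
        stype = U12 if (intron.start, intron.end) == (500, 700) else U2
        t.introns[j] = replace(intron, splice_type=stype)
    return Gene("g1", {"t1": t}, "t1")


class TestClassification:
    def test_shifted_acceptor_near_u12_acceptor_is_cryptic_3p(self):
        gene = make_gene("+")
        u12 = gene.u12_introns[0]
        assert classify_event(JunctionKey("chr1", 500, 640), gene, u12) == CRYPTIC_3P

    def test_shifted_donor_near_u12_donor_is_cryptic_5p(self):
        gene = make_gene("+")
        u12 = gene.u12_introns[0]
        assert classify_event(JunctionKey("chr1", 560, 700), gene, u12) == CRYPTIC_5P

    def test_minus_strand_swaps_donor_and_acceptor(self):
        gene = make_gene("-")
        u12 = gene.u12_introns[0]
        # on '-', the genomic-right end is the donor: shared right end +
        # shifted left end = shifted acceptor = cryptic_3p
        assert classify_event(JunctionKey("chr1", 560, 700), gene, u12) == CRYPTIC_3P
        assert classify_event(JunctionKey("chr1", 500, 640), gene, u12) == CRYPTIC_5P

    def test_annotated_sites_spanning_u12_is_exon_skip(self):
        gene = make_gene("+")
        u12 = gene.u12_introns[0]
        assert classify_event(JunctionKey("chr1", 200, 1000), gene, u12) == EXON_SKIP

    def test_unrelated_junction_is_other(self):
        gene = make_gene("+")
        u12 = gene.u12_introns[0]
        assert classify_event(JunctionKey("chr1", 210, 660), gene, u12) == "other"

    def test_window_bounds_cryptic_search(self):
        gene = make_gene("+")
        u12 = gene.u12_introns[0]
        far = JunctionKey("chr1", 500, 550)  # acceptor 150 bp from U12 acceptor
        assert classify_event(far, gene, u12, window=100) == "other"
        assert classify_event(far, gene, u12, window=200) == CRYPTIC_3P


class TestFractions:
    def test_fraction_arithmetic(self):
        df = pd.DataFrame(
            [
                {
                    "gene_id": "g1", "chrom": "chr1", "donor": 501, "acceptor": 640,
                    "sample_id": "p1", "condition": "case", "event_class": CRYPTIC_3P,
                    "support_reads": 30, "canonical_reads": 70,
                }
            ]
        )
        pooled = event_fractions(df)
        assert pooled.loc[0, "case_fraction"] == pytest.approx(0.30)

    def test_zero_support_gives_zero_fraction(self):
        df = pd.DataFrame(
            [
                {
                    "gene_id": "g1", "chrom": "chr1", "donor": 501, "acceptor": 640,
                    "sample_id": "p1", "condition": "case", "event_class": CRYPTIC_3P,
                    "support_reads": 0, "canonical_reads": 70,
                }
            ]
        )
        assert event_fractions(df).loc[0, "case_fraction"] == 0.0


class TestOnSimulations:
    def baseline_paths(self, tmp_path):
        cfg = SimulationConfig(
            n_genes=30, n_case_samples=0, n_control_samples=1,
            mean_fragments_per_gene=1000, baseline_retention=0.0,
            baseline_cryptic=0.0, baseline_skip=0.0, seed=9,
        )
        return simulate_cohort(cfg, str(tmp_path / "base"))

    def test_canonical_only_reads_give_no_novel_junctions(self, tmp_path):
        paths = self.baseline_paths(tmp_path)
        models = paths["state"].models
        scan = SampleScan(paths["sams"]["control_01"], models.genome)
        for gid, gene in models.genes.items():
            assert enumerate_novel_junctions(scan, gene, min_support=1) == [], gid

    def test_specificity_under_baseline_conditions(self, tmp_path):
        """With no cryptic/skip signal simulated, no gene shows a supported
        novel event (>=95% required; this setup yields none at all)."""
        paths = self.baseline_paths(tmp_path)
        models = paths["state"].models
        scan = SampleScan(paths["sams"]["control_01"], models.genome)
        with_events = sum(
            bool(enumerate_novel_junctions(scan, gene, min_support=3))
            for gene in models.genes.values()
        )
        assert with_events / len(models.genes) <= 0.05

    def test_min_support_threshold_excludes_weak_junctions(self, small_cohort):
        models = small_cohort["state"].models
        sam = small_cohort["sams"]["case_01"]
        scan = SampleScan(sam, models.genome)
        for gene in models.genes.values():
            weak_allowed = enumerate_novel_junctions(scan, gene, min_support=1)
            strict = dict(
                (j, c) for j, c in enumerate_novel_junctions(scan, gene, min_support=3)
            )
            for junction, count in weak_allowed:
                assert (count >= 3) == (junction in strict)

    def test_cryptic_junction_count_matches_truth_sidecar(self, small_cohort):
        """The novel-junction count at a gene's fixed cryptic site equals the
        brute-force count of cryptic-class reads spanning it (anchor rule)."""
        state = small_cohort["state"]
        models = state.models
        sam = small_cohort["sams"]["case_01"]
        sidecar = pd.read_csv(small_cohort["read_truth"]["case_01"], sep="\t")
        classes = dict(zip(sidecar["read_id"], sidecar["truth_class"]))
        reads = parse_sam_text(sam)
        scan = SampleScan(sam, models.genome)
        checked = 0
        for gid in state.affected_genes:
            sim = state.gene_sims[gid]
            chrom = sim.gene.chrom
            for cls in (CRYPTIC_5P, CRYPTIC_3P):
                span = sim.class_junctions[cls]
                oracle = naive_junction_counts(
                    [r for r in reads if classes[r[0]] == cls], min_anchor=6
                ).get((chrom, span[0], span[1]), 0)
                assert scan.junction_count(chrom, *span) == oracle
                checked += 1
        assert checked > 0

    def test_junction_reads_partition_into_annotated_and_novel(self, small_cohort):
        """Every anchored N span in a gene is either annotated or novel;
        their read counts add up to all anchored junction reads there."""
        models = small_cohort["state"].models
        sam = small_cohort["sams"]["case_01"]
        scan = SampleScan(sam, models.genome)
        for gid, gene in models.genes.items():
            lo, hi = gene.extent
            total = sum(
                c
                for (chrom, s, e), c in scan.junction_counts.items()
                if chrom == gene.chrom and s >= lo and e <= hi
            )
            annotated = sum(
                scan.junction_count(gene.chrom, s, e)
                for (_, s, e) in gene.all_intron_spans()
            )
            novel = sum(c for _, c in enumerate_novel_junctions(scan, gene, min_support=1))
            assert annotated + novel == total, gid

    def test_detect_events_flags_case_exclusive_cryptic_sites(self, small_cohort):
        state = small_cohort["state"]
        models = state.models
        scans = {
            sid: SampleScan(sam, models.genome)
            for sid, sam in small_cohort["sams"].items()
        }
        conditions = {"case_01": "case", "control_01": "control"}
        u12_by_gene = {g: models.genes[g].u12_introns for g in models.u12_genes()}
        df = detect_events(scans, models, u12_by_gene, conditions)
        assert len(df) > 0
        cryptic = df[df["event_class"].isin([CRYPTIC_5P, CRYPTIC_3P])]
        assert set(cryptic["gene_id"]) <= state.affected_genes
        # recurrent gene-specific sites: strong case events, absent in controls
        strong = cryptic[cryptic["case_fraction"] > 0.05]
        assert len(strong) > 0
        assert strong["case_exclusive"].all()
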