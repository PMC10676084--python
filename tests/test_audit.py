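"""Alignment filtering, evidence intervals, per-feature metrics, regressions."""

import numpy as np
import pandas as pd
import pytest

from binaudit.audit import (
    AuditConfig,
    audit_report,
    contamination_evidence,
    filter_alignments,
    logistic_fit,
    ols_fit,
    per_feature_audit,
)
from binaudit.formats_io import (
    AlignmentRecord,
    GeneModel,
    Interval,
    MRNA,
    ReadPlacement,
)


def aln(read, s, e, mapq, primary=True, dup=False, contig="c1"):
    return AlignmentRecord(read, Interval(contig, s, e), mapq, primary, dup)


def plc(read, s, e, contig="c1"):
    return ReadPlacement(read, Interval(contig, s, e), "+")


class TestFilterAlignments:
    def test_mapq_threshold_is_inclusive(self):
        recs = [aln("r1", 0, 10, 10), aln("r2", 0, 10, 20), aln("r3", 0, 10, 30)]
        kept = filter_alignments(recs, AuditConfig(mapq_min=20))
        assert sorted(r.read_id for r in kept) == ["r2", "r3"]

    def test_secondary_discarded_even_with_higher_mapq(self):
        recs = [aln("r1", 0, 10, 40, primary=True), aln("r1", 50, 60, 60, primary=False)]
        (kept,) = filter_alignments(recs)
        assert kept.mapq == 40

    def test_duplicates_never_pass(self):
        recs = [aln("r1", 0, 10, 60, dup=True)]
        assert filter_alignments(recs) == []

    def test_best_per_read_with_leftmost_tiebreak(self):
        recs = [aln("r1", 500, 510, 30), aln("r1", 100, 110, 30), aln("r1", 0, 10, 25)]
        (kept,) = filter_alignments(recs)
        assert kept.target.start == 100

    def test_random_records_match_per_read_brute_force(self, rng):
        cfg = AuditConfig(mapq_min=20)
        for _ in range(50):
            recs = []
            for i in range(int(rng.integers(1, 40))):
                s = int(rng.integers(0, 1000))
                recs.append(
                    aln(
                        f"r{int(rng.integers(0, 8))}", s, s + int(rng.integers(1, 100)),
                        int(rng.integers(0, 61)),
                        primary=bool(rng.random() < 0.8),
                        dup=bool(rng.random() < 0.2),
                    )
                )
            kept = {r.read_id: r for r in filter_alignments(recs, cfg)}
            by_read = {}
            for r in recs:
                if r.is_duplicate or not r.is_primary:
                    continue
                by_read.setdefault(r.read_id, []).append(r)
            for read_id, cands in by_read.items():
                best = sorted(
                    cands,
                    key=lambda r: (-r.mapq, r.target.contig, r.target.start, r.target.end),
                )[0]
                if best.mapq >= 20:
                    assert kept[read_id] == best
                else:
                    assert read_id not in kept
            assert set(kept) <= set(by_read)


class TestContaminationEvidence:
    def test_interval_algebra_example(self):
        placements = [plc("b1", 100, 200)]
        alignments = [aln("b1", 150, 250, 60)]
        inter = contamination_evidence(placements, alignments, {"b1"})
        assert inter == {"c1": [(150, 200)]}
        union = contamination_evidence(
            placements, alignments, {"b1"}, AuditConfig(evidence_mode="union")
        )
        assert union == {"c1": [(100, 250)]}

    def test_disjoint_sets_give_empty_intersection(self):
        ev = contamination_evidence([plc("b1", 0, 50)], [aln("b1", 60, 90, 60)], {"b1"})
        assert ev == {}

    def test_non_contaminant_reads_ignored(self):
        ev = contamination_evidence([plc("h1", 0, 50)], [aln("h1", 0, 50, 60)], {"b9"})
        assert ev == {}

    def test_low_mapq_contaminant_contributes_nothing(self):
        ev = contamination_evidence([plc("b1", 0, 50)], [aln("b1", 0, 50, 5)], {"b1"})
        assert ev == {}

    def test_intersection_subset_of_union_per_base(self, rng):
        for _ in range(30):
            placements = [
                plc(f"b{i}", s := int(rng.integers(0, 150)), s + int(rng.integers(1, 60)))
                for i in range(int(rng.integers(1, 8)))
            ]
            alignments = [
                aln(f"b{i}", s := int(rng.integers(0, 150)), s + int(rng.integers(1, 60)), 60)
                for i in range(int(rng.integers(1, 8)))
            ]
            reads = {p.read_id for p in placements} | {a.read_id for a in alignments}
            inter = contamination_evidence(placements, alignments, reads)
            union = contamination_evidence(
                placements, alignments, reads, AuditConfig(evidence_mode="union")
            )
            for contig, ivs in inter.items():
                in_b = {b for s, e in ivs for b in range(s, e)}
                un_b = {b for s, e in union.get(contig, []) for b in range(s, e)}
                assert in_b <= un_b

    def test_matches_per_base_set_oracle(self, rng):
        for _ in range(40):
            n_p, n_a = int(rng.integers(0, 7)), int(rng.integers(0, 7))
            placements = [
                plc(f"b{i}", s := int(rng.integers(0, 180)), s + int(rng.integers(1, 50)))
                for i in range(n_p)
            ]
            alignments = [
                aln(f"b{i}", s := int(rng.integers(0, 180)), s + int(rng.integers(1, 50)), 60)
                for i in range(n_a)
            ]
            reads = {p.read_id for p in placements} | {a.read_id for a in alignments}
            a_bases = {b for p in placements for b in range(p.target.start, p.target.end)}
            m_bases = {b for a in alignments for b in range(a.target.start, a.target.end)}
            got = contamination_evidence(placements, alignments, reads)
            got_bases = {b for s, e in got.get("c1", []) for b in range(s, e)}
            assert got_bases == (a_bases & m_bases)
            # returned intervals are sorted, disjoint, maximal
            ivs = got.get("c1", [])
            assert all(e > s for s, e in ivs)
            assert all(ivs[i][1] < ivs[i + 1][0] for i in range(len(ivs) - 1))


def make_gene(gene_id, contig, exon_pairs, cds_pairs=None):
    exons = tuple(Interval(contig, s, e) for s, e in exon_pairs)
    cds = tuple(Interval(contig, s, e) for s, e in (cds_pairs or exon_pairs))
    span = Interval(contig, exons[0].start, exons[-1].end)
    return GeneModel(gene_id, contig, span, (MRNA(f"{gene_id}.t1", exons, cds),))


class TestPerFeatureAudit:
    def _depths(self, length=1000, total=4, contam=1):
        return ({"c1": np.full(length, total)}, {"c1": np.full(length, contam)})

    def test_union_overlap_length(self):
        gene = make_gene("g1", "c1", [(100, 200)])
        ev = {"c1": [(120, 150), (140, 170)]}
        total, contam = self._depths()
        rows = per_feature_audit([gene], ev, total, contam)
        gene_row = rows[rows["feature_class"] == "gene"].iloc[0]
        assert gene_row["unique_contam_bp"] == 50
        assert gene_row["contaminated"]

    def test_no_overlap_flags_uncontaminated(self):
        gene = make_gene("g1", "c1", [(100, 200)])
        rows = per_feature_audit([gene], {}, *self._depths())
        assert not rows["contaminated"].any()
        assert (rows[rows["feature_class"] == "gene"]["total_depth"] == 4).all()

    def test_missing_contig_is_hard_error(self):
        gene = make_gene("g1", "cX", [(0, 10)])
        with pytest.raises(KeyError, match="cX"):
            per_feature_audit([gene], {}, {"c1": np.zeros(10)}, {"c1": np.zeros(10)})

    def test_row_count_is_five_per_gene(self):
        gene = make_gene("g1", "c1", [(100, 200)])  # single exon -> no introns
        rows = per_feature_audit([gene], {}, *self._depths())
        assert len(rows) == 5
        intron = rows[rows["feature_class"] == "intron"].iloc[0]
        assert intron["unique_contam_bp"] == 0 and not intron["contaminated"]

    def test_matches_per_base_brute_force(self, rng):
        length = 400
        for _ in range(25):
            exon_cuts = np.sort(rng.choice(np.arange(10, length - 10), size=4, replace=False))
            gene = make_gene("g1", "c1",
                             [(int(exon_cuts[0]), int(exon_cuts[1])),
                              (int(exon_cuts[2]), int(exon_cuts[3]))])
            ev_pairs = []
            for _ in range(int(rng.integers(0, 5))):
                s = int(rng.integers(0, length - 1))
                ev_pairs.append((s, s + int(rng.integers(1, 80))))
            from binaudit._intervals import merge
            ev = {"c1": merge(ev_pairs)}
            total = {"c1": rng.integers(1, 30, size=length).astype(float)}
            contam = {"c1": rng.integers(0, 5, size=length).astype(float)}
            rows = per_feature_audit([gene], ev, total, contam).set_index("feature_class")
            ev_bases = {b for s, e in ev["c1"] for b in range(s, min(e, length))}
            feats = {
                "gene": set(range(gene.span.start, gene.span.end)),
                "exon": {b for m in gene.mrnas for e_ in m.exons
                         for b in range(e_.start, e_.end)},
                "intron": {b for i in gene.introns() for b in range(i.start, i.end)},
            }
            for fclass, bases in feats.items():
                hit = sorted(bases & ev_bases)
                row = rows.loc[fclass]
                assert row["unique_contam_bp"] == len(hit)
                if hit:
                    assert row["contam_depth"] == pytest.approx(
                        np.mean([contam["c1"][b] for b in hit]))
                    assert row["total_depth"] == pytest.approx(
                        np.mean([total["c1"][b] for b in hit]))
                else:
                    assert row["contam_depth"] == 0.0
                    assert row["total_depth"] == pytest.approx(
                        np.mean([total["c1"][b] for b in sorted(bases)]))

    def test_removing_an_alignment_never_increases_overlap(self, rng):
        genes = [make_gene("g1", "c1", [(50, 150), (200, 300)])]
        placements = [plc(f"b{i}", s := int(rng.integers(0, 300)), s + 60) for i in range(6)]
        alignments = [aln(p.read_id, p.target.start, p.target.end, 60) for p in placements]
        reads = {p.read_id for p in placements}
        total = {"c1": np.ones(400)}
        contam = {"c1": np.ones(400)}
        full_ev = contamination_evidence(placements, alignments, reads)
        full = per_feature_audit(genes, full_ev, total, contam)
        full_bp = full.set_index("feature_class")["unique_contam_bp"]
        for drop in range(len(alignments)):
            sub = alignments[:drop] + alignments[drop + 1:]
            ev = contamination_evidence(placements, sub, reads)
            got = per_feature_audit(genes, ev, total, contam)
            got_bp = got.set_index("feature_class")["unique_contam_bp"]
            assert (got_bp <= full_bp).all()


class TestOlsFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = ols_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response(self):
        fit = ols_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r2 == 0.0

    def test_zero_x_variance_is_hard_error(self):
        with pytest.raises(ValueError, match="variance"):
            ols_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(0, 3, 100)
        y = 0.7 * x + rng.normal(0, 1, 100)
        fit = ols_fit(x, y)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        sse = ((y - intercept - slope * x) ** 2).sum()
        sst = ((y - y.mean()) ** 2).sum()
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)
        assert fit.r2 == pytest.approx(1 - sse / sst, rel=1e-10)


def grid_logistic_oracle(x, y, b0_range, b1_range, steps=41):
    """Coarse-to-fine grid search of the Bernoulli log-likelihood."""
    x, y = np.asarray(x), np.asarray(y)

    def ll(b0, b1):
        z = b0 + b1 * x
        p = 1 / (1 + np.exp(-z))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return (y * np.log(p) + (1 - y) * np.log(1 - p)).sum()

    (lo0, hi0), (lo1, hi1) = b0_range, b1_range
    for _ in range(8):
        g0 = np.linspace(lo0, hi0, steps)
        g1 = np.linspace(lo1, hi1, steps)
        vals = np.array([[ll(a, b) for b in g1] for a in g0])
        i, j = np.unravel_index(vals.argmax(), vals.shape)
        w0, w1 = (hi0 - lo0) / steps, (hi1 - lo1) / steps
        lo0, hi0 = g0[i] - 2 * w0, g0[i] + 2 * w0
        lo1, hi1 = g1[j] - 2 * w1, g1[j] + 2 * w1
    return g0[i], g1[j]


class TestLogisticFit:
    def test_no_effect_data_recovers_logit_of_mean(self):
        # same y-mix at every x by construction
        x = np.repeat(np.arange(10.0), 4)
        y = np.tile([1, 0, 0, 0], 10)
        fit = logistic_fit(x, y)
        assert abs(fit.slope) < 1e-6
        assert fit.intercept == pytest.approx(np.log(0.25 / 0.75), abs=1e-6)
        assert fit.loglik_full >= fit.loglik_null - 1e-9

    def test_one_class_absent_is_hard_error(self):
        with pytest.raises(ValueError, match="class"):
            logistic_fit(np.arange(12.0), np.zeros(12))

    def test_matches_grid_search_oracle(self, rng):
        x = rng.normal(0, 1.5, 120)
        p = 1 / (1 + np.exp(-(0.5 + 1.2 * x)))
        y = (rng.random(120) < p).astype(float)
        fit = logistic_fit(x, y)
        b0, b1 = grid_logistic_oracle(x, y, (-3, 3), (-4, 4))
        assert fit.intercept == pytest.approx(b0, abs=1e-3)
        assert fit.slope == pytest.approx(b1, abs=1e-3)

    def test_llr_pvalue_in_unit_interval(self, rng):
        x = rng.normal(0, 1, 200)
        y = (rng.random(200) < 0.3).astype(float)
        fit = logistic_fit(x, y)
        assert 0.0 <= fit.llr_pvalue <= 1.0
        assert fit.loglik_full >= fit.loglik_null - 1e-9


class TestAuditReport:
    def _rows(self, n_contam, n_clean):
        rows = []
        for i in range(n_contam):
            rows.append((f"g{i}", "gene", 100 + i, 3.0 + i, 15.0 + i, True))
        for i in range(n_clean):
            rows.append((f"h{i}", "gene", 0, 0.0, 20.0, False))
        return pd.DataFrame(
            rows, columns=["gene_id", "feature_class", "unique_contam_bp",
                           "contam_depth", "total_depth", "contaminated"])

    def test_contaminated_gene_percentage(self):
        from binaudit.summary_stats import percent
        assert percent(3_433, 24_494, 0) == 14

    def test_zero_contaminated_rows(self):
        summary, density = audit_report(self._rows(0, 5))
        gene = summary.set_index("feature_class").loc["gene"]
        assert gene["n_contaminated"] == 0
        assert gene["contam_depth_mean"] == 0.0
        assert len(density) == 0
        assert summary.attrs["pct_genes_contaminated"] == 0.0

    def test_means_match_direct_recomputation(self, rng):
        rows = self._rows(12, 30)
        summary, density = audit_report(rows)
        sub = rows[rows["contaminated"]]
        gene = summary.set_index("feature_class").loc["gene"]
        from binaudit.summary_stats import round_half_up
        assert gene["contam_depth_mean"] == round_half_up(sub["contam_depth"].mean(), 2)
        sd = sub["unique_contam_bp"].std(ddof=1)
        assert gene["unique_contam_bp_se"] == round_half_up(sd / np.sqrt(len(sub)), 2)
        assert summary.attrs["pct_genes_contaminated"] == round(100 * 12 / 42)
        assert density["count"].sum() == 12
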