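"""Promoter-map parsing and genome-scale spacer statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twistspacer.errors import InsufficientDataError, PromoterMapFormatError
from twistspacer.genome import (
    PromoterRecord,
    activation_proportion_regression,
    classify_response,
    classify_responses,
    discriminator_gc_comparison,
    filter_promoters,
    read_promoter_map,
    spacer_mean_comparison,
)

MAP_HEADER = (
    "promoter_id\tsigma_factor\ttss\tstrand\tm35_start\tm35_end\tm35_seq"
    "\tm10_start\tm10_end\tm10_seq\tspacer_len\tdiscriminator_seq"
)


def write_map(tmp_path, rows, name="map.tsv"):
    p = tmp_path / name
    p.write_text(MAP_HEADER + "\n" + "\n".join(rows) + "\n")
    return p


def plus_row(pid="p1", spacer=17, sigma="sigma70", disc="ATGCAT"):
    m35_start, m35_end = 100, 105
    m10_start = m35_end + spacer + 1
    m10_end = m10_start + 5
    tss = m10_end + 7
    return (
        f"{pid}\t{sigma}\t{tss}\t+\t{m35_start}\t{m35_end}\tTTGACA"
        f"\t{m10_start}\t{m10_end}\tTATAAT\t{spacer}\t{disc}"
    )


class TestReadPromoterMap:
    def test_valid_rows_parse(self, tmp_path):
        path = write_map(tmp_path, [plus_row("p1", 17), plus_row("p2", 18), plus_row("p3", 19)])
        res = read_promoter_map(path)
        assert len(res.records) == 3
        assert res.n_dropped == 0
        assert res.records[0].spacer_length == 17

    def test_bad_hexamer_dropped(self, tmp_path):
        bad = plus_row("p2").replace("TATAAT", "TATAA")
        path = write_map(tmp_path, [plus_row("p1"), bad])
        res = read_promoter_map(path)
        assert len(res.records) == 1
        assert res.drop_counts["bad_minus10"] == 1

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("promoter_id\tsigma_factor\np1\tsigma70\n")
        with pytest.raises(PromoterMapFormatError):
            read_promoter_map(p)

    def test_duplicate_ids_counted_once(self, tmp_path):
        path = write_map(tmp_path, [plus_row("p1", 17), plus_row("p1", 19)])
        res = read_promoter_map(path)
        assert len(res.records) == 1
        assert res.drop_counts["duplicate_promoter_id"] == 1

    def test_minus_strand_mirror_has_same_spacer(self, tmp_path):
        """A promoter and its reflection through the genomic axis have
        identical spacer lengths."""
        genome_len = 1000
        spacer = 18
        # plus-strand fixture
        m35 = (100, 105)
        m10 = (m35[1] + spacer + 1, m35[1] + spacer + 6)
        tss_p = m10[1] + 7
        plus = (
            f"pp\tsigma70\t{tss_p}\t+\t{m35[0]}\t{m35[1]}\tTTGACA"
            f"\t{m10[0]}\t{m10[1]}\tTATAAT\t{spacer}\tATGC"
        )
        # mirrored coordinates: pos -> genome_len + 1 - pos (start/end swap)
        r = lambda pos: genome_len + 1 - pos
        minus = (
            f"pm\tsigma70\t{r(tss_p)}\t-\t{r(m35[1])}\t{r(m35[0])}\tTTGACA"
            f"\t{r(m10[1])}\t{r(m10[0])}\tTATAAT\t{spacer}\tATGC"
        )
        res = read_promoter_map(write_map(tmp_path, [plus, minus]))
        assert len(res.records) == 2
        from twistspacer.genome import _spacer_gap

        gaps = [
            _spacer_gap(
                {
                    "strand": rec.strand,
                    "m35_start": rec.minus35[0],
                    "m35_end": rec.minus35[1],
                    "m10_start": rec.minus10[0],
                    "m10_end": rec.minus10[1],
                }
            )
            for rec in res.records
        ]
        assert gaps[0] == gaps[1] == spacer


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "logfc, padj, alpha, expected",
        [
            (1.2, 0.01, 0.05, "activated"),
            (-0.8, 0.2, 0.05, "none"),
            (-0.8, 0.07, 0.1, "repressed"),  # relaxed threshold for evolved strains
            (0.0, 0.001, 0.05, "none"),
        ],
    )
    def test_examples(self, logfc, padj, alpha, expected):
        assert classify_response(logfc, padj, alpha) == expected

    def test_invalid_padj_rejected(self):
        with pytest.raises(ValueError):
            classify_response(1.0, 1.5)

    def test_classification_partitions(self, rng):
        df = pd.DataFrame(
            {
                "promoter_id": [f"p{i}" for i in range(200)],
                "logfc": rng.normal(0, 1, 200),
                "padj": rng.uniform(0, 1, 200),
            }
        )
        out = classify_responses(df, alpha=0.05)
        counts = out["response_class"].value_counts()
        assert counts.sum() == 200
        assert set(counts.index) <= {"activated", "none", "repressed"}


def record(pid, spacer, sigma="sigma70", disc=None):
    return PromoterRecord(
        promoter_id=pid,
        sigma_factor=sigma,
        tss=500,
        strand="+",
        minus10=(400, 405, "TATAAT"),
        spacer_length=spacer,
        discriminator_seq=disc,
    )


class TestFilterPromoters:
    def test_sigma_factor_filter(self):
        recs = [record("a", 17), record("b", 17, sigma="sigma38"), record("c", 18)]
        res = filter_promoters(recs)
        assert [r.promoter_id for r in res.records] == ["a", "c"]
        assert res.removed["sigma_factor"] == 1

    def test_length_window_and_16_exclusion(self):
        recs = [record(f"p{n}", n) for n in range(14, 21)]
        res = filter_promoters(recs, exclude_16=True)
        assert sorted(r.spacer_length for r in res.records) == [15, 17, 18, 19]
        res2 = filter_promoters(recs, exclude_16=False)
        assert sorted(r.spacer_length for r in res2.records) == [15, 16, 17, 18, 19]


def responses_frame(pairs):
    return pd.DataFrame(
        [{"promoter_id": pid, "logfc": lf, "padj": pa} for pid, lf, pa in pairs]
    )


class TestSpacerMeanComparison:
    def test_hand_built_groups_match_textbook_t(self):
        """Activated {15,15,17} vs repressed {18,19,19}: the pooled t equals
        the hand-computed two-sample statistic."""
        recs = [record(f"a{i}", n) for i, n in enumerate((15, 15, 17))]
        recs += [record(f"r{i}", n) for i, n in enumerate((18, 19, 19))]
        resp = responses_frame(
            [(f"a{i}", 1.0, 0.01) for i in range(3)]
            + [(f"r{i}", -1.0, 0.01) for i in range(3)]
        )
        out = spacer_mean_comparison(recs, resp)
        # textbook pooled two-sample t computed from scratch
        g1, g2 = np.array([15, 15, 17.0]), np.array([18, 19, 19.0])
        sp2 = ((len(g1) - 1) * g1.var(ddof=1) + (len(g2) - 1) * g2.var(ddof=1)) / (
            len(g1) + len(g2) - 2
        )
        t_hand = (g1.mean() - g2.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_hand = 2 * stats.t.sf(abs(t_hand), 4)
        assert out.t_pooled == pytest.approx(t_hand, abs=1e-12)
        assert out.p_pooled == pytest.approx(p_hand, abs=1e-12)
        assert out.means["activated"] == pytest.approx(g1.mean())
        assert out.counts == {"activated": 3, "none": 0, "repressed": 3}

    def test_empty_group_raises_with_name(self):
        recs = [record("a", 15)]
        resp = responses_frame([("a", 1.0, 0.01)])
        with pytest.raises(InsufficientDataError, match="repressed"):
            spacer_mean_comparison(recs, resp)

    def test_null_p_values_uniform(self, rng):
        """Both groups drawn from the same spacer distribution: the Welch
        p-value is uniform on [0,1] (KS check over 1000 simulations)."""
        pvals = []
        for _ in range(1000):
            a = rng.choice([15, 17, 18, 19], size=30)
            b = rng.choice([15, 17, 18, 19], size=30)
            t, p = stats.ttest_ind(a.astype(float), b.astype(float), equal_var=False)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestProportionRegression:
    def test_all_activated_gives_flat_unit_proportions(self):
        recs = [record(f"p{n}{i}", n) for n in (15, 17, 18, 19) for i in range(5)]
        resp = responses_frame(
            [(f"p{n}{i}", 1.0, 0.01) for n in (15, 17, 18, 19) for i in range(5)]
        )
        out = activation_proportion_regression(recs, resp)
        assert np.allclose(out.table["proportion"], 1.0)
        assert out.slope == pytest.approx(0.0, abs=1e-12)

    def test_exactly_linear_proportions_recovered(self):
        """Proportions constructed to lie on a line over length give back the
        generating slope."""
        recs, rows = [], []
        props = {15: 0.9, 17: 0.7, 18: 0.6, 19: 0.5}  # slope -0.1 per nt
        for n, frac in props.items():
            total = 20
            for i in range(total):
                pid = f"p{n}_{i}"
                recs.append(record(pid, n))
                lf = 1.0 if i < round(frac * total) else -1.0
                rows.append((pid, lf, 0.01))
        out = activation_proportion_regression(recs, responses_frame(rows))
        assert out.slope == pytest.approx(-0.1, abs=1e-12)

    def test_sixteen_excluded_from_regression(self):
        recs = [record(f"p{n}{i}", n) for n in (15, 16, 17) for i in range(4)]
        resp = responses_frame(
            [(f"p{n}{i}", 1.0, 0.01) for n in (15, 16, 17) for i in range(4)]
        )
        out = activation_proportion_regression(recs, resp, exclude_16=True)
        assert 16 not in set(out.table["spacer_len"])

    def test_single_length_insufficient(self):
        recs = [record(f"p{i}", 17) for i in range(5)]
        resp = responses_frame([(f"p{i}", 1.0, 0.01) for i in range(5)])
        with pytest.raises(InsufficientDataError):
            activation_proportion_regression(recs, resp)


class TestDiscriminatorGc:
    def test_extreme_compositions(self):
        recs = [record(f"g{i}", 16, disc="GCGCGC") for i in range(3)]
        recs += [record(f"a{i}", 17, disc="ATATAT") for i in range(3)]
        out = discriminator_gc_comparison(recs)
        assert out.mean_gc_group == 1.0
        assert out.mean_gc_other == 0.0
        assert out.p_value < 0.001

    def test_identical_distributions_mostly_nonsignificant(self, rng):
        """Same GC composition in both groups: significant at alpha = 0.05 in
        <= 7% of simulations."""
        n_sig = 0
        n_runs = 300
        for _ in range(n_runs):
            recs = []
            for i in range(30):
                disc = "".join(rng.choice(list("ACGT"), size=8))
                recs.append(record(f"g{i}", 16, disc=disc))
            for i in range(60):
                disc = "".join(rng.choice(list("ACGT"), size=8))
                recs.append(record(f"o{i}", 17, disc=disc))
            out = discriminator_gc_comparison(recs)
            if out.p_value < 0.05:
                n_sig += 1
        assert n_sig / n_runs <= 0.07

    def test_requires_two_per_group(self):
        recs = [record("g", 16, disc="GCGC"), record("a", 17, disc="ATAT")]
        with pytest.raises(InsufficientDataError):
            discriminator_gc_comparison(recs)
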