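"""Aggregation hierarchy, normality dispatch, comparison designs, reporting."""

import numpy as np
import pandas as pd
import pytest

from astrospat.stats_report import (
    aggregate_to_animal,
    build_report,
    choose_normality_test,
    make_measurement_table,
    normality_pvalue,
    run_comparison,
)


def table_from(records):
    return make_measurement_table(pd.DataFrame(records))


def two_group_rows(values_by_animal, metric="m", region=""):
    rows = []
    for (animal, genotype), vals in values_by_animal.items():
        for v in vals:
            rows.append(
                dict(
                    animal_id=animal,
                    genotype=genotype,
                    region=region,
                    metric_name=metric,
                    value=v,
                )
            )
    return table_from(rows)


class TestAggregate:
    def test_three_images_average(self):
        t = two_group_rows({("a1", "WT"): [1.0, 2.0, 3.0]})
        out = aggregate_to_animal(t)
        assert len(out) == 1
        assert out.loc[0, "value"] == pytest.approx(2.0)
        assert out.loc[0, "n_images"] == 3

    def test_single_image_identity(self):
        t = two_group_rows({("a1", "WT"): [4.2]})
        out = aggregate_to_animal(t)
        assert out.loc[0, "value"] == pytest.approx(4.2)

    def test_matches_groupby_oracle(self, rng):
        rows = []
        for a in range(6):
            for img in range(rng.integers(1, 5)):
                for metric in ("x", "y"):
                    rows.append(
                        dict(
                            animal_id=f"a{a}",
                            genotype="WT" if a < 3 else "HD",
                            region="dm",
                            metric_name=metric,
                            value=float(rng.normal()),
                        )
                    )
        t = table_from(rows)
        out = aggregate_to_animal(t)
        df = pd.DataFrame(rows)
        for r in out.itertuples():
            ref = df[
                (df.animal_id == r.animal_id) & (df.metric_name == r.metric_name)
            ]["value"].mean()
            assert r.value == pytest.approx(ref)

    def test_non_finite_rejected(self):
        t = two_group_rows({("a1", "WT"): [1.0, np.inf]})
        with pytest.raises(ValueError, match="non-finite"):
            aggregate_to_animal(t)


class TestNormalityDispatch:
    @pytest.mark.parametrize(
        "n, expected",
        [(8, "dagostino_pearson"), (20, "dagostino_pearson"), (5, "shapiro_wilk"), (7, "shapiro_wilk"), (3, "shapiro_wilk")],
    )
    def test_dispatch_rule(self, n, expected):
        assert choose_normality_test(n) == expected

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            choose_normality_test(2)

    def test_pvalue_runs_dispatched_test(self, rng):
        name, p = normality_pvalue(rng.normal(size=30))
        assert name == "dagostino_pearson" and 0 <= p <= 1
        name, p = normality_pvalue(rng.normal(size=5))
        assert name == "shapiro_wilk" and 0 <= p <= 1


class TestComparisons:
    def test_identical_groups_not_significant(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        t = two_group_rows(
            {(f"w{i}", "WT"): [v] for i, v in enumerate(vals)}
            | {(f"h{i}", "HD"): [v] for i, v in enumerate(vals)}
        )
        (res,) = run_comparison(t, "m", "two_group_t")
        assert res.statistic == pytest.approx(0.0)
        assert not res.significant

    def test_three_sigma_separation_significant(self):
        rng = np.random.default_rng(0)
        t = two_group_rows(
            {(f"w{i}", "WT"): [float(rng.normal(0, 1))] for i in range(10)}
            | {(f"h{i}", "HD"): [float(rng.normal(3, 1))] for i in range(10)}
        )
        (res,) = run_comparison(t, "m", "two_group_t")
        assert res.significant and res.p_value <= 0.05

    def test_normality_failure_flagged_but_test_reported(self):
        rng = np.random.default_rng(1)
        t = two_group_rows(
            {(f"w{i}", "WT"): [float(rng.exponential() ** 3)] for i in range(12)}
            | {(f"h{i}", "HD"): [float(rng.exponential() ** 3)] for i in range(12)}
        )
        (res,) = run_comparison(t, "m", "two_group_t")
        assert res.normality_test_used == "dagostino_pearson"
        assert res.normality_ok is False
        assert np.isfinite(res.p_value)  # parametric test still run

    def test_paired_t_and_shuffle_invariance(self, rng):
        rows = []
        for i in range(6):
            base = rng.normal(5, 1)
            rows.append(dict(animal_id=f"a{i}", genotype="HD", region="inside", metric_name="d", value=base - 1.0 + rng.normal(0, 0.2)))
            rows.append(dict(animal_id=f"a{i}", genotype="HD", region="outside", metric_name="d", value=base + rng.normal(0, 0.2)))
        t = table_from(rows)
        (res,) = run_comparison(t, "d", "paired_t")
        assert res.df == 5
        assert res.significant
        shuffled = table_from(pd.DataFrame(rows).sample(frac=1, random_state=4))
        (res2,) = run_comparison(shuffled, "d", "paired_t")
        assert res2.p_value == pytest.approx(res.p_value)

    def test_paired_t_requires_balance(self):
        rows = [
            dict(animal_id="a1", genotype="HD", region="inside", metric_name="d", value=1.0),
            dict(animal_id="a1", genotype="HD", region="outside", metric_name="d", value=2.0),
            dict(animal_id="a2", genotype="HD", region="inside", metric_name="d", value=1.5),
        ]
        with pytest.raises(ValueError, match="both conditions"):
            run_comparison(table_from(rows), "d", "paired_t")

    def test_one_way_anova_tukey_structure(self, rng):
        rows = []
        for g, mean in (("a", 0.0), ("b", 0.0), ("c", 4.0)):
            for i in range(8):
                rows.append(
                    dict(animal_id=f"{g}{i}", genotype=g, region="", metric_name="m",
                         value=float(rng.normal(mean, 1)))
                )
        res = run_comparison(table_from(rows), "m", "one_way_anova_tukey")
        omnibus = res[0]
        assert omnibus.test_name == "one-way ANOVA"
        assert omnibus.significant
        pairs = {r.grouping: r for r in res[1:]}
        assert len(pairs) == 3
        assert pairs["genotype: a vs c (Tukey)"].significant
        assert not pairs["genotype: a vs b (Tukey)"].significant

    def test_two_way_anova_sidak(self, rng):
        rows = []
        for g in ("WT", "zQ175"):
            for region in ("dm", "dl", "cm", "cl"):
                shift = 3.0 if (g == "zQ175" and region == "dm") else 0.0
                for i in range(6):
                    rows.append(
                        dict(animal_id=f"{g}{i}", genotype=g, region=region,
                             metric_name="intensity", value=float(rng.normal(shift, 1)))
                    )
        res = run_comparison(table_from(rows), "intensity", "two_way_anova_sidak")
        names = [r.grouping for r in res]
        assert any("interaction" in n or "×" in n for n in names)
        sidak = {r.grouping: r for r in res if "Sidak" in r.grouping}
        assert len(sidak) == 4
        assert sidak["region=dm: WT vs zQ175 (Sidak)"].significant
        assert not sidak["region=cl: WT vs zQ175 (Sidak)"].significant
        for r in res:
            assert 0 <= r.p_value <= 1

    def test_unknown_design_rejected(self):
        t = two_group_rows({("a", "WT"): [1.0]})
        with pytest.raises(ValueError, match="design"):
            run_comparison(t, "m", "anova_of_anovas")


class TestReport:
    def test_empty_input_header_only(self, tmp_path):
        table, text = build_report(pd.DataFrame(), out_dir=tmp_path)
        assert len(table) == 0
        written = pd.read_csv(tmp_path / "measurements.csv")
        assert list(written.columns)  # header exists
        assert len(written) == 0

    def test_round_trip_equal_table(self, tmp_path, rng):
        t = two_group_rows(
            {(f"w{i}", "WT"): list(rng.normal(size=3)) for i in range(4)}
        )
        animal, _ = build_report(t, out_dir=tmp_path)
        back = pd.read_csv(tmp_path / "measurements.csv")
        merged = animal.merge(back, on=["animal_id", "metric_name"], suffixes=("", "_r"))
        assert len(merged) == len(animal)
        np.testing.assert_allclose(merged["value"], merged["value_r"])

    def test_summary_mentions_metrics_and_significance(self):
        t = two_group_rows(
            {(f"w{i}", "WT"): [0.0] for i in range(4)}
            | {(f"h{i}", "HD"): [1.0] for i in range(4)}
        )
        comp = run_comparison(t, "m", "two_group_t")
        _, text = build_report(t, comp)
        assert "## m" in text and "Comparisons" in text
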