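"""Aggregation hierarchy, test dispatch, and tidy reporting.

The unit of analysis is the animal, never the image: per-image measurements
are averaged within each animal (three slices per animal in the original
design) and only the per-animal values enter group comparisons. Normality
testing is dispatched on sample size — D'Agostino–Pearson for n ≥ 8,
Shapiro–Wilk for 3 ≤ n < 8 — and when normality fails the parametric test is
still run, with the failure flagged in the result rather than silently
switching tests. Supported designs: two-group t (two-tailed), paired t,
one-way ANOVA with Tukey post-hoc, two-way ANOVA with Sidak-adjusted
within-level comparisons. Significance is declared at α = 0.05 by default.

The standard tests come from scipy/statsmodels; what is bespoke here is the
dispatch rule, the image → animal → group aggregation order, and the pairing
structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ComparisonResult",
    "MEASUREMENT_COLUMNS",
    "make_measurement_table",
    "aggregate_to_animal",
    "choose_normality_test",
    "normality_pvalue",
    "run_comparison",
    "build_report",
]

MEASUREMENT_COLUMNS = [
    "animal_id",
    "genotype",
    "sex",
    "age_months",
    "region",
    "metric_name",
    "value",
]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    grouping: str
    test_name: str
    statistic: float
    df: float | tuple
    p_value: float
    n_per_group: dict[str, int]
    normality_test_used: str | None = None
    normality_ok: bool | None = None
    alpha: float = ALPHA_DEFAULT

    @property
    def significant(self) -> bool:
        return bool(self.p_value <= self.alpha)


def make_measurement_table(rows: list[dict] | pd.DataFrame) -> pd.DataFrame:
    """Normalize rows into the long measurement format (image level)."""
    df = pd.DataFrame(rows)
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col in ("age_months", "value") else ""
    df = df[MEASUREMENT_COLUMNS].copy()
    df.attrs["aggregation_level"] = df.attrs.get("aggregation_level", "image")
    return df


def aggregate_to_animal(table: pd.DataFrame) -> pd.DataFrame:
    """Average image-level values to one row per (animal, region, metric).

    Arithmetic mean over the images of each animal; the number of images that
    entered each mean is recorded in ``n_images``. Non-finite values are
    rejected rather than silently dropped.
    """
    if table.attrs.get("aggregation_level") == "animal":
        return table
    vals = pd.to_numeric(table["value"], errors="coerce")
    if not np.isfinite(vals).all():
        raise ValueError("measurement table contains non-finite values")
    keys = ["animal_id", "genotype", "sex", "age_months", "region", "metric_name"]
    out = (
        table.assign(value=vals)
        .groupby(keys, dropna=False, sort=False)["value"]
        .agg(value="mean", n_images="size")
        .reset_index()
    )
    out.attrs["aggregation_level"] = "animal"
    return out


def choose_normality_test(n: int) -> str:
    """Sample-size-dispatched normality test name.

    n ≥ 8 → D'Agostino–Pearson; 3 ≤ n < 8 → Shapiro–Wilk; below 3 neither
    test is defined.
    """
    if n < 3:
        raise ValueError(f"normality testing needs n >= 3, got n={n}")
    return "dagostino_pearson" if n >= 8 else "shapiro_wilk"


def normality_pvalue(values: np.ndarray) -> tuple[str, float]:
    """Run the dispatched normality test; returns (test name, p-value)."""
    values = np.asarray(values, dtype=float)
    name = choose_normality_test(len(values))
    if name == "dagostino_pearson":
        p = sps.normaltest(values).pvalue
    else:
        p = sps.shapiro(values).pvalue
    return name, float(p)


def _normality_report(groups: dict[str, np.ndarray], alpha: float):
    used, ok = None, None
    for vals in groups.values():
        if len(vals) >= 3:
            name, p = normality_pvalue(vals)
            used = name if used in (None, name) else "mixed"
            ok = (p > alpha) if ok is None else (ok and p > alpha)
    return used, ok


def run_comparison(
    table: pd.DataFrame,
    metric: str,
    design: str,
    group_col: str = "genotype",
    within_col: str = "region",
    alpha: float = ALPHA_DEFAULT,
) -> list[ComparisonResult]:
    """Compare groups on one metric at animal level under a named design.

    designs: ``two_group_t`` (unpaired two-tailed t), ``paired_t`` (pairs
    matched on ``animal_id`` across the two levels of ``within_col``),
    ``one_way_anova_tukey``, ``two_way_anova_sidak`` (factors ``group_col`` ×
    ``within_col``, with Sidak-adjusted group contrasts within each
    ``within_col`` level on the pooled residual variance).
    """
    df = aggregate_to_animal(table)
    df = df[df["metric_name"] == metric]
    if df.empty:
        raise ValueError(f"no rows for metric {metric!r}")

    if design == "two_group_t":
        levels = sorted(df[group_col].unique())
        if len(levels) != 2:
            raise ValueError(f"two_group_t needs exactly 2 groups, got {levels}")
        a = df.loc[df[group_col] == levels[0], "value"].to_numpy(float)
        b = df.loc[df[group_col] == levels[1], "value"].to_numpy(float)
        res = sps.ttest_ind(a, b)
        used, ok = _normality_report({levels[0]: a, levels[1]: b}, alpha)
        return [
            ComparisonResult(
                metric=metric,
                grouping=f"{group_col}: {levels[0]} vs {levels[1]}",
                test_name="t-test (two-tailed)",
                statistic=float(res.statistic),
                df=float(len(a) + len(b) - 2),
                p_value=float(res.pvalue),
                n_per_group={levels[0]: len(a), levels[1]: len(b)},
                normality_test_used=used,
                normality_ok=ok,
                alpha=alpha,
            )
        ]

    if design == "paired_t":
        levels = sorted(df[within_col].unique())
        if len(levels) != 2:
            raise ValueError(f"paired_t needs exactly 2 conditions, got {levels}")
        wide = df.pivot_table(
            index="animal_id", columns=within_col, values="value", aggfunc="mean"
        )
        if wide[levels].isna().any().any():
            raise ValueError("paired_t requires both conditions for every animal")
        a, b = wide[levels[0]].to_numpy(float), wide[levels[1]].to_numpy(float)
        res = sps.ttest_rel(a, b)
        used, ok = _normality_report({"differences": a - b}, alpha)
        return [
            ComparisonResult(
                metric=metric,
                grouping=f"{within_col}: {levels[0]} vs {levels[1]} (paired)",
                test_name="paired t-test",
                statistic=float(res.statistic),
                df=float(len(a) - 1),
                p_value=float(res.pvalue),
                n_per_group={str(lv): len(a) for lv in levels},
                normality_test_used=used,
                normality_ok=ok,
                alpha=alpha,
            )
        ]

    if design == "one_way_anova_tukey":
        levels = sorted(df[group_col].unique())
        if len(levels) < 2:
            raise ValueError("one-way ANOVA needs >= 2 groups")
        samples = {lv: df.loc[df[group_col] == lv, "value"].to_numpy(float) for lv in levels}
        f = sps.f_oneway(*samples.values())
        used, ok = _normality_report(samples, alpha)
        k = len(levels)
        n_tot = sum(len(v) for v in samples.values())
        out = [
            ComparisonResult(
                metric=metric,
                grouping=f"{group_col} (omnibus)",
                test_name="one-way ANOVA",
                statistic=float(f.statistic),
                df=(k - 1, n_tot - k),
                p_value=float(f.pvalue),
                n_per_group={lv: len(v) for lv, v in samples.items()},
                normality_test_used=used,
                normality_ok=ok,
                alpha=alpha,
            )
        ]
        tk = pairwise_tukeyhsd(
            df["value"].to_numpy(float), df[group_col].to_numpy(), alpha=alpha
        )
        for (g1, g2), p, stat in zip(
            itertools.combinations(tk.groupsunique, 2),
            tk.pvalues,
            tk.meandiffs,
        ):
            out.append(
                ComparisonResult(
                    metric=metric,
                    grouping=f"{group_col}: {g1} vs {g2} (Tukey)",
                    test_name="Tukey HSD",
                    statistic=float(stat),
                    df=(k - 1, n_tot - k),
                    p_value=float(p),
                    n_per_group={str(g1): len(samples[g1]), str(g2): len(samples[g2])},
                    alpha=alpha,
                )
            )
        return out

    if design == "two_way_anova_sidak":
        return _two_way_anova_sidak(df, metric, group_col, within_col, alpha)

    raise ValueError(f"unknown design {design!r}")


def _two_way_anova_sidak(df, metric, group_col, within_col, alpha):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = df.rename(columns={group_col: "g", within_col: "w"})[["g", "w", "value"]].copy()
    model = smf.ols("value ~ C(g) * C(w)", data=d).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    name_map = {
        "C(g)": group_col,
        "C(w)": within_col,
        "C(g):C(w)": f"{group_col} × {within_col}",
    }
    out = []
    for row_name, pretty in name_map.items():
        if row_name not in anova.index:
            continue
        row = anova.loc[row_name]
        out.append(
            ComparisonResult(
                metric=metric,
                grouping=f"{pretty} (main/interaction)",
                test_name="two-way ANOVA",
                statistic=float(row["F"]),
                df=(float(row["df"]), float(anova.loc["Residual", "df"])),
                p_value=float(row["PR(>F)"]),
                n_per_group=d.groupby("g").size().to_dict(),
                alpha=alpha,
            )
        )
    # Sidak-adjusted group contrasts within each level of the second factor,
    # on the pooled residual variance (the multiple-comparison scheme used by
    # common GraphPad-style workflows)
    mse = model.mse_resid
    df_resid = model.df_resid
    g_levels = sorted(d["g"].unique())
    if len(g_levels) == 2:
        w_levels = sorted(d["w"].unique())
        m = len(w_levels)
        for w in w_levels:
            a = d.loc[(d["w"] == w) & (d["g"] == g_levels[0]), "value"].to_numpy(float)
            b = d.loc[(d["w"] == w) & (d["g"] == g_levels[1]), "value"].to_numpy(float)
            if not len(a) or not len(b):
                continue
            se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
            t = (a.mean() - b.mean()) / se
            p_raw = 2 * sps.t.sf(abs(t), df_resid)
            p_adj = float(1 - (1 - p_raw) ** m)  # Sidak over the m comparisons
            out.append(
                ComparisonResult(
                    metric=metric,
                    grouping=f"{within_col}={w}: {g_levels[0]} vs {g_levels[1]} (Sidak)",
                    test_name="two-way ANOVA + Sidak",
                    statistic=float(t),
                    df=float(df_resid),
                    p_value=min(1.0, p_adj),
                    n_per_group={g_levels[0]: len(a), g_levels[1]: len(b)},
                    alpha=alpha,
                )
            )
    return out


def build_report(
    measurements: pd.DataFrame,
    comparisons: list[ComparisonResult] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, str]:
    """Emit the tidy long-format table and a human-readable Markdown summary.

    Returns ``(animal_level_table, summary_markdown)``; when ``out_dir`` is
    given, writes ``measurements.csv`` and ``summary.md`` there.
    """
    table = make_measurement_table(measurements)
    if table["animal_id"].duplicated(keep=False).any():
        pass  # duplicates across images are expected; collisions handled by keys
    animal = aggregate_to_animal(table) if len(table) else table

    lines = ["# Measurement summary", ""]
    if len(animal):
        summary = (
            animal.groupby(["metric_name", "genotype", "region"], dropna=False)["value"]
            .agg(["mean", "sem", "count"])
            .reset_index()
        )
        for metric, grp in summary.groupby("metric_name", sort=True):
            lines.append(f"## {metric}")
            for r in grp.itertuples():
                region = f" [{r.region}]" if r.region else ""
                sem = 0.0 if np.isnan(r.sem) else r.sem
                lines.append(
                    f"- {r.genotype}{region}: {r.mean:.4g} ± {sem:.3g} (n={r.count})"
                )
            lines.append("")
    else:
        lines.append("(no measurements)")
    if comparisons:
        lines.append("## Comparisons")
        for c in comparisons:
            flag = "*" if c.significant else "n.s."
            norm = "" if c.normality_ok in (None, True) else " [normality failed; parametric test reported]"
            lines.append(
                f"- {c.metric} — {c.grouping}: {c.test_name}, stat={c.statistic:.3g}, "
                f"p={c.p_value:.3g} ({flag}){norm}"
            )
    text = "\n".join(lines)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        animal.to_csv(out / "measurements.csv", index=False)
        (out / "summary.md").write_text(text)
    return animal, text
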