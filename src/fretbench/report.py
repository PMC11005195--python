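"""Group statistics, outlier handling and the cross-level summary.

Supported designs mirror the study's statistical toolkit: one-tailed
Student's t (paired/unpaired), Mann-Whitney, one-way ANOVA with Dunnett or
Holm-Sidak post hoc, Kruskal-Wallis with Dunn's post hoc, and a one-sided
chi-square on a 2x2 contingency table. One-tailed directions are always
declared in the design, never inferred from the data. Outliers are removed
by a robust median +/- 3*MAD rule with every exclusion reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MAD_SCALE = 1.4826  # consistency factor: MAD -> sd for normal data


class StatsDesignError(ValueError):
    """Raised for invalid statistical designs or degenerate groups."""


@dataclass
class ComparisonResult:
    test_name: str
    groups: list[str]
    statistic: float
    p_value: float
    direction: str = "two-sided"
    n_per_group: dict[str, int] = field(default_factory=dict)
    excluded_outliers: dict[str, list[float]] = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise StatsDesignError("p-value outside [0, 1]")


@dataclass(frozen=True)
class Design:
    """Declares the test, the one-tailed direction, and post hoc handling.

    ``test`` is one of: t_unpaired, t_paired, mannwhitney, anova_dunnett,
    anova_holm_sidak, kruskal_dunn, chi2_2x2. ``alternative`` for two-group
    tests: "greater" means the first group exceeds the second under H1
    (declare it; it is never inferred from the data). ``control`` names the
    reference group for Dunnett-style comparisons.
    """

    test: str
    alternative: str = "two-sided"
    control: str | None = None
    alpha: float = 0.05


_TWO_GROUP = {"t_unpaired", "t_paired", "mannwhitney"}
_MULTI_GROUP = {"anova_dunnett", "anova_holm_sidak", "kruskal_dunn"}


def _dunn_posthoc(values_by_group: dict[str, np.ndarray], control: str | None) -> pd.DataFrame:
    """Dunn's rank-based post hoc z-tests with tie correction.

    Pairwise z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),
    where ranks are taken over the pooled sample and T corrects for ties;
    two-sided p-values are Holm-adjusted across the comparisons made
    (all pairs, or each group vs. the control when one is named).
    """
    names = list(values_by_group)
    pooled = np.concatenate([values_by_group[g] for g in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, i0 = {}, {}, 0
    for g in names:
        n = values_by_group[g].size
        mean_ranks[g] = ranks[i0 : i0 + n].mean()
        sizes[g] = n
        i0 += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = (
        [(g, control) for g in names if g != control]
        if control is not None
        else [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    )
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        rows.append({"group_1": a, "group_2": b, "statistic": z,
                     "p_raw": 2 * stats.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def compare_groups(
    values_by_group: dict[str, "np.ndarray | list[float]"],
    design: Design,
    contingency: np.ndarray | None = None,
) -> ComparisonResult:
    """Run the declared test on the supplied groups.

    For ``chi2_2x2`` pass the 2x2 ``contingency`` table instead of raw
    values; the one-sided p halves the uncorrected chi-square p when the
    observed association matches the declared direction ("greater": first
    row enriched in the first column), else takes the complementary half.
    """
    if design.test == "chi2_2x2":
        if contingency is None:
            raise StatsDesignError("chi2_2x2 needs a contingency table")
        table = np.asarray(contingency, dtype=float)
        if table.shape != (2, 2):
            raise StatsDesignError("contingency table must be 2x2")
        chi2, p_two, _, expected = stats.chi2_contingency(table, correction=False)
        # association sign: observed vs expected in cell (0, 0)
        matches = table[0, 0] >= expected[0, 0]
        if design.alternative == "two-sided":
            p = p_two
        else:
            wants_positive = design.alternative == "greater"
            p = p_two / 2 if (matches == wants_positive) else 1 - p_two / 2
        return ComparisonResult(
            test_name="chi2_2x2",
            groups=["row_0", "row_1"],
            statistic=float(chi2),
            p_value=float(p),
            direction=design.alternative,
            n_per_group={"row_0": int(table[0].sum()), "row_1": int(table[1].sum())},
        )

    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if any(v.size == 0 for v in groups.values()):
        raise StatsDesignError("every group must be non-empty")
    n_per = {g: int(v.size) for g, v in groups.items()}
    parametric = design.test in {"t_unpaired", "t_paired", "anova_dunnett", "anova_holm_sidak"}
    if parametric and any(v.size < 2 for v in groups.values()):
        raise StatsDesignError("parametric tests need n >= 2 in every group")

    if design.test in _TWO_GROUP:
        if len(groups) != 2:
            raise StatsDesignError(f"{design.test} needs exactly 2 groups")
        (name_a, a), (name_b, b) = groups.items()
        if design.test == "t_unpaired":
            res = stats.ttest_ind(a, b, alternative=design.alternative)
        elif design.test == "t_paired":
            if a.size != b.size:
                raise StatsDesignError("paired t-test needs equal-length groups")
            res = stats.ttest_rel(a, b, alternative=design.alternative)
        else:
            res = stats.mannwhitneyu(a, b, alternative=design.alternative)
        return ComparisonResult(
            test_name=design.test,
            groups=[name_a, name_b],
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            direction=design.alternative,
            n_per_group=n_per,
        )

    if design.test not in _MULTI_GROUP:
        raise StatsDesignError(f"unknown test {design.test!r}")
    if len(groups) < 3:
        raise StatsDesignError(f"{design.test} needs >= 3 groups")
    names = list(groups)
    samples = [groups[g] for g in names]

    if design.test == "kruskal_dunn":
        stat, p = stats.kruskal(*samples)
        posthoc = _dunn_posthoc(groups, design.control)
        name = "kruskal_dunn"
    else:
        stat, p = stats.f_oneway(*samples)
        control = design.control or names[0]
        if control not in groups:
            raise StatsDesignError(f"control group {control!r} not found")
        others = [g for g in names if g != control]
        if design.test == "anova_dunnett":
            # fixed random_state: the Dunnett p-value integrates a
            # multivariate t by quasi-Monte Carlo and must be reproducible
            dres = stats.dunnett(
                *(groups[g] for g in others),
                control=groups[control],
                alternative=design.alternative,
                random_state=np.random.default_rng(0),
            )
            posthoc = pd.DataFrame(
                {
                    "group_1": others,
                    "group_2": control,
                    "statistic": np.atleast_1d(dres.statistic),
                    "p_adj": np.atleast_1d(dres.pvalue),
                }
            )
        else:  # Holm-Sidak adjusted pairwise t vs control
            raws = [
                stats.ttest_ind(groups[g], groups[control], alternative=design.alternative)
                for g in others
            ]
            p_adj = multipletests([r.pvalue for r in raws], method="holm-sidak")[1]
            posthoc = pd.DataFrame(
                {
                    "group_1": others,
                    "group_2": control,
                    "statistic": [r.statistic for r in raws],
                    "p_raw": [r.pvalue for r in raws],
                    "p_adj": p_adj,
                }
            )
        name = design.test
    return ComparisonResult(
        test_name=name,
        groups=names,
        statistic=float(stat),
        p_value=float(p),
        direction=design.alternative,
        n_per_group=n_per,
        posthoc=posthoc,
    )


def remove_outliers(
    values: "np.ndarray | list[float]", method: str = "mad", k: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Robust outlier exclusion: drop points beyond median +/- k*1.4826*MAD.

    Excluded values are returned, never silently dropped. An all-equal
    sample (MAD = 0) excludes nothing.
    """
    if method != "mad":
        raise StatsDesignError(f"unknown outlier method {method!r}")
    vals = np.asarray(values, dtype=float)
    if vals.size < 4:
        raise StatsDesignError("outlier screening needs >= 4 values")
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    if mad == 0:
        return vals.copy(), np.array([])
    keep = np.abs(vals - med) <= k * MAD_SCALE * mad
    return vals[keep], vals[~keep]


def summary_matrix(
    molecular: pd.DataFrame,
    morphological: pd.DataFrame | None,
    groups: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join molecular and morphological readouts per embryo and per group.

    ``molecular`` carries per-embryo E%, R_DA and/or FRET index columns;
    ``morphological`` carries axis ratio and body length. Rows are joined on
    (embryo_id, group). Returns the per-embryo table and per-group medians.
    An empty morphological input yields a molecular-only table (warned).
    """
    mol = molecular.copy()
    if morphological is None or morphological.empty:
        warnings.warn("no morphological input: molecular-only summary", stacklevel=2)
        joined = mol
    else:
        mol_groups = set(mol["group"])
        morph_groups = set(morphological["group"])
        unmatched = mol_groups ^ morph_groups
        if unmatched:
            raise StatsDesignError(f"unmatched group labels: {sorted(unmatched)}")
        joined = mol.merge(morphological, on=["embryo_id", "group"], how="outer")
    if groups is not None:
        missing = set(groups) - set(joined["group"])
        if missing:
            raise StatsDesignError(f"missing groups: {sorted(missing)}")
        joined = joined[joined["group"].isin(groups)]
        joined["group"] = pd.Categorical(joined["group"], categories=groups, ordered=True)
        joined = joined.sort_values("group", kind="stable")
    numeric = joined.select_dtypes("number").columns
    per_group = joined.groupby("group", observed=True)[list(numeric)].median()
    return joined.reset_index(drop=True), per_group
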