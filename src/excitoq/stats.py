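"""Distribution-gated group comparisons and summary statistics.

The reporting convention implemented here gates every comparison on a
D'Agostino–Pearson normality test of each group (α = 0.05):

* any group non-normal, 2 groups  → Mann-Whitney U;
* any group non-normal, > 2 groups → Kruskal-Wallis + Dunn's pairwise test
  (Bonferroni-adjusted, the usual convention for Dunn's procedure);
* all groups normal, 2 groups → Welch's t-test;
* all groups normal, > 2 groups → one-way ANOVA + pairwise t-tests with
  Šidák adjustment;
* repeated (time × group) designs → mixed-design ANOVA followed by Dunnett's
  comparisons of each group against the control, on per-subject means.

Groups smaller than 8 cannot support the normality test; the comparison is
then routed to the nonparametric branch and the audit trail says so.  Every
returned comparison carries a full audit of the branch decision.

Summaries follow the same convention: nonparametric data as median and
interquartile range (linear-interpolation quantiles, the Tukey box-plot
convention), parametric data as mean ± SD / SEM.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "test_group_difference",
    "dunn_posthoc",
    "summarize",
    "MIN_N_FOR_NORMALITY",
]

MIN_N_FOR_NORMALITY = 8
DESIGNS = ("independent_2", "independent_k", "repeated_time_by_group")


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of one gated comparison, with the full branch audit."""

    design: str
    group_labels: list[str]
    group_sizes: dict[str, int]
    normality_p: dict[str, float]
    normality_forced_nonparametric: bool
    chosen_test: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None
    alpha: float
    audit: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        d = {
            "design": self.design,
            "groups": {k: int(v) for k, v in self.group_sizes.items()},
            "normality_p": {k: float(v) for k, v in self.normality_p.items()},
            "normality_forced_nonparametric": self.normality_forced_nonparametric,
            "chosen_test": self.chosen_test,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "alpha": self.alpha,
            "significant": self.significant,
            "audit": list(self.audit),
        }
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d


def _tie_term(ranks_all: np.ndarray) -> float:
    _, counts = np.unique(ranks_all, return_counts=True)
    return float(np.sum(counts**3 - counts))


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    z statistics use the pooled mid-ranks with the standard tie correction;
    two-sided p-values are Bonferroni-adjusted across all pairs by default.
    """
    labels = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in labels]
    all_vals = np.concatenate(values)
    n_total = all_vals.size
    ranks = sps.rankdata(all_vals)
    splits = np.cumsum([v.size for v in values])[:-1]
    rank_groups = np.split(ranks, splits)
    mean_ranks = {g: float(r.mean()) for g, r in zip(labels, rank_groups)}
    tie = _tie_term(all_vals)
    var_factor = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        na = len(np.asarray(groups[a]))
        nb = len(np.asarray(groups[b]))
        se = np.sqrt(var_factor * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p, "p_adj": p_adj})
    return pd.DataFrame(rows)


def _sidak_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        t, p = sps.ttest_ind(groups[a], groups[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(t),
                "p_raw": float(p),
                "p_adj": float(1.0 - (1.0 - p) ** m),
            }
        )
    return pd.DataFrame(rows)


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, pd.DataFrame):
        raise TypeError("pass a mapping of label -> values, or a DataFrame only for repeated designs")
    if not isinstance(groups, dict):
        groups = {f"g{i}": v for i, v in enumerate(groups)}
    return {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}


def test_group_difference(
    groups,
    design: str,
    alpha: float = 0.05,
    control: str | None = None,
) -> GroupComparison:
    """Run the normality-gated comparison ladder on ``groups``.

    ``groups`` is a mapping label → 1-D sample for the independent designs,
    or a long DataFrame with columns ``subject, group, time, value`` for
    ``design="repeated_time_by_group"`` (``control`` names the reference
    group for Dunnett's comparisons; defaults to the first label).
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}, got {design!r}")
    audit: list[str] = []

    if design == "repeated_time_by_group":
        return _repeated_comparison(groups, alpha, control, audit)

    gdict = _as_groups(groups)
    k = len(gdict)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if design == "independent_2" and k != 2:
        raise ValueError(f"design independent_2 with {k} groups (mixed design)")
    if design == "independent_k" and k < 3:
        raise ValueError("design independent_k needs > 2 groups")
    sizes = {g: int(v.size) for g, v in gdict.items()}
    for g, n in sizes.items():
        if n < 3:
            raise ValueError(f"group {g!r} has n={n} < 3")

    # normality gate
    normality_p: dict[str, float] = {}
    forced = any(n < MIN_N_FOR_NORMALITY for n in sizes.values())
    if forced:
        audit.append(
            f"group below n={MIN_N_FOR_NORMALITY}: normality untestable, "
            "nonparametric branch forced"
        )
        normal = False
    else:
        for g, v in gdict.items():
            normality_p[g] = float(sps.normaltest(v).pvalue)
            audit.append(f"D'Agostino-Pearson {g}: p={normality_p[g]:.4g}")
        normal = all(p >= alpha for p in normality_p.values())
        audit.append(
            "all groups consistent with normality" if normal else "normality rejected in >=1 group"
        )

    posthoc = None
    if k == 2:
        a, b = gdict.values()
        if normal:
            stat, p = sps.ttest_ind(a, b, equal_var=False)
            chosen = "welch_t"
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            chosen = "mann_whitney"
    else:
        if normal:
            stat, p = sps.f_oneway(*gdict.values())
            chosen = "one_way_anova_sidak"
            posthoc = _sidak_pairwise(gdict)
        else:
            stat, p = sps.kruskal(*gdict.values())
            chosen = "kruskal_wallis_dunn"
            posthoc = dunn_posthoc(gdict)
    audit.append(f"chosen test: {chosen}")
    return GroupComparison(
        design=design,
        group_labels=list(gdict),
        group_sizes=sizes,
        normality_p=normality_p,
        normality_forced_nonparametric=forced,
        chosen_test=chosen,
        statistic=float(stat),
        p_value=float(p),
        posthoc=posthoc,
        alpha=alpha,
        audit=audit,
    )


def _repeated_comparison(df, alpha: float, control: str | None, audit: list[str]) -> GroupComparison:
    if not isinstance(df, pd.DataFrame):
        raise TypeError("repeated design expects a DataFrame (subject, group, time, value)")
    required = {"subject", "group", "time", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"repeated design needs columns {sorted(required)}")
    import pingouin as pg

    labels = list(dict.fromkeys(df["group"]))
    sizes = df.groupby("group")["subject"].nunique().to_dict()
    if any(n < 3 for n in sizes.values()):
        raise ValueError("every group needs at least 3 subjects")
    aov = pg.mixed_anova(
        data=df, dv="value", within="time", subject="subject", between="group"
    )
    inter = aov.loc[aov["Source"] == "Interaction"]
    grp = aov.loc[aov["Source"] == "group"]
    row = inter if len(inter) else grp
    stat = float(row["F"].iloc[0])
    p = float(row["p_unc"].iloc[0])
    audit.append("mixed-design (repeated-measures) ANOVA, group x time")

    control = control or labels[0]
    subj_means = df.groupby(["group", "subject"])["value"].mean()
    ctrl = subj_means.loc[control].to_numpy()
    others = [g for g in labels if g != control]
    res = sps.dunnett(*[subj_means.loc[g].to_numpy() for g in others], control=ctrl)
    posthoc = pd.DataFrame(
        {
            "group": others,
            "control": control,
            "statistic": np.atleast_1d(res.statistic),
            "p_adj": np.atleast_1d(res.pvalue),
        }
    )
    audit.append(f"Dunnett comparisons vs control {control!r} on subject means")
    audit.append("chosen test: rm_anova_dunnett")
    return GroupComparison(
        design="repeated_time_by_group",
        group_labels=[str(g) for g in labels],
        group_sizes={str(k): int(v) for k, v in sizes.items()},
        normality_p={},
        normality_forced_nonparametric=False,
        chosen_test="rm_anova_dunnett",
        statistic=stat,
        p_value=p,
        posthoc=posthoc,
        alpha=alpha,
        audit=audit,
    )


def summarize(values, distribution: str = "nonparametric") -> dict:
    """Summary in the convention matching the distribution assumption.

    ``nonparametric`` → {median, q1, q3, n} with linear-interpolation
    quantiles; ``parametric`` → {mean, sd, sem, n} with sample sd (ddof=1).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty input")
    if distribution == "nonparametric":
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"median": float(med), "q1": float(q1), "q3": float(q3), "n": int(x.size)}
    if distribution == "parametric":
        sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
        return {
            "mean": float(x.mean()),
            "sd": sd,
            "sem": sd / np.sqrt(x.size),
            "n": int(x.size),
        }
    raise ValueError("distribution must be 'parametric' or 'nonparametric'")
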