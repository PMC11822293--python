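"""Event rates, group comparisons, cross-region correlation and asymmetry.

The statistical unit follows the sensor-level design of the analysis: the
per-channel rate of each subject is averaged across the subjects of a cohort,
and the resulting channel values of a sensor region (11 regions, 19-34
channels each) are compared between cohorts.  Test selection is gated by the
D'Agostino-Pearson normality test at alpha = 0.05: parametric (unpaired t /
one-way ANOVA with Tukey's post hoc) when every compared sample passes,
otherwise nonparametric (Mann-Whitney / Kruskal-Wallis with Dunn's post
hoc).  All tests are two-tailed.

The hemispheric asymmetry index for a lobar pair is

    AI = 200 * (rate_left - rate_right) / (rate_left + rate_right)

bounded in [-200, 200], with the midline (cerebral fissure) sensors excluded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CandidateEvent, events_to_frame
from .layout import REGION_PAIRS, REGIONS, SensorRegionMap

NORMALITY_ALPHA = 0.05

CLASSES = ("ripple", "fast_ripple")


# ---------------------------------------------------------------- rate tables

def compute_rates(
    events: Sequence[CandidateEvent] | pd.DataFrame,
    layout: SensorRegionMap,
    recording_minutes: float,
    subject_id: str = "",
    visit_id: str = "",
) -> pd.DataFrame:
    """Per-channel, per-class event rates for one session.

    Returns one row per (channel, class) over *all* layout channels —
    channels without events appear with rate 0 — with columns
    ``subject_id, visit_id, channel_label, region, class_label, rate,
    recording_minutes``.  Rates are events per minute.
    """
    if recording_minutes <= 0:
        raise ValueError("recording_minutes must be positive")
    frame = (
        events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    )
    known = set(layout.channel_labels)
    if len(frame):
        unknown = set(frame["channel_label"]) - known
        if unknown:
            raise KeyError(f"events on channels not in layout: {sorted(unknown)}")
        counts = (
            frame.groupby(["channel_label", "class_label"]).size()
        )
    else:
        counts = pd.Series(dtype=int)
    rows = []
    for _, lrow in layout.table.iterrows():
        for cls in CLASSES:
            n = int(counts.get((lrow["channel_label"], cls), 0))
            rows.append(
                {
                    "subject_id": subject_id,
                    "visit_id": visit_id,
                    "channel_label": lrow["channel_label"],
                    "region": lrow["region"],
                    "class_label": cls,
                    "rate": n / recording_minutes,
                    "recording_minutes": recording_minutes,
                }
            )
    return pd.DataFrame(rows)


def channelwise_group_matrix(
    tables: Iterable[pd.DataFrame],
    group_assignment: Mapping[str, str],
) -> pd.DataFrame:
    """Average each channel's rate across the subjects of each group.

    ``group_assignment`` maps subject_id -> group name; every subject in the
    tables must be assigned.  Returns columns ``group, class_label,
    channel_label, region, mean_rate``; the channel values of one region are
    the samples each regional comparison runs on.
    """
    cat = pd.concat(list(tables), ignore_index=True)
    missing = set(cat["subject_id"]) - set(group_assignment)
    if missing:
        raise KeyError(f"subjects without a group: {sorted(missing)}")
    cat = cat.assign(group=cat["subject_id"].map(group_assignment))
    # average within subject first (multiple visits), then across subjects
    per_subject = (
        cat.groupby(
            ["group", "subject_id", "class_label", "channel_label", "region"],
            sort=False,
        )["rate"].mean().reset_index()
    )
    out = (
        per_subject.groupby(
            ["group", "class_label", "channel_label", "region"], sort=False
        )["rate"].mean().reset_index().rename(columns={"rate": "mean_rate"})
    )
    return out


# ------------------------------------------------------- regional comparisons

@dataclass
class RegionalComparison:
    region: str
    class_label: str
    groups: tuple[str, ...]
    test_used: str            # t_unpaired | mann_whitney | anova_tukey |
    #                           kruskal_dunn | t_one_sample
    statistic: float
    p_value: float
    group_means: dict[str, float] = field(default_factory=dict)
    posthoc: dict[tuple[str, str], float] | None = None
    degenerate: bool = False


def _is_normalish(x: np.ndarray) -> bool:
    """D'Agostino-Pearson gate; constant samples count as non-normal."""
    if x.size < 8 or np.ptp(x) == 0:
        return False
    return sps.normaltest(x).pvalue > NORMALITY_ALPHA


def dunn_posthoc(
    samples: Mapping[str, np.ndarray]
) -> dict[tuple[str, str], float]:
    """Dunn's multiple-comparisons test after Kruskal-Wallis.

    Rank-sum z statistics on the pooled (tie-averaged) ranks with the
    standard tie correction; two-sided p-values Bonferroni-adjusted for the
    number of pairwise comparisons.
    """
    names = list(samples)
    pooled = np.concatenate([np.asarray(samples[g], dtype=float) for g in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        n = len(samples[g])
        mean_ranks[g] = float(np.mean(ranks[start: start + n]))
        sizes[g] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    out = {}
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)
        out[(a, b)] = float(p)
    return out


def _compare_samples(
    samples: dict[str, np.ndarray], region: str, class_label: str
) -> RegionalComparison:
    names = tuple(samples)
    arrays = [np.asarray(samples[g], dtype=float) for g in names]
    means = {g: float(np.mean(a)) for g, a in zip(names, arrays)}
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return RegionalComparison(
            region=region, class_label=class_label, groups=names,
            test_used="degenerate", statistic=0.0, p_value=float("nan"),
            group_means=means, degenerate=True,
        )
    normal = all(_is_normalish(a) for a in arrays)
    posthoc = None
    if len(names) == 2:
        if normal:
            res = sps.ttest_ind(arrays[0], arrays[1])
            test = "t_unpaired"
        else:
            res = sps.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
            test = "mann_whitney"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if normal:
            res = sps.f_oneway(*arrays)
            tk = sps.tukey_hsd(*arrays)
            posthoc = {
                (names[i], names[j]): float(tk.pvalue[i, j])
                for i, j in itertools.combinations(range(len(names)), 2)
            }
            test = "anova_tukey"
        else:
            res = sps.kruskal(*arrays)
            posthoc = dunn_posthoc(dict(zip(names, arrays)))
            test = "kruskal_dunn"
        stat, p = float(res.statistic), float(res.pvalue)
    return RegionalComparison(
        region=region, class_label=class_label, groups=names,
        test_used=test, statistic=stat, p_value=p, group_means=means,
        posthoc=posthoc,
    )


def compare_regions(
    matrix: pd.DataFrame,
    regions: Sequence[str] | None = None,
    classes: Sequence[str] = CLASSES,
) -> list[RegionalComparison]:
    """Region-by-region group comparison of channel-mean rates.

    ``matrix`` is the output of :func:`channelwise_group_matrix`.  For every
    region and event class the channel values of each group form one sample;
    the normality gate selects the parametric or nonparametric branch
    (see module docstring).  Requires at least 8 channel values per sample.
    """
    regions = list(regions) if regions is not None else list(REGIONS)
    present = set(matrix["region"])
    absent = [r for r in regions if r not in present]
    if absent:
        raise KeyError(f"regions absent from the matrix: {absent}")
    groups = sorted(matrix["group"].unique())
    out = []
    for region in regions:
        for cls in classes:
            sel = matrix[(matrix["region"] == region)
                         & (matrix["class_label"] == cls)]
            samples = {}
            for g in groups:
                vals = sel.loc[sel["group"] == g, "mean_rate"].to_numpy()
                if vals.size < 8:
                    raise ValueError(
                        f"region {region}: {vals.size} channel values for "
                        f"group {g!r}; need >= 8 for the normality gate"
                    )
                samples[g] = vals
            out.append(_compare_samples(samples, region, cls))
    return out


def treatment_contrast(
    tables_drug: Iterable[pd.DataFrame],
    tables_placebo: Iterable[pd.DataFrame],
    regions: Sequence[str] | None = None,
    classes: Sequence[str] = CLASSES,
) -> list[RegionalComparison]:
    """Drug-versus-placebo regional comparisons within one group.

    Both arms' rate tables are reduced to channel means (over subjects) and
    compared region by region exactly as two cohorts would be.
    """
    drug = [t.assign(subject_id="drug:" + t["subject_id"].astype(str))
            for t in tables_drug]
    plac = [t.assign(subject_id="placebo:" + t["subject_id"].astype(str))
            for t in tables_placebo]
    assignment = {s: "drug" for t in drug for s in t["subject_id"].unique()}
    assignment.update(
        {s: "placebo" for t in plac for s in t["subject_id"].unique()}
    )
    matrix = channelwise_group_matrix(drug + plac, assignment)
    return compare_regions(matrix, regions=regions, classes=classes)


# --------------------------------------------------- cross-region correlation

def cross_region_spearman(
    tables: Iterable[pd.DataFrame],
    classes: Sequence[str] = CLASSES,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Spearman correlation of regional rates across subjects.

    Per class: subjects' regional mean rates form an (n_subjects x 11)
    matrix; pairwise Spearman rho between regions gives an 11 x 11
    correlation matrix.  A region with identical rates in every subject has
    undefined rho (recorded as NaN).  The summary holds the median and the
    interquartile range of the off-diagonal correlations per class.
    """
    cat = pd.concat(list(tables), ignore_index=True)
    cat = cat[cat["region"] != ""]
    n_subjects = cat["subject_id"].nunique()
    if n_subjects < 3:
        raise ValueError("cross-region correlation needs >= 3 subjects")
    matrices: dict[str, pd.DataFrame] = {}
    summary_rows = []
    for cls in classes:
        sub = cat[cat["class_label"] == cls]
        wide = (
            sub.groupby(["subject_id", "region"])["rate"].mean().unstack()
        ).reindex(columns=list(REGIONS))
        corr = pd.DataFrame(
            np.full((len(REGIONS), len(REGIONS)), np.nan),
            index=list(REGIONS), columns=list(REGIONS),
        )
        for a, b in itertools.combinations(REGIONS, 2):
            x, y = wide[a].to_numpy(), wide[b].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho = np.nan
            else:
                rho = float(sps.spearmanr(x, y).statistic)
            corr.loc[a, b] = corr.loc[b, a] = rho
        np.fill_diagonal(corr.values, 1.0)
        matrices[cls] = corr
        tri = corr.values[np.triu_indices(len(REGIONS), k=1)]
        tri = tri[~np.isnan(tri)]
        q1, med, q3 = (
            np.percentile(tri, [25, 50, 75]) if tri.size else (np.nan,) * 3
        )
        summary_rows.append(
            {
                "class_label": cls,
                "median_rho": med,
                "iqr_low": q1,
                "iqr_high": q3,
                "n_pairs": int(tri.size),
            }
        )
    return matrices, pd.DataFrame(summary_rows)


# ------------------------------------------------------------ asymmetry index

@dataclass(frozen=True)
class AsymmetryResult:
    subject_id: str
    region_pair: str          # C | F | O | P | T | All
    class_label: str
    ai: float

    def __post_init__(self) -> None:
        if abs(self.ai) > 200.0 + 1e-9:
            raise ValueError("AI must lie in [-200, 200]")


def _pair_regions(region_pair: str) -> tuple[list[str], list[str]]:
    if region_pair == "All":
        left = [p[0] for p in REGION_PAIRS.values()]
        right = [p[1] for p in REGION_PAIRS.values()]
        return left, right
    if region_pair not in REGION_PAIRS:
        raise KeyError(
            f"unknown region pair {region_pair!r}; "
            f"expected one of {list(REGION_PAIRS)} or 'All'"
        )
    left, right = REGION_PAIRS[region_pair]
    return [left], [right]


def asymmetry_index(
    table: pd.DataFrame, region_pair: str, class_label: str
) -> AsymmetryResult:
    """Hemispheric asymmetry index for one subject's rate table.

    ``AI = 200 * (L - R) / (L + R)`` where L and R are the hemispheric
    rates: the mean channel rate of the pair's left and right region.
    'All' pools the five lobar pairs with equal regional weight (the mean
    of the five regional means — paired regions differ slightly in channel
    count, and equal weighting keeps a left/right-symmetric subject at
    AI = 0); midline sensors never contribute.  Undefined — and an error —
    when both hemispheric rates are zero.
    """
    left_regions, right_regions = _pair_regions(region_pair)
    sub = table[table["class_label"] == class_label]

    def hemi_rate(regions: list[str]) -> float:
        means = [
            sub.loc[sub["region"] == r, "rate"].mean() for r in regions
        ]
        if any(np.isnan(v) for v in means):
            raise ValueError(f"no channels for region pair {region_pair!r}")
        return float(np.mean(means))

    l_rate = hemi_rate(left_regions)
    r_rate = hemi_rate(right_regions)
    if l_rate == 0.0 and r_rate == 0.0:
        raise ValueError(
            f"asymmetry index undefined: both hemispheric rates are zero "
            f"({region_pair}, {class_label})"
        )
    ai = 200.0 * (l_rate - r_rate) / (l_rate + r_rate)
    subject = str(table["subject_id"].iloc[0]) if len(table) else ""
    return AsymmetryResult(
        subject_id=subject, region_pair=region_pair,
        class_label=class_label, ai=ai,
    )


def asymmetry_table(
    tables: Iterable[pd.DataFrame],
    region_pairs: Sequence[str] = ("C", "F", "O", "P", "T", "All"),
    classes: Sequence[str] = CLASSES,
) -> pd.DataFrame:
    """Per-subject AI values for each lobar pair and class (NaN when
    undefined)."""
    rows = []
    for table in tables:
        for pair in region_pairs:
            for cls in classes:
                try:
                    res = asymmetry_index(table, pair, cls)
                    ai = res.ai
                except ValueError:
                    ai = np.nan
                rows.append(
                    {
                        "subject_id": str(table["subject_id"].iloc[0]),
                        "region_pair": pair,
                        "class_label": cls,
                        "ai": ai,
                    }
                )
    return pd.DataFrame(rows)


def test_asymmetry(
    ai_values: Mapping[str, Sequence[float]],
    region_pair: str = "",
    class_label: str = "",
) -> list[RegionalComparison]:
    """Group-level AI tests for one region pair and class.

    Within each group: two-tailed one-sample t-test of the AI values against
    zero (is there systematic lateralization?).  Between each pair of
    groups: two-tailed unpaired t-test.  Zero-variance samples are an error.
    """
    out = []
    arrays = {g: np.asarray(v, dtype=float) for g, v in ai_values.items()}
    for g, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {g!r}: need >= 2 subjects")
        if np.ptp(a) == 0:
            raise ValueError(f"group {g!r}: zero-variance AI sample")
        res = sps.ttest_1samp(a, 0.0)
        out.append(
            RegionalComparison(
                region=region_pair, class_label=class_label, groups=(g,),
                test_used="t_one_sample", statistic=float(res.statistic),
                p_value=float(res.pvalue),
                group_means={g: float(np.mean(a))},
            )
        )
    for a_name, b_name in itertools.combinations(arrays, 2):
        res = sps.ttest_ind(arrays[a_name], arrays[b_name])
        out.append(
            RegionalComparison(
                region=region_pair, class_label=class_label,
                groups=(a_name, b_name), test_used="t_unpaired",
                statistic=float(res.statistic), p_value=float(res.pvalue),
                group_means={
                    a_name: float(np.mean(arrays[a_name])),
                    b_name: float(np.mean(arrays[b_name])),
                },
            )
        )
    return out


def comparisons_to_frame(results: Sequence[RegionalComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": r.region,
                "class_label": r.class_label,
                "groups": "|".join(r.groups),
                "test_used": r.test_used,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "degenerate": r.degenerate,
                **{f"mean_{g}": m for g, m in r.group_means.items()},
            }
            for r in results
        ]
    )
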