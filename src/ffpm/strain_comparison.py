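"""Per-substrate inference and census statistics.

Each of the 95 carbon sources is compared between the infected (EHB+) and
cured (EHB-) strains by a two-sided Welch t-test on the day-7 replicate-mean
turbidity, with Benjamini-Hochberg control of the false discovery rate across
all substrates on which at least one strain showed measurable growth
(substrates negligible for both strains are not tested; their adjusted p is
absent, not 1). Each substrate is then classified into one of five outcomes,
and the census aggregates the classification into the headline counts
(substrates used per strain, significantly different, direction of the
difference) and whole-percent shares of 95.

The census is computed from the rule set (thresholds + adjusted p +
direction of the means), never from stored outcome labels, so it can be
reproduced from a printed summary table alone. One consequence, documented
deliberately: "EHB+ higher" counts include outcome-3 substrates (measurable
growth by the infected strain only, with a significant test), because a
strain that grows where the other does not is the extreme case of growing
higher.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .kinetics import GrowthThresholds, endpoint_matrix, is_measurable
from .plate_data import (
    STRAIN_MINUS,
    STRAIN_PLUS,
    WAVELENGTH_TURBIDITY,
    KineticDataset,
    Outcome,
    PlateLayout,
    SubstrateSummary,
)

__all__ = [
    "WelchResult",
    "welch_test",
    "welch_rounding_interval",
    "bh_adjust",
    "classify_outcome",
    "summarize_substrates",
    "CensusReport",
    "census",
]


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> WelchResult:
    """Two-sided Welch (unequal-variance) t-test from summary statistics.

    Returns the absolute t statistic, the Welch-Satterthwaite degrees of
    freedom and the two-sided p-value. The df never exceed ``n1 + n2 - 2``,
    with equality exactly when the per-group standard errors coincide.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch test requires at least 2 observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("degenerate Welch test: both standard deviations are zero")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return WelchResult(t=abs(float(res.statistic)), df=float(df), p=float(res.pvalue))


class WelchInterval(NamedTuple):
    t_min: float
    t_max: float
    df_min: float
    df_max: float


def welch_rounding_interval(
    mean1: float,
    sd1: float,
    mean2: float,
    sd2: float,
    n: int = 5,
    half: float = 0.005,
) -> WelchInterval:
    """Attainable (t, df) interval given means/SDs rounded to +-``half``.

    A summary table printed at two decimals hides the underlying values
    inside +-0.005 bands; recomputing t and df from the printed numbers can
    therefore land well away from the printed statistics. This evaluates the
    extreme t and df reachable from any true values inside those bands
    (equal group sizes ``n``), so a printed row can be checked for internal
    consistency: its printed t and df must fall inside the interval.

    The t extremes come from the extreme numerator |m1 - m2| -+ 2*half over
    the extreme pooled standard error; df is monotone in the variance ratio
    on either side of 1, so the extremes over the SD box are attained at its
    corners, with the maximum 2n - 2 reachable exactly when the two SD bands
    overlap. An SD printed as 0.00 makes the upper t unbounded.
    """
    num = abs(mean1 - mean2)
    num_lo, num_hi = max(0.0, num - 2 * half), num + 2 * half
    s1_lo, s1_hi = max(0.0, sd1 - half), sd1 + half
    s2_lo, s2_hi = max(0.0, sd2 - half), sd2 + half

    def se(a: float, b: float) -> float:
        return math.sqrt((a**2 + b**2) / n)

    se_lo, se_hi = se(s1_lo, s2_lo), se(s1_hi, s2_hi)
    t_max = math.inf if se_lo == 0 else num_hi / se_lo
    t_min = num_lo / se_hi

    def df(a: float, b: float) -> float:
        v1, v2 = a**2 / n, b**2 / n
        if v1 == 0 and v2 == 0:
            return float(2 * (n - 1))  # ratio unconstrained; handled via corners
        if v1 == 0 or v2 == 0:
            return float(n - 1)
        return (v1 + v2) ** 2 / (v1**2 / (n - 1) + v2**2 / (n - 1))

    corners = [df(a, b) for a in (s1_lo, s1_hi) for b in (s2_lo, s2_hi)]
    df_min, df_max = min(corners), max(corners)
    overlap = max(s1_lo, s2_lo) <= min(s1_hi, s2_hi)
    if overlap:  # equal true SDs attainable -> Welch df collapses to 2n - 2
        df_max = float(2 * (n - 1))
    if s1_lo == 0 or s2_lo == 0:  # extreme variance ratios attainable
        df_min = float(n - 1)
    return WelchInterval(t_min=t_min, t_max=t_max, df_min=df_min, df_max=df_max)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Values are capped at 1 and monotone-enforced. Absent entries must be
    excluded by the caller before adjustment.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_outcome(
    mean_plus: float,
    mean_minus: float,
    p_adj: float | None,
    thresholds: GrowthThresholds = GrowthThresholds(),
) -> Outcome:
    """Classify one substrate into the five endpoint outcomes.

    Code 1: both strains negligible (mean <= lower bound). Code 3: infected
    strain measurable, cured strain negligible. Both measurable: code 2 when
    the adjusted p is absent or >= alpha, code 5 (infected higher) or code 4
    (cured higher) when significant. The undefined mirror case (cured strain
    measurable only) is returned as code 4 with the mirror flag set.
    """
    for m, label in ((mean_plus, "EHB+"), (mean_minus, "EHB-")):
        if not np.isfinite(m):
            raise ValueError(f"{label} mean must be finite")
        if m > thresholds.upper:
            raise ValueError(
                f"{label} mean {m} exceeds the measurable upper bound {thresholds.upper}"
            )
    neg_plus = mean_plus <= thresholds.lower
    neg_minus = mean_minus <= thresholds.lower
    if neg_plus and neg_minus:
        return Outcome(code=1)
    if neg_minus:
        return Outcome(code=3)
    if neg_plus:
        return Outcome(code=4, mirror=True)
    significant = p_adj is not None and p_adj < thresholds.alpha
    if not significant:
        return Outcome(code=2)
    if mean_plus > mean_minus:
        return Outcome(code=5)
    if mean_minus > mean_plus:
        return Outcome(code=4)
    raise ValueError("significant difference with exactly equal means is undefined")


def summarize_substrates(
    dataset: KineticDataset,
    layout: PlateLayout,
    thresholds: GrowthThresholds = GrowthThresholds(),
    wavelength: int = WAVELENGTH_TURBIDITY,
) -> list[SubstrateSummary]:
    """Endpoint means, Welch tests, BH adjustment and outcome per substrate.

    Covers the 95 non-control substrates. The BH adjustment runs across
    exactly the substrates where at least one strain's endpoint mean exceeds
    the lower growth bound; both-negligible substrates keep an absent
    adjusted p, matching the printed NA convention.
    """
    table = endpoint_matrix(
        dataset, layout, wavelength=wavelength, time=thresholds.endpoint_day
    )
    plus = table.loc[STRAIN_PLUS]
    minus = table.loc[STRAIN_MINUS]
    n_plus, n_minus = len(plus), len(minus)

    rows: list[SubstrateSummary] = []
    tested_idx: list[int] = []
    raw_ps: list[float] = []
    for i, substrate in enumerate(table.columns):
        mp, sp = float(plus[substrate].mean()), float(plus[substrate].std(ddof=1))
        mm, sm = float(minus[substrate].mean()), float(minus[substrate].std(ddof=1))
        if sp == 0 and sm == 0:
            t = df = p_raw = None
        else:
            t, df, p_raw = welch_test(mp, sp, n_plus, mm, sm, n_minus)
        row = SubstrateSummary(
            substrate=substrate,
            substrate_class=layout.class_of(substrate),
            mean_plus=mp,
            sd_plus=sp,
            mean_minus=mm,
            sd_minus=sm,
            t=t,
            df=df,
            p_raw=p_raw,
        )
        rows.append(row)
        tested = not (mp <= thresholds.lower and mm <= thresholds.lower)
        if tested and p_raw is not None:
            tested_idx.append(i)
            raw_ps.append(p_raw)

    adjusted = bh_adjust(raw_ps)
    for i, p_adj in zip(tested_idx, adjusted):
        rows[i].p_adj = float(p_adj)
    for row in rows:
        row.outcome = classify_outcome(
            row.mean_plus, row.mean_minus, row.p_adj, thresholds
        )
    return rows


@dataclass(frozen=True)
class CensusReport:
    """Headline counts over the 95 substrates, rule-based.

    ``n_plus_higher`` and ``n_minus_higher`` partition the significant
    substrates by direction of the mean difference; percentages are whole
    percents of 95.
    """

    n_substrates: int
    used_plus: int
    used_minus: int
    n_significant: int
    n_plus_higher: int
    n_minus_higher: int
    n_no_difference: int
    n_plus_only: int
    n_negligible_both: int
    pct_plus_higher: int
    pct_minus_higher: int
    pct_significant: int
    per_class_fractions: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_substrates",
                "used_plus",
                "used_minus",
                "n_significant",
                "n_plus_higher",
                "n_minus_higher",
                "n_no_difference",
                "n_plus_only",
                "n_negligible_both",
                "pct_plus_higher",
                "pct_minus_higher",
                "pct_significant",
            )
        }
        d["per_class_fractions"] = dict(self.per_class_fractions)
        return d


def _pct(count: int, total: int) -> int:
    """Percent of ``total`` rounded to the nearest whole percent."""
    return int(round(100 * count / total))


def census(
    rows: Sequence[SubstrateSummary],
    thresholds: GrowthThresholds = GrowthThresholds(),
) -> CensusReport:
    """Rule-based census over the 95 non-control substrates.

    Buckets are recomputed from means, thresholds and adjusted p-values (not
    from stored outcome labels), so a printed summary table is a sufficient
    input. The water control must not be present.
    """
    rows = list(rows)
    if any(r.substrate.lower() == "water" for r in rows):
        raise ValueError("census input must exclude the water control row")
    n = len(rows)

    def measurable(m: float) -> bool:
        return is_measurable(m, thresholds)

    def significant(r: SubstrateSummary) -> bool:
        return r.p_adj is not None and r.p_adj < thresholds.alpha

    used_plus = sum(measurable(r.mean_plus) for r in rows)
    used_minus = sum(measurable(r.mean_minus) for r in rows)
    sig = [r for r in rows if significant(r)]
    n_plus_higher = sum(r.mean_plus > r.mean_minus for r in sig)
    n_minus_higher = sum(r.mean_minus > r.mean_plus for r in sig)
    n_plus_only = sum(
        measurable(r.mean_plus) and r.mean_minus <= thresholds.lower for r in rows
    )
    n_negligible_both = sum(
        r.mean_plus <= thresholds.lower and r.mean_minus <= thresholds.lower
        for r in rows
    )
    n_no_difference = sum(
        measurable(r.mean_plus) and measurable(r.mean_minus) and not significant(r)
        for r in rows
    )

    per_class: dict[str, float] = {}
    classes = sorted({r.substrate_class for r in rows})
    for cls in classes:
        members = [r for r in rows if r.substrate_class == cls]
        hits = sum(significant(r) and r.mean_plus > r.mean_minus for r in members)
        per_class[cls] = hits / len(members)

    return CensusReport(
        n_substrates=n,
        used_plus=used_plus,
        used_minus=used_minus,
        n_significant=len(sig),
        n_plus_higher=n_plus_higher,
        n_minus_higher=n_minus_higher,
        n_no_difference=n_no_difference,
        n_plus_only=n_plus_only,
        n_negligible_both=n_negligible_both,
        pct_plus_higher=_pct(n_plus_higher, n),
        pct_minus_higher=_pct(n_minus_higher, n),
        pct_significant=_pct(len(sig), n),
        per_class_fractions=per_class,
    )
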