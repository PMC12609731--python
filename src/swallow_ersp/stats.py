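"""Nonparametric statistical battery for the biomarker tables.

Normality (Lilliefors) and homoscedasticity (Levene) screens, a
Kruskal-Wallis omnibus per channel x band, pairwise Mann-Whitney U
post hocs with Cliff's delta, paired C3-vs-C4 Wilcoxon signed-rank
with the rank-biserial correlation, and Pearson chi-square for
demographic contingency tables.  All tests are two-sided at alpha =
0.05 and no multiplicity correction is applied by default (the study
design is exploratory); Holm or Benjamini-Hochberg adjustment is
available behind a flag.

Effect-size orientation: Cliff's delta is positive when the first
sample is stochastically larger; the rank-biserial r is positive when
the first paired sample dominates.  Every result row records the
group order so signs are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors
from statsmodels.stats.multitest import multipletests

ALPHA_LEVEL = 0.05

#: Exact p-value computation for the rank tests below this combined n
#: (no ties); beyond it the tie-corrected normal approximation is used.
EXACT_N_LIMIT = 12


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    effect_size: float | None = None
    effect_type: str | None = None  # "cliffs_delta" | "rank_biserial"
    groups: tuple[str, ...] = ()
    n_per_group: tuple[int, ...] = ()
    alpha_level: float = ALPHA_LEVEL
    note: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.effect_size is not None and not (-1.0 <= self.effect_size <= 1.0):
            raise ValueError(f"effect size {self.effect_size} outside [-1, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_level

    def as_row(self) -> dict:
        return {
            "test": self.test, "statistic": self.statistic,
            "p_value": self.p_value, "effect_size": self.effect_size,
            "effect_type": self.effect_type,
            "groups": "|".join(self.groups),
            "n_per_group": "|".join(map(str, self.n_per_group)),
            "significant": self.significant, "note": self.note,
        }


def _arr(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.size == 0:
        raise ValueError("empty sample")
    return a


def lilliefors_test(sample, label: str = "") -> StatResult:
    """Kolmogorov-Smirnov test of normality with estimated mean and SD."""
    x = _arr(sample)
    if len(x) < 4:
        raise ValueError("Lilliefors needs n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("constant sample has no normality to test")
    stat, p = _sm_lilliefors(x, dist="norm")
    return StatResult(test="lilliefors", statistic=float(stat),
                      p_value=float(min(p, 1.0)), groups=(label,),
                      n_per_group=(len(x),))


def levene_test(samples, labels: tuple[str, ...] = (),
                center: str = "mean") -> StatResult:
    """Levene homoscedasticity test (``center='median'`` gives
    Brown-Forsythe)."""
    arrs = [_arr(s) for s in samples]
    if len(arrs) < 2:
        raise ValueError("Levene needs at least 2 samples")
    stat, p = sps.levene(*arrs, center=center)
    return StatResult(test="levene", statistic=float(stat), p_value=float(p),
                      groups=labels or tuple(f"g{i}" for i in range(len(arrs))),
                      n_per_group=tuple(len(a) for a in arrs))


def kruskal_wallis(samples, labels: tuple[str, ...] = ()) -> StatResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = k - 1)."""
    arrs = [_arr(s) for s in samples]
    if len(arrs) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    for a in arrs:
        if len(a) < 2:
            raise ValueError("each group needs n >= 2")
    if all(np.array_equal(a, arrs[0]) for a in arrs[1:]) and np.ptp(arrs[0]) == 0:
        # identical constant groups: H = 0 by definition, scipy raises
        return StatResult(test="kruskal_wallis", statistic=0.0, p_value=1.0,
                          groups=labels, n_per_group=tuple(map(len, arrs)))
    stat, p = sps.kruskal(*arrs)
    return StatResult(test="kruskal_wallis", statistic=float(stat),
                      p_value=float(p),
                      groups=labels or tuple(f"g{i}" for i in range(len(arrs))),
                      n_per_group=tuple(len(a) for a in arrs))


def cliffs_delta(x, y) -> float:
    """delta = (#{x_i > y_j} - #{x_i < y_j}) / (n_x n_y); positive when
    x is stochastically larger."""
    x, y = _arr(x), _arr(y)
    # O(n log n): for each y_j count x strictly below / above it
    xs = np.sort(x)
    below = np.searchsorted(xs, y, side="left")    # pairs with x_i < y_j
    above = len(x) - np.searchsorted(xs, y, side="right")  # x_i > y_j
    return float((above.sum() - below.sum()) / (len(x) * len(y)))


def mann_whitney_u(x, y, labels: tuple[str, str] = ("x", "y")) -> StatResult:
    """Two-sided Mann-Whitney U with Cliff's delta.

    Exact null enumeration when the combined sample is small and
    tie-free; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x, y = _arr(x), _arr(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) + len(y) <= EXACT_N_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    delta = cliffs_delta(x, y)
    return StatResult(test="mann_whitney_u", statistic=float(res.statistic),
                      p_value=float(res.pvalue), effect_size=delta,
                      effect_type="cliffs_delta", groups=labels,
                      n_per_group=(len(x), len(y)),
                      note=f"method={method}; delta>0 means {labels[0]} larger")


def rank_biserial(paired_x, paired_y) -> float:
    """r = (W+ - W-) / (W+ + W-) on the signed ranks of the nonzero
    differences; positive when x > y dominates."""
    x, y = _arr(paired_x), _arr(paired_y)
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    return float((w_pos - w_neg) / (w_pos + w_neg))


def wilcoxon_signed_rank(paired_x, paired_y,
                         labels: tuple[str, str] = ("x", "y")) -> StatResult:
    """Two-sided Wilcoxon signed-rank test with rank-biserial r.

    Zero differences are dropped (Wilcoxon's original treatment); the
    p-value is exact for few nonzero differences and a normal
    approximation beyond.
    """
    x, y = _arr(paired_x), _arr(paired_y)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero")
    if nz.size < 4:
        raise ValueError("need >= 4 nonzero differences for a p-value")
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (nz.size <= EXACT_N_LIMIT and not has_ties) else "approx"
    res = sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                       method=method)
    r = rank_biserial(x, y)
    return StatResult(test="wilcoxon_signed_rank", statistic=float(res.statistic),
                      p_value=float(res.pvalue), effect_size=r,
                      effect_type="rank_biserial", groups=labels,
                      n_per_group=(len(x), len(y)),
                      note=f"method={method}; r>0 means {labels[0]} larger")


def chi_square_independence(counts, row_labels: tuple[str, ...] = (),
                            col_labels: tuple[str, ...] = ()) -> StatResult:
    """Pearson chi-square of independence, no continuity correction."""
    t = np.asarray(counts, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        raise ValueError("zero marginal row or column")
    stat, p, dof, expected = sps.chi2_contingency(t, correction=False)
    note = ""
    if np.any(expected < 5):
        note = "warning: expected count < 5 in some cell"
    return StatResult(test="chi_square", statistic=float(stat),
                      p_value=float(p),
                      groups=row_labels or tuple(f"r{i}" for i in range(t.shape[0])),
                      n_per_group=tuple(int(v) for v in t.sum(axis=1)),
                      note=note, extra={"dof": int(dof),
                                        "expected": expected.tolist(),
                                        "columns": list(col_labels)})


# ---------------------------------------------------------------------------
# full analysis over biomarker tables


def run_group_analysis(eri_table: pd.DataFrame,
                       li_table: pd.DataFrame | None = None,
                       demographics: dict[str, pd.DataFrame] | None = None,
                       channels: tuple[str, ...] = ("C3", "Cz", "C4"),
                       bands: tuple[str, ...] = ("alpha", "beta"),
                       correction: str | None = None,
                       min_n: int = 4) -> pd.DataFrame:
    """The full statistical battery over an ERI/LI biomarker table.

    Per channel x band: Lilliefors and Levene screens, Kruskal-Wallis
    omnibus, and all pairwise Mann-Whitney U tests with Cliff's delta.
    Per group x band: paired C3-vs-C4 Wilcoxon with rank-biserial r.
    Per band: Kruskal-Wallis (or pairwise Mann-Whitney for two groups)
    on the LI.  Optional contingency tables are tested with Pearson
    chi-square.  ``correction`` in {None, 'holm', 'fdr_bh'} adjusts the
    post-hoc p-values.

    Returns one row per test (see ``StatResult.as_row``), with
    ``context`` identifying what was compared.
    """
    import logging
    logger = logging.getLogger(__name__)

    results: list[tuple[str, StatResult]] = []
    groups = sorted(eri_table["group"].unique())

    def by(group: str, channel: str, band: str) -> np.ndarray:
        sel = ((eri_table["group"] == group)
               & (eri_table["channel"] == channel)
               & (eri_table["band"] == band))
        return eri_table.loc[sel, "eri_db"].to_numpy()

    posthoc_idx: list[int] = []
    for band in bands:
        for ch in channels:
            samples = {g: by(g, ch, band) for g in groups}
            usable = {g: s for g, s in samples.items() if len(s) >= min_n}
            ctx = f"ERI {ch} {band}"
            for g, s in usable.items():
                if np.ptp(s) > 0:
                    results.append((f"{ctx} normality {g}", lilliefors_test(s, g)))
            if len(usable) >= 2:
                results.append((f"{ctx} homoscedasticity",
                                levene_test(list(usable.values()),
                                            tuple(usable))))
            if len(usable) >= 3:
                results.append((f"{ctx} omnibus",
                                kruskal_wallis(list(usable.values()),
                                               tuple(usable))))
            names = list(usable)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    a, b = names[i], names[j]
                    res = mann_whitney_u(usable[a], usable[b], (a, b))
                    posthoc_idx.append(len(results))
                    results.append((f"{ctx} posthoc {a} vs {b}", res))
            skipped = set(samples) - set(usable)
            for g in skipped:
                logger.warning("%s: group %s skipped (n=%d < %d)",
                               ctx, g, len(samples[g]), min_n)

    # paired C3 vs C4 within each group (lateralization of ERD strength)
    for band in bands:
        for g in groups:
            sub = eri_table[(eri_table["group"] == g)
                            & (eri_table["band"] == band)]
            wide = sub.pivot(index="subject_id", columns="channel",
                             values="eri_db")
            if "C3" not in wide or "C4" not in wide:
                continue
            wide = wide.dropna(subset=["C3", "C4"])
            if len(wide) < min_n:
                logger.warning("paired C3-C4 %s %s skipped (n=%d)",
                               g, band, len(wide))
                continue
            try:
                res = wilcoxon_signed_rank(wide["C3"], wide["C4"],
                                           ("C3", "C4"))
            except ValueError as exc:
                logger.warning("paired C3-C4 %s %s: %s", g, band, exc)
                continue
            results.append((f"paired C3 vs C4 {g} {band}", res))

    # LI group comparisons
    if li_table is not None and len(li_table):
        li_ok = li_table[~li_table["denominator_flag"]
                         & np.isfinite(li_table["li"])]
        for band in bands:
            samples = {g: li_ok.loc[(li_ok["group"] == g)
                                    & (li_ok["band"] == band), "li"].to_numpy()
                       for g in groups}
            usable = {g: s for g, s in samples.items() if len(s) >= min_n}
            if len(usable) >= 3:
                results.append((f"LI {band} omnibus",
                                kruskal_wallis(list(usable.values()),
                                               tuple(usable))))
            names = list(usable)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    a, b = names[i], names[j]
                    res = mann_whitney_u(usable[a], usable[b], (a, b))
                    posthoc_idx.append(len(results))
                    results.append((f"LI {band} posthoc {a} vs {b}", res))

    if demographics:
        for name, table in demographics.items():
            res = chi_square_independence(
                table.to_numpy(), tuple(map(str, table.index)),
                tuple(map(str, table.columns)))
            results.append((f"demographics {name}", res))

    if correction:
        pvals = [results[i][1].p_value for i in posthoc_idx]
        if pvals:
            _, adj, _, _ = multipletests(pvals, method=correction)
            for i, p_adj in zip(posthoc_idx, adj):
                ctx, res = results[i]
                res.extra["p_adjusted"] = float(p_adj)
                res.note = (res.note + f"; {correction} p_adj={p_adj:.4g}").strip("; ")

    rows = []
    for ctx, res in results:
        row = {"context": ctx}
        row.update(res.as_row())
        if "p_adjusted" in res.extra:
            row["p_adjusted"] = res.extra["p_adjusted"]
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_report(report: pd.DataFrame) -> str:
    """Human-readable Markdown summary of a statistics report."""
    lines = ["# Group statistics", ""]
    for _, r in report.iterrows():
        eff = ""
        if pd.notna(r.get("effect_size")):
            eff = f", {r['effect_type']}={r['effect_size']:.3f}"
        star = " *" if r["significant"] else ""
        lines.append(f"- {r['context']}: {r['test']} stat={r['statistic']:.4g}, "
                     f"p={r['p_value']:.4g}{eff}{star}")
    lines.append("")
    lines.append(f"(* p < {ALPHA_LEVEL}, two-sided, no multiplicity correction "
                 "unless a p_adjusted column is present)")
    return "\n".join(lines)
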