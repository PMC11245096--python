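"""Two-way ANOVA with sequential sums of squares, % contribution,
significance screening, and Tukey HSD post hoc comparisons.

The decomposition is sequential (Type-I): factor A (lineage) enters first,
then B (habitat), then the A×B interaction, each term's SS being the drop
in residual SS when it is added.  On unbalanced data this is
order-sensitive, so the entry order is explicit and configurable.  Empty
cells are tolerated — term degrees of freedom come from design-matrix rank
increments, so an inestimable interaction simply loses df.

% contribution of a term is its share of total SS *including* the
residual, so contributions over all terms sum to 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import parse_lineage

__all__ = [
    "TermStats",
    "AnovaTable",
    "TukeyPair",
    "TukeyResult",
    "twoway_anova_sequential",
    "percent_contribution",
    "tukey_hsd",
    "oneway_anova",
    "screen_features",
    "binary_trait_screen",
    "within_lineage_tests",
    "FeatureScreenResult",
    "WithinLineageResult",
    "ALPHA_DEFAULT",
]

#: Hard significance screen used throughout.
ALPHA_DEFAULT = 1e-5

_REL_TOL = 1e-8


@dataclass(frozen=True)
class TermStats:
    name: str
    df: int
    ss: float
    f: Optional[float]  # None marks undefined
    p: Optional[float]


@dataclass(frozen=True)
class AnovaTable:
    response: str
    terms: tuple[TermStats, ...]  # (A, B, A:B, residual) in entry order
    pct_contribution: Mapping[str, float] = field(default_factory=dict)

    @property
    def total_ss(self) -> float:
        return sum(t.ss for t in self.terms)

    def term(self, name: str) -> TermStats:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [t.name for t in self.terms],
                "df": [t.df for t in self.terms],
                "ss": [t.ss for t in self.terms],
                "f": [t.f for t in self.terms],
                "p": [t.p for t in self.terms],
                "pct": [self.pct_contribution.get(t.name) for t in self.terms],
            }
        )


def _dummies(labels: np.ndarray) -> np.ndarray:
    """Full-indicator matrix, one column per level (rank handled by lstsq)."""
    levels = pd.unique(labels)
    return (labels[:, None] == levels[None, :]).astype(float)


def _rss_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of the least-squares fit of y on x."""
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return float(resid @ resid), int(rank)


def twoway_anova_sequential(
    y: Sequence[float],
    a: Sequence[str],
    b: Sequence[str],
    *,
    response: str = "y",
    factor_names: tuple[str, str] = ("A", "B"),
) -> AnovaTable:
    """Sequential (Type-I) two-way ANOVA with interaction.

    Parameters
    ----------
    y, a, b
        Response values and the two factor label vectors, equal length.
    factor_names
        Names for the two factors in the output table; the first factor
        named enters the decomposition first.

    Returns
    -------
    AnovaTable
        Terms in entry order plus interaction and residual; F is tested
        against the residual mean square.  A constant response yields all
        zero SS with F and p marked undefined (``None``).

    Raises
    ------
    ValueError
        On length mismatch, fewer observations than fitted cells + 1, or a
        factor with a single level.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=object)
    b = np.asarray(b, dtype=object)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("y, a, b must have equal length")
    if len(pd.unique(a)) < 2 or len(pd.unique(b)) < 2:
        raise ValueError("each factor needs at least 2 levels")
    n = len(y)
    cells = pd.unique(np.asarray([f"{x}\x00{z}" for x, z in zip(a, b)], dtype=object))
    if n < len(cells) + 1:
        raise ValueError(
            f"need at least {len(cells) + 1} observations for {len(cells)} cells"
        )

    intercept = np.ones((n, 1))
    da, db = _dummies(a), _dummies(b)
    dab = np.asarray(
        [da[:, i] * db[:, j] for i in range(da.shape[1]) for j in range(db.shape[1])]
    ).T

    designs = [
        intercept,
        np.hstack([intercept, da]),
        np.hstack([intercept, da, db]),
        np.hstack([intercept, da, db, dab]),
    ]
    rss, ranks = zip(*(_rss_rank(x, y) for x in designs))

    name_a, name_b = factor_names
    term_names = [name_a, name_b, f"{name_a}:{name_b}"]
    ss_terms = [max(rss[i] - rss[i + 1], 0.0) for i in range(3)]
    df_terms = [ranks[i + 1] - ranks[i] for i in range(3)]
    ss_res = rss[3]
    df_res = n - ranks[3]

    constant = rss[0] <= _REL_TOL * max(1.0, float(y @ y))
    ms_res = ss_res / df_res if df_res > 0 else math.nan

    terms: list[TermStats] = []
    for name, ss, df in zip(term_names, ss_terms, df_terms):
        if constant or df == 0 or df_res == 0 or ms_res == 0 or math.isnan(ms_res):
            f_val: Optional[float] = None
            p_val: Optional[float] = None
        else:
            f_val = (ss / df) / ms_res
            p_val = float(stats.f.sf(f_val, df, df_res))
        terms.append(TermStats(name=name, df=df, ss=ss, f=f_val, p=p_val))
    terms.append(TermStats(name="residual", df=df_res, ss=ss_res, f=None, p=None))
    return percent_contribution(AnovaTable(response=response, terms=tuple(terms)))


def percent_contribution(t: AnovaTable) -> AnovaTable:
    """Fill ``pct_contribution``: each term's SS share of the total SS.

    The denominator includes the residual, so shares sum to 100.  A zero
    total leaves every share undefined (NaN).
    """
    total = t.total_ss
    if total <= 0:
        pct = {term.name: math.nan for term in t.terms}
    else:
        pct = {term.name: 100.0 * term.ss / total for term in t.terms}
    return replace(t, pct_contribution=pct)


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    mean_difference: float
    ci_low: float
    ci_high: float
    p_adj: float
    degenerate: bool = False


@dataclass(frozen=True)
class TukeyResult:
    pairs: tuple[TukeyPair, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.pairs])


def tukey_hsd(
    y: Sequence[float], g: Sequence[str], alpha: float = 0.05
) -> TukeyResult:
    """Tukey–Kramer pairwise comparisons of group means.

    For groups *i*, *j*: difference of means, confidence half-width
    ``q(1-alpha; k, df) * sqrt(MSE/2 * (1/n_i + 1/n_j))``, and adjusted p
    from the studentized-range distribution.  With two groups this reduces
    exactly to the pooled two-sample t-test (``q = sqrt(2)|t|``).

    Zero residual variance is handled degenerately: p_adj is 0 or 1 by the
    sign of the difference, intervals collapse, and pairs are flagged.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=object)
    levels = list(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    groups = {lev: y[g == lev] for lev in levels}
    for lev, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {lev!r} is empty")
    n = len(y)
    k = len(levels)
    df_res = n - k
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")
    sse = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values())
    mse = sse / df_res

    pairs: list[TukeyPair] = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = levels[i], levels[j]
            vi, vj = groups[gi], groups[gj]
            diff = float(vi.mean() - vj.mean())
            if mse <= 0:
                pairs.append(
                    TukeyPair(gi, gj, diff, diff, diff,
                              0.0 if diff != 0 else 1.0, degenerate=True)
                )
                continue
            se = math.sqrt(mse / 2.0 * (1.0 / len(vi) + 1.0 / len(vj)))
            q_stat = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q_stat, k, df_res))
            q_crit = float(stats.studentized_range.ppf(1.0 - alpha, k, df_res))
            half = q_crit * se
            pairs.append(
                TukeyPair(gi, gj, diff, diff - half, diff + half,
                          min(max(p_adj, 0.0), 1.0))
            )
    return TukeyResult(pairs=tuple(pairs))


def oneway_anova(y: Sequence[float], g: Sequence[str], *, response: str = "y") -> AnovaTable:
    """One-way ANOVA through the same sequential machinery (single factor)."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=object)
    if len(pd.unique(g)) < 2:
        raise ValueError("factor needs at least 2 levels")
    n = len(y)
    intercept = np.ones((n, 1))
    dg = _dummies(g)
    rss0, rank0 = _rss_rank(intercept, y)
    rss1, rank1 = _rss_rank(np.hstack([intercept, dg]), y)
    df_g = rank1 - rank0
    df_res = n - rank1
    ss_g = max(rss0 - rss1, 0.0)
    constant = rss0 <= _REL_TOL * max(1.0, float(y @ y))
    ms_res = rss1 / df_res if df_res > 0 else math.nan
    if constant or df_res == 0 or ms_res == 0 or math.isnan(ms_res):
        f_val = p_val = None
    else:
        f_val = (ss_g / df_g) / ms_res
        p_val = float(stats.f.sf(f_val, df_g, df_res))
    terms = (
        TermStats("group", df_g, ss_g, f_val, p_val),
        TermStats("residual", df_res, rss1, None, None),
    )
    return percent_contribution(AnovaTable(response=response, terms=terms))


# ---------------------------------------------------------------------------
# Screening drivers over genome tables


@dataclass(frozen=True)
class FeatureScreenResult:
    feature: str
    anova: AnovaTable
    significant_terms: tuple[str, ...]
    tukey: Mapping[str, TukeyResult] = field(default_factory=dict)
    skipped_constant: bool = False


def _class_labels(genomes: pd.DataFrame) -> pd.Series:
    return genomes["lineage"].map(lambda s: parse_lineage(s).at_rank("class"))


def _habitat_binary(genomes: pd.DataFrame) -> pd.Series:
    return np.where(genomes["habitat"] == "soil", "soil", "non-soil")


def screen_features(
    genomes: pd.DataFrame,
    features: Iterable[str],
    grouping: str = "by-class",
    alpha: float = ALPHA_DEFAULT,
    preference_map: Optional[Mapping[str, str]] = None,
    *,
    run_tukey: bool = True,
) -> list[FeatureScreenResult]:
    """Two-way lineage x habitat screen over continuous genome features.

    ``grouping='by-class'`` uses the class name as the lineage factor;
    ``grouping='SPL-vs-NSPL'`` maps classes through ``preference_map``
    (class -> 'SPL'/'NSPL'), dropping unmapped classes.  Habitat is
    binarized soil vs non-soil.  Tukey runs only on significant terms.
    """
    features = list(features)
    missing = [f for f in features if f not in genomes.columns]
    if missing:
        raise ValueError(f"feature column(s) missing: {missing}")
    if grouping == "by-class":
        sub = genomes
        lineage_factor = _class_labels(sub).to_numpy()
    elif grouping == "SPL-vs-NSPL":
        if preference_map is None:
            raise ValueError("grouping 'SPL-vs-NSPL' requires a preference_map")
        cls = _class_labels(genomes)
        keep = cls.isin(preference_map.keys()).to_numpy()
        sub = genomes[keep]
        lineage_factor = cls[keep].map(preference_map).to_numpy()
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    habitat_factor = np.asarray(_habitat_binary(sub))

    results: list[FeatureScreenResult] = []
    for feat in features:
        yv = sub[feat].to_numpy(dtype=float)
        tab = twoway_anova_sequential(
            yv, lineage_factor, habitat_factor,
            response=feat, factor_names=("lineage", "habitat"),
        )
        sig = tuple(
            t.name for t in tab.terms
            if t.p is not None and t.p < alpha and t.name != "residual"
        )
        tukey: dict[str, TukeyResult] = {}
        if run_tukey:
            if "lineage" in sig:
                tukey["lineage"] = tukey_hsd(yv, lineage_factor)
            if "habitat" in sig:
                tukey["habitat"] = tukey_hsd(yv, habitat_factor)
        results.append(
            FeatureScreenResult(feature=feat, anova=tab, significant_terms=sig, tukey=tukey)
        )
    return results


def binary_trait_screen(
    traits: pd.DataFrame,
    lineage: Sequence[str],
    habitat: Sequence[str],
    alpha: float = ALPHA_DEFAULT,
) -> list[FeatureScreenResult]:
    """Apply the same two-way machinery to 0/1 trait columns.

    The dichotomous presence/absence matrix is treated as a numeric 1/0
    response (linear-probability ANOVA).  All-constant traits are skipped
    and flagged rather than fitted.
    """
    lineage = np.asarray(lineage, dtype=object)
    habitat = np.asarray(habitat, dtype=object)
    vals = traits.to_numpy()
    if not np.isin(vals[~pd.isna(vals)], [0, 1]).all():
        raise ValueError("trait matrix entries must be 0 or 1")
    results: list[FeatureScreenResult] = []
    for trait in traits.columns:
        yv = traits[trait].to_numpy(dtype=float)
        if np.all(yv == yv[0]):
            empty = percent_contribution(
                AnovaTable(
                    response=trait,
                    terms=(
                        TermStats("lineage", 0, 0.0, None, None),
                        TermStats("habitat", 0, 0.0, None, None),
                        TermStats("lineage:habitat", 0, 0.0, None, None),
                        TermStats("residual", len(yv) - 1, 0.0, None, None),
                    ),
                )
            )
            results.append(
                FeatureScreenResult(
                    feature=trait, anova=empty, significant_terms=(),
                    skipped_constant=True,
                )
            )
            continue
        tab = twoway_anova_sequential(
            yv, lineage, habitat, response=trait, factor_names=("lineage", "habitat")
        )
        sig = tuple(
            t.name for t in tab.terms
            if t.p is not None and t.p < alpha and t.name != "residual"
        )
        results.append(FeatureScreenResult(feature=trait, anova=tab, significant_terms=sig))
    return results


@dataclass(frozen=True)
class WithinLineageResult:
    class_name: str
    feature: str
    anova: Optional[AnovaTable]
    significant: bool
    indeterminate: bool
    n_soil: int
    n_nonsoil: int


def within_lineage_tests(
    genomes: pd.DataFrame,
    class_name: str,
    features: Iterable[str],
    alpha: float = ALPHA_DEFAULT,
) -> list[WithinLineageResult]:
    """Soil vs non-soil one-way comparison restricted to one class.

    Classes with fewer than 2 genomes on either side yield indeterminate
    results (flagged, never raised).
    """
    features = list(features)
    missing = [f for f in features if f not in genomes.columns]
    if missing:
        raise ValueError(f"feature column(s) missing: {missing}")
    cls = _class_labels(genomes)
    sub = genomes[cls == class_name]
    hab = np.asarray(_habitat_binary(sub))
    n_soil = int((hab == "soil").sum())
    n_nonsoil = int((hab == "non-soil").sum())
    out: list[WithinLineageResult] = []
    for feat in features:
        if n_soil < 2 or n_nonsoil < 2:
            out.append(
                WithinLineageResult(class_name, feat, None, False, True, n_soil, n_nonsoil)
            )
            continue
        tab = oneway_anova(sub[feat].to_numpy(dtype=float), hab, response=feat)
        p = tab.term("group").p
        out.append(
            WithinLineageResult(
                class_name, feat, tab,
                significant=p is not None and p < alpha,
                indeterminate=False,
                n_soil=n_soil, n_nonsoil=n_nonsoil,
            )
        )
    return out
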