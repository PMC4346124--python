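"""Mucin phenotype scoring and the categorical statistics of the study.

Immunostaining percent-positivity for MUC2, MUC5AC, MUC6 and CD10 is
binned into the ordinal scores -, +, ++, +++ at 5 / 30 / 60 % boundaries;
gastric markers (MUC5AC, MUC6) and intestinal markers (MUC2, CD10) then
classify each tumour as pure gastric (G), mixed (GI), complete intestinal
(I) or null (N).  Trend and association tests: Cochran-Armitage for 2 x k
ordered tables, Fisher's exact test for 2 x 2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GASTRIC_MARKERS = ("MUC5AC", "MUC6")
INTESTINAL_MARKERS = ("MUC2", "CD10")
ALL_MARKERS = GASTRIC_MARKERS + INTESTINAL_MARKERS

SCORE_ORDER = ("-", "+", "++", "+++")
# Band boundaries: [0,5) -, [5,30) +, [30,60) ++, [60,100] +++
_BAND_EDGES = (5.0, 30.0, 60.0)

PHENOTYPE_LABELS = ("G", "GI", "I", "N")


@dataclass(frozen=True)
class MarkerScore:
    marker: str
    percent_positive: float
    score: str


@dataclass(frozen=True)
class MucinPhenotype:
    label: str
    gastric_positive: bool
    intestinal_positive: bool


def score_marker(percent_positive: float, marker: str = "") -> MarkerScore:
    """Bin percent positivity into the ordinal -, +, ++, +++ score."""
    p = float(percent_positive)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percent positive out of [0,100]: {p}")
    if p < _BAND_EDGES[0]:
        score = "-"
    elif p < _BAND_EDGES[1]:
        score = "+"
    elif p < _BAND_EDGES[2]:
        score = "++"
    else:
        score = "+++"
    return MarkerScore(marker, p, score)


def classify_phenotype(scores: dict[str, str | MarkerScore]) -> MucinPhenotype:
    """G / GI / I / N from the four marker scores.

    A marker is positive at score >= "+" (>= 5% positive cells).  Gastric
    positivity: MUC5AC and/or MUC6; intestinal positivity: MUC2 and/or
    CD10.  G = gastric only, I = intestinal only, GI = both, N = neither.
    """
    missing = [m for m in ALL_MARKERS if m not in scores]
    if missing:
        raise ValueError(f"missing marker: {missing[0]}")

    def positive(marker: str) -> bool:
        s = scores[marker]
        s = s.score if isinstance(s, MarkerScore) else s
        if s not in SCORE_ORDER:
            raise ValueError(f"invalid score for {marker}: {s!r}")
        return s != "-"

    gastric = any(positive(m) for m in GASTRIC_MARKERS)
    intestinal = any(positive(m) for m in INTESTINAL_MARKERS)
    if gastric and intestinal:
        label = "GI"
    elif gastric:
        label = "G"
    elif intestinal:
        label = "I"
    else:
        label = "N"
    return MucinPhenotype(label, gastric, intestinal)


def classify_from_percentages(row: dict[str, float]) -> MucinPhenotype:
    return classify_phenotype(
        {m: score_marker(row[m], m) for m in ALL_MARKERS}
    )


def cochran_armitage(
    successes, totals, scores=None
) -> tuple[float, float]:
    """Cochran-Armitage trend test for a 2 x k table of ordered groups.

    ``successes[i]`` of ``totals[i]`` positive outcomes in group *i*;
    default group scores 1..k.  Returns (Z, two-sided asymptotic p); Z is
    0 when the outcome proportion is identical across groups and is
    negated when the group order is reversed.
    """
    x = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if x.shape != n.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need 1-D successes/totals for k >= 2 groups")
    if (n <= 0).any():
        raise ValueError("column totals must be > 0")
    if ((x < 0) | (x > n)).any():
        raise ValueError("successes must be within [0, total] per group")
    w = np.arange(1, x.size + 1, dtype=float) if scores is None else np.asarray(
        scores, dtype=float
    )
    N = n.sum()
    pbar = x.sum() / N
    if pbar in (0.0, 1.0):
        raise ValueError("zero-margin table: all outcomes identical")
    num = float((w * x).sum() - pbar * (w * n).sum())
    var = pbar * (1.0 - pbar) * float((n * w**2).sum() - (n * w).sum() ** 2 / N)
    z = num / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(1.0, p))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact test p for a 2 x 2 table.

    Two-sided by probability ordering: sums hypergeometric probabilities
    of all tables with the observed margins that are at most as probable
    as the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("cells must be non-negative")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("cells must be integers")
        t = np.round(t).astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("margins must be positive")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


@dataclass
class PhenotypeReport:
    """Group x phenotype contingency plus trend/exact test results."""

    table: pd.DataFrame  # groups x (G, GI, I, N) counts
    gastric_positive: pd.Series  # per sample, phenotype in {G, GI}
    trend_tests: pd.DataFrame
    fisher_tests: pd.DataFrame


def phenotype_by_group_report(
    phenotypes: pd.Series,
    metadata: pd.DataFrame,
    group_col: str = "vienna_group",
    orderings: list[tuple[str, ...]] | None = None,
    fisher_pairs: list[tuple[str, str]] | None = None,
) -> PhenotypeReport:
    """Phenotype counts per group plus the configured group comparisons.

    The binary outcome for trend/exact tests is "expresses gastric markers"
    (phenotype G or GI) versus not.  ``orderings`` are ordered group tuples
    for Cochran-Armitage; ``fisher_pairs`` are group pairs for Fisher's
    exact test.  Defaults compare low-grade vs high-grade vs invasive
    groups (A vs B, A..Cd trend, and A vs B exact).
    """
    groups = metadata.set_index("sample_id")[group_col]
    unknown = [s for s in phenotypes.index if s not in groups.index]
    if unknown:
        raise ValueError(f"unknown group for samples: {unknown}")
    groups = groups.loc[phenotypes.index]
    present = sorted(groups.unique())

    table = (
        pd.crosstab(groups.rename("group"), phenotypes.rename("phenotype"))
        .reindex(index=present, columns=list(PHENOTYPE_LABELS), fill_value=0)
    )
    gastric = phenotypes.isin(("G", "GI"))

    if phenotypes.empty:
        return PhenotypeReport(
            table, gastric, pd.DataFrame(), pd.DataFrame()
        )
    if orderings is None:
        candidates = [tuple(g for g in ("A", "B") if g in present),
                      tuple(g for g in ("A", "B", "Cm", "Cd") if g in present)]
        orderings = list(dict.fromkeys(t for t in candidates if len(t) >= 2))
    if fisher_pairs is None:
        fisher_pairs = [("A", "B")] if {"A", "B"} <= set(present) else []

    trend_rows = []
    for ordering in orderings:
        succ = [int(gastric[groups == g].sum()) for g in ordering]
        tot = [int((groups == g).sum()) for g in ordering]
        try:
            z, p = cochran_armitage(succ, tot)
        except ValueError as exc:
            trend_rows.append(
                {"ordering": ">".join(ordering), "z": np.nan, "p": np.nan,
                 "note": str(exc)}
            )
            continue
        trend_rows.append(
            {"ordering": ">".join(ordering), "z": z, "p": p, "note": ""}
        )

    fisher_rows = []
    for a, b in fisher_pairs:
        t = np.array(
            [
                [int(gastric[groups == a].sum()), int((~gastric)[groups == a].sum())],
                [int(gastric[groups == b].sum()), int((~gastric)[groups == b].sum())],
            ]
        )
        try:
            p = fisher_exact_2x2(t)
            note = ""
        except ValueError as exc:
            p, note = np.nan, str(exc)
        fisher_rows.append({"group1": a, "group2": b, "p": p, "note": note})

    return PhenotypeReport(
        table, gastric, pd.DataFrame(trend_rows), pd.DataFrame(fisher_rows)
    )
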