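"""Assemblage condition and diversity indices.

The FORAM-Index (FI) scores reef water quality from the functional-group
composition of a benthic foraminiferal assemblage,

    FI = 10 * Ps + Po + 2 * Ph,

where Ps, Po and Ph are the proportions of symbiont-bearing, opportunistic
and smaller heterotrophic foraminifera among the classified specimens.
FI > 4 indicates conditions supporting reef development and coral recovery,
FI in [2, 4] a marginal environment, FI < 2 a stressed one.

Fisher alpha is the log-series diversity parameter linking species richness
S and specimen count N through S = alpha * ln(1 + N / alpha).  Wall-structure
ternary composition expresses each assemblage as percentages of hyaline,
porcellaneous and agglutinated tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import AssemblageMatrix, TaxonAnnotation, ValidationError, island_of

__all__ = [
    "ForamIndexResult",
    "DiversityResult",
    "TernaryComposition",
    "foram_index",
    "foram_index_table",
    "site_foram_index",
    "classify_fi",
    "fisher_alpha",
    "diversity",
    "ternary_composition",
    "ternary_table",
    "indices_table",
]


@dataclass(frozen=True)
class ForamIndexResult:
    sample_id: str
    T: float                 # total classified abundance (specimens or percent mass)
    Ps: float
    Po: float
    Ph: float
    fi: float
    category: str


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    S: int
    N: int
    alpha: float


@dataclass(frozen=True)
class TernaryComposition:
    sample_id: str
    hyaline_pct: float
    porcellaneous_pct: float
    agglutinated_pct: float


def _group_map(annotations: Iterable[TaxonAnnotation]) -> dict[str, TaxonAnnotation]:
    return {a.taxon_id: a for a in annotations}


def classify_fi(fi: float) -> str:
    """Reef-condition category: > 4 reef development, [2, 4] marginal, < 2 stressed."""
    if fi > 4.0:
        return "reef_development"
    if fi < 2.0:
        return "stressed"
    return "marginal"


def foram_index(
    assemblage_row: Mapping[str, float] | pd.Series,
    annotations: Iterable[TaxonAnnotation],
    sample_id: str | None = None,
) -> ForamIndexResult:
    """FORAM-Index of one sample.

    Proportions are computed over classified material only: taxa annotated
    ``unknown`` are excluded from the total T rather than lumped into the
    heterotrophic group (lumping would bias FI toward 2).  The result is
    invariant to uniform rescaling of the row, so percent and count input
    give identical FI.
    """
    row = pd.Series(assemblage_row, dtype=float)
    if sample_id is None:
        sample_id = str(row.name) if row.name is not None else ""
    groups = _group_map(annotations)
    s = o = h = 0.0
    for taxon, value in row.items():
        if value == 0:
            continue
        ann = groups.get(taxon)
        g = ann.functional_group if ann is not None else "unknown"
        if g == "symbiont_bearing":
            s += value
        elif g == "opportunistic":
            o += value
        elif g == "heterotrophic":
            h += value
    T = s + o + h
    if T <= 0:
        raise ValidationError(f"sample {sample_id!r}: no classifiable specimens")
    Ps, Po, Ph = s / T, o / T, h / T
    fi = 10.0 * Ps + Po + 2.0 * Ph
    return ForamIndexResult(sample_id, T, Ps, Po, Ph, fi, classify_fi(fi))


def foram_index_table(
    assemblage: AssemblageMatrix, annotations: Iterable[TaxonAnnotation]
) -> list[ForamIndexResult]:
    annotations = list(annotations)
    return [
        foram_index(assemblage.row(sid), annotations, sample_id=str(sid))
        for sid in assemblage.sample_ids
    ]


def site_foram_index(
    sample_results: Sequence[ForamIndexResult],
    grouping: Mapping[str, str] | None = None,
    method: str = "mean_of_sample_fi",
) -> pd.DataFrame:
    """Aggregate per-sample FI to site (island) level.

    ``mean_of_sample_fi`` (default) averages the per-sample FI values;
    ``pooled_counts`` pools the classified group masses across samples and
    recomputes FI from the pooled proportions.  When no grouping is given,
    sites are derived from sample-id prefixes.
    """
    if method not in ("mean_of_sample_fi", "pooled_counts"):
        raise ValidationError(f"unknown site averaging method {method!r}")
    if not sample_results:
        raise ValidationError("no samples to aggregate")
    if grouping is None:
        grouping = {r.sample_id: island_of(r.sample_id) for r in sample_results}
    missing = [r.sample_id for r in sample_results if r.sample_id not in grouping]
    if missing:
        raise ValidationError(f"samples missing from site grouping: {missing}")
    sites: dict[str, list[ForamIndexResult]] = {}
    for r in sample_results:
        sites.setdefault(grouping[r.sample_id], []).append(r)
    rows = []
    for site, members in sites.items():
        if not members:
            raise ValidationError(f"site {site!r} has no samples")
        if method == "mean_of_sample_fi":
            fi = float(np.mean([m.fi for m in members]))
        else:
            s = sum(m.Ps * m.T for m in members)
            o = sum(m.Po * m.T for m in members)
            h = sum(m.Ph * m.T for m in members)
            T = s + o + h
            fi = (10.0 * s + o + 2.0 * h) / T
        rows.append({"site": site, "n_samples": len(members), "fi": fi,
                     "category": classify_fi(fi)})
    return pd.DataFrame(rows).set_index("site")


def fisher_alpha(S: int, N: int) -> float:
    """Fisher's log-series alpha: the unique root of alpha*ln(1 + N/alpha) = S.

    ``f(alpha) = alpha*ln(1 + N/alpha) - S`` is strictly increasing in alpha
    (its limit is S - N < 0 at alpha -> 0+ and +inf at alpha -> inf for
    S < N), so bracketed root-finding on [1e-8, 1e8] is safe.
    """
    if S < 1:
        raise ValidationError("fisher_alpha requires at least one species")
    if S >= N:
        raise ValidationError(
            f"log-series undefined for S >= N (got S={S}, N={N})"
        )

    def f(a: float) -> float:
        return a * math.log1p(N / a) - S

    return float(brentq(f, 1e-8, 1e8, xtol=1e-14, rtol=8.9e-16, maxiter=200))


def diversity(sample_id: str, S: int, N: int) -> DiversityResult:
    return DiversityResult(sample_id, int(S), int(N), fisher_alpha(S, N))


def ternary_composition(
    assemblage_row: Mapping[str, float] | pd.Series,
    annotations: Iterable[TaxonAnnotation],
    sample_id: str | None = None,
) -> TernaryComposition:
    """Wall-structure percentages, renormalized over classified material."""
    row = pd.Series(assemblage_row, dtype=float)
    if sample_id is None:
        sample_id = str(row.name) if row.name is not None else ""
    walls = {a.taxon_id: a.wall_type for a in annotations}
    totals = {"hyaline": 0.0, "porcellaneous": 0.0, "agglutinated": 0.0}
    for taxon, value in row.items():
        if value == 0:
            continue
        w = walls.get(taxon, "unknown")
        if w in totals:
            totals[w] += value
    T = sum(totals.values())
    if T <= 0:
        raise ValidationError(f"sample {sample_id!r}: no specimens with known wall type")
    return TernaryComposition(
        sample_id,
        100.0 * totals["hyaline"] / T,
        100.0 * totals["porcellaneous"] / T,
        100.0 * totals["agglutinated"] / T,
    )


def ternary_table(
    assemblage: AssemblageMatrix,
    annotations: Iterable[TaxonAnnotation],
    by_island: bool = False,
) -> pd.DataFrame:
    """Per-sample (or island-averaged) ternary wall compositions."""
    annotations = list(annotations)
    rows = []
    for sid in assemblage.sample_ids:
        t = ternary_composition(assemblage.row(sid), annotations, sample_id=str(sid))
        rows.append({
            "sample_id": t.sample_id,
            "hyaline_pct": t.hyaline_pct,
            "porcellaneous_pct": t.porcellaneous_pct,
            "agglutinated_pct": t.agglutinated_pct,
        })
    df = pd.DataFrame(rows).set_index("sample_id")
    if by_island:
        df = df.groupby([island_of(s) for s in df.index]).mean()
        df.index.name = "island_id"
    return df


def indices_table(
    assemblage: AssemblageMatrix,
    annotations: Iterable[TaxonAnnotation],
    specimen_counts: Mapping[str, int] | None = None,
    richness: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Combined per-sample index table.

    Columns: sample_id, S, N, fisher_alpha, T, Ps, Po, Ph, FI, category.
    Fisher alpha needs true richness S and specimen count N; when the matrix
    is in counts mode these default to the observed row richness and total,
    otherwise they must be supplied (percent abundances carry neither).
    Fisher alpha is reported rounded to 2 decimals, matching conventional
    survey tables; FI components keep full precision.
    """
    annotations = list(annotations)
    fi_results = {r.sample_id: r for r in foram_index_table(assemblage, annotations)}
    rows = []
    for sid in assemblage.sample_ids:
        sid = str(sid)
        r = fi_results[sid]
        if specimen_counts is not None and richness is not None:
            S, N = int(richness[sid]), int(specimen_counts[sid])
        elif assemblage.mode == "counts":
            row = assemblage.row(sid)
            S, N = int((row > 0).sum()), int(round(row.sum()))
        else:
            S = N = None
        alpha = round(fisher_alpha(S, N), 2) if S is not None and 1 <= S < N else float("nan")
        rows.append({
            "sample_id": sid,
            "S": S,
            "N": N,
            "fisher_alpha": alpha,
            "T": r.T,
            "Ps": r.Ps,
            "Po": r.Po,
            "Ph": r.Ph,
            "FI": r.fi,
            "category": r.category,
        })
    return pd.DataFrame(rows).set_index("sample_id")
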