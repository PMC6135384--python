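"""Canonical correspondence analysis (CCA) with permutation tests.

CCA ordinates a samples x taxa abundance matrix in the chi-square metric
while constraining the site configuration to the space spanned by a set of
environmental covariates.  Following ter Braak's weighted eigenanalysis:

1. scale the abundance table Y to unit grand total, P = Y / y++, with row
   and column masses r = P 1, c = P' 1;
2. form the standardized residual matrix
   Q_ij = (P_ij - r_i c_j) / sqrt(r_i c_j),
   whose total sum of squares is the total inertia (the chi-square statistic
   of Y divided by its grand total);
3. standardize the environmental variables to zero mean and unit variance in
   the row-mass metric and project Q onto the column space of the row-mass
   weighted environment matrix;
4. the singular value decomposition of the projected matrix gives the
   constrained axes (eigenvalues = squared singular values); the orthogonal
   residual yields the unconstrained axes.

Species scores are reported in scaling 2 (species principal coordinates,
which equal abundance-weighted averages of the linear-combination site
scores); site scores come in both LC (linear combinations of the
environment) and WA (weighted averages of species scores) flavours.

Significance of the constraint is assessed with a permutation test on the
pseudo-F statistic, permuting whole rows of the environment table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AssemblageMatrix, ValidationError

__all__ = [
    "CCAResult",
    "cca",
    "correspondence_analysis",
    "permutation_test",
    "triplot_coordinates",
]

_TOL = 1e-10


@dataclass
class CCAResult:
    """Eigenvalues, scores and inertia partition of a (constrained)
    correspondence analysis."""

    eigenvalues: np.ndarray          # constrained block first, each descending
    n_constrained: int
    site_scores_lc: pd.DataFrame     # standard coordinates, constrained axes
    site_scores_wa: pd.DataFrame
    species_scores: pd.DataFrame     # scaling-2 principal coordinates
    biplot_scores: pd.DataFrame      # env variable x constrained axis
    total_inertia: float
    constrained_inertia: float
    pseudo_F: float | None = None
    permutation_p: float | None = None
    n_permutations: int = 0
    rng_seed: int | None = None

    @property
    def unconstrained_inertia(self) -> float:
        return self.total_inertia - self.constrained_inertia

    def axis_names(self) -> list[str]:
        k = self.n_constrained
        return [f"CCA{i + 1}" for i in range(k)] + [
            f"CA{i + 1}" for i in range(len(self.eigenvalues) - k)
        ]

    def summary(self) -> dict:
        return {
            "eigenvalues": [float(e) for e in self.eigenvalues],
            "n_constrained": self.n_constrained,
            "total_inertia": self.total_inertia,
            "constrained_inertia": self.constrained_inertia,
            "unconstrained_inertia": self.unconstrained_inertia,
            "proportion_explained": self.constrained_inertia / self.total_inertia,
            "pseudo_F": self.pseudo_F,
            "permutation_p": self.permutation_p,
            "n_permutations": self.n_permutations,
            "rng_seed": self.rng_seed,
        }


def _prepare_community(assemblage) -> tuple[np.ndarray, list, list]:
    if isinstance(assemblage, AssemblageMatrix):
        df = assemblage.data
    elif isinstance(assemblage, pd.DataFrame):
        df = assemblage
    else:
        df = pd.DataFrame(np.asarray(assemblage, dtype=float))
    Y = df.to_numpy(dtype=float)
    if (Y < 0).any():
        raise ValidationError("community matrix must be nonnegative")
    rows = Y.sum(axis=1)
    bad = np.nonzero(rows <= 0)[0]
    if bad.size:
        raise ValidationError(f"zero-abundance sample {df.index[bad[0]]!r}")
    cols = Y.sum(axis=0)
    keep = cols > 0
    taxa = [t for t, k in zip(df.columns, keep) if k]
    return Y[:, keep], list(df.index), taxa


def _residual_matrix(Y: np.ndarray):
    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return Q, r, c


def _standardize_env(X: np.ndarray, r: np.ndarray, names) -> np.ndarray:
    """Center and scale env columns in the row-mass metric."""
    mean = r @ X
    Xc = X - mean
    var = r @ (Xc ** 2)
    dead = np.nonzero(var <= _TOL * max(1.0, np.abs(X).max()) ** 2)[0]
    if dead.size:
        raise ValidationError(
            f"no variance in constraints: {[names[j] for j in dead]}"
        )
    return Xc / np.sqrt(var)


def _independent_columns(B: np.ndarray) -> list[int]:
    """Greedy maximal independent column subset, preferring earlier columns."""
    keep: list[int] = []
    basis = np.zeros((B.shape[0], 0))
    for j in range(B.shape[1]):
        col = B[:, j:j + 1]
        if basis.shape[1]:
            proj = basis @ np.linalg.lstsq(basis, col, rcond=None)[0]
            resid = col - proj
        else:
            resid = col
        if np.linalg.norm(resid) > 1e-8 * max(np.linalg.norm(col), 1e-30):
            keep.append(j)
            basis = np.hstack([basis, col])
    return keep


def _flip_axes(U: np.ndarray, V: np.ndarray, anchor: np.ndarray) -> None:
    """Fix the sign of each axis so the anchor entry of largest magnitude is
    positive (in place; U and V flip together so U S V' is unchanged)."""
    for k in range(U.shape[1]):
        idx = int(np.argmax(np.abs(anchor[:, k])))
        if anchor[idx, k] < 0:
            U[:, k] *= -1.0
            V[:, k] *= -1.0
            anchor[:, k] *= -1.0


def cca(
    assemblage,
    environment: pd.DataFrame | np.ndarray | None,
    *,
    n_permutations: int = 0,
    rng_seed: int | None = None,
    drop_collinear: bool = False,
) -> CCAResult:
    """Constrained (or, with ``environment=None``, plain) correspondence
    analysis.

    Parameters
    ----------
    assemblage :
        AssemblageMatrix or DataFrame, samples x taxa, nonnegative, no zero
        rows.  All-zero taxon columns are dropped.
    environment :
        samples x variables table aligned to the assemblage rows.  Variables
        are standardized internally in the row-mass metric.  A rank-deficient
        matrix (after centering) raises an error listing the collinear
        columns unless ``drop_collinear=True``, in which case the dependent
        columns are aliased out of the constraint space with a warning —
        the usual situation when covariates are constant within islands, so
        there are fewer distinct environment rows than variables.  Biplot
        scores are reported for every supplied variable either way.
    n_permutations :
        if > 0, run the pseudo-F permutation test with this many row
        permutations of the environment table.
    """
    Y, sample_ids, taxon_ids = _prepare_community(assemblage)
    Q, r, c = _residual_matrix(Y)
    total_inertia = float((Q ** 2).sum())
    sqrt_r = np.sqrt(r)

    if environment is None:
        # plain CA: all axes unconstrained
        U, s, Vt = np.linalg.svd(Q, full_matrices=False)
        keep = s > _TOL * max(s[0], 1.0) if s.size else s > 0
        U, s, V = U[:, keep], s[keep], Vt[keep].T
        _flip_axes(U, V, (U / sqrt_r[:, None]).copy())
        lc = U / sqrt_r[:, None]
        wa = (Q @ V) / sqrt_r[:, None] / s[None, :]
        species = (V * s[None, :]) / np.sqrt(c)[:, None]
        names = [f"CA{i+1}" for i in range(s.size)]
        return CCAResult(
            eigenvalues=s ** 2,
            n_constrained=0,
            site_scores_lc=pd.DataFrame(lc, index=sample_ids, columns=names),
            site_scores_wa=pd.DataFrame(wa, index=sample_ids, columns=names),
            species_scores=pd.DataFrame(species, index=taxon_ids, columns=names),
            biplot_scores=pd.DataFrame(index=[], columns=names),
            total_inertia=total_inertia,
            constrained_inertia=0.0,
        )

    if isinstance(environment, pd.DataFrame):
        env_names = list(environment.columns)
        if list(environment.index) != list(sample_ids):
            if set(environment.index) != set(sample_ids):
                raise ValidationError(
                    "environment and assemblage sample ids do not match"
                )
            environment = environment.loc[sample_ids]
        X = environment.to_numpy(dtype=float)
    else:
        X = np.asarray(environment, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        env_names = [f"env{j+1}" for j in range(X.shape[1])]
    if X.shape[0] != len(sample_ids):
        raise ValidationError("environment row count does not match assemblage")

    Xs = _standardize_env(X, r, env_names)
    B_full = sqrt_r[:, None] * Xs
    indep = _independent_columns(B_full)
    aliased = [env_names[j] for j in range(B_full.shape[1]) if j not in indep]
    if aliased:
        if not drop_collinear:
            raise ValidationError(
                f"environment matrix is rank deficient; collinear columns: {aliased}"
            )
        warnings.warn(f"aliased collinear constraint(s): {aliased}", stacklevel=2)
    B = B_full[:, indep]
    q = B.shape[1]
    n = len(sample_ids)

    coef, *_ = np.linalg.lstsq(B, Q, rcond=None)
    Q_fit = B @ coef
    U, s, Vt = np.linalg.svd(Q_fit, full_matrices=False)
    keep = s > _TOL * max(s[0] if s.size else 0.0, 1.0)
    U, s, V = U[:, keep], s[keep], Vt[keep].T
    n_constrained = int(s.size)

    Q_res = Q - Q_fit
    Ur, sr, Vrt = np.linalg.svd(Q_res, full_matrices=False)
    keepr = sr > _TOL * max(sr[0] if sr.size else 0.0, 1.0)
    Ur, sr, Vr = Ur[:, keepr], sr[keepr], Vrt[keepr].T

    lc_anchor = (U / sqrt_r[:, None]).copy()
    _flip_axes(U, V, lc_anchor)
    _flip_axes(Ur, Vr, (Ur / sqrt_r[:, None]).copy())

    constrained_inertia = float((s ** 2).sum())
    names = [f"CCA{i+1}" for i in range(n_constrained)] + [
        f"CA{i+1}" for i in range(sr.size)
    ]

    lc = np.hstack([U / sqrt_r[:, None], Ur / sqrt_r[:, None]])
    wa = np.hstack([
        (Q @ V) / sqrt_r[:, None] / s[None, :],
        (Q_res @ Vr) / sqrt_r[:, None] / sr[None, :] if sr.size else
        np.zeros((n, 0)),
    ])
    species = np.hstack([
        (V * s[None, :]) / np.sqrt(c)[:, None],
        (Vr * sr[None, :]) / np.sqrt(c)[:, None],
    ])
    # biplot scores: weighted correlation of standardized env vars with the
    # constrained LC axes (standard coordinates)
    biplot = Xs.T @ (r[:, None] * (U / sqrt_r[:, None]))

    result = CCAResult(
        eigenvalues=np.concatenate([s ** 2, sr ** 2]),
        n_constrained=n_constrained,
        site_scores_lc=pd.DataFrame(lc, index=sample_ids, columns=names),
        site_scores_wa=pd.DataFrame(wa, index=sample_ids, columns=names),
        species_scores=pd.DataFrame(species, index=taxon_ids, columns=names),
        biplot_scores=pd.DataFrame(
            biplot, index=env_names, columns=names[:n_constrained]
        ),
        total_inertia=total_inertia,
        constrained_inertia=constrained_inertia,
    )

    if n_permutations > 0:
        F_obs, p = _permutation_pvalue(Q, r, X, env_names, q, n, n_permutations, rng_seed)
        result.pseudo_F = F_obs
        result.permutation_p = p
        result.n_permutations = n_permutations
        result.rng_seed = rng_seed
    return result


def correspondence_analysis(assemblage) -> CCAResult:
    """Plain (unconstrained) CA of an abundance matrix."""
    return cca(assemblage, None)


def _constrained_ssq(Q: np.ndarray, r: np.ndarray, X: np.ndarray, names) -> float:
    Xs = _standardize_env(X, r, names)
    B = np.sqrt(r)[:, None] * Xs
    coef, *_ = np.linalg.lstsq(B, Q, rcond=None)
    return float(((B @ coef) ** 2).sum())


def _pseudo_F(constrained: float, total: float, q: int, n: int) -> float:
    residual = total - constrained
    if n - q - 1 <= 0:
        raise ValidationError("too few samples for the pseudo-F denominator")
    return (constrained / q) / (residual / (n - q - 1))


def _permutation_pvalue(Q, r, X, names, q, n, n_permutations, rng_seed):
    total = float((Q ** 2).sum())
    F_obs = _pseudo_F(_constrained_ssq(Q, r, X, names), total, q, n)
    rng = np.random.default_rng(rng_seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        F = _pseudo_F(_constrained_ssq(Q, r, X[perm], names), total, q, n)
        if F >= F_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return F_obs, p


def permutation_test(
    assemblage,
    environment,
    n_permutations: int = 999,
    rng_seed: int | None = None,
) -> tuple[float, float]:
    """Pseudo-F permutation test of the environmental constraint.

    pseudo-F = (constrained inertia / q) / (residual inertia / (n - q - 1));
    the null distribution permutes whole sample rows of the environment
    table; p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    Y, sample_ids, _ = _prepare_community(assemblage)
    Q, r, c = _residual_matrix(Y)
    if isinstance(environment, pd.DataFrame):
        names = list(environment.columns)
        X = environment.loc[sample_ids].to_numpy(dtype=float)
    else:
        X = np.asarray(environment, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"env{j+1}" for j in range(X.shape[1])]
    n = X.shape[0]
    Xs = _standardize_env(X, r, names)
    q = len(_independent_columns(np.sqrt(r)[:, None] * Xs))
    return _permutation_pvalue(Q, r, X, names, q, n, n_permutations, rng_seed)


def triplot_coordinates(
    result: CCAResult, axes: tuple[int, int] = (1, 2), sites: str = "wa"
) -> dict[str, pd.DataFrame]:
    """Plain coordinate tables for a triplot on a pair of axes (1-based).

    Returns a dict with ``sites`` (points), ``species`` (points) and
    ``arrows`` (environment vectors, scaled so the longest arrow matches the
    site-score spread for joint display).
    """
    a, b = axes
    if a == b:
        raise ValidationError("triplot needs two distinct axes")
    names = list(result.site_scores_lc.columns)
    for ax in (a, b):
        if not 1 <= ax <= len(names):
            raise ValidationError(f"axis {ax} out of range 1..{len(names)}")
    cols = [names[a - 1], names[b - 1]]
    if sites == "lc":
        site_pts = result.site_scores_lc[cols].copy()
    elif sites == "wa":
        site_pts = result.site_scores_wa[cols].copy()
    else:
        raise ValidationError("sites must be 'lc' or 'wa'")
    species_pts = result.species_scores[cols].copy()
    arrow_cols = [c for c in cols if c in result.biplot_scores.columns]
    arrows = result.biplot_scores[arrow_cols].copy() if arrow_cols else pd.DataFrame()
    if len(arrows) and arrows.to_numpy().size:
        arrow_len = np.linalg.norm(arrows.to_numpy(), axis=1).max()
        spread = np.abs(site_pts.to_numpy()).max()
        if arrow_len > 0:
            arrows = arrows * (spread / arrow_len)
    return {"sites": site_pts, "species": species_pts, "arrows": arrows}
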