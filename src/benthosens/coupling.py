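"""Coupling statistics: community structure and TDI versus the
process-driven sensitivity layers and fishing abrasion.

* Bray-Curtis dissimilarity between station compositions;
* the BIO-ENV procedure: an exhaustive search over subsets of
  environmental variables for the subset whose between-station
  Euclidean distance matrix best rank-correlates (Spearman, on the
  lower-triangle vectors) with the community dissimilarity matrix,
  with a label-permutation test for significance;
* pairwise Spearman correlation tests;
* a Gaussian GLM on the log-transformed TDI with risk and abrasion as
  predictors, and its back-transformed prediction map.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr

from .grids import EnvGrid, combine_masks

__all__ = [
    "DissimilarityMatrix",
    "BioEnvResult",
    "TDIModelFit",
    "community_dissimilarity",
    "bioenv",
    "bioenv_permutation_test",
    "spearman_tests",
    "fit_tdi_glm",
    "predict_tdi_map",
]

MAX_EXHAUSTIVE_VARS = 20


@dataclass
class DissimilarityMatrix:
    """A labelled symmetric dissimilarity matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("dissimilarities must be >= 0")

    def condensed(self) -> np.ndarray:
        """Lower-triangle vector in scipy condensed order."""
        return squareform(self.d, checks=False)


def community_dissimilarity(relative_biomass: pd.DataFrame) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity between station compositions.

    Rows are stations, columns taxa; each row must be a composition
    (non-negative, positive total). Rows are normalised to sum to one
    before the distance so absolute catch size never enters.
    """
    x = relative_biomass.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("relative biomass must be >= 0")
    totals = x.sum(axis=1)
    if np.any(totals == 0):
        empty = list(relative_biomass.index[totals == 0])
        raise ValueError(f"empty station rows: {empty[:5]}")
    x = x / totals[:, None]
    d = squareform(pdist(x, metric="braycurtis"))
    return DissimilarityMatrix(labels=[str(i) for i in relative_biomass.index],
                               d=d)


@dataclass
class BioEnvResult:
    """Ranked output of the BIO-ENV subset search.

    ``ranking`` rows carry (subset, rho) ordered best first; ties on rho
    go to the smaller subset, then lexicographic order. ``p_value`` is
    filled in by :func:`bioenv_permutation_test`.
    """

    ranking: list[tuple[tuple[str, ...], float]]
    best_subset: tuple[str, ...]
    best_rho: float
    selection_frequency: dict[str, float]
    p_value: float | None = None
    # internal state reused by the permutation test
    _community_ranks: np.ndarray | None = field(default=None, repr=False)
    _subset_rank_squares: dict[tuple[str, ...], np.ndarray] | None = field(
        default=None, repr=False)
    _n_stations: int = 0


def _rank_rho(ranks_a: np.ndarray, ranks_b: np.ndarray) -> float:
    """Pearson correlation of two pre-ranked vectors (= Spearman rho)."""
    za = ranks_a - ranks_a.mean()
    zb = ranks_b - ranks_b.mean()
    denom = np.sqrt((za @ za) * (zb @ zb))
    if denom == 0:
        return np.nan
    return float((za @ zb) / denom)


def bioenv(community: DissimilarityMatrix, env: pd.DataFrame,
           max_subset_size: int | None = None,
           top_k: int = 10) -> BioEnvResult:
    """Exhaustive BIO-ENV search.

    ``env`` rows must match the community's stations (same order or a
    matching index). Variables are z-scored before Euclidean distances;
    the search covers every non-empty subset up to ``max_subset_size``
    (all sizes when None). ``selection_frequency`` reports how often
    each variable appears among the ``top_k`` best subsets.
    """
    n = len(community.labels)
    env = env.copy()
    env.index = env.index.map(str)
    if set(env.index) == set(community.labels) and len(env) == n:
        env = env.loc[community.labels]
    elif len(env) != n:
        raise ValueError("env table and community matrix station mismatch")
    variables = list(env.columns)
    if max_subset_size is None and len(variables) > MAX_EXHAUSTIVE_VARS:
        raise ValueError(
            f"{len(variables)} candidate variables make the exhaustive "
            "search combinatorially infeasible; pass max_subset_size"
        )
    max_size = len(variables) if max_subset_size is None else \
        min(max_subset_size, len(variables))

    x = env.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"constant environmental variables: {const}")
    z = (x - x.mean(axis=0)) / sd

    comm_ranks = rankdata(community.condensed())
    results: list[tuple[tuple[str, ...], float]] = []
    rank_squares: dict[tuple[str, ...], np.ndarray] = {}
    col = {v: i for i, v in enumerate(variables)}
    for size in range(1, max_size + 1):
        for subset in itertools.combinations(variables, size):
            cols = [col[v] for v in subset]
            dvec = pdist(z[:, cols], metric="euclidean")
            env_ranks = rankdata(dvec)
            rho = _rank_rho(comm_ranks, env_ranks)
            results.append((subset, rho))
            rank_squares[subset] = squareform(env_ranks, checks=False)
    results.sort(key=lambda item: (-item[1], len(item[0]), item[0]))
    top = results[:top_k]
    freq = {
        v: sum(v in subset for subset, _ in top) / len(top)
        for v in variables
    }
    best_subset, best_rho = results[0]
    return BioEnvResult(
        ranking=results,
        best_subset=best_subset,
        best_rho=best_rho,
        selection_frequency=freq,
        _community_ranks=comm_ranks,
        _subset_rank_squares=rank_squares,
        _n_stations=n,
    )


def bioenv_permutation_test(result: BioEnvResult, n_perm: int = 999,
                            seed: int | np.random.Generator = 0) -> float:
    """Permutation p-value for the best BIO-ENV correlation.

    Station labels of the environmental table are permuted and the
    whole subset search re-run each time; permuting the labels and
    recomputing Euclidean distances is identical to permuting the rows
    and columns of each subset's distance matrix, so the precomputed
    rank matrices are reused. p = (1 + #{best permuted rho >= observed})
    / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    if result._subset_rank_squares is None:
        raise ValueError("result lacks search state; rerun bioenv()")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = result._n_stations
    comm_ranks = result._community_ranks
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        best = -np.inf
        for square in result._subset_rank_squares.values():
            permuted = squareform(square[np.ix_(perm, perm)], checks=False)
            rho = _rank_rho(comm_ranks, permuted)
            if rho > best:
                best = rho
        if best >= result.best_rho:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    result.p_value = p
    return p


def spearman_tests(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and two-sided p over a variable table.

    Missing values are dropped pairwise; pairs with fewer than three
    complete observations or a constant variable get NaN. Raw p-values,
    no multiplicity correction.
    """
    cols = list(table.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    np.fill_diagonal(pval.values, np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            pair = table[[cols[i], cols[j]]].dropna()
            if len(pair) < 3 or pair[cols[i]].nunique() < 2 \
                    or pair[cols[j]].nunique() < 2:
                r = p = np.nan
            else:
                r, p = spearmanr(pair[cols[i]], pair[cols[j]])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
    return rho, pval


@dataclass
class TDIModelFit:
    """Gaussian GLM of log(TDI) on risk and abrasion."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    fitted: pd.Series          # on the log scale
    response_transform: str = "log"
    dropped_predictors: tuple[str, ...] = ()

    def linear_predictor(self, risk, abrasion) -> np.ndarray:
        lp = np.full(np.shape(risk), self.params["const"], dtype=float)
        if "risk" in self.params:
            lp = lp + self.params["risk"] * np.asarray(risk, dtype=float)
        if "abrasion" in self.params:
            lp = lp + self.params["abrasion"] * np.asarray(abrasion, dtype=float)
        return lp

    def predict(self, risk, abrasion) -> np.ndarray:
        """Back-transformed (exponentiated) prediction on the TDI scale."""
        return np.exp(self.linear_predictor(risk, abrasion))


def fit_tdi_glm(tdi: np.ndarray | pd.Series, risk: np.ndarray | pd.Series,
                abrasion: np.ndarray | pd.Series) -> TDIModelFit:
    """Fit log(TDI) ~ risk + abrasion (Gaussian family, identity link).

    Requires positive TDI at >= 10 stations. A zero-variance predictor
    is dropped with a warning; perfectly collinear predictors raise.
    """
    df = pd.DataFrame({
        "tdi": np.asarray(tdi, dtype=float),
        "risk": np.asarray(risk, dtype=float),
        "abrasion": np.asarray(abrasion, dtype=float),
    }).dropna()
    if len(df) < 10:
        raise ValueError("need at least 10 stations with complete data")
    if (df["tdi"] <= 0).any():
        raise ValueError("TDI must be > 0 for the log transform")
    predictors = ["risk", "abrasion"]
    dropped = tuple(p for p in predictors if df[p].nunique() < 2)
    if dropped:
        warnings.warn(
            f"degenerate predictor(s) dropped: {dropped}", stacklevel=2)
        predictors = [p for p in predictors if p not in dropped]
    if len(predictors) == 2:
        r = np.corrcoef(df["risk"], df["abrasion"])[0, 1]
        if np.isclose(abs(r), 1.0):
            raise ValueError("risk and abrasion are perfectly collinear")
    y = np.log(df["tdi"])
    X = sm.add_constant(df[predictors])
    fit = sm.GLM(y, X, family=sm.families.Gaussian()).fit()
    return TDIModelFit(
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        fitted=fit.fittedvalues,
        dropped_predictors=dropped,
    )


def predict_tdi_map(fit: TDIModelFit, risk: EnvGrid,
                    abrasion: EnvGrid) -> EnvGrid:
    """Predicted-TDI surface from the fitted model.

    exp(linear predictor) cellwise; a cell is masked wherever either
    predictor is masked. Grids must already share one spec.
    """
    if risk.spec != abrasion.spec:
        raise ValueError("risk and abrasion grids are not aligned")
    mask = combine_masks(risk, abrasion)
    vals = fit.predict(risk.values, abrasion.values)
    vals = np.where(mask, np.nan, vals)
    return EnvGrid(spec=risk.spec, values=vals, mask=mask,
                   name="tdi_predicted", units="score")
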