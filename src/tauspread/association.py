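"""Tau covariance and its association with connectome distance.

The central inference of the package: if tau pathology spreads along
functional connections, ROI pairs that are functionally close should show
correlated tau levels across subjects.  This module computes
covariate-adjusted inter-regional tau covariance (Fisher-z partial
correlations across subjects), regresses covariance on shortest-path
functional distance over all ROI pairs (standardized beta), and calibrates
that beta against degree- and weight-preserving connectome null models with
an exact permutation test.  Subject-level analyses relate each subject's tau
values to their distance from the subject's own epicentre, continuously and
across distance quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import ConnectomeDistance, R_CLIP
from .atlas import RoiAtlas
from .errors import (CollinearityError, InsufficientDataError,
                     InvalidArgumentError, RewireFailureError)


# --------------------------------------------------------------------------
# covariate adjustment and covariance
# --------------------------------------------------------------------------

def build_design(covariates: pd.DataFrame | None, index: pd.Index) -> pd.DataFrame:
    """Intercept + covariate design matrix, one-hot coding categoricals.

    Categorical columns (object/category dtype) are dummy-coded against a
    reference level (the first level is dropped).
    """
    design = pd.DataFrame({"intercept": 1.0}, index=index)
    if covariates is not None:
        cov = covariates.loc[index]
        for col in cov.columns:
            if cov[col].dtype == object or isinstance(cov[col].dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(cov[col], prefix=col, drop_first=True, dtype=float)
                design = pd.concat([design, dummies], axis=1)
            else:
                design[col] = cov[col].astype(float)
    x = design.to_numpy()
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # greedily locate the dependent columns for the error message
        keep: list[int] = []
        bad: list[str] = []
        for j in range(x.shape[1]):
            cols = keep + [j]
            if np.linalg.matrix_rank(x[:, cols]) == len(cols):
                keep.append(j)
            else:
                bad.append(design.columns[j])
        raise CollinearityError(bad)
    return design


def residualize(values: pd.DataFrame, covariates: pd.DataFrame | None) -> pd.DataFrame:
    """Per-ROI OLS residuals of a subject x ROI table against the covariates.

    With no covariates the design is the intercept only, so the residuals are
    the column-centred values.  Residuals are orthogonal to every design
    column by construction.
    """
    design = build_design(covariates, values.index)
    x = design.to_numpy()
    y = values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return pd.DataFrame(resid, index=values.index, columns=values.columns)


@dataclass(frozen=True)
class CovarianceMatrix:
    """ROI x ROI Fisher-z partial correlations of tau across subjects."""

    matrix: np.ndarray
    covariates: tuple[str, ...]
    n_subjects: int
    correlation_kind: str        # "pearson" | "spearman"

    @property
    def n_roi(self) -> int:
        return self.matrix.shape[0]


def tau_covariance(values: pd.DataFrame, covariates: pd.DataFrame | None = None,
                   kind: str = "pearson") -> CovarianceMatrix:
    """Covariate-adjusted inter-regional tau covariance.

    Pearson: correlate per-ROI residuals across subjects.  Spearman: ranks
    are taken per ROI before residualization, then treated as Pearson
    (partial rank correlation).  Correlations are clipped to +/-0.999999
    before the Fisher z-transform; ROIs constant across subjects get missing
    pair entries.
    """
    if kind not in ("pearson", "spearman"):
        raise InvalidArgumentError(f"unknown correlation kind {kind!r}")
    n_cov = 0 if covariates is None else covariates.shape[1]
    if len(values) <= n_cov + 2:
        raise InsufficientDataError(
            f"need n_subjects > {n_cov + 2}, got {len(values)}")
    work = values
    if kind == "spearman":
        work = values.rank(axis=0)
    resid = residualize(work, covariates)
    r_matrix = _safe_corrcoef(resid.to_numpy())
    z = np.arctanh(np.clip(r_matrix, -R_CLIP, R_CLIP))
    np.fill_diagonal(z, np.nan)
    cov_names = tuple() if covariates is None else tuple(covariates.columns)
    return CovarianceMatrix(matrix=z, covariates=cov_names,
                            n_subjects=len(values), correlation_kind=kind)


def _safe_corrcoef(y: np.ndarray) -> np.ndarray:
    """Column-wise correlation with zero-variance columns set missing."""
    sd = y.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(y, rowvar=False)
    flat = np.flatnonzero(sd == 0)
    r[flat, :] = np.nan
    r[:, flat] = np.nan
    return r


def euclidean_adjusted_covariance(cov: CovarianceMatrix,
                                  euclid: np.ndarray) -> CovarianceMatrix:
    """Sensitivity variant: remove the pairwise Euclidean-distance component.

    The vector of pairwise z values is residualized against inter-regional
    Euclidean distance across ROI pairs (pair-level adjustment) and the
    matrix rebuilt; the mean z level is retained so only the distance slope
    is removed.
    """
    n = cov.n_roi
    if euclid.shape != (n, n):
        raise InvalidArgumentError("Euclidean matrix does not match the atlas")
    iu, ju = np.triu_indices(n, k=1)
    z = cov.matrix[iu, ju]
    d = euclid[iu, ju]
    ok = np.isfinite(z) & np.isfinite(d)
    adjusted = z.copy()
    if d[ok].std() > 0:  # a constant distance carries nothing to remove
        x = np.column_stack([np.ones(ok.sum()), d[ok]])
        beta, *_ = np.linalg.lstsq(x, z[ok], rcond=None)
        adjusted[ok] = z[ok] - x @ beta + beta[0]
    out = np.full((n, n), np.nan)
    out[iu, ju] = adjusted
    out[ju, iu] = adjusted
    return CovarianceMatrix(matrix=out,
                            covariates=cov.covariates + ("euclidean_pairwise",),
                            n_subjects=cov.n_subjects,
                            correlation_kind=cov.correlation_kind)


# --------------------------------------------------------------------------
# covariance vs distance regression
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationResult:
    beta_std: float
    p_param: float
    n_pairs: int
    scope: str


def _pair_vectors(cov_matrix: np.ndarray, dist_matrix: np.ndarray,
                  rois: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    if rois is None:
        iu, ju = np.triu_indices(cov_matrix.shape[0], k=1)
    else:
        iu, ju = np.triu_indices(rois.size, k=1)
        iu, ju = rois[iu], rois[ju]
    z = cov_matrix[iu, ju]
    d = dist_matrix[iu, ju]
    ok = np.isfinite(z) & np.isfinite(d)
    return z[ok], d[ok]


def covariance_vs_distance(cov: CovarianceMatrix,
                           dist: ConnectomeDistance | np.ndarray,
                           scope: str = "whole-brain",
                           atlas: RoiAtlas | None = None) -> AssociationResult:
    """Standardized regression of pairwise tau covariance on functional distance.

    Each unordered ROI pair contributes one observation; both variables are
    z-scored so the OLS slope is the standardized beta.  ``scope`` is
    ``"whole-brain"`` or a network name (pairs with both ROIs in the
    network; requires ``atlas``).  Infinite-distance and missing pairs are
    excluded.
    """
    dmat = dist.matrix if isinstance(dist, ConnectomeDistance) else np.asarray(dist)
    if dmat.shape[0] != cov.n_roi:
        raise InvalidArgumentError("distance matrix does not match the covariance")
    rois = None
    if scope != "whole-brain":
        if atlas is None:
            raise InvalidArgumentError("network scope requires an atlas")
        rois = atlas.rois_in_network(scope)
        if rois.size == 0:
            raise InvalidArgumentError(f"unknown network {scope!r}")
    z, d = _pair_vectors(cov.matrix, dmat, rois)
    if z.size < 10:
        raise InsufficientDataError(f"only {z.size} usable pairs in scope {scope!r}")
    res = stats.linregress(_zscore(d), _zscore(z))
    return AssociationResult(beta_std=float(res.slope), p_param=float(res.pvalue),
                             n_pairs=int(z.size), scope=scope)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise InsufficientDataError("zero variance in regression variable")
    return (x - x.mean()) / sd


# --------------------------------------------------------------------------
# connectome null models and exact test
# --------------------------------------------------------------------------

def null_models(thresholded_fc: np.ndarray, B: int = 1000, seed: int = 0,
                swaps_per_edge: int = 10) -> Iterator[np.ndarray]:
    """Degree- and weight-preserving rewired connectomes (lazy, deterministic).

    Each replicate rewires the binary graph by Maslov-Sneppen pairwise edge
    swaps (``swaps_per_edge * |E|`` accepted swaps) so the degree sequence is
    preserved exactly, then reassigns the original multiset of edge weights
    to the rewired edges by random permutation.
    """
    w = np.asarray(thresholded_fc, dtype=float)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    on = w[iu, ju] > 0
    edges_i, edges_j = iu[on].copy(), ju[on].copy()
    weights = w[iu[on], ju[on]]
    n_edges = edges_i.size
    if n_edges < 2:
        raise RewireFailureError("need at least 2 edges to rewire")

    rng = np.random.default_rng(seed)
    for _ in range(B):
        ei, ej = _maslov_sneppen(edges_i, edges_j, n, swaps_per_edge * n_edges, rng)
        perm = rng.permutation(n_edges)
        null = np.zeros((n, n))
        null[ei, ej] = weights[perm]
        null[ej, ei] = weights[perm]
        yield null


def _maslov_sneppen(edges_i: np.ndarray, edges_j: np.ndarray, n: int,
                    n_swaps: int, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Rewire an undirected edge list by accepted pairwise swaps."""
    ei = edges_i.tolist()
    ej = edges_j.tolist()
    n_edges = len(ei)
    present = {a * n + b for a, b in zip(ei, ej)}
    accepted = 0
    attempts = 0
    max_attempts = max(100 * n_swaps, 1000)
    chunk = 4096
    buf_e1 = buf_e2 = buf_flip = None
    pos = chunk  # force a refill on first use
    while accepted < n_swaps:
        attempts += 1
        if attempts > max_attempts:
            raise RewireFailureError(
                f"rewiring stalled after {attempts} attempts "
                f"({accepted}/{n_swaps} swaps)")
        if pos >= chunk:  # draw randomness in batches; the loop is hot
            buf_e1 = rng.integers(n_edges, size=chunk)
            buf_e2 = rng.integers(n_edges, size=chunk)
            buf_flip = rng.random(chunk) < 0.5
            pos = 0
        e1 = int(buf_e1[pos]); e2 = int(buf_e2[pos]); flip = buf_flip[pos]
        pos += 1
        if e1 == e2:
            continue
        a, b = ei[e1], ej[e1]
        c, d = ei[e2], ej[e2]
        if flip:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        p, q = (a, d) if a < d else (d, a)
        r, s = (c, b) if c < b else (b, c)
        k1, k2 = p * n + q, r * n + s
        if k1 == k2 or k1 in present or k2 in present:
            continue
        present.discard(a * n + b if a < b else b * n + a)
        present.discard(c * n + d if c < d else d * n + c)
        present.add(k1)
        present.add(k2)
        ei[e1], ej[e1] = p, q
        ei[e2], ej[e2] = r, s
        accepted += 1
    return np.asarray(ei), np.asarray(ej)


@dataclass(frozen=True)
class NullDistribution:
    betas: np.ndarray
    p_exact: float
    seed: int | None = None

    @property
    def B(self) -> int:
        return self.betas.size


def exact_test(actual: AssociationResult | float,
               null_betas: np.ndarray, seed: int | None = None) -> NullDistribution:
    """Exact permutation p-value of the observed beta against null betas.

    One-sided on magnitude with the add-one rule:
    ``p = (1 + #{null |beta| >= actual |beta|}) / (B + 1)``.
    """
    beta = actual.beta_std if isinstance(actual, AssociationResult) else float(actual)
    betas = np.asarray(null_betas, dtype=float)
    if not np.all(np.isfinite(betas)) or not np.isfinite(beta):
        raise InvalidArgumentError("all betas must be finite")
    n_extreme = int((np.abs(betas) >= abs(beta)).sum())
    p = (1 + n_extreme) / (betas.size + 1)
    return NullDistribution(betas=betas, p_exact=p, seed=seed)


def null_distribution(cov: CovarianceMatrix, thresholded_fc: np.ndarray,
                      actual: AssociationResult, B: int = 1000, seed: int = 0,
                      density: float = 0.30) -> NullDistribution:
    """Convenience wrapper: rewire, re-derive distances, re-regress, exact test."""
    from .connectome import fc_to_distance

    betas = np.empty(B)
    for b, null in enumerate(null_models(thresholded_fc, B=B, seed=seed)):
        ndist = fc_to_distance(null, density=density)
        betas[b] = covariance_vs_distance(cov, ndist, scope=actual.scope).beta_std
    return exact_test(actual, betas, seed=seed)


# --------------------------------------------------------------------------
# subject-level gradients
# --------------------------------------------------------------------------

def subject_gradient(values: pd.Series, epi_dist: pd.Series) -> float:
    """Standardized slope of one subject's tau values on epicentre distance.

    ``values`` is indexed by roi_id; only the non-epicentre ROIs present in
    ``epi_dist`` enter the regression.
    """
    common = epi_dist.index.intersection(values.index)
    y = values.loc[common].to_numpy(dtype=float)
    d = epi_dist.loc[common].to_numpy(dtype=float)
    ok = np.isfinite(y) & np.isfinite(d)
    if ok.sum() < 10:
        raise InsufficientDataError(f"only {int(ok.sum())} usable ROIs")
    res = stats.linregress(_zscore(d[ok]), _zscore(y[ok]))
    return float(res.slope)


def cohort_gradients(values: pd.DataFrame,
                     epi_dists: dict[str, pd.Series]) -> pd.DataFrame:
    """Per-subject standardized epicentre-distance slopes with summary stats."""
    rows = [{"subject_id": s, "beta_std": subject_gradient(values.loc[s], d)}
            for s, d in epi_dists.items() if s in values.index]
    if not rows:
        raise InsufficientDataError("no subjects with both values and distances")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class QuartileGradient:
    """Distance-quartile means per subject and their pairwise comparisons."""

    quartile_means: pd.DataFrame          # subject_id, quartile (1..4), mean_value
    pairwise_tests: pd.DataFrame          # quartile_a, quartile_b, statistic, p_value
    value_kind: str
    assignments: dict[str, pd.Series] = field(repr=False, default_factory=dict)


def _quartile_of_rank(m: int) -> np.ndarray:
    """Quartile index (0-3) for ranks 0..m-1, sizes as near-equal as possible."""
    return (np.arange(m) * 4) // m


def quartile_gradient(values: pd.DataFrame, epi_dists: dict[str, pd.Series],
                      value_kind: str = "positivity") -> QuartileGradient:
    """Tau across quartiles of functional distance to the subject's epicentre.

    Per subject, non-epicentre ROIs are ranked by that subject's epicentre
    distance (ties resolved toward the lower roi_id, hence the lower
    quartile) and cut into four near-equal groups — quartile 1 closest,
    quartile 4 most distant (sizes 48/47/48/47 for 190 ROIs).  Per-quartile
    per-subject means are compared with all six paired two-sided Wilcoxon
    signed-rank tests, reported uncorrected.
    """
    rows = []
    assignments: dict[str, pd.Series] = {}
    for subject, dist in epi_dists.items():
        if subject not in values.index:
            continue
        common = dist.index.intersection(values.columns)
        d = dist.loc[common]
        order = np.lexsort((common.to_numpy(), d.to_numpy()))
        q = np.empty(len(common), dtype=int)
        q[order] = _quartile_of_rank(len(common))
        assign = pd.Series(q + 1, index=common, name="quartile")
        assignments[subject] = assign
        vals = values.loc[subject, common]
        for quartile in range(1, 5):
            rows.append({"subject_id": subject, "quartile": quartile,
                         "mean_value": float(vals[assign == quartile].mean())})
    if not rows:
        raise InsufficientDataError("no subjects with usable epicentre distances")
    means = pd.DataFrame(rows)
    n_subjects = means["subject_id"].nunique()
    if n_subjects < 6:
        raise InsufficientDataError(
            f"need >= 6 subjects for signed-rank tests, got {n_subjects}")

    wide = means.pivot(index="subject_id", columns="quartile", values="mean_value")
    tests = []
    for qa, qb in combinations(range(1, 5), 2):
        res = stats.wilcoxon(wide[qa], wide[qb], alternative="two-sided")
        tests.append({"quartile_a": qa, "quartile_b": qb,
                      "statistic": float(res.statistic), "p_value": float(res.pvalue)})
    return QuartileGradient(quartile_means=means, pairwise_tests=pd.DataFrame(tests),
                            value_kind=value_kind, assignments=assignments)
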