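"""Tracer harmonization: SUVR to tau-positivity probability via Gaussian mixtures.

Different tau tracers produce SUVRs on different scales, so multicentre
cohorts cannot pool raw SUVRs.  Per tracer and per ROI, a two-component
Gaussian mixture is fitted to the pooled patient + control SUVR sample (the
controls anchor the tau-negative end of the range); a scan's positivity
probability for a ROI is then 100 x the posterior probability that its SUVR
came from the higher-mean ("tau-positive") component.  The result is a
uniform 0-100% scale comparable across tracers.

Low-tau ROIs can be genuinely unimodal; a two-component fit of a unimodal
sample just splits the noise.  Fits whose component separation (Ashman's D)
falls below 3.5 are therefore flagged as collapsed and their transform falls
back to the tracer-level mixture fitted on the pooled values of all ROIs,
which preserves the cross-ROI SUVR ordering that a per-ROI rescaling would
destroy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

from .errors import FitFailureError, InsufficientDataError, InvalidArgumentError, MissingModelError

logger = logging.getLogger(__name__)

MIN_SAMPLE = 20
#: Variance floor (SUVR^2) guarding against component collapse during EM.
VAR_FLOOR = 1e-4
#: Minimum component separation (Ashman's D, the mean gap in units of the
#: RMS component SD) for a fit to count as genuinely bimodal.  A
#: two-component fit of a single Gaussian lands near D ~ 2.5, and fits
#: around D ~ 3-4 are dominated by within-ROI severity spread rather than a
#: clean negative/positive split; only decisively separated ROIs keep their
#: own transform, everything else shares the tracer-level mixture so the
#: cross-ROI SUVR ordering stays comparable.
MIN_ASHMAN_D = 5.0
#: Both components must carry at least this much weight; a fit that isolates
#: a couple of outliers as its own component is not a usable
#: negative/positive split.
MIN_COMPONENT_WEIGHT = 0.10

POOLED_ROI_ID = -1  # roi_id under which the tracer-level pooled fit is stored


@dataclass(frozen=True)
class MixtureEntry:
    """One fitted two-component mixture, components ordered by mean."""

    mean_neg: float
    sd_neg: float
    weight_neg: float
    mean_pos: float
    sd_pos: float
    weight_pos: float
    flag: str = "ok"   # "ok" | "collapsed"

    def posterior_pos(self, values: np.ndarray) -> np.ndarray:
        """Posterior probability of the tau-positive component (Bayes rule)."""
        x = np.asarray(values, dtype=float)
        log_neg = (np.log(self.weight_neg)
                   - 0.5 * np.log(2 * np.pi * self.sd_neg ** 2)
                   - 0.5 * ((x - self.mean_neg) / self.sd_neg) ** 2)
        log_pos = (np.log(self.weight_pos)
                   - 0.5 * np.log(2 * np.pi * self.sd_pos ** 2)
                   - 0.5 * ((x - self.mean_pos) / self.sd_pos) ** 2)
        denom = logsumexp(np.stack([log_neg, log_pos]), axis=0)
        return np.exp(log_pos - denom)


def fit_mixture(values: np.ndarray, seed: int = 0,
                min_sample: int = MIN_SAMPLE) -> MixtureEntry:
    """Fit a two-component Gaussian mixture to one ROI's SUVR sample.

    EM is initialized by k-means with a fixed seed, iterated to a 1e-6
    log-likelihood tolerance (max 500 iterations) with the variance floored
    at 1e-4 SUVR^2.  Components are reported ordered by mean.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise InvalidArgumentError("values must be a 1-D sample")
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("values must be finite")
    if x.size < min_sample:
        raise InsufficientDataError(
            f"need >= {min_sample} values to fit a mixture, got {x.size}")
    if np.ptp(x) == 0:
        raise FitFailureError("degenerate sample: zero variance")

    gmm = GaussianMixture(n_components=2, covariance_type="spherical",
                          reg_covar=VAR_FLOOR, tol=1e-6, max_iter=500,
                          init_params="kmeans", n_init=1, random_state=seed)
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    with warnings.catch_warnings():
        # near-unimodal samples can ride the tolerance for the full 500
        # iterations; the fit is still usable and flagged downstream
        warnings.simplefilter("ignore", ConvergenceWarning)
        gmm.fit(x[:, None])
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]

    ashman_d = np.sqrt(2.0) * (means[1] - means[0]) / np.sqrt(sds[0] ** 2 + sds[1] ** 2)
    usable = ashman_d >= MIN_ASHMAN_D and weights.min() >= MIN_COMPONENT_WEIGHT
    flag = "ok" if usable else "collapsed"
    return MixtureEntry(mean_neg=float(means[0]), sd_neg=float(sds[0]),
                        weight_neg=float(weights[0]), mean_pos=float(means[1]),
                        sd_pos=float(sds[1]), weight_pos=float(weights[1]),
                        flag=flag)


class TracerMixtureModel:
    """Per-tracer, per-ROI mixtures plus a tracer-level pooled fallback."""

    def __init__(self, entries: dict[tuple[str, int], MixtureEntry]):
        self.entries = dict(entries)

    @property
    def tracers(self) -> list[str]:
        return sorted({t for t, _ in self.entries})

    def entry(self, tracer: str, roi_id: int) -> MixtureEntry:
        """The mixture used for a ROI: its own fit, or the pooled fallback."""
        if (tracer, roi_id) not in self.entries:
            raise MissingModelError(f"no fitted model for tracer {tracer!r} roi {roi_id}")
        e = self.entries[(tracer, roi_id)]
        if e.flag == "collapsed" and (tracer, POOLED_ROI_ID) in self.entries:
            return self.entries[(tracer, POOLED_ROI_ID)]
        return e

    @classmethod
    def fit(cls, cohort: pd.DataFrame, seed: int = 0,
            min_sample: int = MIN_SAMPLE) -> "TracerMixtureModel":
        """Fit mixtures from a long-format cohort (baseline scans, all groups).

        ROIs whose per-ROI fit fails or collapses fall back to the
        tracer-level mixture fitted on all ROI values pooled; collapsed-fit
        counts are logged per tracer.
        """
        frame = cohort
        if "timepoint_years" in frame.columns:
            frame = frame[frame["timepoint_years"] == 0.0]
        entries: dict[tuple[str, int], MixtureEntry] = {}
        for tracer, block in frame.groupby("tracer"):
            pooled = fit_mixture(block["suvr"].to_numpy(), seed=seed,
                                 min_sample=min_sample)
            entries[(tracer, POOLED_ROI_ID)] = MixtureEntry(
                **{**pooled.__dict__, "flag": "ok"})
            n_collapsed = 0
            for roi_id, roi_block in block.groupby("roi_id"):
                try:
                    entry = fit_mixture(roi_block["suvr"].to_numpy(), seed=seed,
                                        min_sample=min_sample)
                except (FitFailureError, InsufficientDataError):
                    entry = MixtureEntry(**{**pooled.__dict__, "flag": "collapsed"})
                entries[(tracer, int(roi_id))] = entry
                n_collapsed += entry.flag == "collapsed"
            if n_collapsed:
                logger.info("tracer %s: %d ROI fit(s) collapsed; pooled fallback used",
                            tracer, n_collapsed)
        return cls(entries)

    def to_positivity(self, roi_values: np.ndarray, tracer: str) -> np.ndarray:
        """Transform one scan's per-ROI SUVRs to positivity percentages (0-100)."""
        values = np.asarray(roi_values, dtype=float)
        out = np.empty_like(values)
        for roi_id, v in enumerate(values):
            out[roi_id] = 100.0 * self.entry(tracer, roi_id).posterior_pos(v)
        return out

    def apply(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Add a ``positivity`` column (0-100) to a long-format cohort table."""
        out = cohort.reset_index(drop=True).copy()
        prob = np.empty(len(out))
        for (tracer, roi_id), block in out.groupby(["tracer", "roi_id"]):
            entry = self.entry(tracer, int(roi_id))
            prob[block.index] = 100.0 * entry.posterior_pos(block["suvr"].to_numpy())
        out["positivity"] = prob
        return out

    # -- persistence ------------------------------------------------------

    def to_tsv(self, path) -> None:
        rows = [{"tracer": t, "roi_id": r, **e.__dict__}
                for (t, r), e in sorted(self.entries.items())]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                                  float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "TracerMixtureModel":
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
        entries = {}
        for row in frame.itertuples(index=False):
            d = row._asdict()
            key = (d.pop("tracer"), int(d.pop("roi_id")))
            entries[key] = MixtureEntry(**d)
        return cls(entries)


def leave_one_site_out(positivity: pd.DataFrame, sites: pd.Series
                       ) -> tuple[pd.Series, float]:
    """Leave-one-site-out robustness check on mean positivity maps.

    Parameters
    ----------
    positivity:
        Subject x ROI positivity table (0-100).
    sites:
        Site label per subject (aligned on the index of ``positivity``).

    Returns
    -------
    (correlations, levene_p):
        Pearson r between the full-cohort mean map and each
        leave-one-site-out mean map, and Levene's p-value for variance
        homogeneity across the LOSO mean maps.
    """
    from scipy.stats import levene, pearsonr

    sites = sites.loc[positivity.index]
    unique = sites.unique()
    if len(unique) < 2:
        raise InvalidArgumentError("leave-one-site-out needs >= 2 sites")
    full_mean = positivity.mean(axis=0)
    corr = {}
    loso_maps = []
    for site in sorted(unique):
        rest = positivity.loc[sites != site]
        if rest.empty:
            raise InvalidArgumentError(f"site {site!r} contains every subject")
        loso_mean = rest.mean(axis=0)
        corr[site] = pearsonr(full_mean, loso_mean).statistic
        loso_maps.append(loso_mean.to_numpy())
    _, p = levene(*loso_maps)
    return pd.Series(corr, name="loso_r"), float(p)
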