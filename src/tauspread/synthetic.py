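"""Synthetic multicentre tau-PET study generator.

Real multicentre tau-PET cohorts are access-restricted, so every downstream
stage of this package is exercised on synthetic cohorts whose statistical
structure matches what the analysis assumes:

* a parcellation with network labels and spatially clustered centroids;
* a modular "true" connectome from which BOLD series can be sampled;
* tau-PET SUVRs that decay exponentially with connectome distance from a
  planted epicentre, with multiplicative longitudinal accumulation,
  additive site/age/sex nuisance effects, per-tracer scaling, and regional
  noise that can be correlated along the connectome (connected regions
  accumulate noise together — the generative converse of the
  covariance-vs-distance inference);
* post-mortem cohorts discretized to ordinal 0-3 tangle ratings.

The generative model for patient ROI ``i`` at follow-up time ``t`` (years) is

    SUVR_i(t) = tracer_scale * [ baseline + A_s * e_i * (1 + rate * t * e_i) ]
                + site + age_slope * (age - 70) + sex_offset * 1[female]
                + noise_i,

with ``e_i = exp(-decay_rate * d_i)``, ``d_i`` the shortest-path connectome
distance from ROI ``i`` to the nearest epicentre ROI, and ``A_s`` the
subject's severity: ``amplitude`` scaled by a mean-preserving lognormal
factor (controls have ``A_s = 0``).  Everything is deterministic given the
scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .atlas import CANONICAL_NETWORKS, RoiAtlas
from .connectome import ConnectomeDistance, fc_to_distance, threshold_density
from .errors import FitFailureError, InvalidArgumentError

__all__ = [
    "SpreadScenario", "SyntheticTruth", "generate_atlas", "generate_connectome",
    "sample_bold", "simulate_tau_cohort", "simulate_postmortem",
    "strong_coupling_scenario", "build_study", "Study",
]


# --------------------------------------------------------------------------
# scenario definition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpreadScenario:
    """Parameters of one planted tau-spread scenario.

    ``noise_correlation`` is the fraction of regional noise variance shared
    along the connectome (0 = independent regional noise); it is what gives
    synthetic cohorts a connectivity-shaped tau covariance structure.
    """

    epicentre_rois: tuple[int, ...]
    amplitude: float = 2.5            # SUVR elevation at the epicentre
    decay_rate: float = 2.0           # per mean connectome distance
    baseline_suvr: float = 1.0
    noise_sd: float = 0.15            # SUVR
    noise_correlation: float = 0.8    # fraction of noise variance on the connectome
    severity_sd: float = 0.35         # lognormal sigma of per-subject severity
    site_effects: dict[str, float] = field(
        default_factory=lambda: {"site_a": 0.0, "site_b": 0.03, "site_c": -0.03})
    age_slope: float = 0.002          # SUVR per year of age (centred at 70)
    sex_offset: float = 0.02          # SUVR, added for female subjects
    tracer_scale: dict[str, float] = field(default_factory=lambda: {"synthetic": 1.0})
    accumulation_rate: float = 0.10   # fraction/year at the epicentre
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.epicentre_rois) == 0:
            raise InvalidArgumentError("epicentre_rois must be nonempty")
        if self.amplitude <= 0:
            raise InvalidArgumentError("amplitude must be > 0")
        if self.decay_rate < 0 or self.noise_sd < 0:
            raise InvalidArgumentError("decay_rate and noise_sd must be >= 0")
        if self.baseline_suvr <= 0:
            raise InvalidArgumentError("baseline_suvr must be > 0")
        if not 0 <= self.noise_correlation <= 1:
            raise InvalidArgumentError("noise_correlation must be in [0, 1]")
        if self.severity_sd < 0:
            raise InvalidArgumentError("severity_sd must be >= 0")
        if any(s <= 0 for s in self.tracer_scale.values()):
            raise InvalidArgumentError("tracer scales must be positive")

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["epicentre_rois"] = list(self.epicentre_rois)
        with open(path, "w") as fh:
            yaml.safe_dump({"scenario": payload}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SpreadScenario":
        with open(path) as fh:
            payload = yaml.safe_load(fh)["scenario"]
        if "seed" not in payload:
            raise InvalidArgumentError("scenario config must set a seed")
        payload["epicentre_rois"] = tuple(payload["epicentre_rois"])
        return cls(**payload)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth accompanying a simulated cohort."""

    scenario: SpreadScenario
    true_distance_to_epicentre: np.ndarray   # per ROI, min distance to the set
    expected_tau: np.ndarray                 # baseline patient expectation at t=0


# --------------------------------------------------------------------------
# atlas and connectome
# --------------------------------------------------------------------------

def generate_atlas(n_roi: int, n_networks: int, seed: int,
                   cluster_sd_mm: float = 8.0) -> RoiAtlas:
    """Generate a parcellation with near-equal networks and clustered centroids.

    ROIs are partitioned into contiguous near-equal network blocks; each
    network gets a random spatial centre and its ROI centroids scatter around
    it (SD ``cluster_sd_mm``), so same-network ROIs are spatially clustered.
    """
    if n_networks < 1 or n_roi < n_networks:
        raise InvalidArgumentError(
            f"need n_roi >= n_networks >= 1, got {n_roi}, {n_networks}")
    rng = np.random.default_rng(seed)
    if n_networks <= len(CANONICAL_NETWORKS):
        names = CANONICAL_NETWORKS[:n_networks]
    else:
        names = tuple(f"network_{k}" for k in range(n_networks))

    blocks = np.array_split(np.arange(n_roi), n_networks)
    centres = rng.uniform(-70.0, 70.0, size=(n_networks, 3))
    rows = []
    for name, centre, block in zip(names, centres, blocks):
        coords = centre + rng.normal(0.0, cluster_sd_mm, size=(block.size, 3))
        for j, roi in enumerate(block):
            rows.append({
                "roi_id": int(roi),
                "roi_name": f"{name}_{j}",
                "network": name,
                "hemisphere": "left" if coords[j, 0] < 0 else "right",
                "x": coords[j, 0], "y": coords[j, 1], "z": coords[j, 2],
            })
    return RoiAtlas(pd.DataFrame(rows))


def generate_connectome(atlas: RoiAtlas, within_strength: float = 0.6,
                        between_strength: float = 0.1, noise_sd: float = 0.0,
                        seed: int = 0, between_jitter: float = 0.0) -> np.ndarray:
    """Modular "true" connectome: a network block matrix plus symmetric noise.

    Expected within-network weights exceed expected between-network weights.
    ``between_jitter`` spreads the between-network couplings per network
    pair (uniform on +/- the jitter), mimicking the graded inter-network
    coupling of real functional connectomes.  Because the matrix is the
    correlation target from which BOLD series are sampled, a noisy draw is
    projected to the nearest valid correlation structure (eigenvalue
    clipping + diagonal renormalization); with ``noise_sd=0`` and zero
    jitter the block values are returned exactly.
    """
    if not 0 <= between_strength < within_strength <= 1:
        raise InvalidArgumentError(
            "require 0 <= between_strength < within_strength <= 1")
    if noise_sd < 0 or between_jitter < 0:
        raise InvalidArgumentError("noise_sd and between_jitter must be >= 0")
    rng = np.random.default_rng(seed)
    labels = atlas.network_labels
    networks = atlas.networks
    codes = np.searchsorted(np.sort(networks), labels)
    same = labels[:, None] == labels[None, :]
    k = len(networks)
    pair_strength = np.full((k, k), between_strength)
    if between_jitter > 0:
        jit = rng.uniform(-between_jitter, between_jitter, size=(k, k))
        jit = np.triu(jit, 1)
        pair_strength = np.clip(pair_strength + jit + jit.T,
                                0.02, within_strength - 0.05)
    w = np.where(same, within_strength, pair_strength[np.ix_(codes, codes)])
    if noise_sd > 0 or between_jitter > 0:
        if noise_sd > 0:
            noise = np.triu(rng.normal(0.0, noise_sd, size=w.shape), 1)
            w = w + noise + noise.T
        c = w + np.eye(w.shape[0])
        eigval, eigvec = np.linalg.eigh(c)
        if eigval[0] < 1e-6:  # PSD projection so BOLD sampling stays exact
            c = (eigvec * np.clip(eigval, 1e-6, None)) @ eigvec.T
            d = np.sqrt(np.diag(c))
            c = c / np.outer(d, d)
        w = c - np.eye(w.shape[0])
    np.fill_diagonal(w, 0.0)
    return np.clip(w, -0.999, 0.999)


def _correlation_from_weights(connectome: np.ndarray,
                              max_loading: float = 0.5) -> np.ndarray:
    """Turn a zero-diagonal weight matrix into a valid correlation matrix.

    Adds the identity, then applies minimal diagonal loading if the result is
    not positive semi-definite; fails if the required loading is implausibly
    large (the weights were not correlation-like).
    """
    w = np.asarray(connectome, dtype=float)
    if not np.allclose(w, w.T, atol=1e-10):
        raise InvalidArgumentError("connectome must be symmetric")
    c = w + np.eye(w.shape[0])
    min_eig = float(np.linalg.eigvalsh(c)[0])
    if min_eig < 0:
        loading = -min_eig + 1e-10
        if loading > max_loading:
            raise FitFailureError(
                f"connectome not PSD after diagonal loading (needs {loading:.3f})")
        c = c + loading * np.eye(c.shape[0])
    d = np.sqrt(np.diag(c))
    return c / np.outer(d, d)


def sample_bold(connectome: np.ndarray, n_frames: int, tr: float = 2.0,
                seed: int = 0, fd_spike_frames: tuple[int, ...] = (),
                fd_spike_mm: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Sample ROI BOLD series whose correlation converges to the connectome.

    Frames are iid multivariate normal draws (no autocorrelation): FC
    estimation downstream only needs the cross-sectional correlation target.
    Returns ``(series, fd_trace)`` where ``series`` is (n_roi, n_frames) and
    the frame-wise displacement trace is nonnegative, below the scrubbing
    threshold everywhere except at injected spike frames.
    """
    if n_frames < 2:
        raise InvalidArgumentError("need n_frames >= 2")
    corr = _correlation_from_weights(connectome)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))
    series = chol @ rng.standard_normal((corr.shape[0], n_frames))

    fd = np.abs(rng.normal(0.15, 0.08, size=n_frames))
    fd = np.minimum(fd, 0.45)  # baseline motion stays below the 0.5 mm threshold
    for frame in fd_spike_frames:
        if not 0 <= frame < n_frames:
            raise InvalidArgumentError(f"spike frame {frame} outside series")
        fd[frame] = fd_spike_mm
    return series, fd


# --------------------------------------------------------------------------
# tau cohorts
# --------------------------------------------------------------------------

def _distance_to_set(matrix: np.ndarray, rois: np.ndarray) -> np.ndarray:
    """Mean shortest-path distance from every ROI to an epicentre set.

    Matches the analysis-side epicentre-distance definition (mean over the
    set); a member's own term is zero, so a tightly coupled epicentre sits
    well below its neighbours.
    """
    return matrix[:, rois].mean(axis=1)


def distance_coupling(connectome_distance: ConnectomeDistance | np.ndarray,
                      length_scale: float = 1.0) -> np.ndarray:
    """Noise-coupling kernel decaying with functional distance.

    ``K_ij = exp(-d_ij / (length_scale * mean(d)))``, projected to the
    nearest valid correlation matrix.  Feeding this to
    :func:`simulate_tau_cohort` as ``noise_coupling`` plants regional noise
    whose correlation decreases continuously with functional distance —
    functionally close regions accumulate tau together.
    """
    matrix = (connectome_distance.matrix
              if isinstance(connectome_distance, ConnectomeDistance)
              else np.asarray(connectome_distance, dtype=float))
    iu = np.triu_indices(matrix.shape[0], k=1)
    finite = np.isfinite(matrix[iu])
    d_scale = float(matrix[iu][finite].mean()) if finite.any() else 1.0
    with np.errstate(over="ignore"):
        k = np.exp(-matrix / (length_scale * d_scale))
    np.fill_diagonal(k, 0.0)
    eigval, eigvec = np.linalg.eigh(k + np.eye(k.shape[0]))
    if eigval[0] < 1e-6:
        c = (eigvec * np.clip(eigval, 1e-6, None)) @ eigvec.T
        dd = np.sqrt(np.diag(c))
        k = c / np.outer(dd, dd) - np.eye(k.shape[0])
        np.fill_diagonal(k, 0.0)
    return k


def simulate_tau_cohort(connectome_distance: ConnectomeDistance | np.ndarray,
                        scenario: SpreadScenario, n_subjects: int,
                        timepoints: tuple[float, ...] = (0.0,),
                        n_controls: int = 0,
                        noise_coupling: np.ndarray | None = None,
                        ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a long-format tau-PET cohort with planted connectome spread.

    Parameters
    ----------
    connectome_distance:
        ROI x ROI shortest-path distances defining epicentre proximity.
    timepoints:
        Follow-up times in years; must be sorted with the first equal to 0.
    n_controls:
        Tau-negative subjects (amplitude 0) appended after the patients; the
        mixture-model harmonization needs both ends of the SUVR range.
    noise_coupling:
        Optional ROI x ROI weight matrix (typically the true connectome)
        shaping the correlated component of the regional noise.  Required
        when ``scenario.noise_correlation > 0``.
    """
    matrix = (connectome_distance.matrix
              if isinstance(connectome_distance, ConnectomeDistance)
              else np.asarray(connectome_distance, dtype=float))
    n_roi = matrix.shape[0]
    epi = np.asarray(scenario.epicentre_rois, dtype=int)
    if epi.min() < 0 or epi.max() >= n_roi:
        raise InvalidArgumentError("epicentre ROI outside the atlas")
    tps = tuple(float(t) for t in timepoints)
    if sorted(tps) != list(tps) or tps[0] != 0.0:
        raise InvalidArgumentError("timepoints must be sorted with first = 0")
    if n_subjects < 1:
        raise InvalidArgumentError("need at least one subject")

    rho = scenario.noise_correlation
    chol = None
    if rho > 0 and scenario.noise_sd > 0:
        if noise_coupling is None:
            raise InvalidArgumentError(
                "noise_correlation > 0 requires a noise_coupling matrix")
        corr = _correlation_from_weights(noise_coupling)
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(n_roi))

    d = _distance_to_set(matrix, epi)
    # decay_rate is expressed per mean inter-ROI connectome distance: raw
    # path-length units depend on the weight scale and threshold, so the
    # normalization keeps scenario parameters portable across connectomes
    iu = np.triu_indices(n_roi, k=1)
    finite = np.isfinite(matrix[iu])
    d_scale = float(matrix[iu][finite].mean()) if finite.any() else 1.0
    with np.errstate(over="ignore"):
        e = np.exp(-scenario.decay_rate * d / d_scale)   # exp(-inf) -> 0 if disconnected
    expected_tau = scenario.baseline_suvr + scenario.amplitude * e

    rng = np.random.default_rng(scenario.seed)
    sites = list(scenario.site_effects)
    tracers = list(scenario.tracer_scale)
    rows = []
    total = n_subjects + n_controls
    for s in range(total):
        group = "patient" if s < n_subjects else "control"
        subject = f"{'sub' if group == 'patient' else 'ctl'}-{s:04d}"
        age = float(rng.uniform(55.0, 85.0))
        sex = "female" if rng.random() < 0.5 else "male"
        site = sites[int(rng.integers(len(sites)))]
        tracer = tracers[int(rng.integers(len(tracers)))]
        scale = scenario.tracer_scale[tracer]
        covar = (scenario.site_effects[site]
                 + scenario.age_slope * (age - 70.0)
                 + (scenario.sex_offset if sex == "female" else 0.0))
        if group == "patient":
            # mean-preserving lognormal severity: cohorts are heterogeneous in
            # how far tau has progressed, which is what makes intermediate
            # regions show intermediate positivity rates across subjects
            sev = float(np.exp(scenario.severity_sd * rng.standard_normal()
                               - scenario.severity_sd ** 2 / 2.0))
            amp = scenario.amplitude * sev
        else:
            amp = 0.0
        for t in tps:
            signal = scenario.baseline_suvr + amp * e * (1.0 + scenario.accumulation_rate * t * e)
            if scenario.noise_sd > 0:
                eps = rng.standard_normal(n_roi)
                if chol is not None:
                    shared = chol @ rng.standard_normal(n_roi)
                    eps = np.sqrt(1.0 - rho) * eps + np.sqrt(rho) * shared
                noise = scenario.noise_sd * eps
            else:
                noise = np.zeros(n_roi)
            suvr = scale * signal + covar + noise
            rows.append(pd.DataFrame({
                "subject_id": subject, "roi_id": np.arange(n_roi),
                "timepoint_years": t, "suvr": suvr, "tracer": tracer,
                "site": site, "age": age, "sex": sex, "group": group,
            }))
    cohort = pd.concat(rows, ignore_index=True)
    truth = SyntheticTruth(scenario=scenario, true_distance_to_epicentre=d,
                           expected_tau=expected_tau)
    return cohort, truth


def simulate_postmortem(expected_tau: np.ndarray, ordinal_cuts: tuple[float, ...],
                        noise_sd: float, n_subjects: int, seed: int,
                        density_scale: float = 25.0) -> pd.DataFrame:
    """Simulate post-mortem tau: NFT densities and ordinal 0-3 severity ratings.

    Per subject and ROI a latent tau burden is drawn around ``expected_tau``;
    the quantitative density (tangles per mm^2) is the nonnegative latent
    burden times ``density_scale`` and the ordinal rating is the bin index of
    the latent burden among the three ``ordinal_cuts``.
    """
    cuts = np.asarray(ordinal_cuts, dtype=float)
    if cuts.ndim != 1 or np.any(np.diff(cuts) <= 0):
        raise InvalidArgumentError("ordinal_cuts must be strictly increasing")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    expected = np.asarray(expected_tau, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        latent = expected + rng.normal(0.0, noise_sd, size=expected.size)
        rows.append(pd.DataFrame({
            "subject_id": f"pm-{s:04d}",
            "roi_id": np.arange(expected.size),
            "rating": np.digitize(latent, cuts),
            "density": np.maximum(latent, 0.0) * density_scale,
            "age": float(rng.uniform(60.0, 90.0)),
            "sex": "female" if rng.random() < 0.5 else "male",
        }))
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# bundled study conditions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Study:
    """A self-consistent synthetic study: atlas, true connectome, distances."""

    atlas: RoiAtlas
    connectome: np.ndarray
    distance: ConnectomeDistance
    scenario: SpreadScenario


def strong_coupling_scenario(epicentre_rois: tuple[int, ...], seed: int) -> SpreadScenario:
    """The default strong-coupling spread scenario used throughout the docs."""
    return SpreadScenario(epicentre_rois=tuple(int(r) for r in epicentre_rois), seed=seed)


def build_study(seed: int, n_roi: int = 200, n_networks: int = 7,
                within_strength: float = 0.7, between_strength: float = 0.3,
                connectome_noise_sd: float = 0.02, between_jitter: float = 0.12,
                epicentre_coupling: float = 0.95, density: float = 0.30,
                n_epicentre: int = 10) -> Study:
    """Build the default synthetic study conditions.

    The connectome is modular with moderate, per-network-pair heterogeneous
    between-network coupling, so that shortest-path distances spread over a
    usable dynamic range.  The epicentre is planted as the first
    ``n_epicentre`` ROIs of the first network and made a tightly coupled
    sub-cluster (mutual weight ``epicentre_coupling``), reflecting that
    disease epicentres sit in strongly interconnected regions.
    """
    atlas = generate_atlas(n_roi, n_networks, seed=seed)
    first_network = atlas.rois_in_network(atlas.networks[0])
    epi = np.asarray(first_network[:n_epicentre])
    # the template must be connected after density thresholding (as a real
    # group connectome is); redraw the coupling heterogeneity until it is
    for attempt in range(50):
        w = generate_connectome(atlas, within_strength, between_strength,
                                noise_sd=connectome_noise_sd,
                                seed=seed + 1 + 1_000_003 * attempt,
                                between_jitter=between_jitter)
        w[np.ix_(epi, epi)] = epicentre_coupling
        np.fill_diagonal(w, 0.0)
        dist = fc_to_distance(
            threshold_density(np.arctanh(np.clip(w, -0.999999, 0.999999)),
                              density=density), density=density)
        if dist.n_disconnected_pairs == 0:
            break
    else:
        raise FitFailureError("could not draw a connected thresholded template")
    scenario = strong_coupling_scenario(tuple(int(r) for r in epi), seed=seed + 2)
    return Study(atlas=atlas, connectome=w, distance=dist, scenario=scenario)
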