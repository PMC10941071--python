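"""Seeded synthetic cohorts with a planted cortical hierarchy.

The generator emulates the data structure the downstream analyses assume:
an adult-lifespan cohort (default 176 subjects, ages 20-78) measured on a
bilateral parcel atlas (default 400 parcels, 7 networks), with

* receptor maps organized along a planted unimodal-transmodal template
  ``g`` with per-subject hierarchy strength ``h_s``, age/sex effects,
  network-modular covariance, and spatially smooth residual variation;
* cortical thickness sharing a latent covariance component with the
  receptor maps;
* BOLD series built from latent factors whose parcel loadings follow the
  template and are stronger within networks.

Every draw is reproducible from ``CohortSpec.seed``; the ``truth`` record
stores the planted quantities so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import NETWORKS, ParcelAtlas, ParcelFeatureMatrix

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))
_HEAD_RADIUS_MM = 70.0
_HEMI_OFFSET_MM = 8.0


def make_atlas(n_parcels: int, seed: int = 0) -> ParcelAtlas:
    """Quasi-uniform, mirror-symmetric spherical parcel lattice.

    Half the parcels are placed on the right-hemisphere half-sphere using a
    Fibonacci lattice (with a seeded phase so distinct seeds give distinct
    but equally uniform lattices) and mirrored across x=0 to form the left
    hemisphere.  Network labels are seven contiguous latitude bands per
    hemisphere — spatially contiguous caps, so label maps carry the spatial
    autocorrelation that spin tests rely on.  Volumetric centroids are the
    sphere coordinates scaled to a 70 mm head radius with the hemispheres
    pushed apart along x.

    Parameters
    ----------
    n_parcels : even integer >= 14 (so every network is represented in
        each hemisphere).
    """
    if n_parcels % 2 != 0 or n_parcels < 14:
        raise ValueError("n_parcels must be even and >= 14")
    n = n_parcels // 2
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, np.pi)

    i = np.arange(n)
    z = -1.0 + 2.0 * (i + 0.5) / n
    # azimuth confined to (-pi/2, pi/2) => x > 0 (right hemisphere)
    phi = np.mod(i * _GOLDEN_ANGLE + phase, np.pi) - np.pi / 2.0
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    right = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    right /= np.linalg.norm(right, axis=1, keepdims=True)
    left = right * np.array([-1.0, 1.0, 1.0])

    sphere = np.vstack([left, right])
    hemisphere = np.array(["L"] * n + ["R"] * n, dtype=object)

    # 7 contiguous latitude bands per hemisphere, identical across
    # hemispheres by mirror symmetry of the lattice
    network = np.empty(n_parcels, dtype=object)
    order = np.argsort(z, kind="stable")
    bands = np.array_split(order, len(NETWORKS))
    for label, idx in zip(NETWORKS, bands):
        network[idx] = label            # left hemisphere rows 0..n-1
        network[idx + n] = label        # mirrored right hemisphere rows

    offset = np.where(hemisphere == "L", -_HEMI_OFFSET_MM, _HEMI_OFFSET_MM)
    centroid = sphere * _HEAD_RADIUS_MM
    centroid[:, 0] += offset

    return ParcelAtlas(
        parcel_id=np.arange(n_parcels),
        hemisphere=hemisphere,
        network=network,
        sphere_xyz=sphere,
        centroid_xyz=centroid,
    )


def hierarchy_template(atlas: ParcelAtlas) -> np.ndarray:
    """Default planted unimodal-transmodal axis: standardized sphere z.

    The network bands are latitude bands, so this axis runs from the
    sensory end (Vis) to the associative end (Default) of the label order.
    """
    z = atlas.sphere_xyz[:, 2]
    return (z - z.mean()) / z.std()


def spatial_kernel(atlas: ParcelAtlas, length_scale: float) -> np.ndarray:
    """Gaussian kernel on chord distance between sphere coordinates.

    Used both for the generator's smooth residual component and for
    constructing smooth isotropic null maps in calibration studies.
    """
    xyz = atlas.sphere_xyz
    d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * length_scale**2))


def smooth_maps(atlas: ParcelAtlas, n_maps: int, length_scale: float,
                rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_maps`` independent smooth isotropic maps (rows), unit variance.

    Maps are Gaussian-kernel-weighted mixtures of white noise, standardized
    per map; spatial autocorrelation is controlled by ``length_scale``
    (chord units on the unit sphere).
    """
    K = spatial_kernel(atlas, length_scale)
    white = rng.standard_normal((n_maps, atlas.n_parcels))
    maps = white @ K.T
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= maps.std(axis=1, keepdims=True)
    return maps


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort (defaults = the study conditions).

    Ages are drawn stratified by decade over ``age_range`` (emulating a
    lifespan sample with near-equal decade cells); ``hierarchy_mean``/``sd``
    set the distribution of the per-subject hierarchy coefficient h_s;
    age slopes are per centered decade.  ``noise_sd`` is the white residual
    scale of the receptor maps; ``spatial_noise_sd``/``spatial_noise_scale``
    control an additional spatially smooth residual component (set to 0 to
    recover a purely white-noise model).  ``modularity`` scales the
    within-network BOLD factor loadings; ``receptor_network_sd`` the
    per-subject network factors in the receptor maps.
    """

    n_subjects: int = 176
    age_range: tuple = (20.0, 78.0)
    sex_ratio: float = 0.5
    gradient_template: np.ndarray | None = None
    hierarchy_mean: float = 0.6
    hierarchy_sd: float = 0.4
    age_slope_linear: float = -0.10
    age_slope_quadratic: float = -0.02
    sex_effect: float = 0.10
    modularity: float = 0.15
    receptor_network_sd: float = 0.25
    #: per-network multiplier on both the receptor network factors and the
    #: BOLD modular loadings, ordered as NETWORKS (sensory -> associative):
    #: associative systems are more coherent in both modalities, which
    #: plants the elevated associative nodal density and the shared
    #: network-level coupling between receptor covariance and FC
    network_strengths: tuple = (0.6, 0.7, 0.85, 1.0, 1.1, 1.25, 1.35)
    #: spread of per-parcel "hub" loadings on the network factors, shared
    #: between the receptor maps and the BOLD modular loadings: parcels
    #: that covary strongly with their network in receptor expression are
    #: also more strongly modularly connected, planting an edge-level
    #: within-network coupling between the two modalities
    hub_spread: float = 0.5
    #: correlation between the thickness and receptor network factors:
    #: thickness covariance is network-organized and overlaps with, but is
    #: not identical to, the receptor covariance (mediation stays partial)
    thickness_share_corr: float = 0.6
    noise_sd: float = 1.0
    spatial_noise_sd: float = 0.2
    spatial_noise_scale: float = 0.3
    thickness_loading: float = 0.4
    thickness_noise_sd: float = 0.15
    n_timepoints: int = 240
    bold_axis_strength: float = 1.4
    bold_noise_sd: float = 1.0
    mean_level: float = 2.0
    mean_template_slope: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.modularity < 0:
            raise ValueError("modularity must be >= 0")


@dataclass
class SyntheticCohort:
    """A simulated dataset plus the record of its planted parameters."""

    atlas: ParcelAtlas
    d1dr: ParcelFeatureMatrix
    thickness: ParcelFeatureMatrix
    timeseries: dict            # subject id -> parcels x timepoints array
    covariates: pd.DataFrame    # subject, age, sex, fd
    truth: dict


def _draw_ages(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.age_range
    edges = np.linspace(lo, min(hi + 2.0, lo + 60.0), 7)[:6]
    n = spec.n_subjects
    per = np.full(6, n // 6)
    per[: n % 6] += 1
    ages = []
    for b, count in enumerate(per):
        b_lo = edges[b]
        b_hi = min(b_lo + 10.0, hi)
        ages.append(rng.uniform(b_lo, b_hi, count))
    ages = np.concatenate(ages)
    rng.shuffle(ages)
    return ages


def simulate_cohort(spec: CohortSpec, atlas: ParcelAtlas) -> SyntheticCohort:
    """Generate one cohort: receptor maps, thickness, BOLD, covariates, truth.

    Receptor model per subject s and parcel p::

        d1dr[s, p] = mu(p) + h_s * g(p) + b1*age_c + b2*age_c^2 + bsex*sex
                     + nu * f[s, network(p)] + smooth_s(p) + white noise

    with ``mu`` co-linear with the template ``g``, ``age_c`` the centered age
    in decades, ``f`` iid standard-normal per-subject network factors and
    ``smooth_s`` a spatially smooth residual field.
    """
    P = atlas.n_parcels
    g = spec.gradient_template
    if g is None:
        g = hierarchy_template(atlas)
    g = np.asarray(g, dtype=float)
    if g.shape != (P,):
        raise ValueError(f"gradient_template must have length {P}")

    rng = np.random.default_rng(spec.seed)
    ages = _draw_ages(spec, rng)
    n = spec.n_subjects
    n_female = int(round(spec.sex_ratio * n))
    sex = np.zeros(n)
    sex[rng.permutation(n)[:n_female]] = 1.0
    fd = np.exp(rng.normal(np.log(0.15), 0.4, n))
    subjects = [f"sub-{i:04d}" for i in range(n)]
    covariates = pd.DataFrame({"age": ages, "sex": sex, "fd": fd}, index=subjects)

    age_c = (ages - ages.mean()) / 10.0
    h = rng.normal(spec.hierarchy_mean, spec.hierarchy_sd, n)
    mu = spec.mean_level + spec.mean_template_slope * g

    net_of = np.array([NETWORKS.index(lbl) for lbl in atlas.network])
    strengths = np.asarray(spec.network_strengths, dtype=float)
    if strengths.shape != (len(NETWORKS),):
        raise ValueError("network_strengths must have one entry per network")
    net_factors = rng.standard_normal((n, len(NETWORKS)))
    # per-parcel hub loadings, shared with the BOLD modular loadings below;
    # thickness gets a partially overlapping hub profile so its edge-level
    # covariance pattern correlates with, but is not collinear with, the
    # receptor one
    hub_u = rng.random(P) - 0.5
    hub = 1.0 + spec.hub_spread * hub_u
    alpha = spec.thickness_share_corr
    hub_th = 1.0 + spec.hub_spread * (
        alpha * hub_u + np.sqrt(1.0 - alpha**2) * (rng.random(P) - 0.5))
    net_loading = strengths[net_of] * hub
    # thickness is network-organized but without the associative strength
    # gradient: its modular covariance overlaps the receptor one only
    # through shared network identity and the partially shared hubs
    net_loading_th = hub_th

    d1 = (
        mu[None, :]
        + h[:, None] * g[None, :]
        + (spec.age_slope_linear * age_c
           + spec.age_slope_quadratic * age_c**2
           + spec.sex_effect * sex)[:, None]
        + spec.receptor_network_sd * net_loading[None, :] * net_factors[:, net_of]
        + rng.normal(0.0, spec.noise_sd, (n, P))
    )
    if spec.spatial_noise_sd > 0:
        d1 += spec.spatial_noise_sd * smooth_maps(
            atlas, n, spec.spatial_noise_scale, rng)

    # thickness shares the structured (axis + modular) receptor component at
    # a single loading; its network factors are only partially correlated
    # with the receptor ones, so the overlap is real but incomplete
    th_factors = (alpha * net_factors
                  + np.sqrt(1.0 - alpha**2)
                  * rng.standard_normal((n, len(NETWORKS))))
    shared = (h[:, None] * g[None, :]
              + spec.receptor_network_sd * net_loading_th[None, :]
              * th_factors[:, net_of])
    thick = (
        2.5
        + spec.thickness_loading * shared
        + rng.normal(0.0, spec.thickness_noise_sd, (n, P))
    )
    if spec.spatial_noise_sd > 0:
        thick += 0.5 * spec.thickness_noise_sd * smooth_maps(
            atlas, n, spec.spatial_noise_scale, rng)

    # BOLD: latent factors whose loadings vary smoothly along the planted
    # axis (a chain of Gaussian bumps over g, so connectivity profiles decay
    # continuously with hierarchy distance) plus network factors scaled by
    # the modularity parameter, plus white observation noise.
    T = spec.n_timepoints
    centers = np.quantile(g, np.linspace(0.05, 0.95, 9))
    width = 1.5 * np.mean(np.diff(centers))
    L = np.exp(-((g[:, None] - centers[None, :]) ** 2) / (2.0 * width**2))
    L /= np.linalg.norm(L, axis=1, keepdims=True)
    L *= spec.bold_axis_strength
    timeseries = {}
    for s, sid in enumerate(subjects):
        z_axis = rng.standard_normal((len(centers), T))
        z_net = rng.standard_normal((len(NETWORKS), T))
        ts = (
            L @ z_axis
            + spec.modularity * net_loading[:, None] * z_net[net_of, :]
            + rng.normal(0.0, spec.bold_noise_sd, (P, T))
        )
        timeseries[sid] = ts

    truth = {
        "h": h,
        "gradient_template": g,
        "network_labels": np.array(atlas.network, dtype=object),
        "mu": mu,
        "age_slope_linear": spec.age_slope_linear,
        "age_slope_quadratic": spec.age_slope_quadratic,
        "sex_effect": spec.sex_effect,
        "receptor_network_sd": spec.receptor_network_sd,
        "modularity": spec.modularity,
        "network_strengths": strengths,
        "hub_loadings": hub,
    }

    d1dr = ParcelFeatureMatrix(d1, subjects, covariates, modality="bp")
    thickness = ParcelFeatureMatrix(thick, subjects, covariates, modality="thickness")
    return SyntheticCohort(atlas, d1dr, thickness, timeseries, covariates, truth)


def inject_outliers(fm: ParcelFeatureMatrix, rate: float, magnitude: float,
                    seed: int = 0):
    """Displace a random fraction of cells by +/- magnitude * stratum IQR.

    Exactly ``floor(rate * n_cells)`` distinct (subject, parcel) cells are
    displaced; the stratum is the subject's age decade x sex, and the IQR is
    that parcel's type-7 IQR within the stratum (parcel-wide IQR when the
    stratum IQR is zero).  Returns the perturbed matrix and the boolean
    truth mask of displaced cells.
    """
    if not (0.0 <= rate <= 0.05):
        raise ValueError("rate must be in [0, 0.05]")
    values = fm.values
    n, P = values.shape
    mask = np.zeros((n, P), dtype=bool)
    k = int(np.floor(rate * n * P))
    if k == 0:
        return fm.copy_with(values), mask

    rng = np.random.default_rng(seed)
    flat = rng.choice(n * P, size=k, replace=False)
    rows, cols = np.unravel_index(flat, (n, P))
    signs = rng.choice([-1.0, 1.0], size=k)

    from .covariance import _stratify  # shared stratification rule
    strata = _stratify(fm.covariates["age"].to_numpy(),
                       fm.covariates["sex"].to_numpy(), min_size=4)

    out = values.copy()
    for r, c, sg in zip(rows, cols, signs):
        idx = np.flatnonzero(strata == strata[r])
        q1, q3 = np.percentile(values[idx, c], [25, 75])
        iqr = q3 - q1
        if iqr == 0.0:
            q1, q3 = np.percentile(values[:, c], [25, 75])
            iqr = q3 - q1
        out[r, c] += sg * magnitude * iqr
        mask[r, c] = True
    return fm.copy_with(out), mask


# ---------------------------------------------------------------------------
# cohort I/O (the TSV formats read by the rest of the pipeline)

def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.atlas.to_tsv(out / "atlas.tsv")
    cohort.d1dr.to_tsv(out / "d1dr.tsv")
    cohort.thickness.to_tsv(out / "thickness.tsv")
    cov = cohort.covariates.copy()
    cov.index.name = "subject"
    cov.to_csv(out / "covariates.tsv", sep="\t", float_format="%.10g")
    for sid, ts in cohort.timeseries.items():
        pd.DataFrame(ts).to_csv(out / f"ts_{sid}.tsv", sep="\t", index=False,
                                header=False, float_format="%.6g")
    truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in cohort.truth.items()}
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def read_cohort(in_dir) -> SyntheticCohort:
    src = Path(in_dir)
    atlas = ParcelAtlas.from_tsv(src / "atlas.tsv")
    covariates = pd.read_csv(src / "covariates.tsv", sep="\t", index_col="subject")
    d1dr = ParcelFeatureMatrix.from_tsv(src / "d1dr.tsv", covariates, "bp")
    thickness = ParcelFeatureMatrix.from_tsv(src / "thickness.tsv", covariates,
                                             "thickness")
    timeseries = {}
    for f in sorted(src.glob("ts_*.tsv")):
        sid = f.stem[3:]
        timeseries[sid] = pd.read_csv(f, sep="\t", header=None).to_numpy(dtype=float)
    truth = {}
    tf = src / "truth.json"
    if tf.exists():
        truth = {k: (np.asarray(v) if isinstance(v, list) else v)
                 for k, v in json.loads(tf.read_text()).items()}
    return SyntheticCohort(atlas, d1dr, thickness, timeseries, covariates, truth)
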