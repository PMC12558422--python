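"""Synthetic city and cohort generator.

Emulates a mid-size city (regular 50-m raster, 7 facility types scattered as
homogeneous Poisson point processes, 6 socioeconomic clusters as a
nearest-seed partition) and an older-adult cohort (default n=251) whose
marginals and urban-index dependencies are calibrated to the study
conditions this package models:

* frailty prevalence 17.5% with a positive logit-linear dependence on the
  standardized urban-quality index (intercept solved by bisection so the
  cohort-average probability hits the target exactly);
* FTS-5 domain vectors drawn conditional on the frailty label, so
  frail <=> total > 25 holds by construction, with mean total rising with
  the index;
* BMI per frailty group (frail 31.5 +/- 4.4, nonfrail 28.5 +/- 4.5 kg/m^2),
  handgrip declining with the index (quartile means calibrated by moment
  matching to Q1 ~ 22.8 / Q4 ~ 19.1 kg);
* laboratory analytes tied to the index through a Gaussian copula whose
  latent correlation is set from the target Spearman rho via
  rho_p = 2 sin(pi rho_s / 6), with truncated-normal marginals;
* a CONUT-driving nutritional-risk latent, from which albumin, lymphocytes
  and cholesterol are drawn with negative loadings, calibrated so
  Spearman(index, CONUT total) matches its target.

Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, ndtr, ndtri

from .facilities import DEFAULT_BANDS, FacilityLayer, FacilityType
from .grid import GridSpec, RasterField
from .index import build_summary_index, extract_index_at_points

__all__ = [
    "CityConfig",
    "CohortConfig",
    "City",
    "Cohort",
    "spearman_to_pearson",
    "calibrate_logistic_intercept",
    "generate_city",
    "generate_cohort",
    "simulate_study",
    "calibrate_handgrip",
    "calibrate_conut_latent",
]


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate normal inducing Spearman ``rho_s``.

    Inverts Spearman's rho for the Gaussian copula: rho_p = 2 sin(pi rho_s / 6).
    """
    if abs(rho_s) > 1:
        raise ValueError(f"|rho_s| must be <= 1, got {rho_s}")
    return float(2 * np.sin(np.pi * rho_s / 6))


def calibrate_logistic_intercept(target_prev: float, beta: float, z_values) -> float:
    """Intercept alpha with mean(expit(alpha + beta z)) = target_prev.

    The mean is strictly increasing in alpha, so plain bisection converges;
    iterated to an interval width of 1e-12 (mean within ~1e-6 of target).
    """
    if not 0 < target_prev < 1:
        raise ValueError("target prevalence must be in (0, 1)")
    z = np.asarray(z_values, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z values must be finite")

    def f(alpha: float) -> float:
        return float(np.mean(expit(alpha + beta * z))) - target_prev

    lo, hi = -60.0, 60.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("no finite bracket for the intercept")
    while hi - lo > 1e-12:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# configuration


def _default_intensities() -> dict[FacilityType, float]:
    # points/km^2, tuned so each layer's nearest-facility distance straddles
    # its own bands (roughly half the city in the "close" zone per layer)
    return {
        FacilityType.vegetables_fruits: 2.5,
        FacilityType.senior_centers: 0.9,
        FacilityType.pharmacies: 0.9,
        FacilityType.emergency_health: 0.25,
        FacilityType.squares_parks: 5.5,
        FacilityType.family_health: 0.45,
        FacilityType.exercise_facilities: 1.4,
    }


#: Cluster seed positions as fractions of the grid extent: six
#: sociodemographic sectors (NE high SES, SE low SES, N lower-middle,
#: historic center, S medium-high, industrial belt).
_CLUSTER_SEED_FRACTIONS = (
    (0.75, 0.75),
    (0.75, 0.25),
    (0.35, 0.85),
    (0.50, 0.50),
    (0.25, 0.25),
    (0.88, 0.50),
)


@dataclass
class CityConfig:
    grid: GridSpec = field(default_factory=GridSpec)
    intensities: dict[FacilityType, float] = field(default_factory=_default_intensities)
    # absolute (x, y) in meters; default scales with the grid extent
    cluster_seeds: tuple[tuple[float, float], ...] | None = None
    # share of participants living in each cluster
    cluster_weights: tuple[float, ...] = (0.12, 0.175, 0.185, 0.11, 0.235, 0.175)

    def __post_init__(self) -> None:
        if self.cluster_seeds is None:
            g = self.grid
            self.cluster_seeds = tuple(
                (g.origin_x + fx * g.width, g.origin_y + fy * g.height)
                for fx, fy in _CLUSTER_SEED_FRACTIONS
            )
        self.intensities = {FacilityType(k): float(v) for k, v in self.intensities.items()}
        if any(v <= 0 for v in self.intensities.values()):
            raise ValueError("facility intensities must be > 0")
        if len(self.cluster_seeds) != 6:
            raise ValueError("exactly 6 cluster seeds required")
        if len(self.cluster_weights) != 6 or any(w <= 0 for w in self.cluster_weights):
            raise ValueError("6 positive cluster weights required")


@dataclass
class CohortConfig:
    n_participants: int = 251
    n_lab_subset: int = 70
    target_frailty_prevalence: float = 0.175
    frailty_index_slope: float = 0.4  # logit units per index SD

    # FTS-5 totals conditional on frailty label (truncated normal)
    fts_nonfrail_mean: float = 11.5
    fts_frail_mean: float = 29.0
    fts_nonfrail_sd: float = 6.0
    fts_frail_sd: float = 3.5
    fts_index_slope: float = 1.0  # points per index SD

    bmi_frail: tuple[float, float] = (31.5, 4.4)
    bmi_nonfrail: tuple[float, float] = (28.5, 4.5)
    age_frail: tuple[float, float] = (75.6, 7.4)
    age_nonfrail: tuple[float, float] = (73.8, 5.2)
    female_prop: float = 0.745
    gait_speed: tuple[float, float] = (0.95, 0.25)
    gait_index_slope: float = 0.03  # m/s lost per index SD

    # handgrip = base - slope * z + noise; base/slope from calibrate_handgrip
    # against quartile targets Q1 ~ 22.8, Q4 ~ 19.1 kg
    handgrip_base: float = 21.17
    handgrip_slope: float = 1.46
    handgrip_sd: float = 6.5

    # target Spearman rho between index and each marker (lab subset)
    lab_target_rho: dict[str, float] = field(
        default_factory=lambda: {
            "bilirubin": 0.33,
            "serum_iron": 0.27,
            "transferrin_sat": 0.24,
            "rbc": 0.26,
            "rdw": 0.23,
        }
    )
    # truncated-normal marginal (mean, sd) per analyte
    lab_marginals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "bilirubin": (0.70, 0.30),
            "serum_iron": (85.0, 30.0),
            "transferrin_sat": (28.0, 10.0),
            "rbc": (4.60, 0.50),
            "rdw": (13.5, 1.2),
            "albumin": (4.00, 0.35),
            "lymphocytes": (1900.0, 600.0),
            "cholesterol": (190.0, 40.0),
        }
    )
    conut_target_rho: float = 0.25
    # Spearman rho between index and the latent nutritional-risk factor;
    # inflated above conut_target_rho (calibrate_conut_latent) because the
    # coarse CONUT banding attenuates rank correlation
    conut_latent_spearman: float = 0.34
    conut_loading: float = 0.85  # |loading| of each CONUT analyte on the risk factor

    def __post_init__(self) -> None:
        if not 0 < self.target_frailty_prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_lab_subset > self.n_participants:
            raise ValueError("lab subset larger than cohort")
        if any(abs(r) >= 1 for r in self.lab_target_rho.values()):
            raise ValueError("|rho| must be < 1")
        if any(sd <= 0 for _, sd in self.lab_marginals.values()):
            raise ValueError("marginal SDs must be > 0")


# ---------------------------------------------------------------------------
# city


@dataclass
class City:
    grid: GridSpec
    layers: dict[FacilityType, FacilityLayer]
    cluster_raster: np.ndarray  # (n_rows, n_cols) of cluster ids 1..6
    config: CityConfig
    seed: int

    @cached_property
    def index_raster(self) -> RasterField:
        return build_summary_index(self.grid, list(self.layers.values()))


def generate_city(config: CityConfig, seed: int) -> City:
    """Sample facility layers (homogeneous Poisson, >= 1 point enforced by
    resampling) and the nearest-seed cluster partition of the grid."""
    grid = config.grid
    area_km2 = grid.width * grid.height / 1e6
    if area_km2 <= 0:
        raise ValueError("zero-area grid")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.extent

    layers: dict[FacilityType, FacilityLayer] = {}
    for ftype in FacilityType:
        lam = config.intensities[ftype] * area_km2
        n = 0
        while n < 1:
            n = rng.poisson(lam)
        pts = np.column_stack(
            [rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)]
        )
        layers[ftype] = FacilityLayer(ftype, pts, DEFAULT_BANDS[ftype])

    cx, cy = grid.cell_centers()
    seeds = np.asarray(config.cluster_seeds)
    d2 = (cx[..., None] - seeds[:, 0]) ** 2 + (cy[..., None] - seeds[:, 1]) ** 2
    cluster_raster = np.argmin(d2, axis=-1) + 1
    return City(grid, layers, cluster_raster, config, seed)


# ---------------------------------------------------------------------------
# cohort


@dataclass
class Cohort:
    frame: pd.DataFrame
    lab_subset: np.ndarray  # participant_id values with laboratory panels
    provenance: dict

    @property
    def lab_frame(self) -> pd.DataFrame:
        return self.frame[self.frame["participant_id"].isin(self.lab_subset)]


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Blom normal scores of the (average) ranks of ``values``."""
    r = sps.rankdata(values, method="average")
    n = len(values)
    return ndtri((r - 0.375) / (n + 0.25))


def _trunc_ppf(u: np.ndarray, mean: float, sd: float, upper: float = np.inf) -> np.ndarray:
    a = (0.0 - mean) / sd
    b = (upper - mean) / sd if np.isfinite(upper) else np.inf
    return sps.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _split_total_into_domains(
    totals: np.ndarray, rng: np.random.Generator, max_tries: int = 200
) -> np.ndarray:
    """Split each FTS-5 total into 5 domain scores in [0, 10].

    Dirichlet proportions with rejection of splits exceeding the per-domain
    cap; stubborn rows (totals near 50 need nearly equal splits) fall back to
    clipping at 10 and redistributing the excess over remaining headroom.
    """
    n = len(totals)
    out = np.empty((n, 5))
    pending = np.arange(n)
    for _ in range(max_tries):
        if pending.size == 0:
            break
        props = rng.dirichlet(np.full(5, 2.0), size=pending.size)
        cand = props * totals[pending, None]
        ok = np.all(cand <= 10.0, axis=1)
        out[pending[ok]] = cand[ok]
        pending = pending[~ok]
    for i in pending:  # waterfall fallback, always feasible for totals <= 50
        props = rng.dirichlet(np.full(5, 2.0))
        x = props * totals[i]
        for _ in range(10):
            excess = np.clip(x - 10.0, 0, None).sum()
            x = np.minimum(x, 10.0)
            if excess <= 1e-12:
                break
            headroom = 10.0 - x
            if headroom.sum() < excess - 1e-9:
                raise RuntimeError("infeasible conditional sampling of FTS domains")
            x = x + excess * headroom / headroom.sum()
        out[i] = np.minimum(x, 10.0)
    return out


def _sample_locations(city: City, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Participant coordinates: cluster by weight, uniform within a random
    cell of that cluster."""
    grid = city.grid
    weights = np.asarray(city.config.cluster_weights, dtype=float)
    cells_by_cluster = {
        c: np.column_stack(np.nonzero(city.cluster_raster == c)) for c in range(1, 7)
    }
    # a very coarse grid can leave a cluster with no cells; drop it
    nonempty = np.array([len(cells_by_cluster[c]) > 0 for c in range(1, 7)])
    weights = np.where(nonempty, weights, 0.0)
    weights = weights / weights.sum()
    cluster_ids = rng.choice(np.arange(1, 7), size=n, p=weights)
    xy = np.empty((n, 2))
    for i, c in enumerate(cluster_ids):
        cells = cells_by_cluster[c]
        row, col = cells[rng.integers(len(cells))]
        xy[i, 0] = grid.origin_x + (col + rng.random()) * grid.cell_size
        xy[i, 1] = grid.origin_y + (row + rng.random()) * grid.cell_size
    return xy, cluster_ids


def generate_cohort(city: City, config: CohortConfig, seed: int) -> Cohort:
    """Draw a synthetic cohort over ``city``; deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    n = config.n_participants

    xy, cluster_ids = _sample_locations(city, n, rng)
    idx_vals = extract_index_at_points(city.index_raster, xy).astype(float)
    sd = idx_vals.std()
    z = (idx_vals - idx_vals.mean()) / sd if sd > 0 else np.zeros(n)

    # frailty label with index dependence and exact marginal prevalence
    beta = config.frailty_index_slope
    alpha = calibrate_logistic_intercept(config.target_frailty_prevalence, beta, z)
    frail = rng.random(n) < expit(alpha + beta * z)

    # FTS-5 totals conditional on the label (inverse-CDF truncated normal),
    # mean shifted with the index; frail <=> total > 25 by construction
    mean = np.where(frail, config.fts_frail_mean, config.fts_nonfrail_mean)
    mean = mean + config.fts_index_slope * z
    sdv = np.where(frail, config.fts_frail_sd, config.fts_nonfrail_sd)
    lo = np.where(frail, 25.0 + 1e-9, 0.0)
    hi = np.where(frail, 50.0, 25.0)
    a, b = (lo - mean) / sdv, (hi - mean) / sdv
    totals = sps.truncnorm.ppf(rng.random(n), a, b, loc=mean, scale=sdv)
    domains = _split_total_into_domains(totals, rng)

    # demographics and physical measures
    bmi = np.where(
        frail,
        rng.normal(*config.bmi_frail, n),
        rng.normal(*config.bmi_nonfrail, n),
    )
    age = np.clip(
        np.where(frail, rng.normal(*config.age_frail, n), rng.normal(*config.age_nonfrail, n)),
        65.0,
        None,
    )
    female = rng.random(n) < config.female_prop
    gait = np.clip(
        rng.normal(*config.gait_speed, n) - config.gait_index_slope * z, 0.1, None
    )
    handgrip = np.clip(
        config.handgrip_base - config.handgrip_slope * z + rng.normal(0, config.handgrip_sd, n),
        2.0,
        None,
    )

    # laboratory panel: Gaussian copula against the index normal scores
    z_lat = _normal_scores(idx_vals)
    labs: dict[str, np.ndarray] = {}
    for name, rho_s in config.lab_target_rho.items():
        rho_p = spearman_to_pearson(rho_s)
        latent = rho_p * z_lat + np.sqrt(1 - rho_p**2) * rng.standard_normal(n)
        u = ndtr(latent)
        m, s = config.lab_marginals[name]
        upper = 100.0 if name == "transferrin_sat" else np.inf
        labs[name] = _trunc_ppf(u, m, s, upper)

    # nutritional-risk factor driving the CONUT analytes (negative loadings)
    rho_c = spearman_to_pearson(config.conut_latent_spearman)
    risk = rho_c * z_lat + np.sqrt(1 - rho_c**2) * rng.standard_normal(n)
    a_load = config.conut_loading
    for name in ("albumin", "lymphocytes", "cholesterol"):
        latent = -a_load * risk + np.sqrt(1 - a_load**2) * rng.standard_normal(n)
        m, s = config.lab_marginals[name]
        labs[name] = _trunc_ppf(ndtr(latent), m, s)

    pid = np.arange(1, n + 1)
    lab_subset = np.sort(rng.choice(pid, size=config.n_lab_subset, replace=False))

    frame = pd.DataFrame(
        {
            "participant_id": pid,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "cluster": cluster_ids,
            "age": age,
            "sex": np.where(female, "F", "M"),
            "bmi": bmi,
            "handgrip_kg": handgrip,
            "gait_speed_ms": gait,
            "fts_nutrition": domains[:, 0],
            "fts_pa": domains[:, 1],
            "fts_nervous": domains[:, 2],
            "fts_strength": domains[:, 3],
            "fts_gait": domains[:, 4],
            "frail": frail.astype(int),
            "index": idx_vals.astype(int),
            "albumin": labs["albumin"],
            "lymphocytes": labs["lymphocytes"],
            "cholesterol": labs["cholesterol"],
            "bilirubin": labs["bilirubin"],
            "serum_iron": labs["serum_iron"],
            "transferrin_sat": labs["transferrin_sat"],
            "rbc": labs["rbc"],
            "rdw": labs["rdw"],
            "in_lab_subset": np.isin(pid, lab_subset).astype(int),
        }
    )
    provenance = {
        "cohort_seed": int(seed),
        "city_seed": int(city.seed),
        "cohort_config": asdict(config),
        "city_config": {
            "grid": asdict(city.config.grid),
            "intensities": {k.value: v for k, v in city.config.intensities.items()},
            "cluster_seeds": list(map(list, city.config.cluster_seeds)),
            "cluster_weights": list(city.config.cluster_weights),
        },
    }
    # make provenance JSON-friendly
    lt = provenance["cohort_config"]
    lt["lab_target_rho"] = dict(lt["lab_target_rho"])
    return Cohort(frame=frame, lab_subset=lab_subset, provenance=provenance)


def simulate_study(
    seed: int,
    city_config: CityConfig | None = None,
    cohort_config: CohortConfig | None = None,
) -> tuple[City, Cohort]:
    """One seeded end-to-end draw: a city and a cohort living in it."""
    ss = np.random.SeedSequence(seed)
    city_seed, cohort_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    city = generate_city(city_config or CityConfig(), city_seed)
    cohort = generate_cohort(city, cohort_config or CohortConfig(), cohort_seed)
    return city, cohort


# ---------------------------------------------------------------------------
# calibration oracles (used to set the frozen defaults above)


def _quartile_z_means(n_seeds: int, base_seed: int = 0) -> tuple[float, float]:
    from .index import assign_quartiles

    m1, m4 = [], []
    for k in range(n_seeds):
        city, cohort = simulate_study(base_seed + k)
        idx = cohort.frame["index"].to_numpy(float)
        zq = (idx - idx.mean()) / idx.std()
        qa = assign_quartiles(idx)
        m1.append(zq[qa.members("Q1")].mean())
        m4.append(zq[qa.members("Q4")].mean())
    return float(np.mean(m1)), float(np.mean(m4))


def calibrate_handgrip(
    q1_target: float = 22.8, q4_target: float = 19.1, n_seeds: int = 50, base_seed: int = 0
) -> tuple[float, float]:
    """Moment-match handgrip base and index slope to quartile-mean targets.

    With handgrip = base - slope * z + noise, E[handgrip | Q] =
    base - slope * E[z | Q]; the quartile z-means are estimated by
    simulation and the 2x2 linear system solved for (base, slope).
    """
    m1, m4 = _quartile_z_means(n_seeds, base_seed)
    slope = (q1_target - q4_target) / (m4 - m1)
    base = q1_target + slope * m1
    return base, slope


def calibrate_conut_latent(
    target: float = 0.25,
    n_seeds: int = 60,
    base_seed: int = 0,
    bracket: tuple[float, float] = (0.15, 0.60),
    tol: float = 0.005,
) -> float:
    """Bisection for the index<->risk latent Spearman that yields the target
    Spearman(index, CONUT total) on the lab subset, averaged over seeds.

    The coarse CONUT banding attenuates rank correlation, so the latent value
    exceeds the target."""
    from .scoring import LabPanel, score_conut
    from .stats import correlate

    def mean_rho(latent: float) -> float:
        vals = []
        cfg = CohortConfig(conut_latent_spearman=latent)
        for k in range(n_seeds):
            _, cohort = simulate_study(base_seed + k, cohort_config=cfg)
            sub = cohort.lab_frame
            conut = [
                score_conut(
                    LabPanel(albumin=r.albumin, lymphocytes=r.lymphocytes,
                             total_cholesterol=r.cholesterol)
                ).total
                for r in sub.itertuples()
            ]
            vals.append(correlate(sub["index"], conut, "spearman").coefficient)
        return float(np.mean(vals))

    lo, hi = bracket
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mean_rho(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
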