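"""Synthetic neonatal cohort generation.

Emulates the statistical structure of a term/preterm neonatal imaging study:
a spherical Voronoi-style cortical parcellation (143 parcels per hemisphere
by default), realistic gestational/postmenstrual age demographics, and
parcel-wise feature tables for eight cortical metrics (FA, MD, ODI, fICVF,
thickness, surface area, curvature, sulcation) with metric- and
region-specific age trajectories, sex effects, prematurity-graded group
effects and sparse individual extreme deviations. Every injected effect is
recorded in a :class:`GroundTruth` object so downstream stages can be tested
for recovery without any real data.

The generative model for a value of metric ``m`` at parcel ``p`` (region
``r``) in subject ``i`` is::

    y = baseline[m][r] + age_slope[m][r] * (PMA_i - 40)
        + sex_effect[m] * sex_i
        + preterm_effect[m][r] * g(GA_i) * I(preterm_i)
        + extreme_offset + noise,   noise ~ N(0, noise_sd[m][r]^2)

where ``g(GA) = max(0, 37 - GA) / 14`` grades the group effect linearly in
the degree of prematurity (GA 23 weeks -> full effect, GA >= 37 -> none).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The eight cortical metrics, in canonical order.
METRICS: tuple[str, ...] = (
    "FA", "MD", "ODI", "fICVF", "thickness", "SA", "curvature", "sulcation",
)

#: Coarse cortical regions used for region-specific effects.
REGIONS: tuple[str, ...] = (
    "frontal", "parietal", "temporal", "occipital",
    "insula", "cingulate", "somatosensory",
)

#: Metrics bounded to [0, 1] (clipped after generation).
UNIT_INTERVAL_METRICS = ("FA", "ODI", "fICVF")

#: Metrics that must stay strictly positive.
POSITIVE_METRICS = ("MD", "thickness", "SA")

# Region anchor directions on the left unit hemisphere (x <= 0 lateral,
# y anterior, z superior). Mirrored in x for the right hemisphere.
_REGION_ANCHORS = {
    "frontal": (-0.45, 0.80, 0.40),
    "parietal": (-0.45, -0.45, 0.77),
    "temporal": (-0.90, 0.15, -0.40),
    "occipital": (-0.35, -0.92, -0.10),
    "insula": (-0.97, 0.22, 0.05),
    "cingulate": (-0.08, 0.10, 0.60),
    "somatosensory": (-0.50, 0.10, 0.86),
}


class ConfigError(ValueError):
    """Raised when an :class:`EffectConfig` is incomplete or inconsistent."""


@dataclass(frozen=True)
class ParcelSet:
    """A cortical parcellation: one row per parcel.

    ``table`` columns: parcel_id (0-based, contiguous; left hemisphere
    first), hemisphere ('left'/'right'), region, x, y, z (unit-sphere
    coordinates).
    """

    table: pd.DataFrame

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def regions(self) -> np.ndarray:
        return self.table["region"].to_numpy()

    @property
    def parcel_ids(self) -> np.ndarray:
        return self.table["parcel_id"].to_numpy()


@dataclass(frozen=True)
class SubjectRecord:
    """One study participant."""

    subject_id: str
    group: str  # 'term' or 'preterm'
    ga_birth: float  # gestational age at birth, weeks
    pma_scan: float  # postmenstrual age at scan, weeks
    sex: int  # 0 = female, 1 = male
    bsid_motor: float | None = None
    bsid_language: float | None = None
    bsid_cognitive: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("term", "preterm"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "term" and self.ga_birth < 37:
            raise ValueError("term subjects require GA at birth >= 37 weeks")
        if self.group == "preterm" and self.ga_birth >= 37:
            raise ValueError("preterm subjects require GA at birth < 37 weeks")
        if self.pma_scan < self.ga_birth:
            raise ValueError("PMA at scan cannot precede GA at birth")


@dataclass(frozen=True)
class EffectConfig:
    """Generative ground truth for the synthetic cohort.

    ``baseline``, ``age_slope``, ``preterm_effect`` and ``noise_sd`` are
    nested ``{metric: {region: value}}`` mappings in metric units (slopes in
    units/week; preterm effects are the shift at maximal prematurity, i.e.
    GA 23 weeks). ``sex_effect`` is per metric (added for male subjects).
    Extreme deviations are injected per (subject, metric) with probability
    ``extreme_rate`` at 1-5 uniformly chosen parcels, with magnitude uniform
    in ``extreme_magnitude_range`` multiples of the local noise SD and sign
    drawn from the metric's typical preterm direction with probability
    ``extreme_sign_consistency`` (a 0 direction means a random sign).
    """

    baseline: dict[str, dict[str, float]]
    age_slope: dict[str, dict[str, float]]
    sex_effect: dict[str, float]
    preterm_effect: dict[str, dict[str, float]]
    noise_sd: dict[str, dict[str, float]]
    extreme_rate: float = 0.10
    extreme_magnitude_range: tuple[float, float] = (3.5, 6.0)
    extreme_parcel_count_range: tuple[int, int] = (1, 5)
    extreme_sign_consistency: float = 0.75
    extreme_direction: dict[str, int] = field(default_factory=dict)
    extreme_groups: tuple[str, ...] = ("preterm",)
    pma_center: float = 40.0
    scan_window: tuple[float, float] = (37.0, 45.14)
    seed: int = 0

    def validate(self) -> None:
        for name, mapping in (
            ("baseline", self.baseline),
            ("age_slope", self.age_slope),
            ("preterm_effect", self.preterm_effect),
            ("noise_sd", self.noise_sd),
        ):
            for m in METRICS:
                if m not in mapping:
                    raise ConfigError(f"{name} missing metric {m!r}")
                for r in REGIONS:
                    if r not in mapping[m]:
                        raise ConfigError(f"{name}[{m!r}] missing region {r!r}")
        for m in METRICS:
            if m not in self.sex_effect:
                raise ConfigError(f"sex_effect missing metric {m!r}")
            for r in REGIONS:
                if self.noise_sd[m][r] <= 0:
                    raise ConfigError(f"noise_sd[{m!r}][{r!r}] must be > 0")
        if not 0.0 <= self.extreme_rate <= 1.0:
            raise ConfigError("extreme_rate must be in [0, 1]")
        lo, hi = self.extreme_magnitude_range
        if not (3.1 < lo <= hi):
            raise ConfigError(
                "extreme_magnitude_range lower bound must exceed the 3.1 "
                "detection threshold"
            )

    def as_arrays(self, regions: np.ndarray) -> dict[str, np.ndarray]:
        """Expand the nested mappings to (n_parcels, n_metrics) arrays."""
        out = {}
        for name, mapping in (
            ("baseline", self.baseline),
            ("age_slope", self.age_slope),
            ("preterm_effect", self.preterm_effect),
            ("noise_sd", self.noise_sd),
        ):
            arr = np.empty((len(regions), len(METRICS)))
            for j, m in enumerate(METRICS):
                per_region = {r: mapping[m][r] for r in REGIONS}
                arr[:, j] = [per_region[r] for r in regions]
            out[name] = arr
        out["sex_effect"] = np.array([self.sex_effect[m] for m in METRICS])
        return out


@dataclass
class FeatureTable:
    """Subjects x parcels x metrics feature array with linked metadata.

    The universal currency of the pipeline. ``values[i, p, j]`` holds the
    per-parcel mean of metric ``METRICS[j]`` (per-parcel *sum* for surface
    area) for subject ``i`` at parcel ``p``.
    """

    values: np.ndarray  # (n_subjects, n_parcels, n_metrics)
    subjects: pd.DataFrame  # one row per subject, aligned with axis 0
    parcels: ParcelSet
    metrics: tuple[str, ...] = METRICS

    def __post_init__(self) -> None:
        n_s, n_p, n_m = self.values.shape
        if n_s != len(self.subjects):
            raise ValueError("subject table does not match value array")
        if n_p != self.parcels.n_parcels:
            raise ValueError("parcel set does not match value array")
        if n_m != len(self.metrics):
            raise ValueError("metric axis does not match metric list")

    @property
    def subject_ids(self) -> np.ndarray:
        return self.subjects["subject_id"].to_numpy()

    def subset(self, subject_ids) -> "FeatureTable":
        """Row-subset by subject id, preserving the given order."""
        idx = pd.Index(self.subject_ids)
        pos = idx.get_indexer(list(subject_ids))
        if (pos < 0).any():
            missing = [s for s, p in zip(subject_ids, pos) if p < 0]
            raise KeyError(f"unknown subject ids: {missing}")
        return FeatureTable(
            values=self.values[pos],
            subjects=self.subjects.iloc[pos].reset_index(drop=True),
            parcels=self.parcels,
            metrics=self.metrics,
        )

    def flatten(self) -> np.ndarray:
        """(n_subjects, n_parcels * n_metrics) view, parcel-major."""
        n_s = self.values.shape[0]
        return self.values.reshape(n_s, -1)

    def to_long(self) -> pd.DataFrame:
        """Tidy long-format frame: subject_id, parcel_id, metric, value."""
        n_s, n_p, n_m = self.values.shape
        return pd.DataFrame(
            {
                "subject_id": np.repeat(self.subject_ids, n_p * n_m),
                "parcel_id": np.tile(np.repeat(self.parcels.parcel_ids, n_m), n_s),
                "metric": np.tile(list(self.metrics), n_s * n_p),
                "value": self.values.ravel(),
            }
        )


@dataclass
class GroundTruth:
    """What the generator actually injected; the oracle for recovery tests."""

    extreme_mask_true: np.ndarray  # (n_subjects, n_parcels, n_metrics) in {-1, 0, +1}
    effect_parcels: dict[str, np.ndarray]  # metric -> parcel ids with preterm effect
    n_clipped: int = 0

    @property
    def n_injected(self) -> int:
        return int(np.count_nonzero(self.extreme_mask_true))


def default_effect_config(seed: int = 0, **overrides) -> EffectConfig:
    """The study-like default generative configuration.

    Baselines and noise levels are plausible for the neonatal cortex at
    term-equivalent age (cortical thickness ~1.1 mm, cortical FA ~0.15, MD
    ~1.2 um^2/ms, ODI ~0.3, fICVF ~0.5, per-parcel surface area ~140 mm^2).
    Age-slope and preterm-effect directions follow the observed regional
    pattern: FA falls posteriorly with age, MD falls centrally/insular, ODI
    rises widely (not somatosensory), fICVF rises in insula/frontal cortex,
    thickness and SA grow everywhere (SA much the strongest relative to
    noise), sulcation deepens in the cingulate, curvature is stable.
    Preterm birth at term-equivalent age raises posterior MD, lowers
    posterior fICVF, thickens anterior cortex, and raises FA / lowers ODI in
    the insula.
    """

    def per_region(default=0.0, **special):
        return {r: special.get(r, default) for r in REGIONS}

    baseline = {
        "FA": per_region(0.15),
        "MD": per_region(1.20),
        "ODI": per_region(0.30),
        "fICVF": per_region(0.50),
        "thickness": per_region(1.10),
        "SA": per_region(140.0),
        "curvature": per_region(0.10),
        "sulcation": per_region(0.50),
    }
    age_slope = {
        "FA": per_region(0.0, parietal=-0.004, occipital=-0.004, temporal=-0.003),
        "MD": per_region(
            0.0, somatosensory=-0.012, insula=-0.012, cingulate=-0.010,
            frontal=-0.006,
        ),
        "ODI": per_region(0.008, parietal=0.010, temporal=0.010, somatosensory=0.0),
        "fICVF": per_region(0.0, insula=0.008, frontal=0.005),
        "thickness": per_region(0.015),
        "SA": per_region(5.0),  # ~3.6%/week of the 140 mm^2 baseline
        "curvature": per_region(0.0),
        "sulcation": per_region(0.0, cingulate=0.010),
    }
    sex_effect = {
        "FA": 0.002, "MD": -0.010, "ODI": 0.003, "fICVF": 0.004,
        "thickness": 0.010, "SA": 4.0, "curvature": 0.0, "sulcation": 0.0,
    }
    preterm_effect = {
        "FA": per_region(0.0, insula=0.020),
        "MD": per_region(0.0, parietal=0.080, occipital=0.080),
        "ODI": per_region(0.0, insula=-0.040),
        "fICVF": per_region(0.0, parietal=-0.060, occipital=-0.060),
        "thickness": per_region(0.0, frontal=0.100, insula=0.100, parietal=0.070),
        "SA": per_region(0.0),
        "curvature": per_region(0.0),
        "sulcation": per_region(0.0),
    }
    noise_sd = {
        "FA": per_region(0.020),
        "MD": per_region(0.050),
        "ODI": per_region(0.030),
        "fICVF": per_region(0.040),
        "thickness": per_region(0.070),
        "SA": per_region(12.0),
        "curvature": per_region(0.015),
        "sulcation": per_region(0.080),
    }
    extreme_direction = {
        "FA": +1, "MD": +1, "ODI": -1, "fICVF": -1,
        "thickness": +1, "SA": 0, "curvature": 0, "sulcation": 0,
    }
    cfg = EffectConfig(
        baseline=baseline,
        age_slope=age_slope,
        sex_effect=sex_effect,
        preterm_effect=preterm_effect,
        noise_sd=noise_sd,
        extreme_direction=extreme_direction,
        seed=seed,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def generate_parcellation(n_per_hemisphere: int, seed: int) -> ParcelSet:
    """Place parcels on the unit sphere by farthest-point sampling.

    The sampler is initialised with the seven region anchor directions (so a
    minimal parcellation has one parcel per region) and then greedily adds
    the candidate point farthest from all chosen seeds, per hemisphere. Each
    parcel takes the region label of its nearest anchor. Deterministic given
    the seed; the right hemisphere mirrors the left in x.
    """
    if n_per_hemisphere < 7:
        raise ValueError(
            "n_per_hemisphere must be >= 7 (one parcel per region minimum)"
        )
    rng = np.random.default_rng(seed)
    anchors = _normalize(np.array([_REGION_ANCHORS[r] for r in REGIONS]))

    # dense candidate cloud on the left hemisphere (x <= 0)
    cand = rng.standard_normal((4096, 3))
    cand = _normalize(cand)
    cand[:, 0] = -np.abs(cand[:, 0])

    chosen = list(anchors)
    # squared chordal distance of every candidate to its nearest chosen seed
    min_d = np.min(
        ((cand[:, None, :] - anchors[None, :, :]) ** 2).sum(-1), axis=1
    )
    for _ in range(n_per_hemisphere - 7):
        k = int(np.argmax(min_d))
        chosen.append(cand[k])
        d_new = ((cand - cand[k]) ** 2).sum(-1)
        min_d = np.minimum(min_d, d_new)
    left = np.array(chosen[:n_per_hemisphere])
    labels = [REGIONS[int(np.argmin(((p - anchors) ** 2).sum(-1)))] for p in left]

    right = left.copy()
    right[:, 0] = -right[:, 0]
    n = n_per_hemisphere
    table = pd.DataFrame(
        {
            "parcel_id": np.arange(2 * n),
            "hemisphere": ["left"] * n + ["right"] * n,
            "region": labels + labels,
            "x": np.concatenate([left[:, 0], right[:, 0]]),
            "y": np.concatenate([left[:, 1], right[:, 1]]),
            "z": np.concatenate([left[:, 2], right[:, 2]]),
        }
    )
    return ParcelSet(table)


def _truncated_normal(rng, mean, sd, low, high, size):
    """Draw from N(mean, sd) truncated to [low, high] by resampling."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < low) | (out > high)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def sample_demographics(
    n_term: int,
    n_preterm: int,
    seed: int,
    *,
    with_outcomes: bool = True,
    outcome_ga_coupling: float = 0.0,
    female_fraction: float = 0.46,
    scan_window: tuple[float, float] = (37.0, 45.14),
) -> pd.DataFrame:
    """Sample term/preterm subject records age-matched at scan.

    Term GA at birth falls in [37, 42.14] weeks, preterm in [23, 36.86];
    PMA at scan is drawn in the scan window independently of group (the two
    cohorts are age-matched at scan) but never before birth. BSID-III-like
    outcome scores are N(100, 15) truncated to [40, 160], coupled to GA only
    through ``outcome_ga_coupling`` (points per week, default 0).
    """
    if n_term < 0 or n_preterm < 0:
        raise ValueError("subject counts must be non-negative")
    if n_term + n_preterm < 1:
        raise ValueError("at least one subject is required")
    rng = np.random.default_rng(seed)
    ga_term = _truncated_normal(rng, 40.1, 1.2, 37.0, 42.14, n_term)
    ga_pre = _truncated_normal(rng, 32.0, 3.5, 23.0, 36.86, n_preterm)
    ga = np.concatenate([ga_term, ga_pre])
    n = n_term + n_preterm
    lo, hi = scan_window
    pma = np.empty(n)
    for i in range(n):  # PMA >= GA at birth: per-subject lower bound
        pma[i] = _truncated_normal(rng, 40.9, 1.8, max(lo, ga[i]), hi, 1)[0]
    sex = (rng.random(n) >= female_fraction).astype(int)  # 0 female, 1 male
    frame = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "group": ["term"] * n_term + ["preterm"] * n_preterm,
            "ga_birth": ga,
            "pma_scan": pma,
            "sex": sex,
        }
    )
    if with_outcomes:
        for name in ("bsid_motor", "bsid_language", "bsid_cognitive"):
            base = 100.0 + outcome_ga_coupling * (ga - 40.0)
            frame[name] = _truncated_normal(
                rng, 0.0, 15.0, -60.0 - (base - 100.0), 60.0 - (base - 100.0), n
            ) + base
    return frame


def generate_features(
    subjects: pd.DataFrame,
    parcels: ParcelSet,
    config: EffectConfig,
) -> tuple[FeatureTable, GroundTruth]:
    """Generate the feature table and its ground truth from the linear model.

    Noise is iid Gaussian per cell. Extreme deviations are injected per
    (subject, metric) for subjects in ``config.extreme_groups`` only.
    Bounded metrics are clipped to [0, 1] and positive metrics floored at a
    tiny epsilon after generation; clipping events are counted and logged.
    """
    config.validate()
    lo, hi = config.scan_window
    pma = subjects["pma_scan"].to_numpy(float)
    if np.any((pma < lo - 1e-9) | (pma > hi + 1e-9)):
        bad = subjects.loc[(pma < lo) | (pma > hi), "subject_id"].tolist()
        raise ValueError(f"PMA at scan outside configured window for {bad}")

    regions = parcels.regions
    arrs = config.as_arrays(regions)
    n_s, n_p, n_m = len(subjects), parcels.n_parcels, len(METRICS)

    ga = subjects["ga_birth"].to_numpy(float)
    sex = subjects["sex"].to_numpy(float)
    is_pre = (subjects["group"] == "preterm").to_numpy()
    prematurity = np.clip((37.0 - ga) / 14.0, 0.0, 1.0) * is_pre

    expected = (
        arrs["baseline"][None, :, :]
        + arrs["age_slope"][None, :, :] * (pma - config.pma_center)[:, None, None]
        + arrs["sex_effect"][None, None, :] * sex[:, None, None]
        + arrs["preterm_effect"][None, :, :] * prematurity[:, None, None]
    )

    rng = np.random.default_rng(config.seed)
    values = expected + rng.normal(0.0, 1.0, size=(n_s, n_p, n_m)) * arrs["noise_sd"]

    # sparse heterogeneous extreme deviations
    mask_true = np.zeros((n_s, n_p, n_m), dtype=np.int8)
    in_scope = np.isin(subjects["group"].to_numpy(), config.extreme_groups)
    k_lo, k_hi = config.extreme_parcel_count_range
    m_lo, m_hi = config.extreme_magnitude_range
    for i in range(n_s):
        if not in_scope[i]:
            continue
        for j, metric in enumerate(METRICS):
            if rng.random() >= config.extreme_rate:
                continue
            k = int(rng.integers(k_lo, k_hi + 1))
            sel = rng.choice(n_p, size=min(k, n_p), replace=False)
            base_dir = config.extreme_direction.get(metric, 0)
            for p in sel:
                mag = rng.uniform(m_lo, m_hi) * arrs["noise_sd"][p, j]
                if base_dir == 0:
                    sign = 1 if rng.random() < 0.5 else -1
                else:
                    keep = rng.random() < config.extreme_sign_consistency
                    sign = base_dir if keep else -base_dir
                values[i, p, j] += sign * mag
                mask_true[i, p, j] = sign

    # bound constraints
    n_clipped = 0
    for j, metric in enumerate(METRICS):
        col = values[:, :, j]
        if metric in UNIT_INTERVAL_METRICS:
            bad = (col < 0.0) | (col > 1.0)
            n_clipped += int(bad.sum())
            values[:, :, j] = np.clip(col, 0.0, 1.0)
        elif metric in POSITIVE_METRICS:
            bad = col <= 0.0
            n_clipped += int(bad.sum())
            values[:, :, j] = np.maximum(col, 1e-6)
    if n_clipped:
        logger.info("clipped %d values to metric bounds", n_clipped)

    effect_parcels = {
        m: parcels.parcel_ids[arrs["preterm_effect"][:, j] != 0.0]
        for j, m in enumerate(METRICS)
    }
    table = FeatureTable(
        values=values,
        subjects=subjects.reset_index(drop=True),
        parcels=parcels,
    )
    truth = GroundTruth(
        extreme_mask_true=mask_true,
        effect_parcels=effect_parcels,
        n_clipped=n_clipped,
    )
    return table, truth
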