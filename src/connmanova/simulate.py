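"""Synthetic multi-site cohort and metric-panel generator.

The generator emulates the statistical structure the four-step analysis
assumes: a 2x2 sex-by-diagnosis cohort with exact group/sex counts, four
acquisition sites, uniform ages, correlated DAS cognitive scores, per-group
TICV distributions, and five subjects x parcels metric panels built from
per-parcel baselines plus additive age/site/DAS confound effects and
exchangeably correlated Gaussian noise. A sex-by-diagnosis interaction of
size ``delta`` (in noise-sd units) can be planted on a chosen parcel set of
the connectivity-density panel only; ``delta = 0`` generates null data.

Every panel row is scaled multiplicatively by the subject's TICV relative to
the population mean, so head size is a genuine common factor and the
pipeline's divide-by-TICV normalization removes it exactly. Given a spec and
a seed the generator is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas, default_atlas, default_target_parcels, synthetic_atlas
from .cohort import DAS_SCALES, METRICS, CohortTable, MetricPanel
from .exceptions import AlignmentError, SchemaError

__all__ = [
    "SyntheticSpec",
    "default_paper_spec",
    "scaled_down_spec",
    "generate_cohort",
    "generate_panels",
    "generate_dataset",
    "CALIBRATED_DELTA",
]

# Planted interaction size (noise-sd units) at which the full pipeline detects
# the effect essentially always at N = 193, p = 165 (see scripts/calibrate_delta.py).
CALIBRATED_DELTA = 1.0

# Table-1-style per-group DAS means/sds (scales v, nv, s, gca, snc).
_DAS_MEAN_ASD = {"v": 103.12, "nv": 100.83, "s": 98.34, "gca": 101.94, "snc": 99.57}
_DAS_SD_ASD = {"v": 30.36, "nv": 29.46, "s": 28.44, "gca": 29.88, "snc": 30.04}
_DAS_MEAN_TD = {"v": 98.61, "nv": 97.77, "s": 98.65, "gca": 98.16, "snc": 97.47}
_DAS_SD_TD = {"v": 27.69, "nv": 25.79, "s": 24.97, "gca": 26.85, "snc": 25.97}

# metric -> (baseline level, noise sd) in the metric's own units
_METRIC_BASELINES = {
    "area": (1500.0, 150.0),
    "thickness": (2.5, 0.25),
    "curvature": (0.15, 0.02),
    "volume": (4000.0, 400.0),
    "CD": (10.0, 1.0),
}


@dataclass
class SyntheticSpec:
    """All the knobs of the generator; defaults emulate the study cohort."""

    n_asd: int = 110
    n_asd_female: int = 55
    n_td: int = 83
    n_td_female: int = 40
    n_sites: int = 4
    site_probs: tuple[float, ...] | None = None  # None = uniform
    age_range: tuple[float, float] = (7.0, 18.0)
    das_mean_asd: dict = field(default_factory=lambda: dict(_DAS_MEAN_ASD))
    das_sd_asd: dict = field(default_factory=lambda: dict(_DAS_SD_ASD))
    das_mean_td: dict = field(default_factory=lambda: dict(_DAS_MEAN_TD))
    das_sd_td: dict = field(default_factory=lambda: dict(_DAS_SD_TD))
    rho_das: float = 0.7
    ticv_mean_asd: float = 212.94
    ticv_sd_asd: float = 30.07
    ticv_mean_td: float = 217.56
    ticv_sd_td: float = 25.94
    metric_baselines: dict = field(default_factory=lambda: dict(_METRIC_BASELINES))
    age_slope: float = 0.05  # noise-sd units per year of (centered) age
    site_offset_scale: float = 0.3  # sd of per-site shifts, noise-sd units
    das_slope: float = 0.01  # noise-sd units per (centered) GCA point
    rho_parcel: float = 0.2  # exchangeable inter-parcel noise correlation
    delta: float = 0.0  # planted interaction, noise-sd units (0 = null)
    target_parcels: tuple[str, ...] = field(default_factory=default_target_parcels)
    atlas: ParcelAtlas = field(default_factory=default_atlas)

    def __post_init__(self) -> None:
        if self.n_asd_female > self.n_asd or self.n_td_female > self.n_td:
            raise SchemaError("female counts cannot exceed group sizes")
        if min(self.n_asd, self.n_td) < 1:
            raise SchemaError("both groups must be non-empty")
        if self.delta < 0:
            raise SchemaError("delta must be >= 0")
        if not (0.0 <= self.rho_parcel < 1.0) or not (0.0 <= self.rho_das < 1.0):
            raise SchemaError("correlations must lie in [0, 1)")
        for sd in (self.ticv_sd_asd, self.ticv_sd_td):
            if sd <= 0:
                raise SchemaError("TICV sds must be > 0")
        unknown = set(self.target_parcels) - set(self.atlas.labels)
        if unknown:
            raise SchemaError(f"target parcel(s) not in atlas: {sorted(unknown)[:5]}")

    @property
    def n(self) -> int:
        return self.n_asd + self.n_td

    @property
    def ticv_ref(self) -> float:
        """Population-mean TICV used as the head-size scaling reference."""
        return (self.n_asd * self.ticv_mean_asd + self.n_td * self.ticv_mean_td) / self.n

    def to_dict(self) -> dict:
        d = asdict(self)
        d["atlas"] = list(self.atlas.labels)
        return d


def default_paper_spec(delta: float = 0.0) -> SyntheticSpec:
    """The study-sized spec: N = 193 (110 ASD / 55 F, 83 TD / 40 F), 4 sites,
    ages 7-18, Table-1 DAS and TICV parameters, 165-parcel atlas. ``delta``
    plants the sex-by-diagnosis interaction on the default 22-parcel target
    set of the CD panel (0 keeps the spec null-generating)."""
    return SyntheticSpec(delta=delta)


def scaled_down_spec(
    n_asd: int = 56,
    n_asd_female: int = 28,
    n_td: int = 44,
    n_td_female: int = 21,
    n_parcels: int = 30,
    n_targets: int = 6,
    delta: float = 0.0,
    null_confounds: bool = False,
) -> SyntheticSpec:
    """A reduced-dimension spec for calibration studies (default N=100, p=30).

    ``null_confounds=True`` zeroes the age/site/DAS effect sizes so the
    generated panels are exactly null given ``delta = 0``.
    """
    atlas = synthetic_atlas(n_parcels)
    spec = SyntheticSpec(
        n_asd=n_asd,
        n_asd_female=n_asd_female,
        n_td=n_td,
        n_td_female=n_td_female,
        delta=delta,
        target_parcels=atlas.labels[:n_targets],
        atlas=atlas,
    )
    if null_confounds:
        spec.age_slope = 0.0
        spec.site_offset_scale = 0.0
        spec.das_slope = 0.0
    return spec


# -- cohort --------------------------------------------------------------------


def _exchangeable_cov(sds: np.ndarray, rho: float) -> np.ndarray:
    corr = np.full((len(sds), len(sds)), rho)
    np.fill_diagonal(corr, 1.0)
    return corr * np.outer(sds, sds)


def _truncated_positive_normal(rng, mean, sd, size):
    x = rng.normal(mean, sd, size)
    while (x <= 0).any():  # pragma: no cover - essentially never at study params
        bad = x <= 0
        x[bad] = rng.normal(mean, sd, bad.sum())
    return x


def generate_cohort(spec: SyntheticSpec, seed: int) -> CohortTable:
    """Draw a cohort: exact group/sex counts, uniform ages, correlated DAS,
    truncated-normal TICV per group. Deterministic given (spec, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    n = spec.n
    probs = spec.site_probs or tuple(1.0 / spec.n_sites for _ in range(spec.n_sites))
    if abs(sum(probs) - 1.0) > 1e-9 or len(probs) != spec.n_sites:
        raise SchemaError("site_probs must have n_sites entries summing to 1")

    rows = []
    for group, (ng, nf) in (("ASD", (spec.n_asd, spec.n_asd_female)),
                            ("TD", (spec.n_td, spec.n_td_female))):
        sex = np.concatenate([-np.ones(nf, int), np.ones(ng - nf, int)])
        rng.shuffle(sex)
        dx = 1 if group == "ASD" else -1
        mean = spec.das_mean_asd if dx == 1 else spec.das_mean_td
        sd = spec.das_sd_asd if dx == 1 else spec.das_sd_td
        mu = np.array([mean[s] for s in DAS_SCALES])
        sig = np.array([sd[s] for s in DAS_SCALES])
        das = rng.multivariate_normal(mu, _exchangeable_cov(sig, spec.rho_das), ng,
                                      method="cholesky")
        tm, ts = (spec.ticv_mean_asd, spec.ticv_sd_asd) if dx == 1 else (
            spec.ticv_mean_td, spec.ticv_sd_td)
        ticv = _truncated_positive_normal(rng, tm, ts, ng)
        age = rng.uniform(*spec.age_range, ng)
        site = rng.choice(spec.n_sites, ng, p=probs)
        for i in range(ng):
            rows.append(
                {
                    "site": f"site{site[i] + 1}",
                    "sex": int(sex[i]),
                    "diagnosis": dx,
                    "age": age[i],
                    **{f"das_{s}": das[i, k] for k, s in enumerate(DAS_SCALES)},
                    "ticv": ticv[i],
                }
            )
    frame = pd.DataFrame(rows)
    frame.insert(0, "subject_id", [f"sub-{i + 1:04d}" for i in range(n)])
    return CohortTable(frame)


# -- panels --------------------------------------------------------------------


def generate_panels(
    spec: SyntheticSpec, cohort: CohortTable, seed: int
) -> dict[str, MetricPanel]:
    """Generate the five metric panels for a cohort.

    Each panel = parcel baseline + noise-sd * (age, site and DAS effects +
    exchangeably correlated Gaussian noise), all multiplied by the subject's
    relative head size (TICV / reference). The CD panel additionally carries
    ``delta * sex * diagnosis`` (noise-sd units) on the target parcels only.
    """
    if cohort.n != spec.n:
        raise AlignmentError(f"cohort size {cohort.n} does not match spec N = {spec.n}")
    atlas = spec.atlas
    p = atlas.p
    n = cohort.n
    age_c = cohort.age - np.mean(spec.age_range)
    gca_c = cohort.frame["das_gca"].to_numpy(float) - 100.0
    site_idx = (
        cohort.frame["site"].str.removeprefix("site").astype(int).to_numpy() - 1
    )
    sexdiag = (cohort.sex * cohort.diagnosis).astype(float)
    head_factor = (cohort.ticv / spec.ticv_ref)[:, None]
    target_mask = np.array([l in set(spec.target_parcels) for l in atlas.labels])

    ss = np.random.SeedSequence([seed, 202])
    children = ss.spawn(len(METRICS))
    panels: dict[str, MetricPanel] = {}
    for child, metric in zip(children, METRICS):
        rng = np.random.default_rng(child)
        base_level, noise_sd = spec.metric_baselines[metric]
        parcel_base = base_level * (1.0 + 0.3 * rng.uniform(-1.0, 1.0, p))
        site_offsets = rng.normal(0.0, spec.site_offset_scale, spec.n_sites)
        common = rng.standard_normal((n, 1))
        idio = rng.standard_normal((n, p))
        noise = np.sqrt(spec.rho_parcel) * common + np.sqrt(1.0 - spec.rho_parcel) * idio
        signal = (
            spec.age_slope * age_c
            + site_offsets[site_idx]
            + spec.das_slope * gca_c
        )[:, None]
        values = parcel_base[None, :] + noise_sd * (signal + noise)
        if metric == "CD" and spec.delta > 0:
            values[:, target_mask] += noise_sd * spec.delta * sexdiag[:, None]
        values = values * head_factor
        panels[metric] = MetricPanel(
            metric_name=metric,
            values=pd.DataFrame(values, index=list(cohort.subject_ids),
                                columns=list(atlas.labels)),
            atlas=atlas,
        )
    return panels


def generate_dataset(spec: SyntheticSpec, seed: int) -> tuple[CohortTable, dict[str, MetricPanel]]:
    """Cohort plus its five panels from one seed."""
    cohort = generate_cohort(spec, seed)
    return cohort, generate_panels(spec, cohort, seed)
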