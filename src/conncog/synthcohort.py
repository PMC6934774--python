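"""Synthetic structural-connectome cohorts with a planted group effect.

Generates subject tables and FA-weighted connectivity matrices for three
groups — healthy volunteers (HV), cognitively preserved (CP) and cognitively
impaired (CI) MS patients — with the statistical structure the downstream
analysis assumes:

* a shared edge template (topology + per-edge mean FA) drawn once per cohort;
* multiplicative attenuation of edge weights at a designated set of
  "vulnerable" nodes in patients, with an extra attenuation step in CI;
* per-subject edge dropout (missingness) and Gaussian FA noise;
* age/sex demographics per group and an optional linear age effect on edge
  weights, so confound regression can be exercised against known ground truth;
* per-test cognitive z-scores whose group label is consistent, by
  construction, with the impairment rule (two or more tests below -1.5).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "SimulationConfig",
    "SubjectRecord",
    "ConnectivityMatrix",
    "CohortError",
    "CognitiveSimulationError",
    "classify_cognitive_status",
    "generate_cog_scores",
    "generate_cohort",
    "subjects_to_frame",
    "subjects_from_frame",
]

GROUPS = ("HV", "CP", "CI")

AGE_RANGE = (18.0, 65.0)


class CohortError(ValueError):
    """Invalid simulation configuration or inputs."""


class CognitiveSimulationError(CohortError):
    """Rejection sampling of cognitive profiles exhausted its attempt budget.

    Usually signals cognitive means/SDs that are incompatible with the
    requested group label (e.g. a CI mean far above the impairment cut-off).
    """


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Demographic and cognition defaults follow the observed three-group MS
    study composition (45 HV / 104 CP / 84 CI; group ages 37.8/41.9/44.6 y;
    global cognition z of 0.014 +/- 0.436 in CP and -1.099 +/- 0.571 in CI).
    Edge-weight defaults are a plausible white-matter FA range; no empirical
    edge-weight distribution is imposed.
    """

    n_hv: int = 45
    n_cp: int = 104
    n_ci: int = 84
    n_nodes: int = 76
    edge_presence_prob: float = 0.5
    base_weight_low: float = 0.30
    base_weight_high: float = 0.60
    subject_noise_sd: float = 0.04
    subject_dropout_prob: float = 0.05
    delta_cp: float = 0.10
    delta_ci: float = 0.15
    vulnerable_nodes: tuple[int, ...] = tuple(range(10))
    age_slope: float = -0.001          # FA units per year, applied to all edges
    age_ref: float = 40.0              # age at which the slope term vanishes
    n_cog_tests: int = 9
    cog_factor_loading: float = 0.7    # implied common-factor loading of tests
    cog_means: Mapping[str, float] = field(
        default_factory=lambda: {"CP": 0.014, "CI": -1.099}
    )
    cog_sds: Mapping[str, float] = field(
        default_factory=lambda: {"CP": 0.436, "CI": 0.571}
    )
    age_means: Mapping[str, float] = field(
        default_factory=lambda: {"HV": 37.77, "CP": 41.90, "CI": 44.57}
    )
    age_sds: Mapping[str, float] = field(
        default_factory=lambda: {"HV": 11.01, "CP": 9.07, "CI": 11.27}
    )
    female_props: Mapping[str, float] = field(
        default_factory=lambda: {"HV": 0.60, "CP": 0.74, "CI": 0.62}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hv, self.n_cp, self.n_ci) < 0:
            raise CohortError("group sizes must be >= 0")
        if self.n_nodes < 2:
            raise CohortError("need at least 2 nodes")
        if not 0.0 < self.edge_presence_prob <= 1.0:
            raise CohortError("edge_presence_prob must be in (0, 1]")
        if not 0.0 <= self.subject_dropout_prob <= 1.0:
            raise CohortError("subject_dropout_prob must be in [0, 1]")
        if not (0.0 <= self.base_weight_low <= self.base_weight_high <= 1.0):
            raise CohortError("base weight bounds must satisfy 0 <= low <= high <= 1")
        if self.delta_cp < 0 or self.delta_ci < 0 or self.delta_cp + self.delta_ci >= 1:
            raise CohortError("attenuations must satisfy 0 <= delta_cp + delta_ci < 1")
        vuln = tuple(self.vulnerable_nodes)
        if any(v < 0 or v >= self.n_nodes for v in vuln):
            raise CohortError("vulnerable_nodes must lie in [0, n_nodes)")
        if len(set(vuln)) != len(vuln):
            raise CohortError("vulnerable_nodes contains duplicates")
        if (self.delta_cp > 0 or self.delta_ci > 0) and not vuln:
            raise CohortError(
                "vulnerable_nodes is empty but delta_cp/delta_ci > 0: "
                "the group effect has nowhere to act"
            )
        if self.n_cog_tests < 1:
            raise CohortError("need at least one cognitive test")
        if not 0.0 < self.cog_factor_loading < 1.0:
            raise CohortError("cog_factor_loading must be in (0, 1)")
        for grp in ("CP", "CI"):
            if grp not in self.cog_means or grp not in self.cog_sds:
                raise CohortError(f"cognitive parameters missing for group {grp}")
        for grp in GROUPS:
            if grp not in self.age_means or grp not in self.age_sds:
                raise CohortError(f"age parameters missing for group {grp}")
            p = self.female_props.get(grp)
            if p is None or not 0.0 <= p <= 1.0:
                raise CohortError(f"female proportion for {grp} must be in [0, 1]")

    # -- serialization --------------------------------------------------

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["vulnerable_nodes"] = list(d["vulnerable_nodes"])
        for key in ("cog_means", "cog_sds", "age_means", "age_sds", "female_props"):
            d[key] = dict(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "vulnerable_nodes" in d:
            d["vulnerable_nodes"] = tuple(d["vulnerable_nodes"])
        return cls(**d)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: group, demographics, cognitive profile and derived status."""

    subject_id: str
    group: str                       # HV | CP | CI
    age: float
    sex: str                         # F | M
    cog_z: tuple[float, ...] | None  # None for HV (battery not administered)
    cognitive_status: str            # preserved | impaired | not_applicable

    @property
    def global_z(self) -> float | None:
        if self.cog_z is None:
            return None
        return float(np.mean(self.cog_z))


@dataclass
class ConnectivityMatrix:
    """A subject's symmetric FA-weighted adjacency matrix with node labels."""

    subject_id: str
    node_labels: list[str]
    weights: np.ndarray

    def validate(self, atol: float = 1e-8) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise CohortError(f"{self.subject_id}: weights must be square")
        if len(self.node_labels) != w.shape[0]:
            raise CohortError(f"{self.subject_id}: label/matrix size mismatch")
        if not np.allclose(w, w.T, atol=atol):
            raise CohortError(f"{self.subject_id}: matrix is not symmetric")
        if np.any(np.diag(w) != 0):
            raise CohortError(f"{self.subject_id}: diagonal must be zero")
        if np.any(w < 0) or np.any(w > 1):
            raise CohortError(f"{self.subject_id}: FA weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def classify_cognitive_status(
    z: Sequence[float], threshold: float = -1.5, min_tests: int = 2
) -> str:
    """Apply the impairment rule: impaired iff >= ``min_tests`` scores fall
    strictly below ``threshold``; returns ``"impaired"`` or ``"preserved"``.
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise CohortError("empty cognitive score vector")
    n_below = int(np.sum(z < threshold))
    return "impaired" if n_below >= min_tests else "preserved"


def _deviation_scale(sd: float, loading: float) -> float:
    # Within-subject spread chosen so the subject's global level acts as a
    # common factor with (approximately) the configured standardized loading.
    return sd * math.sqrt(1.0 - loading**2) / loading


_PROFILE_ATTEMPTS = 500
_THRESHOLD = -1.5
_MIN_TESTS = 2
_FALLBACK_DEV_CAP = 10.0  # in units of the within-subject deviation scale


def _constructed_profile(
    g: float, want: str, k: int, scale: float, rng: np.random.Generator
) -> np.ndarray | None:
    """Deterministic rule-consistent profile with mean exactly ``g``.

    Used when rejection sampling is hopeless for this global level. Returns
    None when the construction would require deviations larger than
    ``_FALLBACK_DEV_CAP`` x scale (incompatible parameters).
    """
    margin = 0.05 + 0.45 * rng.random()
    if want == "impaired":
        low = (_THRESHOLD - margin) - g            # deviation of pinned tests
        dev = np.full(k, -_MIN_TESTS * low / (k - _MIN_TESTS))
        dev[:_MIN_TESTS] = low
    else:
        n_high = k - (_MIN_TESTS - 1)
        z_high = max(g, _THRESHOLD + margin)
        z_abs = (k * g - n_high * z_high) / (_MIN_TESTS - 1)
        dev = np.full(k, z_high - g)
        dev[:_MIN_TESTS - 1] = z_abs - g
    if np.max(np.abs(dev)) > _FALLBACK_DEV_CAP * scale:
        return None
    return g + rng.permutation(dev)


def generate_cog_scores(
    group: str, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw a rule-consistent cognitive profile for a CP or CI subject.

    The subject's global z-level G is drawn once from the group's
    global-cognition distribution; per-test scores are G plus mean-centred
    correlated deviations, so the profile mean equals G exactly and the
    sample mean of global z across subjects is unbiased for the configured
    group mean. Profiles whose derived label contradicts the group are
    rejection-resampled within a bounded attempt budget; if the budget is
    exhausted (a rare global level for the requested label), a deterministic
    rule-consistent profile with the same mean is constructed instead.
    Raises when even that construction would need implausible deviations,
    signalling incompatible cognitive means/SDs.
    """
    if group not in ("CP", "CI"):
        raise CohortError("cognitive scores are generated for CP/CI only")
    mu = float(config.cog_means[group])
    sd = float(config.cog_sds[group])
    scale = _deviation_scale(sd, config.cog_factor_loading)
    want = "impaired" if group == "CI" else "preserved"
    k = config.n_cog_tests
    if k <= _MIN_TESTS:
        raise CohortError(f"n_cog_tests must exceed {_MIN_TESTS}")
    g = rng.normal(mu, sd)
    for _ in range(_PROFILE_ATTEMPTS):
        eps = rng.standard_normal(k)
        z = g + scale * (eps - eps.mean())
        if classify_cognitive_status(z) == want:
            return z
    z = _constructed_profile(g, want, k, scale, rng)
    if z is None or classify_cognitive_status(z) != want:
        raise CognitiveSimulationError(
            f"could not draw a {want} profile for group {group}: "
            "cognitive means/SDs are incompatible with the labeling rule"
        )
    return z


def _truncated_normal_age(
    mean: float, sd: float, rng: np.random.Generator
) -> float:
    lo, hi = AGE_RANGE
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[SubjectRecord], list[ConnectivityMatrix]]:
    """Generate one cohort: subject records plus one connectivity matrix each.

    A shared edge template (presence + per-edge mean FA) is drawn once; each
    subject's present-edge weights are the template mean, attenuated by group
    at vulnerable-incident edges, shifted by the linear age effect, plus
    Gaussian noise, truncated to [0, 1]. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    m = iu.size

    present = rng.random(m) < config.edge_presence_prob
    mean_w = rng.uniform(config.base_weight_low, config.base_weight_high, size=m)

    vuln = np.zeros(n, dtype=bool)
    vuln[list(config.vulnerable_nodes)] = True
    vuln_pair = vuln[iu] | vuln[ju]

    node_labels = [f"node{j:03d}" for j in range(n)]
    subjects: list[SubjectRecord] = []
    matrices: list[ConnectivityMatrix] = []

    counts = {"HV": config.n_hv, "CP": config.n_cp, "CI": config.n_ci}
    for group in GROUPS:
        attn = np.ones(m)
        if group in ("CP", "CI"):
            attn[vuln_pair] *= 1.0 - config.delta_cp
        if group == "CI":
            attn[vuln_pair] *= 1.0 - config.delta_ci
        for idx in range(counts[group]):
            sid = f"{group}{idx + 1:03d}"
            age = _truncated_normal_age(
                config.age_means[group], config.age_sds[group], rng
            )
            sex = "F" if rng.random() < config.female_props[group] else "M"
            if group == "HV":
                cog_z, status = None, "not_applicable"
            else:
                z = generate_cog_scores(group, config, rng)
                cog_z = tuple(float(v) for v in z)
                status = classify_cognitive_status(z)

            keep = present & (rng.random(m) >= config.subject_dropout_prob)
            noise = rng.normal(0.0, config.subject_noise_sd, size=m)
            w = mean_w * attn + config.age_slope * (age - config.age_ref) + noise
            np.clip(w, 0.0, 1.0, out=w)
            w[~keep] = 0.0

            full = np.zeros((n, n))
            full[iu, ju] = w
            full += full.T

            subjects.append(
                SubjectRecord(sid, group, age, sex, cog_z, status)
            )
            matrices.append(ConnectivityMatrix(sid, list(node_labels), full))

    return subjects, matrices


# -- subject-table I/O ------------------------------------------------------


def subjects_to_frame(subjects: Sequence[SubjectRecord]):
    """Subject records as a DataFrame (cog-test columns cog_z_1..n)."""
    import pandas as pd

    n_tests = max(
        (len(s.cog_z) for s in subjects if s.cog_z is not None), default=0
    )
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "age": s.age,
            "sex": s.sex,
            "cognitive_status": s.cognitive_status,
        }
        for t in range(n_tests):
            row[f"cog_z_{t + 1}"] = (
                s.cog_z[t] if s.cog_z is not None else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def subjects_from_frame(frame) -> list[SubjectRecord]:
    cog_cols = sorted(
        (c for c in frame.columns if c.startswith("cog_z_")),
        key=lambda c: int(c.split("_")[-1]),
    )
    out = []
    for _, row in frame.iterrows():
        z = tuple(float(row[c]) for c in cog_cols)
        cog = None if (not z or any(math.isnan(v) for v in z)) else z
        out.append(
            SubjectRecord(
                str(row["subject_id"]),
                str(row["group"]),
                float(row["age"]),
                str(row["sex"]),
                cog,
                str(row["cognitive_status"]),
            )
        )
    return out
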