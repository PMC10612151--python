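"""Seeded synthetic cohorts with the study's statistical structure.

The generator emulates a 101-case fusiform-excision cohort: body sites
drawn from the study's site mix (head 66, neck 6, abdomen 11, upper limbs
13, lower limbs 5 out of 101), per-site lesion widths from truncated
normals anchored to the reported per-site means/SDs, lengths as
width x a truncated-normal length-width ratio (2.18 +/- 0.39), a
pre-drawn designed incision equal to the model arc plus small additive
drawing noise, and a postoperative incision equal to the model arc times
a multiplicative noise factor. A second layer embeds the true cm lengths
into raw photo units with random scales and reference objects — the exact
inverse of the photographic correction, so correcting the simulated raw
values recovers the truth.

One integer seed governs everything; per-layer substreams are derived
from it deterministically, so a seed fixes the cohort byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import LOCATIONS, compute_model_columns
from .errors import CohortValidationError

__all__ = ["CohortSimConfig", "simulate_cohort", "simulate_photo_layer"]

#: Study site counts (head, neck, abdomen, upper limbs, lower limbs).
DEFAULT_SITE_COUNTS: Dict[str, int] = {
    "head": 66,
    "neck": 6,
    "abdomen": 11,
    "upper_limbs": 13,
    "lower_limbs": 5,
}

#: Per-site preoperative width mean and SD, cm.
DEFAULT_WIDTH_MEAN_SD: Dict[str, Tuple[float, float]] = {
    "head": (0.565, 0.175),
    "neck": (0.650, 0.182),
    "abdomen": (0.726, 0.290),
    "upper_limbs": (0.702, 0.232),
    "lower_limbs": (0.702, 0.361),
}


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study conditions: 101 cases, the study's site
    mix, per-site width distributions, length-width ratio 2.18 +/- 0.39
    truncated at 1.05, 0.05 cm of additive drawing noise on the designed
    incision and 5% multiplicative noise on the postoperative incision.
    """

    n_total: int = 101
    site_mix: Dict[str, float] = field(
        default_factory=lambda: {k: v / 101.0 for k, v in DEFAULT_SITE_COUNTS.items()}
    )
    width_mean_sd: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WIDTH_MEAN_SD)
    )
    ratio_mean: float = 2.18
    ratio_sd: float = 0.39
    ratio_floor: float = 1.05
    width_floor: float = 0.05
    design_noise_sd: float = 0.05
    post_noise_cv: float = 0.05
    age_mean: float = 37.0
    age_sd: float = 14.5
    female_fraction: float = 58.0 / 101.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_total < 1:
            raise CohortValidationError(f"n_total must be >= 1, got {self.n_total}")
        if set(self.site_mix) != set(LOCATIONS):
            raise CohortValidationError(
                f"site_mix must cover exactly the sites {LOCATIONS}, got {sorted(self.site_mix)}"
            )
        probs = np.array([self.site_mix[s] for s in LOCATIONS], dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise CohortValidationError("site_mix proportions must be non-negative and sum to 1")
        for site, (mu, sd) in self.width_mean_sd.items():
            if mu <= 0 or sd < 0:
                raise CohortValidationError(f"width distribution for {site!r} invalid: {(mu, sd)}")
        for name in ("ratio_sd", "design_noise_sd", "post_noise_cv", "age_sd"):
            if getattr(self, name) < 0:
                raise CohortValidationError(f"{name} must be non-negative")
        if self.ratio_floor < 1.0:
            raise CohortValidationError("ratio_floor below 1 would allow non-canonical designs")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise CohortValidationError("female_fraction must lie in [0, 1]")

    def with_seed(self, seed: int) -> "CohortSimConfig":
        return replace(self, seed=seed)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    """Normal(mean, sd) conditioned on being above ``lower``."""
    if sd == 0.0:
        return np.full(size, max(mean, lower))
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(config: Optional[CohortSimConfig] = None, seed: Optional[int] = None) -> pd.DataFrame:
    """Draw one synthetic cohort in corrected-mode schema.

    Per case: site ~ site mix; width ~ truncated normal for that site
    (floored at ``width_floor``); length = ratio x width with
    ratio ~ truncated normal; designed incision = model arc + additive
    normal noise; postoperative incision = model arc x (1 + CV noise).
    Deterministic given the seed. Model columns are included.
    """
    config = config or CohortSimConfig()
    if seed is not None:
        config = config.with_seed(seed)
    config.validate()
    n = config.n_total
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_site, rng_demo, rng_size, rng_design, rng_post = (
        np.random.Generator(np.random.PCG64(s)) for s in streams
    )

    probs = np.array([config.site_mix[s] for s in LOCATIONS], dtype=float)
    sites = rng_site.choice(len(LOCATIONS), size=n, p=probs / probs.sum())
    location = np.array(LOCATIONS, dtype=object)[sites]

    age = np.clip(rng_demo.normal(config.age_mean, config.age_sd, size=n), 1.0, 95.0)
    sex = np.where(rng_demo.random(n) < config.female_fraction, "female", "male")

    width = np.empty(n)
    for i, site in enumerate(LOCATIONS):
        mask = sites == i
        if mask.any():
            mu, sd = config.width_mean_sd[site]
            width[mask] = _truncated_normal(rng_size, mu, sd, config.width_floor, int(mask.sum()))
    ratio = _truncated_normal(rng_size, config.ratio_mean, config.ratio_sd, config.ratio_floor, n)
    length = ratio * width

    df = pd.DataFrame(
        {
            "case_id": [f"case_{i + 1:04d}" for i in range(n)],
            "age": np.round(age, 1),
            "sex": sex,
            "location": location,
            "corrected_width": width,
            "corrected_length": length,
        }
    )
    df = compute_model_columns(df)
    arc = df["model_arc"].to_numpy(float)
    designed = arc + rng_design.normal(0.0, config.design_noise_sd, size=n)
    df["designed_arc"] = np.maximum(designed, 0.01)  # a drawn line cannot have negative length
    df["post_incision"] = arc * (1.0 + rng_post.normal(0.0, config.post_noise_cv, size=n))
    cols = [
        "case_id", "age", "sex", "location",
        "corrected_width", "corrected_length", "designed_arc", "post_incision",
        "model_beta", "model_alpha", "model_arc",
    ]
    return df[cols]


def simulate_photo_layer(
    records: pd.DataFrame, scale_jitter: float = 0.0, seed: int = 0, base_scale: float = 1.0
) -> pd.DataFrame:
    """Embed true cm lengths into raw photo units (raw-mode schema).

    Draws per-case preoperative/postoperative scales and reference-object
    readings (log-normally jittered around ``base_scale`` and 1) and
    constructs the raw values as the exact algebraic inverse of the
    photographic correction, so applying :mod:`fusiform.photo` to the
    output recovers the input lengths to floating-point accuracy. With
    ``scale_jitter=0`` and unit base scale the raw values equal the cm
    values.
    """
    if scale_jitter < 0:
        raise CohortValidationError(f"scale_jitter must be non-negative, got {scale_jitter!r}")
    if base_scale <= 0:
        raise CohortValidationError(f"base_scale must be positive, got {base_scale!r}")
    required = {"corrected_length", "corrected_width", "designed_arc", "post_incision"}
    missing = required - set(records.columns)
    if missing:
        raise CohortValidationError(f"records lack corrected columns: {sorted(missing)}")
    n = len(records)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 0x9E37])))
    jit = lambda: np.exp(rng.normal(0.0, scale_jitter, size=n)) if scale_jitter > 0 else np.ones(n)
    pre_s = base_scale * jit()
    post_s = base_scale * jit()
    pre_r = jit()
    post_r = jit()

    out = pd.DataFrame(index=records.index)
    for col in ("case_id", "age", "sex", "location"):
        if col in records.columns:
            out[col] = records[col]
    out["measured_length"] = records["corrected_length"].to_numpy(float) * pre_s
    out["measured_width"] = records["corrected_width"].to_numpy(float) * pre_s
    out["pre_i"] = records["designed_arc"].to_numpy(float) * pre_s
    out["pre_s"] = pre_s
    out["pre_r"] = pre_r
    out["post_i"] = records["post_incision"].to_numpy(float) * post_s * post_r / pre_r
    out["post_s"] = post_s
    out["post_r"] = post_r
    return out
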