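"""Synthetic cohort generation with known ground-truth LDAEP parameters.

Each subject carries generative ERP parameters (component intercepts at 75 dB
and slopes in μV/dB), noise parameters, and covariates (age, BDI-II subscale
scores, menstrual phase, hormonal-contraceptive type, adverse-mood flag).

Default group structure mirrors a two-group contraceptive study: 30 current
HC users vs. 24 non-users (17 past + 7 never users), with N1 slope
distributions Normal(−0.080, 0.033) for users and Normal(−0.052, 0.040) for
non-users, and P2 slopes Normal(0.120, 0.068) vs. Normal(0.084, 0.046).
The N1P2 slope is not drawn separately: it is the identity P2 − N1, with the
two component slopes drawn independently (a modeling choice; the resulting
N1P2 spread, ~0.076 for users, is consistent with the target group summaries).

BDI-II subscale scores are drawn from a right-skewed negative-binomial
distribution; subjects flagged with adverse mood effects receive an additive
shift on the somatic-affective subscale (default ≈ half a subscale SD, a
medium effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ldaep_lab.paradigm import ConfigurationError

__all__ = ["GroupSpec", "CohortSpec", "SubjectProfile", "generate_cohort"]

GROUPS = ("current_user", "past_user", "never_user")


@dataclass
class SubjectProfile:
    """Ground-truth generative parameters and covariates for one subject."""

    subject_id: str
    group: str
    hc_type: str  # combined | progestin_only | none
    age: float
    bdi_cognitive: int
    bdi_somatic_affective: int
    menstrual_phase: str  # follicular | ovulatory | luteal | unknown
    adverse_mood: bool
    true_n1_intercept_uv: float
    true_n1_slope_uv_per_db: float
    true_p2_intercept_uv: float
    true_p2_slope_uv_per_db: float
    noise_sigma_uv: float
    blink_rate_hz: float
    line_amp_uv: float

    @property
    def bdi_total(self) -> int:
        return self.bdi_cognitive + self.bdi_somatic_affective

    @property
    def true_n1p2_slope_uv_per_db(self) -> float:
        return self.true_p2_slope_uv_per_db - self.true_n1_slope_uv_per_db


@dataclass
class GroupSpec:
    """Per-group generative distributions (means/SDs)."""

    n: int
    n1_slope: tuple[float, float]  # (mean, sd) in μV/dB
    p2_slope: tuple[float, float]
    age: tuple[float, float]
    n1_intercept: tuple[float, float] = (-4.0, 1.0)  # μV at 75 dB
    p2_intercept: tuple[float, float] = (4.5, 1.2)
    bdi_cognitive_mean: float = 5.0
    bdi_somatic_mean: float = 5.0
    bdi_dispersion: float = 2.5  # negative-binomial size parameter
    adverse_mood_prevalence: float = 0.0
    # P(follicular), P(ovulatory), P(luteal), P(unknown)
    phase_probs: tuple[float, float, float, float] = (0.3, 0.25, 0.3, 0.15)
    combined_hc_fraction: float = 0.0  # fraction of users on combined HC

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("group size must be >= 1")
        for name in ("n1_slope", "p2_slope", "age", "n1_intercept", "p2_intercept"):
            if getattr(self, name)[1] < 0:
                raise ConfigurationError(f"negative SD for {name}")


def _default_groups() -> dict[str, GroupSpec]:
    user_slopes = dict(n1_slope=(-0.080, 0.033), p2_slope=(0.120, 0.068))
    nonuser_slopes = dict(n1_slope=(-0.052, 0.040), p2_slope=(0.084, 0.046))
    return {
        "current_user": GroupSpec(
            n=30,
            age=(25.3, 3.9),
            adverse_mood_prevalence=11 / 30,
            phase_probs=(8 / 30, 6 / 30, 6 / 30, 10 / 30),
            combined_hc_fraction=17 / 30,
            **user_slopes,
        ),
        "past_user": GroupSpec(
            n=17,
            age=(27.2, 5.2),
            adverse_mood_prevalence=14 / 17,
            phase_probs=(4 / 17, 4 / 17, 6 / 17, 3 / 17),
            **nonuser_slopes,
        ),
        "never_user": GroupSpec(
            n=7,
            age=(23.4, 3.4),
            adverse_mood_prevalence=0.0,
            phase_probs=(2 / 7, 1 / 7, 3 / 7, 1 / 7),
            **nonuser_slopes,
        ),
    }


@dataclass
class CohortSpec:
    """Cohort-level generative specification."""

    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    noise_sigma_uv: float = 6.0
    blink_rate_hz: float = 0.15
    line_amp_uv: float = 5.0
    adverse_mood_somatic_shift: float = 2.0  # ≈0.5 SD, a medium effect
    bdi_threshold: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.groups:
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r}")


def _draw_nb(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    """Right-skewed, overdispersed counts: negative binomial via gamma-Poisson."""
    lam = rng.gamma(shape=size_param, scale=mean / size_param, size=n)
    return rng.poisson(lam)


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectProfile], pd.DataFrame]:
    """Draw subject profiles and the corresponding cohort table.

    Returns
    -------
    profiles
        One :class:`SubjectProfile` per subject (ground truth included).
    table
        DataFrame with one row per subject: covariates, analysis grouping
        (``group`` retains the three-level label; ``group2`` is the merged
        current-user vs. non-user contrast) and ``true_*`` slope columns for
        recovery testing.  The statistical layer never requires the ``true_*``
        columns; they exist so simulation studies can bypass signal
        processing.
    """
    rng = np.random.default_rng(spec.seed)
    profiles: list[SubjectProfile] = []
    idx = 0
    for group in GROUPS:
        if group not in spec.groups:
            continue
        g = spec.groups[group]
        n1_slopes = rng.normal(g.n1_slope[0], g.n1_slope[1], g.n)
        p2_slopes = rng.normal(g.p2_slope[0], g.p2_slope[1], g.n)
        n1_inter = np.minimum(rng.normal(g.n1_intercept[0], g.n1_intercept[1], g.n), -1.0)
        p2_inter = np.maximum(rng.normal(g.p2_intercept[0], g.p2_intercept[1], g.n), 1.0)
        ages = np.clip(rng.normal(g.age[0], g.age[1], g.n), 18.0, 40.0)
        adverse = rng.random(g.n) < g.adverse_mood_prevalence
        bdi_cog = _draw_nb(rng, g.bdi_cognitive_mean, g.bdi_dispersion, g.n)
        bdi_som = _draw_nb(rng, g.bdi_somatic_mean, g.bdi_dispersion, g.n)
        bdi_som = bdi_som + np.where(
            adverse, np.rint(spec.adverse_mood_somatic_shift).astype(int), 0
        )
        phases = rng.choice(
            ["follicular", "ovulatory", "luteal", "unknown"],
            size=g.n,
            p=np.asarray(g.phase_probs) / np.sum(g.phase_probs),
        )
        if group == "current_user":
            n_combined = int(round(g.combined_hc_fraction * g.n))
            hc = np.array(["combined"] * n_combined + ["progestin_only"] * (g.n - n_combined))
            rng.shuffle(hc)
        else:
            hc = np.array(["none"] * g.n)
        for i in range(g.n):
            idx += 1
            profiles.append(
                SubjectProfile(
                    subject_id=f"sub-{idx:03d}",
                    group=group,
                    hc_type=str(hc[i]),
                    age=float(ages[i]),
                    bdi_cognitive=int(bdi_cog[i]),
                    bdi_somatic_affective=int(bdi_som[i]),
                    menstrual_phase=str(phases[i]),
                    adverse_mood=bool(adverse[i]),
                    true_n1_intercept_uv=float(n1_inter[i]),
                    true_n1_slope_uv_per_db=float(n1_slopes[i]),
                    true_p2_intercept_uv=float(p2_inter[i]),
                    true_p2_slope_uv_per_db=float(p2_slopes[i]),
                    noise_sigma_uv=spec.noise_sigma_uv,
                    blink_rate_hz=spec.blink_rate_hz,
                    line_amp_uv=spec.line_amp_uv,
                )
            )
    table = cohort_table(profiles, bdi_threshold=spec.bdi_threshold)
    return profiles, table


def cohort_table(profiles: list[SubjectProfile], bdi_threshold: int = 13) -> pd.DataFrame:
    """Build the per-subject covariate table from profiles."""
    rows = []
    for p in profiles:
        rows.append(
            dict(
                subject_id=p.subject_id,
                group=p.group,
                group2="current_user" if p.group == "current_user" else "non_user",
                hc_type=p.hc_type,
                age=p.age,
                bdi_cognitive=p.bdi_cognitive,
                bdi_somatic_affective=p.bdi_somatic_affective,
                bdi_total=p.bdi_total,
                above_bdi_threshold=p.bdi_total >= bdi_threshold,
                menstrual_phase=p.menstrual_phase,
                adverse_mood=p.adverse_mood,
                true_n1_slope=p.true_n1_slope_uv_per_db,
                true_p2_slope=p.true_p2_slope_uv_per_db,
                true_n1p2_slope=p.true_n1p2_slope_uv_per_db,
            )
        )
    return pd.DataFrame(rows)
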