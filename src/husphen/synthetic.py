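"""Synthetic study inputs: cohorts, B-mode phantoms, Doppler waveforms, scores.

Every generator is a pure function of its spec (including the seed), so the
full analysis pipeline is testable without any acquired data. The defaults
emulate the study design they stand in for: two diet arms (standard diet SD
vs Western diet WD), eight mice per sex per arm followed weekly from 8 to
24 weeks of age, 8-bit B-mode frames on a 0.02 mm/px grid (~11 x 13 mm
field), and pulsatile arterial velocity traces with controllable systolic
peak (PSV), end-diastolic (EDV) and cycle-mean (MV) velocities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .doppler import DopplerTrace
from .errors import InfeasibleTargetError, GeometryError, ValidationError
from .liver import BModeImage, ROISpec

# --------------------------------------------------------------------------
# cohort tables
# --------------------------------------------------------------------------


class Gaussian(NamedTuple):
    """A mean/SD effect-size pair in the variable's own units."""

    mean: float
    sd: float


#: Caloric density of the two diets (kcal/g).
KCAL_PER_G = {"SD": 3.150, "WD": 4.2594}

ANALYTES = ("glucose", "cholesterol", "triglycerides", "alt", "ast", "bun",
            "insulin")


def _default_biochem_base() -> dict[str, Gaussian]:
    return {
        "glucose": Gaussian(155.0, 20.0),      # mg/dL
        "cholesterol": Gaussian(110.0, 15.0),  # mg/dL
        "triglycerides": Gaussian(90.0, 15.0),  # mg/dL
        "alt": Gaussian(30.0, 8.0),            # U/L
        "ast": Gaussian(55.0, 12.0),           # U/L
        "bun": Gaussian(22.0, 3.0),            # mg/dL
        "insulin": Gaussian(0.6, 0.2),         # ng/mL
    }


def _default_biochem_wd_shift() -> dict[str, dict[int, Gaussian]]:
    # Endpoint shifts follow the direction of the diet effects the cohort
    # emulates: hyperglycemia, hypercholesterolemia, higher transaminases
    # and insulin, lower urea, early triglyceride rise then fall.
    return {
        "glucose": {24: Gaussian(60.0, 15.0)},
        "cholesterol": {16: Gaussian(40.0, 12.0), 24: Gaussian(70.0, 15.0)},
        "triglycerides": {8: Gaussian(25.0, 10.0), 16: Gaussian(-20.0, 10.0)},
        "alt": {24: Gaussian(10.0, 6.0)},
        "ast": {24: Gaussian(35.0, 12.0)},
        "bun": {24: Gaussian(-6.0, 2.0)},
        "insulin": {24: Gaussian(0.8, 0.3)},
    }


@dataclass
class CohortConfig:
    """Design and effect sizes of a synthetic longitudinal cohort.

    Effect sizes are mean/SD pairs (:class:`Gaussian`) in the variable's
    units; WD effects are expressed as additive deltas on the sex-specific
    base so that zeroing them makes the two diet arms exchangeable.
    """

    n_per_group: int = 8
    sexes: tuple[str, ...] = ("male", "female")
    diets: tuple[str, ...] = ("SD", "WD")
    ages_weeks: tuple[int, ...] = tuple(range(8, 25))
    seed: int = 0
    baseline_bw: Mapping[str, Gaussian] = field(
        default_factory=lambda: {"male": Gaussian(23.0, 1.5),
                                 "female": Gaussian(18.0, 1.2)})
    bw_slope_base: Mapping[str, Gaussian] = field(
        default_factory=lambda: {"male": Gaussian(0.30, 0.05),
                                 "female": Gaussian(0.20, 0.04)})
    bw_slope_wd_extra: Mapping[str, Gaussian] = field(
        default_factory=lambda: {"male": Gaussian(0.25, 0.08),
                                 "female": Gaussian(0.15, 0.06)})
    bw_noise_sd: float = 0.4
    intake_base: Mapping[str, Gaussian] = field(
        default_factory=lambda: {"male": Gaussian(3.3, 0.25),
                                 "female": Gaussian(2.9, 0.20)})
    hyperphagia_window: tuple[int, int] = (8, 12)
    hyperphagia_delta: Gaussian = Gaussian(0.5, 0.1)
    late_intake_delta: Gaussian = Gaussian(-0.3, 0.1)
    intake_noise_sd: float = 0.15
    biochem_weeks: tuple[int, ...] = (8, 16, 24)
    biochem_base: Mapping[str, Gaussian] = field(
        default_factory=_default_biochem_base)
    biochem_wd_shift: Mapping[str, Mapping[int, Gaussian]] = field(
        default_factory=_default_biochem_wd_shift)
    bcs_wd_male_shift_from_week: int = 16
    liver_weight: Gaussian = Gaussian(1.10, 0.12)
    liver_wd_extra: Gaussian = Gaussian(0.25, 0.10)
    attrition_prob: float = 0.03
    kcal_per_g: Mapping[str, float] = field(
        default_factory=lambda: dict(KCAL_PER_G))

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        ages = tuple(self.ages_weeks)
        if len(ages) < 1 or any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValidationError("ages_weeks must be strictly increasing")
        if not set(self.sexes) <= {"male", "female"} or not self.sexes:
            raise ValidationError("sexes must be a non-empty subset of {male, female}")
        if not set(self.diets) <= {"SD", "WD"} or not self.diets:
            raise ValidationError("diets must be a non-empty subset of {SD, WD}")
        if not 0.0 <= self.attrition_prob <= 1.0:
            raise ValidationError("attrition_prob must be in [0, 1]")
        for name, value in self._gaussians():
            if value.sd < 0:
                raise ValidationError(f"{name} has negative SD {value.sd}")
        for name in ("bw_noise_sd", "intake_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def _gaussians(self):
        for attr in ("baseline_bw", "bw_slope_base", "bw_slope_wd_extra",
                     "intake_base", "biochem_base"):
            for key, g in getattr(self, attr).items():
                yield f"{attr}[{key}]", Gaussian(*g)
        for attr in ("hyperphagia_delta", "late_intake_delta",
                     "liver_weight", "liver_wd_extra"):
            yield attr, Gaussian(*getattr(self, attr))
        for analyte, shifts in self.biochem_wd_shift.items():
            for week, g in shifts.items():
                yield f"biochem_wd_shift[{analyte}][{week}]", Gaussian(*g)

    def null(self, quiet: bool = False, seed: int | None = None) -> "CohortConfig":
        """A copy with every diet effect removed.

        With ``quiet=True`` all biological variation, measurement noise and
        attrition are removed as well, so the two diet arms are identical.
        """
        def zero(g: Gaussian) -> Gaussian:
            return Gaussian(0.0, 0.0)

        def calm(g: Gaussian) -> Gaussian:
            return Gaussian(g.mean, 0.0) if quiet else Gaussian(*g)

        cfg = replace(
            self,
            seed=self.seed if seed is None else seed,
            bw_slope_wd_extra={s: zero(g) for s, g in self.bw_slope_wd_extra.items()},
            hyperphagia_delta=Gaussian(0.0, 0.0),
            late_intake_delta=Gaussian(0.0, 0.0),
            biochem_wd_shift={a: {w: zero(g) for w, g in d.items()}
                              for a, d in self.biochem_wd_shift.items()},
            liver_wd_extra=Gaussian(0.0, 0.0),
            bcs_wd_male_shift_from_week=10**6,
            baseline_bw={s: calm(g) for s, g in self.baseline_bw.items()},
            bw_slope_base={s: calm(g) for s, g in self.bw_slope_base.items()},
            intake_base={s: calm(g) for s, g in self.intake_base.items()},
            biochem_base={a: calm(g) for a, g in self.biochem_base.items()},
            liver_weight=calm(self.liver_weight),
        )
        if quiet:
            cfg = replace(cfg, bw_noise_sd=0.0, intake_noise_sd=0.0,
                          attrition_prob=0.0)
        return cfg


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """One record per mouse x timepoint with the configured diet effects.

    Body weight follows a per-mouse linear trend (sex-specific base slope
    plus the WD extra) with Gaussian measurement noise; WD groups receive
    the hyperphagia window on intake and the configured biochemistry shifts;
    attrition truncates whole mice after a random timepoint.
    """
    rng = np.random.default_rng(config.seed)
    ages = np.asarray(config.ages_weeks)
    age0 = ages[0]
    biochem_weeks = [w for w in config.biochem_weeks if w in set(ages)]
    fasting_week = biochem_weeks[-1] if biochem_weeks else None
    final_week = ages[-1]

    rows: list[dict] = []
    for sex in config.sexes:
        for diet in config.diets:
            for i in range(config.n_per_group):
                mouse_id = f"{diet}_{sex[0].upper()}_{i + 1:02d}"
                b0 = rng.normal(*config.baseline_bw[sex])
                slope = rng.normal(*config.bw_slope_base[sex])
                wd_extra = rng.normal(*config.bw_slope_wd_extra[sex])
                if diet == "WD":
                    slope += wd_extra
                intake0 = rng.normal(*config.intake_base[sex])
                hyper = rng.normal(*config.hyperphagia_delta)
                late = rng.normal(*config.late_intake_delta)
                bw_noise = rng.normal(0.0, 1.0, len(ages)) * config.bw_noise_sd
                intake_noise = (rng.normal(0.0, 1.0, len(ages))
                                * config.intake_noise_sd)
                liver = rng.normal(*config.liver_weight)
                liver_extra = rng.normal(*config.liver_wd_extra)
                if diet == "WD":
                    liver += liver_extra
                # biochem draws at every configured week, fixed draw order
                biochem: dict[tuple[str, int], float] = {}
                for analyte in ANALYTES:
                    base = config.biochem_base[analyte]
                    for week in biochem_weeks:
                        val = rng.normal(*base)
                        if diet == "WD":
                            shift = config.biochem_wd_shift.get(analyte, {})
                            if week in shift:
                                val += rng.normal(*shift[week])
                            else:
                                rng.normal(0.0, 1.0)  # keep draw order aligned
                        biochem[(analyte, week)] = max(val, 0.0)
                # attrition: truncate after a random timepoint (never baseline)
                n_keep = len(ages)
                attrit = rng.random()
                cut = rng.integers(1, max(len(ages), 2))
                if attrit < config.attrition_prob and len(ages) > 1:
                    n_keep = int(cut)

                for j, age in enumerate(ages[:n_keep]):
                    bw = b0 + slope * (age - age0) + bw_noise[j]
                    intake = intake0 + intake_noise[j]
                    if diet == "WD":
                        lo, hi = config.hyperphagia_window
                        if lo <= age <= hi:
                            intake += hyper
                        elif age > hi:
                            intake += late
                    bcs = 3
                    if (diet == "WD" and sex == "male"
                            and age >= config.bcs_wd_male_shift_from_week):
                        bcs = 4
                    row = {
                        "mouse_id": mouse_id,
                        "sex": sex,
                        "diet": diet,
                        "age_weeks": int(age),
                        "bw": max(bw, 1.0),
                        "bcs": bcs,
                        "food_intake_daily": max(intake, 0.0),
                        "kcal_per_g": config.kcal_per_g[diet],
                        "fasting": bool(age == fasting_week),
                        "liver_weight": liver if age == final_week else np.nan,
                    }
                    for analyte in ANALYTES:
                        row[analyte] = biochem.get((analyte, age), np.nan)
                    rows.append(row)
    return pd.DataFrame(rows)


def generate_score_sheet(
    config: CohortConfig,
    prevalence: Mapping[tuple[str, str], Mapping[str, Mapping[int, float]]],
) -> pd.DataFrame:
    """Per-mouse ordinal grades drawn from per-group score distributions.

    ``prevalence`` maps ``(sex, diet)`` to ``{score_column: {level: prob}}``;
    each probability vector must sum to 1 (tolerance 1e-9).
    """
    for group, cols in prevalence.items():
        for col, dist in cols.items():
            total = float(sum(dist.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"probabilities for {group}/{col} sum to {total}, not 1"
                )
            if any(p < 0 for p in dist.values()):
                raise ValidationError(f"negative probability in {group}/{col}")
    rng = np.random.default_rng([config.seed, 0x5C0])
    rows = []
    for sex in config.sexes:
        for diet in config.diets:
            dists = prevalence.get((sex, diet))
            if dists is None:
                continue
            for i in range(config.n_per_group):
                row = {"mouse_id": f"{diet}_{sex[0].upper()}_{i + 1:02d}",
                       "sex": sex, "diet": diet}
                for col, dist in dists.items():
                    levels = np.array(sorted(dist))
                    probs = np.array([dist[k] for k in levels], dtype=float)
                    row[col] = int(rng.choice(levels, p=probs / probs.sum()))
                rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# B-mode speckle phantoms
# --------------------------------------------------------------------------

#: Normalizer making the Rayleigh multiplier mean-one: E[Rayleigh(1)] = sqrt(pi/2).
_RAYLEIGH_MEAN = math.sqrt(math.pi / 2.0)


@dataclass(frozen=True)
class Region:
    """A labeled phantom region with its target echo statistics."""

    label: str
    mask: np.ndarray
    target_mean: float
    heterogeneity_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_mean <= 255.0:
            raise ValidationError(
                f"region {self.label!r}: target_mean {self.target_mean} "
                "outside [0, 255]")
        if self.heterogeneity_sd < 0:
            raise ValidationError(f"region {self.label!r}: negative SD")


@dataclass
class PhantomSpec:
    """Geometry and texture statistics of a synthetic B-mode phantom.

    Speckle is fully developed multiplicative Rayleigh noise with the scale
    chosen so the multiplier has unit mean (regional means are preserved in
    expectation); the point-spread function is a Gaussian blur applied to
    the multiplier field.
    """

    regions: Sequence[Region]
    image_shape: tuple[int, int] = (550, 650)
    pixel_spacing: float = 0.02
    speckle: bool = True
    psf_sigma: float = 1.5
    background_mean: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_spacing <= 0:
            raise ValidationError("pixel_spacing must be > 0")
        if self.psf_sigma < 0:
            raise ValidationError("psf_sigma must be >= 0")
        if not 0.0 <= self.background_mean <= 255.0:
            raise ValidationError("background_mean outside [0, 255]")
        occupancy = np.zeros(self.image_shape, dtype=int)
        for region in self.regions:
            if region.mask.shape != tuple(self.image_shape):
                raise ValidationError(
                    f"region {region.label!r} mask shape mismatch")
            occupancy += region.mask.astype(int)
        if (occupancy > 1).any():
            raise GeometryError("region masks overlap")


def rect_mask(shape: tuple[int, int], r0: int, r1: int, c0: int, c1: int
              ) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask


def generate_phantom(spec: PhantomSpec,
                     plane_label: str | None = None) -> BModeImage:
    """Render an 8-bit phantom image from a :class:`PhantomSpec`.

    The continuous image is ``base * blur(multiplier)`` where ``base`` holds
    the regional target means plus per-pixel Gaussian heterogeneity and the
    multiplier is mean-one Rayleigh speckle; intensities are quantized to
    8 bits by round-half-even.
    """
    rng = np.random.default_rng(spec.seed)
    base = np.full(spec.image_shape, spec.background_mean, dtype=float)
    for region in spec.regions:
        n = int(region.mask.sum())
        values = np.full(n, region.target_mean)
        if region.heterogeneity_sd > 0:
            values = values + rng.normal(0.0, region.heterogeneity_sd, n)
        base[region.mask] = values
    if spec.speckle:
        mult = rng.rayleigh(scale=1.0, size=spec.image_shape) / _RAYLEIGH_MEAN
        if spec.psf_sigma > 0:
            mult = gaussian_filter(mult, spec.psf_sigma)
    else:
        mult = 1.0
    img = np.clip(np.rint(base * mult), 0, 255).astype(np.uint8)
    return BModeImage(
        pixels=img,
        pixel_spacing=spec.pixel_spacing,
        plane_label=plane_label,
        masks={r.label: r.mask for r in spec.regions},
    )


def liver_kidney_phantom(
    liver_mean: float = 94.8,
    cortex_mean: float = 120.0,
    liver_het: float = 6.0,
    cortex_het: float = 6.0,
    seed: int = 0,
    speckle: bool = True,
    psf_sigma: float = 1.5,
    image_shape: tuple[int, int] = (550, 650),
    pixel_spacing: float = 0.02,
) -> BModeImage:
    """A liver/right-kidney long-axis phantom with depth-matched regions.

    The liver parenchyma and renal-cortex blocks share the same depth band
    so protocol ROIs can be placed at equal distance from the probe.
    """
    nr, nc = image_shape
    r0, r1 = int(0.33 * nr), int(0.80 * nr)
    regions = [
        Region("liver", rect_mask(image_shape, r0, r1, int(0.06 * nc),
                                  int(0.46 * nc)), liver_mean, liver_het),
        Region("renal_cortex", rect_mask(image_shape, r0, r1, int(0.52 * nc),
                                         int(0.92 * nc)), cortex_mean,
               cortex_het),
    ]
    spec = PhantomSpec(regions=regions, image_shape=image_shape,
                       pixel_spacing=pixel_spacing, speckle=speckle,
                       psf_sigma=psf_sigma, seed=seed)
    return generate_phantom(spec, plane_label="liver_kidney_long")


def liver_kidney_rois(
    image_shape: tuple[int, int] = (550, 650),
    area_mm2: float = 0.1,
) -> tuple[ROISpec, ROISpec]:
    """Depth-matched liver and renal-cortex ROIs for the default phantom."""
    nr, nc = image_shape
    row = 0.565 * nr
    return (ROISpec((row, 0.26 * nc), area_mm2),
            ROISpec((row, 0.72 * nc), area_mm2))


# --------------------------------------------------------------------------
# pulsatile Doppler waveforms
# --------------------------------------------------------------------------

#: Cycle phase fractions: systolic upstroke, exponential run-off,
#: late-diastolic recovery, end-diastolic hold.
UPSTROKE_FRAC = 0.15
DECAY_FRAC = 0.70
RECOVERY_FRAC = 0.08
HOLD_FRAC = 0.07

_K_MIN, _K_MAX = 1e-4, 50.0


@dataclass(frozen=True)
class WaveformSpec:
    """Shape targets of a synthetic arterial velocity waveform.

    Each cycle rises linearly from EDV to PSV over 15% of the period, decays
    exponentially (rate ``k``) toward zero for 70%, recovers linearly to EDV
    and holds it until the next upstroke. Without ``mv_target`` the decay
    rate is set so the run-off lands exactly on EDV; with ``mv_target`` the
    rate is solved by bisection so the cycle-mean velocity matches it, which
    lets the diastolic run-off dip below EDV (the physiological trace shape
    cannot otherwise produce a cycle mean under EDV).
    """

    hr: float = 400.0              # beats/min
    psv: float = 30.0              # mm/s
    edv: float = 15.0              # mm/s
    mv_target: float | None = None  # mm/s
    n_cycles: int = 4
    sampling_rate: float = 8000.0  # Hz
    noise_sd: float = 0.0          # mm/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValidationError("hr must be > 0")
        if not 0 <= self.edv <= self.psv:
            raise ValidationError("need 0 <= edv <= psv")
        if self.n_cycles < 3:
            raise ValidationError("n_cycles must be >= 3")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def _cycle_mean(psv: float, edv: float, k: float) -> float:
    """Closed-form cycle-mean velocity of the noiseless waveform."""
    if k < 1e-12:
        decay_mean = psv
        v_end = psv
    else:
        decay_mean = psv * (1.0 - math.exp(-k)) / k
        v_end = psv * math.exp(-k)
    return (UPSTROKE_FRAC * (psv + edv) / 2.0
            + DECAY_FRAC * decay_mean
            + RECOVERY_FRAC * (v_end + edv) / 2.0
            + HOLD_FRAC * edv)


def mv_feasible_range(psv: float, edv: float) -> tuple[float, float]:
    """Attainable cycle-mean velocities for the waveform shape."""
    return _cycle_mean(psv, edv, _K_MAX), _cycle_mean(psv, edv, _K_MIN)


def solve_decay_rate(psv: float, edv: float, mv_target: float,
                     rtol: float = 1e-9) -> float:
    """Decay rate whose cycle mean equals ``mv_target`` (bisection).

    The cycle mean is strictly decreasing in the rate, so the root is
    unique; a target outside :func:`mv_feasible_range` raises
    :class:`~husphen.errors.InfeasibleTargetError`.
    """
    lo_mean, hi_mean = mv_feasible_range(psv, edv)
    if not lo_mean < mv_target < hi_mean:
        raise InfeasibleTargetError(
            f"mv_target {mv_target} outside attainable cycle-mean range "
            f"({lo_mean:.4g}, {hi_mean:.4g})")
    k_lo, k_hi = _K_MIN, _K_MAX
    for _ in range(200):
        k = 0.5 * (k_lo + k_hi)
        m = _cycle_mean(psv, edv, k)
        if abs(m - mv_target) <= rtol * mv_target:
            return k
        if m > mv_target:
            k_lo = k
        else:
            k_hi = k
    return 0.5 * (k_lo + k_hi)


def _default_decay_rate(psv: float, edv: float) -> float:
    if psv <= 0 or psv == edv:
        return 0.0
    floor = max(edv / psv, 0.02)
    return math.log(1.0 / floor)


def waveform_samples(phase: np.ndarray, psv: float, edv: float,
                     k: float) -> np.ndarray:
    """Evaluate the noiseless waveform at cycle phases in [0, 1)."""
    v = np.empty_like(phase)
    v_end = psv * math.exp(-k) if k > 0 else psv
    up = phase < UPSTROKE_FRAC
    v[up] = edv + (psv - edv) * phase[up] / UPSTROKE_FRAC
    dec = (~up) & (phase < UPSTROKE_FRAC + DECAY_FRAC)
    u = (phase[dec] - UPSTROKE_FRAC) / DECAY_FRAC
    v[dec] = psv * np.exp(-k * u)
    rec = (~up) & (~dec) & (phase < UPSTROKE_FRAC + DECAY_FRAC + RECOVERY_FRAC)
    w = (phase[rec] - UPSTROKE_FRAC - DECAY_FRAC) / RECOVERY_FRAC
    v[rec] = v_end + (edv - v_end) * w
    hold = ~(up | dec | rec)
    v[hold] = edv
    return v


def generate_waveform(spec: WaveformSpec) -> DopplerTrace:
    """Synthesize a pulsatile velocity trace from a :class:`WaveformSpec`."""
    period = 60.0 / spec.hr
    dt = 1.0 / spec.sampling_rate
    n = int(round(spec.n_cycles * period * spec.sampling_rate)) + 1
    t = np.arange(n) * dt
    if spec.mv_target is not None:
        k = solve_decay_rate(spec.psv, spec.edv, spec.mv_target)
    else:
        k = _default_decay_rate(spec.psv, spec.edv)
    phase = (t / period) % 1.0
    v = waveform_samples(phase, spec.psv, spec.edv, k)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd, n)
    return DopplerTrace(time=t, velocity=v, hr_hint=spec.hr)
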