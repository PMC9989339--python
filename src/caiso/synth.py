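"""Synthetic data with known ground truth: raw MC-ICP-MS sessions, a
steady-state calcium isotope mass-balance model, and a four-group clinical
cohort calibrated to the study's printed summary statistics.

The session generator emulates the acquisition scheme of the reduction
module (blank–standard–blank–sample–blank–standard…, 40 cycles per block):
sample ratios are the natural-abundance reference ratios shifted by a known
true delta, fractionated by the exponential mass-bias law (constant or
linearly drifting β), with optional per-cycle ratio noise, additive blank,
doubly-charged-Sr contamination at mass 43.5, a non-mass-dependent ⁴³Ca
spike, and a deliberate sample/standard intensity mismatch.  All ground
truth is echoed into block metadata, never into the measured intensities.

The cohort generator draws, per clinical group, serum δ⁴⁴/⁴²Ca and ba-PWV
from a bivariate normal, urine calcium from a moment-matched lognormal, and
assigns arteriosclerosis either mechanistically (applying the clinical
classifier to the drawn ba-PWV/age/sex) or marginally (Bernoulli at a given
prevalence).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants
from .clinical import classify_arteriosclerosis, classify_pad
from .errors import GenerationError, SpecificationError
from .reduction import AnalysisSession, BlockType, IsotopeCycleBlock

__all__ = [
    "SessionSpec",
    "generate_session",
    "MassBalanceScenario",
    "steady_state_deltas",
    "GroupSpec",
    "CohortSpec",
    "default_cohort_spec",
    "generate_cohort",
    "correlated_pair",
]


# ---------------------------------------------------------------------------
# raw-session generator
# ---------------------------------------------------------------------------

@dataclass
class SessionSpec:
    """Ground-truth recipe for one synthetic acquisition session.

    ``true_delta44_42`` may be a single value or a sequence (one sample block
    per value), on the in-house (bracketing standard) scale.  ``beta`` is the
    exponential-law mass-bias factor; ``beta_drift`` optionally gives
    (start, end) values interpolated linearly over run index.  Noise is the
    1-sd per-cycle relative ratio noise in per mille.
    """

    true_delta44_42: float | tuple[float, ...] = 0.0
    n_cycles: int = 40
    beta: float = 1.6
    beta_drift: tuple[float, float] | None = None
    cycle_noise_permil: float = 0.0
    blank_level: float = 0.001          # volts, per mass
    sr_ratio_43p5_44: float = 0.0       # target blank-corrected 43.5/44 ratio
    spike43_permil: float = 0.0         # non-mass-dependent δ43 spike on samples
    intensity_mismatch: float = 1.0     # sample/standard beam-intensity ratio
    massbias_pair_offset_43: float = 0.0  # extra β on the 43/42 pair, all blocks
    base_intensity_42: float = 0.93     # volts → ⁴⁴Ca beam ≈ 3 V
    seed: int | None = None

    def deltas(self) -> tuple[float, ...]:
        d = self.true_delta44_42
        return tuple(d) if isinstance(d, (tuple, list, np.ndarray)) else (float(d),)

    def validate(self) -> None:
        if self.n_cycles < 2:
            raise GenerationError("n_cycles must be ≥2")
        if self.cycle_noise_permil < 0:
            raise GenerationError("cycle noise must be ≥0")
        if self.blank_level < 0 or self.base_intensity_42 <= 0:
            raise GenerationError("intensities must be nonnegative (base > 0)")
        if self.intensity_mismatch <= 0:
            raise GenerationError("intensity_mismatch must be positive")


def _measured_ratios(
    spec: SessionSpec,
    rng: np.random.Generator,
    beta: float,
    delta44: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle measured (44/42, 43/42) ratios for one standard or sample block."""
    if delta44 is None:  # standard: true composition = reference
        r44_true = constants.R44_42_REFERENCE
        r43_true = constants.R43_42_REFERENCE
    else:
        d43 = constants.EXPONENTIAL_LAW_SLOPE * delta44 + spec.spike43_permil
        r44_true = constants.R44_42_REFERENCE * (1.0 + delta44 / 1000.0)
        r43_true = constants.R43_42_REFERENCE * (1.0 + d43 / 1000.0)
    k44 = (constants.MASS_44 / constants.MASS_42) ** (-beta)
    k43 = (constants.MASS_43 / constants.MASS_42) ** (
        -(beta + spec.massbias_pair_offset_43)
    )
    r44 = np.full(spec.n_cycles, r44_true * k44)
    r43 = np.full(spec.n_cycles, r43_true * k43)
    if spec.cycle_noise_permil > 0:
        r44 = r44 * (1.0 + rng.normal(0, spec.cycle_noise_permil, spec.n_cycles) / 1000.0)
        r43 = r43 * (1.0 + rng.normal(0, spec.cycle_noise_permil, spec.n_cycles) / 1000.0)
    return r44, r43


def generate_session(spec: SessionSpec, rng: np.random.Generator | None = None) -> AnalysisSession:
    """Build a complete blank/standard/sample session from a ground-truth spec."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    deltas = spec.deltas()
    # layout: B S (B X B S) per sample; β drifts linearly over run index
    plan: list[tuple[str, float | None]] = [("blank", None), ("standard", None)]
    for d in deltas:
        plan += [("blank", None), ("sample", d), ("blank", None), ("standard", None)]
    n_blocks = len(plan)

    def beta_at(run_index: int) -> float:
        if spec.beta_drift is None:
            return spec.beta
        b0, b1 = spec.beta_drift
        return b0 + (b1 - b0) * run_index / max(n_blocks - 1, 1)

    blocks: list[IsotopeCycleBlock] = []
    sample_no = 0
    for run_index, (kind, delta) in enumerate(plan):
        block_id = f"b{run_index:03d}_{kind}"
        if kind == "blank":
            level = np.full(spec.n_cycles, spec.blank_level)
            blocks.append(
                IsotopeCycleBlock(
                    block_id=block_id,
                    block_type=BlockType.BLANK,
                    run_index=run_index,
                    intensity_42=level.copy(),
                    intensity_43=level.copy(),
                    intensity_43p5=level.copy(),
                    intensity_44=level.copy(),
                    label="blank",
                )
            )
            continue
        is_sample = kind == "sample"
        r44, r43 = _measured_ratios(spec, rng, beta_at(run_index), delta)
        scale = spec.intensity_mismatch if is_sample else 1.0
        i42 = np.full(spec.n_cycles, spec.base_intensity_42 * scale)
        i43 = i42 * r43
        i44 = i42 * r44
        i435 = (
            spec.sr_ratio_43p5_44 * i44
            if (is_sample and spec.sr_ratio_43p5_44 > 0)
            else np.zeros(spec.n_cycles)
        )
        if np.any(i44 + spec.blank_level < 0):
            raise GenerationError("specification implies negative intensities")
        meta: dict = {"beta": beta_at(run_index)}
        label = "bracketing standard"
        if is_sample:
            sample_no += 1
            label = f"sample-{sample_no:02d}"
            meta.update(
                true_delta44_42=delta,
                true_delta43_42=constants.EXPONENTIAL_LAW_SLOPE * delta
                + spec.spike43_permil,
                sr_ratio_43p5_44=spec.sr_ratio_43p5_44,
                spike43_permil=spec.spike43_permil,
                intensity_mismatch=spec.intensity_mismatch,
            )
        blocks.append(
            IsotopeCycleBlock(
                block_id=block_id,
                block_type=BlockType.SAMPLE if is_sample else BlockType.STANDARD,
                run_index=run_index,
                intensity_42=i42 + spec.blank_level,
                intensity_43=i43 + spec.blank_level,
                intensity_43p5=i435 + spec.blank_level,
                intensity_44=i44 + spec.blank_level,
                label=label,
                meta=meta,
            )
        )
    session = AnalysisSession(
        blocks=blocks,
        standard_scale="WIGL",
        meta={"true_deltas": list(deltas), "spec": spec},
    )
    session.validate()
    return session


# ---------------------------------------------------------------------------
# steady-state isotope mass balance
# ---------------------------------------------------------------------------

#: urine–blood fractionation: urine is heavier than blood by +1.2‰
DELTA_URINE_OFFSET = 1.2
#: bone mineralisation takes up light Ca from blood: bone−blood ≈ −0.30‰
DELTA_BONE_OFFSET = -0.30


@dataclass
class MassBalanceScenario:
    """Steady-state box model of whole-body calcium isotope routing.

    Dietary input at ``delta_input`` leaves the exchangeable (serum) pool via
    urine, net bone mineralisation and vascular mineral accretion, with flux
    fractions summing to 1 and fixed per-route fractionation offsets relative
    to serum.  At steady state serum adjusts so the flux-weighted output
    delta equals the input delta (isotope mass conservation).
    """

    delta_input: float = 0.0
    f_urine: float = 0.5
    f_bone_net: float = 0.5
    f_vascular: float = 0.0
    offset_urine: float = DELTA_URINE_OFFSET
    offset_bone: float = DELTA_BONE_OFFSET
    offset_vascular: float = DELTA_BONE_OFFSET  # vessel mineral assumed bone-like

    def validate(self) -> None:
        f = (self.f_urine, self.f_bone_net, self.f_vascular)
        if any(x < 0 for x in f):
            raise SpecificationError("flux fractions must be nonnegative")
        if abs(sum(f) - 1.0) > 1e-9:
            raise SpecificationError(f"flux fractions must sum to 1, got {sum(f)}")


def steady_state_deltas(scenario: MassBalanceScenario) -> tuple[float, float]:
    """Closed-form steady-state (serum δ, urine δ) for a mass-balance scenario.

    serum δ = δ_input − (f_u·Δ_u + f_b·Δ_b + f_v·Δ_v);  urine δ = serum δ + Δ_u.
    The flux-weighted mean of the output deltas equals δ_input exactly.
    """
    scenario.validate()
    s = scenario
    serum = s.delta_input - (
        s.f_urine * s.offset_urine
        + s.f_bone_net * s.offset_bone
        + s.f_vascular * s.offset_vascular
    )
    urine = serum + s.offset_urine
    return serum, urine


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """Per-group distribution parameters for the cohort generator."""

    n: int
    serum_delta_mean: float
    serum_delta_sd: float
    urine_delta_mean: float
    urine_delta_sd: float
    urine_ca_mean: float       # µg/g; lognormal moment-matched
    urine_ca_sd: float
    pwv_mean: float            # cm/s
    pwv_sd: float
    age_center: float          # years
    age_spread: float
    male_fraction: float = 0.5
    #: None → arteriosclerosis assigned mechanically by the ba-PWV rule;
    #: a float → independent Bernoulli at that prevalence
    arterio_prevalence: float | None = None
    rho_serum_pwv: float = 0.3
    # remaining chemistry (normal approximations; medians/IQRs mapped to
    # center and half-IQR/0.6745)
    sbp_mean: float = 140.0
    sbp_sd: float = 20.0
    bmi_mean: float = 28.0
    bmi_sd: float = 4.5
    egfr_mean: float = 60.0
    egfr_sd: float = 20.0
    po4_mean: float = 1.1
    po4_sd: float = 0.2
    albumin_mean: float = 40.0
    albumin_sd: float = 4.0
    creatinine_median: float = 100.0   # µmol/L, lognormal
    creatinine_spread: float = 0.25    # sd of log10 creatinine
    fgf23_log10_mean: float = 2.0      # reported on the log10 scale
    fgf23_log10_sd: float = 0.2
    vitd_mean: float = 100.0
    vitd_sd: float = 35.0
    abi_mean: float = 1.10
    abi_sd: float = 0.12

    def validate(self) -> None:
        if self.n < 0:
            raise GenerationError("group n must be ≥0")
        for name in ("serum_delta_sd", "urine_delta_sd", "urine_ca_sd", "pwv_sd"):
            if getattr(self, name) < 0:
                raise GenerationError(f"{name} must be ≥0")
        if self.urine_ca_mean <= 0:
            raise GenerationError("urine Ca mean must be positive for the lognormal")
        if self.arterio_prevalence is not None and not 0 <= self.arterio_prevalence <= 1:
            raise GenerationError("prevalence must lie in [0, 1]")
        if not -1 < self.rho_serum_pwv < 1:
            raise GenerationError("rho must lie in (−1, 1)")


@dataclass
class CohortSpec:
    groups: dict[str, GroupSpec]
    seed: int | None = None
    #: if True, blank out serum/urine deltas and PWV at roughly the study's
    #: per-variable availability (cross-sectional missingness), else complete
    mimic_missingness: bool = False


def default_cohort_spec(seed: int | None = None) -> CohortSpec:
    """Study-condition defaults: the four printed groups and their summary moments."""
    groups = {
        "control": GroupSpec(
            n=28, serum_delta_mean=-0.70, serum_delta_sd=0.16,
            urine_delta_mean=0.54, urine_delta_sd=0.19,
            urine_ca_mean=119.0, urine_ca_sd=86.0,
            pwv_mean=1227.0, pwv_sd=229.0,
            age_center=41.0, age_spread=19.0, male_fraction=0.44,
            arterio_prevalence=0.068,
            egfr_mean=86.0, egfr_sd=7.2, po4_mean=1.13, po4_sd=0.16,
            albumin_mean=40.8, albumin_sd=2.7, creatinine_median=75.0,
            creatinine_spread=0.05, fgf23_log10_mean=1.65, fgf23_log10_sd=0.08,
            vitd_mean=120.0, vitd_sd=33.8, sbp_mean=129.0, sbp_sd=17.0,
            bmi_mean=26.0, bmi_sd=2.8,
        ),
        "mild_moderate": GroupSpec(
            n=9, serum_delta_mean=-0.60, serum_delta_sd=0.14,
            urine_delta_mean=0.48, urine_delta_sd=0.15,
            urine_ca_mean=30.0, urine_ca_sd=38.0,
            pwv_mean=1694.0, pwv_sd=264.0,
            age_center=70.0, age_spread=4.5, male_fraction=0.56,
            arterio_prevalence=0.429,
            egfr_mean=47.0, egfr_sd=24.0, po4_mean=1.12, po4_sd=0.29,
            albumin_mean=39.0, albumin_sd=4.2, creatinine_median=110.0,
            creatinine_spread=0.10, fgf23_log10_mean=1.98, fgf23_log10_sd=0.10,
            vitd_mean=112.6, vitd_sd=30.8, sbp_mean=152.0, sbp_sd=25.0,
            bmi_mean=29.8, bmi_sd=6.7,
        ),
        "dialysis": GroupSpec(
            n=22, serum_delta_mean=0.14, serum_delta_sd=0.24,
            urine_delta_mean=0.69, urine_delta_sd=0.39,
            urine_ca_mean=29.0, urine_ca_sd=20.0,
            pwv_mean=2050.0, pwv_sd=713.0,
            age_center=71.0, age_spread=5.2, male_fraction=0.59,
            arterio_prevalence=0.75,
            egfr_mean=6.7, egfr_sd=2.0, po4_mean=1.51, po4_sd=0.51,
            albumin_mean=32.6, albumin_sd=3.0, creatinine_median=666.0,
            creatinine_spread=0.07, fgf23_log10_mean=3.29, fgf23_log10_sd=0.39,
            vitd_mean=44.24, vitd_sd=25.3, sbp_mean=145.0, sbp_sd=10.0,
            bmi_mean=29.1, bmi_sd=5.2,
        ),
        "transplant": GroupSpec(
            n=19, serum_delta_mean=-0.47, serum_delta_sd=0.16,
            urine_delta_mean=0.92, urine_delta_sd=0.42,
            urine_ca_mean=31.0, urine_ca_sd=22.0,
            pwv_mean=1585.0, pwv_sd=318.0,
            age_center=58.0, age_spread=7.4, male_fraction=0.79,
            arterio_prevalence=0.692,
            egfr_mean=57.0, egfr_sd=21.0, po4_mean=1.03, po4_sd=0.2,
            albumin_mean=41.0, albumin_sd=11.0, creatinine_median=115.0,
            creatinine_spread=0.10, fgf23_log10_mean=2.02, fgf23_log10_sd=0.13,
            vitd_mean=109.0, vitd_sd=42.5, sbp_mean=144.0, sbp_sd=8.5,
            bmi_mean=28.7, bmi_sd=1.7,
        ),
    }
    return CohortSpec(groups=groups, seed=seed)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and sd."""
    if mean <= 0:
        raise GenerationError("lognormal moment matching needs a positive mean")
    if sd == 0:
        return float(np.log(mean)), 0.0
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def correlated_pair(
    n: int,
    rho: float,
    rng: np.random.Generator,
    mean: tuple[float, float] = (0.0, 0.0),
    sd: tuple[float, float] = (1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n samples from a bivariate normal with population correlation rho."""
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x = mean[0] + sd[0] * z1
    y = mean[1] + sd[1] * (rho * z1 + np.sqrt(max(1.0 - rho * rho, 0.0)) * z2)
    return x, y


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a complete cohort table from a :class:`CohortSpec`.

    Deterministic under a fixed spec and seed: the master seed expands into
    one independent child stream per group via ``numpy``'s SeedSequence
    spawning, in group-insertion order.
    """
    master = seed if seed is not None else spec.seed
    children = np.random.SeedSequence(master).spawn(len(spec.groups) + 1)
    frames = []
    sid = 0
    for (gname, g), child in zip(spec.groups.items(), children):
        g.validate()
        rng = np.random.default_rng(child)
        n = g.n
        if n == 0:
            continue
        serum_d, pwv = correlated_pair(
            n,
            g.rho_serum_pwv,
            rng,
            mean=(g.serum_delta_mean, g.pwv_mean),
            sd=(g.serum_delta_sd, g.pwv_sd),
        )
        pwv = np.maximum(pwv, 300.0)  # physical floor
        urine_d = rng.normal(g.urine_delta_mean, g.urine_delta_sd, n)
        mu, sigma = _lognormal_params(g.urine_ca_mean, g.urine_ca_sd)
        urine_ca = rng.lognormal(mu, sigma, n) if sigma > 0 else np.full(n, g.urine_ca_mean)
        age = np.maximum(rng.normal(g.age_center, g.age_spread, n), 18.0)
        sex = np.where(rng.random(n) < g.male_fraction, "male", "female")
        abi = np.maximum(rng.normal(g.abi_mean, g.abi_sd, n), 0.4)
        creat = 10.0 ** rng.normal(np.log10(g.creatinine_median), g.creatinine_spread, n)

        if g.arterio_prevalence is None:
            arts = [
                classify_arteriosclerosis(float(p), float(a), s)[0]
                for p, a, s in zip(pwv, age, sex)
            ]
        else:
            arts = list(rng.random(n) < g.arterio_prevalence)
        pads = [classify_pad(float(a))[0] for a in abi]

        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"S{sid + i:03d}" for i in range(n)],
                    "group": gname,
                    "age_years": age,
                    "sex": sex,
                    "sbp_mmhg": rng.normal(g.sbp_mean, g.sbp_sd, n),
                    "bmi_kg_m2": rng.normal(g.bmi_mean, g.bmi_sd, n),
                    "egfr": rng.normal(g.egfr_mean, g.egfr_sd, n),
                    "ca_mmol_l": rng.normal(2.35, 0.12, n),
                    "po4": rng.normal(g.po4_mean, g.po4_sd, n),
                    "albumin": rng.normal(g.albumin_mean, g.albumin_sd, n),
                    "pth_pmol_l": np.maximum(rng.normal(8.0, 5.0, n), 0.5),
                    "alp_u_l": np.maximum(rng.normal(85.0, 30.0, n), 20.0),
                    "creatinine_umol_l": creat,
                    "fgf23_log10": rng.normal(g.fgf23_log10_mean, g.fgf23_log10_sd, n),
                    "vitd": rng.normal(g.vitd_mean, g.vitd_sd, n),
                    "abi": abi,
                    "ba_pwv_cm_s": pwv,
                    "urine_ca_ug_g": urine_ca,
                    "urine_delta44_42": urine_d,
                    "serum_delta44_42": serum_d,
                    "pad_present": pads,
                    "arteriosclerosis_present": arts,
                }
            )
        )
        sid += n
    if not frames:
        raise GenerationError("empty cohort specification")
    cohort = pd.concat(frames, ignore_index=True)

    if spec.mimic_missingness:
        rng = np.random.default_rng(children[-1])
        n_all = len(cohort)
        for col, frac in (
            ("serum_delta44_42", 53 / 78),
            ("urine_delta44_42", 36 / 78),
            ("urine_ca_ug_g", 52 / 78),
            ("ba_pwv_cm_s", 51 / 78),
            ("abi", 61 / 78),
        ):
            drop = rng.random(n_all) >= frac
            cohort.loc[drop, col] = np.nan
        cohort["arteriosclerosis_present"] = cohort["arteriosclerosis_present"].astype(object)
        cohort["pad_present"] = cohort["pad_present"].astype(object)
        cohort.loc[cohort["ba_pwv_cm_s"].isna(), "arteriosclerosis_present"] = None
        cohort.loc[cohort["abi"].isna(), "pad_present"] = None
    return cohort
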