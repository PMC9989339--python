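"""Cycle-level MC-ICP-MS data reduction to δ⁴⁴/⁴²Ca and δ⁴³/⁴²Ca.

The measurement model: each acquisition block records per-cycle Faraday-cup
intensities at masses 42, 43, 43.5 and 44 (the half mass monitors doubly
charged ⁸⁷Sr, a proxy for ⁸⁶Sr²⁺/⁸⁸Sr²⁺ isobaric interference on ⁴³Ca/⁴⁴Ca).
Instrument blanks measured before each standard and sample are subtracted,
samples are normalised to the arithmetic mean of the bracketing standard
ratios (standard-sample bracketing cancels any constant instrumental mass
bias), and four quality-control filters screen each analysis:

1. interference — reject if the blank-corrected 43.5/44 ratio exceeds 1e-5;
2. intensity match — reject if the sample ⁴⁴Ca beam deviates from the
   bracketing standard beam by more than 10%;
3. mass-bias-factor spread — reject if 2·sd of the exponential-law factors
   computed from the 43/42, 44/42 and 44/43 ratios exceeds 0.1;
4. mass dependence — reject if |0.50667·δ⁴⁴/⁴² − δ⁴³/⁴²| exceeds 0.1‰
   (mass-dependently fractionated Ca satisfies δ43/42 ≈ 0.50667·δ44/42).

Rejected analyses are emitted flagged, never dropped.  No interference
correction is ever applied — the screen only rejects.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import constants
from .config import ReductionConfig
from .errors import CalibrationError, DataError, ReductionError, StructureError
from .scales import DEFAULT_REGISTRY, ScaleRegistry

__all__ = [
    "BlockType",
    "IsotopeCycleBlock",
    "AnalysisSession",
    "RatioSummary",
    "QCCheck",
    "QCReport",
    "DeltaMeasurement",
    "ConcentrationCalibration",
    "ConcentrationResult",
    "subtract_blank",
    "summarize_ratios",
    "check_interference",
    "delta_bracketed",
    "mass_bias_factor",
    "mass_bias_factors",
    "qc_mass_bias_spread",
    "qc_mass_dependence",
    "qc_intensity_match",
    "reduce_session",
    "quantify_concentration",
]


class BlockType(str, Enum):
    BLANK = "blank"
    STANDARD = "standard"
    SAMPLE = "sample"


@dataclass
class IsotopeCycleBlock:
    """One acquisition block: per-cycle intensities at masses 42/43/43.5/44."""

    block_id: str
    block_type: BlockType
    run_index: int
    intensity_42: np.ndarray
    intensity_43: np.ndarray
    intensity_43p5: np.ndarray
    intensity_44: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.block_type = BlockType(self.block_type)
        arrays = {}
        n = None
        for name in ("intensity_42", "intensity_43", "intensity_43p5", "intensity_44"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or arr.size < 1:
                raise DataError(f"block {self.block_id}: {name} must be a non-empty 1-D array")
            if not np.all(np.isfinite(arr)):
                raise DataError(f"block {self.block_id}: non-finite value in {name}")
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise DataError(f"block {self.block_id}: cycle arrays have unequal length")
            arrays[name] = arr
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)

    @property
    def n_cycles(self) -> int:
        return int(self.intensity_42.size)


@dataclass
class AnalysisSession:
    """An ordered run of blank/standard/sample blocks plus session metadata."""

    blocks: list[IsotopeCycleBlock]
    date: str = ""
    operator: str = ""
    standard_scale: str = "WIGL"
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Check run-order invariants; raise :class:`StructureError` on violation."""
        last = -math.inf
        for b in self.blocks:
            if b.run_index <= last:
                raise StructureError(
                    f"run_index not strictly increasing at block {b.block_id}"
                )
            last = b.run_index
        for i, b in enumerate(self.blocks):
            if b.block_type in (BlockType.STANDARD, BlockType.SAMPLE):
                if i == 0 or self.blocks[i - 1].block_type is not BlockType.BLANK:
                    raise StructureError(
                        f"block {b.block_id} ({b.block_type.value}) lacks an "
                        "immediately preceding blank"
                    )
            if b.block_type is BlockType.SAMPLE:
                before = any(
                    x.block_type is BlockType.STANDARD for x in self.blocks[:i]
                )
                after = any(
                    x.block_type is BlockType.STANDARD for x in self.blocks[i + 1:]
                )
                if not (before and after):
                    raise StructureError(
                        f"sample block {b.block_id} is not bracketed by standards"
                    )


@dataclass
class RatioSummary:
    """Block-level ratio means, per-mille cycle spreads, and beam intensity."""

    r44_42: float
    r43_42: float
    r43p5_44: float
    two_sd_44_42: float  # 2·sd of per-cycle per-mille deviations from the block mean
    two_sd_43_42: float
    mean_intensity_44: float
    n_cycles: int
    block_id: str = ""


@dataclass
class QCCheck:
    passed: bool
    value: float


@dataclass
class QCReport:
    """Outcome of the four acceptance filters for one sample analysis."""

    interference: QCCheck
    intensity: QCCheck
    massbias_spread: QCCheck
    massdependence: QCCheck

    @property
    def overall_accept(self) -> bool:
        return (
            self.interference.passed
            and self.intensity.passed
            and self.massbias_spread.passed
            and self.massdependence.passed
        )

    def failed_checks(self) -> list[str]:
        return [
            name
            for name, chk in (
                ("interference", self.interference),
                ("intensity", self.intensity),
                ("massbias_spread", self.massbias_spread),
                ("massdependence", self.massdependence),
            )
            if not chk.passed
        ]


@dataclass
class DeltaMeasurement:
    """Reduced result for one sample analysis on a named reference scale."""

    block_id: str
    label: str
    delta44_42: float
    delta43_42: float
    scale: str
    internal_2se: float
    qc: QCReport

    @property
    def usable(self) -> bool:
        return self.qc.overall_accept

    def on_scale(self, to_scale: str, registry: ScaleRegistry = DEFAULT_REGISTRY) -> "DeltaMeasurement":
        from .scales import convert_scale

        return DeltaMeasurement(
            block_id=self.block_id,
            label=self.label,
            delta44_42=convert_scale(self.delta44_42, self.scale, to_scale, registry),
            delta43_42=convert_scale(self.delta43_42, self.scale, to_scale, registry),
            scale=registry.resolve(to_scale),
            internal_2se=self.internal_2se,
            qc=self.qc,
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def subtract_blank(block: IsotopeCycleBlock, blank: IsotopeCycleBlock) -> IsotopeCycleBlock:
    """Subtract the blank block's per-mass mean intensity from every cycle.

    Negative corrected intensities are retained (reduction stays linear) but
    flagged in the returned block's ``meta``.
    """
    if blank.block_type is not BlockType.BLANK:
        raise StructureError(f"block {blank.block_id} is not a blank block")
    if blank.run_index >= block.run_index:
        raise StructureError(
            f"blank {blank.block_id} does not precede block {block.block_id}"
        )
    corrected = {}
    negative = False
    for name in ("intensity_42", "intensity_43", "intensity_43p5", "intensity_44"):
        mean_blank = float(np.mean(getattr(blank, name)))
        arr = getattr(block, name) - mean_blank
        negative = negative or bool(np.any(arr < 0))
        corrected[name] = arr
    meta = dict(block.meta)
    meta["blank_corrected"] = True
    meta["blank_block_id"] = blank.block_id
    meta["negative_intensities"] = negative
    return IsotopeCycleBlock(
        block_id=block.block_id,
        block_type=block.block_type,
        run_index=block.run_index,
        label=block.label,
        meta=meta,
        **corrected,
    )


def summarize_ratios(block: IsotopeCycleBlock) -> RatioSummary:
    """Mean per-cycle ratios plus 2·sd per-mille cycle spreads for one block.

    Spreads are 2× the (population) standard deviation of the per-cycle
    per-mille deviations from the block-mean ratio.
    """
    i42, i43, i435, i44 = (
        block.intensity_42,
        block.intensity_43,
        block.intensity_43p5,
        block.intensity_44,
    )
    if np.mean(i42) <= 0 or np.mean(i44) <= 0:
        raise ReductionError(
            f"block {block.block_id}: nonpositive mean intensity at mass 42 or 44"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r44 = i44 / i42
        r43 = i43 / i42
        r435 = np.where(i44 != 0, i435 / i44, 0.0)
    if not (np.all(np.isfinite(r44)) and np.all(np.isfinite(r43))):
        raise ReductionError(f"block {block.block_id}: non-finite per-cycle ratio")

    def _spread(r: np.ndarray) -> float:
        m = float(np.mean(r))
        if m == 0:
            return 0.0
        dev_permil = (r / m - 1.0) * 1000.0
        return 2.0 * float(np.std(dev_permil))

    return RatioSummary(
        r44_42=float(np.mean(r44)),
        r43_42=float(np.mean(r43)),
        r43p5_44=float(np.mean(r435)),
        two_sd_44_42=_spread(r44),
        two_sd_43_42=_spread(r43),
        mean_intensity_44=float(np.mean(i44)),
        n_cycles=block.n_cycles,
        block_id=block.block_id,
    )


def check_interference(summary: RatioSummary, threshold: float = 1e-5) -> QCCheck:
    """Doubly-charged-Sr screen: fail iff the 43.5/44 ratio strictly exceeds the threshold."""
    value = summary.r43p5_44
    return QCCheck(passed=not value > threshold, value=value)


def delta_bracketed(
    sample: RatioSummary,
    std_before: RatioSummary,
    std_after: RatioSummary,
    which: str = "44_42",
    weight: float = 0.5,
) -> float:
    """Per-mille delta of a sample ratio against interpolated bracketing standards.

    ``weight`` is the interpolation fraction toward the *after* standard
    (0.5 → arithmetic mean, the default bracketing convention).
    """
    attr = {"44_42": "r44_42", "43_42": "r43_42"}.get(which)
    if attr is None:
        raise ReductionError(f"unknown ratio selector {which!r}")
    r_s = getattr(sample, attr)
    r_b = getattr(std_before, attr)
    r_a = getattr(std_after, attr)
    if min(r_s, r_b, r_a) <= 0:
        raise ReductionError("nonpositive ratio in bracketed delta")
    r_std = (1.0 - weight) * r_b + weight * r_a
    return (r_s / r_std - 1.0) * 1000.0


def mass_bias_factor(
    measured_ratio: float,
    reference_ratio: float,
    mass_pair: tuple[float, float],
) -> float:
    """Exponential-law mass-bias factor β = ln(R_ref/R_meas)/ln(m_num/m_den)."""
    if measured_ratio <= 0 or reference_ratio <= 0:
        raise ReductionError("nonpositive ratio in mass-bias factor")
    m_num, m_den = mass_pair
    if m_num == m_den:
        raise ReductionError("mass pair must contain distinct masses")
    return math.log(reference_ratio / measured_ratio) / math.log(m_num / m_den)


def mass_bias_factors(
    summary: RatioSummary,
    r44_42_ref: float = constants.R44_42_REFERENCE,
    r43_42_ref: float = constants.R43_42_REFERENCE,
) -> tuple[float, float, float]:
    """The three QC mass-bias factors, from the 43/42, 44/42 and 44/43 ratios."""
    b43_42 = mass_bias_factor(
        summary.r43_42, r43_42_ref, (constants.MASS_43, constants.MASS_42)
    )
    b44_42 = mass_bias_factor(
        summary.r44_42, r44_42_ref, (constants.MASS_44, constants.MASS_42)
    )
    if summary.r43_42 <= 0:
        raise ReductionError("nonpositive 43/42 ratio")
    b44_43 = mass_bias_factor(
        summary.r44_42 / summary.r43_42,
        r44_42_ref / r43_42_ref,
        (constants.MASS_44, constants.MASS_43),
    )
    return (b43_42, b44_42, b44_43)


def qc_mass_bias_spread(betas, threshold: float = 0.1) -> QCCheck:
    """Fail iff 2× the sample standard deviation of the three factors exceeds the threshold."""
    b = np.asarray(betas, dtype=float)
    if b.size != 3:
        raise ReductionError(f"expected exactly three mass-bias factors, got {b.size}")
    stat = 2.0 * float(np.std(b, ddof=1))
    return QCCheck(passed=not stat > threshold, value=stat)


def qc_mass_dependence(
    delta44_42: float,
    delta43_42: float,
    coef: float = constants.MASS_DEPENDENCE_COEF,
    threshold: float = 0.1,
) -> QCCheck:
    """Fail iff |coef·δ⁴⁴/⁴² − δ⁴³/⁴²| exceeds the threshold (per mille).

    A ⁴³Ca excess that does not scale with mass (e.g. an unscreened
    interference or spike) breaks the exponential-law proportionality between
    the two delta values and trips this filter.
    """
    stat = abs(coef * delta44_42 - delta43_42)
    return QCCheck(passed=not stat > threshold, value=stat)


def qc_mass_dependence_cycle(
    delta44_cycles: np.ndarray,
    delta43_cycles: np.ndarray,
    coef: float = constants.MASS_DEPENDENCE_COEF,
    threshold: float = 0.1,
) -> QCCheck:
    """Cycle-level variant: 2·sd of the per-cycle paired values coef·δ44 − δ43."""
    d = coef * np.asarray(delta44_cycles, float) - np.asarray(delta43_cycles, float)
    if d.size < 2:
        raise ReductionError("cycle-level mass-dependence needs ≥2 cycles")
    stat = 2.0 * float(np.std(d, ddof=1))
    return QCCheck(passed=not stat > threshold, value=stat)


def qc_intensity_match(
    sample_mean_i44: float, bracketing_std_mean_i44: float, threshold: float = 0.10
) -> QCCheck:
    """Fail iff the sample ⁴⁴Ca beam deviates from the standard beam by > threshold."""
    if sample_mean_i44 <= 0 or bracketing_std_mean_i44 <= 0:
        raise ReductionError("nonpositive mean intensity in intensity-match check")
    dev = abs(sample_mean_i44 / bracketing_std_mean_i44 - 1.0)
    return QCCheck(passed=not dev > threshold, value=dev)


# ---------------------------------------------------------------------------
# session orchestration
# ---------------------------------------------------------------------------

def _trim_block(block: IsotopeCycleBlock, n_sd: float) -> IsotopeCycleBlock:
    """Drop cycles whose 44/42 ratio deviates more than n_sd sd from the block mean."""
    r = block.intensity_44 / block.intensity_42
    sd = np.std(r, ddof=1) if r.size > 1 else 0.0
    if sd == 0:
        return block
    keep = np.abs(r - np.mean(r)) <= n_sd * sd
    if keep.sum() < 2 or keep.all():
        return block
    meta = dict(block.meta)
    meta["cycles_trimmed"] = int((~keep).sum())
    return IsotopeCycleBlock(
        block_id=block.block_id,
        block_type=block.block_type,
        run_index=block.run_index,
        intensity_42=block.intensity_42[keep],
        intensity_43=block.intensity_43[keep],
        intensity_43p5=block.intensity_43p5[keep],
        intensity_44=block.intensity_44[keep],
        label=block.label,
        meta=meta,
    )


def _internal_2se(
    sample: IsotopeCycleBlock, r_std_44: float, r_std_43: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Per-cycle bracketed deltas and the 2·se of the 44/42 delta."""
    d44 = (sample.intensity_44 / sample.intensity_42 / r_std_44 - 1.0) * 1000.0
    d43 = (sample.intensity_43 / sample.intensity_42 / r_std_43 - 1.0) * 1000.0
    n = d44.size
    se = 2.0 * float(np.std(d44, ddof=1)) / math.sqrt(n) if n > 1 else 0.0
    return se, d44, d43


def reduce_session(
    session: AnalysisSession, config: ReductionConfig | None = None
) -> list[DeltaMeasurement]:
    """Reduce every sample block of a session to a flagged delta measurement.

    For each sample: blank-correct the sample and its bracketing standards
    with the nearest preceding blank, summarise ratios, compute both bracketed
    deltas on the in-house (bracketing-standard) scale, evaluate all four QC
    filters, and emit a :class:`DeltaMeasurement` carrying a full
    :class:`QCReport`.  Rejected analyses are emitted flagged, never dropped.
    """
    cfg = config or ReductionConfig()
    cfg.validate()
    session.validate()
    blocks = session.blocks

    # nearest preceding blank for every standard/sample
    corrected: dict[int, IsotopeCycleBlock] = {}
    last_blank: IsotopeCycleBlock | None = None
    for i, b in enumerate(blocks):
        if b.block_type is BlockType.BLANK:
            last_blank = b
        else:
            if last_blank is None:
                raise StructureError(f"block {b.block_id} has no preceding blank")
            cb = subtract_blank(b, last_blank)
            if cfg.trim_cycles:
                cb = _trim_block(cb, cfg.trim_sd)
            corrected[i] = cb

    summaries = {i: summarize_ratios(cb) for i, cb in corrected.items()}

    results: list[DeltaMeasurement] = []
    for i, b in enumerate(blocks):
        if b.block_type is not BlockType.SAMPLE:
            continue
        i_before = max(
            (j for j in corrected if j < i and blocks[j].block_type is BlockType.STANDARD),
            default=None,
        )
        i_after = min(
            (j for j in corrected if j > i and blocks[j].block_type is BlockType.STANDARD),
            default=None,
        )
        if i_before is None or i_after is None:
            raise StructureError(f"sample block {b.block_id} is not bracketed by standards")
        s_sample = summaries[i]
        s_before = summaries[i_before]
        s_after = summaries[i_after]

        if cfg.bracketing == "linear":
            ri_b = blocks[i_before].run_index
            ri_a = blocks[i_after].run_index
            weight = (b.run_index - ri_b) / (ri_a - ri_b) if ri_a != ri_b else 0.5
        else:
            weight = 0.5

        d44 = delta_bracketed(s_sample, s_before, s_after, "44_42", weight)
        d43 = delta_bracketed(s_sample, s_before, s_after, "43_42", weight)

        r_std_44 = (1 - weight) * s_before.r44_42 + weight * s_after.r44_42
        r_std_43 = (1 - weight) * s_before.r43_42 + weight * s_after.r43_42
        se2, d44_cyc, d43_cyc = _internal_2se(corrected[i], r_std_44, r_std_43)

        betas = mass_bias_factors(s_sample, cfg.r44_42_reference, cfg.r43_42_reference)
        std_i44 = 0.5 * (s_before.mean_intensity_44 + s_after.mean_intensity_44)

        if cfg.massdep_mode == "cycle":
            massdep = qc_mass_dependence_cycle(
                d44_cyc, d43_cyc, cfg.massdep_coef, cfg.massdep_threshold
            )
        else:
            massdep = qc_mass_dependence(d44, d43, cfg.massdep_coef, cfg.massdep_threshold)

        qc = QCReport(
            interference=check_interference(s_sample, cfg.interference_threshold),
            intensity=qc_intensity_match(
                s_sample.mean_intensity_44, std_i44, cfg.intensity_threshold
            ),
            massbias_spread=qc_mass_bias_spread(betas, cfg.massbias_spread_threshold),
            massdependence=massdep,
        )
        results.append(
            DeltaMeasurement(
                block_id=b.block_id,
                label=b.label,
                delta44_42=d44,
                delta43_42=d43,
                scale=session.standard_scale,
                internal_2se=se2,
                qc=qc,
            )
        )
    return results


# ---------------------------------------------------------------------------
# concentration quantification (quadrupole ICP-MS)
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationCalibration:
    """OLS calibration line through drift-normalised counts vs concentration.

    Analyte counts are divided by the ratio of each point's internal-standard
    (⁴⁵Sc) counts to the session-mean internal-standard counts before fitting,
    which removes slow instrumental drift.
    """

    concentrations: np.ndarray  # ng/g
    analyte_counts: np.ndarray
    istd_counts: np.ndarray
    range_low: float = 0.5
    range_high: float = 250.0

    slope: float = field(init=False)
    intercept: float = field(init=False)
    istd_session_mean: float = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, float)
        a = np.asarray(self.analyte_counts, float)
        s = np.asarray(self.istd_counts, float)
        if c.size < 2 or a.size != c.size or s.size != c.size:
            raise CalibrationError("need ≥2 calibration points with matching counts")
        if np.any(s <= 0):
            raise CalibrationError("internal-standard counts must be positive")
        if np.allclose(c, c[0]):
            raise CalibrationError("identical calibration concentrations (singular fit)")
        self.istd_session_mean = float(np.mean(s))
        norm = a / (s / self.istd_session_mean)
        # OLS line: counts = slope·conc + intercept
        slope, intercept = np.polyfit(c, norm, 1)
        if slope == 0:
            raise CalibrationError("zero calibration slope")
        self.slope = float(slope)
        self.intercept = float(intercept)


@dataclass
class ConcentrationResult:
    value_ng_g: float
    in_range: bool


def quantify_concentration(
    analyte_counts: float, istd_counts: float, calib: ConcentrationCalibration
) -> ConcentrationResult:
    """Map drift-normalised unknown counts through the calibration line.

    Values outside the calibrated envelope (0.5–250 ng/g by default) are
    returned with the out-of-range flag set, never clamped.
    """
    if istd_counts <= 0:
        raise CalibrationError("internal-standard counts must be positive")
    norm = analyte_counts / (istd_counts / calib.istd_session_mean)
    value = (norm - calib.intercept) / calib.slope
    in_range = calib.range_low <= value <= calib.range_high
    return ConcentrationResult(value_ng_g=float(value), in_range=in_range)
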