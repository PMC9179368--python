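"""Spectrum quality gate and cohort exclusion bookkeeping.

A spectrum enters the analysis only if the amplitudes of four reference
metabolites exceed predefined arbitrary-unit thresholds: choline > 0.2,
creatine > 0.1, myo-inositol > 0 and the second creatine resonance > 0.
Amplitude here means baseline-corrected peak maximum in a fixed ppm
window; since the thresholds are in vendor arbitrary units, QC always
runs on raw, pre-normalization intensities and the thresholds are fully
configurable for other cohorts.

Cohort-level exclusions (no tumor diagnosed, IDH status undeterminable)
are applied before the QC gate, and every removal is tallied in an
exclusion ledger so that retained + excluded always equals the input
size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra_io import Cohort, Spectrum

#: ppm positions at which QC amplitudes are estimated.
QC_POSITIONS = {"cho": 3.22, "cr": 3.03, "mins": 3.53, "cr2": 3.93}

EXCLUSION_REASONS = ("no_tumor", "idh_undetermined", "qc_fail")


class WindowOutOfRangeError(ValueError):
    """The requested ppm window does not overlap the spectrum's axis."""


class UnknownExclusionReasonError(ValueError):
    pass


@dataclass(frozen=True)
class QcThresholds:
    """Minimum metabolite amplitudes (arbitrary units) for inclusion."""

    cho_min: float = 0.2
    cr_min: float = 0.1
    mins_min: float = 0.0
    cr2_min: float = 0.0
    strict_inequality: bool = True

    def as_dict(self) -> dict:
        return {
            "cho": self.cho_min,
            "cr": self.cr_min,
            "mins": self.mins_min,
            "cr2": self.cr2_min,
        }


@dataclass
class QcResult:
    amplitudes: dict
    passed: bool
    failed_criteria: list = field(default_factory=list)


def estimate_amplitude(
    spectrum: Spectrum,
    position: float,
    window_halfwidth: float = 0.08,
    flank_width: float = 0.08,
) -> float:
    """Baseline-corrected peak amplitude near ``position`` (ppm).

    The amplitude is the maximum intensity inside
    ``[position - hw, position + hw]`` minus a local baseline estimate:
    the median intensity over two flanking bands of width ``flank_width``
    directly adjacent to the window.  This makes the estimate invariant
    under additive offsets and equivariant under positive scaling.
    """
    axis = spectrum.axis.values
    hw = window_halfwidth
    in_window = (axis >= position - hw) & (axis <= position + hw)
    if not np.any(in_window):
        raise WindowOutOfRangeError(
            f"window {position}±{hw} ppm lies outside the axis "
            f"[{axis[-1]:.3f}, {axis[0]:.3f}] ppm"
        )
    peak = float(np.max(spectrum.intensities[in_window]))
    lo, hi = position - hw, position + hw
    in_flank = ((axis >= lo - flank_width) & (axis < lo)) | (
        (axis > hi) & (axis <= hi + flank_width)
    )
    baseline = float(np.median(spectrum.intensities[in_flank])) if np.any(in_flank) else 0.0
    return peak - baseline


def qc_spectrum(
    spectrum: Spectrum,
    thresholds: QcThresholds = QcThresholds(),
    window_halfwidth: float = 0.08,
    flank_width: float = 0.08,
) -> QcResult:
    """Apply the metabolite-amplitude quality gate to one spectrum."""
    amplitudes = {
        name: estimate_amplitude(spectrum, pos, window_halfwidth, flank_width)
        for name, pos in QC_POSITIONS.items()
    }
    failed = []
    for name, minimum in thresholds.as_dict().items():
        amp = amplitudes[name]
        ok = amp > minimum if thresholds.strict_inequality else amp >= minimum
        if not ok:
            failed.append(name)
    return QcResult(amplitudes=amplitudes, passed=not failed, failed_criteria=failed)


def apply_exclusions(
    cohort: Cohort,
    thresholds: QcThresholds = QcThresholds(),
    predefined_exclusions: dict | None = None,
    window_halfwidth: float = 0.08,
    flank_width: float = 0.08,
) -> tuple:
    """Remove predefined exclusions, then QC failures; tally both.

    Predefined exclusions (id → reason) are applied first, so a spectrum
    that is both predefined-excluded and QC-failing is counted once,
    under its predefined reason.  Returns ``(retained_cohort, ledger)``
    where the ledger maps reason → count and the retained cohort
    preserves the input order and carries the ledger.
    """
    predefined = dict(predefined_exclusions or {})
    for spec_id, reason in predefined.items():
        if reason not in EXCLUSION_REASONS:
            raise UnknownExclusionReasonError(
                f"unknown exclusion reason {reason!r} for id {spec_id!r}; "
                f"valid reasons: {EXCLUSION_REASONS}"
            )
    ledger: dict = {}
    retained = []
    for spec in cohort:
        if spec.id in predefined:
            reason = predefined[spec.id]
            ledger[reason] = ledger.get(reason, 0) + 1
            spec.flags.add(f"excluded:{reason}")
            continue
        result = qc_spectrum(spec, thresholds, window_halfwidth, flank_width)
        if not result.passed:
            ledger["qc_fail"] = ledger.get("qc_fail", 0) + 1
            spec.flags.add("excluded:qc_fail")
            continue
        retained.append(spec)
    out = Cohort(spectra=retained, name=cohort.name, exclusion_ledger=ledger)
    assert len(out) + sum(ledger.values()) == len(cohort)
    return out, ledger
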