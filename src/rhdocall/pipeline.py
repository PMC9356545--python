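"""End-to-end per-family inference and cohort evaluation.

``run_family`` chains the stages: Mendelian screen, informative-SNP
classification, fetal-fraction estimation, proband-anchored phasing, expected
profiles and the Spearman call — once per parent — and returns everything a
report needs. ``evaluate_cohort`` tallies a simulated cohort into the outcome
categories used for method validation (gate exclusions, wrong calls, correct
calls) and the positive prediction rate over called families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import EstimationError, PhasingError, QCError, ValidationError
from .fetal_fraction import DEFAULT_FF_THRESHOLD, estimate_ff, ff_gate
from .informative import classify
from .inference import DEFAULT_MARGIN, call_haplotype, expected_profiles
from .io import join_trio_counts
from .mendel import DEFAULT_MAX_MENDEL_FRACTION, mendelian_check
from .phasing import DEFAULT_MIN_INFORMATIVE, informative_gate, phase_parent
from .simulate import SimTruth
from .types import (
    AlleleCounts,
    Call,
    CallResult,
    FFEstimate,
    MendelianReport,
    Parent,
    PhasedParent,
    QcFlag,
    TrioGenotypes,
)


@dataclass
class RunConfig:
    """Thresholds of the gated pipeline (defaults as validated)."""

    ff_threshold: float = DEFAULT_FF_THRESHOLD
    min_informative: int = DEFAULT_MIN_INFORMATIVE  # require strictly more than this
    margin: float = DEFAULT_MARGIN
    max_mendel_fraction: float = DEFAULT_MAX_MENDEL_FRACTION


@dataclass
class FamilyResult:
    mendel: Optional[MendelianReport]
    ff: Optional[FFEstimate]
    calls: dict  # Parent -> CallResult
    phased: dict = field(default_factory=dict)  # Parent -> PhasedParent

    @property
    def results(self) -> list[CallResult]:
        return [self.calls[Parent.PATERNAL], self.calls[Parent.MATERNAL]]


def _no_call(parent: Parent, flags: set[QcFlag], ff: Optional[float]) -> CallResult:
    return CallResult(
        parent=parent, call=Call.NO_CALL, rho_h0=None, rho_h1=None,
        n_informative=0, ff_used=ff, qc_flags=set(flags),
    )


def run_family(
    trio: Sequence[TrioGenotypes],
    counts: Sequence[AlleleCounts],
    config: RunConfig = RunConfig(),
    phased_override: Optional[dict] = None,
) -> FamilyResult:
    """Run the full inference chain for one family.

    ``phased_override`` (Parent -> PhasedParent) supplies pre-phased parental
    haplotypes for families without a proband; phasing is then skipped for the
    parents it covers.
    """
    phased_override = phased_override or {}
    counts_by_key = {c.site.key: c for c in counts}
    classes = classify(trio, counts)

    # Family-level QC: Mendelian/paternity screen (requires a proband).
    mendel: Optional[MendelianReport] = None
    have_proband = any(g.complete for g in trio)
    if have_proband:
        mendel = mendelian_check(trio, config.max_mendel_fraction)
        if not mendel.passed:
            flags = {QcFlag.MENDELIAN_FAIL}
            return FamilyResult(
                mendel=mendel,
                ff=None,
                calls={p: _no_call(p, flags, None) for p in Parent},
            )
    elif not phased_override:
        raise QCError(
            "no proband genotypes and no pre-phased haplotypes: cannot infer"
        )

    try:
        ff_est = estimate_ff(classes)
        ff_ok = ff_gate(ff_est, config.ff_threshold)
        ff_value: Optional[float] = ff_est.ff
    except EstimationError:
        ff_est, ff_ok, ff_value = None, False, None

    calls: dict = {}
    phased_map: dict = {}
    for parent in Parent:
        phased: Optional[PhasedParent]
        if parent in phased_override:
            phased = phased_override[parent]
        else:
            try:
                phased = phase_parent(classes, parent)
            except PhasingError:
                phased = None
        if phased is None:
            calls[parent] = _no_call(parent, {QcFlag.FEW_SNPS}, ff_value)
            continue
        phased_map[parent] = phased
        profiles = None
        n_effective = 0
        if ff_ok and ff_value is not None:
            try:
                profiles = expected_profiles(phased, counts_by_key, ff_value)
                n_effective = profiles.n_sites
            except ValidationError:
                profiles = None
        else:
            n_effective = sum(
                1
                for s in phased.sites
                if s.key in counts_by_key and counts_by_key[s.key].depth > 0
            )
        n_ok = n_effective > config.min_informative
        calls[parent] = call_haplotype(
            profiles,
            ff_ok=ff_ok,
            n_ok=n_ok,
            margin=config.margin,
            parent=parent,
            ff_used=ff_value,
            n_informative=n_effective,
        )
    return FamilyResult(mendel=mendel, ff=ff_est, calls=calls, phased=phased_map)


@dataclass
class CohortMetrics:
    """Outcome tally for one parent over a cohort, plus the prediction rate."""

    parent: Parent
    n_recruited: int
    n_low_ff: int
    n_few_snps: int
    n_no_call_other: int  # ties / degenerate profiles / Mendelian exclusions
    n_fail: int
    n_success: int

    @property
    def n_called(self) -> int:
        return self.n_fail + self.n_success

    @property
    def positive_prediction_rate(self) -> Optional[float]:
        """Correct calls over called families, as a fraction; None if none called."""
        return self.n_success / self.n_called if self.n_called else None

    def to_dict(self) -> dict:
        rate = self.positive_prediction_rate
        return {
            "parent": self.parent.value,
            "n_recruited": self.n_recruited,
            "n_low_ff": self.n_low_ff,
            "n_few_snps": self.n_few_snps,
            "n_no_call_other": self.n_no_call_other,
            "n_fail": self.n_fail,
            "n_success": self.n_success,
            "positive_prediction_rate_pct": None if rate is None else 100.0 * rate,
        }


def tally_outcomes(
    outcomes: Sequence[tuple],  # (CallResult, truth "H0"/"H1")
    parent: Parent,
) -> CohortMetrics:
    """Count outcome categories from (call, truth) pairs for one parent."""
    n_low_ff = n_few = n_other = n_fail = n_success = 0
    for call_result, truth in outcomes:
        if call_result.call is Call.NO_CALL:
            if QcFlag.LOW_FF in call_result.qc_flags:
                n_low_ff += 1
            elif QcFlag.FEW_SNPS in call_result.qc_flags:
                n_few += 1
            else:
                n_other += 1
        elif call_result.call.value == truth:
            n_success += 1
        else:
            n_fail += 1
    return CohortMetrics(
        parent=parent,
        n_recruited=len(outcomes),
        n_low_ff=n_low_ff,
        n_few_snps=n_few,
        n_no_call_other=n_other,
        n_fail=n_fail,
        n_success=n_success,
    )


def evaluate_cohort(
    cohort: Sequence[SimTruth],
    config: RunConfig = RunConfig(),
) -> dict:
    """Run the pipeline on every simulated family and tally per-parent outcomes.

    Returns Parent -> CohortMetrics.
    """
    if not cohort:
        raise ValidationError("cohort is empty")
    outcomes = {p: [] for p in Parent}
    for truth in cohort:
        result = run_family(truth.trio, truth.plasma, config)
        for parent in Parent:
            outcomes[parent].append((result.calls[parent], truth.transmitted[parent]))
    return {p: tally_outcomes(outcomes[p], p) for p in Parent}
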