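"""End-to-end quantification chains.

The study workflow is: calibrate size-dependent consensus thresholds on a
sphere phantom (once, across all software variants), then for every patient
and every variant pick the size-appropriate threshold, delineate the lesion
and extract SUVmax/SUVmean/MTV/TLG, and finally compare the variants'
measurements statistically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .calibration import ThresholdSelection, ThresholdTable, build_threshold_table, threshold_for_size
from .delineation import LesionMetrics, compute_lesion_metrics, segment_fixed_threshold
from .image import VolumetricImage, region_to_mask
from .phantom import Cohort, CohortSpec, PhantomSpec, generate_nema_phantom, generate_patient_cohort
from .stats import ComparisonReport, build_comparison_report
from .suv import SubjectInfo
from .variants import VariantConvention, apply_calibration, smoothed_reference_max

__all__ = [
    "calibrate_thresholds",
    "quantify_lesion",
    "quantify_cohort",
    "WorkflowResult",
    "run_workflow",
]

_FULL_GRID = (slice(None), slice(None), slice(None))


def calibrate_thresholds(spec: PhantomSpec,
                         variants: Sequence[VariantConvention]) -> ThresholdTable:
    """Simulate one phantom acquisition and calibrate all variants on it."""
    image, _ = generate_nema_phantom(spec)
    regions = [spec.search_region(i) for i in range(len(spec.sphere_diameters_mm))]
    return build_threshold_table(
        {v.name: image for v in variants},
        regions,
        spec.sphere_volumes_cm3(),
        conventions={v.name: v for v in variants},
    )


def quantify_lesion(image: VolumetricImage, subject: SubjectInfo,
                    table: ThresholdTable, convention: VariantConvention,
                    search_region=None) -> tuple[LesionMetrics, ThresholdSelection]:
    """Measure one lesion the way one software variant would.

    The variant's calibration offset is applied to the volume, the
    size-appropriate consensus threshold is selected by fixed-point
    iteration, snapped to the variant's threshold grid, and the delineated
    VOI is summarised into metrics.
    """
    region = _FULL_GRID if search_region is None else search_region
    read = apply_calibration(image, convention)
    selection = threshold_for_size(table, read, region, convention=convention)
    th = convention.snap_threshold(selection.threshold_percent)
    ref = smoothed_reference_max(read, region_to_mask(region, read.shape), convention)
    mask = segment_fixed_threshold(read, region, th, reference_max=ref)
    metrics = compute_lesion_metrics(read, mask, subject, convention)
    return metrics, selection


def quantify_cohort(cohort: Cohort, table: ThresholdTable,
                    ) -> dict[str, list[LesionMetrics]]:
    """Measure every cohort lesion with every variant's conventions."""
    out: dict[str, list[LesionMetrics]] = {v.name: [] for v in cohort.variants}
    for record in cohort.records:
        for variant in cohort.variants:
            metrics, _ = quantify_lesion(record.image, record.subject, table, variant)
            out[variant.name].append(metrics)
    return out


@dataclass
class WorkflowResult:
    threshold_table: ThresholdTable
    cohort: Cohort
    per_variant_metrics: dict[str, list[LesionMetrics]]
    report: ComparisonReport


def run_workflow(phantom_spec: PhantomSpec, cohort_spec: CohortSpec,
                 alpha: float = 0.05, holm: bool = False,
                 population_sd: bool = False) -> WorkflowResult:
    """Full chain: phantom → calibration → cohort → quantification → report."""
    table = calibrate_thresholds(phantom_spec, cohort_spec.variants)
    cohort = generate_patient_cohort(cohort_spec)
    metrics = quantify_cohort(cohort, table)
    report = build_comparison_report(metrics, alpha=alpha, holm=holm,
                                     population_sd=population_sd)
    return WorkflowResult(table, cohort, metrics, report)
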