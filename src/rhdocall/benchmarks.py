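"""Reference simulated cohorts for method validation.

Clinical NIPT cohorts are not distributable, so method performance is
characterised on simulated cohorts at the fetal-fraction regimes the two
enrichment chemistries produce in practice: multiplex-PCR amplification
(lower FF — short fetal templates are preferentially lost — with ~15
parent-informative SNPs at high per-site depth) and hybrid capture (higher
FF, more informative SNPs, lower per-site depth). Each benchmark runs the
full gated pipeline and reports the positive prediction rate over called
families.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pipeline import RunConfig, evaluate_cohort
from .simulate import FFDistribution, SimConfig, simulate_cohort
from .types import Parent


@dataclass(frozen=True)
class CohortSpec:
    name: str
    parent: Parent
    n_families: int
    ff: FFDistribution
    n_parent_snps: int
    n_ff_snps: int
    depth: float


# Multiplex-PCR-like maternal benchmark: FF around 7.3% (sd 0.03, floor 0.5%),
# 15 maternal-informative SNPs at depth 5000, 20 FF-informative SNPs.
MULTIPLEX_MATERNAL = CohortSpec(
    name="multiplex_maternal",
    parent=Parent.MATERNAL,
    n_families=300,
    ff=FFDistribution(mean=0.073, sd=0.03, truncation=0.005),
    n_parent_snps=15,
    n_ff_snps=20,
    depth=5000.0,
)

# Hybrid-capture-like maternal benchmark: FF around 11.6% (sd 0.06, floor 3%),
# 40 maternal-informative SNPs at depth 400; capture yields fewer FF sites.
CAPTURE_MATERNAL = CohortSpec(
    name="capture_maternal",
    parent=Parent.MATERNAL,
    n_families=300,
    ff=FFDistribution(mean=0.1156, sd=0.06, truncation=0.03),
    n_parent_snps=40,
    n_ff_snps=10,
    depth=400.0,
)

# Paternal benchmark: intermediate FF regime, 15 paternal-informative SNPs.
PATERNAL = CohortSpec(
    name="paternal",
    parent=Parent.PATERNAL,
    n_families=200,
    ff=FFDistribution(mean=0.09, sd=0.03, truncation=0.03),
    n_parent_snps=15,
    n_ff_snps=20,
    depth=5000.0,
)


def run_benchmark(spec: CohortSpec, master_seed: int, config: RunConfig = RunConfig()) -> dict:
    """Simulate the cohort, run the pipeline, and return the tally for the
    benchmark's parent as a plain dict (including the rate in percent)."""
    template = SimConfig(
        depth=spec.depth,
        depth_model="poisson",
        n_ff_snps=spec.n_ff_snps,
        n_paternal_snps=spec.n_parent_snps if spec.parent is Parent.PATERNAL else 0,
        n_maternal_snps=spec.n_parent_snps if spec.parent is Parent.MATERNAL else 0,
    )
    cohort = simulate_cohort(spec.n_families, template, spec.ff, master_seed=master_seed)
    metrics = evaluate_cohort(cohort, config)[spec.parent]
    return metrics.to_dict()
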