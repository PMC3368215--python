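"""High-level orchestration: prescan -> Min-Sum -> calls -> metrics.

The functions here are the programmatic equivalent of the command-line
subcommands: one call runs the whole phasing stack on a genotype matrix,
another scores a result against simulator truth.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from .evaluation import (
    MetricsReport,
    ibd_metrics,
    imputation_metrics,
    phasing_yield,
    switch_error,
)
from .io import GeneticMap, GenotypeMatrix
from .model_core import ModelParams
from .phaser import (
    IBDSegmentCall,
    PhaseResult,
    build_graph,
    call_phase,
    extract_ibd_calls,
    impute,
    min_sum,
)
from .prescan import PlausibleSegment, precompute_tables, scan_all_pairs
from .simulator import SimulatedCohort, all_true_ibd

logger = logging.getLogger("ibdphase")


@dataclass
class PhasingRun:
    """Everything one phasing run produces."""

    phase: PhaseResult
    ibd_calls: list[IBDSegmentCall]
    segments: list[PlausibleSegment]
    converged: bool
    n_iters: int
    seconds: float


def run_phasing(
    geno: GenotypeMatrix, gmap: GeneticMap, params: ModelParams | None = None
) -> PhasingRun:
    """Prescan all pairs, run Min-Sum over the plausible segments, and
    emit phase calls, imputed alleles and IBD segment calls."""
    params = params or ModelParams()
    t0 = time.time()
    tables = precompute_tables(gmap, geno.freqs, params)
    segments = scan_all_pairs(geno, gmap, params)
    graph = build_graph(geno, segments, gmap, params, tables=tables)
    result = min_sum(graph, params)
    phase = call_phase(result, geno, params)
    phase = impute(result, geno, params, phase)
    calls = extract_ibd_calls(result, gmap, phase=phase)
    dt = time.time() - t0
    logger.info(
        "phased %d individuals x %d markers: %d segments, %d IBD calls, "
        "%d iterations (%s) in %.1fs",
        geno.n_individuals, geno.n_markers, len(segments), len(calls),
        result.n_iters, "converged" if result.converged else "NOT converged", dt,
    )
    return PhasingRun(
        phase=phase,
        ibd_calls=calls,
        segments=segments,
        converged=result.converged,
        n_iters=result.n_iters,
        seconds=dt,
    )


def evaluate_run(
    run: PhasingRun,
    cohort: SimulatedCohort,
    geno: GenotypeMatrix | None = None,
    mask: np.ndarray | None = None,
    min_truth_length_cm: float = 1.0,
) -> MetricsReport:
    """Score a phasing run against simulator truth.

    ``geno`` is the matrix that was actually phased (possibly degraded);
    ``mask`` marks genotypes hidden before phasing, enabling the
    imputation metrics.
    """
    geno = geno if geno is not None else cohort.genotypes
    rep = MetricsReport()
    rate, within, _ = switch_error(cohort.truth_haps, run.phase, geno, cohort.gmap)
    rep.switch_errors_per_morgan = rate
    rep.within_segment_errors_per_morgan = within
    rep.yield_fraction = phasing_yield(run.phase, geno)
    truth = all_true_ibd(cohort.mosaics, cohort.gmap)
    ibd = ibd_metrics(run.ibd_calls, truth, cohort.gmap, min_truth_length_cm)
    rep.ibd_sensitivity = ibd["sensitivity"]
    rep.ibd_fdr = ibd["fdr"]
    rep.ibd_sensitivity_resolved = ibd["sensitivity_resolved"]
    rep.ibd_fdr_resolved = ibd["fdr_resolved"]
    if mask is not None:
        err, ay = imputation_metrics(cohort.genotypes.dosages, run.phase, mask)
        rep.imputation_error = err
        rep.allele_yield = ay
    return rep
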