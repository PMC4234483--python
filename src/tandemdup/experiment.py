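"""Simulate -> map -> call -> evaluate, as one reproducible experiment.

This is the harness behind the benchmark sweeps: a synthetic reference is
generated, duplications spiked in, reads laid out and surrogate-mapped, the
caller run with its defaults, and the call set scored against the truth at
50% mutual overlap.  Everything derives from ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np

from .evaluate import EvaluationReport, match_and_score
from .pipeline import CallerConfig, CallResult, call_duplications
from .simulate import (
    SimulationConfig,
    SimulationTruth,
    make_reference,
    oracle_map,
    simulate_read_layout,
    spike_duplications,
)


@dataclass
class ExperimentResult:
    config: SimulationConfig
    truth: SimulationTruth
    call_result: CallResult
    report: EvaluationReport

    @property
    def mean_support(self) -> float:
        """Mean everted pairs per *matched* call — tracks effective coverage."""
        matched_calls = {c for _, c in self.report.matched_pairs}
        supports = [
            c.support
            for c in self.call_result.calls
            if (c.start, c.end) in matched_calls
        ]
        return float(np.mean(supports)) if supports else float("nan")


def run_experiment(
    cfg: SimulationConfig,
    caller: Optional[CallerConfig] = None,
) -> ExperimentResult:
    if caller is None:
        caller = CallerConfig(seed=cfg.seed)
    reference = make_reference(cfg.reference_length, gc=cfg.gc, seed=cfg.seed)
    donor, truth = spike_duplications(reference, cfg)
    layout = simulate_read_layout(truth.donor_length, cfg)
    truth.reads = layout
    pair_set = oracle_map(
        layout, truth.donor_map, contig=cfg.contig,
        max_mismatches=cfg.max_mismatches, seed=cfg.seed,
    )
    call_result = call_duplications(pair_set, caller)
    report = match_and_score(
        truth.intervals, [(c.start, c.end) for c in call_result.calls]
    )
    return ExperimentResult(cfg, truth, call_result, report)


def sweep(
    base: SimulationConfig,
    seeds: List[int],
    caller: Optional[CallerConfig] = None,
    **overrides,
) -> List[ExperimentResult]:
    """Run one experiment per seed with field overrides applied to ``base``."""
    results = []
    for seed in seeds:
        cfg = replace(base, seed=seed, **overrides)
        results.append(run_experiment(cfg, caller))
    return results


def mean_metric(results: List[ExperimentResult], name: str) -> float:
    values = [getattr(r.report, name) for r in results]
    return float(np.nanmean(values))
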