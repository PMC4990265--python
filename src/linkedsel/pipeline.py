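"""High-level convenience pipeline: simulate -> lookups -> fit -> evaluate.

Used by the worked examples and the reproduction script; each step is the
corresponding library call, bundled for one-call runs on synthetic data.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

from linkedsel.evaluation_maps import (
    DiversityMap,
    collate,
    mode_contributions,
    predict_map,
    stratify,
    window_r2,
)
from linkedsel.inference import FitResult, OptConfig, fit
from linkedsel.selection_effects import (
    BSLookup,
    EffectiveSizeContext,
    SweepLookup,
    build_bs_lookup,
    build_sweep_lookup,
)
from linkedsel.synthetic_data import (
    GroundTruth,
    SyntheticConfig,
    make_genome,
    simulate_polymorphism,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: SyntheticConfig
    genome: object
    table: object
    truth: GroundTruth
    k_bar: float
    bs_lookup: BSLookup
    sweep_lookup: SweepLookup
    fit_result: FitResult
    dmap: DiversityMap


def run_synthetic_pipeline(config: SyntheticConfig, *, variant: str = "both",
                           opt_config: OptConfig | None = None,
                           lookup_method: str = "auto") -> PipelineResult:
    """Simulate a data set from ``config`` and fit the selected model variant.

    The fit uses the estimated (not true) mutation-rate proxy and lineage
    depth, exactly as a real-data analysis would.
    """
    t0 = time.time()
    genome = make_genome(config)
    table, truth, proxy = simulate_polymorphism(genome, method=lookup_method)
    logger.info("simulated %d sites in %.1fs", len(table), time.time() - t0)
    grid = config.grid()
    ctx = EffectiveSizeContext(Ne=config.Ne)
    t0 = time.time()
    bs_lk = build_bs_lookup(table, genome.annotations, grid, genome.gmap,
                            method=lookup_method)
    sw_lk = build_sweep_lookup(table, genome.substitutions, grid, genome.gmap,
                               ctx, method=lookup_method)
    logger.info("lookups (%s/%s) in %.1fs", bs_lk.method, sw_lk.method,
                time.time() - t0)
    t0 = time.time()
    res = fit(table, bs_lk, sw_lk, proxy.k_bar, variant=variant,
              opt_config=opt_config)
    logger.info("fit in %.1fs: logCL=%.1f", time.time() - t0, res.logCL)
    dmap = predict_map(res.params, bs_lk, sw_lk, table, genome.gmap,
                       proxy.k_bar)
    return PipelineResult(config=config, genome=genome, table=table,
                          truth=truth, k_bar=proxy.k_bar, bs_lookup=bs_lk,
                          sweep_lookup=sw_lk, fit_result=res, dmap=dmap)


def evaluate_pipeline(result: PipelineResult, *, window_bp: int = 1_000_000,
                      n_bins: int = 1600, collate_cls: str = "nonsyn",
                      collate_max_dist: float = 0.002,
                      collate_bins: int = 40) -> dict:
    """Standard evaluation summaries for a pipeline result."""
    r2, wtab = window_r2(result.dmap, window_bp)
    n_bins_eff = min(n_bins, max(len(result.dmap) // 20, 2))
    strat = stratify(result.dmap, n_bins=n_bins_eff)
    modes = mode_contributions(result.dmap)
    curve = collate(result.dmap, result.genome.substitutions, collate_cls,
                    result.genome.gmap, collate_max_dist, collate_bins)
    return {"window_r2": r2, "windows": wtab, "stratify": strat,
            "modes": modes, "collated": curve}
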