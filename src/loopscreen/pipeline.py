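"""End-to-end pipelines: genotype-comparison Hi-C analysis and screen calling.

Both pipelines are deterministic given their config (all randomness flows
from one root seed, split per stage) and emit a machine-readable run report
recording inputs, parameters, feature counts and scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import matrixcore as mc
from . import aggregates as ag
from . import screen as sc

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_hic_pipeline", "run_screen_pipeline"]


@dataclass
class PipelineConfig:
    """Parameters for the pipelines; defaults follow the published analysis
    settings (100-kb APA flank, 3-Mb extended-loop window, 6-Mb stripe
    submatrix, top 10,000 sites, 100 million contacts, alpha 0.05, odds-ratio
    cutoff 0.7)."""

    out_dir: str = "results"
    seed: int = 0
    # matrix processing
    scale_total: float = 1e8
    subsample_to: float | None = None
    ice_tol: float = 1e-5
    ice_max_iter: int = 1000
    ice_mask_frac: float = 0.02
    # aggregation
    apa_flank: int = 100_000
    apa_size: int = 3
    ext_window: float = 3_000_000.0
    stripe_flank: int = 3_000_000
    top_n_sites: int = 10_000
    loess_span: float = 0.75
    loess_degree: int = 2
    # screen statistics
    alpha: float = 0.05
    or_cutoff: float = 0.7
    p0: float | str = "auto"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.or_cutoff < 0:
            raise ValueError("or_cutoff must be non-negative")
        if self.top_n_sites < 1:
            raise ValueError("top_n_sites must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _save_aggregate(m: ag.AggregateMap, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# flank\t{m.flank}\n# resolution\t{m.resolution}\n"
                 f"# n_used\t{m.n_used}\n")
        np.savetxt(fh, m.grid, delimiter="\t")


def process_matrix(cm: mc.ContactMatrix, config: PipelineConfig,
                   seed: int) -> tuple[mc.ContactMatrix, mc.ExpectedProfile,
                                       mc.ContactMatrix]:
    """raw -> (subsample) -> ICE -> scale; returns scaled, expected, O/E."""
    if config.subsample_to is not None:
        cm = mc.subsample_contacts(cm, config.subsample_to, seed=seed)
    balanced, _bias = mc.ice_normalize(cm, tol=config.ice_tol,
                                       max_iter=config.ice_max_iter,
                                       mask_frac=config.ice_mask_frac)
    scaled = mc.scale_to_total(balanced, config.scale_total)
    exp = mc.expected_by_distance(scaled)
    oe = mc.oe_transform(scaled, exp)
    return scaled, exp, oe


def run_hic_pipeline(samples: dict[str, mc.ContactMatrix],
                     loops: list[ag.Loop], sites: ag.AnchorSet,
                     config: PipelineConfig = PipelineConfig(),
                     reference: str | None = None,
                     write_artifacts: bool = True) -> dict:
    """Genotype-comparison pipeline over named contact matrices.

    For each sample: balance, depth-scale, APA on primary and extended loops
    (with scores), distance-normalized aggregate stripe analysis with LOESS
    quantification; differential aggregate maps against ``reference`` (the
    first sample by default).  Returns the run report; artifacts (TSV grids,
    profiles, report JSON) go under ``config.out_dir`` when requested.
    """
    if not samples:
        raise ValueError("no input samples")
    out = Path(config.out_dir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
    reference = reference if reference is not None else next(iter(samples))
    if reference not in samples:
        raise ValueError(f"reference {reference!r} not among samples")
    rng = np.random.default_rng(config.seed)
    stage_seeds = {name: int(s) for name, s in
                   zip(samples, rng.integers(0, 2 ** 31 - 1, len(samples)))}

    extended = ag.enumerate_extended_loops(loops, window=config.ext_window)
    top_sites = ag.select_top_sites(sites, n=config.top_n_sites)
    report: dict = {
        "config": {k: v for k, v in asdict(config).items()},
        "reference": reference,
        "n_primary_loops": len(loops),
        "n_extended_loops": len(extended),
        "n_sites": len(top_sites),
        "samples": {},
    }
    apa_maps: dict[str, dict[str, ag.AggregateMap]] = {}
    for name, raw in samples.items():
        try:
            scaled, exp, _oe = process_matrix(raw, config, stage_seeds[name])
            m_primary = ag.apa(scaled, loops, flank=config.apa_flank)
            m_ext = ag.apa(scaled, extended, flank=config.apa_flank)
            agg, p5, p3 = ag.aggregate_stripes(scaled, top_sites,
                                               flank=config.stripe_flank)
            fit3 = ag.fit_local_polynomial(p3.distances, p3.values,
                                           span=config.loess_span,
                                           degree=config.loess_degree)
            fit5 = ag.fit_local_polynomial(p5.distances, p5.values,
                                           span=config.loess_span,
                                           degree=config.loess_degree)
        except Exception as err:
            raise RuntimeError(f"sample {name!r}: pipeline failed: {err}") from err
        apa_maps[name] = {"primary": m_primary, "extended": m_ext}
        report["samples"][name] = {
            "total_raw": raw.total,
            "apa_primary_score": ag.apa_score(m_primary, config.apa_size),
            "apa_extended_score": ag.apa_score(m_ext, config.apa_size),
            "apa_primary_n": m_primary.n_used,
            "apa_extended_n": m_ext.n_used,
            "stripe_n": p3.n_used,
            "stripe3_mean_1_3mb": p3.mean_over(1e6, 3e6),
            "stripe5_mean_1_3mb": p5.mean_over(1e6, 3e6),
        }
        if write_artifacts:
            _save_aggregate(m_primary, out / f"{name}.apa_primary.tsv")
            _save_aggregate(m_ext, out / f"{name}.apa_extended.tsv")
            _save_aggregate(agg, out / f"{name}.stripe_aggregate.tsv")
            np.savetxt(out / f"{name}.stripe3_fit.tsv",
                       np.column_stack([fit3.grid, p3.values, fit3.fitted,
                                        fit3.ci_half]),
                       delimiter="\t",
                       header="distance_bp\tmean_oe\tloess\tci95_half")
            np.savetxt(out / f"{name}.stripe5_fit.tsv",
                       np.column_stack([fit5.grid, p5.values, fit5.fitted,
                                        fit5.ci_half]),
                       delimiter="\t",
                       header="distance_bp\tmean_oe\tloess\tci95_half")
    for name in samples:
        if name == reference:
            continue
        for kind in ("primary", "extended"):
            diff = ag.differential_map(apa_maps[name][kind],
                                       apa_maps[reference][kind])
            report["samples"][name][f"apa_{kind}_diff_center"] = \
                float(diff.grid[diff.grid.shape[0] // 2, diff.grid.shape[1] // 2])
            if write_artifacts:
                _save_aggregate(diff, out / f"{name}_vs_{reference}.apa_{kind}_diff.tsv")
    if write_artifacts:
        with open(out / "hic_report.json", "w") as fh:
            json.dump(report, fh, indent=1)
    return report


def run_screen_pipeline(case: sc.ScreenDataset, controls: list[sc.ScreenDataset],
                        config: PipelineConfig = PipelineConfig(),
                        write_artifacts: bool = True) -> dict:
    """Screen calling pipeline: step 1 -> step 2 -> OR filter -> ranking."""
    if not controls:
        raise ValueError("at least one control dataset is required")
    params = sc.ScreenParams(p0=config.p0, alpha=config.alpha,
                             or_cutoff=config.or_cutoff)
    result = sc.classify_fitness_enhancers(case, controls, params)
    fishtail = sc.fishtail_coordinates(case)
    hits = result.index[result["fitness_enhancer"]].tolist()
    report = {
        "config": {k: v for k, v in asdict(config).items()},
        "n_genes": int(len(result)),
        "n_controls": len(controls),
        "n_fitness_enhancers": len(hits),
        "fitness_enhancers": hits[:50],
        "top_gene": result.index[0] if len(result) else None,
    }
    if write_artifacts:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_csv(out / "screen_results.tsv", sep="\t")
        fishtail.to_csv(out / "fishtail.tsv", sep="\t")
        with open(out / "screen_report.json", "w") as fh:
            json.dump(report, fh, indent=1)
    return report
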