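"""Synthetic Hi-C maps and gene-trap screen tables with planted ground truth.

The contact-map generator is phenomenological, not mechanistic: it composes a
power-law distance decay with Gaussian focal loops at CTCF anchor pairs and
exponential stripes emanating from anchors, then draws Poisson counts.  The
stripe decay length ``L`` is the single knob that stands in for how far
loop extrusion reaches past an anchor; genotype presets encode the expected
qualitative ordering of that reach (shorter in deacetylase knockouts, longer
when the acetyltransferase or the release/brake factors are lost).  Preset
numbers are generator configuration chosen for realism, not measurements.

The screen generator draws per-gene insertion totals from a log-normal depth
profile (Poisson per sample) and sense counts binomially; planted
fitness-enhancer genes get an elevated sense fraction and clonal expansion in
the case sample only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .matrixcore import BinnedGenome, ContactMatrix
from .aggregates import AnchorSet, Loop, enumerate_extended_loops

__all__ = [
    "HiCSimParams",
    "SimTruth",
    "GENOTYPES",
    "simulate_sites_and_loops",
    "genotype_preset",
    "simulate_contact_map",
    "simulate_genotype",
    "simulate_screen",
    "estimate_stripe_decay",
    "recover_stripe_decay",
]


@dataclass
class HiCSimParams:
    """Configuration for one synthetic cis contact map.

    Amplitudes are enrichment factors over the local distance-decay
    background; ``stripe_len`` is in bp.  ``depth`` is the expected symmetric
    total count (off-diagonals twice), i.e. the cis sequencing depth of the
    simulated chromosome.
    """

    chrom: str = "chrS"
    chrom_length: int = 50_000_000
    resolution: int = 100_000
    background: float = 1.0
    decay_exponent: float = 1.0
    short_amp: float = 35.0
    short_len: float = 50_000.0
    anchors: tuple[int, ...] = ()
    anchor_scores: tuple[float, ...] = ()
    loops: tuple[tuple[int, int], ...] = ()
    loop_amp: float = 4.0
    loop_sigma: float = 100_000.0
    stripe_amp: float = 2.0
    stripe_len: float = 600_000.0
    ext_amp: float = 1.0
    ext_window: float = 3_000_000.0
    depth: float = 10_000_000.0
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.background < 0 or self.loop_amp < 0 or self.stripe_amp < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.decay_exponent <= 0 or self.stripe_len <= 0:
            raise ValueError("decay exponent and stripe length must be positive")
        for a in self.anchors:
            if not 0 <= a < self.chrom_length:
                raise ValueError(f"anchor {a} outside chromosome")

    @property
    def genome(self) -> BinnedGenome:
        return BinnedGenome((self.chrom,), (self.chrom_length,), self.resolution)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HiCSimParams":
        with open(path) as fh:
            d = json.load(fh)
        d["anchors"] = tuple(d["anchors"])
        d["anchor_scores"] = tuple(d["anchor_scores"])
        d["loops"] = tuple(tuple(lp) for lp in d["loops"])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth serialized alongside every simulated dataset."""

    params: dict
    planted_loops: list = field(default_factory=list)
    stripe_len: float | None = None
    planted_genes: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def simulate_sites_and_loops(chrom: str = "chrS", chrom_length: int = 50_000_000,
                             resolution: int = 100_000, seed: int = 20_001,
                             spacing: float = 1_200_000.0, jitter: float = 300_000.0,
                             margin: float = 3_300_000.0
                             ) -> tuple[AnchorSet, list[Loop]]:
    """CTCF-like anchor sites (jittered spacing, log-normal scores) and loops.

    Anchors are laid out with inter-anchor gaps uniform in
    ``spacing +/- jitter`` inside a ``margin`` on both chromosome ends (so
    aggregate windows fit).  Primary loops connect consecutive anchor pairs.
    """
    rng = np.random.default_rng(seed)
    positions = []
    pos = margin + rng.uniform(0, spacing)
    while pos < chrom_length - margin:
        positions.append(int(pos))
        pos += rng.uniform(spacing - jitter, spacing + jitter)
    scores = rng.lognormal(mean=3.0, sigma=1.0, size=len(positions))
    sites = AnchorSet(pd.DataFrame({
        "chrom": chrom, "pos": positions, "score": scores,
    }))
    loops = [Loop(chrom, a5, a3) for a5, a3 in zip(positions[:-1], positions[1:])]
    return sites, loops


# stripe decay length L (bp), focal loop amplitude, extended-loop amplitude.
# Ordering encodes the qualitative genotype phenotypes: HDAC8 loss shortens
# stripes/loops, ESCO1 or WAPL loss lengthens them (additively in the double
# knockout), and PDS5A loss lengthens interactions while weakening CTCF-focal
# enrichment; deleting PDS5A rescues the HDAC8 shortening.
GENOTYPES: dict[str, tuple[float, float, float]] = {
    "dHDAC8":        (300_000.0, 4.0, 0.4),
    "WT":            (600_000.0, 4.0, 1.0),
    "dESCO1":        (1_000_000.0, 4.0, 2.0),
    "dWAPL":         (1_400_000.0, 4.0, 2.4),
    "dESCO1_dWAPL":  (2_000_000.0, 4.0, 3.0),
    "dPDS5A":        (1_200_000.0, 1.5, 2.0),
    "dHDAC8_dPDS5A": (1_100_000.0, 1.5, 2.0),
}


def genotype_preset(name: str, seed: int = 0, layout_seed: int = 20_001,
                    **overrides) -> HiCSimParams:
    """Fully populated simulation parameters for a named genotype.

    All presets share one anchor/loop layout (``layout_seed``) so that maps
    differ only in the planted architecture parameters and count noise.
    """
    if name not in GENOTYPES:
        raise ValueError(f"unknown genotype {name!r}; valid: {sorted(GENOTYPES)}")
    stripe_len, loop_amp, ext_amp = GENOTYPES[name]
    base = replace(HiCSimParams(name=name, seed=seed, stripe_len=stripe_len,
                                loop_amp=loop_amp, ext_amp=ext_amp),
                   **overrides)
    if not base.anchors:
        sites, loops = simulate_sites_and_loops(
            base.chrom, base.chrom_length, base.resolution, seed=layout_seed)
        base = replace(
            base,
            anchors=tuple(int(p) for p in sites.table["pos"]),
            anchor_scores=tuple(float(s) for s in sites.table["score"]),
            loops=tuple((lp.anchor5, lp.anchor3) for lp in loops),
        )
    return base


def _gaussian_bump(enrich: np.ndarray, b1: int, b2: int,
                   amp: float, sigma_bins: float) -> None:
    """Add a 2-D Gaussian enrichment bump at (b1, b2) in place."""
    n = enrich.shape[0]
    r = max(int(np.ceil(4 * sigma_bins)), 1)
    i0, i1 = max(b1 - r, 0), min(b1 + r + 1, n)
    j0, j1 = max(b2 - r, 0), min(b2 + r + 1, n)
    ii = np.arange(i0, i1)[:, None] - b1
    jj = np.arange(j0, j1)[None, :] - b2
    enrich[i0:i1, j0:j1] += amp * np.exp(-(ii ** 2 + jj ** 2) / (2 * sigma_bins ** 2))


def simulate_contact_map(params: HiCSimParams) -> tuple[ContactMatrix, SimTruth]:
    """Draw one Poisson contact map from the planted intensity model.

    Intensity per pixel:
    ``lambda_ij = B (|i-j|+1)^(-alpha) * (1 + loops + extended loops + stripes)
    + S exp(-|i-j| res / short_len)``
    where loops are Gaussian bumps at anchor-pair pixels, extended loops the
    same at 5'-to-farther-3' pairs (amplitude ``ext_amp``), and stripes decay
    exponentially with genomic distance from each anchor along its row (3')
    and column (5').  The additive short-range term models the sub-200-kb
    contact mass that dominates real cis coverage; architectural features
    enrich only the power-law component, so anchor-bin marginals stay close
    to their neighbors' (as in real maps) and ICE balancing does not erase
    the planted signal.  The intensity is rescaled so the expected symmetric
    total equals ``depth``; counts are Poisson, seeded by ``params.seed``.
    """
    genome = params.genome
    n = genome.n_bins(params.chrom)
    res = params.resolution
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    base = params.background * (d + 1.0) ** (-params.decay_exponent)

    enrich = np.ones((n, n))
    sigma_bins = params.loop_sigma / res
    primary = [Loop(params.chrom, a5, a3) for a5, a3 in params.loops]
    for lp in primary:
        _gaussian_bump(enrich, lp.anchor5 // res, lp.anchor3 // res,
                       params.loop_amp, sigma_bins)
    extended = enumerate_extended_loops(primary, params.ext_window) if primary else []
    for lp in extended:
        _gaussian_bump(enrich, lp.anchor5 // res, lp.anchor3 // res,
                       params.ext_amp, sigma_bins)
    decay = np.exp(-np.arange(n) * res / params.stripe_len)
    for a in params.anchors:
        ab = a // res
        # 3' stripe: along the row to the right of the anchor
        enrich[ab, ab + 1:] += params.stripe_amp * decay[1:n - ab]
        # 5' stripe: along the column above the anchor
        enrich[:ab, ab] += params.stripe_amp * decay[ab:0:-1]

    short = params.short_amp * np.exp(-d * res / params.short_len)
    lam = base * enrich + params.background * short
    lam = np.triu(lam)
    lam = lam + np.triu(lam, 1).T  # symmetric intensity
    sym_total = lam.sum()
    lam *= params.depth / sym_total

    rng = np.random.default_rng(params.seed)
    iu, ju = np.triu_indices(n)
    counts = rng.poisson(lam[iu, ju])
    keep = counts > 0
    cm = ContactMatrix(genome, params.chrom, iu[keep], ju[keep],
                       counts[keep].astype(float), stage="raw")
    truth = SimTruth(params=asdict(params),
                     planted_loops=[(lp.anchor5, lp.anchor3) for lp in primary],
                     stripe_len=params.stripe_len)
    return cm, truth


def simulate_genotype(name: str, seed: int = 0, **overrides
                      ) -> tuple[ContactMatrix, AnchorSet, list[Loop], SimTruth]:
    """Convenience: preset -> simulated map plus its anchor/loop annotations."""
    params = genotype_preset(name, seed=seed, **overrides)
    cm, truth = simulate_contact_map(params)
    sites = AnchorSet(pd.DataFrame({
        "chrom": params.chrom,
        "pos": list(params.anchors),
        "score": list(params.anchor_scores),
    }))
    loops = [Loop(params.chrom, a5, a3) for a5, a3 in params.loops]
    return cm, sites, loops, truth


def estimate_stripe_decay(distances_bp: np.ndarray, values: np.ndarray,
                          fit_range: tuple[float, float] = (500_000.0, 3_000_000.0),
                          sigma: np.ndarray | None = None) -> float:
    """Estimate the stripe decay length L (bp) from an aggregate profile.

    Fits ``c + A exp(-d / L)`` to the mean-O/E stripe profile by robust
    (soft-L1) least squares over a grid of starting decay lengths;
    single-pixel spikes where the profile crosses other anchors or planted
    loops are downweighted by the robust loss.  The default fit range starts
    at 500 kb because the first few bins are dominated by short-range contact
    mass that dilutes the relative stripe signal.  Returns L in bp.
    """
    from scipy.optimize import least_squares

    d = np.asarray(distances_bp, float)
    y = np.asarray(values, float)
    sel = (d >= fit_range[0]) & (d <= fit_range[1]) & np.isfinite(y)
    if sigma is not None:
        sigma = np.asarray(sigma, float)[sel]
        sigma = np.where(sigma > 0, sigma, np.nanmedian(sigma[sigma > 0]))
    d, y = d[sel], y[sel]
    if len(d) < 5:
        raise ValueError("too few profile points in the fit range")
    if sigma is None:
        # Poisson noise per profile point grows roughly like sqrt(separation)
        # (the underlying counts thin out with distance); weight accordingly.
        w = 1.0 / np.sqrt(d / d[0])
    else:
        w = 1.0 / sigma
        w /= w.max()
    scale = float(np.median(np.abs(np.diff(y)))) + 1e-6
    amp0 = max(y.max() - y.min(), 1e-3)

    def resid(theta):
        c, a, logL = theta
        return w * (c + a * np.exp(-d / np.exp(logL)) - y)

    best = None
    for L0 in (2e5, 5e5, 1e6, 2e6, 4e6):
        sol = least_squares(
            resid, x0=[1.0, amp0 * np.exp(d[0] / L0), np.log(L0)],
            loss="soft_l1", f_scale=scale,
            bounds=([0.85, 0.0, np.log(5e4)], [1.15, 100.0, np.log(1e7)]))
        if best is None or sol.cost < best.cost:
            best = sol
    return float(np.exp(best.x[2]))


def recover_stripe_decay(params: HiCSimParams, n_reps: int = 10,
                         seed: int = 0, flank: int = 5_000_000) -> float:
    """Measure the stripe decay length from replicate simulated maps.

    Simulates ``n_reps`` maps from ``params`` (independent count noise),
    depth-scales each, extracts dot-masked control-normalized stripe
    profiles, pools the 5' and 3' arms across replicates, and fits the
    exponential decay with empirical per-distance standard errors as
    weights.  Pooling replicates before fitting mirrors how replicate Hi-C
    libraries are merged before aggregate analysis.  Returns L-hat in bp.
    """
    from .matrixcore import scale_to_total
    from .aggregates import AnchorSet as _AnchorSet, stripe_decay_profiles

    rng = np.random.default_rng(seed)
    sites = _AnchorSet(pd.DataFrame({
        "chrom": params.chrom, "pos": list(params.anchors),
        "score": list(params.anchor_scores)}))
    rows = []
    dists = None
    for rep_seed in rng.integers(0, 2 ** 31 - 1, size=n_reps):
        cm, _ = simulate_contact_map(replace(params, seed=int(rep_seed)))
        scaled = scale_to_total(cm)
        p5, p3 = stripe_decay_profiles(scaled, sites, flank=flank)
        dists = p3.distances
        rows.append(p5.values)
        rows.append(p3.values)
    stack = np.vstack(rows)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        n_obs = np.sum(np.isfinite(stack), axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
        se = np.where(n_obs > 1, sd / np.sqrt(np.maximum(n_obs, 1)), np.nan)
    return estimate_stripe_decay(dists, mean, sigma=se,
                                 fit_range=(500_000.0, float(flank)))


def simulate_screen(n_genes: int = 20_000, mean_insertions: float = 100.0,
                    p0: float = 0.5, planted: list[tuple[int, float, float]] = (),
                    n_controls: int = 3, seed: int = 0, depth_sigma: float = 1.0
                    ) -> tuple["ScreenDataset", list["ScreenDataset"], SimTruth]:
    """Synthetic gene-trap screen: one case sample plus null controls.

    Per-gene expected insertion totals are log-normal across genes (median
    ``mean_insertions``, log-sd ``depth_sigma``), shared between samples;
    realized totals are Poisson and sense counts Binomial(total, p_g).  Null
    genes have ``p_g = p0`` everywhere.  ``planted`` entries
    ``(gene_index, sense_fraction, expansion)`` raise the sense fraction and
    scale the expected total by ``expansion`` in the case sample only; a
    planted gene's base expected total is pinned to ``mean_insertions`` so
    the planted effect size is reproducible.  Controls are always null.
    """
    from .screen import ScreenDataset

    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    for g, frac, exp_ in planted:
        if not 0 <= g < n_genes:
            raise ValueError(f"planted gene index {g} outside universe")
        if not 0 < frac < 1:
            raise ValueError(f"planted sense fraction {frac} outside (0, 1)")
        if exp_ <= 0:
            raise ValueError("expansion must be positive")

    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{k:05d}" for k in range(n_genes)], name="gene")
    lam = rng.lognormal(mean=np.log(mean_insertions), sigma=depth_sigma,
                        size=n_genes)
    for g, _frac, _exp in planted:
        lam[g] = mean_insertions

    def draw(case: bool, sample_seed: int) -> pd.DataFrame:
        srng = np.random.default_rng(sample_seed)
        lam_s = lam.copy()
        p_g = np.full(n_genes, p0)
        if case:
            for g, frac, exp_ in planted:
                lam_s[g] *= exp_
                p_g[g] = frac
        totals = srng.poisson(lam_s)
        sense = srng.binomial(totals, p_g)
        return pd.DataFrame({"sense": sense, "antisense": totals - sense},
                            index=genes)

    sub = rng.integers(0, 2 ** 31 - 1, size=n_controls + 1)
    case = ScreenDataset("case", "case", draw(True, int(sub[0])))
    controls = [ScreenDataset(f"control{k + 1}", "control",
                              draw(False, int(sub[k + 1])))
                for k in range(n_controls)]
    truth = SimTruth(params={"n_genes": n_genes, "mean_insertions": mean_insertions,
                             "p0": p0, "n_controls": n_controls, "seed": seed,
                             "depth_sigma": depth_sigma},
                     planted_genes=[(genes[g], frac, exp_)
                                    for g, frac, exp_ in planted])
    return case, controls, truth
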