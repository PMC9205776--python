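"""Feature-anchored aggregation over contact matrices.

Implements aggregate peak analysis (APA) for primary and extended loops,
differential aggregate maps, distance-normalized aggregate stripe analysis
around CTCF anchors, and LOESS quantification of stripe profiles with a
pointwise 95% confidence band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrixcore import ContactMatrix, expected_by_distance

logger = logging.getLogger(__name__)

__all__ = [
    "Loop",
    "AnchorSet",
    "AggregateMap",
    "StripeProfile",
    "SmoothFit",
    "read_loops",
    "write_loops",
    "read_anchors",
    "enumerate_extended_loops",
    "apa",
    "apa_score",
    "differential_map",
    "select_top_sites",
    "aggregate_stripes",
    "stripe_decay_profiles",
    "fit_local_polynomial",
]


@dataclass(frozen=True, order=True)
class Loop:
    """A chromatin loop given by its two anchor midpoints (bp)."""

    chrom: str
    anchor5: int
    anchor3: int

    def __post_init__(self) -> None:
        if self.anchor5 >= self.anchor3:
            raise ValueError("anchor5 must lie upstream of anchor3")

    @property
    def span(self) -> int:
        return self.anchor3 - self.anchor5


@dataclass
class AnchorSet:
    """Point features (e.g. CTCF peak summits) with a score, as a DataFrame."""

    table: pd.DataFrame  # columns: chrom, pos, score

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "score"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"anchor table needs columns {sorted(required)}")
        if not np.all(np.isfinite(self.table["score"])):
            raise ValueError("anchor scores must be finite")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class AggregateMap:
    """Mean submatrix around a feature list: odd square grid of side w.

    ``w = 2 * flank / resolution + 1``; the center pixel is at index
    ``(w - 1) / 2`` on both axes.
    """

    grid: np.ndarray
    flank: int
    resolution: int
    n_used: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        w = 2 * self.flank // self.resolution + 1
        if self.flank % self.resolution:
            raise ValueError("flank must be divisible by resolution")
        if self.grid.shape != (w, w):
            raise ValueError(f"grid shape {self.grid.shape} != ({w}, {w})")

    @property
    def side(self) -> int:
        return self.grid.shape[0]

    @property
    def center(self) -> int:
        return (self.side - 1) // 2


@dataclass
class StripeProfile:
    """Mean O/E along one arm of the aggregate stripe (distance 0 = anchor)."""

    side: str  # "5prime" or "3prime"
    distances: np.ndarray  # bp offsets, 0..flank
    values: np.ndarray  # mean O/E per distance
    n_used: int

    def mean_over(self, lo_bp: float, hi_bp: float) -> float:
        """Mean enrichment over distances in [lo_bp, hi_bp]."""
        sel = (self.distances >= lo_bp) & (self.distances <= hi_bp)
        return float(np.nanmean(self.values[sel]))


def read_loops(path) -> list[Loop]:
    """Read loops from BEDPE (6+ columns); anchors become interval midpoints.

    Inter-chromosomal rows are dropped (count logged).  Malformed rows raise
    with their row number.
    """
    loops: list[Loop] = []
    dropped = 0
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"row {row_no}: BEDPE needs >= 6 columns")
            try:
                c1, s1, e1, c2, s2, e2 = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
            except ValueError:
                raise ValueError(f"row {row_no}: malformed BEDPE row") from None
            if c1 != c2:
                dropped += 1
                continue
            m1, m2 = (s1 + e1) // 2, (s2 + e2) // 2
            if m1 > m2:
                m1, m2 = m2, m1
            loops.append(Loop(c1, m1, m2))
    if dropped:
        logger.info("read_loops: dropped %d inter-chromosomal rows", dropped)
    return loops


def write_loops(loops: list[Loop], path, width: int = 1) -> None:
    """Write loops as 6-column BEDPE with ``width``-bp anchor intervals."""
    with open(path, "w") as fh:
        for lp in loops:
            fh.write(f"{lp.chrom}\t{lp.anchor5}\t{lp.anchor5 + width}\t"
                     f"{lp.chrom}\t{lp.anchor3}\t{lp.anchor3 + width}\n")


def read_anchors(path) -> AnchorSet:
    """Read BED5 (chrom, start, end, name, score); position = midpoint."""
    rows = []
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ValueError(f"row {row_no}: BED needs >= 5 columns")
            rows.append((f[0], (int(f[1]) + int(f[2])) // 2, float(f[4])))
    return AnchorSet(pd.DataFrame(rows, columns=["chrom", "pos", "score"]))


def write_anchors(anchors: AnchorSet, path, width: int = 1) -> None:
    with open(path, "w") as fh:
        for k, row in enumerate(anchors.table.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + width}\t"
                     f"site{k}\t{float(row.score)!r}\n")


def enumerate_extended_loops(loops: list[Loop], window: float = 3e6,
                             longer_than_seed: bool = False,
                             boundary_inclusive: bool = True) -> list[Loop]:
    """Pair each primary 5' anchor with every other 3' anchor within ``window``.

    An extended loop joins a primary loop's 5' anchor to any distinct 3'
    anchor from the full loop list that lies downstream within ``window`` bp
    (boundary inclusive by default), excluding pairs already present in the
    primary list.  ``longer_than_seed`` restricts candidates to pairs longer
    than the seed primary loop.  Output is deduplicated and sorted.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    primary = {(lp.chrom, lp.anchor5, lp.anchor3) for lp in loops}
    anchors3: dict[str, set[int]] = {}
    for lp in loops:
        anchors3.setdefault(lp.chrom, set()).add(lp.anchor3)
    out: set[tuple[str, int, int]] = set()
    for lp in loops:
        for a3 in anchors3[lp.chrom]:
            if a3 <= lp.anchor5:
                continue
            dist = a3 - lp.anchor5
            if (dist > window) if boundary_inclusive else (dist >= window):
                continue
            if longer_than_seed and dist <= lp.span:
                continue
            key = (lp.chrom, lp.anchor5, a3)
            if key in primary:
                continue
            out.add(key)
    return sorted(Loop(*k) for k in out)


def _check_stage(cm: ContactMatrix, preferred: tuple[str, ...], what: str) -> None:
    if cm.stage not in preferred:
        logger.info("%s: matrix stage is %r (typically run on %s)",
                    what, cm.stage, "/".join(preferred))


def apa(cm: ContactMatrix, loops: list[Loop], flank: int = 100_000) -> AggregateMap:
    """Aggregate peak analysis: mean submatrix centered on loop anchor pairs.

    Rows span the 5' anchor +/- flank, columns the 3' anchor +/- flank.  Loops
    whose window would cross a chromosome edge are skipped (counted); at least
    one usable loop is required.
    """
    res = cm.genome.resolution
    if flank % res:
        raise ValueError("flank must be divisible by resolution")
    _check_stage(cm, ("scaled", "oe"), "apa")
    f = flank // res
    w = 2 * f + 1
    n = cm.n_bins
    dense = cm.to_dense()
    acc = np.zeros((w, w))
    used = skipped = 0
    for lp in loops:
        if lp.chrom != cm.chrom:
            skipped += 1
            continue
        b5 = lp.anchor5 // res
        b3 = lp.anchor3 // res
        if b5 - f < 0 or b5 + f >= n or b3 - f < 0 or b3 + f >= n:
            skipped += 1
            continue
        acc += dense[b5 - f:b5 + f + 1, b3 - f:b3 + f + 1]
        used += 1
    if used == 0:
        raise ValueError("no usable loops (all out of bounds or wrong chromosome)")
    if skipped:
        logger.info("apa: skipped %d/%d loops", skipped, len(loops))
    return AggregateMap(acc / used, flank=flank, resolution=res, n_used=used)


def apa_score(m: AggregateMap, size: int = 3) -> float:
    """Mean signal of the central ``size x size`` block of an aggregate map."""
    if size % 2 == 0:
        raise ValueError("size must be odd")
    if size > m.side:
        raise ValueError("size exceeds map side length")
    c, h = m.center, size // 2
    return float(m.grid[c - h:c + h + 1, c - h:c + h + 1].mean())


def differential_map(a: AggregateMap, b: AggregateMap) -> AggregateMap:
    """Element-wise difference ``a - b`` of two same-shape aggregate maps."""
    if (a.side, a.flank, a.resolution) != (b.side, b.flank, b.resolution):
        raise ValueError("aggregate maps have mismatched shape/flank/resolution")
    out = AggregateMap.__new__(AggregateMap)
    out.grid = a.grid - b.grid
    out.flank = a.flank
    out.resolution = a.resolution
    out.n_used = min(a.n_used, b.n_used)
    return out


def select_top_sites(sites: AnchorSet, n: int = 10_000) -> AnchorSet:
    """Keep the ``n`` highest-scoring sites; ties broken by (chrom, pos)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    t = sites.table.sort_values(["score", "chrom", "pos"],
                                ascending=[False, True, True],
                                kind="stable")
    if len(t) < n:
        logger.warning("select_top_sites: only %d sites available (asked %d)",
                       len(t), n)
    return AnchorSet(t.head(n).reset_index(drop=True))


def aggregate_stripes(cm: ContactMatrix, sites: AnchorSet, flank: int = 3_000_000
                      ) -> tuple[AggregateMap, StripeProfile, StripeProfile]:
    """Distance-normalized aggregate map around anchor diagonal pixels.

    Each site's ``(2*flank/res + 1)``-sided submatrix, centered on the site's
    diagonal pixel, is divided element-wise by the matrix's expected value at
    each pixel's separation before averaging, so enrichment at stripes is
    measured relative to the distance decay.  Returns the aggregate map plus
    the 5' and 3' stripe profiles (center column upward / center row rightward).
    """
    res = cm.genome.resolution
    if flank % res:
        raise ValueError("flank must be divisible by resolution")
    _check_stage(cm, ("balanced", "scaled"), "aggregate_stripes")
    f = flank // res
    w = 2 * f + 1
    n = cm.n_bins
    exp = expected_by_distance(cm)
    # within a diagonal-centered window, pixel (r, q) sits at separation |r-q|
    offs = np.arange(w)
    dmat = np.abs(offs[:, None] - offs[None, :])
    edenom = exp.values[dmat]
    edenom[edenom == 0] = np.nan
    dense = cm.to_dense()
    acc = np.zeros((w, w))
    used = skipped = 0
    for row in sites.table.itertuples(index=False):
        if row.chrom != cm.chrom:
            skipped += 1
            continue
        c = int(row.pos) // res
        if c - f < 0 or c + f >= n:
            skipped += 1
            continue
        acc += dense[c - f:c + f + 1, c - f:c + f + 1] / edenom
        used += 1
    if used == 0:
        raise ValueError("no usable sites (all out of bounds or wrong chromosome)")
    if skipped:
        logger.info("aggregate_stripes: skipped %d/%d sites", skipped, len(sites))
    agg = AggregateMap(acc / used, flank=flank, resolution=res, n_used=used)
    dists = np.arange(f + 1) * res
    p3 = StripeProfile("3prime", dists, agg.grid[f, f:].copy(), used)
    p5 = StripeProfile("5prime", dists, agg.grid[:f + 1, f][::-1].copy(), used)
    return agg, p5, p3


def stripe_decay_profiles(cm: ContactMatrix, sites: AnchorSet,
                          flank: int = 3_000_000, exclude_bins: int = 3
                          ) -> tuple[StripeProfile, StripeProfile]:
    """Expected-normalized stripe profiles with focal-dot pixels masked out.

    Same per-site extraction as :func:`aggregate_stripes`, but (i) pixels
    within ``exclude_bins`` of any *other* anchor are dropped from the
    average — loops and crossing stripes sit at anchor/anchor pixels, so
    masking them leaves the bare decay of the stripe — and (ii) each distance
    is normalized by a control profile taken over bin pairs that are both
    away from every anchor, instead of the global expected.  The control
    cancels whatever genome-wide distance structure (including the aggregate
    contribution of the features themselves) sits in the denominator, which a
    decay-length fit would otherwise absorb into the decay.
    """
    res = cm.genome.resolution
    if flank % res:
        raise ValueError("flank must be divisible by resolution")
    f = flank // res
    n = cm.n_bins
    dense = cm.to_dense()
    centers = [int(p) // res for p in
               sites.table.loc[sites.table["chrom"] == cm.chrom, "pos"]]
    anchor_bins = np.array(sorted(centers), dtype=np.int64)
    bin_idx = np.arange(n)
    near_anchor = np.min(
        np.abs(bin_idx[:, None] - anchor_bins[None, :]), axis=1) <= exclude_bins
    clear = ~near_anchor & ~cm.mask
    control = np.full(f + 1, np.nan)
    for dd in range(f + 1):
        ok = clear[:n - dd] & clear[dd:] if dd else clear
        if ok.sum():
            control[dd] = dense[bin_idx[:n - dd][ok], bin_idx[:n - dd][ok] + dd].mean()
    acc3 = np.zeros(f + 1)
    cnt3 = np.zeros(f + 1, dtype=np.int64)
    acc5 = np.zeros(f + 1)
    cnt5 = np.zeros(f + 1, dtype=np.int64)
    used = 0
    for c in centers:
        if c - f < 0 or c + f >= n:
            continue
        used += 1
        for sign, acc, cnt in ((1, acc3, cnt3), (-1, acc5, cnt5)):
            bins = c + sign * np.arange(f + 1)
            nearest = np.min(np.abs(bins[:, None] - anchor_bins[None, :]), axis=1)
            ok = (nearest > exclude_bins) | (bins == c)
            acc[ok] += dense[c, bins[ok]]
            cnt[ok] += 1
    if used == 0:
        raise ValueError("no usable sites")
    with np.errstate(invalid="ignore", divide="ignore"):
        v3 = np.where(cnt3 > 0, acc3 / np.maximum(cnt3, 1), np.nan) / control
        v5 = np.where(cnt5 > 0, acc5 / np.maximum(cnt5, 1), np.nan) / control
    dists = np.arange(f + 1) * res
    return (StripeProfile("5prime", dists, v5, used),
            StripeProfile("3prime", dists, v3, used))


@dataclass
class SmoothFit:
    """A LOESS fit on a grid with pointwise 95% confidence half-widths."""

    grid: np.ndarray
    fitted: np.ndarray
    ci_half: np.ndarray
    span: float
    degree: int

    def covers(self, truth: np.ndarray) -> np.ndarray:
        """Boolean per grid point: does the 95% band contain ``truth``?"""
        truth = np.asarray(truth, float)
        return (np.abs(truth - self.fitted) <= self.ci_half + 1e-12)


def _loess_lvector(x: np.ndarray, x0: float, k: int, degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Equivalent-kernel weight vector l(x0) over the k span-nearest points."""
    d = np.abs(x - x0)
    idx = np.argpartition(d, k - 1)[:k]
    h = d[idx].max()
    if h == 0:
        h = 1.0
    u = np.clip(d[idx] / h, 0, 1)
    wts = (1 - u ** 3) ** 3
    X = np.vander(x[idx] - x0, degree + 1, increasing=True)
    WX = wts[:, None] * X
    XtWX = X.T @ WX
    # e1^T (X'WX)^-1 X'W  — ridge jitter guards near-singular local designs
    try:
        beta_map = np.linalg.solve(XtWX, WX.T)
    except np.linalg.LinAlgError:
        beta_map = np.linalg.solve(XtWX + 1e-12 * np.eye(degree + 1), WX.T)
    return idx, beta_map[0]


def fit_local_polynomial(x: np.ndarray, y: np.ndarray, span: float = 0.75,
                         degree: int = 2, grid: np.ndarray | None = None) -> SmoothFit:
    """LOESS: locally weighted polynomial regression with a 95% CI band.

    At each evaluation point the ``span``-nearest neighbors get tricube
    weights and a degree-``degree`` weighted least-squares fit; the fitted
    value is a linear functional l(x0)'y of the observations.  The residual
    variance is estimated from the smoother matrix at the data points
    (sigma^2 = RSS / [n - 2 tr(L) + tr(L'L)]) and the pointwise standard
    error is sigma * ||l(x0)||, giving fitted +/- 1.96 SE as the 95% band.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all x identical")
    k = max(int(np.ceil(span * n)), degree + 1)
    k = min(k, n)

    # smoother matrix at the data points -> residual variance estimate
    L = np.zeros((n, n))
    for i in range(n):
        idx, lvec = _loess_lvector(x, x[i], k, degree)
        L[i, idx] = lvec
    fitted_data = L @ y
    resid = y - fitted_data
    delta1 = n - 2 * np.trace(L) + np.sum(L * L)
    sigma2 = float(resid @ resid) / delta1 if delta1 > 0 else 0.0
    sigma2 = max(sigma2, 0.0)

    if grid is None:
        grid = np.sort(x)
    grid = np.asarray(grid, float)
    fitted = np.empty(len(grid))
    se = np.empty(len(grid))
    for g, x0 in enumerate(grid):
        idx, lvec = _loess_lvector(x, x0, k, degree)
        fitted[g] = lvec @ y[idx]
        se[g] = np.sqrt(sigma2 * float(lvec @ lvec))
    if not np.all(np.isfinite(fitted)):
        raise ValueError("LOESS produced non-finite fitted values")
    return SmoothFit(grid, fitted, 1.96 * se, span, degree)
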