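"""Binned cis contact matrices: I/O, ICE balancing, scaling, subsampling, O/E.

The data model is deliberately small: one chromosome per matrix, upper-triangle
sparse storage (``bin_i <= bin_j``), and an explicit processing ``stage`` that
moves only forward through ``raw -> balanced -> scaled -> oe``.  The ``total``
of a matrix counts off-diagonal pixels twice (i.e. it is the sum of the full
symmetric matrix), matching how sequencing depth is usually quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinnedGenome",
    "ContactMatrix",
    "ExpectedProfile",
    "read_chrom_sizes",
    "read_contacts",
    "write_contacts",
    "ice_normalize",
    "scale_to_total",
    "subsample_contacts",
    "expected_by_distance",
    "oe_transform",
]

STAGES = ("raw", "balanced", "scaled", "oe")


@dataclass(frozen=True)
class BinnedGenome:
    """A fixed-resolution bin grid over a set of chromosomes.

    Bins are 0-based and half-open: bin ``i`` covers
    ``[i * resolution, (i + 1) * resolution)``; a genomic position maps to bin
    ``floor(pos / resolution)``.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    resolution: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("all chromosome lengths must be positive")

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str) -> int:
        return -(-self.length(chrom) // self.resolution)

    def pos_to_bin(self, chrom: str, pos: int) -> int:
        if not 0 <= pos < self.length(chrom):
            raise ValueError(f"position {pos} outside chromosome {chrom}")
        return int(pos // self.resolution)


@dataclass
class ContactMatrix:
    """Sparse symmetric cis contact map (upper triangle stored).

    ``mask`` flags low-coverage bins excluded from balancing and from
    expected-profile denominators.  ``bins1``/``bins2``/``values`` are parallel
    arrays with ``bins1 <= bins2``; duplicate pixels are not allowed (folding
    and summing happens at construction).
    """

    genome: BinnedGenome
    chrom: str
    bins1: np.ndarray
    bins2: np.ndarray
    values: np.ndarray
    stage: str = "raw"
    mask: np.ndarray = field(default=None)  # boolean, True = excluded

    def __post_init__(self) -> None:
        n = self.n_bins
        self.bins1 = np.asarray(self.bins1, dtype=np.int64)
        self.bins2 = np.asarray(self.bins2, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.bins1.shape != self.bins2.shape or self.bins1.shape != self.values.shape:
            raise ValueError("bins1, bins2, values must have equal length")
        if self.bins1.size:
            if self.bins1.min() < 0 or self.bins2.max() >= n:
                raise ValueError("bin index out of chromosome range")
            if np.any(self.bins1 > self.bins2):
                raise ValueError("entries must satisfy bin_i <= bin_j")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("values must be finite and non-negative")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ValueError("mask length must equal bin count")

    @property
    def n_bins(self) -> int:
        return self.genome.n_bins(self.chrom)

    @property
    def total(self) -> float:
        """Sum of the full symmetric matrix (off-diagonal counted twice)."""
        off = self.bins1 != self.bins2
        return float(self.values.sum() + self.values[off].sum())

    def to_dense(self) -> np.ndarray:
        """Full symmetric dense array (diagonal appears once)."""
        n = self.n_bins
        m = np.zeros((n, n))
        m[self.bins1, self.bins2] = self.values
        m[self.bins2, self.bins1] = self.values
        return m

    @classmethod
    def from_dense(cls, dense: np.ndarray, genome: BinnedGenome, chrom: str,
                   stage: str = "raw", mask: np.ndarray | None = None) -> "ContactMatrix":
        iu, ju = np.triu_indices(dense.shape[0])
        v = dense[iu, ju]
        keep = v != 0
        return cls(genome, chrom, iu[keep], ju[keep], v[keep], stage=stage, mask=mask)

    def with_values(self, values: np.ndarray, stage: str,
                    mask: np.ndarray | None = None) -> "ContactMatrix":
        return ContactMatrix(self.genome, self.chrom, self.bins1.copy(),
                             self.bins2.copy(), np.asarray(values, float),
                             stage=stage,
                             mask=self.mask.copy() if mask is None else mask)


@dataclass
class ExpectedProfile:
    """Mean contact value per genomic separation (in bins), zeros included.

    ``values[d]`` is the average over all in-range, non-masked bin pairs at
    separation ``d``; ``n_pairs[d]`` the number of such pairs.
    """

    values: np.ndarray
    n_pairs: np.ndarray
    resolution: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.n_pairs = np.asarray(self.n_pairs, np.int64)
        if np.any(self.values < 0):
            raise ValueError("expected values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def read_chrom_sizes(path, resolution: int) -> BinnedGenome:
    """Read a two-column ``name<TAB>length`` chrom-sizes file."""
    names, lengths = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2]
            names.append(name)
            lengths.append(int(length))
    return BinnedGenome(tuple(names), tuple(lengths), resolution)


def write_contacts(cm: ContactMatrix, path) -> None:
    """Write triplet text with a ``#``-prefixed metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# chrom\t{cm.chrom}\n")
        fh.write(f"# resolution\t{cm.genome.resolution}\n")
        fh.write(f"# stage\t{cm.stage}\n")
        fh.write(f"# total\t{float(cm.total)!r}\n")
        masked = np.flatnonzero(cm.mask)
        fh.write("# mask\t" + ",".join(map(str, masked)) + "\n")
        for i, j, v in zip(cm.bins1, cm.bins2, cm.values):
            fh.write(f"{i}\t{j}\t{float(v)!r}\n")


def read_contacts(path, genome: BinnedGenome, chrom: str) -> ContactMatrix:
    """Read a ``bin1<TAB>bin2<TAB>value`` triplet file.

    Entries are folded into the upper triangle and duplicate pixels summed.
    Header metadata lines (``# key<TAB>value``) restore stage and mask when
    present; plain files default to stage ``raw``.
    """
    n = genome.n_bins(chrom)
    stage = "raw"
    mask = np.zeros(n, dtype=bool)
    pixels: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2:
                    key, val = parts
                    if key == "stage":
                        stage = val
                    elif key == "mask" and val:
                        mask[[int(x) for x in val.split(",")]] = True
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"row {row_no}: expected 3 tab-separated fields")
            try:
                i, j, v = int(fields[0]), int(fields[1]), float(fields[2])
            except ValueError:
                raise ValueError(f"row {row_no}: malformed entry {line!r}") from None
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(
                    f"row {row_no}: bin index out of range for {chrom} ({n} bins)")
            if v < 0:
                raise ValueError(f"row {row_no}: negative value {v}")
            if i > j:
                i, j = j, i
            pixels[(i, j)] = pixels.get((i, j), 0.0) + v
    if pixels:
        keys = np.array(sorted(pixels), dtype=np.int64)
        b1, b2 = keys[:, 0], keys[:, 1]
        vals = np.array([pixels[(i, j)] for i, j in keys], float)
    else:
        b1 = b2 = np.empty(0, np.int64)
        vals = np.empty(0, float)
    return ContactMatrix(genome, chrom, b1, b2, vals, stage=stage, mask=mask)


def ice_normalize(cm: ContactMatrix, tol: float = 1e-5, max_iter: int = 1000,
                  mask_frac: float = 0.02) -> tuple[ContactMatrix, np.ndarray]:
    """Iterative correction: equalize bin marginals of the symmetric matrix.

    Plain ICE: repeatedly divide by the (unit-mean-normalized) marginal vector
    until the coefficient of variation of non-masked marginals drops below
    ``tol``.  The diagonal is included in marginals once.  The lowest-coverage
    ``mask_frac`` fraction of bins, plus any bin with zero coverage, is masked
    (bias 0, rows emptied).  Returns the balanced matrix and the bias vector
    ``b`` (unit mean over non-masked bins) with ``out_ij = raw_ij * b_i * b_j``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if cm.stage not in ("raw", "balanced"):
        raise ValueError(f"cannot balance a matrix at stage {cm.stage!r}")
    n = cm.n_bins
    dense = cm.to_dense()

    coverage = dense.sum(axis=0)
    masked = cm.mask | (coverage == 0)
    n_extra = int(np.floor(mask_frac * n))
    if n_extra > 0:
        order = np.argsort(coverage, kind="stable")
        masked[order[:n_extra]] = True
    active = ~masked
    if not active.any():
        raise ValueError("all bins masked; nothing to balance")
    dense[masked, :] = 0.0
    dense[:, masked] = 0.0

    bias = np.ones(n)
    cv = np.inf
    for _ in range(max_iter):
        marg = dense.sum(axis=0)
        m_act = marg[active]
        mean = m_act.mean()
        if mean == 0:
            raise ValueError("all active marginals zero; cannot balance")
        cv = m_act.std() / mean
        if cv < tol:
            break
        corr = np.ones(n)
        nz = active & (marg > 0)
        corr[nz] = marg[nz] / mean
        dense /= np.outer(corr, corr)
        bias /= corr
    else:
        raise RuntimeError(
            f"ICE did not converge in {max_iter} iterations (CV={cv:.3e})")

    # renormalize biases to unit mean over active bins; rescale matrix to match
    b_mean = bias[active].mean()
    bias /= b_mean
    dense /= b_mean ** 2
    bias[masked] = 0.0
    out = ContactMatrix.from_dense(dense, cm.genome, cm.chrom,
                                   stage="balanced", mask=masked)
    return out, bias


def scale_to_total(cm: ContactMatrix, target_total: float = 1e8) -> ContactMatrix:
    """Linearly rescale so the symmetric total equals ``target_total``."""
    if cm.stage == "oe":
        raise ValueError("cannot depth-scale an O/E matrix")
    total = cm.total
    if total <= 0:
        raise ValueError("empty matrix: total is zero")
    return cm.with_values(cm.values * (target_total / total), stage="scaled")


def subsample_contacts(cm: ContactMatrix, target_total: float,
                       seed: int, exact: bool = False) -> ContactMatrix:
    """Thin raw counts down to ``target_total`` expected contacts.

    Default is independent per-pixel binomial thinning with probability
    ``target_total / cm.total`` (equal in expectation to read-level
    subsampling).  ``exact=True`` instead draws a multinomial over pixels so
    the realized total is exact.
    """
    if cm.stage != "raw":
        raise ValueError("subsampling requires raw integer counts")
    total = cm.total
    if target_total > total:
        raise ValueError(f"target_total {target_total} exceeds matrix total {total}")
    counts = np.rint(cm.values).astype(np.int64)
    if not np.allclose(counts, cm.values):
        raise ValueError("raw matrix has non-integer counts")
    rng = np.random.default_rng(seed)
    p = target_total / total
    if p == 1.0:
        return cm.with_values(cm.values.copy(), stage="raw")
    if exact:
        # draw target pairs without replacement-in-expectation via multinomial
        # on the symmetric weights, halved back onto the upper triangle
        off = cm.bins1 != cm.bins2
        weights = counts.astype(float)
        weights[off] *= 2
        draw = rng.multinomial(int(round(target_total)), weights / weights.sum())
        vals = draw.astype(float)
        vals[off] /= 2
    else:
        vals = rng.binomial(counts, p).astype(float)
    return cm.with_values(vals, stage="raw")


def expected_by_distance(cm: ContactMatrix) -> ExpectedProfile:
    """Per-distance mean contact over all non-masked in-range bin pairs.

    Zero pixels count toward the average; pairs touching a masked bin are
    excluded from numerator and denominator alike.
    """
    if cm.stage not in ("balanced", "scaled"):
        raise ValueError(f"expected profile needs a balanced or scaled matrix, "
                         f"got stage {cm.stage!r}")
    n = cm.n_bins
    active = (~cm.mask).astype(np.float64)
    d = cm.bins2 - cm.bins1
    keep = active[cm.bins1].astype(bool) & active[cm.bins2].astype(bool)
    sums = np.bincount(d[keep], weights=cm.values[keep], minlength=n)
    # pairs at distance d with both bins active = correlation of the active
    # indicator with itself at lag d
    n_pairs = np.array([int(active[:n - dd] @ active[dd:]) for dd in range(n)],
                       dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        exp = np.where(n_pairs > 0, sums / np.maximum(n_pairs, 1), 0.0)
    return ExpectedProfile(exp, n_pairs, cm.genome.resolution)


def oe_transform(cm: ContactMatrix, exp: ExpectedProfile) -> ContactMatrix:
    """Observed/expected: divide each pixel by the mean at its separation.

    Pixels whose expected value is zero are dropped.
    """
    if len(exp) != cm.n_bins or exp.resolution != cm.genome.resolution:
        raise ValueError("expected profile computed on a different bin grid")
    d = cm.bins2 - cm.bins1
    denom = exp.values[d]
    keep = denom > 0
    vals = cm.values[keep] / denom[keep]
    return ContactMatrix(cm.genome, cm.chrom, cm.bins1[keep], cm.bins2[keep],
                         vals, stage="oe", mask=cm.mask.copy())
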