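"""Haploid gene-trap screen statistics.

In a haploid insertional-mutagenesis screen, intronic gene-trap insertions in
the sense orientation disrupt a gene while antisense insertions do not.  After
outgrowth under selection, genes whose loss confers a fitness advantage in the
case background accumulate an excess of sense insertions.  The calling scheme:

* step 1 — per-gene two-sided exact binomial test of the sense count against a
  null sense fraction, Benjamini–Hochberg corrected (q < alpha), with a
  sense/antisense direction label;
* step 2 — per-gene two-sided ("bidirectional") Fisher exact test of the case
  sense/antisense counts against every independent control dataset;
* an odds-ratio floor (default 0.7) plus a one-sided ("greater") Fisher test
  against the element-wise aggregated control counts;
* a fitness enhancer is a gene that is step-1 sense-enriched in the case but
  in no control, passes step 2 versus all controls, and passes the aggregated
  odds-ratio filter; hits are ranked by the aggregated one-sided p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScreenDataset",
    "read_screen_tsv",
    "write_screen_tsv",
    "percent_sense",
    "binom_two_sided",
    "fisher_two_sided",
    "fisher_greater",
    "bh_qvalues",
    "step1_binomial",
    "step2_fisher",
    "aggregate_or_filter",
    "classify_fitness_enhancers",
    "fishtail_coordinates",
]


@dataclass
class ScreenDataset:
    """Per-gene sense/antisense insertion counts for one sample."""

    name: str
    role: str  # "case" or "control"
    counts: pd.DataFrame  # index: gene id; columns: sense, antisense

    def __post_init__(self) -> None:
        if self.role not in ("case", "control"):
            raise ValueError("role must be 'case' or 'control'")
        c = self.counts
        if not {"sense", "antisense"}.issubset(c.columns):
            raise ValueError("counts need 'sense' and 'antisense' columns")
        if c.index.has_duplicates:
            raise ValueError("duplicate gene ids in sample")
        if (c[["sense", "antisense"]] < 0).any().any():
            raise ValueError("insertion counts must be non-negative")

    def aligned(self, genes: pd.Index) -> pd.DataFrame:
        """Counts reindexed to a shared gene universe; missing genes = (0, 0)."""
        return self.counts.reindex(genes, fill_value=0)[["sense", "antisense"]]


def read_screen_tsv(path, name: str | None = None, role: str = "case") -> ScreenDataset:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"gene": str, "sense": np.int64, "antisense": np.int64})
    if not {"gene", "sense", "antisense"}.issubset(df.columns):
        raise ValueError("screen TSV needs columns gene, sense, antisense")
    return ScreenDataset(name or str(path), role, df.set_index("gene"))


def write_screen_tsv(ds: ScreenDataset, path) -> None:
    out = ds.counts.reset_index()
    out.columns = ["gene", "sense", "antisense"]
    out.to_csv(path, sep="\t", index=False)


def percent_sense(sense: int, antisense: int) -> float:
    """Percent of insertions in sense orientation; NaN when no insertions."""
    total = sense + antisense
    if total == 0:
        return float("nan")
    return 100.0 * sense / total


def binom_two_sided(k: np.ndarray, n: np.ndarray, p0: float) -> np.ndarray:
    """Vectorized exact two-sided binomial p-values (minlike method).

    p = sum of Binomial(n, p0) point probabilities not exceeding P(X = k)
    (with a small relative tolerance), the same convention as
    ``scipy.stats.binomtest``.  Computed grouped by n so that screens with
    tens of thousands of genes stay fast.
    """
    k = np.asarray(k, np.int64)
    n = np.asarray(n, np.int64)
    if not 0 < p0 < 1:
        raise ValueError("null sense fraction must be in (0, 1)")
    p = np.ones(len(k), float)
    rtol = 1 + 1e-7
    for nv in np.unique(n):
        if nv == 0:
            continue
        sel = n == nv
        pmf = stats.binom.pmf(np.arange(nv + 1), nv, p0)
        order = np.argsort(pmf, kind="stable")
        csum = np.cumsum(pmf[order])
        sorted_pmf = pmf[order]
        # for each observed k: total mass of outcomes with pmf <= pmf[k]*rtol
        pos = np.searchsorted(sorted_pmf, pmf[k[sel]] * rtol, side="right")
        p[sel] = np.minimum(csum[pos - 1], 1.0)
    return p


_FISHER_CACHE: dict[tuple[int, int, int, int, str], float] = {}


def _fisher(a: int, b: int, c: int, d: int, alternative: str) -> float:
    """Cached Fisher exact p; degenerate tables (a zero margin) give p = 1."""
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    key = (a, b, c, d, alternative)
    out = _FISHER_CACHE.get(key)
    if out is None:
        out = float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])
        _FISHER_CACHE[key] = out
    return out


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    return _fisher(a, b, c, d, "two-sided")


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p for sense enrichment in the first row."""
    return _fisher(a, b, c, d, "greater")


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    return multipletests(p, method="fdr_bh")[1]


def step1_binomial(ds: ScreenDataset, p0: float | str = "auto",
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene FDR-corrected binomial test for orientation bias.

    ``p0="auto"`` uses the dataset-wide sense fraction as the null.  Genes
    with zero insertions get p = q = NaN and are excluded from the BH
    correction.  ``significant`` means q < alpha; ``direction`` is "sense"
    when the gene's sense fraction exceeds p0, else "antisense".
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    c = ds.counts
    sense = c["sense"].to_numpy(np.int64)
    anti = c["antisense"].to_numpy(np.int64)
    total = sense + anti
    if p0 == "auto":
        grand = total.sum()
        if grand == 0:
            raise ValueError("dataset has no insertions; cannot set p0 automatically")
        p0 = float(sense.sum()) / grand
    if not 0 < p0 < 1:
        raise ValueError(f"null sense fraction p0={p0} outside (0, 1)")
    p = np.full(len(c), np.nan)
    q = np.full(len(c), np.nan)
    nz = total > 0
    p[nz] = binom_two_sided(sense[nz], total[nz], p0)
    if nz.any():
        q[nz] = bh_qvalues(p[nz])
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, sense / np.maximum(total, 1), np.nan)
    direction = np.where(frac > p0, "sense", "antisense")
    sig = (q < alpha) & nz
    return pd.DataFrame({
        "sense": sense, "antisense": anti, "total": total,
        "p": p, "q": q, "direction": direction, "significant": sig,
    }, index=c.index)


def step2_fisher(case: ScreenDataset, controls: list[ScreenDataset],
                 alpha: float = 0.05, genes: pd.Index | None = None) -> pd.DataFrame:
    """Two-sided Fisher test of case counts against each control, per gene.

    The shared gene universe is the union of all samples (missing genes count
    (0, 0)).  ``passes_all`` requires p < alpha versus every control.
    """
    if not controls:
        raise ValueError("at least one control dataset is required")
    if genes is None:
        genes = case.counts.index
        for ctl in controls:
            genes = genes.union(ctl.counts.index)
    cc = case.aligned(genes)
    out = pd.DataFrame(index=genes)
    passes = np.ones(len(genes), bool)
    for ctl in controls:
        tc = ctl.aligned(genes)
        pvals = np.array([
            fisher_two_sided(int(a), int(b), int(c_), int(d))
            for a, b, c_, d in zip(cc["sense"], cc["antisense"],
                                   tc["sense"], tc["antisense"])
        ])
        out[f"p_{ctl.name}"] = pvals
        passes &= pvals < alpha
    out["passes_all"] = passes
    return out


def aggregated_odds_ratio(sense_case: int, anti_case: int,
                          sense_ctl: int, anti_ctl: int) -> float:
    """Cross-product odds ratio, Haldane–Anscombe corrected on zero cells.

    Values > 1 mean relative sense enrichment in the case sample.
    """
    cells = [sense_case, anti_case, sense_ctl, anti_ctl]
    if min(cells) == 0:
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    return (a * d) / (b * c)


def aggregate_or_filter(case: ScreenDataset, controls: list[ScreenDataset],
                        or_cutoff: float = 0.7, alpha: float = 0.05,
                        genes: pd.Index | None = None) -> pd.DataFrame:
    """Odds-ratio floor and one-sided Fisher against pooled control counts.

    Controls are aggregated by element-wise summation; ``passes`` requires
    odds_ratio >= or_cutoff and a one-sided (sense-greater) Fisher p < alpha.
    The Haldane correction applies to the odds ratio only, never to p.
    """
    if not controls:
        raise ValueError("at least one control dataset is required")
    if genes is None:
        genes = case.counts.index
        for ctl in controls:
            genes = genes.union(ctl.counts.index)
    cc = case.aligned(genes)
    agg = sum(ctl.aligned(genes) for ctl in controls)
    ors = np.empty(len(genes))
    gp = np.empty(len(genes))
    for i, (a, b, c_, d) in enumerate(zip(cc["sense"], cc["antisense"],
                                          agg["sense"], agg["antisense"])):
        ors[i] = aggregated_odds_ratio(int(a), int(b), int(c_), int(d))
        gp[i] = fisher_greater(int(a), int(b), int(c_), int(d))
    return pd.DataFrame({
        "odds_ratio": ors, "greater_p": gp,
        "passes": (ors >= or_cutoff) & (gp < alpha),
    }, index=genes)


@dataclass
class ScreenParams:
    """Thresholds for fitness-enhancer classification."""

    p0: float | str = "auto"
    alpha: float = 0.05
    or_cutoff: float = 0.7


def classify_fitness_enhancers(case: ScreenDataset, controls: list[ScreenDataset],
                               params: ScreenParams = ScreenParams(),
                               full: bool = False) -> pd.DataFrame:
    """Full screen calling: step 1, step 2, OR filter, enhancer flag, ranking.

    A fitness enhancer must be (i) step-1 sense-enriched (q < alpha) in the
    case and in no control, (ii) step-2 significant versus every control, and
    (iii) pass the aggregated odds-ratio filter.  Because the flag is a
    conjunction, step-2 and OR statistics are by default evaluated only for
    genes surviving (i) (others NaN); ``full=True`` computes them everywhere.
    Result rows are ordered by aggregated one-sided p (flagged genes first).
    """
    if not controls:
        raise ValueError("at least one control dataset is required")
    genes = case.counts.index
    for ctl in controls:
        genes = genes.union(ctl.counts.index)
    if len(genes) == 0:
        cols = ["sense", "antisense", "total", "percent_sense", "step1_p",
                "step1_q", "direction", "step1_pass", "step2_pass",
                "odds_ratio", "greater_p", "or_pass", "fitness_enhancer"]
        return pd.DataFrame(columns=cols)

    def _pad(ds: ScreenDataset) -> ScreenDataset:
        return ScreenDataset(ds.name, ds.role, ds.aligned(genes))

    case_p = _pad(case)
    ctls_p = [_pad(c) for c in controls]
    s1_case = step1_binomial(case_p, params.p0, params.alpha)
    sense_enriched = s1_case["significant"] & (s1_case["direction"] == "sense")
    in_any_control = pd.Series(False, index=genes)
    for ctl in ctls_p:
        s1c = step1_binomial(ctl, params.p0, params.alpha)
        in_any_control |= s1c["significant"] & (s1c["direction"] == "sense")
    step1_pass = sense_enriched & ~in_any_control

    cand = genes if full else genes[step1_pass]
    res = pd.DataFrame(index=genes)
    res["sense"] = s1_case["sense"]
    res["antisense"] = s1_case["antisense"]
    res["total"] = s1_case["total"]
    res["percent_sense"] = [percent_sense(s, a)
                            for s, a in zip(res["sense"], res["antisense"])]
    res["step1_p"] = s1_case["p"]
    res["step1_q"] = s1_case["q"]
    res["direction"] = s1_case["direction"]
    res["step1_pass"] = step1_pass
    res["step2_pass"] = pd.NA
    res["odds_ratio"] = np.nan
    res["greater_p"] = np.nan
    res["or_pass"] = pd.NA
    if len(cand):
        case_c = ScreenDataset(case.name, "case", case_p.counts.loc[cand])
        s2 = step2_fisher(case_c, ctls_p, params.alpha, genes=cand)
        orf = aggregate_or_filter(case_c, ctls_p, params.or_cutoff,
                                  params.alpha, genes=cand)
        res.loc[cand, "step2_pass"] = s2["passes_all"]
        res.loc[cand, "odds_ratio"] = orf["odds_ratio"]
        res.loc[cand, "greater_p"] = orf["greater_p"]
        res.loc[cand, "or_pass"] = orf["passes"]
    s2 = res["step2_pass"].map(lambda v: bool(v) if v is not pd.NA else False)
    orp = res["or_pass"].map(lambda v: bool(v) if v is not pd.NA else False)
    res["fitness_enhancer"] = res["step1_pass"] & s2 & orp
    res = res.sort_values(["fitness_enhancer", "greater_p", "step1_q"],
                          ascending=[False, True, True], na_position="last",
                          kind="stable")
    return res


def fishtail_coordinates(ds: ScreenDataset) -> pd.DataFrame:
    """Per-gene (total insertions, percent sense) scatter coordinates.

    Matches the usual fishtail plot: x = total insertions (log scale when
    plotted), y = percent of insertions in sense orientation.  Genes without
    insertions are excluded.
    """
    c = ds.counts
    total = c["sense"] + c["antisense"]
    keep = total > 0
    return pd.DataFrame({
        "total": total[keep],
        "percent_sense": 100.0 * c.loc[keep, "sense"] / total[keep],
    })
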