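"""Windowed diversity statistics and variant-sharing classification.

Implements, over non-overlapping genomic windows (500 kb by default):

* nucleotide diversity π per subgroup — unbiased per-site heterozygosity
  Σ [n/(n−1)]·2·p̂(1−p̂) divided by the nominal window width in bp;
* Weir & Cockerham (1984) θ (F_ST), both "total" across all subgroups and
  pairwise per subgroup pair, aggregated as a ratio of sums of the per-site
  variance components a/(a+b+c);
* mean composite LD r² between unphased dosage vectors within a window.

Plus the variant-sharing classification: a variant is "observed" in a group
iff its alternate-allele count there is > 0; the exact set of observing
groups defines mutually exclusive private/shared categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vcfio import GenotypePanel

__all__ = [
    "FrequencyTable",
    "SharingTable",
    "allele_frequencies",
    "classify_sharing",
    "private_variants_per_accession",
    "nucleotide_diversity_windows",
    "fst_windows",
    "ld_r2_windows",
    "window_bounds",
    "WINDOW_BP",
]

WINDOW_BP = 500_000


@dataclass
class FrequencyTable:
    """Per-variant per-group alternate-allele frequencies and allele counts.

    ``freq`` and ``n_alleles`` are variants × groups DataFrames indexed by
    "chrom:pos" ids; frequency is NaN where a group has no observed alleles.
    """

    freq: pd.DataFrame
    n_alleles: pd.DataFrame

    @property
    def groups(self) -> list[str]:
        return list(self.freq.columns)

    def alt_observed(self) -> pd.DataFrame:
        """Boolean: alt-allele count > 0 in the group."""
        counts = self.freq * self.n_alleles
        return (counts.fillna(0.0) > 0.5)  # counts are integers up to rounding


@dataclass
class SharingTable:
    """Mutually exclusive sharing categories over segregating variants."""

    per_variant: pd.Series  # variant_id -> category
    category_counts: pd.Series
    private_per_group: pd.Series


def _group_dosage_stats(panel: GenotypePanel):
    """Per group: (alt freq, diploid count, het fraction) arrays over sites."""
    out = {}
    for g, idx in panel.group_indices().items():
        if idx.size == 0:
            raise ValueError(f"group {g!r} has zero samples")
        d = panel.dosages[idx]
        obs = ~np.isnan(d)
        n_ind = obs.sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            p = np.nansum(d, axis=0) / (2.0 * n_ind)
            h = np.nansum(d == 1.0, axis=0) / n_ind
        out[g] = (p, n_ind, h)
    return out


def allele_frequencies(panel: GenotypePanel) -> FrequencyTable:
    """Alt-allele frequency and allele count per variant per subgroup.

    Frequencies are computed over non-missing alleles only; a variant with
    no observed genotypes in a group gets frequency NaN (excluded
    downstream).
    """
    stats = _group_dosage_stats(panel)
    ids = panel.variant_ids().values
    freq = pd.DataFrame(
        {g: np.where(n > 0, p, np.nan) for g, (p, n, _h) in stats.items()}, index=ids
    )
    n_alleles = pd.DataFrame(
        {g: 2 * n for g, (_p, n, _h) in stats.items()}, index=ids
    )
    return FrequencyTable(freq=freq, n_alleles=n_alleles)


def classify_sharing(freqs: FrequencyTable) -> SharingTable:
    """Assign each variant to a private/shared category.

    Categories: "private-<G>" (alt observed only in G), "shared-<G1>+<G2>"
    (exactly that pair, "+"-joined in sorted order), "shared-all", and
    "absent" when no group carries the alternate allele.
    """
    groups = freqs.groups
    if len(groups) < 2:
        raise ValueError("sharing classification needs at least 2 groups")
    obs = freqs.alt_observed()

    def category(row) -> str:
        hit = [g for g in groups if row[g]]
        if not hit:
            return "absent"
        if len(hit) == 1:
            return f"private-{hit[0]}"
        if len(hit) == len(groups):
            return "shared-all"
        return "shared-" + "+".join(sorted(hit))

    per_variant = obs.apply(category, axis=1)
    per_variant.name = "category"
    counts = per_variant.value_counts()
    private = pd.Series(
        {g: int(counts.get(f"private-{g}", 0)) for g in groups}, name="private"
    )
    return SharingTable(per_variant, counts, private)


def private_variants_per_accession(panel: GenotypePanel) -> pd.Series:
    """Count, per accession, variants whose alt allele only it carries."""
    d = panel.dosages
    carrier = np.nan_to_num(d, nan=0.0) > 0
    n_carriers = carrier.sum(axis=0)
    single = n_carriers == 1
    counts = carrier[:, single].sum(axis=1)
    return pd.Series(counts, index=panel.samples, name="private_variants")


def window_bounds(positions: np.ndarray, chrom_length: int | None, w: int):
    """Tile [0, L) with non-overlapping windows of width w (last may be short).

    Returns (starts, ends, window index per 1-based position).
    """
    length = int(chrom_length) if chrom_length else int(positions.max())
    starts = np.arange(0, length, w)
    ends = np.minimum(starts + w, length)
    idx = (positions - 1) // w
    return starts, ends, idx


def _window_frame(chrom, starts, ends, w):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "partial": (ends - starts) < w,
        }
    )


def nucleotide_diversity_windows(
    panel: GenotypePanel,
    w: int = WINDOW_BP,
    chrom_length: int | None = None,
    include_indels: bool = False,
) -> pd.DataFrame:
    """Per-window per-group nucleotide diversity π (per bp).

    π = Σ_sites [n/(n−1)]·2·p̂(1−p̂) / w with p̂ and the allele count n
    group-local at each site; sites with fewer than 2 observed alleles in a
    group are skipped; monomorphic sites contribute 0.  The divisor is the
    nominal window width even for the trailing partial window.  By default
    only SNPs enter; set include_indels=True to use all variants.
    """
    frames = []
    for chrom, sub in _iter_chromosomes(panel, include_indels):
        stats = _group_dosage_stats(sub)
        pos = sub.variants["pos"].to_numpy()
        starts, ends, widx = window_bounds(pos, chrom_length, w)
        out = _window_frame(chrom, starts, ends, w)
        for g, (p, n_ind, _h) in stats.items():
            n_all = 2.0 * n_ind
            usable = n_all >= 2
            site_pi = np.zeros_like(p)
            site_pi[usable] = (
                n_all[usable] / (n_all[usable] - 1.0)
                * 2.0 * p[usable] * (1.0 - p[usable])
            )
            sums = np.bincount(widx, weights=site_pi, minlength=len(starts))
            out[f"pi_{g}"] = sums / float(w)
            any_usable = np.bincount(widx, weights=usable.astype(float),
                                     minlength=len(starts))
            out.loc[any_usable == 0, f"pi_{g}"] = np.where(
                np.bincount(widx, minlength=len(starts))[any_usable == 0] > 0,
                np.nan, 0.0,
            )
        out["n_variants"] = np.bincount(widx, minlength=len(starts)).astype(int)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def _iter_chromosomes(panel: GenotypePanel, include_indels: bool):
    keep = np.ones(panel.n_variants, dtype=bool)
    if not include_indels:
        keep = (panel.variants["vtype"] == "SNP").to_numpy()
    sub = panel.take_variants(keep)
    for chrom in pd.unique(sub.variants["chrom"]):
        yield chrom, sub.take_variants((sub.variants["chrom"] == chrom).to_numpy())


def weir_cockerham_components(p: np.ndarray, n_ind: np.ndarray, h: np.ndarray):
    """Per-site Weir & Cockerham (1984) variance components a, b, c.

    Inputs are (r groups × m sites) arrays of alt-allele frequency, observed
    diploid counts and heterozygote fractions.  Sites unusable for the
    estimator (a group without data, n̄ ≤ 1, or monomorphic across the
    compared groups) are returned with a NaN usable mask.
    """
    p = np.atleast_2d(p)
    n = np.atleast_2d(n_ind).astype(float)
    h = np.atleast_2d(h)
    r = p.shape[0]
    if r < 2:
        raise ValueError("need at least two groups")

    with np.errstate(invalid="ignore", divide="ignore"):
        s_tot = n.sum(axis=0)
        nbar = s_tot / r
        nc = (s_tot - (n ** 2).sum(axis=0) / s_tot) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / s_tot
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / s_tot

        inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0

    usable = (
        (n > 0).all(axis=0)
        & (nbar > 1.0)
        & (nc > 0)
        & (pbar > 0.0)
        & (pbar < 1.0)
    )
    return a, b, c, usable


def _theta_by_window(a, b, c, usable, widx, n_windows) -> np.ndarray:
    num = np.bincount(widx[usable], weights=a[usable], minlength=n_windows)
    den = np.bincount(
        widx[usable], weights=(a + b + c)[usable], minlength=n_windows
    )
    n_use = np.bincount(widx[usable], minlength=n_windows)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = num / den
    theta[n_use == 0] = np.nan
    return theta


def fst_windows(
    panel: GenotypePanel,
    w: int = WINDOW_BP,
    chrom_length: int | None = None,
    include_indels: bool = False,
) -> pd.DataFrame:
    """Windowed Weir–Cockerham θ: total (all groups) and per group pair.

    θ is the ratio of sums a/(a+b+c) over usable sites per window; negative
    windowed values are reported as-is (not clamped).  Windows with no
    usable site get NaN.
    """
    frames = []
    for chrom, sub in _iter_chromosomes(panel, include_indels):
        stats = _group_dosage_stats(sub)
        groups = list(stats)
        pos = sub.variants["pos"].to_numpy()
        starts, ends, widx = window_bounds(pos, chrom_length, w)
        nw = len(starts)
        out = _window_frame(chrom, starts, ends, w)

        def stack(gs):
            return (
                np.vstack([stats[g][0] for g in gs]),
                np.vstack([stats[g][1] for g in gs]),
                np.vstack([stats[g][2] for g in gs]),
            )

        a, b, c, use = weir_cockerham_components(*stack(groups))
        out["fst_total"] = _theta_by_window(a, b, c, use, widx, nw)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                pair = [groups[i], groups[j]]
                a, b, c, use = weir_cockerham_components(*stack(pair))
                out[f"fst_{groups[i]}_{groups[j]}"] = _theta_by_window(
                    a, b, c, use, widx, nw
                )
        out["n_variants"] = np.bincount(widx, minlength=nw).astype(int)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete.

    Returns NaN when fewer than 3 shared non-missing samples remain or
    either vector is constant on the shared set.
    """
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return np.nan
    xs, ys = x[ok], y[ok]
    vx, vy = xs.var(), ys.var()
    if vx == 0.0 or vy == 0.0:
        return np.nan
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_r2_windows(
    panel: GenotypePanel,
    w: int = WINDOW_BP,
    chrom_length: int | None = None,
    max_pairs: int = 10_000,
    seed: int = 0,
    include_indels: bool = False,
) -> pd.DataFrame:
    """Mean composite r² over intra-window variant pairs, per subgroup.

    All pairs are used up to ``max_pairs`` per window/group; beyond that a
    seeded uniform subsample of pairs is taken.  Pairs involving a
    zero-variance variant (within the group) are skipped.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for chrom, sub in _iter_chromosomes(panel, include_indels):
        gidx = sub.group_indices()
        pos = sub.variants["pos"].to_numpy()
        starts, ends, widx = window_bounds(pos, chrom_length, w)
        nw = len(starts)
        out = _window_frame(chrom, starts, ends, w)
        for g, rows in gidx.items():
            d = sub.dosages[rows]
            means = np.full(nw, np.nan)
            for k in range(nw):
                cols = np.flatnonzero(widx == k)
                if cols.size < 2:
                    continue
                ii, jj = np.triu_indices(cols.size, k=1)
                if ii.size > max_pairs:
                    take = rng.choice(ii.size, size=max_pairs, replace=False)
                    ii, jj = ii[take], jj[take]
                vals = [
                    pairwise_r2(d[:, cols[i]], d[:, cols[j]])
                    for i, j in zip(ii, jj)
                ]
                vals = np.asarray(vals, dtype=float)
                if np.isfinite(vals).any():
                    means[k] = np.nanmean(vals)
            out[f"r2_{g}"] = means
        out["n_variants"] = np.bincount(widx, minlength=nw).astype(int)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)
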