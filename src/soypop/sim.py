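"""Synthetic data with known ground truth for a structured inbred panel.

Generates genotypes for a three-subgroup population under the
Balding–Nichols model (per-variant subgroup allele frequencies drawn from a
Beta distribution around an ancestral frequency p with variance F·p·(1−p)),
quantitative phenotypes with known causal variants and heritability, SV call
sets, CNV window read counts, and toy gene models with a reference sequence.
Every generator takes an explicit seed and is bit-reproducible; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vcfio import GenotypePanel
from .effects import GeneModel

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_structured_genotypes",
    "simulate_phenotype",
    "simulate_sv_calls",
    "simulate_window_read_counts",
    "simulate_gene_models",
    "SV_TYPES",
]

SV_TYPES = ("INS", "DEL", "DUP", "INV", "TRA", "INVDUP")

DEFAULT_GROUPS = ("Primitive", "World", "Japan")

# nucleotides used for synthetic ref/alt labels at SNP sites
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the structured-population genotype generator.

    F is the Balding–Nichols differentiation parameter (per subgroup or a
    single value for all); rho is the probability that a haplotype copies
    its allele state from the adjacent upstream site, inducing LD decaying
    geometrically with inter-site index distance (0 = independent sites).
    maf_law gives the ancestral-frequency distribution as
    ("uniform", lo, hi); the default Uniform(0.05, 0.95) guarantees
    polymorphism at desk scale.
    """

    n_per_group: int = 50
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_variants: int = 20_000
    chrom: str = "Chr01"
    chrom_length: int = 50_000_000
    F: float | dict[str, float] = 0.1
    maf_law: tuple = ("uniform", 0.05, 0.95)
    rho: float = 0.0
    missing_rate: float = 0.02
    n_causal: int = 10
    h2: float = 0.5
    effect_sd: float = 1.0
    seed: int = 0

    def f_for(self, group: str) -> float:
        return self.F[group] if isinstance(self.F, dict) else self.F

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for g in self.groups:
            f = self.f_for(g)
            if not 0.0 < f < 1.0:
                raise ValueError(f"F for group {g!r} must lie in (0, 1), got {f}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.n_variants > self.chrom_length:
            raise ValueError("more variants than base pairs")
        if self.maf_law[0] != "uniform":
            raise ValueError(f"unknown maf_law {self.maf_law[0]!r}")


@dataclass
class SimTruth:
    """Ground truth recorded by the generators for recovery tests."""

    group_labels: dict[str, str]
    ancestral_freqs: np.ndarray
    subpop_freqs: pd.DataFrame  # columns = groups, rows = variants
    causal_sites: list[str] = field(default_factory=list)  # "chrom:pos" ids
    effect_sizes: np.ndarray = field(default_factory=lambda: np.empty(0))
    h2: float = 0.0
    cnv_segments: list[tuple[str, int, int, int]] = field(default_factory=list)


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n strictly increasing positions in 1..length without a full permutation."""
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 10))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_structured_genotypes(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Balding–Nichols genotypes for a structured diploid panel.

    Per variant: ancestral frequency p ~ maf_law; each subgroup frequency
    ~ Beta(p(1−F)/F, (1−p)(1−F)/F) (mean p, variance F·p·(1−p)), clipped to
    [0.001, 0.999]; haplotypes drawn per site with first-order copying (with
    probability rho the haplotype repeats its previous site's allele state);
    diploid dosages are haplotype pair sums; genotypes masked missing
    uniformly at missing_rate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_variants

    positions = _draw_positions(rng, m, config.chrom_length)
    _, lo, hi = config.maf_law
    p_anc = rng.uniform(lo, hi, size=m)

    subpop = {}
    for g in config.groups:
        f = config.f_for(g)
        a = p_anc * (1.0 - f) / f
        b = (1.0 - p_anc) * (1.0 - f) / f
        subpop[g] = np.clip(rng.beta(a, b), 0.001, 0.999)

    hap_blocks = []
    samples: list[str] = []
    labels: dict[str, str] = {}
    for g in config.groups:
        n_hap = 2 * config.n_per_group
        pg = subpop[g]
        if config.rho == 0.0:
            haps = rng.random((n_hap, m)) < pg
        else:
            haps = np.empty((n_hap, m), dtype=bool)
            haps[:, 0] = rng.random(n_hap) < pg[0]
            for j in range(1, m):
                fresh = rng.random(n_hap) < pg[j]
                copy = rng.random(n_hap) < config.rho
                haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
        hap_blocks.append(haps)
        names = [f"{g}_{i + 1:03d}" for i in range(config.n_per_group)]
        samples.extend(names)
        labels.update({s: g for s in names})

    haps = np.concatenate(hap_blocks, axis=0)
    dosages = (haps[0::2].astype(float) + haps[1::2].astype(float))
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    variants = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": positions,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "vtype": "SNP",
        }
    )
    panel = GenotypePanel(samples, variants, dosages, groups=labels)

    n_causal = min(config.n_causal, m)
    causal_idx = np.sort(rng.choice(m, size=n_causal, replace=False))
    ids = panel.variant_ids()
    truth = SimTruth(
        group_labels=labels,
        ancestral_freqs=p_anc,
        subpop_freqs=pd.DataFrame(subpop),
        causal_sites=[ids.iloc[j] for j in causal_idx],
        effect_sizes=rng.normal(0.0, config.effect_sd, size=n_causal),
        h2=config.h2,
    )
    return panel, truth


def simulate_phenotype(
    panel: GenotypePanel,
    truth: SimTruth,
    seed: int,
    polygenic_frac: float = 0.0,
) -> np.ndarray:
    """Quantitative phenotype y = Σ β_j·dosage_j (+ polygenic) + noise.

    The residual variance is set from the realized genetic variance so that
    the phenotypic variance fraction explained by the genetic value equals
    ``truth.h2``.  ``polygenic_frac`` is the fraction of genetic variance
    contributed by a GRM-distributed background term (g ~ N(0, K) scaled).
    h2 = 0 yields pure noise; h2 = 1 returns the genetic value exactly.
    """
    if not 0.0 <= polygenic_frac <= 1.0:
        raise ValueError("polygenic_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = panel.n_samples

    ids = pd.Index(panel.variant_ids())
    idx = []
    for site in truth.causal_sites:
        j = ids.get_indexer([site])
        if j[0] < 0:
            raise KeyError(f"causal site {site!r} absent from panel")
        idx.append(j[0])

    d = panel.dosages
    if np.isnan(d).any():
        col_means = np.nanmean(d, axis=0)
        d = np.where(np.isnan(d), col_means[None, :], d)

    g = np.zeros(n)
    if idx:
        g = d[:, idx] @ np.asarray(truth.effect_sizes, dtype=float)

    if polygenic_frac > 0.0:
        from .gwas import compute_grm

        K = compute_grm(panel).matrix
        L = np.linalg.cholesky(K + 1e-6 * np.eye(n))
        u = L @ rng.normal(size=n)
        var_c = g.var() if g.var() > 0 else 1.0
        target = polygenic_frac / (1.0 - polygenic_frac) * var_c if polygenic_frac < 1 else None
        if target is None:
            g = u  # fully polygenic
        elif u.var() > 0:
            g = g + u * np.sqrt(target / u.var())

    h2 = truth.h2
    if h2 == 0.0 or g.var() == 0.0:
        return rng.normal(0.0, 1.0, size=n)
    var_e = g.var() * (1.0 - h2) / h2
    return g + rng.normal(0.0, np.sqrt(var_e), size=n)


def simulate_sv_calls(
    accessions: list[str],
    rates: dict[str, float],
    genome_length: int = 50_000_000,
    length_law: tuple = ("loguniform", 50, 100_000),
    chrom: str = "Chr01",
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson SV call set: per accession and type, count ~ Poisson(rate·G).

    ``rates`` maps SVTYPE → events per bp.  Lengths follow ``length_law``
    ("loguniform", lo, hi).  Returns a DataFrame with columns
    accession, chrom, pos, svtype, svlen, end (svlen stored absolute).
    """
    unknown = set(rates) - set(SV_TYPES)
    if unknown:
        raise ValueError(f"unknown SVTYPE(s) in rate spec: {sorted(unknown)}")
    if any(r < 0 for r in rates.values()):
        raise ValueError("SV rates must be >= 0")
    law, lo, hi = length_law
    if law != "loguniform":
        raise ValueError(f"unknown length law {law!r}")

    rng = np.random.default_rng(seed)
    rows = []
    for acc in accessions:
        for svtype in SV_TYPES:
            rate = rates.get(svtype, 0.0)
            k = rng.poisson(rate * genome_length)
            if k == 0:
                continue
            pos = rng.integers(1, genome_length + 1, size=k)
            svlen = np.exp(rng.uniform(np.log(lo), np.log(hi), size=k)).astype(int)
            svlen = np.maximum(svlen, 1)
            for p, ln in zip(pos, svlen):
                rows.append((acc, chrom, int(p), svtype, int(ln), int(p + ln)))
    df = pd.DataFrame(
        rows, columns=["accession", "chrom", "pos", "svtype", "svlen", "end"]
    )
    return df.sort_values(["accession", "chrom", "pos"], ignore_index=True)


def simulate_window_read_counts(
    cnv_segments: list[tuple[str, int, int, int]],
    mean_depth: float = 30.0,
    window: int = 100_000,
    read_length: int = 100,
    chrom: str = "Chr01",
    chrom_length: int = 5_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired test/reference window read counts for the CNV ratio test.

    Reference counts ~ Poisson(λ) with λ = mean_depth·window/read_length
    (reads needed to cover the window at the given depth); test counts
    ~ Poisson(λ·c/2) with c the local copy number from ``cnv_segments``
    (tuples chrom,start,end,copy_number; 1-based inclusive; default c=2).
    Returns columns chrom, start, end (0-based half-open), copy_number,
    test_count, ref_count.
    """
    for seg in cnv_segments:
        if seg[3] < 0:
            raise ValueError(f"copy number must be >= 0: {seg}")
    rng = np.random.default_rng(seed)
    lam = mean_depth * window / read_length

    starts = np.arange(0, chrom_length, window)
    ends = np.minimum(starts + window, chrom_length)
    cn = np.full(starts.size, 2.0)
    for seg_chrom, s, e, c in cnv_segments:
        if seg_chrom != chrom:
            continue
        hit = (starts < e) & (ends > s - 1)  # windows overlapping the segment
        cn[hit] = c

    scale = ends - starts
    lam_w = lam * scale / window
    ref = rng.poisson(lam_w)
    test = rng.poisson(lam_w * cn / 2.0)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "copy_number": cn.astype(int),
            "test_count": test,
            "ref_count": ref,
        }
    )


_CODONS_NO_STOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOPS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def simulate_gene_models(
    n_genes: int,
    seed: int = 0,
    chrom: str = "Chr01",
) -> tuple[dict[str, str], list[GeneModel]]:
    """Toy reference sequence plus gene models with UTR/exon/intron/CDS.

    Each gene has 1–4 exons, a CDS starting with ATG and ending in a stop
    codon (length divisible by 3, no internal stops), UTRs on both ends and
    introns of >= 30 bp; about half the genes sit on the minus strand.
    Returns ({chrom: sequence}, [GeneModel...]) with 1-based inclusive
    coordinates.
    """
    rng = np.random.default_rng(seed)
    pieces: list[str] = []
    genes: list[GeneModel] = []
    cursor = 0  # 0-based length of assembled sequence so far

    def rand_seq(k: int) -> str:
        return "".join(_BASES[rng.integers(0, 4, size=k)])

    for i in range(n_genes):
        gap = int(rng.integers(100, 500))
        pieces.append(rand_seq(gap))
        cursor += gap

        n_codons = int(rng.integers(30, 101))
        cds_seq = (
            "ATG"
            + "".join(rng.choice(_CODONS_NO_STOP, size=n_codons))
            + str(rng.choice(_STOPS))
        )
        utr5 = rand_seq(int(rng.integers(10, 51)))
        utr3 = rand_seq(int(rng.integers(10, 51)))
        transcript = utr5 + cds_seq + utr3
        t_len = len(transcript)
        cds_lo, cds_hi = len(utr5), len(utr5) + len(cds_seq)  # [lo, hi)

        n_exons = int(rng.integers(1, 5))
        # exon cut points within the transcript, each exon >= 5 bp
        while True:
            cuts = np.sort(rng.integers(5, t_len - 4, size=n_exons - 1)) if n_exons > 1 else np.array([], dtype=int)
            bounds = np.concatenate([[0], cuts, [t_len]])
            if np.all(np.diff(bounds) >= 5):
                break
        intron_lens = rng.integers(30, 200, size=n_exons - 1)

        # lay out gene on the plus orientation first (relative coords)
        rel_exons: list[tuple[int, int]] = []  # [start, end) relative
        gene_seq_parts: list[str] = []
        offset = 0
        for k in range(n_exons):
            ex_seq = transcript[bounds[k]: bounds[k + 1]]
            rel_exons.append((offset, offset + len(ex_seq)))
            gene_seq_parts.append(ex_seq)
            offset += len(ex_seq)
            if k < n_exons - 1:
                gene_seq_parts.append(rand_seq(int(intron_lens[k])))
                offset += int(intron_lens[k])
        gene_seq = "".join(gene_seq_parts)
        g_len = len(gene_seq)

        # CDS sub-intervals: intersect transcript CDS range with exon chunks
        rel_cds: list[tuple[int, int]] = []
        for k, (gs, ge) in enumerate(rel_exons):
            ts, te = bounds[k], bounds[k + 1]
            lo = max(ts, cds_lo)
            hi = min(te, cds_hi)
            if lo < hi:
                rel_cds.append((gs + (lo - ts), gs + (hi - ts)))

        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            gene_seq = _revcomp(gene_seq)
            rel_exons = [(g_len - e, g_len - s) for s, e in rel_exons][::-1]
            rel_cds = [(g_len - e, g_len - s) for s, e in rel_cds][::-1]

        base = cursor  # 0-based genomic offset of the gene
        exons = [(base + s + 1, base + e) for s, e in rel_exons]  # 1-based incl.
        cds = [(base + s + 1, base + e) for s, e in rel_cds]
        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1:04d}",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds=cds,
            )
        )
        pieces.append(gene_seq)
        cursor += g_len

    pieces.append(rand_seq(int(rng.integers(100, 500))))
    return {chrom: "".join(pieces)}, genes
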