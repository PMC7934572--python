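"""Genotype container, VCF input/output, GWAS-side filtering and imputation.

The central in-memory object is :class:`GenotypePanel`: an accessions ×
biallelic-variants dosage matrix (0/1/2 counts of the alternate allele,
``NaN`` for missing) with per-variant chromosome/position/allele metadata and
optional sample→subgroup labels.  All downstream statistics consume this
panel.  Coordinates are 1-based inclusive externally (VCF convention);
windowed statistics convert to 0-based half-open internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "GenotypePanel",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "filter_variants",
    "impute_missing",
    "read_group_table",
    "read_phenotype_table",
    "aggregate_chromosome_counts",
]


def _variant_type(ref: str, alt: str) -> str:
    return "SNP" if len(ref) == 1 and len(alt) == 1 else "INDEL"


@dataclass
class GenotypePanel:
    """Samples × biallelic variants dosage matrix with variant metadata.

    Parameters
    ----------
    samples
        Ordered accession identifiers (rows of ``dosages``).
    variants
        DataFrame with columns ``chrom, pos, ref, alt, vtype`` (``pos``
        1-based; ``vtype`` in {"SNP", "INDEL"}), one row per stored variant,
        positions non-decreasing within each chromosome.
    dosages
        float array, shape ``(n_samples, n_variants)``; entries in
        {0, 1, 2} or NaN (missing).  Fractional entries only appear after
        imputation.
    groups
        Optional mapping sample → subgroup label (e.g. "Primitive",
        "World", "Japan").
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> pd.Series:
        v = self.variants
        return v["chrom"].astype(str) + ":" + v["pos"].astype(str)

    def missing_fraction(self) -> np.ndarray:
        """Per-variant fraction of missing genotype calls."""
        return np.mean(np.isnan(self.dosages), axis=0)

    def alt_freq(self) -> np.ndarray:
        """Per-variant alternate-allele frequency over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def group_indices(self) -> dict[str, np.ndarray]:
        """Row indices per subgroup, in group-label sorted order."""
        if self.groups is None:
            raise ValueError("panel has no subgroup labels")
        out: dict[str, np.ndarray] = {}
        for g in sorted(set(self.groups.values())):
            idx = np.array(
                [i for i, s in enumerate(self.samples) if self.groups.get(s) == g],
                dtype=int,
            )
            out[g] = idx
        return out

    def take_variants(self, mask_or_index) -> "GenotypePanel":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def is_complete(self) -> bool:
        return not np.isnan(self.dosages).any()


@dataclass
class FilterReport:
    """Accounting of a variant-filtering pass; counts partition the input."""

    input_count: int
    removed_maf: int = 0
    removed_missing: int = 0
    removed_multiallelic: int = 0
    retained_count: int = 0

    def __post_init__(self) -> None:
        total = (
            self.removed_maf
            + self.removed_missing
            + self.removed_multiallelic
            + self.retained_count
        )
        if total != self.input_count:
            raise ValueError(
                f"filter counts {total} do not partition input {self.input_count}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "input",
                    "removed_maf",
                    "removed_missing",
                    "removed_multiallelic",
                    "retained",
                ],
                "count": [
                    self.input_count,
                    self.removed_maf,
                    self.removed_missing,
                    self.removed_multiallelic,
                    self.retained_count,
                ],
            }
        )


def read_vcf(path: str, groups: dict[str, str] | None = None) -> tuple[GenotypePanel, int]:
    """Read a VCF 4.x with GT fields into a :class:`GenotypePanel`.

    Multiallelic records are dropped (and counted); half-calls (e.g. ``1/.``)
    are treated as missing.  Returns ``(panel, n_multiallelic_dropped)``.
    """
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path!r}: {exc}") from exc
    samples = list(vf.header.samples)
    if not samples:
        raise ValueError(f"VCF {path!r} contains no samples")

    rows = []
    cols = []
    n_multi = 0
    record_no = 0
    try:
        for rec in vf:
            record_no += 1
            alts = rec.alts or ()
            if len(alts) != 1:
                n_multi += 1
                continue
            dos = np.full(len(samples), np.nan)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT", (None, None))
                if gt is None or any(a is None for a in gt):
                    continue  # missing or half-call
                dos[i] = float(sum(gt))
            rows.append((rec.chrom, rec.pos, rec.ref, alts[0],
                         _variant_type(rec.ref, alts[0])))
            cols.append(dos)
    except (OSError, ValueError) as exc:
        raise ValueError(
            f"malformed VCF record near record {record_no + 1} in {path!r}: {exc}"
        ) from exc
    finally:
        vf.close()

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vtype"])
    dosages = (
        np.array(cols).T if cols else np.empty((len(samples), 0))
    )
    return GenotypePanel(samples, variants, dosages, groups=groups), n_multi


def write_vcf(panel: GenotypePanel, path: str) -> None:
    """Write a panel as a minimal VCF 4.2 with GT genotypes.

    Requires integer dosages (imputed fractional dosages have no GT
    representation).  Missing entries are written as ``./.``.
    """
    d = panel.dosages
    finite = d[~np.isnan(d)]
    if finite.size and not np.all(finite == np.round(finite)):
        raise ValueError("cannot write fractional (imputed) dosages as GT")

    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for chrom in pd.unique(panel.variants["chrom"]):
        sub = panel.variants.loc[panel.variants["chrom"] == chrom]
        length = int(sub["pos"].max()) + int(sub["ref"].str.len().max()) + 1
        header.contigs.add(str(chrom), length=length)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in panel.samples:
        header.add_sample(s)

    gt_codes = {0.0: (0, 0), 1.0: (0, 1), 2.0: (1, 1)}
    with pysam.VariantFile(path, "w", header=header) as out:
        for j, row in panel.variants.iterrows():
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                alleles=(row["ref"], row["alt"]),
            )
            for i, s in enumerate(panel.samples):
                v = d[i, j]
                if np.isnan(v):
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = gt_codes[v]
            out.write(rec)


def filter_variants(
    panel: GenotypePanel,
    maf_min: float = 0.025,
    missing_max: float = 0.05,
) -> tuple[GenotypePanel, FilterReport]:
    """Apply the GWAS-side variant filters.

    A variant is retained iff MAF >= ``maf_min`` (computed over non-missing
    dosages) AND missing fraction <= ``missing_max``.  Boundary values are
    retained.  A variant failing both criteria is counted once, under the MAF
    removal (fixed precedence).
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    if not 0.0 <= missing_max <= 1.0:
        raise ValueError("missing_max must lie in [0, 1]")

    maf = panel.maf()
    miss = panel.missing_fraction()
    with np.errstate(invalid="ignore"):
        fail_maf = maf < maf_min  # NaN MAF (all-missing) compares False
        fail_missing = miss > missing_max
    keep = ~(fail_maf | fail_missing)

    report = FilterReport(
        input_count=panel.n_variants,
        removed_maf=int(np.sum(fail_maf)),
        removed_missing=int(np.sum(fail_missing & ~fail_maf)),
        retained_count=int(np.sum(keep)),
    )
    if report.retained_count == 0 and panel.n_variants > 0:
        warnings.warn("all variants removed by filtering; panel is empty")
    return panel.take_variants(keep), report


def impute_missing(panel: GenotypePanel, mode: str = "mean") -> GenotypePanel:
    """Fill missing dosages per variant.

    mode "mean": missing → mean dosage of non-missing samples (fractional).
    mode "major": missing → most frequent observed dosage class (ties go to
    the lower dosage).
    """
    if mode not in ("mean", "major"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    d = panel.dosages.copy()
    miss = np.isnan(d)
    if not miss.any():
        return replace(panel, dosages=d)

    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = panel.variant_ids()[all_missing].tolist()
        raise ValueError(f"cannot impute variants with no observed genotypes: {bad}")

    for j in np.flatnonzero(miss.any(axis=0)):
        obs = d[~miss[:, j], j]
        if mode == "mean":
            fill = float(obs.mean())
        else:
            classes, counts = np.unique(obs, return_counts=True)
            fill = float(classes[np.argmax(counts)])
        d[miss[:, j], j] = fill
    return replace(panel, dosages=d)


def read_group_table(path: str) -> dict[str, str]:
    """Read a sample→subgroup TSV (columns: sample_id, subgroup)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("group table needs two columns: sample_id, subgroup")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_phenotype_table(path: str) -> pd.Series:
    """Read a phenotype TSV (columns: sample_id, value) into a Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("phenotype table needs two columns: sample_id, value")
    return pd.Series(df.iloc[:, 1].astype(float).values, index=df.iloc[:, 0].astype(str))


def aggregate_chromosome_counts(table: pd.DataFrame) -> pd.Series:
    """Sum per-chromosome variant-count columns into genome-wide totals.

    Expects one row per chromosome and integer count columns (e.g.
    ``filtered_snp``, ``filtered_indel``); returns the column sums plus a
    ``filtered_total`` (and ``raw_total``) convenience entry when both class
    columns are present.
    """
    num = table.select_dtypes("number")
    totals = num.sum(axis=0).astype(int)
    for stem in ("raw", "filtered"):
        snp, ind = f"{stem}_snp", f"{stem}_indel"
        if snp in totals.index and ind in totals.index:
            totals[f"{stem}_total"] = totals[snp] + totals[ind]
    return totals
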