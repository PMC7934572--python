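"""Codon-aware variant-effect classification against gene models.

A lightweight per-variant classifier in the spirit of SnpEff: each variant
is located against canonical gene models (one transcript per gene) and
assigned an effect term, an impact class (High/Moderate/Low/Modifier) and,
for coding SNVs and stop events, a functional class
(Nonsense/Missense/Silent).  Coding SNVs are resolved by mutating the
affected codon and translating with the standard nuclear code; CDS indels
are frameshift when the length change is not a multiple of three.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "EffectCall",
    "annotate_variant",
    "annotate_panel",
    "summarize_impacts",
    "functional_class_summary",
    "write_gff3",
    "read_gff3",
    "write_fasta",
    "read_fasta",
    "IMPACT_OF_EFFECT",
    "FUNCTIONAL_CLASS_OF_EFFECT",
]

IMPACT_OF_EFFECT = {
    "stop_gained": "High",
    "stop_lost": "High",
    "start_lost": "High",
    "frameshift": "High",
    "splice_site": "High",
    "missense": "Moderate",
    "inframe_indel": "Moderate",
    "synonymous": "Low",
    "intronic": "Modifier",
    "UTR": "Modifier",
    "intergenic": "Modifier",
}

# functional classes apply to coding SNVs and stop events only
FUNCTIONAL_CLASS_OF_EFFECT = {
    "stop_gained": "Nonsense",
    "stop_lost": "Missense",
    "start_lost": "Missense",
    "missense": "Missense",
    "synonymous": "Silent",
}

_SEVERITY = {"High": 0, "Moderate": 1, "Low": 2, "Modifier": 3}

SPLICE_WINDOW = 2  # bp into the intron on each side

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class GeneModel:
    """Canonical transcript of a gene: exon and CDS intervals plus strand.

    Intervals are 1-based inclusive, stored in ascending genomic order.
    Concatenated CDS length must be divisible by 3.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        for a, b in self.exons + self.cds:
            if a > b:
                raise ValueError(f"empty interval ({a},{b}) in {self.gene_id}")
        if self.cds_length() % 3 != 0:
            raise ValueError(
                f"CDS length {self.cds_length()} of {self.gene_id} not divisible by 3"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    def cds_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases in translation order."""
        pos = np.concatenate(
            [np.arange(a, b + 1) for a, b in self.cds]
        ) if self.cds else np.empty(0, dtype=int)
        return pos[::-1] if self.strand == "-" else pos

    def cds_sequence(self, reference: dict[str, str]) -> str:
        seq = "".join(
            reference[self.chrom][a - 1: b] for a, b in self.cds
        )
        if self.strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        return seq


@dataclass
class EffectCall:
    variant_id: str
    gene_id: str | None
    effect: str
    impact: str
    functional_class: str | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    def __post_init__(self) -> None:
        if IMPACT_OF_EFFECT[self.effect] != self.impact:
            raise ValueError(
                f"impact {self.impact!r} inconsistent with effect {self.effect!r}"
            )


def _splice_regions(gene: GeneModel) -> list[tuple[int, int]]:
    """2-bp intronic windows flanking each exon junction."""
    regions = []
    for (a1, b1), (a2, _b2) in zip(gene.exons, gene.exons[1:]):
        regions.append((b1 + 1, min(b1 + SPLICE_WINDOW, a2 - 1)))
        regions.append((max(a2 - SPLICE_WINDOW, b1 + 1), a2 - 1))
    return regions


def _in_any(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(a <= pos <= b for a, b in intervals)


def _annotate_in_gene(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene: GeneModel,
    reference: dict[str, str],
    variant_id: str,
) -> EffectCall:
    def call(effect: str, **kw) -> EffectCall:
        return EffectCall(
            variant_id=variant_id,
            gene_id=gene.gene_id,
            effect=effect,
            impact=IMPACT_OF_EFFECT[effect],
            functional_class=FUNCTIONAL_CLASS_OF_EFFECT.get(effect),
            **kw,
        )

    is_snv = len(ref) == 1 and len(alt) == 1
    if _in_any(pos, _splice_regions(gene)):
        return call("splice_site")
    in_cds = _in_any(pos, gene.cds)
    if not in_cds:
        if _in_any(pos, gene.exons):
            return call("UTR")
        return call("intronic")

    if not is_snv:
        # indel inside CDS: net length change decides the frame effect
        delta = abs(len(alt) - len(ref))
        return call("frameshift" if delta % 3 != 0 else "inframe_indel")

    cds_pos = gene.cds_positions()
    idx = int(np.flatnonzero(cds_pos == pos)[0])
    codon_i = idx // 3
    codon_pos = cds_pos[3 * codon_i: 3 * codon_i + 3]
    seq = reference[chrom]

    def base_at(p: int) -> str:
        b = seq[p - 1]
        return b.translate(_COMPLEMENT) if gene.strand == "-" else b

    ref_codon = "".join(base_at(p) for p in codon_pos)
    alt_base = alt.translate(_COMPLEMENT) if gene.strand == "-" else alt
    within = idx - 3 * codon_i
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]

    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    kw = dict(ref_codon=ref_codon, alt_codon=alt_codon, ref_aa=ref_aa, alt_aa=alt_aa)

    if ref_aa != "*" and alt_aa == "*":
        return call("stop_gained", **kw)
    if ref_aa == "*" and alt_aa != "*":
        return call("stop_lost", **kw)
    if codon_i == 0 and ref_aa == "M" and alt_aa != "M":
        return call("start_lost", **kw)
    if ref_aa == alt_aa:
        return call("synonymous", **kw)
    return call("missense", **kw)


def annotate_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene_models: list[GeneModel],
    reference: dict[str, str],
) -> EffectCall:
    """Classify one variant against gene models (most severe call wins).

    ``pos`` is 1-based; the variant's ref allele must match the reference
    sequence.  Overlapping genes are resolved by impact severity
    High > Moderate > Low > Modifier, ties by lowest gene id.
    """
    if chrom not in reference:
        raise ValueError(f"chromosome {chrom!r} absent from reference")
    observed = reference[chrom][pos - 1: pos - 1 + len(ref)].upper()
    if observed != ref.upper():
        raise ValueError(
            f"ref allele mismatch at {chrom}:{pos}: VCF says {ref!r}, "
            f"reference has {observed!r}"
        )
    variant_id = f"{chrom}:{pos}"

    calls = [
        _annotate_in_gene(chrom, pos, ref, alt, g, reference, variant_id)
        for g in gene_models
        if g.chrom == chrom and g.start <= pos <= g.end
    ]
    if not calls:
        return EffectCall(variant_id, None, "intergenic", "Modifier")
    return min(calls, key=lambda c: (_SEVERITY[c.impact], c.gene_id))


def annotate_panel(panel, gene_models, reference) -> list[EffectCall]:
    """Annotate every variant of a GenotypePanel."""
    return [
        annotate_variant(row.chrom, int(row.pos), row.ref, row.alt,
                         gene_models, reference)
        for row in panel.variants.itertuples()
    ]


def functional_class_summary(counts: dict[str, int]) -> pd.Series:
    """Total and one-decimal percentage shares of functional-class counts.

    Input maps class name (Nonsense/Missense/Silent) to a count; the output
    Series holds the per-class counts, ``total`` and ``<class>_pct`` shares.
    """
    total = int(sum(counts.values()))
    out = {k: int(v) for k, v in counts.items()}
    out["total"] = total
    for k, v in counts.items():
        out[f"{k}_pct"] = round(100.0 * v / total, 1) if total else 0.0
    return pd.Series(out)


def summarize_impacts(
    calls: list[EffectCall],
    sharing: pd.Series | None = None,
) -> dict[str, pd.DataFrame | pd.Series]:
    """Contingency counts of impact × sharing category plus class totals.

    ``sharing`` maps variant_id → sharing category; variants without an
    entry are pooled under "all".  Returns a dict with the impact table,
    effect-term counts and the functional-class summary
    (Nonsense + Missense + Silent total and percentages).
    """
    df = pd.DataFrame(
        {
            "variant_id": [c.variant_id for c in calls],
            "impact": [c.impact for c in calls],
            "effect": [c.effect for c in calls],
            "functional_class": [c.functional_class for c in calls],
        }
    )
    if sharing is not None:
        df["sharing"] = df["variant_id"].map(sharing).fillna("all")
    else:
        df["sharing"] = "all"

    impacts = ["High", "Moderate", "Low", "Modifier"]
    impact_table = (
        df.pivot_table(index="impact", columns="sharing", aggfunc="size", fill_value=0)
        .reindex(impacts, fill_value=0)
        if len(df)
        else pd.DataFrame(index=pd.Index(impacts, name="impact"))
    )
    fc_counts = (
        df["functional_class"].dropna().value_counts().to_dict() if len(df) else {}
    )
    for k in ("Nonsense", "Missense", "Silent"):
        fc_counts.setdefault(k, 0)
    return {
        "impact_by_sharing": impact_table,
        "effect_counts": df["effect"].value_counts() if len(df) else pd.Series(dtype=int),
        "functional_classes": functional_class_summary(fc_counts),
    }


# ---------------------------------------------------------------------------
# GFF3 / FASTA round trip

def write_fasta(reference: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in reference.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_gff3(genes: list[GeneModel], path: str) -> None:
    """Emit gene/mRNA/exon/CDS (and UTR) features as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gid, mid = g.gene_id, f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tsoypop\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{g.chrom}\tsoypop\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={gid}\n"
            )
            for a, b in g.exons:
                fh.write(
                    f"{g.chrom}\tsoypop\texon\t{a}\t{b}\t.\t{g.strand}\t.\tParent={mid}\n"
                )
            for a, b in g.cds:
                fh.write(
                    f"{g.chrom}\tsoypop\tCDS\t{a}\t{b}\t.\t{g.strand}\t0\t"
                    f"ID=cds.{mid};Parent={mid}\n"
                )


def read_gff3(path: str) -> list[GeneModel]:
    """Parse GFF3 gene models (one canonical mRNA per gene) via gffutils."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else gene
        exons = [(f.start, f.end) for f in db.children(parent, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(parent, featuretype="CDS")]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=exons or [(gene.start, gene.end)],
                cds=cds,
            )
        )
    return sorted(genes, key=lambda g: (g.chrom, g.start))
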