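"""Cross-family aggregation of per-family retained variant sets.

Combines the outputs of the per-family filter cascade into the study-level
products: a gene-sharing table (which genes harbour retained variants in
several families, and whether the identical variant recurs), a sharing
census over family-count thresholds, and a cohort summary report
(consequence-class breakdown, population-frequency bins, per-chromosome and
per-family counts, and the private-gene share).
"""
from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Mapping, Sequence

import pandas as pd

from .cohort import AnnotatedVariant, Consequence, VariantKey
from .util import pct_half_up

__all__ = [
    "GeneSharingTable",
    "SummaryReport",
    "MAF_BINS",
    "maf_bin",
    "build_sharing_table",
    "sharing_census",
    "summarize",
    "read_retained_tsv",
    "write_retained_tsv",
]

#: Population-frequency bins, half-open upward so no variant is counted
#: twice: novel (no population record), [0, 0.001), [0.001, 0.01),
#: and [0.01, threshold).
MAF_BINS = ("novel", "<0.001", "0.001-0.01", "0.01-0.05")


def maf_bin(pop_af: float | None) -> str:
    if pop_af is None:
        return "novel"
    if pop_af < 0.001:
        return "<0.001"
    if pop_af < 0.01:
        return "0.001-0.01"
    return "0.01-0.05"


@dataclass
class GeneSharingTable:
    """Gene -> families with a retained variant, plus identical-variant flags.

    ``identical_variant[gene]`` is True when one exact variant
    (chrom, pos, ref, alt) was retained in at least two distinct families —
    the strictest reading of "same variant across families".
    """

    families_by_gene: dict[str, frozenset[str]]
    identical_variant: dict[str, bool]

    @property
    def genes(self) -> set[str]:
        return set(self.families_by_gene)

    def n_families(self, gene: str) -> int:
        return len(self.families_by_gene[gene])


def build_sharing_table(
    per_family_retained: Mapping[str, Sequence[AnnotatedVariant]],
) -> GeneSharingTable:
    """Aggregate retained variants into the gene-sharing table.

    Sharing counts distinct families: two retained variants in one gene in
    one family still count that family once.
    """
    families_by_gene: dict[str, set[str]] = {}
    families_by_key: dict[VariantKey, set[str]] = {}
    gene_of_key: dict[VariantKey, str] = {}
    for family_id, variants in per_family_retained.items():
        for v in variants:
            families_by_gene.setdefault(v.gene, set()).add(family_id)
            families_by_key.setdefault(v.key, set()).add(family_id)
            gene_of_key[v.key] = v.gene
    identical = {gene: False for gene in families_by_gene}
    for key, fams in families_by_key.items():
        if len(fams) >= 2:
            identical[gene_of_key[key]] = True
    return GeneSharingTable(
        families_by_gene={g: frozenset(f) for g, f in families_by_gene.items()},
        identical_variant=identical,
    )


def sharing_census(
    table: GeneSharingTable, thresholds: Sequence[int] = (2, 3, 4, 5)
) -> dict[int, int]:
    """Count genes shared by at least t families, for each threshold t."""
    counts = {}
    for t in thresholds:
        counts[t] = sum(
            1 for fams in table.families_by_gene.values() if len(fams) >= t
        )
    return counts


@dataclass
class SummaryReport:
    """Cohort-level tallies over all retained variants.

    Percentages are computed on the unrounded ratios and then rounded
    half-up to the printed precision: integer percent for consequence and
    frequency-bin shares, one decimal for the private-gene share.
    """

    consequence_counts: dict[Consequence, int]
    consequence_pct: dict[Consequence, float]
    maf_bin_counts: dict[str, int]
    maf_bin_pct: dict[str, float]
    chrom_counts: dict[str, int]
    per_family_counts: dict[str, int]
    median_per_family: float
    total_variants: int
    total_genes: int
    private_genes: int
    private_gene_pct: float


def summarize(
    per_family_retained: Mapping[str, Sequence[AnnotatedVariant]],
) -> SummaryReport:
    """Build the cohort summary over all families' retained variants."""
    consequence_counts: dict[Consequence, int] = {}
    bin_counts = {b: 0 for b in MAF_BINS}
    chrom_counts: dict[str, int] = {}
    per_family_counts: dict[str, int] = {}
    total = 0
    for family_id, variants in per_family_retained.items():
        per_family_counts[family_id] = len(variants)
        for v in variants:
            total += 1
            consequence_counts[v.consequence] = (
                consequence_counts.get(v.consequence, 0) + 1
            )
            bin_counts[maf_bin(v.pop_af)] += 1
            chrom_counts[v.chrom] = chrom_counts.get(v.chrom, 0) + 1
    table = build_sharing_table(per_family_retained)
    total_genes = len(table.genes)
    private = sum(
        1 for fams in table.families_by_gene.values() if len(fams) == 1
    )
    return SummaryReport(
        consequence_counts=consequence_counts,
        consequence_pct={
            c: pct_half_up(n, total) for c, n in consequence_counts.items()
        },
        maf_bin_counts=bin_counts,
        maf_bin_pct={
            b: pct_half_up(n, total) if total else 0.0
            for b, n in bin_counts.items()
        },
        chrom_counts=chrom_counts,
        per_family_counts=per_family_counts,
        median_per_family=(
            float(median(per_family_counts.values()))
            if per_family_counts
            else 0.0
        ),
        total_variants=total,
        total_genes=total_genes,
        private_genes=private,
        private_gene_pct=(
            pct_half_up(private, total_genes, 1) if total_genes else 0.0
        ),
    )


# ---------------------------------------------------------------------------
# Retained-variant TSV round-trip (the handoff format between CLI stages)
# ---------------------------------------------------------------------------

_RETAINED_COLUMNS = [
    "family_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "pop_af",
    "n_damaging_predictors",
    "carrier_genotypes",
]


def write_retained_tsv(
    per_family_retained: Mapping[str, Sequence[AnnotatedVariant]], path
) -> None:
    rows = []
    for family_id, variants in per_family_retained.items():
        for v in variants:
            rows.append(
                {
                    "family_id": family_id,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "gene": v.gene,
                    "consequence": v.consequence.value,
                    "pop_af": "" if v.pop_af is None else v.pop_af,
                    "n_damaging_predictors": v.n_damaging,
                    "carrier_genotypes": ";".join(
                        f"{s}={g.value}" for s, g in sorted(v.genotypes.items())
                    ),
                }
            )
    pd.DataFrame(rows, columns=_RETAINED_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_retained_tsv(path) -> dict[str, list[AnnotatedVariant]]:
    """Read a retained.tsv back into minimal per-family variant records.

    Predictions are not carried by the TSV; records come back with the
    damaging count reflected only in the original file's column, which is
    sufficient for sharing/summary aggregation (neither re-applies the
    damaging rule).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[str, list[AnnotatedVariant]] = {}
    for row in df.itertuples(index=False):
        v = AnnotatedVariant(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            gene=str(row.gene),
            consequence=Consequence(str(row.consequence)),
            pop_af=None if pd.isna(row.pop_af) else float(row.pop_af),
        )
        out.setdefault(str(row.family_id), []).append(v)
    return out
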