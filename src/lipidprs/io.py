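"""Reading/writing the standard formats and harmonizing summary-statistic
alleles against a target genotype panel.

Genotypes travel as VCF 4.2 (GT fields, biallelic records, 1-based positions,
read through :mod:`cyvcf2`); summary statistics and weight tables as
tab-separated text with a mandatory header. Harmonization aligns each summary
record's effect allele to the panel's alt allele, resolving allele swaps by
sign flip and strand flips by complementation, and (by default) dropping
strand-ambiguous A/T and C/G variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    GenotypeMatrix,
    SchemaError,
    SummaryStats,
    WeightTable,
    variant_keys,
)

DEFAULT_CALL_RATE = 0.9

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class FormatError(ValueError):
    """Input file could not be parsed in the expected format."""


class EmptyOverlapError(ValueError):
    """No variant is shared between summary statistics and the target panel."""


def read_genotypes(path: str, min_call_rate: float = DEFAULT_CALL_RATE) -> GenotypeMatrix:
    """Parse a VCF into a :class:`GenotypeMatrix` of alt-allele dosages.

    Multiallelic records and variants with call rate at or below
    ``min_call_rate`` are dropped (counts available on the returned object as
    ``.n_multiallelic_dropped`` / ``.n_low_call_rate_dropped``).
    """
    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows = []
        dosage_rows = []
        n_multi = 0
        for record in vcf:
            if len(record.ALT) != 1:
                n_multi += 1
                continue
            # genotypes: [allele_a, allele_b, phased]; -1 encodes missing
            geno = np.asarray(record.genotypes, dtype=int)[:, :2]
            dose = geno.sum(axis=1).astype(float)
            dose[(geno < 0).any(axis=1)] = np.nan
            rows.append(
                (str(record.CHROM), int(record.POS), record.ID or ".", record.REF, record.ALT[0])
            )
            dosage_rows.append(dose)
    except FormatError:
        raise
    except Exception as exc:  # cyvcf2/htslib parse failure
        raise FormatError(f"malformed VCF {path}: {exc}") from exc

    if not rows:
        raise FormatError(f"no biallelic records found in {path}")
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    dosages = np.column_stack(dosage_rows)
    gm = GenotypeMatrix(samples, variants, dosages)

    keep = gm.call_rate() > min_call_rate
    n_low = int((~keep).sum())
    if n_low:
        gm = gm.subset_variants(np.flatnonzero(keep))
    gm.n_multiallelic_dropped = n_multi
    gm.n_low_call_rate_dropped = n_low
    return gm


def write_genotypes(genotypes: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 with GT-only biallelic records."""
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(genotypes.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        for j, var in genotypes.variants.iterrows():
            calls = [
                gt_codes.get(d, "./.") if np.isfinite(d) else "./."
                for d in genotypes.dosages[:, j]
            ]
            fh.write(
                f"{var['chrom']}\t{int(var['pos'])}\t{var.get('id', '.')}\t"
                f"{var['ref']}\t{var['alt']}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_summary_stats(path: str) -> SummaryStats:
    """Load a tab-separated summary-statistics table (validated, extra columns kept)."""
    table = pd.read_csv(path, sep="\t")
    return SummaryStats(table)


def write_summary_stats(stats: SummaryStats, path: str) -> None:
    stats.table.to_csv(path, sep="\t", index=False)


def read_weights(path: str) -> WeightTable:
    table = pd.read_csv(path, sep="\t")
    provenance = "classical"
    if "provenance" in table.columns and len(table):
        provenance = str(table["provenance"].iloc[0])
        table = table.drop(columns=["provenance"])
    return WeightTable(table, provenance=provenance)


def write_weights(weights: WeightTable, path: str) -> None:
    out = weights.table.copy()
    out["provenance"] = weights.provenance
    out.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizationReport:
    """Accounting of an allele-harmonization pass."""

    n_stats: int
    n_position_overlap: int
    n_matched: int
    n_sign_flipped: int
    n_strand_flipped: int
    n_dropped_ambiguous: int
    n_dropped_mismatch: int

    @property
    def overlap_fraction(self) -> float:
        """Fraction of the source study's variants usable in the target panel."""
        return self.n_matched / self.n_stats if self.n_stats else 0.0

    @property
    def overlap_percent(self) -> float:
        """Overlap as a percentage rounded to one decimal (reporting convention)."""
        return round(100.0 * self.overlap_fraction, 1)


def _is_ambiguous(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def harmonize(
    stats: SummaryStats,
    genotypes: GenotypeMatrix,
    drop_ambiguous: bool = True,
    provenance: str = "classical",
) -> tuple[WeightTable, HarmonizationReport]:
    """Align summary-statistic effect alleles to the target panel's alt alleles.

    Matching is positional on (chrom, pos). If the effect allele equals the
    panel alt allele the weight is the reported beta; if it equals the ref
    allele the weight is ``-beta`` and the effect allele is recoded to alt;
    otherwise a strand flip (base complement) is attempted before the same two
    checks. Strand-ambiguous A/T and C/G variants are dropped when
    ``drop_ambiguous`` (complementation cannot be verified for them);
    unresolvable allele sets are dropped and counted.
    """
    panel = genotypes.variants.set_index(variant_keys(genotypes.variants))
    skeys = stats.keys()
    n_overlap = int(skeys.isin(panel.index).sum())
    if n_overlap == 0:
        raise EmptyOverlapError("no variants shared between summary statistics and target panel")

    out_rows = []
    n_match = n_sign = n_strand = n_amb = n_mis = 0
    for key, row in zip(skeys, stats.table.itertuples(index=False)):
        if key not in panel.index:
            continue
        eff, oth = str(row.effect_allele), str(row.other_allele)
        if drop_ambiguous and _is_ambiguous(eff, oth):
            n_amb += 1
            continue
        var = panel.loc[key]
        ref, alt = str(var["ref"]), str(var["alt"])
        weight = None
        for flip_strand in (False, True):
            if flip_strand:
                if eff not in _COMPLEMENT or oth not in _COMPLEMENT:
                    break
                eff_c, oth_c = _COMPLEMENT[eff], _COMPLEMENT[oth]
            else:
                eff_c, oth_c = eff, oth
            if eff_c == alt and oth_c == ref:
                weight = float(row.beta)
            elif eff_c == ref and oth_c == alt:
                weight = -float(row.beta)
                n_sign += 1
            if weight is not None:
                if flip_strand:
                    n_strand += 1
                break
        if weight is None:
            n_mis += 1
            continue
        n_match += 1
        out_rows.append((str(var["chrom"]), int(var["pos"]), alt, weight))

    report = HarmonizationReport(
        n_stats=stats.n_variants,
        n_position_overlap=n_overlap,
        n_matched=n_match,
        n_sign_flipped=n_sign,
        n_strand_flipped=n_strand,
        n_dropped_ambiguous=n_amb,
        n_dropped_mismatch=n_mis,
    )
    table = pd.DataFrame(out_rows, columns=["chrom", "pos", "effect_allele", "weight"])
    return WeightTable(table, provenance=provenance), report
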