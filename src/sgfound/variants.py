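"""Rare-variant prioritization and HGVS coding-coordinate arithmetic.

Implements the filtering cascade used to nominate X-linked candidates from
exome calls: strict population-allele-frequency filtering (pass iff
AF < 0.001 in every annotated population database; absent annotations are
treated as AF 0, i.e. "absent from public aggregation databases"), and
restriction to a list of muscle-expressed genes.  External pathogenicity
predictor scores (CADD, PrimateAI, SIFT, PolyPhen2, SpliceAI) are carried
through untouched; no thresholds are applied to them.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import pysam

__all__ = [
    "VariantRecord",
    "GeneList",
    "read_vcf",
    "write_vcf",
    "filter_rare",
    "prioritize_gene_list",
    "allele_frequency",
    "cds_to_codon",
    "parse_hgvs_c",
    "format_hgvs_c",
    "DEFAULT_AF_THRESHOLD",
]

DEFAULT_AF_THRESHOLD = 1e-3
DEFAULT_AF_FIELDS = ("gnomAD_AF", "ExAC_AF", "AF")
SCORE_FIELDS = ("CADD", "PrimateAI", "SIFT", "PolyPhen2", "SpliceAI")


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    cds_pos: int | None = None
    population_af: dict[str, float] = field(default_factory=dict)
    external_scores: dict[str, object] = field(default_factory=dict)
    filter_status: str = "pass"
    filter_reason: str = ""

    @property
    def passed(self) -> bool:
        return self.filter_status == "pass"


class GeneList:
    """Case-normalized set of gene symbols (e.g. muscle-expressed genes)."""

    def __init__(self, symbols):
        cleaned = {s.strip().upper() for s in symbols if s and s.strip()}
        if not cleaned:
            raise ValueError("gene list must be nonempty")
        self._symbols = cleaned

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneList":
        lines = Path(path).read_text().splitlines()
        return cls(line.split("#")[0] for line in lines)

    def __contains__(self, symbol) -> bool:
        return symbol is not None and symbol.strip().upper() in self._symbols

    def __len__(self) -> int:
        return len(self._symbols)

    def __iter__(self):
        return iter(sorted(self._symbols))


def read_vcf(path: str | Path, af_fields=DEFAULT_AF_FIELDS) -> list[VariantRecord]:
    """Read a VCF into VariantRecords, splitting multi-allelic sites."""
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                info = dict(rec.info)
                afs = {}
                for name in af_fields:
                    if name in info:
                        val = info[name]
                        if isinstance(val, tuple):
                            val = val[0]
                        afs[name] = val
                gene = info.get("GENE")
                if isinstance(gene, tuple):
                    gene = gene[0]
                cds = info.get("CDS_POS")
                if isinstance(cds, tuple):
                    cds = cds[0]
                scores = {k: info[k] for k in SCORE_FIELDS if k in info}
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=str(gene) if gene is not None else None,
                        cds_pos=int(cds) if cds is not None else None,
                        population_af=afs,
                        external_scores=scores,
                    )
                )
    return records


def write_vcf(records, path: str | Path) -> None:
    """Write passing variants back out as an uncompressed VCF."""
    header = pysam.VariantHeader()
    contigs = {r.chrom for r in records}
    for c in sorted(contigs):
        header.contigs.add(c)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("CDS_POS", 1, "Integer", "Position in coding DNA")
    header.info.add("FILTER_STATUS", 1, "String", "sgfound filter status")
    af_names = sorted({name for r in records for name in r.population_af})
    for name in af_names:
        header.info.add(name, 1, "Float", f"Population allele frequency ({name})")
    score_names = sorted({name for r in records for name in r.external_scores})
    for name in score_names:
        header.info.add(name, 1, "String", f"External predictor score ({name})")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt)
            )
            if r.gene:
                rec.info["GENE"] = r.gene
            if r.cds_pos is not None:
                rec.info["CDS_POS"] = r.cds_pos
            rec.info["FILTER_STATUS"] = r.filter_status
            for name, val in r.population_af.items():
                try:
                    rec.info[name] = float(val)
                except (TypeError, ValueError):
                    continue
            for name, val in r.external_scores.items():
                rec.info[name] = str(val)
            out.write(rec)


def filter_rare(
    variants: list[VariantRecord],
    af_threshold: float = DEFAULT_AF_THRESHOLD,
) -> list[VariantRecord]:
    """Strict population-frequency filter.

    A variant passes iff AF < ``af_threshold`` (strictly) in every database
    field it is annotated with; an absent annotation counts as AF 0.  A
    variant already failed by an earlier stage is left untouched.
    """
    for v in variants:
        if v.filter_status not in ("pass",):
            continue
        for db, raw in v.population_af.items():
            try:
                af = float(raw)
            except (TypeError, ValueError):
                v.filter_status = "fail_other"
                v.filter_reason = f"malformed AF value {raw!r} in {db}"
                break
            if not math.isfinite(af):
                v.filter_status = "fail_other"
                v.filter_reason = f"malformed AF value {raw!r} in {db}"
                break
            if af >= af_threshold:
                v.filter_status = "fail_af"
                v.filter_reason = f"AF {af:g} >= {af_threshold:g} in {db}"
                break
    return variants


def prioritize_gene_list(
    variants: list[VariantRecord], gene_list: GeneList
) -> list[VariantRecord]:
    """Keep variants whose gene is on the (muscle-expressed) gene list;
    unannotated variants fail."""
    for v in variants:
        if v.filter_status != "pass":
            continue
        if v.gene is None or v.gene not in gene_list:
            v.filter_status = "fail_gene_list"
            v.filter_reason = f"gene {v.gene!r} not in list"
    return variants


def allele_frequency(allele_count: int, allele_number: int) -> float:
    """Population allele frequency ``count / number`` (e.g. 6/205,256 →
    2.92e-05 at three significant figures)."""
    if allele_number <= 0:
        raise ValueError("allele_number must be positive")
    if not 0 <= allele_count <= allele_number:
        raise ValueError("require 0 <= allele_count <= allele_number")
    return allele_count / allele_number


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def cds_to_codon(cds_pos: int) -> tuple[int, int]:
    """Map a coding-DNA position to (codon index, position within codon),
    both 1-based: c.233 → codon 78 position 2 (p.S78N)."""
    if cds_pos < 1:
        raise ValueError("cds_pos must be >= 1")
    return (cds_pos + 2) // 3, (cds_pos - 1) % 3 + 1


_HGVS_C_RE = re.compile(
    r"^\s*c\.\s*(\d+)\s*([ACGT])\s*>\s*([ACGT])\s*$", re.IGNORECASE
)


def parse_hgvs_c(notation: str) -> tuple[int, str, str]:
    """Parse an HGVS coding single-nucleotide substitution, e.g.
    ``"c.233G>A"`` (whitespace-tolerant) → ``(233, "G", "A")``.

    Anything outside that grammar (indels, splice-site offsets, protein
    notation) raises ``ValueError``.
    """
    m = _HGVS_C_RE.match(notation)
    if not m:
        raise ValueError(
            f"unsupported HGVS syntax {notation!r}: only single-nucleotide "
            "substitutions 'c.<pos><ref>><alt>' are handled"
        )
    pos, ref, alt = m.groups()
    return int(pos), ref.upper(), alt.upper()


def format_hgvs_c(cds_pos: int, ref: str, alt: str) -> str:
    return f"c.{cds_pos}{ref.upper()}>{alt.upper()}"
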