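"""Reading and writing the formats the pipeline touches.

VCF 4.x (GT:DP:GQ) is read with :mod:`cyvcf2`; the writer emits plain
uncompressed VCF text so that simulator output round-trips byte for byte.
Phenotype, progeny and candidate tables are UTF-8 tab-separated files with a
header row.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, GenotypeMatrix, Individual, ValidationError, VariantSite
from .segregation import ProgenyRecord

log = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ["id", "family", "generation", "phenotype"]
PROGENY_COLUMNS = ["parent_id", "pollination", "n_mutant", "n_wildtype", "n_germinated", "n_planted"]


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    individuals: Sequence[Individual] | None = None,
    multiallelic: str = "error",
) -> GenotypeMatrix:
    """Load a multi-sample VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    individuals
        Optional phenotype-table individuals; when given, VCF sample names
        must match their ids exactly (a reconciliation error otherwise) and
        the matrix columns carry their family/phenotype metadata.
    multiallelic
        ``"error"`` (default) rejects multi-allelic records, ``"skip"`` drops
        them, ``"split"`` expands them into one biallelic site per ALT allele.

    Genotypes with an incomplete GT (any missing allele) are stored as
    missing; an absent DP or GQ value is stored as 0, which downstream
    confidence masking turns into a missing call.
    """
    if multiallelic not in ("error", "skip", "split"):
        raise ValueError(f"unknown multiallelic policy {multiallelic!r}")
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns")
    if individuals is not None:
        by_id = {ind.id: ind for ind in individuals}
        missing_ids = [s for s in samples if s not in by_id]
        if missing_ids:
            raise FormatError(
                f"{path}: VCF samples not present in phenotype table: {missing_ids}"
            )
        inds = [by_id[s] for s in samples]
    else:
        inds = [Individual(id=s, family="unknown", phenotype="unknown") for s in samples]

    sites: list[VariantSite] = []
    dosage_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    qual_rows: list[np.ndarray] = []
    n_skipped = 0

    for variant in vcf:
        alts = variant.ALT
        if len(alts) != 1:
            if multiallelic == "error":
                raise FormatError(
                    f"{path}: multi-allelic record at {variant.CHROM}:{variant.POS} "
                    "(pass multiallelic='skip' or 'split' to allow)"
                )
            if multiallelic == "skip":
                n_skipped += 1
                continue
        for alt_index, alt in enumerate(alts, start=1):
            site = VariantSite(chrom=variant.CHROM, pos=variant.POS, ref=variant.REF, alt=alt)
            if not site.is_snp:
                n_skipped += 1
                continue
            gts = variant.genotypes  # [[a0, a1, phased], ...]
            if gts is None:
                raise FormatError(f"{path}: record without GT at {site.label}")
            dos = np.full(len(samples), MISSING, dtype=np.int8)
            for j, gt in enumerate(gts):
                a = gt[:-1]
                if len(a) != 2 or min(a) < 0:
                    continue  # half-missing or haploid calls are treated as missing
                dos[j] = sum(1 for allele in a if allele == alt_index)
            depth_rows.append(_format_field(variant, "DP", len(samples)))
            qual_rows.append(_format_field(variant, "GQ", len(samples)))
            dosage_rows.append(dos)
            sites.append(site)
    if n_skipped:
        log.warning("%s: skipped %d non-biallelic-SNP records", path, n_skipped)

    n = len(sites)
    return GenotypeMatrix(
        sites=sites,
        individuals=inds,
        dosage=np.array(dosage_rows, dtype=np.int8).reshape(n, len(samples)),
        depth=np.array(depth_rows, dtype=np.int32).reshape(n, len(samples)),
        quality=np.array(qual_rows, dtype=np.float32).reshape(n, len(samples)),
    )


def _format_field(variant, key: str, n_samples: int) -> np.ndarray:
    arr = variant.format(key)
    if arr is None:
        return np.zeros(n_samples)
    arr = np.asarray(arr, dtype=float).reshape(n_samples, -1)[:, 0]
    arr = np.where(np.isfinite(arr) & (arr >= 0), arr, 0.0)
    return arr


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as uncompressed VCF 4.2 with GT:DP:GQ calls.

    Dosages are emitted relative to REF/ALT regardless of each site's
    mutant-allele polarity, so read->write->read round-trips losslessly.
    """
    path = Path(path)
    chroms = []
    for s in matrix.sites:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    gt_for = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=zygomap\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.ids) + "\n")
        for i, site in enumerate(matrix.sites):
            calls = [
                f"{gt_for[int(d)]}:{int(dp)}:{int(round(float(q)))}"
                for d, dp, q in zip(matrix.dosage[i], matrix.depth[i], matrix.quality[i])
            ]
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT:DP:GQ\t"
                + "\t".join(calls)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------

def read_phenotype_table(
    path: str | Path,
    label_map: Mapping[str, str] | None = None,
) -> list[Individual]:
    """Read a tab-separated table of individuals (id, family, generation, phenotype).

    ``label_map`` translates free-form phenotype labels (families name their
    phenotypes differently, e.g. *dwarf*/*DWARF*) to mutant/wildtype.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty phenotype table", stacklevel=2)
        return []
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: phenotype table lacks columns {missing_cols}")
    if df.empty:
        warnings.warn(f"{path}: empty phenotype table", stacklevel=2)
        return []
    individuals: list[Individual] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        label = str(row.phenotype)
        phenotype = label_map.get(label, label) if label_map else label
        key = (str(row.family), str(row.id))
        if key in seen:
            raise ValidationError(f"{path}: duplicate individual id {row.id!r} in family {row.family!r}")
        seen.add(key)
        individuals.append(
            Individual(
                id=str(row.id),
                family=str(row.family),
                generation=str(row.generation),
                phenotype=phenotype,
            )
        )
    return individuals


def write_phenotype_table(individuals: Sequence[Individual], path: str | Path) -> None:
    df = pd.DataFrame(
        [(i.id, i.family, i.generation, i.phenotype) for i in individuals],
        columns=PHENOTYPE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Progeny (M3 segregation) table
# ---------------------------------------------------------------------------

def read_progeny_table(path: str | Path) -> list[ProgenyRecord]:
    """Read M3 segregation counts (one row per selfed/outcrossed M2 parent).

    Validates 0 <= n_mutant + n_wildtype <= n_germinated <= n_planted; a few
    germinated plants may remain unphenotyped, so the classified counts may
    fall short of the germinated total.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in PROGENY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: progeny table lacks columns {missing_cols}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ProgenyRecord(
                parent_id=str(row.parent_id),
                pollination=str(row.pollination),
                n_mutant=int(row.n_mutant),
                n_wildtype=int(row.n_wildtype),
                n_germinated=int(row.n_germinated),
                n_planted=int(row.n_planted),
                parent_phenotype=str(getattr(row, "parent_phenotype", "unknown")),
            )
        )
    return records


def write_progeny_table(records: Sequence[ProgenyRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.parent_id, r.pollination, r.n_mutant, r.n_wildtype, r.n_germinated, r.n_planted, r.parent_phenotype)
            for r in records
        ],
        columns=PROGENY_COLUMNS + ["parent_phenotype"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Candidate report
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = [
    "chrom",
    "pos",
    "base_exchange",
    "is_transition",
    "f_mutant_group",
    "f_wildtype_group",
    "total_alleles",
    "ref_alleles",
    "mut_alleles_mutant_group",
    "mut_alleles_wildtype_group",
    "n_informative",
]


def write_candidates(report: pd.DataFrame, path: str | Path) -> None:
    """Write the candidate-SNP report (one row per passing site).

    An empty candidate set yields a header-only file; that is a legal
    pipeline outcome, not an error.
    """
    path = Path(path)
    cols = [c for c in CANDIDATE_COLUMNS if c in report.columns] + [
        c for c in report.columns if c not in CANDIDATE_COLUMNS
    ]
    try:
        report.loc[:, cols].to_csv(path, sep="\t", index=False, lineterminator="\n")
    except OSError as exc:
        raise OSError(f"failed to write candidate report to {path}: {exc}") from exc


def read_candidates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
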