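"""Tables and file formats used across the pipeline.

All tabular inputs and outputs are plain TSV/CSV with headers.  VCF input is
read through :mod:`cyvcf2`; positions stay 1-based as in the VCF standard and
any internal interval logic is half-open 0-based — the reader is the boundary.
Validation is strict: malformed rows are rejected with the (1-based, header
included) line number, and every row a reader drops is recorded with a reason
code rather than silently discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

GENOTYPES = ("outgroup", "derived1", "derived2", "hybrid1", "hybrid2")
MATERIALS = ("RNA", "DNA")
SITE_CLASSES = ("synonymous", "nonsynonymous", "other")


class FormatError(ValueError):
    """A file failed validation; the message names the offending line/field."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Gene x sample integer read counts plus the sample sheet.

    ``counts`` is indexed by gene_id with one column per sample_id;
    ``samples`` is indexed by sample_id with columns
    ``genotype``, ``material``, ``timepoint_h`` (NaN for DNA) and
    ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        validate_sample_sheet(self.samples)
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise FormatError(f"samples absent from sample sheet: {missing[:5]}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("expression counts must be integral")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            gene = self.counts.index[(self.counts < 0).any(axis=1)][0]
            raise FormatError(f"negative count for gene {gene!r}")

    def subset_genotypes(self, genotypes) -> "ExpressionMatrix":
        keep = self.samples.index[self.samples["genotype"].isin(genotypes)]
        return ExpressionMatrix(self.counts[list(keep)], self.samples.loc[keep])


@dataclass
class AlleleCountTable:
    """Per (gene, sample) two-allele counts for one or both hybrids.

    ``counts`` is indexed by (gene_id, sample_id) with float columns
    ``count_a`` (outgroup allele) and ``count_b`` (derived allele); floats so
    that size-factor normalized tables share the container.  ``samples`` is
    the hybrid sample sheet (genotype, material, timepoint_h, replicate).
    ``snps`` is an optional per-SNP table with columns gene_id, sample_id,
    pos, count_a, count_b, dist_to_intron_bp, dna_coverage.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    snps: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        validate_sample_sheet(self.samples)
        for col in ("count_a", "count_b"):
            if col not in self.counts.columns:
                raise FormatError(f"allele table missing column {col!r}")
            if (self.counts[col].to_numpy() < 0).any():
                raise FormatError(f"negative value in column {col!r}")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate (gene, sample) key {dup}")

    def totals(self) -> pd.Series:
        return self.counts["count_a"] + self.counts["count_b"]


@dataclass
class PopulationData:
    """Biallelic-oriented variant table for one population.

    ``sites``: one row per VCF record with chrom, pos (1-based), ref, alt,
    qual, n_alt_alleles, is_snp, site_class, gene_id.
    ``alleles``: (n_sites, 2N) int matrix of allele indices with -1 for
    missing; columns are the two haploid genomes of each individual.
    ``depth``/``gq``: (n_sites, N) per-genotype DP and GQ (NaN if absent).
    ``dropped``: reason-coded log of records excluded so far.
    """

    sites: pd.DataFrame
    alleles: np.ndarray
    depth: np.ndarray
    gq: np.ndarray
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "pos", "reason"])
    )

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[1] // 2


def validate_sample_sheet(samples: pd.DataFrame) -> None:
    for col in ("genotype", "material", "timepoint_h", "replicate"):
        if col not in samples.columns:
            raise FormatError(f"sample sheet missing column {col!r}")
    if samples.index.duplicated().any():
        dup = samples.index[samples.index.duplicated()][0]
        raise FormatError(f"duplicate sample id {dup!r}")
    bad = set(samples["genotype"]) - set(GENOTYPES)
    if bad:
        raise FormatError(f"unknown genotype labels {sorted(bad)}")
    bad = set(samples["material"]) - set(MATERIALS)
    if bad:
        raise FormatError(f"unknown material labels {sorted(bad)}")


# ---------------------------------------------------------------------------
# expression counts


def read_counts(counts_path, samples_path) -> ExpressionMatrix:
    """Read a long-format (gene_id, sample_id, count) TSV plus sample CSV."""
    df = pd.read_csv(counts_path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    _require_columns(df, ("gene_id", "sample_id", "count"), counts_path)
    bad = df.index[pd.to_numeric(df["count"], errors="coerce").isna()]
    if len(bad):
        raise FormatError(f"{counts_path}: non-numeric count at line {bad[0] + 2}")
    neg = df.index[df["count"] < 0]
    if len(neg):
        raise FormatError(f"{counts_path}: negative count at line {neg[0] + 2}")
    dup = df.duplicated(["gene_id", "sample_id"])
    if dup.any():
        raise FormatError(
            f"{counts_path}: duplicate (gene, sample) at line {df.index[dup][0] + 2}"
        )
    wide = df.pivot(index="gene_id", columns="sample_id", values="count")
    if wide.isna().any().any():
        gene = wide.index[wide.isna().any(axis=1)][0]
        raise FormatError(f"{counts_path}: missing sample entries for gene {gene!r}")
    samples = read_sample_sheet(samples_path)
    order = [s for s in samples.index if s in wide.columns]
    return ExpressionMatrix(wide[order].astype(np.int64), samples.loc[order])


def write_counts(em: ExpressionMatrix, counts_path, samples_path) -> None:
    long = em.counts.stack().rename("count").reset_index()
    long.columns = ["gene_id", "sample_id", "count"]
    long.to_csv(counts_path, sep="\t", index=False)
    write_sample_sheet(em.samples, samples_path)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in sheet.columns:
        raise FormatError(f"{path}: sample sheet missing column 'sample_id'")
    sheet = sheet.set_index("sample_id")
    validate_sample_sheet(sheet)
    sheet["timepoint_h"] = pd.to_numeric(sheet["timepoint_h"], errors="coerce")
    sheet["replicate"] = sheet["replicate"].astype(int)
    return sheet


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.rename_axis("sample_id").reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# allele counts


def read_alleles(path, samples_path, snp_path=None) -> AlleleCountTable:
    """Read long-format (gene_id, sample_id, allele in {A,B}, count) TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    _require_columns(df, ("gene_id", "sample_id", "allele", "count"), path)
    bad = df.index[~df["allele"].isin(["A", "B"])]
    if len(bad):
        raise FormatError(f"{path}: allele not in {{A,B}} at line {bad[0] + 2}")
    neg = df.index[df["count"] < 0]
    if len(neg):
        raise FormatError(f"{path}: negative count at line {neg[0] + 2}")
    wide = df.pivot_table(
        index=["gene_id", "sample_id"], columns="allele", values="count",
        aggfunc="sum", fill_value=0.0,
    )
    wide = wide.rename(columns={"A": "count_a", "B": "count_b"})
    for col in ("count_a", "count_b"):
        if col not in wide.columns:
            wide[col] = 0.0
    samples = read_sample_sheet(samples_path)
    snps = None
    if snp_path is not None:
        snps = pd.read_csv(snp_path, sep="\t", dtype={"gene_id": str, "sample_id": str})
        _require_columns(
            snps,
            ("gene_id", "pos", "dist_to_intron_bp", "dna_coverage"),
            snp_path,
        )
    hybrid_samples = [s for s in samples.index if s in wide.index.get_level_values(1)]
    return AlleleCountTable(wide[["count_a", "count_b"]], samples.loc[hybrid_samples], snps)


def write_alleles(table: AlleleCountTable, path, samples_path, snp_path=None) -> None:
    long = (
        table.counts.rename(columns={"count_a": "A", "count_b": "B"})
        .stack()
        .rename("count")
        .reset_index()
    )
    long.columns = ["gene_id", "sample_id", "allele", "count"]
    long.to_csv(path, sep="\t", index=False)
    write_sample_sheet(table.samples, samples_path)
    if snp_path is not None and table.snps is not None:
        table.snps.to_csv(snp_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# population data (VCF + site annotation)


def read_population(vcf_path, annotation_path) -> PopulationData:
    """Read a VCF 4.x plus a per-site class annotation TSV.

    The annotation TSV has columns chrom, pos (1-based), site_class
    (synonymous/nonsynonymous/other) and gene_id.  Records without a GT field
    are an error; indels and multiallelic records are kept but flagged so the
    population filter can drop them with a reason code.
    """
    from cyvcf2 import VCF

    ann = pd.read_csv(annotation_path, sep="\t", dtype={"chrom": str, "gene_id": str})
    _require_columns(ann, ("chrom", "pos", "site_class", "gene_id"), annotation_path)
    bad = ann.index[~ann["site_class"].isin(SITE_CLASSES)]
    if len(bad):
        raise FormatError(
            f"{annotation_path}: unknown site_class at line {bad[0] + 2}"
        )
    ann = ann.set_index(["chrom", "pos"])
    if ann.index.duplicated().any():
        raise FormatError(f"{annotation_path}: duplicate (chrom, pos)")

    vcf = VCF(str(vcf_path), gts012=False)
    rows, allele_rows, dp_rows, gq_rows = [], [], [], []
    for var in vcf:
        gts = var.genotypes
        if gts is None or len(gts) == 0:
            raise FormatError(f"{vcf_path}: record {var.CHROM}:{var.POS} lacks GT")
        alleles = []
        for g in gts:
            alleles.extend(int(a) for a in g[:-1])
        key = (str(var.CHROM), int(var.POS))
        site_class, gene_id = "other", ""
        if key in ann.index:
            site_class = ann.loc[key, "site_class"]
            gene_id = ann.loc[key, "gene_id"]
        rows.append(
            {
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": ",".join(var.ALT),
                "qual": float(var.QUAL) if var.QUAL is not None else np.nan,
                "n_alt_alleles": len(var.ALT),
                "is_snp": var.is_snp and not var.is_indel,
                "site_class": site_class,
                "gene_id": gene_id,
            }
        )
        allele_rows.append(alleles)
        dp = var.format("DP")
        gq = var.format("GQ")
        n = len(gts)
        dp_rows.append(
            dp.astype(float).ravel()[:n] if dp is not None else np.full(n, np.nan)
        )
        gq_rows.append(
            gq.astype(float).ravel()[:n] if gq is not None else np.full(n, np.nan)
        )
    sites = pd.DataFrame(rows)
    if len(sites) and sites.duplicated(["chrom", "pos"]).any():
        raise FormatError(f"{vcf_path}: duplicate position within a chromosome")
    return PopulationData(
        sites=sites,
        alleles=np.asarray(allele_rows, dtype=np.int16)
        if allele_rows
        else np.empty((0, 0), dtype=np.int16),
        depth=np.asarray(dp_rows, dtype=float) if dp_rows else np.empty((0, 0)),
        gq=np.asarray(gq_rows, dtype=float) if gq_rows else np.empty((0, 0)),
    )


def write_vcf(path, chrom, positions, ref, alt, genotype_pairs, quals=None,
              depth=None, gq=None, sample_names=None) -> None:
    """Write a minimal diploid VCF 4.2 text file.

    ``genotype_pairs`` is (n_sites, N, 2) allele indices, -1 for missing.
    """
    geno = np.asarray(genotype_pairs)
    n_sites, n_ind, _ = geno.shape
    if sample_names is None:
        sample_names = [f"ind{i + 1}" for i in range(n_ind)]
    fmt_fields = "GT"
    if depth is not None:
        fmt_fields += ":DP"
    if gq is not None:
        fmt_fields += ":GQ"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        if gq is not None:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for i in range(n_sites):
            qual = "." if quals is None else f"{quals[i]:g}"
            cells = []
            for j in range(n_ind):
                a, b = geno[i, j]
                gt = "./." if a < 0 or b < 0 else f"{a}/{b}"
                cell = gt
                if depth is not None:
                    cell += f":{int(depth[i, j])}"
                if gq is not None:
                    cell += f":{int(gq[i, j])}"
                cells.append(cell)
            fh.write(
                f"{chrom}\t{positions[i]}\t.\t{ref[i]}\t{alt[i]}\t{qual}\tPASS\t.\t"
                + fmt_fields
                + "\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# misc


def write_results(records, path) -> None:
    """Write a results bundle (nested dict / records) as JSON."""
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2, default=_json_default)
        fh.write("\n")


def read_results(path):
    with open(path) as fh:
        return json.load(fh)


def read_run_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: run config must be a YAML mapping")
    return cfg


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
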