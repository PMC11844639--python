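"""Container types and readers/writers for genotypes, protein matrices and result tables.

Two affinity platforms are compared throughout the package: platform ``A``
(aptamer-based, SomaScan-RFU-like raw scale) and platform ``B``
(antibody/PEA-based, Olink-NPX-like raw scale).  Protein matrices are held
as pandas DataFrames (samples x probes); genotypes as a dosage DataFrame
(samples x variants, values in [0, 2] counting the alternate allele) plus a
variant metadata table.

Conventions
-----------
* Genomic coordinates are 1-based and windows are closed intervals
  (VCF convention).
* Multi-allelic VCF records are rejected by default; ``split_multiallelic``
  turns each ALT allele into its own bi-allelic variant.
* Missing dosages are left as NaN here; association scans mean-impute them,
  allele-frequency counting never does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PLATFORM_A = "A"  # aptamer
PLATFORM_B = "B"  # antibody

#: VEP-style consequence classes counted as protein-altering.
PAV_CLASSES = frozenset({"missense", "start_loss", "stop_gain", "stop_loss"})
CONSEQUENCE_CLASSES = PAV_CLASSES | {"other", "none"}

UNASSIGNED = "unassigned"

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "consequence_class", "consequence_gene"]


class SampleMismatchError(ValueError):
    """Raised when a matrix does not line up with the sample table."""


def check_sample_alignment(expected, actual, what: str = "matrix") -> None:
    """Refuse to proceed when sample ids differ (checked, never assumed)."""
    expected = list(expected)
    actual = list(actual)
    if expected != actual:
        missing = sorted(set(expected) - set(actual))
        extra = sorted(set(actual) - set(expected))
        raise SampleMismatchError(
            f"{what}: sample ids do not match the sample table "
            f"(missing={missing[:5]}, unexpected={extra[:5]}, "
            f"order_differs={set(expected) == set(actual)})"
        )


# ---------------------------------------------------------------------------
# sample table / probe map
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ["age", "sex", "site", "plate", "ancestry", "bmi", "t2d"]


def validate_sample_table(samples: pd.DataFrame, groups=None) -> pd.DataFrame:
    """Validate a sample table (index = sample_id).

    ``groups`` is the declared set of ancestry labels; the sentinel label
    ``"unassigned"`` is always allowed (participants that could not be
    assigned to a reference group are excluded from per-ancestry analyses).
    """
    if samples.index.has_duplicates:
        dup = samples.index[samples.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dup[:5]}")
    if samples.index.isna().any() or (samples.index.astype(str) == "").any():
        raise ValueError("missing sample id")
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if groups is not None:
        allowed = set(groups) | {UNASSIGNED}
        bad = set(samples["ancestry"].unique()) - allowed
        if bad:
            raise ValueError(f"undeclared ancestry labels: {sorted(bad)}")
    return samples


def read_sample_table(path, groups=None) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", index_col=0)
    samples.index = samples.index.astype(str)
    return validate_sample_table(samples, groups)


def read_probe_map(path) -> pd.DataFrame:
    """Read the probe -> UniProt/gene/TSS map.

    Columns: probe_id, platform, uniprot_id, gene_symbol, chrom, tss.
    """
    pm = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return validate_probe_map(pm)


def validate_probe_map(pm: pd.DataFrame) -> pd.DataFrame:
    required = ["probe_id", "platform", "uniprot_id", "gene_symbol", "chrom", "tss"]
    missing = [c for c in required if c not in pm.columns]
    if missing:
        raise ValueError(f"probe map missing columns: {missing}")
    if pm.duplicated(["probe_id", "platform"]).any():
        dup = pm.loc[pm.duplicated(["probe_id", "platform"]), "probe_id"].tolist()
        raise ValueError(f"duplicate (probe_id, platform): {dup[:5]}")
    if pm["uniprot_id"].isna().any() or (pm["uniprot_id"].astype(str) == "").any():
        raise ValueError("every probe must carry a uniprot_id")
    if (pm["tss"] < 1).any():
        raise ValueError("tss must be >= 1 (1-based coordinates)")
    return pm


# ---------------------------------------------------------------------------
# protein matrices
# ---------------------------------------------------------------------------


@dataclass
class ProteinMatrix:
    """One platform's abundance matrix (samples x probes) with a named layer."""

    platform: str
    values: pd.DataFrame
    layer: str = "raw"  # raw | transformed | residualized

    def __post_init__(self):
        if self.platform not in (PLATFORM_A, PLATFORM_B):
            raise ValueError(f"platform must be 'A' or 'B', got {self.platform!r}")
        if np.isinf(self.values.to_numpy(dtype=float, na_value=np.nan)).any():
            raise ValueError("protein matrix contains infinite values")

    @property
    def sample_ids(self):
        return list(self.values.index)

    @property
    def probe_ids(self):
        return list(self.values.columns)


def read_matrix_tsv(path, platform: str, layer: str = "raw") -> ProteinMatrix:
    """Read a samples-rows TSV (header = probe ids, first column = sample ids)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate probe id in header: {dup}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col].str.strip() if raw[col].dtype == object else raw[col],
                                  errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].astype(str).str.strip() != "")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric cell at row {raw.index[i]!r}, column {col!r}: "
                f"{raw[col].iloc[i]!r}"
            )
        values[col] = converted
    return ProteinMatrix(platform=platform, values=values, layer=layer)


def write_matrix_tsv(matrix: ProteinMatrix, path, precision: int = 10) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=f"%.{precision}g",
                         index_label="sample_id")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeData:
    """Dosage matrix (samples x variants) plus per-variant metadata.

    ``variants`` is indexed by variant_id with columns ``chrom`` (str),
    ``pos`` (1-based int), ``ref``, ``alt``, ``consequence_class`` and
    ``consequence_gene``.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self):
        if self.variants.index.has_duplicates:
            dup = self.variants.index[self.variants.index.duplicated()].tolist()
            raise ValueError(f"duplicate variant ids: {dup[:5]}")
        if list(self.dosages.columns) != list(self.variants.index):
            raise ValueError("dosage columns must match variant table order")
        vals = self.dosages.to_numpy(dtype=float, na_value=np.nan)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0) < -1e-9 or np.nanmax(vals, initial=0) > 2 + 1e-9:
                raise ValueError("dosages must lie in [0, 2]")
        if (self.variants["pos"] < 1).any():
            raise ValueError("positions must be >= 1")
        bad = set(self.variants["consequence_class"].unique()) - CONSEQUENCE_CLASSES
        if bad:
            raise ValueError(f"unknown consequence classes: {sorted(bad)}")

    @property
    def sample_ids(self):
        return list(self.dosages.index)

    @property
    def variant_ids(self):
        return list(self.variants.index)

    def subset_samples(self, sample_ids) -> "GenotypeData":
        missing = [s for s in sample_ids if s not in self.dosages.index]
        if missing:
            raise ValueError(f"samples not in genotype data: {missing[:5]}")
        return GenotypeData(self.dosages.loc[list(sample_ids)], self.variants)

    def dosage(self, variant_id: str) -> np.ndarray:
        return self.dosages[variant_id].to_numpy(dtype=float)


def read_genotype_vcf(path, samples=None, split_multiallelic: bool = False) -> GenotypeData:
    """Read a VCF into a dosage matrix.

    Dosage is the DS field when present, otherwise the alternate-allele count
    from GT; missing genotypes become NaN.  Multi-allelic records raise unless
    ``split_multiallelic`` is set, in which case each ALT allele becomes its
    own bi-allelic variant (dosage counting that allele).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    if samples is not None:
        missing = [s for s in samples if s not in vcf_samples]
        if missing:
            raise ValueError(f"requested samples not in VCF: {missing}")
        sel = [vcf_samples.index(s) for s in samples]
        out_samples = list(samples)
    else:
        sel = list(range(len(vcf_samples)))
        out_samples = vcf_samples

    cols, meta = [], []
    for rec_no, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1 and not split_multiallelic:
            raise ValueError(
                f"multi-allelic record at line ~{rec_no} ({v.CHROM}:{v.POS}); "
                "set split_multiallelic=True to split"
            )
        try:
            ds = v.format("DS")
        except Exception:
            ds = None
        gts = np.array(v.genotypes, dtype=object)
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=float)
        alleles[alleles < 0] = np.nan
        for alt_index, alt in enumerate(v.ALT, start=1):
            vid = v.ID if (v.ID and len(v.ALT) == 1) else f"{v.CHROM}:{v.POS}:{v.REF}:{alt}"
            if ds is not None and len(v.ALT) == 1:
                dose = np.asarray(ds, dtype=float).reshape(len(vcf_samples), -1)[:, 0]
            else:
                dose = np.nansum(alleles == alt_index, axis=1).astype(float)
                dose[np.isnan(alleles).all(axis=1)] = np.nan
            cols.append(dose[sel])
            meta.append((vid, str(v.CHROM), int(v.POS), v.REF, alt, "none", ""))

    variants = pd.DataFrame(meta, columns=["variant_id"] + VARIANT_COLUMNS).set_index("variant_id")
    dosages = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((len(out_samples), 0)),
        index=out_samples, columns=variants.index,
    )
    return GenotypeData(dosages, variants)


def write_genotype_vcf(genotypes: GenotypeData, path) -> None:
    """Write hard genotypes back to VCF v4.2 (GT field, ./. for missing).

    Dosages must be integral (0/1/2); round-trips exactly through
    :func:`read_genotype_vcf`.
    """
    dos = genotypes.dosages.to_numpy(dtype=float, na_value=np.nan)
    observed = dos[~np.isnan(dos)]
    if observed.size and not np.allclose(observed, np.round(observed)):
        raise ValueError("write_genotype_vcf requires hard (integral) genotypes")
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    order = genotypes.variants.sort_values(["chrom", "pos"]).index
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(genotypes.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in genotypes.sample_ids) + "\n")
        for vid in order:
            row = genotypes.variants.loc[vid]
            calls = [
                "./." if np.isnan(d) else gt_codes[int(round(d))]
                for d in genotypes.dosages[vid].to_numpy(dtype=float)
            ]
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def read_variant_annotation(path) -> pd.DataFrame:
    """Read a VEP-style annotation TSV: variant_id, consequence_class, consequence_gene."""
    ann = pd.read_csv(path, sep="\t", dtype=str).fillna({"consequence_gene": ""})
    bad = set(ann["consequence_class"].unique()) - CONSEQUENCE_CLASSES
    if bad:
        raise ValueError(f"unknown consequence classes: {sorted(bad)}")
    return ann.set_index("variant_id")


def attach_annotation(genotypes: GenotypeData, annotation: pd.DataFrame) -> GenotypeData:
    """Return a copy of ``genotypes`` with consequence columns filled from an annotation table."""
    variants = genotypes.variants.copy()
    hit = variants.index.intersection(annotation.index)
    variants.loc[hit, "consequence_class"] = annotation.loc[hit, "consequence_class"]
    variants.loc[hit, "consequence_gene"] = annotation.loc[hit, "consequence_gene"]
    return GenotypeData(genotypes.dosages, variants)


# ---------------------------------------------------------------------------
# negative controls / external sentinels
# ---------------------------------------------------------------------------


def read_negative_controls(path) -> pd.DataFrame:
    """Long-format negative-control table: columns probe_id, value (>= 2 per probe)."""
    ctrl = pd.read_csv(path, sep="\t")
    counts = ctrl.groupby("probe_id").size()
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(f"probes with < 2 negative-control values: {thin.index.tolist()[:5]}")
    return ctrl


def read_sentinel_table(path) -> pd.DataFrame:
    """External sentinel table: source (eqtl|ms_pqtl|gwas), variant_id, gene, context, sign."""
    ext = pd.read_csv(path, sep="\t", dtype=str)
    bad = set(ext["source"].unique()) - {"eqtl", "ms_pqtl", "gwas"}
    if bad:
        raise ValueError(f"unknown sentinel sources: {sorted(bad)}")
    if ext["variant_id"].isna().any():
        raise ValueError("sentinel rows must carry a variant_id")
    need_gene = ext["source"] == "eqtl"
    if (need_gene & (ext["gene"].isna() | (ext["gene"] == ""))).any():
        raise ValueError("eqtl sentinel rows require a target gene")
    if not set(ext["sign"].unique()) <= {"+", "-"}:
        raise ValueError("sign must be '+' or '-'")
    return ext


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_result_table(records: pd.DataFrame, path, precision: int = 6) -> None:
    """Write any result table as TSV with a stable column order and one header row."""
    records.to_csv(path, sep="\t", index=False, float_format=f"%.{precision}g")


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
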