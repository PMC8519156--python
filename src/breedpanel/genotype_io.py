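"""Reading, writing and quality control of genotype data.

Supports PLINK 1.9 binary filesets (SNP-major .bed with .bim/.fam) and
plain VCF v4.2, plus the QC filters applied before panel design: marker
and sample call-rate filters, identity-by-state duplicate removal and
restriction to autosomes.  An Illumina GenCall-score filter cannot be
applied to hard-called PLINK/VCF genotypes and is assumed to have been
run upstream by the genotyping lab.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, TARGET_LABEL, GenotypeMatrix
from .errors import EmptyResultError, FormatError, LabelingError

log = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01
# two-bit PLINK code -> dosage of the A1 allele
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
# dosage (0,1,2) -> two-bit code; missing handled separately
_BED_ENCODE = {0: 0b11, 1: 0b10, 2: 0b00, MISSING: 0b01}

# ----------------------------------------------------------------------
# labels


def read_labels(path) -> pd.DataFrame:
    """Read a ``sample_id<TAB>population`` table (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "population"]:
        raise FormatError(
            f"labels file {path} must have header 'sample_id<TAB>population'"
        )
    return df[["sample_id", "population"]]


def write_labels(samples: pd.DataFrame, path) -> None:
    out = samples.rename(columns={"id": "sample_id"})[["sample_id", "population"]]
    out.to_csv(path, sep="\t", index=False)


def _join_labels(sample_ids: list[str], labels_path) -> pd.DataFrame:
    populations = pd.Series(TARGET_LABEL, index=pd.Index(sample_ids, name="id"))
    if labels_path is not None:
        labels = read_labels(labels_path)
        unknown = set(labels["sample_id"]) - set(sample_ids)
        if unknown:
            raise LabelingError(
                f"labels reference samples absent from genotype data: {sorted(unknown)[:5]}"
            )
        populations.loc[labels["sample_id"].to_list()] = labels["population"].to_list()
    return pd.DataFrame({"id": sample_ids, "population": populations.to_numpy()})


# ----------------------------------------------------------------------
# PLINK bed/bim/fam


def read_plink(bed_path, bim_path, fam_path, labels_path=None) -> GenotypeMatrix:
    """Read a SNP-major PLINK 1.9 binary fileset.

    Dosages count the .bim A1 allele (2 = homozygous A1).  Sample
    population labels are joined from ``labels_path``; unlabeled samples
    get the ``TARGET`` label.
    """
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    n_markers, n_samples = len(bim), len(fam)
    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: PLINK bed magic bytes absent")
    if len(raw) < 3 or raw[2] != _SNP_MAJOR:
        raise FormatError(f"{bed_path}: only SNP-major bed files are supported")
    bytes_per_marker = (n_samples + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != n_markers * bytes_per_marker:
        raise FormatError(
            f"{bed_path}: payload of {payload.size} bytes inconsistent with "
            f"{n_markers} markers x {n_samples} samples"
        )
    blocks = payload.reshape(n_markers, bytes_per_marker)
    # unpack the 4 two-bit genotypes per byte, lowest bits = first sample
    codes = np.stack([(blocks >> s) & 0b11 for s in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(n_markers, -1)[:, :n_samples]
    calls = np.ascontiguousarray(_BED_DECODE[codes].T)

    markers = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    samples = _join_labels(fam["iid"].to_list(), labels_path)
    return GenotypeMatrix.create(calls, markers, samples)


def write_plink(gm: GenotypeMatrix, prefix) -> None:
    """Write a SNP-major PLINK 1.9 bed/bim/fam fileset."""
    prefix = str(prefix)
    n_samples, n_markers = gm.calls.shape
    encode = np.zeros(4, dtype=np.uint8)
    for dosage, code in _BED_ENCODE.items():
        encode[dosage] = code  # MISSING == -1 indexes the last slot
    codes = encode[gm.calls.T]  # (n_markers, n_samples)
    pad = (-n_samples) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((n_markers, pad), dtype=np.uint8)], axis=1
        )
    quads = codes.reshape(n_markers, -1, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())
    bim = gm.markers.copy()
    bim.insert(2, "cm", 0)
    bim[["chrom", "id", "cm", "pos", "a1", "a2"]].to_csv(
        prefix + ".bim", sep="\t", header=False, index=False
    )
    fam = pd.DataFrame(
        {
            "fid": gm.samples["id"],
            "iid": gm.samples["id"],
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


# ----------------------------------------------------------------------
# VCF


def read_vcf(vcf_path, labels_path=None) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF; dosage counts the ALT allele.

    Multi-allelic and non-SNP records are skipped (count logged).
    """
    from cyvcf2 import VCF

    reader = VCF(str(vcf_path), gts012=True)
    if "##FORMAT=<ID=GT" not in reader.raw_header:
        raise FormatError(f"{vcf_path}: no GT field in FORMAT")
    sample_ids = list(reader.samples)
    rows, meta = [], []
    skipped = 0
    for v in reader:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        gt = np.asarray(v.gt_types, dtype=np.int8)  # 0/1/2 = ALT count, 3 = missing
        gt[gt == 3] = MISSING
        rows.append(gt)
        meta.append(
            (v.ID or f"{v.CHROM}:{v.POS}", str(v.CHROM), int(v.POS), v.ALT[0], v.REF)
        )
    if skipped:
        log.info("read_vcf: skipped %d multi-allelic/non-SNP records", skipped)
    calls = (
        np.asarray(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    markers = pd.DataFrame(meta, columns=["id", "chrom", "pos", "a1", "a2"])
    samples = _join_labels(sample_ids, labels_path)
    return GenotypeMatrix.create(calls, markers, samples)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype fields."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples["id"])
            + "\n"
        )
        for j, row in enumerate(gm.markers.itertuples(index=False)):
            gts = "\t".join(gt_strings[int(g)] for g in gm.calls[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.a2}\t{row.a1}\t.\t.\t.\tGT\t{gts}\n"
            )


# ----------------------------------------------------------------------
# QC filters


def qc_filter(
    gm: GenotypeMatrix,
    min_marker_call_rate: float = 0.9,
    min_sample_call_rate: float = 0.9,
) -> GenotypeMatrix:
    """Drop markers, then samples, whose call rate is <= the threshold.

    Marker call rates are computed on the input matrix; sample call rates
    on the marker-filtered matrix (single pass each, markers first).
    """
    for t in (min_marker_call_rate, min_sample_call_rate):
        if not 0.0 <= t <= 1.0:
            raise ValueError("call-rate thresholds must lie in [0, 1]")
    observed = gm.calls != MISSING
    marker_rate = observed.mean(axis=0)
    keep_m = marker_rate > min_marker_call_rate
    if not keep_m.any():
        raise EmptyResultError("call-rate filter removed every marker")
    out = gm.subset_markers(keep_m)
    sample_rate = (out.calls != MISSING).mean(axis=1)
    keep_s = sample_rate > min_sample_call_rate
    if not keep_s.any():
        raise EmptyResultError("call-rate filter removed every sample")
    out = out.subset_samples(keep_s)
    log.info(
        "qc_filter: removed %d/%d markers, %d/%d samples",
        gm.n_markers - out.n_markers,
        gm.n_markers,
        gm.n_samples - out.n_samples,
        gm.n_samples,
    )
    return out


def pairwise_ibs(gm: GenotypeMatrix) -> np.ndarray:
    """Mean identity-by-state proportion for every sample pair.

    Per-locus IBS between dosages x_i, x_j is ``1 - |x_i - x_j| / 2``,
    averaged over jointly non-missing markers (NaN if none).
    """
    x = gm.calls_float()
    n = gm.n_samples
    ibs = np.full((n, n), np.nan)
    for i in range(n):
        diff = np.abs(x[i] - x[i:])  # vectorized over later rows
        sim = 1.0 - diff / 2.0
        with np.errstate(invalid="ignore"):
            ibs[i, i:] = np.nanmean(sim, axis=1)
        ibs[i:, i] = ibs[i, i:]
    return ibs


def ibs_duplicate_filter(gm: GenotypeMatrix, threshold: float = 0.98) -> GenotypeMatrix:
    """Remove the later-indexed sample of any pair with IBS > threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("IBS threshold must lie in (0, 1]")
    ibs = pairwise_ibs(gm)
    n = gm.n_samples
    removed = np.zeros(n, dtype=bool)
    for i in range(n):
        if removed[i]:
            continue
        for j in range(i + 1, n):
            if removed[j]:
                continue
            if np.isfinite(ibs[i, j]) and ibs[i, j] > threshold:
                removed[j] = True
    if removed.any():
        dropped = gm.samples["id"][removed].to_list()
        log.info("ibs_duplicate_filter: removed %d duplicates: %s", len(dropped), dropped)
    return gm.subset_samples(~removed)


def default_autosomes(n: int = 29) -> set[str]:
    """Autosome label set; 29 autosomes for cattle."""
    return {str(i) for i in range(1, n + 1)}


def autosome_filter(gm: GenotypeMatrix, autosome_labels=None) -> GenotypeMatrix:
    """Retain only markers whose chromosome label is in the autosome set."""
    labels = set(map(str, autosome_labels)) if autosome_labels is not None else default_autosomes()
    keep = gm.markers["chrom"].astype(str).isin(labels).to_numpy()
    log.info("autosome_filter: removed %d non-autosomal markers", int((~keep).sum()))
    return gm.subset_markers(keep)
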