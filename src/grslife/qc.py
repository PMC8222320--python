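"""Genotype input, minor-allele dosage encoding, and SNP-level quality control.

Dosages count copies of the sample minor allele (0/1/2, NaN = missing).
QC filters, applied in a fixed fate order so each SNP receives exactly one
exclusion label: non-autosomal -> indel -> call rate -> MAF -> HWE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

AUTOSOMES = {str(c) for c in range(1, 23)}

#: order in which filters claim a failing SNP
FATE_ORDER = ("non_autosomal", "indel", "call_rate", "maf", "hwe")

SNP_META_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "is_indel",
    "minor_allele",
    "major_allele",
]


@dataclass
class GenotypeMatrix:
    """Participants x SNPs minor-allele dosage table with per-SNP metadata.

    Attributes
    ----------
    participant_ids : list of str
        Row labels, in matrix order.
    snps : pandas.DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, ref, alt,
        is_indel, minor_allele, major_allele``.
    dosage : numpy.ndarray
        Float array of shape ``(n_participants, n_snps)`` holding minor-allele
        counts in {0, 1, 2}; missing calls are NaN.
    """

    participant_ids: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.participant_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.participant_ids)} participants x {len(self.snps)} SNPs"
            )
        missing = [c for c in SNP_META_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"snps table missing columns: {missing}")

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP over non-missing calls.

        The matrix is minor-allele oriented at read time, but missingness or
        subsetting can push a frequency past 0.5, so fold back onto [0, 0.5].
        """
        with np.errstate(invalid="ignore"):
            f = np.nanmean(self.dosage, axis=0) / 2.0
        return np.where(np.isnan(f), 0.0, np.minimum(f, 1.0 - f))

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(hom-major, het, hom-minor) counts for SNP column ``j``."""
        col = self.dosage[:, j]
        col = col[~np.isnan(col)]
        return (
            int(np.sum(col == 0)),
            int(np.sum(col == 1)),
            int(np.sum(col == 2)),
        )

    def select_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Column subset preserving participant order."""
        mask = np.asarray(mask)
        return GenotypeMatrix(
            participant_ids=list(self.participant_ids),
            snps=self.snps.loc[mask].reset_index(drop=True),
            dosage=self.dosage[:, mask],
        )

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage,
            index=pd.Index(self.participant_ids, name="participant_id"),
            columns=self.snps["snp_id"].tolist(),
        )


@dataclass
class QcReport:
    """Per-filter exclusion accounting; each SNP is assigned exactly one fate."""

    n_input: int
    n_excluded_call_rate: int
    n_excluded_maf: int
    n_excluded_hwe: int
    n_excluded_indel: int
    n_excluded_nonautosomal: int
    n_retained: int
    fates: pd.DataFrame = field(repr=False)  # columns: snp_id, fate

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_call_rate": self.n_excluded_call_rate,
            "n_excluded_maf": self.n_excluded_maf,
            "n_excluded_hwe": self.n_excluded_hwe,
            "n_excluded_indel": self.n_excluded_indel,
            "n_excluded_nonautosomal": self.n_excluded_nonautosomal,
            "n_retained": self.n_retained,
        }

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.fates.to_csv(out_dir / "qc_fates.tsv", sep="\t", index=False)
        (out_dir / "qc_summary.json").write_text(
            json.dumps(self.summary(), indent=2) + "\n"
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _orient_to_minor(
    alt_dosage: np.ndarray, ref: str, alt: str
) -> tuple[np.ndarray, str, str]:
    """Flip an ALT-count column so dosage counts the sample minor allele.

    Frequency exactly 0.5 keeps the ALT orientation.
    """
    with np.errstate(invalid="ignore"):
        f_alt = np.nanmean(alt_dosage) / 2.0
    if np.isnan(f_alt) or f_alt <= 0.5:
        return alt_dosage, alt, ref
    return 2.0 - alt_dosage, ref, alt


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from VCF v4.2 or PLINK ``.traw`` dosage text.

    Missing genotypes (``./.`` / ``NA``) map to NaN; every SNP column is
    re-oriented to count the minor allele computed from the sample.

    Raises
    ------
    ValueError
        On multi-allelic records (message names the record) or an
        unrecognised format.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "traw":
        return _read_traw(path)
    raise ValueError(f"unknown genotype format: {format!r} (expected 'vcf' or 'traw')")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    participant_ids = list(vcf.samples)
    meta_rows = []
    columns = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multi-allelic record not supported: {v.CHROM}:{v.POS} "
                f"({v.ID or '.'}) with ALT={v.ALT}"
            )
        alt = v.ALT[0]
        alleles = np.array(
            [[g[0], g[1]] for g in v.genotypes], dtype=float
        )  # -1 encodes missing
        dos = alleles.sum(axis=1)
        dos[(alleles < 0).any(axis=1)] = np.nan
        dos, minor, major = _orient_to_minor(dos, v.REF, alt)
        meta_rows.append(
            {
                "snp_id": v.ID or f"{v.CHROM}:{v.POS}",
                "chrom": str(v.CHROM),
                "pos": int(v.POS),
                "ref": v.REF,
                "alt": alt,
                "is_indel": bool(v.is_indel or len(v.REF) != 1 or len(alt) != 1),
                "minor_allele": minor,
                "major_allele": major,
            }
        )
        columns.append(dos)
    snps = pd.DataFrame(meta_rows, columns=SNP_META_COLUMNS)
    dosage = (
        np.column_stack(columns) if columns else np.empty((len(participant_ids), 0))
    )
    return GenotypeMatrix(participant_ids, snps, dosage)


def _read_traw(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    required = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"malformed .traw header, missing columns: {missing}")
    sample_cols = [c for c in df.columns if c not in required]
    meta_rows = []
    columns = []
    for _, row in df.iterrows():
        counted, other = str(row["COUNTED"]), str(row["ALT"])
        if "," in counted or "," in other:
            raise ValueError(f"multi-allelic record not supported: {row['SNP']}")
        dos = pd.to_numeric(row[sample_cols], errors="coerce").to_numpy(dtype=float)
        dos, minor, major = _orient_to_minor(dos, other, counted)
        meta_rows.append(
            {
                "snp_id": str(row["SNP"]),
                "chrom": str(row["CHR"]),
                "pos": int(row["POS"]),
                # .traw carries no REF/ALT semantics; record major/minor
                "ref": major,
                "alt": minor,
                "is_indel": len(counted) != 1 or len(other) != 1,
                "minor_allele": minor,
                "major_allele": major,
            }
        )
        columns.append(dos)
    snps = pd.DataFrame(meta_rows, columns=SNP_META_COLUMNS)
    dosage = np.column_stack(columns) if columns else np.empty((len(sample_cols), 0))
    return GenotypeMatrix(sample_cols, snps, dosage)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype fields."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    for contig in dict.fromkeys(gm.snps["chrom"]):
        lines.append(f"##contig=<ID={contig}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.participant_ids)
    )
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, snp in gm.snps.iterrows():
        col = gm.dosage[:, j]
        # stored dosage counts the minor allele; GT needs ALT counts
        alt_dos = col if snp["minor_allele"] == snp["alt"] else 2.0 - col
        gts = ["./." if np.isnan(d) else gt_map[d] for d in alt_dos]
        lines.append(
            f"{snp['chrom']}\t{snp['pos']}\t{snp['snp_id']}\t{snp['ref']}\t"
            f"{snp['alt']}\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")


def write_traw(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write PLINK transposed dosage text; COUNTED is the minor allele."""
    path = Path(path)
    header = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"] + list(
        gm.participant_ids
    )
    rows = []
    for j, snp in gm.snps.iterrows():
        vals = [
            "NA" if np.isnan(d) else str(int(d)) for d in gm.dosage[:, j]
        ]
        rows.append(
            [
                snp["chrom"],
                snp["snp_id"],
                "0",
                str(snp["pos"]),
                snp["minor_allele"],
                snp["major_allele"],
            ]
            + vals
        )
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided conditional exact test for Hardy-Weinberg equilibrium.

    Sums the probabilities of all heterozygote counts (conditional on the
    observed allele counts) that are no more probable than the observed one.
    Returns a p-value in (0, 1]; a monomorphic site returns 1.0.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers: {counts}")
    n_AA, n_Aa, n_aa = (int(c) for c in counts)
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped individual required")

    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if rare == 0:
        return 1.0

    # conditional distribution of the het count via the standard recurrence,
    # anchored near the mode for numerical stability
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}

    homr = (rare - mid) // 2
    homc = n - mid - homr
    h, cr, cc = mid, homr, homc
    while h > 1:
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (cr + 1) * (cc + 1))
        h -= 2
        cr += 1
        cc += 1
    h, cr, cc = mid, homr, homc
    while h <= rare - 2:
        probs[h + 2] = probs[h] * 4.0 * cr * cc / ((h + 2.0) * (h + 1.0))
        h += 2
        cr -= 1
        cc -= 1

    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


# ---------------------------------------------------------------------------
# QC driver
# ---------------------------------------------------------------------------


def apply_qc(
    gm: GenotypeMatrix,
    call_rate_min: float = 0.99,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-5,
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter SNPs on autosome membership, indel status, call rate, MAF, HWE.

    Each SNP gets the fate of the first filter it fails, evaluated in
    :data:`FATE_ORDER`; thresholds are inclusive pass (call rate >= min,
    MAF >= min, HWE p >= min).
    """
    for name, thr in (
        ("call_rate_min", call_rate_min),
        ("maf_min", maf_min),
        ("hwe_p_min", hwe_p_min),
    ):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {thr}")
    if gm.n_snps == 0:
        raise ValueError("empty genotype matrix")

    call_rate = gm.call_rate()
    maf = gm.maf()
    fates = []
    for j in range(gm.n_snps):
        snp = gm.snps.iloc[j]
        if str(snp["chrom"]) not in AUTOSOMES:
            fate = "non_autosomal"
        elif snp["is_indel"]:
            fate = "indel"
        elif call_rate[j] < call_rate_min:
            fate = "call_rate"
        elif maf[j] < maf_min:
            fate = "maf"
        elif hwe_exact_test(*gm.genotype_counts(j)) < hwe_p_min:
            fate = "hwe"
        else:
            fate = "retained"
        fates.append(fate)

    fates_df = pd.DataFrame({"snp_id": gm.snps["snp_id"], "fate": fates})
    keep = np.array([f == "retained" for f in fates])
    counts = fates_df["fate"].value_counts()
    report = QcReport(
        n_input=gm.n_snps,
        n_excluded_call_rate=int(counts.get("call_rate", 0)),
        n_excluded_maf=int(counts.get("maf", 0)),
        n_excluded_hwe=int(counts.get("hwe", 0)),
        n_excluded_indel=int(counts.get("indel", 0)),
        n_excluded_nonautosomal=int(counts.get("non_autosomal", 0)),
        n_retained=int(keep.sum()),
        fates=fates_df,
    )
    return gm.select_snps(keep), report
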