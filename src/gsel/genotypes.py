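"""SNP genotype matrices: I/O, filtering, imputation and the genomic relationship matrix.

Dosages are stored as an accession-by-marker float array coding the count of
the alternate allele (0/1/2); missing calls are ``NaN``. The genomic
relationship matrix follows VanRaden's first method (no shrinkage):
``G = W W' / (2 * sum p_j (1 - p_j))`` with ``W`` the dosage matrix centered by
twice the observed alternate-allele frequency of each marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, MatrixError, ConfigurationError

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"

#: smallest eigenvalue below which G is treated as singular
PSD_TOL = 1e-8
#: diagonal ridge added to a (near-)singular G before inversion
GRM_RIDGE = 1e-6


@dataclass
class GenotypeMatrix:
    """Accession-by-marker dosage matrix with missingness mask.

    Parameters
    ----------
    accession_ids : array of str, unique, one per row.
    marker_ids : array of str, unique, one per column.
    dosages : float array of shape (n_accessions, n_markers); alternate-allele
        counts in {0, 1, 2} (continuous values appear after mean imputation);
        missing entries are NaN.
    """

    accession_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.accession_ids = np.asarray(self.accession_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        n, m = self.dosages.shape
        if len(self.accession_ids) != n or len(self.marker_ids) != m:
            raise ConfigurationError("id lengths do not match dosage shape")
        if len(set(self.accession_ids)) != n:
            raise ConfigurationError("duplicate accession ids")
        if len(set(self.marker_ids)) != m:
            raise ConfigurationError("duplicate marker ids")

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, True where the call is missing."""
        return np.isnan(self.dosages)

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-marker alternate-allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        """Per-marker minor-allele frequency over non-missing calls."""
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.accession_ids.copy(), self.marker_ids.copy(), self.dosages.copy()
        )


@dataclass
class GRM:
    """Symmetric positive-semidefinite genomic relationship matrix."""

    accession_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.accession_ids = np.asarray(self.accession_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.accession_ids)
        if self.values.shape != (n, n):
            raise ConfigurationError("GRM shape does not match accession count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise MatrixError("GRM is not symmetric within 1e-10")

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    def index_of(self, accession_ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.array([pos[a] for a in accession_ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"accession {exc} not in GRM") from exc


def grm_inverse(grm: GRM, ridge: float = GRM_RIDGE) -> np.ndarray:
    """Invert a GRM, adding a diagonal ridge when it is numerically singular.

    A ridge of `ridge` is added whenever the smallest eigenvalue falls below
    ``PSD_TOL`` (duplicated accessions make G exactly singular).
    """
    g = grm.values
    w = np.linalg.eigvalsh(g)
    if w[0] < -PSD_TOL:
        raise MatrixError(f"GRM has negative eigenvalue {w[0]:.3e}")
    if w[0] < PSD_TOL:
        g = g + ridge * np.eye(grm.n)
    try:
        return np.linalg.inv(g)
    except np.linalg.LinAlgError as exc:
        raise MatrixError("GRM singular even after ridge") from exc


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from a VCF or a dosage TSV file.

    VCF records that are not biallelic SNPs are skipped (counted and logged).
    Half-missing diploid calls (e.g. ``./1``) are treated as missing; phased
    and unphased separators are both accepted.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage-tsv":
        return read_dosage_tsv(path)
    raise ConfigurationError(f"unknown genotype format: {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    accessions = np.array(vcf.samples, dtype=object)
    columns: list[np.ndarray] = []
    marker_ids: list[str] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        col = np.full(len(accessions), np.nan)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                col[i] = a + b
        columns.append(col)
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    vcf.close()
    if n_skipped:
        logger.warning("skipped %d non-biallelic/non-SNP VCF records", n_skipped)
    if not columns:
        raise EmptyInputError(f"no usable biallelic SNP records in {path}")
    return GenotypeMatrix(accessions, np.array(marker_ids, dtype=object),
                          np.column_stack(columns))


def read_dosage_tsv(path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN])
    except Exception as exc:
        raise FormatError(f"cannot parse dosage TSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise EmptyInputError(f"no markers in {path}")
    return GenotypeMatrix(
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
        df.to_numpy(dtype=np.float64),
    )


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.dosages, index=g.accession_ids, columns=g.marker_ids)
    df.index.name = "accession_id"
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal biallelic-SNP VCF 4.2 (synthetic chrom/pos, GT only).

    Non-integer (imputed) dosages cannot be represented and raise an error.
    """
    d = g.dosages
    ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
    if not ok.all():
        raise FormatError("cannot write non-integer dosages as VCF genotypes")
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(a) for a in g.accession_ids) + "\n")
        for j, mid in enumerate(g.marker_ids):
            calls = "\t".join(
                "./." if np.isnan(x) else gt_code[x] for x in d[:, j]
            )
            fh.write(f"1\t{j + 1}\t{mid}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def read_grm_tsv(path) -> GRM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GRM(df.index.to_numpy(dtype=object), df.to_numpy(dtype=np.float64))


def write_grm_tsv(grm: GRM, path) -> None:
    df = pd.DataFrame(grm.values, index=grm.accession_ids,
                      columns=grm.accession_ids)
    df.index.name = "accession_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# filtering / imputation / GRM
# ---------------------------------------------------------------------------

def filter_markers(g: GenotypeMatrix, max_missing: float = 0.05,
                   min_maf: float = 0.025) -> GenotypeMatrix:
    """Remove markers with more than `max_missing` missing-call fraction or a
    minor-allele frequency strictly below `min_maf`.

    Both statistics are computed over non-missing calls across all accessions
    in the matrix. A marker with MAF exactly equal to `min_maf` is retained.
    """
    if not (0.0 <= max_missing <= 1.0 and 0.0 <= min_maf <= 1.0):
        raise ConfigurationError("thresholds must lie in [0, 1]")
    miss_frac = g.missing.mean(axis=0)
    with np.errstate(invalid="ignore"):
        maf = g.maf
    fail_missing = miss_frac > max_missing
    # markers with all calls missing have NaN maf -> fail both rules
    fail_maf = ~(maf >= min_maf)
    keep = ~(fail_missing | fail_maf)
    logger.info(
        "filter_markers: removed %d for missingness > %.3g, %d for MAF < %.3g "
        "(%d retained of %d)",
        int(fail_missing.sum()), max_missing, int(fail_maf.sum()), min_maf,
        int(keep.sum()), g.n_markers,
    )
    if not keep.any():
        raise EmptyInputError("all markers removed by filtering")
    return GenotypeMatrix(g.accession_ids.copy(), g.marker_ids[keep],
                          g.dosages[:, keep])


def impute_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the marker's mean dosage over observed calls."""
    miss = g.missing
    if not miss.any():
        return g.copy()
    if miss.all(axis=0).any():
        raise EmptyInputError(
            "marker(s) with all calls missing; run filter_markers first")
    d = g.dosages.copy()
    col_mean = np.nanmean(d, axis=0)
    rows, cols = np.nonzero(miss)
    d[rows, cols] = col_mean[cols]
    return GenotypeMatrix(g.accession_ids.copy(), g.marker_ids.copy(), d)


def compute_grm(g: GenotypeMatrix) -> GRM:
    """VanRaden method-1 GRM from complete dosages (no shrinkage).

    Columns are centered by twice their observed allele frequency and the
    cross-product is normalised by ``2 * sum p (1 - p)``.
    """
    d = g.dosages
    if np.isnan(d).any():
        raise MatrixError("missing dosages present; impute first")
    p = d.mean(axis=0) / 2.0
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise MatrixError(
            "monomorphic marker(s) present; remove them with filter_markers")
    w = d - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    values = (w @ w.T) / denom
    values = 0.5 * (values + values.T)
    return GRM(g.accession_ids.copy(), values)
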