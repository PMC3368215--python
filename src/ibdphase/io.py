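"""Data containers and readers/writers for the standard formats.

Genotypes are held as an n x m matrix of minor-allele dosages ({0, 1, 2},
-1 for missing) together with sample allele frequencies; the genetic map
holds per-marker chromosome, base-pair position and cumulative genetic
position in Morgans.  Marker indices are 0-based and intervals half-open
everywhere internally; base-pair positions follow the 1-based VCF
convention in files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("ibdphase")

MISSING = -1


@dataclass
class GeneticMap:
    """Per-marker genetic map.

    Attributes
    ----------
    chrom : chromosome label (single chromosome per run).
    bp : (m,) base-pair positions, strictly increasing.
    morgans : (m,) cumulative genetic positions in Morgans, nondecreasing.
    marker_ids : (m,) marker identifiers.
    """

    chrom: str
    bp: np.ndarray
    morgans: np.ndarray
    marker_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.morgans = np.asarray(self.morgans, dtype=float)
        if self.bp.shape != self.morgans.shape:
            raise ValueError("bp and genetic positions must align")
        if np.any(np.diff(self.bp) <= 0):
            raise ValueError("base-pair positions must be strictly increasing")
        if np.any(np.diff(self.morgans) < 0):
            raise ValueError("genetic positions must be nondecreasing")
        if self.marker_ids is None:
            self.marker_ids = np.array(
                [f"{self.chrom}:{p}" for p in self.bp], dtype=object
            )
        else:
            self.marker_ids = np.asarray(self.marker_ids, dtype=object)

    @property
    def n_markers(self) -> int:
        return self.bp.shape[0]

    @property
    def length_morgans(self) -> float:
        """Genetic length of the mapped region."""
        return float(self.morgans[-1] - self.morgans[0])

    def intervals(self) -> np.ndarray:
        """(m-1,) genetic lengths of the inter-marker intervals, Morgans."""
        return np.diff(self.morgans)

    def marker_weights(self) -> np.ndarray:
        """Local genetic length of each marker (half of each flanking
        interval); weights sum to the chromosome genetic length."""
        d = self.intervals()
        w = np.zeros(self.n_markers)
        w[:-1] += d / 2.0
        w[1:] += d / 2.0
        return w

    def subset(self, keep: np.ndarray) -> "GeneticMap":
        return GeneticMap(
            self.chrom, self.bp[keep], self.morgans[keep], self.marker_ids[keep]
        )


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for n individuals at m markers.

    ``dosages[i, j]`` counts minor alleles (0, 1, 2) or is -1 when missing.
    ``freqs`` are minor-allele frequencies computed over non-missing
    genotypes; minor-allele orientation (0 < f <= 0.5) is enforced by
    :func:`from_raw_dosages`.  Monomorphic markers must be dropped upstream
    (the emission model needs 0 < f < 1).
    """

    sample_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.freqs = np.asarray(self.freqs, dtype=float)
        n, m = self.dosages.shape
        if self.sample_ids.shape[0] != n or self.marker_ids.shape[0] != m:
            raise ValueError("ids do not match dosage matrix shape")
        if self.freqs.shape[0] != m:
            raise ValueError("frequency vector does not match marker count")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @classmethod
    def from_raw_dosages(
        cls,
        sample_ids,
        marker_ids,
        dosages: np.ndarray,
        drop_monomorphic: bool = True,
    ) -> tuple["GenotypeMatrix", np.ndarray]:
        """Build a matrix from raw alt-allele dosages.

        Flips markers so the counted allele is the minor one, computes
        sample frequencies over non-missing genotypes and drops markers
        with zero minor alleles or no data.

        Returns
        -------
        (matrix, kept) : the matrix and the boolean mask of retained
        markers (aligned to the input marker order).
        """
        dosages = np.asarray(dosages, dtype=np.int8)
        marker_ids = np.asarray(marker_ids, dtype=object)
        obs = dosages != MISSING
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(obs, dosages, 0).sum(axis=0) / np.maximum(2 * n_obs, 1)
        flip = f > 0.5
        if np.any(flip):
            cols = dosages[:, flip]
            dosages = dosages.copy()
            dosages[:, flip] = np.where(cols == MISSING, MISSING, 2 - cols)
            f[flip] = 1.0 - f[flip]
        kept = (n_obs > 0) & (f > 0.0)
        if drop_monomorphic and not np.all(kept):
            logger.info("dropping %d monomorphic/empty markers", (~kept).sum())
            dosages = dosages[:, kept]
            marker_ids = marker_ids[kept]
            f = f[kept]
        else:
            kept = np.ones(dosages.shape[1], dtype=bool)
        return cls(sample_ids, marker_ids, dosages, f), kept

    def het_mask(self) -> np.ndarray:
        return self.dosages == 1


# ---------------------------------------------------------------------------
# VCF


def load_genotypes(path: str, fmt: str = "vcf") -> tuple[GenotypeMatrix, GeneticMap]:
    """Load genotypes (and marker coordinates) from VCF or transposed text."""
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "plink-transposed":
        return read_transposed(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def read_vcf(path: str) -> tuple[GenotypeMatrix, GeneticMap]:
    """Read a biallelic-SNP VCF.

    Multi-allelic and non-SNP records are skipped with a logged count.
    Returns the genotype matrix plus a provisional map with bp positions
    only (genetic positions zero; attach a real map with
    :func:`load_map`).
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = np.array(vcf.samples, dtype=object)
    rows, ids, bps = [], [], []
    chrom = None
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise ValueError("multiple chromosomes in one input are unsupported")
        # gts012: 0/1/2 dosage of ALT, 3 = missing
        gt = var.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        bps.append(var.POS)
    if skipped:
        logger.info("skipped %d multi-allelic/non-SNP records", skipped)
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    dosages = np.stack(rows, axis=1)
    geno, kept = GenotypeMatrix.from_raw_dosages(samples, np.array(ids, object), dosages)
    bp = np.array(bps, dtype=np.int64)[kept]
    gmap = GeneticMap(chrom or "1", bp, np.zeros(bp.shape[0]), geno.marker_ids)
    return geno, gmap


def write_vcf(
    path: str,
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    phased: np.ndarray | None = None,
    phased_mask: np.ndarray | None = None,
) -> None:
    """Write genotypes (optionally phased) as a plain-text VCF.

    ``phased`` holds per-haplotype alleles (n, m, 2) with -1 for no-call;
    sites flagged in ``phased_mask`` are written with ``|``, others with
    ``/``.  Allele identities are not tracked internally, so REF/ALT are
    written as placeholder nucleotides (A = major, C = minor).
    """
    n, m = geno.dosages.shape
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={gmap.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.sample_ids))
            + "\n"
        )
        unphased_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(m):
            cols = [
                gmap.chrom,
                str(int(gmap.bp[j])),
                str(geno.marker_ids[j]),
                "A",
                "C",
                ".",
                ".",
                ".",
                "GT",
            ]
            for i in range(n):
                if phased is not None and phased_mask is not None and phased_mask[i, j]:
                    a1, a2 = phased[i, j]
                    s1 = "." if a1 == MISSING else str(int(a1))
                    s2 = "." if a2 == MISSING else str(int(a2))
                    cols.append(f"{s1}|{s2}")
                else:
                    cols.append(unphased_strings[int(geno.dosages[i, j])])
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# PLINK-style transposed text (markers as rows, individuals as columns)


def write_transposed(path: str, geno: GenotypeMatrix, gmap: GeneticMap) -> None:
    df = pd.DataFrame(
        np.where(geno.dosages == MISSING, np.nan, geno.dosages).T,
        index=pd.Index(geno.marker_ids, name="marker"),
        columns=geno.sample_ids,
    )
    df.insert(0, "chrom", gmap.chrom)
    df.insert(1, "bp", gmap.bp)
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def read_transposed(path: str) -> tuple[GenotypeMatrix, GeneticMap]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    chrom = str(df["chrom"].iloc[0])
    bp = df["bp"].to_numpy(dtype=np.int64)
    body = df.drop(columns=["chrom", "bp"])
    dosages = body.to_numpy(dtype=float).T
    dosages = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int8)
    geno, kept = GenotypeMatrix.from_raw_dosages(
        np.array(body.columns, dtype=object),
        np.array(df.index, dtype=object),
        dosages,
    )
    gmap = GeneticMap(chrom, bp[kept], np.zeros(kept.sum()), geno.marker_ids)
    return geno, gmap


# ---------------------------------------------------------------------------
# HapMap-format genetic map: chrom, position, rate (cM/Mb), cumulative cM


def write_map(path: str, gmap: GeneticMap) -> None:
    cm = 100.0 * (gmap.morgans - gmap.morgans[0])
    d_cm = np.diff(cm)
    d_mb = np.diff(gmap.bp) / 1e6
    rate = np.zeros_like(cm)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate[:-1] = np.where(d_mb > 0, d_cm / d_mb, 0.0)
    pd.DataFrame(
        {
            "Chromosome": gmap.chrom,
            "Position(bp)": gmap.bp,
            "Rate(cM/Mb)": rate,
            "Map(cM)": cm,
        }
    ).to_csv(path, sep="\t", index=False)


def load_map(path: str, geno_map: GeneticMap | None = None) -> GeneticMap:
    """Read a HapMap-format map and (optionally) align it to the markers of
    a loaded genotype set by base-pair position.

    Cumulative cM is converted to Morgans.  Markers absent from the map get
    genetic positions linearly interpolated on the bp scale between the
    flanking mapped positions (logged).
    """
    df = pd.read_csv(path, sep=r"\s+|\t", engine="python")
    if df.shape[1] < 4:
        raise ValueError("map file needs columns: chrom, position, rate, map(cM)")
    chrom = str(df.iloc[0, 0])
    bp = df.iloc[:, 1].to_numpy(dtype=np.int64)
    cm = df.iloc[:, 3].to_numpy(dtype=float)
    if np.any(np.diff(bp) <= 0):
        k = int(np.where(np.diff(bp) <= 0)[0][0]) + 2
        raise ValueError(f"map positions not strictly increasing at line {k}")
    if np.any(np.diff(cm) < 0):
        k = int(np.where(np.diff(cm) < 0)[0][0]) + 2
        raise ValueError(f"genetic map not nondecreasing at line {k}")
    morgans = cm / 100.0
    if geno_map is None:
        return GeneticMap(chrom, bp, morgans)
    # align to genotype markers by bp; interpolate the unmapped ones
    pos = geno_map.bp
    mapped = np.isin(pos, bp)
    if not np.all(mapped):
        logger.info("interpolating %d markers absent from the map", (~mapped).sum())
    interp = np.interp(pos, bp, morgans)
    return GeneticMap(geno_map.chrom, pos, interp, geno_map.marker_ids)
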