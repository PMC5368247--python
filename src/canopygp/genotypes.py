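"""Biallelic SNP dosage matrices: container, VCF/CSV input, VCF output.

Dosages count copies of the alternate allele (0/1/2); missing calls are NaN.
VCF reading goes through cyvcf2 and keeps only biallelic SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "read_genotypes", "write_vcf"]


@dataclass
class GenotypeMatrix:
    """Accession x marker dosage matrix.

    ``dosages`` is float (to admit NaN for missing calls) but every non-NaN
    entry is 0, 1 or 2.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.accession_ids) or m != len(self.marker_ids):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset(self, accession_ids: list[str]) -> "GenotypeMatrix":
        index = {a: i for i, a in enumerate(self.accession_ids)}
        missing = [a for a in accession_ids if a not in index]
        if missing:
            raise KeyError(f"accessions not in genotype matrix: {missing[:5]}")
        rows = [index[a] for a in accession_ids]
        return GenotypeMatrix(list(accession_ids), list(self.marker_ids), self.dosages[rows])

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per marker, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.accession_ids, columns=self.marker_ids)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read dosages from a VCF (``.vcf``) or a CSV dosage matrix.

    The CSV layout is accessions in rows (first column = accession id),
    markers in columns.
    """
    path = Path(path)
    if path.suffix.lower() in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        return _read_vcf(path)
    df = pd.read_csv(path, index_col=0, comment="#")
    return GenotypeMatrix(
        [str(a) for a in df.index], [str(m) for m in df.columns], df.to_numpy(dtype=float)
    )


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        if not variant.is_snp or len(variant.ALT) != 1:
            continue
        # gts012: 0/1/2 = dosage of ALT, 3 = missing
        g = variant.gt_types.astype(float)
        g[g == 3] = np.nan
        rows.append(g)
        marker_ids.append(variant.ID or f"{variant.CHROM}_{variant.POS}")
    vcf.close()
    if not rows:
        raise ValueError(f"no biallelic SNPs found in {path}")
    return GenotypeMatrix(samples, marker_ids, np.column_stack(rows))


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a minimal VCFv4.2 with GT fields.

    Markers are laid out on a single synthetic chromosome at consecutive
    positions; ref/alt alleles are placeholders (A/T).  Intended for
    simulated data only.
    """
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.accession_ids) + "\n")
        for j, marker in enumerate(genotypes.marker_ids):
            calls = [
                gt_map.get(genotypes.dosages[i, j], "./.")
                for i in range(genotypes.n_accessions)
            ]
            fh.write(f"1\t{j + 1}\t{marker}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")
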