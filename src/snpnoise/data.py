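"""Core data containers: marker map, genotype matrix, phenotype table.

Genotypes are biallelic SNP dosages coded 0/1/2 (copies of the B allele for
AA/AB/BB) with an explicit boolean missingness mask. Tables round-trip
through plain CSV; a minimal GT-only VCF export/import is provided for
interoperability with standard tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "EmptyPanelError",
    "MarkerMap",
    "GenotypeMatrix",
    "PhenotypeTable",
]


class ConfigError(ValueError):
    """Invalid or infeasible configuration."""


class EmptyPanelError(ValueError):
    """A filter removed every marker from the panel."""


@dataclass(frozen=True)
class MarkerMap:
    """Marker identifiers and their chromosome assignment."""

    ids: np.ndarray
    chromosomes: np.ndarray

    def __post_init__(self):
        ids = np.asarray(self.ids, dtype=object)
        chrom = np.asarray(self.chromosomes, dtype=int)
        if ids.shape != chrom.shape or ids.ndim != 1:
            raise ValueError("ids and chromosomes must be 1-D and equal length")
        if len(set(ids.tolist())) != len(ids):
            raise ValueError("marker ids must be unique")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "chromosomes", chrom)

    @property
    def n_markers(self) -> int:
        return len(self.ids)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.ids[idx], self.chromosomes[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"marker": self.ids, "chromosome": self.chromosomes})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MarkerMap":
        df = pd.read_csv(path)
        return cls(df["marker"].to_numpy(dtype=object), df["chromosome"].to_numpy())


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with missingness mask.

    ``dosage[i, j]`` is meaningful only where ``missing_mask[i, j]`` is False.
    ``meta`` carries provenance from the synthetic generator (causal / rare /
    low-call-rate marker ids) and is preserved through QC subsetting.
    """

    samples: list
    markers: MarkerMap
    dosage: np.ndarray
    missing_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = self.dosage.shape
        if len(self.samples) != n or self.markers.n_markers != m:
            raise ValueError("inconsistent shapes between samples/markers/dosage")
        if self.missing_mask.shape != (n, m):
            raise ValueError("missing_mask shape mismatch")
        observed = self.dosage[~self.missing_mask]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("observed dosages must lie in {0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return self.markers.n_markers

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples),
            self.markers,
            self.dosage.copy(),
            self.missing_mask.copy(),
            dict(self.meta),
        )

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to marker positions ``keep`` (index array)."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            list(self.samples),
            self.markers.subset(keep),
            self.dosage[:, keep],
            self.missing_mask[:, keep],
            dict(self.meta),
        )

    def values(self) -> np.ndarray:
        """Float matrix with NaN at missing cells."""
        x = self.dosage.astype(float)
        x[self.missing_mask] = np.nan
        return x

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values(), index=self.samples, columns=self.markers.ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, na_rep="NA", index_label="sample")

    @classmethod
    def from_csv(cls, path, markers: MarkerMap | None = None) -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col=0)
        x = df.to_numpy(dtype=float)
        mask = np.isnan(x)
        dosage = np.where(mask, 0, x).astype(np.int16)
        if markers is None:
            ids = df.columns.to_numpy(dtype=object)
            markers = MarkerMap(ids, np.ones(len(ids), dtype=int))
        return cls(list(df.index), markers, dosage, mask)

    # -- minimal VCF interoperability (GT field only, diploid, unphased) ----

    def to_vcf(self, path) -> None:
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        lines = ["##fileformat=VCFv4.2", "##source=snpnoise"]
        for c in sorted(set(self.markers.chromosomes.tolist())):
            lines.append(f"##contig=<ID={c}>")
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in self.samples)
        )
        pos_within: dict[int, int] = {}
        for j in range(self.n_markers):
            chrom = int(self.markers.chromosomes[j])
            pos_within[chrom] = pos_within.get(chrom, 0) + 1
            calls = [
                "./." if self.missing_mask[i, j] else gt_codes[int(self.dosage[i, j])]
                for i in range(self.n_samples)
            ]
            lines.append(
                f"{chrom}\t{1000 * pos_within[chrom]}\t{self.markers.ids[j]}"
                "\tA\tB\t.\t.\t.\tGT\t" + "\t".join(calls)
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Import a GT-only VCF via cyvcf2 (optional dependency)."""
        from cyvcf2 import VCF  # lazy: optional extra

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        ids, chroms, rows, masks = [], [], [], []
        for var in vcf:
            ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            chroms.append(int(var.CHROM))
            gts = np.array([g[:2] for g in var.genotypes])
            miss = (gts < 0).any(axis=1)
            dos = np.clip(gts, 0, None).sum(axis=1)
            rows.append(np.where(miss, 0, dos))
            masks.append(miss)
        dosage = np.array(rows).T
        mask = np.array(masks).T
        return cls(samples, MarkerMap(np.array(ids, dtype=object), np.array(chroms)), dosage, mask)


@dataclass
class PhenotypeTable:
    """Per-plant phenotype records: line of origin, root elongation, binary vigor label.

    Label convention: 1 = high root vigor (positive/majority class),
    0 = low root vigor (negative/minority class).
    """

    sample_ids: list
    line: np.ndarray
    elongation: np.ndarray
    label: np.ndarray

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.line = np.asarray(self.line, dtype=int)
        self.elongation = np.asarray(self.elongation, dtype=float)
        self.label = np.asarray(self.label, dtype=int)
        n = len(self.sample_ids)
        if not (len(self.line) == len(self.elongation) == len(self.label) == n):
            raise ValueError("phenotype columns must share one length")
        if not set(np.unique(self.label)).issubset({0, 1}):
            raise ValueError("labels must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_ids,
                "line": self.line,
                "elongation": self.elongation,
                "label": self.label,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PhenotypeTable":
        df = pd.read_csv(path)
        return cls(
            list(df["sample"]),
            df["line"].to_numpy(),
            df["elongation"].to_numpy(),
            df["label"].to_numpy(),
        )
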