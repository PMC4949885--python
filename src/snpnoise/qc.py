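"""Marker quality control: call-rate filter, imputation, MAF filter.

The pipeline order is fixed — call-rate filter, then imputation of the
remaining missing calls, then minor-allele-frequency filter — and both
filters use inclusive (<=) thresholds. Missing genotypes are imputed with a
k-nearest-sample dosage average (Euclidean distance over mutually observed
markers, rounded half away from zero to a valid dosage).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .data import EmptyPanelError, GenotypeMatrix

__all__ = [
    "QCReport",
    "marker_call_rate",
    "sample_call_rate",
    "filter_by_call_rate",
    "impute_missing",
    "minor_allele_frequency",
    "filter_by_maf",
    "run_qc",
]


@dataclass
class QCReport:
    """Counts and per-marker statistics from one QC run."""

    n_markers_in: int
    n_removed_callrate: int
    n_imputed_cells: int
    n_removed_maf: int
    n_markers_out: int
    removed_callrate_ids: list
    removed_maf_ids: list
    call_rate: dict          # marker id -> pre-filter call-rate
    maf: dict                # marker id -> post-imputation MAF (surviving call-rate filter)
    sample_call_rate: dict   # sample id -> call-rate (reported, never filtered on)

    def __post_init__(self):
        expected = self.n_markers_in - self.n_removed_callrate - self.n_removed_maf
        if self.n_markers_out != expected:
            raise ValueError("QCReport count identity violated")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def marker_call_rate(G: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per marker."""
    if G.n_samples == 0 or G.n_markers == 0:
        raise ValueError("empty genotype matrix")
    return 1.0 - G.missing_mask.mean(axis=0)


def sample_call_rate(G: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per sample."""
    return 1.0 - G.missing_mask.mean(axis=1)


def filter_by_call_rate(
    G: GenotypeMatrix, threshold: float = 0.85, inclusive: bool = True
) -> tuple[GenotypeMatrix, list]:
    """Remove markers with call-rate <= threshold (< if ``inclusive`` is False)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    cr = marker_call_rate(G)
    drop = cr <= threshold if inclusive else cr < threshold
    if drop.all():
        raise EmptyPanelError("call-rate filter removed every marker")
    removed = G.markers.ids[drop].tolist()
    return G.subset_markers(np.flatnonzero(~drop)), removed


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def impute_missing(G: GenotypeMatrix, k: int = 5) -> GenotypeMatrix:
    """Fill missing calls with the rounded dosage mean of the k nearest samples.

    Sample-sample distances are root-mean-square dosage differences over
    mutually observed markers (the normalization keeps pairs with different
    overlap comparable). Neighbours must have the target marker observed;
    ties in distance break toward the lower sample index. If no neighbour
    observes the marker, the marker's observed mode is used; a fully missing
    marker falls back to dosage 0 with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not G.missing_mask.any():
        return G.copy()
    out = G.copy()
    X = G.dosage.astype(float)
    obs = ~G.missing_mask
    Xz = np.where(obs, X, 0.0)

    # pairwise mean squared difference over mutually observed markers
    mutual = obs.astype(float) @ obs.astype(float).T
    sq = (Xz**2 * obs) @ obs.T + obs @ (Xz**2 * obs).T - 2 * Xz @ Xz.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(np.maximum(sq, 0.0) / mutual)
    dist[mutual == 0] = np.inf
    np.fill_diagonal(dist, np.inf)

    for j in np.flatnonzero(G.missing_mask.any(axis=0)):
        donors = np.flatnonzero(obs[:, j])
        for i in np.flatnonzero(G.missing_mask[:, j]):
            if len(donors) == 0:
                warnings.warn(
                    f"marker {G.markers.ids[j]} fully missing; imputing dosage 0"
                )
                out.dosage[i, j] = 0
                continue
            d = dist[i, donors]
            finite = np.isfinite(d)
            if not finite.any():
                vals, counts = np.unique(X[donors, j], return_counts=True)
                out.dosage[i, j] = int(vals[np.argmax(counts)])
                continue
            order = np.argsort(d[finite], kind="stable")
            chosen = donors[finite][order[:k]]
            val = _round_half_away(float(X[chosen, j].mean()))
            out.dosage[i, j] = int(np.clip(val, 0, 2))
    out.missing_mask[:] = False
    return out


def minor_allele_frequency(G: GenotypeMatrix) -> np.ndarray:
    """MAF per marker: min(f, 1-f) with f = sum(dosage) / (2 n). Requires complete data."""
    if G.missing_mask.any():
        raise ValueError("MAF requires a complete matrix (impute first)")
    f = G.dosage.sum(axis=0) / (2.0 * G.n_samples)
    return np.minimum(f, 1.0 - f)


def filter_by_maf(
    G: GenotypeMatrix, threshold: float = 0.025, inclusive: bool = True
) -> tuple[GenotypeMatrix, list]:
    """Remove markers with MAF <= threshold (< if ``inclusive`` is False)."""
    maf = minor_allele_frequency(G)
    drop = maf <= threshold if inclusive else maf < threshold
    if drop.all():
        raise EmptyPanelError("MAF filter removed every marker")
    removed = G.markers.ids[drop].tolist()
    return G.subset_markers(np.flatnonzero(~drop)), removed


def run_qc(
    G: GenotypeMatrix,
    callrate_max: float = 0.85,
    maf_max: float = 0.025,
    impute_k: int = 5,
) -> tuple[GenotypeMatrix, QCReport]:
    """Call-rate filter -> imputation -> MAF filter, with a count-consistent report."""
    cr = marker_call_rate(G)
    scr = sample_call_rate(G)
    G1, removed_cr = filter_by_call_rate(G, callrate_max, inclusive=True)
    n_imputed = G1.n_missing
    G2 = impute_missing(G1, k=impute_k)
    maf = minor_allele_frequency(G2)
    G3, removed_maf = filter_by_maf(G2, maf_max, inclusive=True)
    report = QCReport(
        n_markers_in=G.n_markers,
        n_removed_callrate=len(removed_cr),
        n_imputed_cells=n_imputed,
        n_removed_maf=len(removed_maf),
        n_markers_out=G3.n_markers,
        removed_callrate_ids=removed_cr,
        removed_maf_ids=removed_maf,
        call_rate={str(i): float(v) for i, v in zip(G.markers.ids, cr)},
        maf={str(i): float(v) for i, v in zip(G2.markers.ids, maf)},
        sample_call_rate={str(s): float(v) for s, v in zip(G.samples, scr)},
    )
    return G3, report
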