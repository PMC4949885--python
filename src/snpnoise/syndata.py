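"""Seeded synthetic sugar-beet populations.

The generator emulates the statistical structure of a small selected
sugar-beet panel: 123 plants from 18 inbred-derived lines (15 high-vigor
lines totalling 99 plants, 3 low-vigor lines totalling 24), genotyped at
192 SNPs spread evenly over the 9 chromosomes. Root elongation is bimodal
(class means 12.9 and 2.6 mm/day) and the binary vigor label is the
dichotomization at the midpoint between the class means.

The genotype-phenotype link is a line-level allele-frequency-contrast model:
a configurable set of causal SNPs segregates at frequency ~0.9 in high-vigor
lines and ~0.1 in low-vigor lines, while background SNPs drift around a
shared base frequency per line. Dosages are Binomial(2, p) draws, which
makes the two classes linearly separable in genotype space by construction.

Fixture-construction stages then overlay the panel's data-quality blemishes:
a fixed count of missing genotype calls (one designated marker pushed below
85 % call-rate), and a set of near-monomorphic markers with MAF <= 2.5 %.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats

from ._seeds import rng_for
from .data import ConfigError, GenotypeMatrix, MarkerMap, PhenotypeTable

__all__ = [
    "SynConfig",
    "generate_population",
    "force_rare_markers",
    "apply_missingness",
    "simulate",
]


@dataclass(frozen=True)
class SynConfig:
    """Parameters of the synthetic population (defaults emulate the panel)."""

    n_samples: int = 123
    n_high: int = 99
    n_low: int = 24
    n_lines_high: int = 15
    n_lines_low: int = 3
    n_markers: int = 192
    n_chromosomes: int = 9
    # genetic architecture
    n_causal: int = 40
    causal_freq_high: float = 0.9
    causal_freq_low: float = 0.1
    base_freq_beta: float = 2.0          # symmetric Beta(a, a) for base frequency
    base_freq_bounds: tuple = (0.1, 0.9)
    line_drift_concentration: float = 30.0
    # phenotype
    elongation_mean_high: float = 12.9   # mm/day
    elongation_mean_low: float = 2.6     # mm/day
    elongation_sd: float = 1.5           # mm/day
    elongation_threshold: float = 7.75   # midpoint of the class means
    # data-quality blemishes
    n_missing_cells: int = 738
    low_callrate_missing: int = 21       # missing calls on the designated marker
    n_rare_markers: int = 16
    rare_max_copies: int = 6             # minor-allele copies out of 2*n_samples

    def validate(self) -> None:
        if self.n_high + self.n_low != self.n_samples:
            raise ConfigError(
                f"class counts {self.n_high}+{self.n_low} != n_samples {self.n_samples}"
            )
        if self.n_causal + self.n_rare_markers > self.n_markers:
            raise ConfigError("causal and forced-rare marker sets cannot be disjoint")
        if self.n_missing_cells > self.n_samples * self.n_markers:
            raise ConfigError("more missing cells than genotype cells")
        if self.low_callrate_missing > self.n_missing_cells:
            raise ConfigError("low-call-rate marker missing count exceeds total")
        if not 0 <= self.causal_freq_high <= 1 or not 0 <= self.causal_freq_low <= 1:
            raise ConfigError("causal allele frequencies must lie in [0, 1]")
        if self.n_lines_high < 1 or self.n_lines_low < 1:
            raise ConfigError("need at least one line per class")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SynConfig":
        cfg = cls(**mapping)
        cfg.validate()
        return cfg


def _split_evenly(total: int, parts: int) -> list[int]:
    """Split ``total`` into ``parts`` integers differing by at most 1 (remainder first)."""
    base, rem = divmod(total, parts)
    return [base + 1] * rem + [base] * (parts - rem)


def generate_population(config: SynConfig, seed: int) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Draw a complete (no missing cells) population under ``config``.

    Plants are allocated to lines as evenly as possible; each line carries one
    true vigor class. Causal markers segregate at the configured frequency
    contrast by line class; background markers drift per line around a shared
    base frequency; dosages are Binomial(2, p). Elongation is drawn from a
    truncated normal on the correct side of the class threshold so the label
    counts are exact for every seed.
    """
    config.validate()
    n, m = config.n_samples, config.n_markers

    # line allocation: high lines first, then low lines
    sizes = _split_evenly(config.n_high, config.n_lines_high) + _split_evenly(
        config.n_low, config.n_lines_low
    )
    n_lines = config.n_lines_high + config.n_lines_low
    line_of_sample = np.repeat(np.arange(n_lines), sizes)
    line_is_high = np.arange(n_lines) < config.n_lines_high

    marker_ids = np.array([f"SNP{j + 1:04d}" for j in range(m)], dtype=object)
    chroms = (np.arange(m) % config.n_chromosomes) + 1  # round-robin assignment
    markers = MarkerMap(marker_ids, chroms)

    rng_c = rng_for(seed, "causal")
    causal = np.sort(rng_c.choice(m, size=config.n_causal, replace=False))
    background = np.setdiff1d(np.arange(m), causal)

    # per-line, per-marker allele frequencies
    rng_f = rng_for(seed, "freqs")
    lo, hi = config.base_freq_bounds
    base = np.clip(
        rng_f.beta(config.base_freq_beta, config.base_freq_beta, size=len(background)),
        lo,
        hi,
    )
    c = config.line_drift_concentration
    p_line = np.empty((n_lines, m))
    p_line[:, background] = np.clip(
        rng_f.beta(base * c, (1 - base) * c, size=(n_lines, len(background))),
        0.02,
        0.98,
    )
    p_line[line_is_high[:, None] & np.isin(np.arange(m), causal)[None, :]] = (
        config.causal_freq_high
    )
    p_line[~line_is_high[:, None] & np.isin(np.arange(m), causal)[None, :]] = (
        config.causal_freq_low
    )

    rng_d = rng_for(seed, "dosage")
    dosage = rng_d.binomial(2, p_line[line_of_sample, :]).astype(np.int16)

    # phenotype: truncated normal on the correct side of the threshold
    rng_e = rng_for(seed, "elongation")
    is_high_sample = line_is_high[line_of_sample]
    elong = np.empty(n)
    thr, sd = config.elongation_threshold, config.elongation_sd
    a_high = (thr - config.elongation_mean_high) / sd
    elong[is_high_sample] = stats.truncnorm.rvs(
        a_high, np.inf, loc=config.elongation_mean_high, scale=sd,
        size=int(is_high_sample.sum()), random_state=rng_e,
    )
    b_low = (thr - config.elongation_mean_low) / sd
    elong[~is_high_sample] = stats.truncnorm.rvs(
        -np.inf, b_low, loc=config.elongation_mean_low, scale=sd,
        size=int((~is_high_sample).sum()), random_state=rng_e,
    )
    labels = (elong > thr).astype(int)

    sample_ids = [f"P{i + 1:03d}" for i in range(n)]
    G = GenotypeMatrix(
        sample_ids,
        markers,
        dosage,
        np.zeros((n, m), dtype=bool),
        meta={"causal_markers": marker_ids[causal].tolist()},
    )
    pheno = PhenotypeTable(sample_ids, line_of_sample + 1, elong, labels)
    return G, pheno


def force_rare_markers(G: GenotypeMatrix, config: SynConfig, seed: int) -> GenotypeMatrix:
    """Overwrite a designated disjoint-from-causal marker set to MAF <= max copies.

    Each forced-rare marker is rewritten as heterozygous carriers in 1..max
    randomly chosen samples (all other samples homozygous reference), so its
    minor-allele count is at most ``rare_max_copies`` of ``2 * n_samples``.
    """
    config.validate()
    out = G.copy()
    rng = rng_for(seed, "rare")
    causal_idx = np.flatnonzero(np.isin(G.markers.ids, G.meta.get("causal_markers", [])))
    eligible = np.setdiff1d(np.arange(G.n_markers), causal_idx)
    if len(eligible) < config.n_rare_markers:
        raise ConfigError("rare-marker set would overlap the causal set")
    rare = np.sort(rng.choice(eligible, size=config.n_rare_markers, replace=False))
    for j in rare:
        copies = int(rng.integers(1, config.rare_max_copies + 1))
        carriers = rng.choice(G.n_samples, size=min(copies, G.n_samples), replace=False)
        out.dosage[:, j] = 0
        out.dosage[carriers, j] = 1
    out.meta["rare_markers"] = G.markers.ids[rare].tolist()
    return out


def apply_missingness(G: GenotypeMatrix, config: SynConfig, seed: int) -> GenotypeMatrix:
    """Mask exactly ``n_missing_cells`` genotype calls.

    One designated marker (outside the causal and forced-rare sets) receives
    ``low_callrate_missing`` masked calls, pushing its call-rate below 0.85.
    The remaining cells are placed by a seeded permutation over all other
    markers' cells, subject to two caps that hold for every seed: no other
    marker may fall to call-rate <= 0.85, and no sample may lose more than
    half of its genotypes.
    """
    config.validate()
    if G.missing_mask.any():
        raise ValueError("apply_missingness expects a complete matrix")
    if config.n_missing_cells < config.low_callrate_missing:
        raise ConfigError("n_missing_cells smaller than low-call-rate marker count")
    out = G.copy()
    n, m = G.n_samples, G.n_markers
    if config.n_missing_cells == 0:
        return out
    rng = rng_for(seed, "missing")

    special = set(
        np.flatnonzero(
            np.isin(
                G.markers.ids,
                G.meta.get("causal_markers", []) + G.meta.get("rare_markers", []),
            )
        ).tolist()
    )
    candidates_star = np.setdiff1d(np.arange(m), sorted(special))
    star = int(rng.choice(candidates_star))
    star_rows = rng.choice(n, size=min(config.low_callrate_missing, n), replace=False)
    out.missing_mask[star_rows, star] = True

    remaining = config.n_missing_cells - len(star_rows)
    # per-marker cap keeping call-rate strictly above 0.85; per-sample cap 50%
    marker_cap = int(np.ceil(0.15 * n)) - 1
    sample_cap = m // 2
    sample_count = np.zeros(n, dtype=int)
    sample_count[star_rows] = 1
    marker_count = np.zeros(m, dtype=int)

    cells = np.array(
        [(i, j) for j in range(m) if j != star for i in range(n)], dtype=int
    )
    order = rng.permutation(len(cells))
    taken = 0
    for idx in order:
        if taken == remaining:
            break
        i, j = cells[idx]
        if sample_count[i] >= sample_cap or marker_count[j] >= marker_cap:
            continue
        out.missing_mask[i, j] = True
        sample_count[i] += 1
        marker_count[j] += 1
        taken += 1
    if taken < remaining:
        raise ConfigError("could not place the requested number of missing cells")
    out.meta["low_callrate_marker"] = str(G.markers.ids[star])
    return out


def simulate(config: SynConfig | None = None, seed: int = 0) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Full fixture: generate, force rare markers, overlay missingness."""
    config = config or SynConfig()
    G, pheno = generate_population(config, seed)
    G = force_rare_markers(G, config, seed)
    G = apply_missingness(G, config, seed)
    return G, pheno
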