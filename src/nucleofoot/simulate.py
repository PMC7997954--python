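"""Synthetic cfDNA / MNase cohort simulator.

The generator produces fragment-level data with the statistical structure
the downstream analysis assumes:

* nucleosome-phased fragment midpoints — per gene, an array of Gaussian
  midpoint clusters at ``tss + k * nucleosome_repeat`` for
  ``k = -K..K``, jittered by ``positioning_jitter_sd``;
* a nucleosome-depleted region (NDR) at active promoters — the k = 0
  nucleosome (the one whose centre falls in the NDR window) is
  suppressed with probability equal to the gene's depletion level, a
  monotone function of expression (TPM);
* assay-specific fragment lengths — normal, truncated at >= 50 bp, with
  cfDNA fragments ~166 bp and MNase-protected cores ~146 bp;
* a uniform background fraction of midpoints across the genome;
* two-group cohorts with planted differential TSSs — group-B samples
  have the whole-promoter occupancy rate of each planted TSS multiplied
  by the effect factor, in the planted direction.

All randomness flows from a single root seed through documented
``numpy.random.SeedSequence`` streams, so cohorts are reproducible
sample-by-sample.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError
from .io import FragmentSet, TssTable

# SeedSequence stream tags (root_seed, TAG, ...)
_STREAM_LANDSCAPE = 0
_STREAM_DESIGN = 1
_STREAM_SAMPLE = 2

ASSAYS = ("cfdna", "mnase")


def derive_rng(root_seed: int, *stream: int) -> np.random.Generator:
    """Deterministic child generator for a named stream of the root seed."""
    return np.random.default_rng(np.random.SeedSequence((int(root_seed),) + tuple(stream)))


def derive_sample_seed(root_seed: int, sample_index: int) -> int:
    """Deterministic per-sample seed: root seed plus sample index."""
    ss = np.random.SeedSequence((int(root_seed), _STREAM_SAMPLE, int(sample_index)))
    return int(ss.generate_state(1)[0])


@dataclasses.dataclass
class SimulatorConfig:
    """Study conditions for the synthetic landscape and samples.

    Defaults describe a desk-scale genome (two 5-Mb chromosomes, 2000
    genes) with per-sample fragment counts chosen so that TSS windows
    receive depths comparable, per kilobase, to a low-coverage
    whole-genome cfDNA library.
    """

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 2000
    min_tss_spacing: int = 4000
    nucleosome_repeat: int = 190
    positioning_jitter_sd: float = 20.0
    cfdna_len_mean: float = 166.0
    cfdna_len_sd: float = 10.0
    mnase_len_mean: float = 146.0
    mnase_len_sd: float = 8.0
    ndr_window: tuple = (-150, 50)
    background_fraction: float = 0.1
    fragments_per_sample: int = 200_000
    expression_zero_fraction: float = 0.3
    expression_lognorm_params: tuple = (2.0, 1.5)
    depletion_strength: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.chrom_length, self.n_genes, self.min_tss_spacing,
               self.nucleosome_repeat, self.fragments_per_sample, self.n_chroms) <= 0:
            raise ConfigurationError("all sizes and lengths must be positive")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ConfigurationError("background_fraction must lie in [0, 1]")
        if not 0.0 <= self.expression_zero_fraction <= 1.0:
            raise ConfigurationError("expression_zero_fraction must lie in [0, 1]")
        if not self.ndr_window[0] < self.ndr_window[1]:
            raise ConfigurationError("ndr_window start must be below its end")
        if self.depletion_strength < 0:
            raise ConfigurationError("depletion_strength must be >= 0")
        if min(self.cfdna_len_mean, self.cfdna_len_sd,
               self.mnase_len_mean, self.mnase_len_sd) <= 0:
            raise ConfigurationError("fragment length parameters must be positive")

    @property
    def nucleosomes_per_side(self) -> int:
        """Number of phased nucleosomes simulated on each side of a TSS."""
        return max(1, self.min_tss_spacing // (2 * self.nucleosome_repeat))


@dataclasses.dataclass
class CohortDesign:
    """Two-group cohort layout with planted differential TSSs.

    ``effect_factor`` multiplies the group-B occupancy rate at each
    differential TSS; ``direction_split`` is the proportion of planted
    TSSs with higher occupancy in group A (those get group-B rate
    divided by the factor, so |log fold change| = log effect_factor in
    both directions).
    """

    n_group_a: int = 28
    n_group_b: int = 10
    n_differential_tss: int = 0
    effect_factor: float = 1.8
    direction_split: float = 0.5

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ConfigurationError("each group needs at least 2 samples")
        if self.effect_factor <= 0:
            raise ParameterError("effect_factor must be positive")
        if self.n_differential_tss > 0 and self.effect_factor == 1.0:
            raise ConfigurationError(
                "effect_factor must differ from 1 when differential TSSs are planted"
            )
        if not 0.0 <= self.direction_split <= 1.0:
            raise ConfigurationError("direction_split must lie in [0, 1]")


@dataclasses.dataclass
class Landscape:
    """A simulated genome annotation: TSSs, expression, depletion levels."""

    tss: TssTable
    expression: pd.Series  # TPM per gene
    depletion: pd.Series  # suppression probability of the NDR nucleosome
    chrom_lengths: dict
    config: SimulatorConfig


@dataclasses.dataclass
class TruthSet:
    """Ground truth of a simulated cohort, for recovery benchmarking."""

    directions: dict  # gene_id -> "up_in_a" | "up_in_b"
    tpm: pd.Series
    depletion: pd.Series

    @property
    def differential_tss_ids(self) -> set:
        return set(self.directions)

    def to_json_dict(self) -> dict:
        return {
            "directions": dict(sorted(self.directions.items())),
            "tpm": {g: float(v) for g, v in self.tpm.items()},
            "depletion": {g: float(v) for g, v in self.depletion.items()},
        }


def depletion_from_tpm(tpm: np.ndarray, strength: float) -> np.ndarray:
    """Suppression probability of the NDR nucleosome given expression.

    A saturating monotone map ``strength * tpm / (tpm + 10)`` clipped to
    [0, 1]: unexpressed genes keep their promoter nucleosome, highly
    expressed genes (TPM >> 10) lose it with probability approaching
    ``strength``.
    """
    return np.clip(strength * tpm / (tpm + 10.0), 0.0, 1.0)


def simulate_landscape(config: SimulatorConfig) -> Landscape:
    """Place TSSs, draw zero-inflated log-normal TPM, derive depletion."""
    rng = derive_rng(config.seed, _STREAM_LANDSCAPE)
    margin = 5 * config.nucleosome_repeat + 1000
    n_per = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        n_per[i] += 1
    chroms, positions = [], []
    for ci, n in enumerate(n_per):
        if n == 0:
            continue
        usable = config.chrom_length - 2 * margin
        spacing = usable / n
        if spacing < config.min_tss_spacing:
            raise ConfigurationError(
                f"{config.n_genes} genes at spacing >= {config.min_tss_spacing} bp "
                f"do not fit on {config.n_chroms} x {config.chrom_length} bp"
            )
        jitter_room = spacing - config.min_tss_spacing
        u = rng.uniform(0.0, jitter_room, size=n) if jitter_room > 0 else np.zeros(n)
        pos = (margin + np.arange(n) * spacing + u).astype(np.int64)
        chroms.extend([f"chr{ci + 1}"] * n)
        positions.extend(pos.tolist())
    strands = rng.choice(np.array(["+", "-"], dtype=object), size=config.n_genes)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    tss = TssTable(
        pd.DataFrame(
            {"chrom": chroms, "tss": positions, "strand": strands},
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    zero = rng.random(config.n_genes) < config.expression_zero_fraction
    mu, sigma = config.expression_lognorm_params
    tpm = rng.lognormal(mu, sigma, size=config.n_genes)
    tpm[zero] = 0.0
    expression = pd.Series(tpm, index=tss.df.index, name="tpm")
    depletion = pd.Series(
        depletion_from_tpm(tpm, config.depletion_strength),
        index=tss.df.index,
        name="depletion",
    )
    chrom_lengths = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    return Landscape(tss, expression, depletion, chrom_lengths, config)


def _truncated_normal_lengths(rng, mean, sd, n, lower=50.0) -> np.ndarray:
    lengths = rng.normal(mean, sd, size=n)
    bad = lengths < lower
    while bad.any():
        lengths[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = lengths < lower
    return np.rint(lengths).astype(np.int64)


def simulate_sample(
    landscape: Landscape,
    config: SimulatorConfig,
    assay: str = "cfdna",
    sample_seed: int = 0,
    sample_id: Optional[str] = None,
    gene_weights: Optional[np.ndarray] = None,
) -> FragmentSet:
    """Draw exactly ``fragments_per_sample`` fragments for one sample.

    Midpoints come from a mixture of nucleosome-centre Gaussians (the
    NDR nucleosome down-weighted by the gene's depletion level) and a
    uniform background; lengths are assay-specific truncated normals.
    ``gene_weights`` rescales per-gene sampling rates (cohort effects).
    """
    if assay not in ASSAYS:
        raise ParameterError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    rng = np.random.default_rng(np.random.SeedSequence(int(sample_seed)))
    cfg = config
    n = cfg.fragments_per_sample
    n_genes = len(landscape.tss)
    tss_pos = landscape.tss.df["tss"].to_numpy()
    gene_chrom = landscape.tss.df["chrom"].to_numpy()
    depl = landscape.depletion.to_numpy()

    n_bg = int(rng.binomial(n, cfg.background_fraction))
    n_nuc = n - n_bg

    if gene_weights is None:
        w = np.full(n_genes, 1.0 / n_genes)
    else:
        gene_weights = np.asarray(gene_weights, dtype=float)
        if gene_weights.shape != (n_genes,) or (gene_weights <= 0).any():
            raise ParameterError("gene_weights must be positive, one per gene")
        w = gene_weights / gene_weights.sum()

    gi = rng.choice(n_genes, size=n_nuc, p=w)
    K = cfg.nucleosomes_per_side
    # probability of the NDR (k = 0) nucleosome among the 2K + 1 positions,
    # with its weight reduced by the depletion level
    w0 = 1.0 - depl[gi]
    p0 = w0 / (2 * K + w0)
    is_center = rng.random(n_nuc) < p0
    k = rng.integers(0, 2 * K, size=n_nuc) - K
    k[k >= 0] += 1  # uniform over {-K..-1, 1..K}
    k[is_center] = 0
    mids = tss_pos[gi] + k * cfg.nucleosome_repeat + rng.normal(
        0.0, cfg.positioning_jitter_sd, size=n_nuc
    )
    nuc_chroms = gene_chrom[gi]

    chrom_names = np.array(sorted(landscape.chrom_lengths), dtype=object)
    chrom_sizes = np.array([landscape.chrom_lengths[c] for c in chrom_names], dtype=float)
    bg_ci = rng.choice(len(chrom_names), size=n_bg, p=chrom_sizes / chrom_sizes.sum())
    bg_mids = rng.uniform(0, chrom_sizes[bg_ci]) if n_bg else np.empty(0)
    bg_chroms = chrom_names[bg_ci]

    all_mids = np.concatenate([mids, bg_mids])
    all_chroms = np.concatenate([nuc_chroms, bg_chroms])
    if assay == "cfdna":
        mean, sd = cfg.cfdna_len_mean, cfg.cfdna_len_sd
    else:
        mean, sd = cfg.mnase_len_mean, cfg.mnase_len_sd
    lengths = _truncated_normal_lengths(rng, mean, sd, n)

    starts = np.rint(all_mids - lengths / 2.0).astype(np.int64)
    # clamp inside chromosome bounds, preserving fragment length
    size_of = np.vectorize(landscape.chrom_lengths.__getitem__, otypes=[np.int64])
    bounds = size_of(all_chroms)
    starts = np.clip(starts, 0, bounds - lengths)
    ends = starts + lengths
    if sample_id is None:
        sample_id = f"sim-{assay}-{sample_seed}"
    return FragmentSet(sample_id=sample_id, chroms=all_chroms, starts=starts, ends=ends)


def simulate_cohort(
    landscape: Landscape, config: SimulatorConfig, design: CohortDesign,
    assay: str = "cfdna",
):
    """Simulate a two-group cohort with planted differential TSSs.

    Returns ``(samples_a, samples_b, truth)``. Group-A samples use unit
    per-gene occupancy rates; group-B samples have the rate at each
    planted TSS multiplied or divided by ``design.effect_factor``
    according to the planted direction.
    """
    rng = derive_rng(config.seed, _STREAM_DESIGN)
    n_genes = len(landscape.tss)
    if design.n_differential_tss > n_genes:
        raise ConfigurationError("cannot plant more differential TSSs than genes")
    diff_idx = rng.choice(n_genes, size=design.n_differential_tss, replace=False)
    n_up_a = int(round(design.direction_split * design.n_differential_tss))
    gene_ids = np.asarray(landscape.tss.gene_ids, dtype=object)
    directions = {}
    weights_b = np.ones(n_genes)
    for j, idx in enumerate(diff_idx):
        gid = str(gene_ids[idx])
        if j < n_up_a:
            directions[gid] = "up_in_a"
            weights_b[idx] = 1.0 / design.effect_factor
        else:
            directions[gid] = "up_in_b"
            weights_b[idx] = design.effect_factor

    samples_a, samples_b = [], []
    for i in range(design.n_group_a):
        seed_i = derive_sample_seed(config.seed, i)
        samples_a.append(
            simulate_sample(landscape, config, assay, seed_i, sample_id=f"A{i:03d}")
        )
    for i in range(design.n_group_b):
        seed_i = derive_sample_seed(config.seed, design.n_group_a + i)
        samples_b.append(
            simulate_sample(
                landscape, config, assay, seed_i,
                sample_id=f"B{i:03d}", gene_weights=weights_b,
            )
        )
    truth = TruthSet(
        directions=directions,
        tpm=landscape.expression.copy(),
        depletion=landscape.depletion.copy(),
    )
    return samples_a, samples_b, truth
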