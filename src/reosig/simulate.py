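"""Synthetic two-group expression data with planted reversal gene pairs.

The generator emulates the statistical structure the rank-based pipeline
assumes in real cohorts: a log-scale expression matrix in which a small
set of gene pairs flips its within-sample ordering between the two
phenotype groups (the planted reversal pairs), embedded among background
genes whose ordering carries no systematic group signal, with additive
Gaussian measurement noise, optional per-sample monotone distortions
standing in for batch effects, and optional missing measurements.

Within-group ordering consistency of a planted pair is controlled by the
target fraction pi. Under the Gaussian noise model the per-sample
probability that the intended order holds is Phi(gap / (sqrt(2) * sd)),
so for pi < 1 the mean gap between the two genes is calibrated in closed
form as

    gap = Phi^{-1}(pi) * sqrt(2) * noise_sd.

For pi = 1 no finite gap achieves exact certainty under noise, so the
configured ``mean_gap`` is used directly; with mean_gap >> noise_sd the
realized consistency is 1 up to vanishing probability. Requesting pi < 1
with zero noise is infeasible and raises.

Every planted pair's realized per-group consistency is measured on the
generated matrix and returned as ground truth, so downstream detection
tests compare against what was actually generated, not only what was
intended.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import ExpressionMatrix, SampleLabels
from .reo import DIRECTION_GT, DIRECTION_LT, PAIR_SEP


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated two-group cohort.

    Defaults are the standard condition used throughout: 200 genes, 10
    planted reversal pairs at full within-group consistency with a mean
    gap large relative to noise, and 100 samples per class.
    """

    n_genes: int = 200
    n_pos: int = 100
    n_neg: int = 100
    n_planted_pairs: int = 10
    consistency: float = 1.0  # target within-group ordering fraction pi
    mean_gap: float = 2.0  # planted-gene mean separation (used when pi = 1)
    noise_sd: float = 0.3  # per-measurement Gaussian noise, log-scale units
    missing_rate: float = 0.0
    seed: int = 0
    baseline_mean: float = 8.0  # typical log2 microarray intensity
    bg_mean_sd: float = 1.5  # spread of background gene means
    bg_group_effect_sd: float = 0.05  # small group-dependent background shifts

    def __post_init__(self) -> None:
        if self.n_planted_pairs * 2 > self.n_genes:
            raise ValueError("need n_genes >= 2 * n_planted_pairs")
        if not 0.5 < self.consistency <= 1.0:
            raise ValueError("consistency must be in (0.5, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.mean_gap <= 0:
            raise ValueError("mean_gap must be positive")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one sample per class")
        if self.consistency < 1.0 and self.noise_sd == 0:
            raise ValueError(
                "consistency < 1 cannot be realized with zero noise; "
                "set noise_sd > 0"
            )

    @property
    def planted_gap(self) -> float:
        """Mean separation of planted pair genes under the noise model."""
        if self.consistency >= 1.0:
            return self.mean_gap
        return float(norm.ppf(self.consistency)) * np.sqrt(2.0) * self.noise_sd

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self)))


@dataclass
class GroundTruth:
    """Planted pairs with intended directions and realized consistencies.

    ``table`` columns: gene_a, gene_b (canonical, gene_a < gene_b),
    direction_pos (dominant direction among positive samples, by
    construction), realized consistency_pos and consistency_neg measured
    on the generated matrix.
    """

    table: pd.DataFrame

    def planted_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["gene_a"], self.table["gene_b"]))

    def oriented_pair_ids(self) -> list[str]:
        ids = []
        for ga, gb, d in zip(
            self.table["gene_a"], self.table["gene_b"], self.table["direction_pos"]
        ):
            a, b = (ga, gb) if d == DIRECTION_GT else (gb, ga)
            ids.append(f"{a}{PAIR_SEP}{b}")
        return ids

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _substreams(entropy, n: int) -> list[np.random.Generator]:
    """Deterministic hierarchy of independent generators under one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(entropy).spawn(n)]


def generate(
    cfg: SyntheticConfig, sampling_seed: int | None = None
) -> tuple[ExpressionMatrix, SampleLabels, GroundTruth]:
    """Generate a two-group matrix with planted reversal pairs.

    Planted pair genes receive group-dependent mean offsets of +-gap/2
    with the offset sign flipped between groups, producing a reversal
    structure whose per-sample ordering holds with probability ~pi under
    the Gaussian noise model. Background genes draw a group-common mean
    plus a small random group effect — realistic null structure, but no
    constructed reversals.

    Because a planted gene's mean moves between groups, any third gene
    whose constant mean fell inside that swing would form an unintended
    stable reversal with it. Planted pair baselines are therefore placed
    in reserved expression bands above the (clipped) background range,
    spaced so that orderings across different pairs never flip — the
    planted pairs are provably the only constructed reversals, which is
    what makes the returned ground truth a complete answer key.

    Deterministic under ``cfg.seed``. The cohort structure (gene slots,
    means, intended directions) is driven by ``cfg.seed`` alone;
    ``sampling_seed`` redraws only the measurement noise and missingness,
    yielding an independent cohort of the same population — the synthetic
    analogue of a validation dataset.
    """
    rng_layout, rng_means = _substreams(cfg.seed, 2)
    noise_entropy = (
        (cfg.seed, 2) if sampling_seed is None else (cfg.seed, 3, sampling_seed)
    )
    rng_noise, rng_missing = _substreams(noise_entropy, 2)
    width = max(4, len(str(cfg.n_genes - 1)))
    genes = [f"G{i:0{width}d}" for i in range(cfg.n_genes)]
    n_samples = cfg.n_pos + cfg.n_neg
    samples = [f"P{i:03d}" for i in range(cfg.n_pos)] + [
        f"N{i:03d}" for i in range(cfg.n_neg)
    ]
    labels = SampleLabels(
        samples, np.r_[np.ones(cfg.n_pos, bool), np.zeros(cfg.n_neg, bool)]
    )

    # planted pairs occupy random gene slots so identity carries no signal
    slot = rng_layout.permutation(cfg.n_genes)
    planted = [
        (int(slot[2 * k]), int(slot[2 * k + 1])) for k in range(cfg.n_planted_pairs)
    ]
    planted_idx = {i for ab in planted for i in ab}
    gap = cfg.planted_gap

    # per-gene, per-group means; background means clipped so the reserved
    # planted band above them is guaranteed empty
    bg_halfwidth = 3.0 * cfg.bg_mean_sd
    mean_pos = np.empty(cfg.n_genes)
    mean_neg = np.empty(cfg.n_genes)
    for g in range(cfg.n_genes):
        if g in planted_idx:
            continue
        base = cfg.baseline_mean + float(
            np.clip(rng_means.normal(0.0, cfg.bg_mean_sd), -bg_halfwidth, bg_halfwidth)
        )
        mean_pos[g] = base + rng_means.normal(0.0, cfg.bg_group_effect_sd)
        mean_neg[g] = base + rng_means.normal(0.0, cfg.bg_group_effect_sd)

    band_spacing = 1.0  # min mean separation between genes of different pairs
    band_start = cfg.baseline_mean + bg_halfwidth + band_spacing + gap / 2
    truth_rows = []
    for k, (ia, ib) in enumerate(planted):
        base = band_start + k * (gap + band_spacing)
        # intended positive-group winner chosen at random per pair
        a_wins_pos = bool(rng_means.integers(0, 2))
        sa = 1.0 if a_wins_pos else -1.0
        mean_pos[ia], mean_pos[ib] = base + sa * gap / 2, base - sa * gap / 2
        mean_neg[ia], mean_neg[ib] = base - sa * gap / 2, base + sa * gap / 2
        ga, gb = genes[ia], genes[ib]
        if ga < gb:
            direction = DIRECTION_GT if a_wins_pos else DIRECTION_LT
            canon = (ga, gb)
        else:
            direction = DIRECTION_LT if a_wins_pos else DIRECTION_GT
            canon = (gb, ga)
        truth_rows.append((canon[0], canon[1], direction, ia, ib))

    means = np.empty((cfg.n_genes, n_samples))
    means[:, : cfg.n_pos] = mean_pos[:, None]
    means[:, cfg.n_pos :] = mean_neg[:, None]
    values = means + rng_noise.normal(0.0, cfg.noise_sd, size=means.shape)
    m = ExpressionMatrix(genes, samples, values)
    if cfg.missing_rate > 0:
        m = inject_missing(m, cfg.missing_rate, rng=rng_missing)

    # realized consistency measured on the generated matrix
    table_rows = []
    pos_cols = np.arange(cfg.n_pos)
    neg_cols = np.arange(cfg.n_pos, n_samples)
    idx = m.gene_index()
    for ga, gb, direction, ia, ib in truth_rows:
        va, vb = m.values[idx[ga]], m.values[idx[gb]]
        with np.errstate(invalid="ignore"):
            gt = va > vb
            lt = va < vb
        want_pos, want_neg = (gt, lt) if direction == DIRECTION_GT else (lt, gt)
        cons_pos = want_pos[pos_cols].sum() / cfg.n_pos
        cons_neg = want_neg[neg_cols].sum() / cfg.n_neg
        table_rows.append((ga, gb, direction, float(cons_pos), float(cons_neg)))
    table = pd.DataFrame(
        table_rows,
        columns=["gene_a", "gene_b", "direction_pos", "consistency_pos", "consistency_neg"],
    ).sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(drop=True)
    return m, labels, GroundTruth(table)


def apply_monotone_distortion(
    m: ExpressionMatrix, seed: int = 0, rng: np.random.Generator | None = None
) -> ExpressionMatrix:
    """Apply an independent strictly increasing transform to each sample.

    Each column is mapped through a * x + b * exp(c * x) with random
    a, b, c > 0 — a smooth monotone distortion emulating per-sample batch
    or scanner effects. Gene ranks within every sample are preserved
    exactly; missing values stay missing.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = m.values.copy()
    for j in range(m.n_samples):
        a = rng.uniform(0.5, 2.0)
        b = rng.uniform(0.05, 0.5)
        c = rng.uniform(0.02, 0.1)  # mild exponent keeps log-scale values finite
        col = out[:, j]
        out[:, j] = a * col + b * np.exp(c * col)
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), out)


def inject_missing(
    m: ExpressionMatrix,
    rate: float,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Mark a uniformly random fraction of gene x sample cells missing."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = m.values.copy()
    if rate > 0:
        mask = rng.random(out.shape) < rate
        out[mask] = np.nan
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), out)
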