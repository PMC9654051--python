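"""Seeded negative-binomial RNA-seq count simulator for a 2-diet x 4-tissue design.

The generator emulates a long-term calorie-restriction experiment: two diet
groups (ad libitum control vs. CR) sampled in four neuroendocrine tissues
(hypothalamus, amygdala, pituitary, adrenal) with a small number of animals
per diet x tissue cell. Counts are negative-binomial with mean

    mu(g, s) = baseline(g) * tissue_offset(g, t(s)) * (length(g)/1e3)
               * diet_fold(g, t(s), diet(s)) * size_factor(s)

and variance mu + phi * mu^2. A known fraction of genes carries a
tissue-independent diet effect (the planted "signature"), a second fraction a
tissue-dependent effect with an independent direction per tissue, and the rest
are null. The returned :class:`SyntheticTruth` records the planted class and
per-tissue fold change of every gene so downstream recovery can be scored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import CountMatrix

DEFAULT_TISSUES = ("hypothalamus", "amygdala", "pituitary", "adrenal")
DIETS = ("control", "CR")

GENE_CLASS_NULL = "null"
GENE_CLASS_SIGNATURE = "signature"
GENE_CLASS_TISSUE_DEP = "tissue_dependent"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the simulated experiment.

    Parameters
    ----------
    n_genes
        Number of genes simulated.
    n_per_cell
        Animals per diet x tissue cell (default 5, i.e. n = 40 samples over
        2 diets x 4 tissues).
    tissues
        Tissue labels; one categorical attribute level each.
    mean_log_baseline, sd_log_baseline
        Per-gene baseline expression (counts per kb of transcript at unit
        library scaling) is log-normal with these natural-log parameters.
    sd_log_tissue
        Log-scale spread of the per-gene, per-tissue baseline offset
        (tissue-specific expression); 0 disables tissue structure.
    dispersion
        NB dispersion phi (Var = mu + phi mu^2); scalar applied to every gene
        or a sequence of per-gene values. 0 degenerates to Poisson.
    frac_signature
        Fraction of genes with a tissue-independent diet effect.
    frac_tissue_dep
        Fraction of genes with a tissue-dependent diet effect (independent
        direction per tissue).
    effect_fold
        Multiplicative diet effect f > 0 applied as f or 1/f.
    gene_length_range
        Transcript length interval in bp (uniform integer draw).
    library_size_sd
        Log-scale SD of per-sample size factors, log-normal(0, sd).
    seed
        Seed for all randomness; identical seeds give bit-identical output.
    """

    n_genes: int
    n_per_cell: int = 5
    tissues: Sequence[str] = DEFAULT_TISSUES
    mean_log_baseline: float = math.log(50.0)
    sd_log_baseline: float = 1.0
    sd_log_tissue: float = 0.5
    dispersion: float | Sequence[float] = 0.3
    frac_signature: float = 0.02
    frac_tissue_dep: float = 0.02
    effect_fold: float = 2.0
    gene_length_range: tuple[int, int] = (500, 5000)
    library_size_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_genes, (int, np.integer)) or self.n_genes < 1:
            raise ValueError(f"n_genes must be a positive integer, got {self.n_genes!r}")
        if not isinstance(self.n_per_cell, (int, np.integer)) or self.n_per_cell < 1:
            raise ValueError(f"n_per_cell must be a positive integer, got {self.n_per_cell!r}")
        if len(self.tissues) < 1 or len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissues must be non-empty and unique")
        if self.sd_log_baseline < 0 or self.sd_log_tissue < 0 or self.library_size_sd < 0:
            raise ValueError("scale parameters must be non-negative")
        phi = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if np.any(phi < 0):
            raise ValueError("dispersion must be >= 0")
        if phi.size not in (1, self.n_genes):
            raise ValueError("dispersion must be scalar or one value per gene")
        if not (0.0 <= self.frac_signature <= 1.0 and 0.0 <= self.frac_tissue_dep <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_signature + self.frac_tissue_dep > 1.0 + 1e-12:
            raise ValueError("frac_signature + frac_tissue_dep must be <= 1")
        if self.effect_fold <= 0:
            raise ValueError(f"effect_fold must be > 0, got {self.effect_fold}")
        lo, hi = self.gene_length_range
        if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer))):
            raise ValueError("gene_length_range must be integer bp bounds")
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid gene_length_range {self.gene_length_range}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_per_cell * len(self.tissues)

    def per_gene_dispersion(self) -> np.ndarray:
        phi = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        return np.broadcast_to(phi, (self.n_genes,)).copy() if phi.size == 1 else phi


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-gene class and per-tissue true fold change."""

    gene_class: pd.Series  # index gene_id, values in the three class labels
    fold_change: pd.DataFrame  # genes x tissues, CR/control mean ratio

    def genes_of_class(self, cls: str) -> list[str]:
        return list(self.gene_class.index[self.gene_class == cls])

    def class_counts(self) -> dict[str, int]:
        return self.gene_class.value_counts().to_dict()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_class": self.gene_class.to_dict(),
            "fold_change": {t: self.fold_change[t].to_dict() for t in self.fold_change.columns},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        gene_class = pd.Series(payload["gene_class"], name="gene_class")
        fold = pd.DataFrame(payload["fold_change"]).loc[gene_class.index]
        return cls(gene_class=gene_class, fold_change=fold)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyntheticTruth):
            return NotImplemented
        return self.gene_class.equals(other.gene_class) and np.allclose(
            self.fold_change.values, other.fold_change.loc[self.fold_change.index, self.fold_change.columns].values
        )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean mu, Var mu + phi mu^2) via numpy's (n, p) parameterisation."""
    counts = np.empty(mu.shape, dtype=np.int64)
    phi_b = np.broadcast_to(phi[:, None], mu.shape)
    poisson = phi_b == 0
    if np.any(poisson):
        counts[poisson] = rng.poisson(mu[poisson])
    if np.any(~poisson):
        n = 1.0 / phi_b[~poisson]
        p = n / (n + mu[~poisson])
        counts[~poisson] = rng.negative_binomial(n, p)
    return counts


def generate_counts(
    config: SyntheticConfig,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate a count matrix, its sample metadata, and the planted truth.

    Returns
    -------
    (CountMatrix, metadata, truth)
        Metadata has columns ``sample_id``, ``diet``, ``tissue`` with one row
        per sample; truth records each gene's planted class and per-tissue
        fold change.
    """
    rng = np.random.default_rng(config.seed)
    n_g, tissues = config.n_genes, list(config.tissues)
    gene_ids = [f"G{i:05d}" for i in range(n_g)]

    lengths = rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, size=n_g)
    baseline = np.exp(rng.normal(config.mean_log_baseline, config.sd_log_baseline, size=n_g))
    tissue_off = np.exp(rng.normal(0.0, config.sd_log_tissue, size=(n_g, len(tissues))))

    # planted classes: exact rounded counts, random gene assignment
    n_sig = round(config.frac_signature * n_g)
    n_td = round(config.frac_tissue_dep * n_g)
    order = rng.permutation(n_g)
    classes = np.full(n_g, GENE_CLASS_NULL, dtype=object)
    classes[order[:n_sig]] = GENE_CLASS_SIGNATURE
    classes[order[n_sig : n_sig + n_td]] = GENE_CLASS_TISSUE_DEP

    f = config.effect_fold
    fold = np.ones((n_g, len(tissues)))
    sig_idx = np.flatnonzero(classes == GENE_CLASS_SIGNATURE)
    td_idx = np.flatnonzero(classes == GENE_CLASS_TISSUE_DEP)
    # signature genes: one direction, shared across tissues
    sig_sign = rng.choice([-1.0, 1.0], size=sig_idx.size)
    fold[sig_idx, :] = (f ** sig_sign)[:, None]
    # tissue-dependent genes: independent direction per tissue (Gh1-like pattern)
    td_sign = rng.choice([-1.0, 1.0], size=(td_idx.size, len(tissues)))
    fold[td_idx, :] = f**td_sign

    sample_ids, diets, sample_tissue_idx = [], [], []
    for ti, tissue in enumerate(tissues):
        for diet in DIETS:
            for r in range(config.n_per_cell):
                sample_ids.append(f"{tissue}_{diet}_{r + 1}")
                diets.append(diet)
                sample_tissue_idx.append(ti)
    sample_tissue_idx = np.asarray(sample_tissue_idx)
    is_cr = np.asarray([d == "CR" for d in diets])
    size_factor = np.exp(rng.normal(0.0, config.library_size_sd, size=len(sample_ids)))

    mu = (
        baseline[:, None]
        * tissue_off[:, sample_tissue_idx]
        * (lengths[:, None] / 1e3)
        * np.where(is_cr[None, :], fold[:, sample_tissue_idx], 1.0)
        * size_factor[None, :]
    )
    counts = _nb_draw(rng, mu, config.per_gene_dispersion())

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        gene_lengths=pd.Series(lengths, index=gene_ids, name="length"),
    )
    meta = pd.DataFrame({"sample_id": sample_ids, "diet": diets,
                         "tissue": [tissues[i] for i in sample_tissue_idx]})
    truth = SyntheticTruth(
        gene_class=pd.Series(classes, index=gene_ids, name="gene_class"),
        fold_change=pd.DataFrame(fold, index=gene_ids, columns=tissues),
    )
    return cm, meta, truth


def generate_posterior_draws(
    location: float, scale: float, n_draws: int, seed: int
) -> np.ndarray:
    """Seeded normal posterior-draw vector, a stand-in for an MCMC chain."""
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    if n_draws < 2:
        raise ValueError(f"n_draws must be >= 2, got {n_draws}")
    return np.random.default_rng(seed).normal(location, scale, size=n_draws)
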