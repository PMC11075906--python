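"""Candidate-support computations downstream of mapping.

Three small utilities used when interpreting mapped loci: correlating a
locus's 8-founder haplotype-effect vector with an external eQTL effect
vector from the same founder population, flagging genes as expressed from a
TPM table, and the Mendelian-ratio / chi-square computation used to infer
recessive lethality from cross genotype counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import HaplotypeEffectVector
from .simulate import N_FOUNDERS


@dataclass(frozen=True)
class EffectCorrelation:
    pearson_r: float
    spearman_rho: float


def correlate_haplotype_effects(v1, v2, founder_order=None) -> EffectCorrelation:
    """Pearson and Spearman correlation between two 8-founder effect vectors.

    Accepts :class:`HaplotypeEffectVector` or plain length-8 vectors. When
    both sides carry a founder order (dataclass attribute or explicit
    ``founder_order`` for the second vector) the orders must match.
    """
    orders = []
    vecs = []
    for v in (v1, v2):
        if isinstance(v, HaplotypeEffectVector):
            orders.append(tuple(v.founder_order))
            vecs.append(np.asarray(v.effects, dtype=float))
        else:
            vecs.append(np.asarray(v, dtype=float))
    if founder_order is not None:
        orders.append(tuple(founder_order))
    if len({o for o in orders}) > 1:
        raise ValueError("founder orders do not match")
    a, b = vecs
    if a.shape != (N_FOUNDERS,) or b.shape != (N_FOUNDERS,):
        raise ValueError("effect vectors must have length 8")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("effect vectors must be non-constant")
    r = stats.pearsonr(a, b).statistic
    rho = stats.spearmanr(a, b).statistic
    return EffectCorrelation(float(r), float(rho))


def filter_expressed_genes(
    expr: pd.DataFrame, tpm_cutoff: float = 0.5, fraction: float = 0.5
) -> pd.Series:
    """Expressed / not-expressed flags from a gene x sample TPM table.

    A gene is flagged not expressed when its median TPM is below
    ``tpm_cutoff`` or at least ``fraction`` of samples fall below the
    cutoff. Returns a boolean Series (True = expressed) indexed by gene.
    """
    X = expr.to_numpy(dtype=float)
    if X.shape[1] < 1:
        raise ValueError("need at least one sample")
    if (X < 0).any():
        raise ValueError("TPM values must be nonnegative")
    median = np.median(X, axis=1)
    frac_below = np.mean(X < tpm_cutoff, axis=1)
    not_expressed = (median < tpm_cutoff) | (frac_below >= fraction)
    return pd.Series(~not_expressed, index=expr.index, name="expressed")


@dataclass(frozen=True)
class MendelianRatioResult:
    proportions_pct: tuple  # unrounded percentages per class
    rounded_pct: tuple  # nearest-integer percentages
    chi_square: float
    p_value: float
    expected_counts: tuple


def mendelian_ratio(counts, expected_ratio) -> MendelianRatioResult:
    """Observed genotype-class proportions and chi-square vs an expected
    Mendelian ratio (e.g. 2:1 het:WT under recessive lethality)."""
    obs = np.asarray(counts, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.size < 2 or obs.size != ratio.size:
        raise ValueError("need matching counts and ratio with >= 2 classes")
    if (obs < 0).any() or (ratio <= 0).any():
        raise ValueError("counts must be >= 0 and ratio terms > 0")
    total = obs.sum()
    if total <= 0:
        raise ValueError("zero total count")
    props = 100.0 * obs / total
    expected = total * ratio / ratio.sum()
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return MendelianRatioResult(
        tuple(props),
        tuple(int(round(v)) for v in props),
        float(chi2),
        float(p),
        tuple(expected),
    )
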