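"""Scoring metrics used by the sixteen detection methods.

All metrics are pure functions on real vectors.  Argument order matters
for the asymmetric ones: the first argument is always the unit under
test (gene or window), the second the genome reference.

Directionality is handled by the detector: distances and divergences
flag the upper tail, correlation and covariance the lower tail.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from hgtbench.composition import AMINO_ACIDS, CODON_TO_AA, SENSE_CODONS


class MetricName(str, Enum):
    MANHATTAN = "MANHATTAN"
    EUCLIDEAN = "EUCLIDEAN"
    CHI2 = "CHI2"
    KL = "KL"
    COVARIANCE = "COVARIANCE"
    PEARSON = "PEARSON"
    MAHALANOBIS = "MAHALANOBIS"
    DELTA_STAR = "DELTA_STAR"
    NONE = "NONE"


#: default pseudocount rule for KL: add 1/(2*dim) to every entry of both
#: vectors, then renormalize.  Prevents log(0) on sparse window counts.
def _regularize(v: np.ndarray, pseudocount: float) -> np.ndarray:
    v = np.asarray(v, dtype=float) + pseudocount
    return v / v.sum()


def kl_divergence(p: np.ndarray, q: np.ndarray, pseudocount: float | None = None) -> float:
    """Kullback-Leibler divergence KL(p || q) after pseudocount
    regularization of both arguments (p = unit under test, q = reference)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("length mismatch")
    if pseudocount is None:
        pseudocount = 1.0 / (2 * p.size)
    p = _regularize(p, pseudocount)
    q = _regularize(q, pseudocount)
    return float(np.sum(p * np.log(p / q)))


def chi2_statistic(p: np.ndarray, q: np.ndarray, support: float) -> float:
    """One-sample chi-square statistic of observed counts ``p * support``
    against expected counts ``q * support``.

    ``p`` and ``q`` are frequency-like vectors on the same scale; cells
    with zero expectation are dropped (they carry no evidence under the
    reference).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("length mismatch")
    if support <= 0:
        raise ValueError("support must be positive")
    o = p * support
    e = q * support
    mask = e > 0
    return float(np.sum((o[mask] - e[mask]) ** 2 / e[mask]))


def vector_metric(
    name: MetricName,
    p: np.ndarray,
    q: np.ndarray,
    support: float | None = None,
) -> float:
    """Evaluate one of the simple vector metrics.

    CHI2 requires ``support`` (the count of units behind ``p``) to scale
    frequencies back to counts.  MAHALANOBIS and DELTA_STAR have
    dedicated entry points.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("length mismatch")
    if name is MetricName.MANHATTAN:
        return float(np.abs(p - q).sum())
    if name is MetricName.EUCLIDEAN:
        return float(np.sqrt(((p - q) ** 2).sum()))
    if name is MetricName.CHI2:
        if support is None:
            raise ValueError("CHI2 requires the support of p")
        return chi2_statistic(p, q, support)
    if name is MetricName.KL:
        return kl_divergence(p, q)
    if name is MetricName.COVARIANCE:
        pc = p - p.mean()
        qc = q - q.mean()
        return float((pc * qc).sum() / (p.size - 1))
    if name is MetricName.PEARSON:
        pc = p - p.mean()
        qc = q - q.mean()
        denom = np.sqrt((pc**2).sum() * (qc**2).sum())
        if denom == 0:
            return 0.0
        return float((pc * qc).sum() / denom)
    if name is MetricName.DELTA_STAR:
        return delta_star(p, q)
    raise ValueError(f"unsupported metric {name}")


def shrink_covariance(cov: np.ndarray, shrinkage: float = 0.1) -> np.ndarray:
    """Shrink a covariance matrix toward its diagonal.

    High-dimensional criterion vectors (256 tetranucleotides) can
    outnumber the observations, leaving the sample covariance singular;
    blending with the diagonal keeps the pseudo-inverse well behaved.
    """
    diag = np.diag(np.diag(cov))
    return (1 - shrinkage) * cov + shrinkage * diag


def mahalanobis(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Mahalanobis distance sqrt((x-m)^T C^- (x-m)) using a pseudo-inverse."""
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if x.shape != mean.shape or cov.shape != (x.size, x.size):
        raise ValueError("dimension mismatch")
    d = x - mean
    cinv = np.linalg.pinv(cov, hermitian=True)
    val = float(d @ cinv @ d)
    return float(np.sqrt(max(val, 0.0)))


def delta_star(rho_p: np.ndarray, rho_q: np.ndarray) -> float:
    """Karlin's relative-abundance distance: the mean absolute difference
    of the two rho vectors, per-mil scaled (x1000)."""
    rho_p = np.asarray(rho_p, dtype=float)
    rho_q = np.asarray(rho_q, dtype=float)
    if rho_p.shape != rho_q.shape:
        raise ValueError("length mismatch")
    return float(np.abs(rho_p - rho_q).mean() * 1000.0)


def karlin_codon_B(
    cu_gene: np.ndarray, cu_ref: np.ndarray, aa_gene: np.ndarray
) -> float:
    """Karlin's codon-bias distance between a gene and a reference.

    B = sum over amino acids a of  aa_gene(a) * sum over codons c of a of
    |f_gene(c|a) - f_ref(c|a)| where f(c|a) is the within-synonymous-family
    normalized codon frequency.  Families with zero mass get uniform
    within-family frequencies so that an absent family contributes only
    through its (zero) amino-acid weight.
    """
    cu_gene = np.asarray(cu_gene, dtype=float)
    cu_ref = np.asarray(cu_ref, dtype=float)
    aa_gene = np.asarray(aa_gene, dtype=float)
    if cu_gene.shape != (len(SENSE_CODONS),) or cu_ref.shape != cu_gene.shape:
        raise ValueError("codon vectors must have length 61")
    if aa_gene.shape != (len(AMINO_ACIDS),):
        raise ValueError("amino-acid vector must have length 20")

    def within_family(cu: np.ndarray) -> np.ndarray:
        out = np.empty_like(cu)
        for a in range(len(AMINO_ACIDS)):
            members = CODON_TO_AA == a
            mass = cu[members].sum()
            if mass > 0:
                out[members] = cu[members] / mass
            else:
                out[members] = 1.0 / members.sum()
        return out

    fg = within_family(cu_gene)
    fr = within_family(cu_ref)
    diff = np.abs(fg - fr)
    b = 0.0
    for a in range(len(AMINO_ACIDS)):
        members = CODON_TO_AA == a
        b += aa_gene[a] * diff[members].sum()
    return float(b)


def delta_star_aa(aa_gene: np.ndarray, aa_ref: np.ndarray) -> float:
    """Amino-acid analogue of delta*: mean absolute frequency difference
    over the 20 amino acids, per-mil scaled."""
    return delta_star(aa_gene, aa_ref)
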