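"""The sixteen parametric HGT detection methods.

Each method couples a compositional criterion, a genome-scanning mode
(per gene, or sliding window with a given size and step), a scoring
metric and a reference-construction rule.  The registry below is the
single source of truth; methods are addressed by their published names
(``GC.windows``, ``GCtotal``, ``GC1-GC3``, ``dint5``, ``dint.di31T2``,
``CU.chi2``, ``CU.karlin``, ``CU.karlin.aa``, ``CU.KL``,
``CU.mahalanobis``, ``oli.Pearson``, ``oli.covariance``, ``oli.chi2``,
``oli.mahalanobis``, ``oli.KL``, ``signature``).

Window scores are projected onto genes as the barycenter of the scores
of the windows containing the gene, weighted by the length of the gene
portion inside each window, so window methods and gene methods can be
compared on the same per-gene footing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from hgtbench import composition as comp
from hgtbench import metrics as met
from hgtbench.composition import CompositionVector, Criterion
from hgtbench.genome_io import AnnotatedGenome, Gene
from hgtbench.metrics import MetricName


class ScanMode(str, Enum):
    GENE = "GENE"
    WINDOW = "WINDOW"


class Direction(str, Enum):
    UPPER = "UPPER"
    LOWER = "LOWER"
    TWO_SIDED = "TWO_SIDED"


class Reference(str, Enum):
    GENE_MEAN = "GENE_MEAN"
    WHOLE_GENOME = "WHOLE_GENOME"
    ROBUST_SIGNATURE = "ROBUST_SIGNATURE"


@dataclass(frozen=True)
class MethodConfig:
    name: str
    criterion: Criterion
    mode: ScanMode
    metric: MetricName
    direction: Direction
    reference: Reference
    window_bp: int | None = None
    step_bp: int | None = None

    def __post_init__(self) -> None:
        if self.mode is ScanMode.WINDOW:
            if not (self.window_bp and self.step_bp):
                raise ValueError(f"{self.name}: WINDOW mode needs window/step")
            if not (self.window_bp >= self.step_bp > 0):
                raise ValueError(f"{self.name}: require window_bp >= step_bp > 0")


_REGISTRY: dict[str, MethodConfig] = {
    cfg.name: cfg
    for cfg in [
        MethodConfig("GC.windows", Criterion.GC, ScanMode.WINDOW,
                     MetricName.MANHATTAN, Direction.UPPER,
                     Reference.WHOLE_GENOME, 20_000, 5_000),
        MethodConfig("GCtotal", Criterion.GC, ScanMode.GENE,
                     MetricName.NONE, Direction.TWO_SIDED, Reference.GENE_MEAN),
        MethodConfig("GC1-GC3", Criterion.GC1GC3, ScanMode.GENE,
                     MetricName.NONE, Direction.TWO_SIDED, Reference.GENE_MEAN),
        MethodConfig("dint5", Criterion.DINUC_NORM, ScanMode.WINDOW,
                     MetricName.DELTA_STAR, Direction.UPPER,
                     Reference.WHOLE_GENOME, 5_000, 5_000),
        MethodConfig("dint.di31T2", Criterion.DINUC31, ScanMode.GENE,
                     MetricName.MAHALANOBIS, Direction.UPPER, Reference.GENE_MEAN),
        MethodConfig("CU.chi2", Criterion.CODON, ScanMode.GENE,
                     MetricName.CHI2, Direction.UPPER, Reference.GENE_MEAN),
        MethodConfig("CU.karlin", Criterion.CODON, ScanMode.GENE,
                     MetricName.DELTA_STAR, Direction.UPPER, Reference.GENE_MEAN),
        MethodConfig("CU.karlin.aa", Criterion.AA, ScanMode.GENE,
                     MetricName.DELTA_STAR, Direction.UPPER, Reference.GENE_MEAN),
        MethodConfig("CU.KL", Criterion.CODON, ScanMode.GENE,
                     MetricName.KL, Direction.UPPER, Reference.GENE_MEAN),
        MethodConfig("CU.mahalanobis", Criterion.CODON, ScanMode.GENE,
                     MetricName.MAHALANOBIS, Direction.UPPER, Reference.GENE_MEAN),
        MethodConfig("oli.Pearson", Criterion.TETRA_NORM, ScanMode.WINDOW,
                     MetricName.PEARSON, Direction.LOWER,
                     Reference.WHOLE_GENOME, 5_000, 1_000),
        MethodConfig("oli.covariance", Criterion.TETRA_NORM, ScanMode.WINDOW,
                     MetricName.COVARIANCE, Direction.LOWER,
                     Reference.WHOLE_GENOME, 5_000, 1_000),
        MethodConfig("oli.chi2", Criterion.TETRA_NORM, ScanMode.WINDOW,
                     MetricName.CHI2, Direction.UPPER,
                     Reference.WHOLE_GENOME, 5_000, 1_000),
        MethodConfig("oli.mahalanobis", Criterion.TETRA_NORM, ScanMode.WINDOW,
                     MetricName.MAHALANOBIS, Direction.UPPER,
                     Reference.WHOLE_GENOME, 5_000, 1_000),
        MethodConfig("oli.KL", Criterion.TETRA_NORM, ScanMode.WINDOW,
                     MetricName.KL, Direction.UPPER,
                     Reference.WHOLE_GENOME, 5_000, 1_000),
        MethodConfig("signature", Criterion.TETRA, ScanMode.WINDOW,
                     MetricName.EUCLIDEAN, Direction.UPPER,
                     Reference.ROBUST_SIGNATURE, 5_000, 500),
    ]
}

METHOD_NAMES: tuple[str, ...] = tuple(_REGISTRY)

#: the seven methods retained after the whole-registry comparison — the
#: best method per criterion family.
RETAINED_METHODS: tuple[str, ...] = (
    "GCtotal", "GC1-GC3", "dint5", "CU.KL", "oli.chi2", "oli.KL", "signature",
)


def method_registry(name: str) -> MethodConfig:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown method {name!r}; valid names: {', '.join(METHOD_NAMES)}"
        ) from None


@dataclass
class WindowScores:
    """Sliding-window scores: (start, end, score) sorted by start."""

    method: str
    windows: list[tuple[int, int, float]]


@dataclass
class GeneScores:
    """Per-gene atypicality scores for one method.

    For ``GC1-GC3`` the two signed deviations (GC1 and GC3 component)
    are kept separately in ``scores`` and ``scores2``; thresholding
    calls a gene atypical only when both components are outliers.
    """

    method: str
    scores: dict[str, float]
    scores2: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# criterion dispatch

_WINDOW_CRITERIA = {
    Criterion.GC: comp.gc_content,
    Criterion.DINUC_NORM: comp.normalized_dinucleotides,
    Criterion.TETRA: comp.tetra_freqs,
    Criterion.TETRA_NORM: comp.normalized_tetranucleotides,
}


def _gene_cds(genome: AnnotatedGenome, gene: Gene) -> str:
    """Coding-strand sequence of the gene, trimmed to a whole number of
    codons for frame-dependent criteria."""
    s = genome.gene_sequence(gene)
    return s[: len(s) - len(s) % 3]


def gene_vector(genome: AnnotatedGenome, gene: Gene, criterion: Criterion) -> CompositionVector:
    """Criterion vector for one gene."""
    if criterion is Criterion.GC:
        return comp.gc_content(genome.gene_sequence(gene))
    cds = _gene_cds(genome, gene)
    if criterion is Criterion.GC1GC3:
        return comp.gc_codon_positions(cds)
    if criterion is Criterion.CODON:
        return comp.codon_usage(cds)
    if criterion is Criterion.AA:
        return comp.amino_acid_usage(cds)
    if criterion is Criterion.DINUC31:
        return comp.dinuc_31(cds)
    raise ValueError(f"criterion {criterion} is not gene-based")


def window_vector(seq: str, criterion: Criterion) -> CompositionVector:
    try:
        fn = _WINDOW_CRITERIA[criterion]
    except KeyError:
        raise ValueError(f"criterion {criterion} is not window-based") from None
    return fn(seq)


# ---------------------------------------------------------------------------
# scanning and references

def scan_windows(genome_length: int, window_bp: int, step_bp: int) -> list[tuple[int, int]]:
    """Sliding-window coordinates: starts at 0, step, 2*step, ... while the
    window fits; if the last regular window stops short of the sequence
    end an extra end-anchored window [length - window, length) is added
    so 3'-terminal genes are covered."""
    if window_bp > genome_length:
        raise ValueError(
            f"window {window_bp} bp exceeds genome length {genome_length}"
        )
    starts = list(range(0, genome_length - window_bp + 1, step_bp))
    windows = [(s, s + window_bp) for s in starts]
    if windows[-1][1] < genome_length:
        windows.append((genome_length - window_bp, genome_length))
    return windows


def robust_host_signature(
    window_vectors: list[CompositionVector],
) -> CompositionVector:
    """Host signature estimated over the majority of windows.

    A provisional mean over all windows is computed; windows are split
    into two groups by 1-d two-means clustering of their Euclidean
    distances to the provisional mean, and if the distant group is the
    minority the mean is recomputed over the near group only.  This
    keeps horizontally acquired regions from contaminating the reference
    signature.
    """
    usable = [v for v in window_vectors if v.usable]
    if not usable:
        raise ValueError("no usable windows")
    mat = np.vstack([v.values for v in usable])
    if len(usable) < 4:
        warnings.warn("fewer than 4 windows; falling back to the plain mean")
        return CompositionVector(
            usable[0].criterion, mat.mean(axis=0), sum(v.support for v in usable)
        )
    provisional = mat.mean(axis=0)
    dists = np.sqrt(((mat - provisional) ** 2).sum(axis=1))
    near_mask = _two_means_near_group(dists)
    if near_mask.sum() > (~near_mask).sum():
        mean = mat[near_mask].mean(axis=0)
        support = int(sum(v.support for v, keep in zip(usable, near_mask) if keep))
    else:
        mean = provisional
        support = int(sum(v.support for v in usable))
    return CompositionVector(usable[0].criterion, mean, support)


def _two_means_near_group(values: np.ndarray) -> np.ndarray:
    """Exact 1-d two-means: boolean mask of the low-value group under the
    split minimizing within-group sum of squares.  Degenerate (constant)
    input puts everything in the near group."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    n = v.size
    if v[0] == v[-1]:
        return np.ones(n, dtype=bool)
    csum = np.cumsum(v)
    csq = np.cumsum(v**2)
    best_cut, best_cost = 1, np.inf
    for cut in range(1, n):  # low group = first `cut` sorted values
        s1, q1 = csum[cut - 1], csq[cut - 1]
        s2, q2 = csum[-1] - s1, csq[-1] - q1
        cost = (q1 - s1**2 / cut) + (q2 - s2**2 / (n - cut))
        if cost < best_cost - 1e-15:
            best_cost, best_cut = cost, cut
    mask = np.zeros(n, dtype=bool)
    mask[order[:best_cut]] = True
    return mask


def genome_reference(
    genome: AnnotatedGenome, config: MethodConfig
) -> CompositionVector:
    """Reference composition for a method: the mean of the per-gene
    vectors, the value over the whole sequence, or the robust
    majority-window signature."""
    if config.reference is Reference.GENE_MEAN:
        vecs = [
            gene_vector(genome, g, config.criterion)
            for g in genome.genes
        ]
        usable = [v for v in vecs if v.usable]
        if not usable:
            raise ValueError("no usable genes for the reference")
        mat = np.vstack([v.values for v in usable])
        return CompositionVector(
            config.criterion, mat.mean(axis=0), sum(v.support for v in usable)
        )
    if config.reference is Reference.WHOLE_GENOME:
        vec = window_vector(genome.record.seq, config.criterion)
        if not vec.usable:
            raise ValueError("whole-genome composition unusable")
        return vec
    if config.reference is Reference.ROBUST_SIGNATURE:
        windows = scan_windows(genome.length, config.window_bp, config.step_bp)
        vecs = [
            window_vector(genome.record.seq[a:b], config.criterion)
            for a, b in windows
        ]
        return robust_host_signature(vecs)
    raise ValueError(f"unknown reference rule {config.reference}")


# ---------------------------------------------------------------------------
# scoring

def _metric_scores(
    vectors: list[CompositionVector],
    reference: CompositionVector,
    config: MethodConfig,
) -> list[float | None]:
    """Apply the configured metric to each unit vector against the
    reference; unusable units get None."""
    usable_idx = [i for i, v in enumerate(vectors) if v.usable]
    out: list[float | None] = [None] * len(vectors)
    if not usable_idx:
        return out
    if config.metric is MetricName.MAHALANOBIS:
        mat = np.vstack([vectors[i].values for i in usable_idx])
        cov = met.shrink_covariance(np.cov(mat, rowvar=False, ddof=1))
        for i in usable_idx:
            out[i] = met.mahalanobis(vectors[i].values, reference.values, cov)
        return out
    for i in usable_idx:
        v = vectors[i]
        if config.metric is MetricName.DELTA_STAR and config.criterion is Criterion.CODON:
            # CU.karlin: Karlin's within-family codon bias B, weighted by
            # the gene's amino-acid usage
            raise RuntimeError("CU.karlin is scored in score_genes")
        out[i] = met.vector_metric(
            config.metric, v.values, reference.values, support=v.support
        )
    return out


def score_windows(genome: AnnotatedGenome, config: MethodConfig) -> WindowScores:
    """Score every sliding window against the genome reference."""
    if config.mode is not ScanMode.WINDOW:
        raise ValueError(f"{config.name} is not a window method")
    coords = scan_windows(genome.length, config.window_bp, config.step_bp)
    vecs = [
        window_vector(genome.record.seq[a:b], config.criterion) for a, b in coords
    ]
    reference = genome_reference(genome, config)
    scores = _metric_scores(vecs, reference, config)
    windows = [
        (a, b, s) for (a, b), s in zip(coords, scores) if s is not None
    ]
    return WindowScores(config.name, windows)


def project_to_genes(ws: WindowScores, genes: list[Gene]) -> GeneScores:
    """Project window scores onto genes: the barycenter of the scores of
    the windows containing the gene, weighted by the length of the gene
    portion lying in each window."""
    starts = np.array([w[0] for w in ws.windows])
    ends = np.array([w[1] for w in ws.windows])
    scores = np.array([w[2] for w in ws.windows])
    gene_scores: dict[str, float] = {}
    for g in genes:
        # overlapping windows: start < g.end and end > g.start
        hi = int(np.searchsorted(starts, g.end, side="left"))
        lo = int(np.searchsorted(ends, g.start, side="right"))
        if lo >= hi:
            raise ValueError(f"gene {g.id!r} overlaps no scored window")
        ov = np.minimum(ends[lo:hi], g.end) - np.maximum(starts[lo:hi], g.start)
        if (ov <= 0).any():  # defensive: window lists are sorted/regular
            keep = ov > 0
            if not keep.any():
                raise ValueError(f"gene {g.id!r} overlaps no scored window")
            ov, sc = ov[keep], scores[lo:hi][keep]
        else:
            sc = scores[lo:hi]
        gene_scores[g.id] = float((sc * ov).sum() / ov.sum())
    return GeneScores(ws.method, gene_scores)


def score_genes(genome: AnnotatedGenome, config: MethodConfig | str) -> GeneScores:
    """Produce one atypicality score per gene for any of the 16 methods."""
    if isinstance(config, str):
        config = method_registry(config)
    if config.mode is ScanMode.WINDOW:
        return project_to_genes(score_windows(genome, config), genome.genes)

    vecs = {g.id: gene_vector(genome, g, config.criterion) for g in genome.genes}
    usable = {gid: v for gid, v in vecs.items() if v.usable}
    if not usable:
        raise ValueError("no usable genes")
    reference = genome_reference(genome, config)

    if config.name == "GCtotal":
        scores = {
            gid: float(v.values[0] - reference.values[0])
            for gid, v in usable.items()
        }
        return GeneScores(config.name, scores)
    if config.name == "GC1-GC3":
        s1 = {gid: float(v.values[0] - reference.values[0]) for gid, v in usable.items()}
        s3 = {gid: float(v.values[1] - reference.values[1]) for gid, v in usable.items()}
        return GeneScores(config.name, s1, s3)
    if config.name == "CU.karlin":
        by_id = {g.id: g for g in genome.genes}
        scores = {}
        for gid, v in usable.items():
            aa = comp.amino_acid_usage(_gene_cds(genome, by_id[gid]))
            scores[gid] = met.karlin_codon_B(v.values, reference.values, aa.values)
        return GeneScores(config.name, scores)

    ordered = list(usable)
    vlist = [usable[gid] for gid in ordered]
    raw = _metric_scores(vlist, reference, config)
    return GeneScores(
        config.name,
        {gid: s for gid, s in zip(ordered, raw) if s is not None},
    )
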