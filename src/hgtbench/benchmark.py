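"""Gene-level evaluation, method combination and experiment driver.

Detection calls are compared with the simulator's truth labels: any
label other than ``"native"`` marks a true horizontal transfer.
Sensitivity is the percentage of HT genes detected, specificity the
percentage of native genes left alone, and the mean error averages the
two complementary error rates.  Two methods are combined by the union
rule: a gene is called if at least one method calls it, which can only
raise sensitivity and lower specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from hgtbench import thresholding as th
from hgtbench.composition import tetra_freqs
from hgtbench.detector import method_registry, score_genes
from hgtbench.genome_io import AnnotatedGenome, NATIVE_LABEL
from hgtbench.simulator import (
    ModelGenomeRecipe,
    experiment_divergence_levels,
    experiment_recipes,
    insert_hts,
    make_species_family,
    standard_genomes,
    synthesize_genome,
)


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 100.0

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else 100.0

    @property
    def mean_error(self) -> float:
        return th.mean_error(self.sensitivity, self.specificity)


def evaluate(calls: Mapping[str, bool], truth: Mapping[str, str]) -> EvalResult:
    """Confusion counts of detection calls against truth labels."""
    if set(calls) != set(truth):
        raise ValueError("calls and truth must cover the same genes")
    tp = fp = tn = fn = 0
    for gid, called in calls.items():
        is_ht = truth[gid] != NATIVE_LABEL
        if called and is_ht:
            tp += 1
        elif called and not is_ht:
            fp += 1
        elif is_ht:
            fn += 1
        else:
            tn += 1
    return EvalResult(tp, fp, tn, fn)


def combine_union(
    calls_a: Mapping[str, bool], calls_b: Mapping[str, bool]
) -> dict[str, bool]:
    """Union combination: a gene is detected if either method detects it."""
    if set(calls_a) != set(calls_b):
        raise ValueError("call sets must cover the same genes")
    return {gid: calls_a[gid] or calls_b[gid] for gid in calls_a}


def signature_distance(seq_a: str, seq_b: str, scale: float = 1.0) -> float:
    """Euclidean distance between the 256-dimensional tetranucleotide
    frequency vectors of two sequences (the genomic-signature distance);
    ``scale`` maps to arbitrary units if desired."""
    va = tetra_freqs(seq_a)
    vb = tetra_freqs(seq_b)
    if not (va.usable and vb.usable):
        raise ValueError("sequence too short or too ambiguous for 4-mers")
    return scale * float(np.sqrt(((va.values - vb.values) ** 2).sum()))


# ---------------------------------------------------------------------------
# threshold tuning and experiment driver

def tune_r(
    genomes: Sequence[AnnotatedGenome],
    methods: Sequence[str],
    r_grid: Sequence[float] = th.DEFAULT_R_GRID,
) -> dict[str, tuple[float, bool]]:
    """Optimal whisker factor per method, tuned over replicate genomes.

    Returns ``method -> (r*, stable)`` where r* is the mean of the
    per-replicate mean-error minimizers and stability means their
    population standard deviation is below 0.5.
    """
    out: dict[str, tuple[float, bool]] = {}
    for name in methods:
        cfg = method_registry(name)
        curves = [
            th.roc_sweep(score_genes(g, cfg), g.truth, cfg.direction, r_grid)
            for g in genomes
        ]
        out[name] = th.optimal_r(curves)
    return out


def evaluate_method(
    genome: AnnotatedGenome, method: str, r: float
) -> tuple[EvalResult, dict[str, bool]]:
    """Score one method on one genome, threshold at whisker factor r,
    and evaluate against the genome's truth labels."""
    cfg = method_registry(method)
    gs = score_genes(genome, cfg)
    calls = th.classify(gs, r, cfg.direction)
    truth = {gid: genome.truth[gid] for gid in calls}
    return evaluate(calls, truth), calls


def run_experiment(
    kind: str,
    methods: Sequence[str],
    seed: int,
    n_genes: int = 400,
    r_values: Mapping[str, float] | None = None,
    n_replicates: int | None = None,
) -> pd.DataFrame:
    """Drive one experiment series end to end.

    ``kind`` is ``standard``, ``origin``, ``quantity``, ``size`` or
    ``host``.  Unless ``r_values`` is supplied, the whisker factor of
    each method is tuned once on five standard model genomes and reused
    across all conditions.  Returns a tidy table with one row per
    condition x method x replicate plus aggregate (mean/sd) rows.
    """
    rng = np.random.default_rng(seed)

    if r_values is None:
        tuning = tune_r(standard_genomes(seed, n_genes=n_genes), methods)
        r_values = {m: r for m, (r, _) in tuning.items()}

    rows: list[dict] = []

    def add(label: str, method: str, rep: int, r: float, res: EvalResult) -> None:
        rows.append(
            dict(condition=label, method=method, replicate=rep, r=r,
                 tp=res.tp, fp=res.fp, tn=res.tn, fn=res.fn,
                 sensitivity=res.sensitivity, specificity=res.specificity,
                 mean_error=res.mean_error)
        )

    if kind == "standard":
        genomes = standard_genomes(
            int(rng.integers(0, 2**31 - 1)), n_genes=n_genes,
            n_replicates=n_replicates or 5,
        )
        for rep, g in enumerate(genomes):
            for m in methods:
                res, _ = evaluate_method(g, m, r_values[m])
                add("standard", m, rep, r_values[m], res)
    else:
        recipes = experiment_recipes(kind)
        levels = experiment_divergence_levels(kind)
        host, donors = make_species_family(
            len(levels), levels, int(rng.integers(0, 2**31 - 1))
        )
        models = {m.id: m for m in [host] + donors}
        for recipe in recipes:
            host_model = models[recipe.host_id or host.id]
            donor_models = [models[did] for did, _ in recipe.donors]
            reps = n_replicates or recipe.n_replicates
            for rep in range(reps):
                s1 = int(rng.integers(0, 2**31 - 1))
                s2 = int(rng.integers(0, 2**31 - 1))
                base = synthesize_genome(
                    host_model, n_genes, s1, f"{recipe.label}_rep{rep}"
                )
                g = insert_hts(base, donor_models, recipe, s2)
                for m in methods:
                    res, _ = evaluate_method(g, m, r_values[m])
                    add(recipe.label, m, rep, r_values[m], res)

    df = pd.DataFrame(rows)
    agg = (
        df.groupby(["condition", "method"], sort=False)
        .agg(
            r=("r", "first"),
            sensitivity_mean=("sensitivity", "mean"),
            sensitivity_sd=("sensitivity", lambda s: s.std(ddof=0)),
            specificity_mean=("specificity", "mean"),
            specificity_sd=("specificity", lambda s: s.std(ddof=0)),
            mean_error_mean=("mean_error", "mean"),
            mean_error_sd=("mean_error", lambda s: s.std(ddof=0)),
        )
        .reset_index()
    )
    df.attrs["aggregate"] = agg
    return df


def run_combination(
    genomes: Sequence[AnnotatedGenome],
    gene_method: str,
    window_method: str,
    r_values: Mapping[str, float],
) -> pd.DataFrame:
    """Union of a gene-based and a window-based method over replicate
    genomes; returns per-replicate and per-pair mean rows."""
    rows = []
    for rep, g in enumerate(genomes):
        res_a, calls_a = evaluate_method(g, gene_method, r_values[gene_method])
        res_b, calls_b = evaluate_method(g, window_method, r_values[window_method])
        union = combine_union(calls_a, calls_b)
        truth = {gid: g.truth[gid] for gid in union}
        res_u = evaluate(union, truth)
        for name, res in (
            (gene_method, res_a),
            (window_method, res_b),
            (f"{gene_method} - {window_method}", res_u),
        ):
            rows.append(
                dict(method=name, replicate=rep,
                     sensitivity=res.sensitivity, specificity=res.specificity,
                     mean_error=res.mean_error)
            )
    return pd.DataFrame(rows)
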