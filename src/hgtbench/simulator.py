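"""Model-genome simulator with gene-level horizontal-transfer truth.

The simulator emulates benchmark genomes in which the position and
origin of every horizontal transfer is known.  A *species model* is a
compositional profile: a codon-usage distribution for coding regions,
an order-2 Markov chain for intergenic DNA, a stop-codon preference and
a gene-length distribution.  A host model is drawn from seeded priors;
donor models interpolate the host's distributions toward an independent
random model with a *divergence* weight in (0, 1], so the expected
tetranucleotide-signature distance to the host grows with the knob.

Model genomes are host genomes with contiguous blocks of donor genes
(plus donor-composition intergenic spacers) spliced into intergenic
positions.  Inserted genes carry their donor id as truth label; native
genes are labeled ``"native"``.  Transfers are deliberately *not*
ameliorated: donor genes keep the donor's composition in full, matching
the premise that freshly acquired DNA has not yet drifted toward the
host signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from hgtbench.composition import BASES, SENSE_CODONS, STOP_CODONS
from hgtbench.genome_io import AnnotatedGenome, Gene, NATIVE_LABEL, SequenceRecord

#: gene length (bp) log-normal parameters and hard bounds
GENE_LENGTH_LOG_MEAN = 6.8  # median ~ 900 bp
GENE_LENGTH_LOG_SD = 0.45
GENE_LENGTH_BOUNDS = (150, 4500)

#: intergenic spacer length range (bp), uniform
INTERGENIC_RANGE = (50, 200)

#: divergence knobs for the close / intermediary / far donor tiers
TIER_DIVERGENCE = {"close": 0.3, "intermediary": 0.55, "far": 0.8}

#: expected bp of one gene plus its trailing spacer under the length
#: priors (used to deficit-match the last inserted block)
_EXPECTED_GENE_UNIT_BP = (
    float(np.exp(GENE_LENGTH_LOG_MEAN + GENE_LENGTH_LOG_SD**2 / 2))
    + (INTERGENIC_RANGE[0] + INTERGENIC_RANGE[1]) / 2.0
)

#: default chromosome size in genes (~4 Mb); tests and desk-scale runs
#: use 400
DEFAULT_N_GENES = 4000


@dataclass(frozen=True)
class SpeciesModel:
    """Compositional profile of one synthetic species."""

    id: str
    codon_dist: np.ndarray  # 61 sense codons
    stop_dist: np.ndarray  # 3 stop codons
    intergenic_init: np.ndarray  # 16 dimer states
    intergenic_trans: np.ndarray  # (16, 4) order-2 transitions
    divergence: float = 0.0

    def __post_init__(self) -> None:
        for name, arr, shape in (
            ("codon_dist", self.codon_dist, (61,)),
            ("stop_dist", self.stop_dist, (3,)),
            ("intergenic_init", self.intergenic_init, (16,)),
            ("intergenic_trans", self.intergenic_trans, (16, 4)),
        ):
            if arr.shape != shape:
                raise ValueError(f"{name}: expected shape {shape}, got {arr.shape}")
            if not np.all(arr >= 0):
                raise ValueError(f"{name}: negative probability")
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must be in [0, 1]")


@dataclass(frozen=True)
class ModelGenomeRecipe:
    """Parameters of one model-genome condition."""

    ht_fraction: float
    size_range_genes: tuple[int, int]
    donors: tuple[tuple[str, float], ...]
    n_replicates: int = 5
    seed: int | None = None
    label: str = ""
    host_id: str | None = None  # None = the family's base host

    def __post_init__(self) -> None:
        if not (0.0 <= self.ht_fraction < 1.0):
            raise ValueError("ht_fraction must be in [0, 1)")
        lo, hi = self.size_range_genes
        if lo < 1 or hi < lo:
            raise ValueError("size_range_genes must satisfy 1 <= min <= max")
        if self.donors:
            total = sum(p for _, p in self.donors)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("donor proportions must sum to 1")


# ---------------------------------------------------------------------------
# species models

def _random_profile(rng: np.random.Generator):
    """Draw an independent compositional profile from the priors."""
    codon = rng.dirichlet(np.full(61, 0.6))
    stop = rng.dirichlet(np.full(3, 1.0))
    init = rng.dirichlet(np.full(16, 1.0))
    trans = np.vstack([rng.dirichlet(np.full(4, 0.8)) for _ in range(16)])
    return codon, stop, init, trans


def _mix(a: np.ndarray, b: np.ndarray, w: float) -> np.ndarray:
    out = (1.0 - w) * a + w * b
    if out.ndim == 1:
        return out / out.sum()
    return out / out.sum(axis=1, keepdims=True)


def make_species_family(
    n_donors: int,
    divergence_levels: Sequence[float],
    seed: int,
    host_id: str = "host",
) -> tuple[SpeciesModel, list[SpeciesModel]]:
    """A host model plus ``n_donors`` donor models.

    Each donor's distributions are a convex combination of the host's
    and an independently drawn random profile, weighted by the donor's
    divergence level, so signature distance to the host is an
    increasing function of the knob (in expectation).
    """
    if len(divergence_levels) != n_donors:
        raise ValueError("need one divergence level per donor")
    if any(not (0.0 <= d <= 1.0) for d in divergence_levels):
        raise ValueError("divergence levels must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h_codon, h_stop, h_init, h_trans = _random_profile(rng)
    host = SpeciesModel(host_id, h_codon, h_stop, h_init, h_trans, 0.0)
    donors = []
    for i, d in enumerate(divergence_levels, start=1):
        r_codon, r_stop, r_init, r_trans = _random_profile(rng)
        donors.append(
            SpeciesModel(
                f"d{i}",
                _mix(h_codon, r_codon, d),
                _mix(h_stop, r_stop, d),
                _mix(h_init, r_init, d),
                _mix(h_trans, r_trans, d),
                d,
            )
        )
    return host, donors


# ---------------------------------------------------------------------------
# sequence synthesis

_CODON_STRINGS = np.array(SENSE_CODONS)
_STOP_STRINGS = np.array(STOP_CODONS)
_DIMER_STATES = [a + b for a in BASES for b in BASES]


def _sample_gene_length(rng: np.random.Generator) -> int:
    """Gene length in bp: log-normal, clipped, rounded to a codon
    multiple (includes start and stop codons)."""
    lo, hi = GENE_LENGTH_BOUNDS
    bp = float(np.exp(rng.normal(GENE_LENGTH_LOG_MEAN, GENE_LENGTH_LOG_SD)))
    bp = min(max(bp, lo), hi)
    n_codons = max(int(round(bp / 3.0)), 3)
    return 3 * n_codons


def _sample_cds(model: SpeciesModel, rng: np.random.Generator, length_bp: int) -> str:
    """One CDS: ATG + i.i.d. sense codons + a stop codon."""
    n_codons = length_bp // 3
    body = rng.choice(61, size=n_codons - 2, p=model.codon_dist)
    stop = rng.choice(3, p=model.stop_dist)
    return "ATG" + "".join(_CODON_STRINGS[body]) + _STOP_STRINGS[stop]


def _sample_intergenic(model: SpeciesModel, rng: np.random.Generator, length: int) -> str:
    """Intergenic DNA from the species' order-2 Markov chain."""
    if length <= 0:
        return ""
    state = int(rng.choice(16, p=model.intergenic_init))
    out = list(_DIMER_STATES[state][: min(2, length)])
    while len(out) < length:
        nxt = int(rng.choice(4, p=model.intergenic_trans[state]))
        out.append(BASES[nxt])
        state = (state % 4) * 4 + nxt
    return "".join(out[:length])


_REVCOMP_TABLE = str.maketrans("ACGT", "TGCA")


def _gene_block(
    model: SpeciesModel,
    rng: np.random.Generator,
    n_genes: int,
    id_prefix: str,
    start_index: int = 0,
) -> tuple[str, list[Gene]]:
    """``n_genes`` genes separated (and flanked on the right) by
    intergenic spacers, as one sequence with local coordinates."""
    parts: list[str] = []
    genes: list[Gene] = []
    pos = 0
    for j in range(n_genes):
        cds = _sample_cds(model, rng, _sample_gene_length(rng))
        strand = "+" if rng.random() < 0.5 else "-"
        placed = cds if strand == "+" else cds.translate(_REVCOMP_TABLE)[::-1]
        genes.append(
            Gene(f"{id_prefix}{start_index + j:05d}", pos, pos + len(placed), strand)
        )
        parts.append(placed)
        pos += len(placed)
        ig = _sample_intergenic(
            model, rng, int(rng.integers(INTERGENIC_RANGE[0], INTERGENIC_RANGE[1] + 1))
        )
        parts.append(ig)
        pos += len(ig)
    return "".join(parts), genes


def synthesize_genome(
    model: SpeciesModel, n_genes: int, seed: int, record_id: str | None = None
) -> AnnotatedGenome:
    """A chromosome of alternating intergenic spacers and genes, all
    drawn from one species model; every gene is labeled native."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    lead = _sample_intergenic(
        model, rng, int(rng.integers(INTERGENIC_RANGE[0], INTERGENIC_RANGE[1] + 1))
    )
    body, genes = _gene_block(model, rng, n_genes, f"{model.id}_g")
    shifted = [replace(g, start=g.start + len(lead), end=g.end + len(lead)) for g in genes]
    seq = lead + body
    truth = {g.id: NATIVE_LABEL for g in shifted}
    rid = record_id or f"{model.id}_genome"
    return AnnotatedGenome(SequenceRecord(rid, seq), shifted, truth)


# ---------------------------------------------------------------------------
# horizontal-transfer insertion

def insert_hts(
    host_genome: AnnotatedGenome,
    donors: Sequence[SpeciesModel],
    recipe: ModelGenomeRecipe,
    seed: int,
) -> AnnotatedGenome:
    """Splice donor gene blocks into intergenic positions of the host.

    Block sizes are uniform over ``recipe.size_range_genes``; each block
    comes wholly from one donor, chosen to keep realized donor bp
    proportions close to the recipe; blocks land at distinct intergenic
    gaps and never nest.  Total inserted bp targets
    ``ht_fraction`` of the *final* genome, within one block.
    """
    if recipe.ht_fraction == 0 or not recipe.donors:
        return host_genome
    rng = np.random.default_rng(seed)
    by_id = {m.id: m for m in donors}
    missing = [did for did, _ in recipe.donors if did not in by_id]
    if missing:
        raise ValueError(f"recipe references unknown donors: {missing}")

    host_bp = host_genome.length
    f = recipe.ht_fraction
    target_bp = f / (1.0 - f) * host_bp  # inserted bp so that H/(L0+H) = f

    # candidate insertion gaps: just after each gene end (all host genes
    # are followed by an intergenic spacer by construction)
    gaps = [g.end for g in host_genome.genes]
    if not gaps:
        raise ValueError("host genome has no genes")
    lo, hi = recipe.size_range_genes
    blocks: list[tuple[int, str, str, list[Gene]]] = []  # (pos, donor, seq, genes)
    used_bp = {did: 0.0 for did, _ in recipe.donors}
    total = 0.0
    counter = 0
    order = rng.permutation(len(gaps))
    while total < target_bp:
        if counter >= len(gaps):
            raise ValueError(
                "infeasible recipe: more blocks required than intergenic gaps"
            )
        # donor with the largest bp deficit relative to its share
        deficits = {
            did: prop * max(target_bp, total) - used_bp[did]
            for did, prop in recipe.donors
        }
        donor_id = max(deficits, key=lambda d: (deficits[d], d))
        n_genes = int(rng.integers(lo, hi + 1))
        # deficit-matched final block: shrink (never grow) the drawn size
        # so the realized fraction lands close to the recipe's target
        remaining = (target_bp - total) / _EXPECTED_GENE_UNIT_BP
        if remaining < n_genes:
            n_genes = int(np.clip(round(remaining), lo, n_genes))
        seq, genes = _gene_block(
            by_id[donor_id], rng, n_genes, f"{donor_id}_ht{counter:03d}_g"
        )
        pos = gaps[order[counter]]
        blocks.append((pos, donor_id, seq, genes))
        used_bp[donor_id] += len(seq)
        total += len(seq)
        counter += 1

    blocks.sort(key=lambda b: b[0])
    host_seq = host_genome.record.seq
    new_parts: list[str] = []
    new_genes: list[Gene] = []
    truth: dict[str, str] = {}
    cursor = 0
    bi = 0
    for g in host_genome.genes:
        # splice any blocks positioned before this gene
        while bi < len(blocks) and blocks[bi][0] <= g.start:
            pos, donor_id, bseq, bgenes = blocks[bi]
            new_parts.append(host_seq[cursor:pos])
            insert_at = sum(len(p) for p in new_parts)
            new_parts.append(bseq)
            for bg in bgenes:
                ng = replace(bg, start=bg.start + insert_at, end=bg.end + insert_at)
                new_genes.append(ng)
                truth[ng.id] = donor_id
            cursor = pos
            bi += 1
        shift = sum(len(p) for p in new_parts) - cursor
        ng = replace(g, start=g.start + shift, end=g.end + shift)
        new_genes.append(ng)
        truth[ng.id] = (host_genome.truth or {}).get(g.id, NATIVE_LABEL)
    # trailing blocks and sequence
    while bi < len(blocks):
        pos, donor_id, bseq, bgenes = blocks[bi]
        new_parts.append(host_seq[cursor:pos])
        insert_at = sum(len(p) for p in new_parts)
        new_parts.append(bseq)
        for bg in bgenes:
            ng = replace(bg, start=bg.start + insert_at, end=bg.end + insert_at)
            new_genes.append(ng)
            truth[ng.id] = donor_id
        cursor = pos
        bi += 1
    new_parts.append(host_seq[cursor:])
    new_seq = "".join(new_parts)
    record = SequenceRecord(host_genome.record.id + "_ht", new_seq)
    return AnnotatedGenome(record, new_genes, truth)


# ---------------------------------------------------------------------------
# canonical conditions

def standard_recipe(n_replicates: int = 5) -> ModelGenomeRecipe:
    """The benchmark's standard condition: 9% HT, block sizes 1-15
    genes, six donors (two per divergence tier) in equal proportions."""
    donors = tuple((f"d{i}", 1.0 / 6.0) for i in range(1, 7))
    return ModelGenomeRecipe(
        ht_fraction=0.09,
        size_range_genes=(1, 15),
        donors=donors,
        n_replicates=n_replicates,
        label="standard",
    )


def standard_divergence_levels() -> tuple[float, ...]:
    """Two donors each from the close, intermediary and far tiers."""
    t = TIER_DIVERGENCE
    return (t["close"], t["close"], t["intermediary"], t["intermediary"],
            t["far"], t["far"])


def standard_genomes(
    seed: int,
    n_genes: int = DEFAULT_N_GENES,
    divergence_levels: Sequence[float] | None = None,
    n_replicates: int = 5,
) -> list[AnnotatedGenome]:
    """Five replicate standard model genomes (9% HT, 1-15 genes per
    block, six donors in equal proportions)."""
    levels = tuple(divergence_levels or standard_divergence_levels())
    host, donors = make_species_family(len(levels), levels, seed)
    recipe = standard_recipe(n_replicates)
    genomes = []
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=2 * n_replicates)
    for k in range(n_replicates):
        base = synthesize_genome(host, n_genes, int(sub[2 * k]), f"standard_rep{k}")
        genomes.append(insert_hts(base, donors, recipe, int(sub[2 * k + 1])))
    return genomes


def experiment_recipes(kind: str) -> list[ModelGenomeRecipe]:
    """Recipes of the four experiment series.

    * ``origin``: one recipe per single donor, 12.5% HT, 5-10 genes.
    * ``quantity``: 1/5/10/20% HT from three donors (one per tier),
      5-10 genes.
    * ``size``: 10% HT with block-size classes small (1-5), medium
      (4-10), large (10-20) and very large (20-30) genes.
    * ``host``: each family member in turn receives 9% HT in equal
      proportions (1.5% each) from the six other members.
    """
    three = tuple((f"d{i}", 1.0 / 3.0) for i in (1, 2, 3))
    if kind == "origin":
        return [
            ModelGenomeRecipe(0.125, (5, 10), ((f"d{i}", 1.0),),
                              n_replicates=3, label=f"origin:d{i}")
            for i in range(1, 11)
        ]
    if kind == "quantity":
        return [
            ModelGenomeRecipe(fr, (5, 10), three, n_replicates=3,
                              label=f"quantity:{int(fr * 100)}%")
            for fr in (0.01, 0.05, 0.10, 0.20)
        ]
    if kind == "size":
        classes = {"small": (1, 5), "medium": (4, 10),
                   "large": (10, 20), "very_large": (20, 30)}
        return [
            ModelGenomeRecipe(0.10, rng_, three, n_replicates=3,
                              label=f"size:{name}")
            for name, rng_ in classes.items()
        ]
    if kind == "host":
        members = ["host"] + [f"d{i}" for i in range(1, 7)]
        recipes = []
        for m in members:
            others = tuple((o, 1.0 / 6.0) for o in members if o != m)
            recipes.append(
                ModelGenomeRecipe(0.09, (1, 15), others, n_replicates=3,
                                  label=f"host:{m}", host_id=m)
            )
        return recipes
    raise ValueError(f"unknown experiment kind {kind!r}")


def experiment_divergence_levels(kind: str) -> tuple[float, ...]:
    """Donor divergence knobs matching :func:`experiment_recipes`."""
    if kind == "origin":
        return tuple(np.round(np.linspace(0.15, 0.9, 10), 3))
    if kind in ("quantity", "size"):
        t = TIER_DIVERGENCE
        return (t["close"], t["intermediary"], t["far"])
    if kind == "host":
        return standard_divergence_levels()
    raise ValueError(f"unknown experiment kind {kind!r}")
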