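"""Geometric-mean-driven feedback evolutionary optimization (GM-FDEF).

Searches a segmentation-model configuration space with:

* multiplicative (log-normal) Gaussian mutation, which is scale-invariant
  for range-sensitive genes such as learning rates,
* a feedback combination step blending each candidate with the historical
  best configuration, with convex weights derived from their fitness
  ratio (the printed cross-weighting: the better partner's fitness
  weights the *other* genome; the conventional reading is available via
  ``swap_alpha_beta``),
* a geometric-mean fitness over min-max-normalized Dice, IoU, boundary
  accuracy and inverse Hausdorff distance — any collapsed metric
  annihilates the score,
* non-dominated Pareto sorting with diversity-gap (crowding-style)
  truncation of the overflowing front, and
* a stagnation/improvement feedback controller adapting the mutation
  scale and the mutation/combination probabilities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Gene",
    "ParamSpace",
    "Genome",
    "ObjectiveVector",
    "FitnessRecord",
    "FeedbackState",
    "init_population",
    "gm_mutate",
    "oriented_objectives",
    "fitness_gm",
    "feedback_combine",
    "pareto_sort",
    "diversity_scores",
    "select_survivors",
    "adapt_feedback",
    "run_optimizer",
    "toy_space",
    "toy_evaluator",
    "random_search",
    "hypervolume",
    "swin_space",
]

_WORST_HD = 1e6


# ---------------------------------------------------------------------------
# search space and genomes


@dataclass(frozen=True)
class Gene:
    """One dimension of the configuration space.

    ``kind`` is one of ``log-continuous`` (sampled/compared on a log
    scale), ``continuous``, ``integer`` or ``categorical`` (with
    ``choices``).
    """

    name: str
    kind: str
    bounds: tuple[float, float] | None = None
    choices: tuple | None = None

    def __post_init__(self):
        if self.kind not in ("log-continuous", "continuous", "integer", "categorical"):
            raise ValueError(f"unknown gene kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.choices:
                raise ValueError(f"gene {self.name!r}: empty choice list")
        else:
            lo, hi = self.bounds
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"gene {self.name!r}: invalid bounds {self.bounds}")
            if self.kind == "log-continuous" and lo <= 0:
                raise ValueError(f"gene {self.name!r}: log-scale bounds must be > 0")


@dataclass(frozen=True)
class ParamSpace:
    genes: tuple[Gene, ...]

    def validate_values(self, values: dict) -> None:
        for gene in self.genes:
            v = values[gene.name]
            if gene.kind == "categorical":
                if v not in gene.choices:
                    raise ValueError(f"{gene.name}={v!r} not in choices")
            else:
                lo, hi = gene.bounds
                if not (lo <= v <= hi):
                    raise ValueError(f"{gene.name}={v} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class Genome:
    """One configuration: a value per gene, an id and its birth generation."""

    values: dict
    id: int
    generation: int = 0


@dataclass(frozen=True)
class ObjectiveVector:
    """Raw evaluation of one configuration (larger Dice/IoU/BA, smaller HD
    is better)."""

    dice: float
    iou: float
    boundary_accuracy: float
    hausdorff: float

    def __post_init__(self):
        if self.hausdorff < 0:
            raise ValueError("hausdorff must be non-negative")


@dataclass(frozen=True)
class FitnessRecord:
    genome_id: int
    objectives: ObjectiveVector
    normalized: tuple[float, float, float, float]
    f_gm: float
    failed: bool = False


@dataclass(frozen=True)
class FeedbackState:
    """Controller state: mutation scale, operator probabilities, history.

    After ``stagnation_s`` consecutive non-improving generations the
    mutation scale and probability are raised (exploration); on
    improvement the scale decays and the combination probability rises
    (exploitation).  The controller constants are exposed because the
    controller is defined qualitatively; these defaults are deliberate,
    conservative choices.
    """

    sigma: float = 0.5
    p_mut: float = 0.8
    p_comb: float = 0.5
    sigma_min: float = 0.15
    sigma_max: float = 1.0
    epsilon: float = 1e-4
    stagnation_s: int = 3
    up_factor: float = 1.5
    down_factor: float = 0.97
    p_step: float = 0.1
    best_history: tuple[float, ...] = ()
    stagnation_count: int = 0


# ---------------------------------------------------------------------------
# variation operators


def _sample_gene(gene: Gene, rng) -> object:
    if gene.kind == "categorical":
        return gene.choices[int(rng.integers(len(gene.choices)))]
    lo, hi = gene.bounds
    if gene.kind == "log-continuous":
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if gene.kind == "integer":
        return int(rng.integers(int(lo), int(hi) + 1))
    return float(rng.uniform(lo, hi))


def init_population(space: ParamSpace, n: int, seed: int) -> list[Genome]:
    """Uniformly sample ``n`` feasible genomes (log-uniform on log genes)."""
    if n < 2:
        raise ValueError("population size must be >= 2")
    rng = np.random.default_rng(seed)
    pop = []
    for i in range(n):
        values = {g.name: _sample_gene(g, rng) for g in space.genes}
        pop.append(Genome(values=values, id=i, generation=0))
    return pop


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def gm_mutate(
    genome: Genome, space: ParamSpace, sigma: float, seed: int, new_id: int | None = None
) -> Genome:
    """Multiplicative Gaussian mutation ``theta * exp(eta)``, eta ~ N(0, s^2).

    Continuous and log-continuous genes are perturbed multiplicatively and
    clamped to bounds; integer genes likewise then rounded half away from
    zero; categorical genes are resampled uniformly with probability
    ``min(1, sigma)``.  ``sigma = 0`` returns an identical genome.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    values = {}
    for gene in space.genes:
        v = genome.values[gene.name]
        if gene.kind == "categorical":
            if rng.uniform() < min(1.0, sigma):
                v = gene.choices[int(rng.integers(len(gene.choices)))]
        else:
            eta = float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
            lo, hi = gene.bounds
            z = v * math.exp(eta)
            if gene.kind == "integer":
                v = int(np.clip(_round_half_away(z), int(lo), int(hi)))
            else:
                v = float(np.clip(z, lo, hi))
        values[gene.name] = v
    return Genome(
        values=values,
        id=genome.id if new_id is None else new_id,
        generation=genome.generation,
    )


def feedback_combine(
    z: Genome,
    h: Genome,
    fz: float,
    fh: float,
    space: ParamSpace,
    seed: int,
    new_id: int | None = None,
    swap_alpha_beta: bool = False,
) -> Genome:
    """Fitness-ratio convex combination of a candidate with the historical best.

    As printed, ``alpha = F(h) / (F(z) + F(h))`` weights the candidate
    ``z`` and ``beta = F(z) / (F(z) + F(h))`` weights ``h`` — the better
    partner's fitness weights the *other* genome.  ``swap_alpha_beta``
    selects the conventional self-weighting instead.  Numeric genes blend
    as ``alpha * z + beta * h`` (integers rounded, all clamped);
    categorical genes take z's value with probability ``alpha``.
    ``alpha + beta = 1`` always; both fitnesses zero falls back to 0.5.
    """
    if fz < 0 or fh < 0:
        raise ValueError("fitness values must be non-negative")
    total = fz + fh
    if total == 0:
        alpha = beta = 0.5
    else:
        alpha, beta = fh / total, fz / total
        if swap_alpha_beta:
            alpha, beta = beta, alpha
    rng = np.random.default_rng(seed)
    values = {}
    for gene in space.genes:
        vz, vh = z.values[gene.name], h.values[gene.name]
        if gene.kind == "categorical":
            values[gene.name] = vz if rng.uniform() < alpha else vh
        else:
            lo, hi = gene.bounds
            c = alpha * vz + beta * vh
            if gene.kind == "integer":
                values[gene.name] = int(np.clip(_round_half_away(c), int(lo), int(hi)))
            else:
                values[gene.name] = float(np.clip(c, lo, hi))
    return Genome(
        values=values, id=z.id if new_id is None else new_id, generation=z.generation
    )


# ---------------------------------------------------------------------------
# fitness


def oriented_objectives(
    obj: ObjectiveVector, hd_epsilon: float = 1e-6
) -> tuple[float, float, float, float]:
    """All four metrics oriented so larger is better (HD inverted)."""
    return (obj.dice, obj.iou, obj.boundary_accuracy, 1.0 / (obj.hausdorff + hd_epsilon))


def fitness_gm(
    objectives: list[ObjectiveVector],
    genome_ids: list[int] | None = None,
    hd_epsilon: float = 1e-6,
    failed: list[bool] | None = None,
) -> list[FitnessRecord]:
    """Geometric-mean fitness over the min-max-normalized pool.

    The normalization pool is the full list passed in (parents plus
    candidates of the generation).  A metric with a degenerate pool range
    contributes the neutral value 0.5 for everyone, keeping the geometric
    mean finite.  The best record in all four metrics scores 1; the worst
    in any single metric scores 0.
    """
    if not objectives:
        raise ValueError("empty normalization pool")
    ids = genome_ids if genome_ids is not None else list(range(len(objectives)))
    fails = failed if failed is not None else [False] * len(objectives)
    arr = np.array([oriented_objectives(o, hd_epsilon) for o in objectives])
    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    span = hi - lo
    normed = np.where(span > 0, (arr - lo) / np.where(span > 0, span, 1.0), 0.5)
    fgm = np.prod(normed, axis=1) ** 0.25
    return [
        FitnessRecord(
            genome_id=i,
            objectives=o,
            normalized=tuple(float(v) for v in nv),
            f_gm=float(g),
            failed=bool(fl),
        )
        for i, o, nv, g, fl in zip(ids, objectives, normed, fgm, fails)
    ]


# ---------------------------------------------------------------------------
# selection


def pareto_sort(records: list[FitnessRecord]) -> list[list[int]]:
    """Non-dominated sorting into fronts of indices into ``records``.

    Dominance: >= in all four oriented objectives and > in at least one.
    Fronts partition the input; order within a front follows input order.
    """
    n = len(records)
    arr = np.array([oriented_objectives(r.objectives) for r in records])
    dominated_by = [set() for _ in range(n)]
    dominates = [set() for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.all(arr[i] >= arr[j]) and np.any(arr[i] > arr[j]):
                dominates[i].add(j)
                dominated_by[j].add(i)
    fronts = []
    remaining = set(range(n))
    counts = [len(dominated_by[i]) for i in range(n)]
    while remaining:
        front = [i for i in sorted(remaining) if counts[i] == 0]
        if not front:  # numerical safety; cannot occur with strict dominance
            front = sorted(remaining)
        for i in front:
            remaining.discard(i)
            for j in dominates[i]:
                counts[j] -= 1
        fronts.append(front)
    return fronts


def diversity_scores(
    front: list[int], records: list[FitnessRecord]
) -> dict[int, float]:
    """Crowding-style diversity gaps, summed over the four objectives.

    Per objective the front is sorted by that objective; an interior
    member scores the gap between its neighbours normalized by the
    pool-wide objective range, boundary members score infinity.  A
    degenerate pool range contributes 0.
    """
    arr = np.array([oriented_objectives(r.objectives) for r in records])
    scores = {i: 0.0 for i in front}
    if len(front) <= 2:
        return {i: float("inf") for i in front}
    for d in range(arr.shape[1]):
        lo = float(arr[:, d].min())
        hi = float(arr[:, d].max())
        span = hi - lo
        order = sorted(front, key=lambda i: (arr[i, d], i))
        if span <= 0:
            continue
        scores[order[0]] = float("inf")
        scores[order[-1]] = float("inf")
        for pos in range(1, len(order) - 1):
            i = order[pos]
            if not math.isinf(scores[i]):
                gap = (arr[order[pos + 1], d] - arr[order[pos - 1], d]) / span
                scores[i] += float(gap)
    return scores


def select_survivors(
    pool: list[tuple[Genome, FitnessRecord]], n: int
) -> list[tuple[Genome, FitnessRecord]]:
    """Front-by-front elitist selection down to exactly ``n`` members.

    Whole fronts are added while they fit; the overflowing front is
    truncated by descending diversity score (infinite-gap boundary
    members first), ties broken by f_gm then id.
    """
    if len(pool) < n:
        raise ValueError(f"pool of {len(pool)} cannot fill population of {n}")
    records = [r for _, r in pool]
    fronts = pareto_sort(records)
    chosen: list[int] = []
    for front in fronts:
        if len(chosen) + len(front) <= n:
            chosen.extend(front)
            if len(chosen) == n:
                break
        else:
            need = n - len(chosen)
            div = diversity_scores(front, records)
            ranked = sorted(
                front,
                key=lambda i: (
                    -div[i],
                    -records[i].f_gm,
                    records[i].genome_id,
                ),
            )
            chosen.extend(ranked[:need])
            break
    return [pool[i] for i in chosen]


# ---------------------------------------------------------------------------
# feedback controller


def adapt_feedback(state: FeedbackState, best_fgm_this_gen: float) -> FeedbackState:
    """One controller update from the generation's best fitness.

    Improvement means exceeding the previous best by more than
    ``epsilon``; after ``stagnation_s`` consecutive non-improvements the
    mutation scale is raised 1.5x (capped) and p_mut stepped up; on
    improvement the scale decays 0.9x (floored) and p_comb steps up.
    """
    prev_best = max(state.best_history) if state.best_history else -np.inf
    improved = best_fgm_this_gen > prev_best + state.epsilon
    history = state.best_history + (best_fgm_this_gen,)
    if improved:
        return replace(
            state,
            sigma=max(state.sigma * state.down_factor, state.sigma_min),
            p_comb=min(state.p_comb + state.p_step, 0.9),
            best_history=history,
            stagnation_count=0,
        )
    count = state.stagnation_count + 1
    if count >= state.stagnation_s:
        return replace(
            state,
            sigma=min(state.sigma * state.up_factor, state.sigma_max),
            p_mut=min(state.p_mut + state.p_step, 0.9),
            best_history=history,
            stagnation_count=0,
        )
    return replace(state, best_history=history, stagnation_count=count)


# ---------------------------------------------------------------------------
# main loop


def _evaluate(evaluator, genome: Genome) -> tuple[ObjectiveVector, bool]:
    try:
        obj = evaluator(genome)
        if not all(
            np.isfinite([obj.dice, obj.iou, obj.boundary_accuracy, obj.hausdorff])
        ):
            raise ValueError("non-finite objectives")
        return obj, False
    except Exception:
        return ObjectiveVector(0.0, 0.0, 0.0, _WORST_HD), True


def run_optimizer(
    space: ParamSpace,
    evaluator,
    n: int = 10,
    t_max: int = 20,
    seed: int = 0,
    stagnation_k: int | None = None,
    state: FeedbackState | None = None,
) -> tuple[list[tuple[Genome, FitnessRecord]], list[dict]]:
    """Evolve a population of configurations for up to ``t_max`` generations.

    Per generation each parent is mutated (gated by ``p_mut``) and
    combined with the historical best evaluated genome (gated by
    ``p_comb``); candidates and parents are pooled, fitness is computed
    over the pool, and elitist Pareto/diversity selection keeps ``n``
    survivors.  Stops early after ``stagnation_k`` generations without
    improvement of the best fitness.  A failing evaluator assigns worst
    objectives and flags the record; the run continues.

    Returns the final population and a history log with one entry per
    evaluation (genome values, objectives, f_gm, generation).
    """
    rng = np.random.default_rng(seed)
    st = state or FeedbackState()
    id_counter = itertools.count()
    parents = init_population(space, n, int(rng.integers(2**31 - 1)))
    for _ in range(n):
        next(id_counter)

    history: list[dict] = []

    def log_eval(genome, record, generation):
        history.append(
            {
                "generation": generation,
                "genome_id": genome.id,
                "values": dict(genome.values),
                "dice": record.objectives.dice,
                "iou": record.objectives.iou,
                "boundary_accuracy": record.objectives.boundary_accuracy,
                "hausdorff": record.objectives.hausdorff,
                "f_gm": record.f_gm,
                "failed": record.failed,
            }
        )

    # generation 0: evaluate the initial parents
    evals = [_evaluate(evaluator, g) for g in parents]
    records = fitness_gm(
        [o for o, _ in evals], [g.id for g in parents], failed=[f for _, f in evals]
    )
    pool = list(zip(parents, records))
    for g, r in pool:
        log_eval(g, r, 0)
    best_idx = int(np.argmax([r.f_gm for _, r in pool]))
    st = adapt_feedback(st, pool[best_idx][1].f_gm)
    stagnant = 0
    best_so_far = pool[best_idx][1].f_gm

    for t in range(1, t_max + 1):
        # the historical-best anchor lives in the current population (the
        # elitist selection guarantees it survived); its fitness is on the
        # same normalization scale as the parents'
        anchor, anchor_rec = max(pool, key=lambda gr: gr[1].f_gm)
        candidates: list[Genome] = []
        for g, r in pool:
            child = Genome(values=dict(g.values), id=next(id_counter), generation=t)
            if rng.uniform() < st.p_mut:
                child = gm_mutate(
                    child, space, st.sigma, int(rng.integers(2**31 - 1))
                )
            if rng.uniform() < st.p_comb:
                child = feedback_combine(
                    child,
                    anchor,
                    r.f_gm,
                    anchor_rec.f_gm,
                    space,
                    int(rng.integers(2**31 - 1)),
                )
            if child.values != g.values:  # skip re-evaluating exact copies
                candidates.append(child)

        cand_evals = [_evaluate(evaluator, g) for g in candidates]
        all_genomes = [g for g, _ in pool] + candidates
        all_objs = [r.objectives for _, r in pool] + [o for o, _ in cand_evals]
        all_failed = [r.failed for _, r in pool] + [f for _, f in cand_evals]
        all_records = fitness_gm(
            all_objs, [g.id for g in all_genomes], failed=all_failed
        )
        big_pool = list(zip(all_genomes, all_records))
        for g, r in big_pool[len(pool):]:
            log_eval(g, r, t)

        gen_best = max(big_pool, key=lambda gr: gr[1].f_gm)
        pool = select_survivors(big_pool, n)
        st = adapt_feedback(st, gen_best[1].f_gm)

        if gen_best[1].f_gm > best_so_far + st.epsilon:
            best_so_far = gen_best[1].f_gm
            stagnant = 0
        else:
            stagnant += 1
        if stagnation_k is not None and stagnant >= stagnation_k:
            break
    return pool, history


# ---------------------------------------------------------------------------
# evaluators and baselines


def toy_space() -> ParamSpace:
    """Two continuous genes with a known optimum at the origin."""
    return ParamSpace(
        genes=(
            Gene("x", "continuous", bounds=(0.0, 1.0)),
            Gene("y", "continuous", bounds=(0.0, 1.0)),
        )
    )


def toy_evaluator(genome: Genome) -> ObjectiveVector:
    """Analytic concave objective surface: optimal at (x, y) = (0, 0).

    dice = 1 - x^2, iou = 1 - y^2, ba = 1 - (x - y)^2 / 2,
    hd = 1 + x^2 + y^2 — so the origin scores (1, 1, 1) with HD 1.
    """
    x, y = float(genome.values["x"]), float(genome.values["y"])
    return ObjectiveVector(
        dice=1.0 - x**2,
        iou=1.0 - y**2,
        boundary_accuracy=1.0 - (x - y) ** 2 / 2.0,
        hausdorff=1.0 + x**2 + y**2,
    )


def swin_space() -> ParamSpace:
    """The transformer-segmenter hyperparameter bounds used in the study:
    learning rate [1e-5, 1e-3] (log scale), attention window {4, 7, 14},
    embedding dimension {96, 128, 192}, depth per stage 2-4."""
    return ParamSpace(
        genes=(
            Gene("learning_rate", "log-continuous", bounds=(1e-5, 1e-3)),
            Gene("window_size", "categorical", choices=(4, 7, 14)),
            Gene("embed_dim", "categorical", choices=(96, 128, 192)),
            Gene("depth", "integer", bounds=(2, 4)),
        )
    )


def random_search(
    space: ParamSpace, evaluator, budget: int, seed: int
) -> list[tuple[Genome, FitnessRecord]]:
    """Uniform random baseline at an equal evaluation budget; returns all
    evaluated genomes with fitness normalized over the full pool."""
    rng = np.random.default_rng(seed)
    genomes = [
        Genome(values={g.name: _sample_gene(g, rng) for g in space.genes}, id=i)
        for i in range(budget)
    ]
    evals = [_evaluate(evaluator, g) for g in genomes]
    records = fitness_gm(
        [o for o, _ in evals], [g.id for g in genomes], failed=[f for _, f in evals]
    )
    return list(zip(genomes, records))


def hypervolume(
    records: list[FitnessRecord],
    upper: np.ndarray,
    n_samples: int = 20000,
    seed: int = 0,
) -> float:
    """Seeded Monte-Carlo hypervolume of a record set in oriented
    objective space, with the origin as reference point and ``upper`` as
    the sampling box.  Using a shared ``upper`` and seed makes two fronts
    directly comparable."""
    pts = np.array([oriented_objectives(r.objectives) for r in records])
    upper = np.asarray(upper, dtype=float)
    rng = np.random.default_rng(seed)
    samples = rng.uniform(0.0, upper, size=(n_samples, len(upper)))
    dominated = np.zeros(n_samples, dtype=bool)
    for p in pts:
        dominated |= np.all(samples <= p, axis=1)
    return float(dominated.mean() * np.prod(upper))
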