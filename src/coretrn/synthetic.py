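"""Synthetic benchmark data with planted ground truth for every pipeline
stage.

The generators emulate the study design the pipeline was built for:

* two cell types profiled in triplicate on a bead array, with a subset of
  TFs differentially expressed between them (log-normal signal noise);
* an abstract corpus in which planted core TFs co-occur with the
  cell-type term at an elevated rate;
* a single-factor over-expression (perturbation) screen whose responses
  follow a planted regulatory DAG;
* promoter sequences carrying planted motif instances that drive log2
  expression through a linear motif-activity model.

Every generator takes its randomness from the master seed through a fixed
per-generator offset, so adding one generator to a script never perturbs
another generator's draws.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .mining import DEFAULT_KEYWORDS, Corpus
from .motifs import PWM, PromoterWindow
from .perturbation import PerturbationMatrix

__all__ = ["SynthConfig", "GroundTruth", "random_dag",
           "generate_expression_dataset", "generate_corpus",
           "generate_perturbation_dataset", "generate_promoter_dataset"]

# fixed RNG stream offsets, one per sub-generator
_OFFSET_EXPRESSION = 11
_OFFSET_CORPUS = 23
_OFFSET_PERTURBATION = 37
_OFFSET_PROMOTER = 53


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: two cell types x 3 replicates,
    a 2-fold (1 log2 unit x 2) planted effect for core TFs, bead-array-like
    log-normal noise, a 500-abstract corpus with strongly elevated core-TF
    co-mention rate, 400-bp promoter windows and a handful of motifs.
    """

    n_tfs: int = 60
    n_core: int = 8
    n_peripheral_genes: int = 240
    n_replicates: int = 3
    log2_effect_size: float = 2.0
    noise_sd: float = 0.25
    n_abstracts: int = 500
    cooccur_rate_core: float = 0.3
    cooccur_rate_bg: float = 0.05
    promoter_length: int = 400
    n_motifs: int = 5
    planted_activity_scale: float = 1.0
    seed: int = 0
    # corpus plumbing
    keyword_prob: float = 0.8
    # perturbation plumbing
    response_relative: float = 0.30
    background_relative: float = 0.01
    perturb_noise_sd: float = 0.1
    transitive_response: str = "one_step"  # direct | one_step | full
    # promoter / motif-activity plumbing
    n_promoters: int = 50
    n_activity_samples: int = 6
    pwm_length: int = 8
    activity_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_core > self.n_tfs:
            raise ValueError("n_core cannot exceed n_tfs")
        for rate in (self.cooccur_rate_core, self.cooccur_rate_bg, self.keyword_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.noise_sd < 0 or self.perturb_noise_sd < 0 or self.activity_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.promoter_length < self.pwm_length:
            raise ValueError("promoter_length must be at least the PWM length")
        if self.transitive_response not in ("direct", "one_step", "full"):
            raise ValueError("transitive_response must be direct, one_step or full")


@dataclass
class GroundTruth:
    """Planted truth shared across generators."""

    core_tf_ids: set = field(default_factory=set)
    dag_edges: set = field(default_factory=set)
    planted_activities: pd.DataFrame | None = None
    planted_site_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.dag_edges and _has_cycle(self.dag_edges):
            raise ValueError("dag_edges must be acyclic")


def _has_cycle(edges: set) -> bool:
    import networkx as nx

    g = nx.DiGraph(list(edges))
    return not nx.is_directed_acyclic_graph(g)


def _rng(config: SynthConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng(int(config.seed) + offset)


def _tf_names(config: SynthConfig) -> list[str]:
    return [f"TF{i + 1:03d}" for i in range(config.n_tfs)]


def _peripheral_names(config: SynthConfig) -> list[str]:
    return [f"PER{i + 1:04d}" for i in range(config.n_peripheral_genes)]


# ---------------------------------------------------------------------------
# expression


def generate_expression_dataset(
    config: SynthConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Two-cell-type expression matrices with planted differential TFs.

    The first ``n_core`` TFs are elevated in cell type A by
    ``log2_effect_size`` log2 units on average; signal is generated on the
    log2 scale (baseline per-gene means, Gaussian replicate noise of
    ``noise_sd``) and exponentiated to linear bead-array-like intensity.
    A small fraction of peripheral probes is left undetected (flat signal,
    detection p-value 1) to exercise the detection filter.
    """
    rng = _rng(config, _OFFSET_EXPRESSION)
    tf_names = _tf_names(config)
    per_names = _peripheral_names(config)
    symbols = tf_names + per_names
    probe_ids = [f"p_{s}" for s in symbols]
    core = set(tf_names[: config.n_core])

    n_genes = len(symbols)
    baseline = rng.uniform(6.0, 11.0, size=n_genes)
    effect = np.array([config.log2_effect_size if s in core else 0.0 for s in symbols])

    # ~5% of peripheral probes are unexpressed in both cell types
    undetected = np.zeros(n_genes, dtype=bool)
    n_undet = config.n_peripheral_genes // 20
    if n_undet:
        undet_idx = config.n_tfs + rng.choice(config.n_peripheral_genes, size=n_undet, replace=False)
        undetected[undet_idx] = True
    baseline[undetected] = 2.0
    effect[undetected] = 0.0

    def make(group: str, add_effect: bool) -> ExpressionMatrix:
        cols = [f"{group}_{r + 1}" for r in range(config.n_replicates)]
        log2_sig = (
            baseline[:, None]
            + (effect[:, None] if add_effect else 0.0)
            + rng.normal(0.0, config.noise_sd, size=(n_genes, config.n_replicates))
        )
        values = pd.DataFrame(2.0**log2_sig, index=pd.Index(probe_ids, name="probe_id"), columns=cols)
        det = np.where(undetected[:, None], 1.0, 1e-4)
        det = pd.DataFrame(np.broadcast_to(det, values.shape).copy(), index=values.index, columns=cols)
        return ExpressionMatrix(
            values=values,
            symbols=pd.Series(symbols, index=values.index),
            sample_groups={c: group for c in cols},
            detection_pvals=det,
        )

    mat_a = make("A", add_effect=True)
    mat_b = make("B", add_effect=False)
    truth = GroundTruth(core_tf_ids=core)
    return mat_a, mat_b, truth


# ---------------------------------------------------------------------------
# corpus

_FILLER_VOCAB = (
    "cell gene expression protein signaling pathway analysis role function "
    "human study regulation receptor response binding factor activity level "
    "growth tissue model effect target mechanism system process data result"
).split()


def generate_corpus(
    config: SynthConfig,
    tf_names: Sequence[str],
    cell_term: str = "monocyte",
    core_tf_names: Sequence[str] | None = None,
) -> tuple[Corpus, GroundTruth]:
    """Token-sequence abstracts with planted TF / cell-term co-mentions.

    Every abstract mentions the cell term (singular or plural); each core
    TF is additionally mentioned with probability ``cooccur_rate_core`` and
    each background TF with ``cooccur_rate_bg``, so that a TF's
    co-occurrence count over the keyword-passing abstracts is binomial at
    its planted rate.  A process keyword is included with probability
    ``keyword_prob``.
    """
    if not tf_names:
        raise ValueError("tf_names must be non-empty")
    rng = _rng(config, _OFFSET_CORPUS)
    if core_tf_names is None:
        core_tf_names = list(tf_names)[: config.n_core]
    core = set(core_tf_names)
    abstracts: list[list[str]] = []
    for _ in range(config.n_abstracts):
        tokens = list(rng.choice(_FILLER_VOCAB, size=8))
        if rng.random() < config.keyword_prob:
            tokens.append(str(rng.choice(DEFAULT_KEYWORDS)))
        tokens.append(cell_term.lower() + ("s" if rng.random() < 0.5 else ""))
        for tf in tf_names:
            rate = config.cooccur_rate_core if tf in core else config.cooccur_rate_bg
            if rng.random() < rate:
                tokens.append(tf.lower())
        order = rng.permutation(len(tokens))
        abstracts.append([tokens[i] for i in order])
    corpus = Corpus(abstracts=abstracts)
    return corpus, GroundTruth(core_tf_ids=core)


# ---------------------------------------------------------------------------
# perturbation


def random_dag(
    n_nodes: int,
    n_top: int,
    rng: np.random.Generator,
    node_names: Sequence[str] | None = None,
) -> tuple[list[str], set]:
    """A random DAG over ``n_nodes`` with exactly ``n_top`` roots.

    Nodes are ordered; the first ``n_top`` have zero in-degree, every later
    node receives at least one parent among its predecessors.
    """
    if not 1 <= n_top <= n_nodes:
        raise ValueError("need 1 <= n_top <= n_nodes")
    if node_names is None:
        node_names = [f"N{i + 1:02d}" for i in range(n_nodes)]
    nodes = list(node_names)
    edges: set = set()
    for i in range(n_top, n_nodes):
        n_parents = 1 + rng.binomial(min(i, 3) - 1, 0.5) if i > 1 else 1
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            edges.add((nodes[p], nodes[i]))
    return nodes, edges


def _response_pairs(edges: set, mode: str) -> set:
    """Planted (regulator, responder) pairs: direct edges plus the
    configured amount of transitivity."""
    import networkx as nx

    g = nx.DiGraph(list(edges))
    pairs = set(edges)
    if mode == "direct":
        return pairs
    if mode == "one_step":
        for a, b in edges:
            for c in g.successors(b):
                if c != a:
                    pairs.add((a, c))
        return pairs
    # full transitive closure
    for n in g.nodes:
        for d in nx.descendants(g, n):
            pairs.add((n, d))
    return pairs


def generate_perturbation_dataset(
    truth: GroundTruth,
    config: SynthConfig,
    measured_only: Sequence[str] = (),
) -> PerturbationMatrix:
    """Relative-expression matrix following the planted DAG.

    Measured element *i* under transduced element *j* gets
    ``response_relative`` (above the edge threshold) when *i* responds to
    *j* per the planted DAG (direct edges plus the transitivity mode in
    the config), else ``background_relative``; log2-scale Gaussian noise
    of sd ``perturb_noise_sd`` multiplies every entry.  Elements in
    ``measured_only`` appear as rows but not columns.
    """
    if truth.dag_edges and _has_cycle(truth.dag_edges):
        raise ValueError("dag_edges must be acyclic")
    rng = _rng(config, _OFFSET_PERTURBATION)
    nodes = sorted({n for e in truth.dag_edges for n in e} | set(measured_only) | set(truth.core_tf_ids))
    transduced = [n for n in nodes if n not in set(measured_only)]
    pairs = _response_pairs(truth.dag_edges, config.transitive_response)
    data = np.empty((len(nodes), len(transduced)))
    for jx, j in enumerate(transduced):
        for ix, i in enumerate(nodes):
            base = config.response_relative if (j, i) in pairs and i != j else config.background_relative
            noise = 2.0 ** rng.normal(0.0, config.perturb_noise_sd) if config.perturb_noise_sd > 0 else 1.0
            data[ix, jx] = base * noise
    rel = pd.DataFrame(
        data, index=pd.Index(nodes, name="measured"), columns=pd.Index(transduced, name="transduced")
    )
    mock = pd.Series(config.background_relative, index=rel.index)
    return PerturbationMatrix(relative_expression=rel, mock=mock)


# ---------------------------------------------------------------------------
# promoters / motif activities


def _sample_pwm(rng: np.random.Generator, length: int, name: str) -> PWM:
    """A sharp random count matrix (dominant base ~94% per position)."""
    counts = np.full((length, 4), 2.0)
    dominant = rng.integers(0, 4, size=length)
    counts[np.arange(length), dominant] = 94.0
    return PWM(name=name, counts=counts)


def generate_promoter_dataset(
    config: SynthConfig,
) -> tuple[list[PromoterWindow], list[PWM], ExpressionMatrix, GroundTruth]:
    """Promoters with planted motif sites driving a linear activity model.

    Site counts ``N[p, m]`` are small Poisson draws; that many instances
    (sampled from the PWM) are implanted at disjoint positions of each
    random background promoter.  Planted activities ``A[m, s]`` are
    Gaussian with sd ``planted_activity_scale``, centered per motif, and
    log2 expression is ``e = c_p + N @ A + eps`` with Gaussian noise of sd
    ``activity_noise_sd``.  The returned ExpressionMatrix holds the log2
    values (``log_scale=True``).
    """
    rng = _rng(config, _OFFSET_PROMOTER)
    if config.promoter_length < config.pwm_length:
        raise ValueError("promoter_length must be at least the PWM length")
    pwms = [_sample_pwm(rng, config.pwm_length, f"MOTIF{m + 1:02d}") for m in range(config.n_motifs)]
    probe_ids = [f"p_PROM{i + 1:03d}" for i in range(config.n_promoters)]

    n_counts = rng.poisson(0.8, size=(config.n_promoters, config.n_motifs)).astype(float)
    windows: list[PromoterWindow] = []
    L = config.pwm_length
    for i, pid in enumerate(probe_ids):
        seq = rng.choice(list("ACGT"), size=config.promoter_length)
        slots = np.arange(config.promoter_length // L)
        rng.shuffle(slots)
        slot_iter = iter(slots)
        for m, pwm in enumerate(pwms):
            probs = pwm.probabilities
            for _ in range(int(n_counts[i, m])):
                try:
                    start = int(next(slot_iter)) * L
                except StopIteration:  # promoter saturated with sites
                    n_counts[i, m] -= 1
                    continue
                # implant a high-affinity instance: consensus everywhere,
                # one PWM-sampled position for minimal site-to-site variation
                site = list(pwm.consensus)
                k = int(rng.integers(0, L))
                site[k] = str(rng.choice(list("ACGT"), p=probs[k]))
                seq[start : start + L] = site
        windows.append(PromoterWindow(probe_id=pid, sequence="".join(seq)))

    samples = [f"s{j + 1}" for j in range(config.n_activity_samples)]
    A = rng.normal(0.0, config.planted_activity_scale, size=(config.n_motifs, config.n_activity_samples))
    A -= A.mean(axis=1, keepdims=True)
    c = rng.uniform(6.0, 10.0, size=config.n_promoters)
    eps = (
        rng.normal(0.0, config.activity_noise_sd, size=(config.n_promoters, config.n_activity_samples))
        if config.activity_noise_sd > 0
        else 0.0
    )
    e = c[:, None] + n_counts @ A + eps
    expr = ExpressionMatrix(
        values=pd.DataFrame(e, index=pd.Index(probe_ids, name="probe_id"), columns=samples),
        symbols=pd.Series(probe_ids, index=probe_ids),
        sample_groups={s: "synthetic" for s in samples},
        log_scale=True,
    )
    truth = GroundTruth(
        planted_activities=pd.DataFrame(A, index=[p.name for p in pwms], columns=samples),
        planted_site_counts=pd.DataFrame(n_counts, index=probe_ids, columns=[p.name for p in pwms]),
    )
    return windows, pwms, expr, truth
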