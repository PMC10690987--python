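"""Synthetic data with planted ground truth for the two-stress-event design.

Generates every input the analysis consumes — a negative-binomial count
matrix over the conditions T1_0h/T1_3h/T1_48h/T2_3h/T2_48h, TF-family
annotations with configurable enrichment among memory genes, an interaction
graph with a planted dense complex on designated hub genes, and 1-kb
promoter sequences with recorded planted motif instances — together with
the truth tables needed to verify recovery.

Gene classes and their true expected log2 effects (first effect: 3 h of the
first stress vs baseline; second effect: 3 h of the second stress vs 3 h of
the first):

==============  ========  ========
class           effect 1  effect 2
==============  ========  ========
NULL                0         0
NONMEM_UP         +b1         0
NONMEM_DOWN       -b1         0
PP                +b1       +b2
MM                -b1       -b2
PM                +b1       -b2
MP                -b1       +b2
==============  ========  ========

Effects are exact on expected means; the only noise is NB sampling
(variance = mu + alpha * mu**2) and per-sample size factors.  The 48-h
conditions reuse their event's 3-h mean; they exist so DEG-count-reduction
statistics can be exercised, and they never enter memory classification.
A single seed drives independent substreams for counts, annotations, graph
and promoters, so each component is individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .decore import CountMatrix
from .motifscan import PromoterRecord, reverse_complement

DEFAULT_CONDITIONS = ("T1_0h", "T1_3h", "T1_48h", "T2_3h", "T2_48h")

GENE_CLASSES = ("NULL", "NONMEM_UP", "NONMEM_DOWN", "PP", "MM", "PM", "MP")
MEMORY_GENE_CLASSES = ("PP", "MM", "PM", "MP")

#: sign of (first, second) log2 effect per class
CLASS_SIGNS = {
    "NULL": (0, 0),
    "NONMEM_UP": (1, 0),
    "NONMEM_DOWN": (-1, 0),
    "PP": (1, 1),
    "MM": (-1, -1),
    "PM": (1, -1),
    "MP": (-1, 1),
}

# Memory classes split 10% of genes in the proportions observed for the four
# classes in repeated-salt-stress transcriptomes (the inverted [+/-] class
# dominating, [-/+] second); the rest is 80% unresponsive and 10%
# non-memory responsive.
DEFAULT_CLASS_PROPORTIONS = {
    "NULL": 0.80,
    "NONMEM_UP": 0.05,
    "NONMEM_DOWN": 0.05,
    "PP": 0.004,
    "MM": 0.003,
    "PM": 0.063,
    "MP": 0.030,
}

# ~6% of a 2000-gene genome are TFs (the genome-wide TF fraction seen in
# plant genomes), with the stress-responsive WRKY/MYB families enriched
# among memory genes.
DEFAULT_TF_FAMILIES = {
    "WRKY": (40, 3.0),
    "MYB": (30, 2.0),
    "bHLH": (20, 1.0),
    "NAC": (20, 1.0),
    "AP2-ERF": (10, 1.0),
}


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    ``effect_first``/``effect_second`` are log2 effect magnitudes;
    ``baseline_logmean_mu``/``sigma`` parameterize the natural-log-normal
    per-gene baseline mean; ``dispersion`` is the NB alpha in
    var = mu + alpha mu**2; ``tf_families`` maps family name ->
    (genome count, enrichment multiplier among memory genes); ``hub_spec``
    is (n_hubs, clique_size, background_edge_prob); ``promoter_spec`` is
    (length, gc, planted_motif_rate).
    """

    n_genes: int = 2000
    conditions: tuple = DEFAULT_CONDITIONS
    n_replicates: int = 3
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    effect_first: float = 3.0
    effect_second: float = 3.0
    baseline_logmean_mu: float = 5.0
    baseline_logmean_sigma: float = 1.0
    dispersion: float = 0.05
    size_factor_range: tuple = (0.7, 1.4)
    tf_families: dict = field(default_factory=lambda: dict(DEFAULT_TF_FAMILIES))
    hub_spec: tuple = (6, 6, 0.05)
    promoter_spec: tuple = (1000, 0.5, 1.0)
    motif_width: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {total}")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        if not (math.isfinite(self.effect_first) and math.isfinite(self.effect_second)):
            raise ValueError("effects must be finite")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValueError("size_factor_range must be a positive interval")
        p = self.hub_spec[2]
        if not (0.0 <= p <= 1.0):
            raise ValueError("background_edge_prob must lie in [0, 1]")
        length, gc, rate = self.promoter_spec
        if length < self.motif_width:
            raise ValueError("promoter length must be >= motif width")
        if not (0.0 <= gc <= 1.0 and 0.0 <= rate <= 1.0):
            raise ValueError("gc and planted_motif_rate must lie in [0, 1]")
        total_family = sum(k for k, _ in self.tf_families.values())
        if total_family > self.n_genes:
            raise ValueError("tf_families genome counts exceed the gene pool")

    def substreams(self) -> dict[str, np.random.Generator]:
        """Independent, reproducible RNG substreams per component."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("counts", "annotations", "network", "promoters")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class TruthTables:
    """Planted ground truth accompanying one simulated dataset."""

    classes: pd.Series                    # gene -> class label
    families: pd.Series | None = None     # gene -> family name or None
    hubs: frozenset = frozenset()         # planted clique members
    motif_instances: list = field(default_factory=list)  # (tf, gene, offset, strand)
    motif_consensi: dict = field(default_factory=dict)   # tf family -> consensus word
    true_log2_effects: pd.DataFrame | None = None        # gene x (effect1, effect2)

    def memory_genes(self) -> set:
        return set(self.classes.index[self.classes.isin(MEMORY_GENE_CLASSES)])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"class": self.classes})
        if self.families is not None:
            df["family"] = self.families
        df["hub"] = [g in self.hubs for g in df.index]
        df.to_csv(path, sep="\t", index_label="gene")


def _gene_ids(n: int) -> pd.Index:
    return pd.Index([f"g{i:05d}" for i in range(n)], name="gene")


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, TruthTables]:
    """Draw the NB count matrix and plant gene classes."""
    config.validate()
    rng = config.substreams()["counts"]
    genes = _gene_ids(config.n_genes)

    class_names = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in class_names])
    classes = pd.Series(
        rng.choice(class_names, size=config.n_genes, p=probs), index=genes, name="class"
    )

    signs = np.array([CLASS_SIGNS[c] for c in classes], dtype=float)
    eff1 = signs[:, 0] * config.effect_first
    eff2 = signs[:, 1] * config.effect_second

    baseline = rng.lognormal(
        config.baseline_logmean_mu, config.baseline_logmean_sigma, size=config.n_genes
    )
    mean_t1_3h = baseline * np.exp2(eff1)
    mean_t2_3h = mean_t1_3h * np.exp2(eff2)
    cond_means = {
        "T1_0h": baseline,
        "T1_3h": mean_t1_3h,
        "T1_48h": mean_t1_3h,
        "T2_3h": mean_t2_3h,
        "T2_48h": mean_t2_3h,
    }

    # per-gene dispersion drawn around the configured value
    if config.dispersion > 0:
        alpha = config.dispersion * rng.lognormal(0.0, 0.25, size=config.n_genes)
    else:
        alpha = np.zeros(config.n_genes)

    lo, hi = config.size_factor_range
    columns, data, design_rows = [], [], []
    for cond in config.conditions:
        mu_cond = cond_means[cond]
        for rep in range(1, config.n_replicates + 1):
            sf = rng.uniform(lo, hi)
            mu = mu_cond * sf
            with np.errstate(divide="ignore"):
                draws = np.where(
                    alpha > 0,
                    rng.negative_binomial(
                        np.where(alpha > 0, 1.0 / np.maximum(alpha, 1e-12), 1.0),
                        np.where(
                            alpha > 0,
                            1.0 / (1.0 + np.maximum(alpha, 1e-12) * mu),
                            0.5,
                        ),
                    ),
                    rng.poisson(mu),
                )
            columns.append(f"{cond}_r{rep}")
            data.append(draws)
            design_rows.append({"sample": f"{cond}_r{rep}", "condition": cond, "replicate": rep})

    counts = pd.DataFrame(
        np.column_stack(data).astype(np.int64), index=genes, columns=columns
    )
    design = pd.DataFrame(design_rows).set_index("sample")
    truth = TruthTables(
        classes=classes,
        true_log2_effects=pd.DataFrame({"effect1": eff1, "effect2": eff2}, index=genes),
    )
    return CountMatrix(counts=counts, design=design), truth


def simulate_annotations(config: SimConfig, truth: TruthTables) -> pd.Series:
    """Assign TF families so each family's expected frequency among memory
    genes is its genome frequency times the configured multiplier.

    The number of family members drawn from the memory-gene pool is binomial
    with success probability ``multiplier * K / n_genes``; identities are
    sampled without replacement from the remaining unassigned genes.  The
    result is also stored on ``truth.families``.
    """
    config.validate()
    rng = config.substreams()["annotations"]
    genes = truth.classes.index
    n = len(genes)
    memory = [g for g in genes if truth.classes[g] in MEMORY_GENE_CLASSES]
    other = [g for g in genes if truth.classes[g] not in MEMORY_GENE_CLASSES]
    mem_pool = list(rng.permutation(memory))
    other_pool = list(rng.permutation(other))

    assignment: dict[str, str | None] = {g: None for g in genes}
    for family, (genome_count, multiplier) in config.tf_families.items():
        if genome_count > len(mem_pool) + len(other_pool):
            raise ValueError(f"family {family!r} larger than remaining gene pool")
        p_mem = min(1.0, multiplier * genome_count / n)
        k_mem = int(rng.binomial(len(memory), p_mem))
        k_mem = min(k_mem, genome_count, len(mem_pool))
        k_other = min(genome_count - k_mem, len(other_pool))
        for _ in range(k_mem):
            assignment[mem_pool.pop()] = family
        for _ in range(k_other):
            assignment[other_pool.pop()] = family
    families = pd.Series(assignment, index=genes, name="family", dtype=object)
    truth.families = families
    return families


def simulate_network(config: SimConfig, truth: TruthTables) -> nx.Graph:
    """Erdős–Rényi background over TF genes plus a planted clique on hub
    genes (drawn from memory TF genes when available).

    Stores the clique members on ``truth.hubs``.
    """
    config.validate()
    if truth.families is None:
        simulate_annotations(config, truth)
    rng = config.substreams()["network"]
    n_hubs, clique_size, p = config.hub_spec

    tf_genes = sorted(truth.families.index[truth.families.notna()])
    memory = truth.memory_genes()
    hub_pool = [g for g in tf_genes if g in memory] or tf_genes
    n_hubs = min(n_hubs, len(hub_pool))
    hubs = sorted(str(g) for g in rng.choice(hub_pool, size=n_hubs, replace=False)) if n_hubs else []
    clique = hubs if clique_size >= len(hubs) else sorted(
        str(g) for g in rng.choice(hubs, size=clique_size, replace=False)
    )

    graph = nx.Graph()
    graph.add_nodes_from(tf_genes)
    if p > 0 and len(tf_genes) > 1:
        er = nx.fast_gnp_random_graph(
            len(tf_genes), p, seed=int(rng.integers(0, 2**31 - 1))
        )
        for i, j in er.edges:
            graph.add_edge(tf_genes[i], tf_genes[j])
    for i, u in enumerate(clique):
        for v in clique[i + 1 :]:
            graph.add_edge(u, v)
    for u, v in graph.edges:
        graph.edges[u, v]["score"] = float(rng.integers(700, 1001))
    truth.hubs = frozenset(clique)
    return graph


def simulate_promoters(
    config: SimConfig, truth: TruthTables
) -> tuple[dict[str, PromoterRecord], dict[str, str]]:
    """I.i.d.-background promoters with planted TF consensus words.

    Each TF family receives a random consensus word of ``motif_width``; each
    memory gene becomes a true target of each family independently with
    probability ``planted_motif_rate``, receiving one non-overlapping
    consensus instance at a recorded offset and strand.  Returns
    (promoters, family -> consensus); instances are recorded on
    ``truth.motif_instances`` as (family, gene, offset, strand).
    """
    config.validate()
    if truth.families is None:
        simulate_annotations(config, truth)
    rng = config.substreams()["promoters"]
    length, gc, rate = config.promoter_spec
    w = config.motif_width
    bases = np.array(list("ACGT"))
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    consensi = {
        family: "".join(rng.choice(bases, size=w, p=base_p))
        for family in config.tf_families
    }
    truth.motif_consensi = dict(consensi)

    genes = truth.classes.index
    memory = sorted(truth.memory_genes())
    promoters: dict[str, PromoterRecord] = {}
    instances: list[tuple] = []
    planted: dict[str, list[tuple[int, int, str, str]]] = {g: [] for g in genes}

    for family, word in consensi.items():
        for gene in memory:
            if rate < 1.0 and rng.random() >= rate:
                continue
            # rejection-sample a non-overlapping offset
            for _ in range(200):
                offset = int(rng.integers(0, length - w + 1))
                if all(
                    offset + w <= s or offset >= s + w for s, _, _, _ in planted[gene]
                ):
                    break
            else:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            planted[gene].append((offset, w, strand, word))
            instances.append((family, gene, offset, strand))

    for gene in genes:
        seq = rng.choice(bases, size=length, p=base_p)
        for offset, width, strand, word in planted[gene]:
            ins = word if strand == "+" else reverse_complement(word)
            seq[offset : offset + width] = list(ins)
        promoters[gene] = PromoterRecord(
            gene=gene, seq="".join(seq), contig=f"chr_{gene}", start=1, end=length, strand="+"
        )
    truth.motif_instances = instances
    return promoters, consensi


def simulate_all(config: SimConfig):
    """Run every generator; returns (CountMatrix, graph, promoters,
    consensi, TruthTables)."""
    cm, truth = simulate_counts(config)
    simulate_annotations(config, truth)
    graph = simulate_network(config, truth)
    promoters, consensi = simulate_promoters(config, truth)
    return cm, graph, promoters, consensi, truth
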