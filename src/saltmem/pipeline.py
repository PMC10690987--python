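"""End-to-end orchestration of the stress-memory analysis.

``run_pipeline`` drives every stage — differential expression over the
five-condition two-stress design, memory classification, TF-family
enrichment, network hub detection and promoter motif scanning — from a
single config, writing stage outputs and a JSON report of the headline
statistics.  ``replay`` recomputes every derived ratio (class shares, DEG
reductions, TF fractions, enrichment p, target shares) from externally
supplied counts, so published summary tables can be checked without the
underlying raw data.  ``ddct`` implements the qPCR 2^-ddCt
relative-expression statistic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import decore, hubnet, memclass, motifscan, setenrich, simdata

logger = logging.getLogger("saltmem")

#: contrasts run by the pipeline, as (reference, alternative)
PIPELINE_CONTRASTS = (
    ("T1_0h", "T1_3h"),
    ("T1_0h", "T1_48h"),
    ("T1_0h", "T2_3h"),
    ("T1_0h", "T2_48h"),
    ("T1_3h", "T2_3h"),
)


@dataclasses.dataclass
class PipelineConfig:
    """Inputs and thresholds for one pipeline run.

    Exactly one of ``sim`` (simulation parameters) or the real-input paths
    (``counts_path`` + ``samples_path``, with optional graph/promoter/motif
    files) must be supplied.
    """

    outdir: str = "saltmem_out"
    seed: int = 0
    sim: simdata.SimConfig | None = None
    counts_path: str | None = None
    samples_path: str | None = None
    annotation_path: str | None = None
    edges_path: str | None = None
    promoters_path: str | None = None
    motifs_path: str | None = None
    score_threshold: float = 400.0
    mcc_top_k: int = 10
    mcode_min_size: int = 4
    p_threshold: float = motifscan.DEFAULT_P_THRESHOLD

    def __post_init__(self) -> None:
        has_sim = self.sim is not None
        has_real = self.counts_path is not None
        if has_sim == has_real:
            raise ValueError("supply exactly one of simulation parameters or count paths")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        if sim is not None:
            sim = simdata.SimConfig(**sim)
        return cls(sim=sim, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the JSON report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}

    stage = "input"
    try:
        if config.sim is not None:
            config.sim.seed = config.seed
            logger.info("simulating dataset: %s", config.sim)
            cm, graph, promoters, consensi, truth = simdata.simulate_all(config.sim)
            annotation = {
                g: f for g, f in truth.families.items() if isinstance(f, str)
            }
            motif_models = [
                motifscan.MotifModel.from_consensus(fam, word)
                for fam, word in consensi.items()
            ]
            cm.to_tsv(outdir / "counts.tsv", outdir / "samples.tsv")
            truth.to_tsv(outdir / "truth.tsv")
            motifscan.write_promoters_fasta(promoters, outdir / "promoters.fasta")
            motifscan.write_meme(consensi, outdir / "motifs.meme")
            nx_edges = [
                (u, v, d.get("score", "")) for u, v, d in graph.edges(data=True)
            ]
            pd.DataFrame(nx_edges, columns=["node1", "node2", "score"]).to_csv(
                outdir / "edges.tsv", sep="\t", index=False, header=False
            )
        else:
            cm = decore.CountMatrix.from_tsv(config.counts_path, config.samples_path)
            annotation = {}
            if config.annotation_path:
                ann = pd.read_csv(config.annotation_path, sep="\t")
                annotation = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))
            graph = (
                hubnet.read_edges(config.edges_path, config.score_threshold)
                if config.edges_path
                else None
            )
            promoters = (
                motifscan.read_promoters_fasta(config.promoters_path)
                if config.promoters_path
                else None
            )
            motif_models = (
                motifscan.read_meme(config.motifs_path) if config.motifs_path else []
            )

        # ---------------------------------------------- differential expression
        stage = "decore"
        factors = decore.size_factors(cm)
        dispersions = decore.estimate_dispersion(cm, factors)
        contrasts: dict[str, decore.ContrastResult] = {}
        deg_counts: dict[str, int] = {}
        for ref, alt in PIPELINE_CONTRASTS:
            res = decore.wald_contrast(cm, factors, dispersions, ref, alt)
            key = f"{alt}_vs_{ref}"
            contrasts[key] = res
            up, down = decore.call_degs(res)
            deg_counts[key] = len(up) + len(down)
            res.to_tsv(outdir / f"contrast_{key}.tsv")
        report["deg_counts"] = deg_counts
        report["deg_reduction"] = {
            "3h": (
                memclass.deg_reduction(
                    deg_counts["T1_3h_vs_T1_0h"], deg_counts["T2_3h_vs_T1_0h"]
                )
                if deg_counts["T1_3h_vs_T1_0h"]
                else None
            ),
            "48h": (
                memclass.deg_reduction(
                    deg_counts["T1_48h_vs_T1_0h"], deg_counts["T2_48h_vs_T1_0h"]
                )
                if deg_counts["T1_48h_vs_T1_0h"]
                else None
            ),
        }
        report["stages"].append(stage)

        # ------------------------------------------------ memory classification
        stage = "memclass"
        catalog = memclass.classify_memory(
            contrasts["T1_3h_vs_T1_0h"], contrasts["T2_3h_vs_T1_3h"]
        )
        catalog.to_tsv(outdir / "memory_catalog.tsv")
        report["smg_total"] = catalog.smg_total
        report["smg_counts"] = catalog.counts
        report["smg_percents"] = catalog.proportions
        report["stages"].append(stage)

        # ----------------------------------------------------------- enrichment
        stage = "setenrich"
        smgs = catalog.smg_genes()
        universe = set(cm.genes)
        if annotation and smgs:
            tf_genes = {g for g in universe if annotation.get(g)}
            report["tf_fraction_smg"] = setenrich.proportion(
                len(smgs & tf_genes), len(smgs)
            )
            report["tf_fraction_genome"] = setenrich.proportion(
                len(tf_genes), len(universe)
            )
            enr = setenrich.fisher_enrichment(smgs, universe, annotation)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            report["enrichment"] = enr.to_dict(orient="records")
        report["stages"].append(stage)

        # ----------------------------------------------------------------- hubs
        stage = "hubnet"
        if graph is not None and graph.number_of_nodes():
            mcc = hubnet.mcc_scores(graph)
            mcc.to_tsv(outdir / "mcc_scores.tsv")
            complexes = hubnet.mcode_complexes(graph)
            with open(outdir / "complexes.json", "w") as fh:
                json.dump(
                    [
                        {"nodes": list(c.nodes), "score": c.score, "seed": c.seed}
                        for c in complexes
                    ],
                    fh,
                    indent=2,
                )
            mcc_top = mcc.top(config.mcc_top_k)
            mcode_set = hubnet.mcode_members(complexes, config.mcode_min_size)
            hubs = hubnet.hub_intersection(mcc_top, mcode_set)
            report["mcc_top"] = mcc_top
            report["mcode_members"] = sorted(mcode_set, key=str)
            report["hubs"] = hubs
            pd.Series(hubs, name="hub").to_csv(outdir / "hubs.tsv", sep="\t", index=False)
        report["stages"].append(stage)

        # ------------------------------------------------------- motif scanning
        stage = "motifscan"
        if promoters and motif_models and smgs:
            target_sets: dict[str, set] = {}
            all_hits = []
            for model in motif_models:
                hits = motifscan.scan(model, promoters, p_threshold=config.p_threshold)
                targets = motifscan.targets_of(hits) & smgs
                target_sets[model.name] = targets
                all_hits.extend((model.name, h) for h in hits)
            pd.DataFrame(
                [
                    {
                        "motif": name,
                        "gene": h.gene,
                        "offset": h.offset,
                        "strand": h.strand,
                        "score_bits": h.score,
                        "pvalue": h.pvalue,
                    }
                    for name, h in all_hits
                ]
            ).to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
            overlap = motifscan.overlap_table(target_sets)
            union = set(overlap.union)
            report["target_counts"] = {n: len(s) for n, s in target_sets.items()}
            report["target_union"] = len(union)
            report["target_union_fraction_of_smgs"] = setenrich.proportion(
                len(union), len(smgs)
            )
            report["common_targets"] = list(overlap.common)
            report["n_common_targets"] = overlap.n_common
        report["stages"].append(stage)
    except Exception:
        logger.exception("pipeline stage %r failed; partial outputs kept in %s", stage, outdir)
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from None

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


# ------------------------------------------------------------------- replay
def replay(
    class_counts: dict[str, int],
    deg_counts_first: tuple[int, int] | None = None,
    deg_counts_second: tuple[int, int] | None = None,
    tf_table: dict[str, int] | None = None,
    target_counts: dict | None = None,
) -> dict:
    """Recompute derived summary statistics from printed counts.

    ``class_counts`` maps PP/MM/PM/MP to gene counts; ``deg_counts_first``
    and ``deg_counts_second`` are (first-event, second-event) DEG counts for
    the 3-h and 48-h contrasts; ``tf_table`` holds smg_tf, smg_total,
    genome_tf, genome_total; ``target_counts`` holds union (TF target-gene
    union size), common_by_class (class -> count among all-TF common
    targets) and optionally binding (count of common targets in a category
    of interest, e.g. a GO molecular-function bin).
    """
    out: dict = {}
    total = sum(class_counts.values())
    out["smg_total"] = total
    out["class_percents"] = {
        c: setenrich.proportion(n, total) for c, n in class_counts.items()
    }
    if deg_counts_first is not None:
        out["deg_reduction_3h"] = memclass.deg_reduction(*deg_counts_first)
    if deg_counts_second is not None:
        out["deg_reduction_48h"] = memclass.deg_reduction(*deg_counts_second)
    if tf_table is not None:
        smg_tf = tf_table["smg_tf"]
        smg_total = tf_table.get("smg_total", total)
        genome_tf = tf_table["genome_tf"]
        genome_total = tf_table["genome_total"]
        out["tf_percent_smg"] = setenrich.proportion(smg_tf, smg_total)
        out["tf_percent_genome"] = setenrich.proportion(genome_tf, genome_total)
        # SMGs vs the disjoint non-SMG remainder of the genome
        out["tf_enrichment_pvalue"] = setenrich.fisher_2x2(
            smg_tf, smg_total, genome_tf, genome_total
        )
    if target_counts is not None:
        union = target_counts["union"]
        out["target_percent_of_smgs"] = setenrich.proportion(union, total)
        common_by_class = target_counts.get("common_by_class")
        if common_by_class is not None:
            n_common = sum(common_by_class.values())
            out["n_common_targets"] = n_common
            if "binding" in target_counts:
                out["binding_percent_of_common"] = setenrich.proportion(
                    target_counts["binding"], n_common
                )
    return out


# --------------------------------------------------------------------- qPCR
@dataclasses.dataclass(frozen=True)
class DdCtRecord:
    group: str
    ct_target: float
    ct_reference: float
    dct: float
    ddct: float
    rel_expression: float


def ddct(table: pd.DataFrame, calibrator: str) -> list[DdCtRecord]:
    """qPCR relative expression by the 2^-ddCt method.

    ``table`` needs columns group, ct_target, ct_reference; replicate rows
    per group are averaged before differencing.  ddCt is each group's
    (Ct_target - Ct_reference) minus the calibrator's, and relative
    expression is 2**(-ddCt) (the calibrator's is exactly 1).
    """
    required = {"group", "ct_target", "ct_reference"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    means = table.groupby("group", sort=False)[["ct_target", "ct_reference"]].mean()
    if not np.isfinite(means.to_numpy(dtype=float)).all():
        raise ValueError("Ct values must be finite")
    if calibrator not in means.index:
        raise ValueError(f"calibrator group {calibrator!r} not present")
    dct = means["ct_target"] - means["ct_reference"]
    ddct_vals = dct - dct[calibrator]
    return [
        DdCtRecord(
            group=g,
            ct_target=float(means.loc[g, "ct_target"]),
            ct_reference=float(means.loc[g, "ct_reference"]),
            dct=float(dct[g]),
            ddct=float(ddct_vals[g]),
            rel_expression=float(2.0 ** (-ddct_vals[g])),
        )
        for g in means.index
    ]
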