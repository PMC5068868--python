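"""End-to-end orchestration: corpus -> matrix -> tree -> stability -> root.

Each stage writes its artifacts under the configured output directory and
the resolved config is echoed there, so a recorded run is reproducible from
its own outputs. A stage failure aborts downstream stages.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

from . import clustering, io, root, simulate, stability
from .config import PipelineConfig

logger = logging.getLogger(__name__)


def _corpus_spec(config: PipelineConfig) -> simulate.CorpusSpec:
    return simulate.CorpusSpec(
        n_experiments=config.n_experiments,
        biosets_per_experiment=config.biosets_per_experiment,
        universe_size=config.universe_size,
        baseline_inclusion_prob=config.baseline_inclusion_prob,
        experiment_specific_genes=config.experiment_specific_genes,
        experiment_share_prob=config.experiment_share_prob,
        signature_size=config.signature_size,
        signature_biosets=tuple(config.signature_biosets or ()),
        signature_inclusion_prob=config.signature_inclusion_prob,
        seed=config.seed,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a summary dict of key results and paths."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    # --- corpus ---------------------------------------------------------
    manifest = None
    if config.gene_lists:
        corpus = io.read_gene_lists(config.gene_lists, format="gmt")
    else:
        corpus, manifest = simulate.generate_list_corpus(_corpus_spec(config))
        io.write_json(manifest, out / "manifest.json")
    io.write_gmt(corpus, out / "corpus.gmt")
    logger.info("corpus: %d biosets", len(corpus))

    # --- matrix / distances / tree / partition --------------------------
    matrix = clustering.build_matrix(corpus)
    matrix.data.to_csv(out / "matrix.tsv", sep="\t", index_label="bioset_id")
    dist = clustering.jaccard_distance_matrix(matrix)
    dist.to_csv(out / "distance.tsv", sep="\t", index_label="bioset_id")
    tree = clustering.hierarchical_cluster(dist, linkage=config.linkage)
    io.write_newick(clustering.to_newick(tree), out / "tree.nwk")
    partition = clustering.cut_tree(tree, config.k)
    partition.to_frame().to_csv(out / "partition.tsv", sep="\t", index=False)
    mds = clustering.classical_mds(dist, dims=config.mds_dims)
    mds.to_csv(out / "mds.tsv", sep="\t", index_label="bioset_id")

    # --- bootstrap stability --------------------------------------------
    stab_config = stability.StabilityConfig(
        B=config.B,
        k=config.k,
        linkage=config.linkage,
        seed=config.seed,
        robust_threshold=config.robust_threshold,
        dissolved_threshold=config.dissolved_threshold,
    )
    report = stability.assess_stability(corpus, stab_config, partition=partition)
    (out / "stability.json").write_text(report.to_json())
    report.summary_frame().to_csv(out / "stability.tsv", sep="\t", index=False)

    # --- root signature --------------------------------------------------
    if config.root_cluster_members:
        members = list(config.root_cluster_members)
    else:
        multi = [c for c in report.clusters if len(c.members) >= 2]
        if not multi:
            raise RuntimeError("no cluster with >= 2 members to root")
        members = max(multi, key=lambda c: c.mean).members
    signature = root.extract_root(
        corpus, members, min_support=config.min_support
    )
    io.write_signature_files(
        signature, out / "signature.gmt", out / "signature.txt"
    )

    # --- specificity ------------------------------------------------------
    others = [b for b in corpus if b.bioset_id not in set(members)]
    overlap = None
    if len(others) >= 2 and len(signature):
        overlap = root.overlap_null(signature, others)
        overlap.pair_counts.to_csv(out / "overlap_pairs.tsv", sep="\t",
                                   index=False)
        overlap.histogram().to_csv(out / "overlap_hist.tsv", sep="\t",
                                   index=False)
    universe = matrix.genes
    references = {
        name: io.read_gene_list(path)
        for name, path in (config.reference_lists or {}).items()
    }
    if references and len(signature):
        table = root.enrichment_table(signature, references, universe)
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        for name, ref in references.items():
            hits = root.list_overlap(signature, ref)
            (out / f"overlap_{name}.txt").write_text("\n".join(hits) + "\n")

    summary = {
        "outdir": str(out),
        "n_biosets": len(corpus),
        "k": config.k,
        "root_members": members,
        "root_size": len(signature),
        "root_cluster_mean_stability": next(
            (c.mean for c in report.clusters
             if sorted(c.members) == sorted(members)),
            None,
        ),
        "mean_null_overlap": overlap.mean if overlap else None,
    }
    io.write_json(summary, out / "summary.json")
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return summary
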