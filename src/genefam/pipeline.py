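"""End-to-end orchestration of the family-characterization pipeline.

Wires the stages together over a genome (real files or a synthetic one):
profile scan -> member selection -> MSA/NJ/bootstrap -> gene structure and
motifs -> tandem + collinear duplication -> Ka/Ks and dating -> expression.
Each stage writes a plain TSV so every figure-style product of the analysis
is available as a table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import domain, duplication, expression, phylo, simulate, structure
from .config import PipelineConfig
from .io import GeneModel, ProteinRecord, summarize_counts, write_bed, write_fasta

logger = logging.getLogger("genefam")


@dataclass
class IdentificationResult:
    members: list[domain.FamilyMember]
    profile: domain.DomainProfile

    @property
    def accepted(self) -> list[domain.FamilyMember]:
        return [m for m in self.members if m.status == "accepted"]

    def counts(self) -> dict[str, int]:
        out = {"total": len(self.members), "accepted": 0,
               "rejected_no_domain": 0, "rejected_multi_domain": 0}
        for m in self.members:
            out[m.status] += 1
        return out


def identify_family(
    proteins: list[tuple[str, str]],
    seed_alignment: list[str],
    config: PipelineConfig,
    gene_models: dict[str, GeneModel] | None = None,
    seed: int = 0,
    n_decoys: int = 10_000,
) -> IdentificationResult:
    """Scan a proteome against the domain profile and select family members."""
    profile = domain.build_profile(seed_alignment)
    domain.calibrate_profile(
        profile, n_decoys=n_decoys, seed=seed,
        database_sequences=[s for _n, s in proteins],
    )
    members = []
    for name, seq in proteins:
        record = ProteinRecord(protein_id=name, sequence=seq)
        _len, record.molecular_weight, record.isoelectric_point = \
            domain.compute_protein_stats(seq)
        hits = domain.scan_protein(profile, record, config.domain_evalue)
        members.append(domain.FamilyMember(
            protein=record, hits=hits,
            gene=(gene_models or {}).get(name),
        ))
    domain.select_family_members(members)
    return IdentificationResult(members=members, profile=profile)


def phylogeny(
    accepted: list[domain.FamilyMember],
    config: PipelineConfig,
    seed: int = 0,
    reference_labels: dict[str, str] | None = None,
):
    """MSA, NJ tree with bootstrap, and (optionally) subfamily labels."""
    sequences = [(m.protein.protein_id, m.protein.sequence) for m in accepted]
    msa = phylo.build_msa(sequences)
    tree = phylo.bootstrap_support(
        msa, replicates=config.bootstrap_replicates, seed=seed,
        collapse=config.collapse_support,
    )
    assignment = None
    if reference_labels:
        assignment = phylo.assign_subfamilies(tree, reference_labels,
                                              min_support=config.collapse_support)
    return msa, tree, assignment


def duplication_analysis(
    accepted: list[domain.FamilyMember],
    all_genes: list[GeneModel],
    cds: dict[str, str],
    config: PipelineConfig,
    seed: int = 0,
):
    """Tandem clusters, collinear blocks, and Ka/Ks-dated paralog pairs."""
    family_genes = [m.gene for m in accepted if m.gene is not None]
    clusters = duplication.detect_tandem_clusters(family_genes, config.tandem_window)

    proteins = [m.protein for m in accepted]
    hits = duplication.all_vs_all_similarity(proteins, config, seed=seed)

    gene_order: dict[str, list[str]] = {}
    for g in sorted(all_genes, key=lambda g: (g.chromosome, g.start)):
        gene_order.setdefault(g.chromosome, []).append(g.gene_id)
    blocks = duplication.chain_collinear_blocks(
        hits, gene_order, gap=config.collinearity_gap, min_anchors=config.min_anchors,
    )

    seqs = {m.protein.protein_id: m.protein.sequence for m in accepted}
    block_pairs = {tuple(sorted(a)) for b in blocks for a in b.anchors}
    pairs = []
    for h in hits:
        key = tuple(sorted((h.query_id, h.subject_id)))
        source = "block_anchor" if key in block_pairs else "similarity"
        pairs.append(duplication.analyze_pair(
            key[0], key[1], seqs[key[0]], seqs[key[1]],
            cds[key[0]], cds[key[1]], r=config.neutral_rate_r, source=source,
        ))
    return clusters, hits, blocks, pairs


def pair_table(pairs: list[duplication.ParalogPair]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_a": p.gene_a, "gene_b": p.gene_b, "Ka": p.Ka, "Ks": p.Ks,
        "Ka_Ks": p.ratio, "selection": p.selection_class, "T_Mya": p.T_mya,
        "source": p.source,
    } for p in pairs])


def run_all(
    out_dir: str | Path,
    seed: int = 0,
    params: simulate.GenomeSimParams | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Simulate a genome and run every stage, writing tables to ``out_dir``.

    Returns a summary dict of the headline numbers of each stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    params = params or simulate.GenomeSimParams(seed=seed)
    genome = simulate.generate_family_genome(params)
    genome.write(out / "synthetic")

    rng = np.random.default_rng(seed + 1)
    seed_rows = [params.domain_consensus] + [
        simulate.mutate_protein(params.domain_consensus, 0.1, rng) for _ in range(9)
    ]
    gene_models = {g.gene_id: g for g in genome.genes}
    ident = identify_family(genome.proteins, seed_rows, config,
                            gene_models=gene_models, seed=seed)
    accepted = ident.accepted
    counts = ident.counts()

    stats_rows = [{
        "protein_id": m.protein.protein_id, "status": m.status,
        "length": m.protein.length, "MW_Da": round(m.protein.molecular_weight, 2),
        "pI": round(m.protein.isoelectric_point, 2),
        "n_domain_hits": len(m.hits),
    } for m in ident.members]
    pd.DataFrame(stats_rows).to_csv(out / "family_members.tsv", sep="\t", index=False)

    truth = genome.truth
    references = {}
    for lineage in sorted(set(truth.lineages.values())):
        members = sorted(g for g, l in truth.lineages.items() if l == lineage)
        if len(members) > 1:
            references[members[0]] = lineage
    msa, tree, assignment = phylogeny(accepted, config, seed=seed,
                                      reference_labels=references or None)
    (out / "family_tree.nwk").write_text(tree.as_newick() + "\n")
    write_fasta(list(zip(msa.row_ids, msa.rows)), out / "family_alignment.fasta")

    family_models = [m.gene for m in accepted if m.gene is not None]
    intron_classes, intron_tally = structure.classify_intron_counts(family_models)
    pd.DataFrame([vars(c) for c in intron_classes]).to_csv(
        out / "gene_structure.tsv", sep="\t", index=False)

    motifs = structure.discover_motifs(
        [m.protein for m in accepted], max_motifs=config.max_motifs,
        width_range=config.motif_width_range, seed=seed,
    )
    occ = structure.map_motifs(motifs, [m.protein for m in accepted], seed=seed)
    pd.DataFrame(occ, columns=["protein_id", "motif_id", "start", "end",
                               "score", "evalue"]).to_csv(
        out / "motif_occurrences.tsv", sep="\t", index=False)

    clusters, hits, blocks, pairs = duplication_analysis(
        accepted, genome.genes, genome.cds, config, seed=seed)
    pair_table(pairs).to_csv(out / "paralog_pairs.tsv", sep="\t", index=False)
    cluster_rows = []
    gene_by_id = {g.gene_id: g for g in genome.genes}
    for k, c in enumerate(clusters):
        start = min(gene_by_id[m].start for m in c.members)
        end = max(gene_by_id[m].end for m in c.members)
        cluster_rows.append((c.chromosome, start, end, f"tandem_{k + 1}"))
    write_bed(cluster_rows, out / "tandem_clusters.bed")

    # expression stage on a matrix generated from the family layout
    fam_ids = [m.protein.protein_id for m in accepted]
    tissues = ["root", "stem", "leaf", "flower", "seed", "fiber"]
    stress_names = ["heat", "cold", "salt"]
    rng2 = np.random.default_rng(seed + 2)
    classes = {g: {s: ["up", "down", "unchanged"][int(rng2.integers(3))]
                   for s in stress_names} for g in fam_ids}
    tissue_patterns = {g: truth.lineages.get(g, "S1") for g in fam_ids}
    silent = set(fam_ids[max(len(fam_ids) - 2, 0):])
    matrix, expr_truth = simulate.generate_expression_matrix(
        fam_ids, tissues, stress_names, tissue_patterns, classes,
        silent_genes=silent, noise=0.05, seed=seed + 3,
    )
    calls = expression.call_expressed(matrix, config.fpkm_expressed)
    diff = expression.differential_table(
        matrix, [(f"{s}_treatment", f"{s}_control", s) for s in stress_names],
        config.fold_up, config.fold_down,
    )
    diff.to_csv(out / "stress_calls.tsv", sep="\t", index_label="gene_id")
    patterns = expression.cluster_expression_patterns(
        matrix, threshold=config.cluster_threshold)

    summary = {
        "n_candidates": counts["total"],
        "n_accepted": counts["accepted"],
        "n_rejected_no_domain": counts["rejected_no_domain"],
        "n_rejected_multi_domain": counts["rejected_multi_domain"],
        "pct_accepted": summarize_counts(counts["accepted"], counts["total"]),
        "n_tandem_clusters": len(clusters),
        "n_collinear_blocks": len(blocks),
        "n_paralog_pairs": len(pairs),
        "intron_tally": intron_tally,
        "n_motifs": len(motifs),
        "n_expressed_any": calls.n_expressed_any(),
        "n_expression_patterns": patterns.n_clusters,
        "n_subfamilies": len(set(assignment.values())) if assignment else 0,
    }
    pd.Series({k: str(v) for k, v in summary.items()}).to_csv(
        out / "summary.tsv", sep="\t", header=False)
    return summary
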