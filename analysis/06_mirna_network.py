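"""miRNA-target network inference with the negativity-constrained elastic net.

Screens miRNAs for age association, restricts candidate edges to the
sequence-prediction prior, fits a per-target constrained elastic net with
10-fold cross-validated penalty selection on both the mRNA and protein
layers, flags edges anti-correlated with age, and scores the mRNA network
against the planted repressive edges.
"""

from common import CONFIG, RESULTS, SEED, load_dataset, load_truth

from stromage.correlation import preprocess_mrna
from stromage.differential import call_age_associated, filter_quantifiable
from stromage.network import (
    NetworkParams,
    annotate_anticorrelated,
    edges_frame,
    infer_network,
    to_graphml,
)


def main() -> None:
    data = load_dataset()
    truth = load_truth()
    design = data["design"]
    quant = filter_quantifiable(data["protein"], CONFIG)
    mrna_gene = preprocess_mrna(data["mrna_probe"], CONFIG)

    mirna_diff = call_age_associated(data["mirna"], design, CONFIG,
                                     alpha_override=CONFIG.subset_alpha)
    candidates = sorted(r.feature_id for r in mirna_diff if r.age_associated)
    mirna_dirs = {r.feature_id: r.direction for r in mirna_diff if r.age_associated}
    print(f"{len(candidates)} candidate age-associated miRNAs "
          f"({len(truth.age_mirnas)} planted)")

    params = NetworkParams(seed=SEED)
    mrna_edges = infer_network(mrna_gene, data["mirna"], data["prior"],
                               candidates, params)
    prot_edges = infer_network(quant, data["mirna"], data["prior"],
                               candidates, params)
    prot_diff = call_age_associated(quant, design, CONFIG)
    mrna_diff_gene = call_age_associated(mrna_gene, design, CONFIG)
    annotate_anticorrelated(mrna_edges, mirna_dirs, mrna_diff_gene)
    annotate_anticorrelated(prot_edges, mirna_dirs, prot_diff)

    edges = mrna_edges + prot_edges
    edges_frame(edges).to_csv(RESULTS / "network_edges.tsv", sep="\t", index=False)
    to_graphml(edges, RESULTS / "network.graphml")

    emitted = {(e.mirna_id, e.gene_id) for e in mrna_edges}
    planted = truth.planted_repressive_edges
    tp = len(emitted & planted)
    print(f"mRNA network: {len(mrna_edges)} edges | precision "
          f"{tp / len(emitted):.3f} | recall {tp / len(planted):.3f}")
    print(f"protein network: {len(prot_edges)} edges, "
          f"{sum(e.anticorrelated for e in prot_edges)} anti-correlated with age")


if __name__ == "__main__":
    main()
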