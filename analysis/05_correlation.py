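"""Cross-layer preprocessing and per-donor mRNA-protein correlation.

Applies the transcript recipe (log2, lowest-quartile probe filter, drop
unmapped probes, average probes per gene, percent-of-max) and the protein
recipe (peptide-normalized, log2, percent-of-max), then correlates matched
genes within each donor.
"""

import json

from common import CONFIG, RESULTS, load_dataset

from stromage.correlation import (
    correlate_per_sample,
    coverage_overlap,
    match_pairs,
    preprocess_mrna,
    preprocess_protein,
)
from stromage.differential import filter_quantifiable


def main() -> None:
    data = load_dataset()
    quant = filter_quantifiable(data["protein"], CONFIG)
    mrna_gene = preprocess_mrna(data["mrna_probe"], CONFIG)
    prot_pct = preprocess_protein(quant, CONFIG)
    pairs = match_pairs(prot_pct, mrna_gene)
    per_donor, mean_r = correlate_per_sample(pairs)
    per_donor.to_frame().to_csv(RESULTS / "per_donor_correlation.tsv", sep="\t")
    cov = coverage_overlap(prot_pct, mrna_gene)
    with open(RESULTS / "coverage.json", "w") as fh:
        json.dump({"mean_r": mean_r, **cov}, fh, indent=2)

    print(f"{len(pairs.gene_id)} matched mRNA/protein gene pairs")
    print(f"transcript coverage of the quantified proteome: "
          f"{100 * cov['fraction_proteins_with_mrna']:.1f}%")
    print(f"per-donor Pearson r: min {per_donor.min():.3f}, "
          f"max {per_donor.max():.3f}, mean {mean_r:.3f}")


if __name__ == "__main__":
    main()
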