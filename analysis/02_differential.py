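"""Quantifiability filtering and the joint ANOVA + Pearson age screen.

Keeps proteins with >= 2 unique peptides identified in >= 14/15 samples,
then calls a protein age-associated when one-way ANOVA across the three
age bands and Pearson correlation against calendar age are both at
p <= 0.05 on log10 intensities.
"""

from common import CONFIG, RESULTS, load_dataset, load_truth

from stromage.differential import call_age_associated, filter_quantifiable, results_frame


def main() -> None:
    data = load_dataset()
    truth = load_truth()
    quant = filter_quantifiable(data["protein"], CONFIG)
    frame = results_frame(call_age_associated(quant, data["design"], CONFIG))
    out = RESULTS / "differential.tsv"
    frame.to_csv(out, sep="\t")

    called = frame[frame["age_associated"]]
    up = int((called["direction"] == "up").sum())
    planted = set(truth.planted_age_proteins) & set(frame.index)
    tp = len(planted & set(called.index))
    print(f"{quant.n_features()} of {data['protein'].n_features()} proteins quantifiable")
    print(f"{len(called)} age-associated calls ({up} up, {len(called) - up} down)")
    print(f"planted age features recovered: {tp}/{len(planted)}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
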