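"""TOST equivalence classification: which proteins stay constant with age?

A protein is "unchanged" when all three pairwise age-group contrasts are
equivalent within +/- 0.3 log10 units (TOST, p <= 0.05 in each pair).
Also reports the overlap between unchanged and age-associated calls.
"""

from common import CONFIG, RESULTS, load_dataset, load_truth

from stromage.differential import call_age_associated, filter_quantifiable
from stromage.stability import classify_unchanged, results_frame


def main() -> None:
    data = load_dataset()
    truth = load_truth()
    quant = filter_quantifiable(data["protein"], CONFIG)
    frame = results_frame(classify_unchanged(quant, data["design"], CONFIG))
    out = RESULTS / "stability.tsv"
    frame.to_csv(out, sep="\t")

    unchanged = set(frame[frame["unchanged"]].index)
    retained = set(frame.index)
    const = truth.planted_constant_proteins & retained
    age = set(truth.planted_age_proteins) & retained
    called = {r.feature_id for r in call_age_associated(quant, data["design"], CONFIG)
              if r.age_associated}
    pct = 100.0 * len(unchanged) / len(retained)
    print(f"{len(unchanged)} of {len(retained)} quantified proteins unchanged ({pct:.0f}%)")
    print(f"planted-constant sensitivity: {len(unchanged & const) / len(const):.3f}")
    print(f"planted age features marked unchanged: {len(unchanged & age)}/{len(age)}")
    print(f"overlap unchanged ∩ age-associated: {len(unchanged & called)}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
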