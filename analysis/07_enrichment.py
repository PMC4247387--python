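"""Gene-set enrichment of the age-associated and unchanged protein lists.

Two-sided hypergeometric test against the quantified proteome as
background, BH q-values reported, raw p <= 0.01 significance filter,
sets with <= 5 background members discarded, and kappa >= 0.5 grouping
of overlapping significant terms.
"""

from common import CONFIG, RESULTS, load_dataset

from stromage.differential import call_age_associated, filter_quantifiable
from stromage.enrichment import enrich_collection, results_frame
from stromage.stability import classify_unchanged
from stromage.stability import results_frame as stab_frame


def main() -> None:
    data = load_dataset()
    quant = filter_quantifiable(data["protein"], CONFIG)
    background = list(quant.meta["gene_symbol"])
    gene_of = quant.meta["gene_symbol"]

    called = [r.feature_id for r in call_age_associated(quant, data["design"], CONFIG)
              if r.age_associated]
    age_genes = sorted({gene_of[f] for f in called})
    stab = stab_frame(classify_unchanged(quant, data["design"], CONFIG))
    unchanged_genes = sorted({gene_of[f] for f in stab[stab["unchanged"]].index})

    for name, lst in (("age", age_genes), ("unchanged", unchanged_genes)):
        res = enrich_collection(lst, background, data["gene_sets"], CONFIG)
        frame = results_frame(res)
        frame.to_csv(RESULTS / f"enrichment_{name}.tsv", sep="\t")
        sig = frame[frame["significant"]]
        print(f"{name} list ({len(lst)} genes): {len(sig)} significant sets "
              f"of {len(frame)} tested, {sig['kappa_group'].nunique()} kappa groups")
        if not sig.empty:
            cols = ["k", "K", "p_two_sided", "q_bh", "direction", "kappa_group"]
            print(sig[cols].to_string())


if __name__ == "__main__":
    main()
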