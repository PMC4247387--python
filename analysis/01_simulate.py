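"""Generate the synthetic aging cohort that all later steps analyse.

Emulates the study design: 15 female donors in three age bands (20-30,
40-50, 60-70), a 1600-protein label-free proteome spanning ~5 decades with
47% planted-constant features and a sparse set of age-linear effects, a
probe-level transcriptome coupled at ~0.28 per-donor correlation, and 12
age-trending miRNAs repressing 15 planted targets each.
"""

from common import DATA, SEED

from stromage.simulate import SimulationParams, write_dataset


def main() -> None:
    params = SimulationParams(seed=SEED)
    paths = write_dataset(DATA, params)
    print(f"wrote synthetic cohort (seed {SEED}) to {DATA}")
    for key, path in paths.items():
        print(f"  {key:12s} {path}")
    print(
        f"design: {3 * params.n_per_group} donors | {params.n_proteins} proteins | "
        f"{params.n_mirnas} miRNAs ({params.n_age_mirnas} age-associated) | "
        f"{params.n_age_mirnas * params.n_prior_edges_per_mirna} planted repressive edges"
    )


if __name__ == "__main__":
    main()
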