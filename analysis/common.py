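"""Shared plumbing for the numbered analysis drivers: locations and loaders."""

from pathlib import Path

from stromage import io as sio
from stromage.config import AnalysisConfig
from stromage.data import Layer

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"

CONFIG = AnalysisConfig()
SEED = 42


def load_dataset():
    design = sio.read_design(DATA / "design.tsv")
    return {
        "design": design,
        "protein": sio.read_table(DATA / "protein.tsv", Layer.protein, design),
        "mrna_probe": sio.read_table(DATA / "mrna_probes.tsv", Layer.mrna_probe, design),
        "mirna": sio.read_table(DATA / "mirna.tsv", Layer.mirna, design),
        "prior": sio.read_target_prior(DATA / "target_prior.tsv"),
        "gene_sets": sio.read_gene_sets(DATA / "gene_sets.gmt"),
    }


def load_truth():
    import json

    from stromage.simulate import GroundTruth

    with open(DATA / "truth.json") as fh:
        return GroundTruth.from_json(json.load(fh))
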