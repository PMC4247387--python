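"""End-to-end orchestration: simulate/load -> filter -> differential ->
stability -> abundance classes -> cross-layer correlation -> miRNA network
-> enrichment, with a reproducibility manifest.

Configuration is a single TOML file with one table per stage; every value
has a default, so ``run_all`` works from an empty config plus
``simulate = true``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from pathlib import Path

import pandas as pd

from . import __version__
from . import abundance, correlation, differential, enrichment, io as sio
from . import network as net
from . import stability
from .config import AnalysisConfig
from .data import Layer, normalize_gene
from .errors import ConfigurationError
from .network import NetworkParams
from .simulate import GroundTruth, SimulationParams, generate_dataset

log = logging.getLogger("stromage")


def load_config(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(manifest: dict, name: str, **counts):
    manifest["stages"][name] = {k: int(v) for k, v in counts.items()}
    log.info("stage %-14s %s", name, counts)


def run_all(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run every stage in dependency order; returns the manifest dict."""
    t0 = time.time()
    if not isinstance(config, dict):
        config = load_config(config)
    run_cfg = config.get("run", {})
    outdir = Path(outdir or run_cfg.get("outdir", "stromage_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(run_cfg.get("seed", 0))
    acfg = AnalysisConfig.from_dict({**config.get("analysis", {}), "rng_seed": seed})
    simulate = bool(run_cfg.get("simulate", False))

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items()},
        "stages": {},
        "inputs": {},
    }

    # ---- inputs -----------------------------------------------------------
    if simulate:
        sim_kwargs = dict(config.get("simulation", {}))
        sim_kwargs.setdefault("seed", seed)
        params = SimulationParams(**sim_kwargs)
        design, protein, probes, mirna, prior, sets, truth = generate_dataset(params)
    else:
        inputs = config.get("inputs", {})
        for key in ("design", "protein", "mrna_probe", "mirna", "prior"):
            if key not in inputs:
                raise ConfigurationError(
                    f"inputs.{key} is required when run.simulate is false"
                )
        design = sio.read_design(inputs["design"])
        protein = sio.read_table(inputs["protein"], Layer.protein, design)
        probes = sio.read_table(inputs["mrna_probe"], Layer.mrna_probe, design)
        mirna = sio.read_table(inputs["mirna"], Layer.mirna, design)
        prior = sio.read_target_prior(inputs["prior"])
        sets = sio.read_gene_sets(inputs["gene_sets"]) if "gene_sets" in inputs else None
        truth = None
        for key, p in inputs.items():
            manifest["inputs"][key] = _sha256(Path(p))
    _stage(manifest, "inputs", donors=len(design), proteins=protein.n_features(),
           probes=probes.n_features(), mirnas=mirna.n_features(),
           prior_edges=len(prior))

    # ---- quantifiability + differential -----------------------------------
    quant = differential.filter_quantifiable(protein, acfg)
    diff = differential.call_age_associated(quant, design, acfg)
    diff_frame = differential.results_frame(diff)
    diff_frame.to_csv(outdir / "differential.tsv", sep="\t")
    called = diff_frame[diff_frame["age_associated"]]
    _stage(manifest, "differential", quantifiable=quant.n_features(),
           age_associated=len(called),
           up=int((called["direction"] == "up").sum()),
           down=int((called["direction"] == "down").sum()))

    # ---- stability ---------------------------------------------------------
    stab = stability.classify_unchanged(quant, design, acfg)
    stab_frame = stability.results_frame(stab)
    stab_frame.to_csv(outdir / "stability.tsv", sep="\t")
    unchanged_ids = set(stab_frame[stab_frame["unchanged"]].index)
    overlap = unchanged_ids & set(called.index)
    _stage(manifest, "stability", unchanged=len(unchanged_ids),
           unchanged_and_age_associated=len(overlap))

    # ---- abundance classes -------------------------------------------------
    bounds = abundance.compute_class_boundaries(quant, design, acfg)
    assigns = abundance.assign_classes(quant, design, bounds, acfg)
    abundance.assignments_frame(assigns).to_csv(
        outdir / "abundance_classes.tsv", sep="\t", index=False
    )
    shifts = abundance.detect_class_shifts(assigns)
    pd.DataFrame(shifts).to_csv(outdir / "class_shifts.tsv", sep="\t", index=False)
    _stage(manifest, "abundance", assignments=len(assigns), shifts=len(shifts))

    # ---- cross-layer correlation ------------------------------------------
    mrna_gene = correlation.preprocess_mrna(probes, acfg)
    prot_pct = correlation.preprocess_protein(quant, acfg)
    pairs = correlation.match_pairs(prot_pct, mrna_gene)
    per_donor, mean_r = correlation.correlate_per_sample(pairs)
    per_donor.to_frame().to_csv(outdir / "per_donor_correlation.tsv", sep="\t")
    cov = correlation.coverage_overlap(prot_pct, mrna_gene)
    manifest["correlation"] = {"mean_r": mean_r, **cov}
    _stage(manifest, "correlation", matched_genes=len(pairs.gene_id),
           donors_used=int(per_donor.notna().sum()))

    # ---- miRNA candidates + networks --------------------------------------
    mirna_diff = differential.call_age_associated(mirna, design, acfg,
                                                  alpha_override=acfg.subset_alpha)
    candidates = sorted(r.feature_id for r in mirna_diff if r.age_associated)
    mirna_dirs = {r.feature_id: r.direction for r in mirna_diff if r.age_associated}
    nparams = NetworkParams(
        mixing_alpha=acfg.enet_mixing_alpha,
        cv_folds=acfg.cv_folds,
        lambda_rule=acfg.lambda_rule,
        seed=seed,
        **config.get("network", {}),
    )
    mrna_edges = net.infer_network(mrna_gene, mirna, prior, candidates, nparams)
    prot_edges = net.infer_network(quant, mirna, prior, candidates, nparams)
    mrna_results = differential.call_age_associated(mrna_gene, design, acfg)
    net.annotate_anticorrelated(mrna_edges, mirna_dirs, mrna_results)
    net.annotate_anticorrelated(prot_edges, mirna_dirs, diff)
    all_edges = mrna_edges + prot_edges
    net.edges_frame(all_edges).to_csv(outdir / "network_edges.tsv", sep="\t",
                                      index=False)
    net.to_graphml(all_edges, outdir / "network.graphml")
    _stage(manifest, "network", candidate_mirnas=len(candidates),
           mrna_edges=len(mrna_edges), protein_edges=len(prot_edges),
           anticorrelated=sum(e.anticorrelated for e in all_edges))

    # ---- enrichment --------------------------------------------------------
    if sets is not None:
        background = [normalize_gene(g) for g in quant.meta["gene_symbol"]]
        gene_of = quant.meta["gene_symbol"]
        age_genes = sorted({normalize_gene(gene_of[f]) for f in called.index})
        unchanged_genes = sorted({normalize_gene(gene_of[f]) for f in unchanged_ids})
        enr_age = enrichment.enrich_collection(age_genes, background, sets, acfg)
        enr_unch = enrichment.enrich_collection(unchanged_genes, background, sets, acfg)
        enrichment.results_frame(enr_age).to_csv(outdir / "enrichment_age.tsv", sep="\t")
        enrichment.results_frame(enr_unch).to_csv(
            outdir / "enrichment_unchanged.tsv", sep="\t"
        )
        _stage(manifest, "enrichment",
               tested=len(enr_age),
               significant_age=sum(r.significant for r in enr_age),
               significant_unchanged=sum(r.significant for r in enr_unch))
    else:
        log.warning("no gene sets supplied; skipping enrichment")

    # ---- recovery vs planted truth ----------------------------------------
    if truth is not None:
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth.to_json(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["recovery"] = recovery_report(
            truth, quant, diff_frame, stab_frame, mrna_edges
        )
        with open(outdir / "recovery.json", "w") as fh:
            json.dump(manifest["recovery"], fh, indent=2, sort_keys=True)
            fh.write("\n")

    manifest["runtime_s"] = round(time.time() - t0, 2)
    digest_src = json.dumps(
        {k: v for k, v in manifest.items() if k != "runtime_s"},
        sort_keys=True, default=str,
    )
    manifest["manifest_digest"] = hashlib.sha256(digest_src.encode()).hexdigest()
    sio.write_manifest(manifest, outdir / "manifest.json")
    return manifest


def recovery_report(
    truth: GroundTruth,
    quant,
    diff_frame: pd.DataFrame,
    stab_frame: pd.DataFrame,
    mrna_edges,
) -> dict:
    """Confusion counts of planted truth vs pipeline calls.

    Planted sets are intersected with the quantifiable features first:
    features removed by the peptide/presence filter cannot be called
    either way.
    """
    retained = set(map(str, quant.feature_ids))
    called = set(diff_frame[diff_frame["age_associated"]].index)
    unchanged = set(stab_frame[stab_frame["unchanged"]].index)

    age_truth = set(truth.planted_age_proteins) & retained
    const_truth = truth.planted_constant_proteins & retained

    # direction agreement on correctly called planted age features
    agree = total = 0
    for fid, slope in truth.planted_age_proteins.items():
        if fid in called:
            total += 1
            want = "up" if slope > 0 else "down"
            if diff_frame.loc[fid, "direction"] == want:
                agree += 1

    emitted = {(e.mirna_id, e.gene_id) for e in mrna_edges}
    planted = set(truth.planted_repressive_edges)
    tp = len(emitted & planted)
    report = {
        "age": {
            "planted_retained": len(age_truth),
            "called": len(called),
            "true_positive": len(called & age_truth),
            "false_negative": len(age_truth - called),
            "direction_agreement": (agree / total) if total else None,
        },
        "unchanged": {
            "planted_constant_retained": len(const_truth),
            "unchanged_called": len(unchanged),
            "constant_sensitivity": (
                len(unchanged & const_truth) / len(const_truth) if const_truth else None
            ),
            "age_marked_unchanged_rate": (
                len(unchanged & age_truth) / len(age_truth) if age_truth else None
            ),
        },
        "network": {
            "planted_edges": len(planted),
            "emitted_edges": len(emitted),
            "true_positive": tp,
            "precision": (tp / len(emitted)) if emitted else None,
            "recall": (tp / len(planted)) if planted else None,
        },
    }
    return report
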