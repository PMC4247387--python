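"""Readers and writers for the delimited-text exchange formats.

Conventions: delimiter is auto-detected between tab and comma on read and
always tab on write; missing intensities are empty cells, never zero; gene
identifiers are case-folded to upper case on ingest so that proteins, mRNA
probes, target priors and gene sets share one join namespace.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    CohortDesign,
    FeatureTable,
    GeneSetCollection,
    Layer,
    TargetPrior,
    normalize_gene,
)
from .errors import ParseError, SchemaError, ValidationError

#: metadata columns expected per layer (beyond the feature-id column)
LAYER_META_COLUMNS = {
    Layer.protein: ["unique_peptide_count", "n_samples_identified", "gene_symbol"],
    Layer.mrna_probe: ["gene_id"],
    Layer.mrna_gene: [],
    Layer.mirna: [],
}
FEATURE_COLUMN = "feature_id"


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_design(path: str | Path, age_bands=None) -> CohortDesign:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_sep(path))
    return CohortDesign.from_frame(frame, age_bands=age_bands)


def write_design(design: CohortDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, layer: Layer | str, design: CohortDesign) -> FeatureTable:
    """Read a feature x sample intensity matrix and validate it against the design."""
    path = Path(path)
    layer = Layer(layer)
    frame = pd.read_csv(path, sep=_sniff_sep(path), dtype={FEATURE_COLUMN: str})
    if FEATURE_COLUMN not in frame.columns:
        raise SchemaError(f"{path}: missing '{FEATURE_COLUMN}' column")
    meta_cols = [c for c in LAYER_META_COLUMNS[layer] if c != FEATURE_COLUMN]
    missing_meta = [c for c in meta_cols if c not in frame.columns]
    if missing_meta:
        raise SchemaError(f"{path}: layer {layer.value} requires columns {missing_meta}")
    sample_cols = [
        c for c in frame.columns if c != FEATURE_COLUMN and c not in meta_cols
    ]
    if set(sample_cols) != set(design.donor_id):
        raise SchemaError(
            f"{path}: sample columns {sorted(sample_cols)} do not match "
            f"design donors {sorted(design.donor_id)}"
        )
    if frame[FEATURE_COLUMN].duplicated().any():
        dupes = frame.loc[frame[FEATURE_COLUMN].duplicated(), FEATURE_COLUMN]
        raise ValidationError(f"{path}: duplicate feature ids {list(dupes)[:5]}")
    values = frame.set_index(FEATURE_COLUMN)[list(design.donor_id)].astype(float)
    if (values.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative intensities present")
    meta = frame.set_index(FEATURE_COLUMN)[meta_cols].copy()
    if "gene_symbol" in meta.columns:
        meta["gene_symbol"] = meta["gene_symbol"].map(normalize_gene)
    if "gene_id" in meta.columns:
        meta["gene_id"] = meta["gene_id"].map(
            lambda g: normalize_gene(g) if pd.notna(g) and str(g).strip() else np.nan
        )
    table = FeatureTable(layer=layer, values=values, meta=meta)
    table.check_design(design)
    return table


def write_table(table: FeatureTable, path: str | Path) -> None:
    meta_cols = [c for c in table.meta.columns]
    out = pd.concat([table.meta[meta_cols], table.values], axis=1)
    out.index.name = FEATURE_COLUMN
    out.to_csv(path, sep="\t")


def read_target_prior(path: str | Path) -> TargetPrior:
    """Two-column (mirna_id, gene_id) delimited text; optional header; dedup."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            sep = "\t" if "\t" in line else ","
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ParseError(f"expected two columns, got {line!r}", line=lineno)
            if lineno == 1 and parts[0].lower() in ("mirna", "mirna_id"):
                continue
            pairs.append((parts[0], parts[1]))
    return TargetPrior.from_pairs(pairs)


def write_target_prior(prior: TargetPrior, path: str | Path) -> None:
    prior.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """GMT dialect: set_id <tab> description <tab> member [<tab> member ...]."""
    items = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"GMT line needs >= 3 tab-separated fields, got {len(parts)}",
                    line=lineno,
                )
            sid, name, members = parts[0], parts[1], [m for m in parts[2:] if m.strip()]
            if not members:
                raise ParseError("gene set has no members", line=lineno)
            items.append((sid, name, members))
    return GeneSetCollection.from_lists(items)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, members in collection.sets.items():
            name = collection.names.get(sid, sid)
            fh.write("\t".join([sid, name, *sorted(members)]) + "\n")


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
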