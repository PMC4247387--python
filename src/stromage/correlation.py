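"""Cross-layer preprocessing and per-donor mRNA-protein correlation.

The transcript recipe: log2-scale all probe intensities, discard the
lowest 25% of probes by across-sample median, discard probes without a
gene id, average remaining probes per gene, and rescale so the global
maximum equals 100%. The protein recipe: divide each per-sample summed
intensity by the number of quantified peptides, log2-scale, rescale the
global maximum to 100%. Matched gene pairs are then correlated per donor
(Pearson across genes) and averaged unweighted across donors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .data import FeatureTable, Layer
from .errors import StromageError, ValidationError


class EmptyResultError(StromageError):
    pass


def percent_of_max(frame: pd.DataFrame) -> pd.DataFrame:
    """Rescale so the global maximum equals 100 (idempotent)."""
    m = np.nanmax(frame.to_numpy(dtype=float))
    if not np.isfinite(m) or m == 0:
        raise ValidationError("cannot rescale: no positive finite values")
    return frame * (100.0 / m)


def preprocess_mrna(probes: FeatureTable, config: AnalysisConfig) -> FeatureTable:
    """Probe-level intensities -> gene-level percent-of-max log2 matrix.

    Order of operations is fixed (and pinned by a regression test):
    log2 -> low-median probe filter -> unmapped-probe filter -> per-gene
    mean -> percent-of-max.
    """
    if "gene_id" not in probes.meta.columns:
        raise ValidationError("mRNA probe table requires 'gene_id' metadata")
    log_vals = probes.log2()
    medians = log_vals.median(axis=1, skipna=True)
    # rank-based: exactly floor(q * n) lowest-median probes are discarded
    n_drop = int(np.floor(config.mrna_low_median_quantile * len(medians)))
    ranks = medians.rank(method="first")
    keep = ranks > n_drop
    mapped = probes.meta["gene_id"].notna()
    kept = log_vals.loc[keep & mapped]
    gene_ids = probes.meta.loc[keep & mapped, "gene_id"]
    if kept.empty:
        raise EmptyResultError("no probes left after filtering")
    gene_vals = kept.groupby(gene_ids.to_numpy()).mean()
    gene_vals = percent_of_max(gene_vals)
    gene_vals.index.name = None
    return FeatureTable(
        layer=Layer.mrna_gene,
        values=gene_vals,
        meta=pd.DataFrame(index=gene_vals.index),
    )


def preprocess_protein(proteins: FeatureTable, config: AnalysisConfig) -> FeatureTable:
    """Peptide-normalized, log2, percent-of-max protein matrix (gene-indexed)."""
    if "unique_peptide_count" not in proteins.meta.columns:
        raise ValidationError("protein table requires 'unique_peptide_count' metadata")
    counts = proteins.meta["unique_peptide_count"].to_numpy(dtype=float)
    if (counts <= 0).any():
        raise ValidationError("zero or negative peptide counts")
    per_pep = proteins.values.div(counts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        arr = per_pep.to_numpy(dtype=float)
        log_vals = pd.DataFrame(
            np.where(arr > 0, np.log2(np.where(arr > 0, arr, 1.0)), np.nan),
            index=per_pep.index,
            columns=per_pep.columns,
        )
    log_vals = percent_of_max(log_vals)
    if "gene_symbol" in proteins.meta.columns:
        gene = proteins.meta["gene_symbol"]
        # one value per gene: average if several accessions share a symbol
        log_vals = log_vals.groupby(gene.to_numpy()).mean()
        log_vals.index.name = None
    return FeatureTable(
        layer=Layer.protein,
        values=log_vals,
        meta=pd.DataFrame(index=log_vals.index),
    )


@dataclass
class MatchedPairMatrix:
    """Genes present in both processed layers, both on percent-of-max scale."""

    gene_id: pd.Index
    mrna: pd.DataFrame
    protein: pd.DataFrame


def match_pairs(protein: FeatureTable, mrna: FeatureTable) -> MatchedPairMatrix:
    shared = protein.values.index.intersection(mrna.values.index)
    return MatchedPairMatrix(
        gene_id=shared,
        mrna=mrna.values.loc[shared],
        protein=protein.values.loc[shared],
    )


def correlate_per_sample(pairs: MatchedPairMatrix) -> tuple[pd.Series, float]:
    """Pearson r per donor over matched genes; unweighted mean across donors.

    Donors with fewer than 3 complete pairs or zero variance in either
    layer are NaN and excluded from the mean.
    """
    rs = {}
    for donor in pairs.mrna.columns:
        x = pairs.mrna[donor].to_numpy(dtype=float)
        y = pairs.protein[donor].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            rs[donor] = float("nan")
            continue
        rs[donor] = float(stats.pearsonr(x[ok], y[ok])[0])
    series = pd.Series(rs, name="pearson_r")
    return series, float(series.dropna().mean())


def coverage_overlap(protein: FeatureTable, mrna: FeatureTable) -> dict:
    """Set arithmetic between the two gene id sets."""
    p = set(map(str, protein.values.index))
    m = set(map(str, mrna.values.index))
    shared = p & m
    return {
        "shared": len(shared),
        "protein_only": len(p - m),
        "mrna_only": len(m - p),
        "fraction_proteins_with_mrna": (len(shared) / len(p)) if p else float("nan"),
    }
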