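"""Synthetic multi-omics cohort generator with planted ground truth.

Emulates the design of a small in-situ aging cohort: three age bands
(young 20-30, middle 40-50, old 60-70) with five donors each, a label-free
proteome spanning ~5 orders of magnitude of intensity with a large constant
fraction and a sparse set of age-linear effects, a probe-level microarray
transcriptome coupled to the proteome at a modest per-donor correlation,
and a miRNAome in which a dozen age-trending miRNAs repress planted target
genes. Every planted effect is recorded in a :class:`GroundTruth` object so
downstream stages can be scored against it.

All randomness flows from a single seed through named
``numpy.random.SeedSequence`` child streams (one per data layer), so any
layer is reproducible independently of the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    CohortDesign,
    DEFAULT_AGE_BANDS,
    FeatureTable,
    GeneSetCollection,
    Layer,
    TargetPrior,
)
from .errors import ConfigurationError

#: order of the named child seed streams derived from ``params.seed``
_STREAMS = ("cohort", "proteome", "transcriptome", "mirnome", "prior", "gene_sets")


@dataclass
class SimulationParams:
    """Knobs of the synthetic cohort; defaults are the emulated study design."""

    n_per_group: int = 5
    age_bands: dict = field(default_factory=lambda: dict(DEFAULT_AGE_BANDS))
    n_proteins: int = 1600
    frac_constant: float = 0.47
    frac_age_assoc: float = 43 / 1607
    dynamic_range_decades: float = 5.0
    base_log10_min: float = 4.0
    noise_sd_log10: float = 0.1
    # residual (neither constant nor age-planted) features get inflated,
    # heterogeneous noise instead of trends: sd ~ U(lo, hi) * noise_sd_log10
    other_noise_factor_min: float = 1.5
    other_noise_factor_max: float = 3.0
    # planted age slopes: |slope| ~ U(slope_min, slope_max) log10/decade,
    # i.e. young->old fold changes of about 2.1-3.8
    age_slope_log10_per_decade_min: float = 0.08
    age_slope_log10_per_decade_max: float = 0.145
    n_block_features: int = 5  # coordinated class-III -> class-IV shift in old
    block_shift_log10: float = -0.9
    max_probes_per_gene: int = 3
    probe_offset_sd_log2: float = 0.6
    probe_noise_sd_log2: float = 0.2
    frac_probes_unmapped: float = 0.05
    mrna_protein_rho: float = 0.28
    mrna_spread_log2: float = 1.5
    mrna_noise_sd_log2: float = 0.33
    frac_genes_without_mrna: float = 0.02
    # array background: probes for transcripts outside the proteome, sitting
    # low so the lowest-quartile probe filter mostly removes background
    n_extra_mrna_genes: int = 1200
    background_mrna_mean_log2: float = 5.0
    background_mrna_sd_log2: float = 1.0
    n_mirnas: int = 120
    n_age_mirnas: int = 12
    mirna_slope_log2_per_decade: float = 0.15
    mirna_noise_sd_log2: float = 0.25
    n_prior_edges_per_mirna: int = 15
    n_decoy_edges_per_mirna: int = 10
    repression_effect: float = -0.4  # log2 units per SD of miRNA expression
    # translation buffering: fraction of the mRNA-level repression that
    # propagates to the protein layer
    protein_repression_transfer: float = 0.5
    peptide_geometric_p: float = 0.25
    n_random_gene_sets: int = 30
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.frac_constant <= 1 or not 0 <= self.frac_age_assoc <= 1:
            raise ConfigurationError("fractions must lie in [0,1]")
        if self.frac_constant + self.frac_age_assoc > 1:
            raise ConfigurationError("frac_constant + frac_age_assoc must be <= 1")
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.n_age_mirnas > self.n_mirnas:
            raise ConfigurationError("n_age_mirnas cannot exceed n_mirnas")


@dataclass
class GroundTruth:
    """Planted effects, keyed by feature / gene / edge identity."""

    planted_age_proteins: dict  # feature_id -> signed slope (log10/decade)
    planted_constant_proteins: set
    planted_block_proteins: list
    planted_repressive_edges: set  # (mirna_id, gene_id)
    decoy_prior_edges: set
    age_mirnas: dict  # mirna_id -> "up" | "down"
    base_log10: dict  # protein feature_id -> base abundance

    def to_json(self) -> dict:
        return {
            "planted_age_proteins": dict(sorted(self.planted_age_proteins.items())),
            "planted_constant_proteins": sorted(self.planted_constant_proteins),
            "planted_block_proteins": list(self.planted_block_proteins),
            "planted_repressive_edges": sorted(map(list, self.planted_repressive_edges)),
            "decoy_prior_edges": sorted(map(list, self.decoy_prior_edges)),
            "age_mirnas": dict(sorted(self.age_mirnas.items())),
            "base_log10": dict(sorted(self.base_log10.items())),
        }

    @classmethod
    def from_json(cls, d: dict) -> "GroundTruth":
        return cls(
            planted_age_proteins=dict(d["planted_age_proteins"]),
            planted_constant_proteins=set(d["planted_constant_proteins"]),
            planted_block_proteins=list(d["planted_block_proteins"]),
            planted_repressive_edges={tuple(e) for e in d["planted_repressive_edges"]},
            decoy_prior_edges={tuple(e) for e in d["decoy_prior_edges"]},
            age_mirnas=dict(d["age_mirnas"]),
            base_log10=dict(d["base_log10"]),
        )


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def generate_cohort(params: SimulationParams) -> CohortDesign:
    """Draw donor ages uniformly within each configured age band."""
    rng = _streams(params.seed)["cohort"]
    donor_ids, ages, groups = [], [], []
    prefix = {"young": "Y", "middle": "M", "old": "O"}
    for group in ("young", "middle", "old"):
        lo, hi = params.age_bands[group]
        for i in range(params.n_per_group):
            donor_ids.append(f"{prefix.get(group, group[:1].upper())}{i + 1}")
            ages.append(int(rng.integers(lo, hi + 1)))
            groups.append(group)
    return CohortDesign(
        donor_id=tuple(donor_ids),
        age_years=tuple(ages),
        age_group=tuple(groups),
        sex=tuple("F" for _ in donor_ids),
        age_bands=dict(params.age_bands),
    )


def _partition_features(params: SimulationParams, rng: np.random.Generator):
    """Assign every protein feature to exactly one planted category."""
    n = params.n_proteins
    n_age = int(round(params.frac_age_assoc * n))
    n_const = int(round(params.frac_constant * n))
    n_block = params.n_block_features if n >= 200 else 0
    # prior-core target genes are reserved whether or not repression is
    # active: the sequence prior exists independently of true effects
    n_targets = params.n_age_mirnas * params.n_prior_edges_per_mirna
    if n_age + n_const + n_block + n_targets > n:
        raise ConfigurationError(
            "planted categories exceed n_proteins; increase n_proteins or "
            "decrease planted fractions"
        )
    order = rng.permutation(n)
    idx = iter(order.tolist())
    age = [next(idx) for _ in range(n_age)]
    block = [next(idx) for _ in range(n_block)]
    targets = [next(idx) for _ in range(n_targets)]
    const = [next(idx) for _ in range(n_const)]
    other = list(idx)
    return age, block, targets, const, other


def _mrna_filter_loss(params: SimulationParams) -> float:
    """Expected fraction of matched genes removed by the low-median probe filter.

    A gene is lost when every one of its probes has an across-sample median
    below the pooled lowest-quartile cutoff. Probe medians are modelled as
    gene baseline + probe offset; the cutoff is solved on the mixture of
    matched and background probe populations. Deterministic (numeric
    integration, no sampling).
    """
    from scipy import optimize, stats as sps

    n_matched = params.n_proteins * (1.0 - params.frac_genes_without_mrna)
    n_bg = params.n_extra_mrna_genes
    if n_matched <= 0:
        return 0.0
    off = params.probe_offset_sd_log2
    sd_m = float(np.hypot(params.mrna_spread_log2, off))
    sd_b = float(np.hypot(params.background_mrna_sd_log2, off))
    mu_m, mu_b = 8.0, params.background_mrna_mean_log2
    w_m = n_matched / (n_matched + n_bg)
    q = 0.25  # the study's lowest-quartile probe rule

    def cdf_mix(c):
        return w_m * sps.norm.cdf(c, mu_m, sd_m) + (1 - w_m) * sps.norm.cdf(c, mu_b, sd_b)

    lo = min(mu_m, mu_b) - 8 * max(sd_m, sd_b)
    hi = max(mu_m, mu_b) + 8 * max(sd_m, sd_b)
    c = optimize.brentq(lambda x: cdf_mix(x) - q, lo, hi)
    b = np.linspace(mu_m - 6 * params.mrna_spread_log2, mu_m + 6 * params.mrna_spread_log2, 801)
    dens = sps.norm.pdf(b, mu_m, params.mrna_spread_log2)
    if off > 0:
        p_low = sps.norm.cdf((c - b) / off)
    else:
        p_low = (b < c).astype(float)
    ks = np.arange(1, params.max_probes_per_gene + 1)
    p_lost = np.mean([p_low**k for k in ks], axis=0)
    return float(np.trapezoid(p_lost * dens, b) / np.trapezoid(dens, b))


def _latent_coupling(params: SimulationParams, base, pep, p_detect, noise_sd) -> float:
    """Latent baseline correlation needed to realize the target observed one.

    The observed per-donor matched-pair correlation is attenuated relative
    to the latent baseline coupling by (i) gene-level nuisance variance on
    both axes (peptide-count division on the protein side; probe offsets,
    probe noise and gene noise on the mRNA side) and (ii) the
    abundance-dependent quantifiability selection, which narrows the
    protein axis. Noise attenuation is linear in r; selection follows the
    classical range-restriction formula r' = r s / sqrt(1 - r^2 (1 - s^2))
    with s the retained/full sd ratio. This inverts the composition; in
    the noise-free, selection-neutral limit the factor is exactly 1.
    """
    from scipy import optimize, stats as sps

    target = params.mrna_protein_rho
    if target == 0:
        return 0.0
    if abs(target) >= 1.0:
        # perfect coupling: exact in the noise-free limit; with noise the
        # observed correlation is simply as high as the layers allow
        return float(np.sign(target))
    l2 = np.log2(10.0)
    sig_p = l2 * np.std(base)
    var_p = l2**2 * float(np.mean(np.square(noise_sd))) + np.var(np.log2(pep))
    att_p = sig_p / np.hypot(sig_p, np.sqrt(var_p)) if sig_p > 0 else 1.0
    sig_m = params.mrna_spread_log2
    inv_k = np.mean([1.0 / k for k in range(1, params.max_probes_per_gene + 1)])
    var_m = (
        params.probe_offset_sd_log2**2 * inv_k
        + params.probe_noise_sd_log2**2 * inv_k
        + params.mrna_noise_sd_log2**2
    )
    att_m = sig_m / np.hypot(sig_m, np.sqrt(var_m)) if sig_m > 0 else 1.0
    # selection: probability of passing the presence filter given abundance
    n_samp = 3 * params.n_per_group
    min_present = int(np.ceil(14 / 15 * n_samp))  # the study's presence rule
    w = sps.binom.sf(min_present - 1, n_samp, p_detect)
    sw = w.sum()
    if sw > 0 and np.std(base) > 0:
        mean_w = (w * base).sum() / sw
        sd_w = np.sqrt((w * (base - mean_w) ** 2).sum() / sw)
        s_p = min(1.0, sd_w / np.std(base))
    else:
        s_p = 1.0
    # mRNA-side selection: low-median probe filtering removes the lower
    # tail of the matched-gene baseline distribution
    lost = _mrna_filter_loss(params)
    if 0.0 < lost < 1.0:
        a = sps.norm.ppf(lost)
        lam = sps.norm.pdf(a) / (1.0 - lost)
        s_m = float(np.sqrt(max(1e-9, 1.0 + a * lam - lam**2)))
    else:
        s_m = 1.0

    def restrict(r, s):
        return r * s / np.sqrt(max(1e-12, 1.0 - r**2 * (1.0 - s**2)))

    def observed(r):
        return restrict(restrict(r, s_p), s_m) * att_p * att_m

    sign = 1.0 if target > 0 else -1.0
    t = abs(target)
    if observed(0.999999) <= t:
        return sign * 0.999999
    return sign * float(optimize.brentq(lambda r: observed(r) - t, 0.0, 0.999999))


def generate_dataset(params: SimulationParams):
    """Generate all layers and the ground truth.

    Returns ``(design, protein, mrna_probe, mirna, prior, gene_sets, truth)``.
    """
    streams = _streams(params.seed)
    design = generate_cohort(params)
    ages = np.array(design.age_years, dtype=float)
    n_samples = len(design)
    age_c = (ages - ages.mean()) / 10.0  # decades, centered

    # ---------------- proteome ----------------
    rng = streams["proteome"]
    n = params.n_proteins
    fids = [f"P{i:04d}" for i in range(1, n + 1)]
    genes = [f"G{i:04d}" for i in range(1, n + 1)]
    age_i, block_i, target_i, const_i, other_i = _partition_features(params, rng)

    base = rng.uniform(
        params.base_log10_min,
        params.base_log10_min + params.dynamic_range_decades,
        size=n,
    )
    slopes = np.zeros(n)  # log10 per decade
    mags = rng.uniform(
        params.age_slope_log10_per_decade_min,
        params.age_slope_log10_per_decade_max,
        size=len(age_i),
    )
    signs = rng.choice([-1.0, 1.0], size=len(age_i))
    slopes[age_i] = mags * signs
    # residual pool: no systematic trend, but heterogeneous (inflated) noise,
    # so it is neither reliably "unchanged" nor age-associated
    noise_sd = np.full(n, params.noise_sd_log10)
    noise_sd[other_i] = params.noise_sd_log10 * rng.uniform(
        params.other_noise_factor_min, params.other_noise_factor_max, size=len(other_i)
    )

    # the planted block sits safely inside class III and drops into class IV
    # for old donors (boundaries are equal-width over the full dynamic range)
    lo = params.base_log10_min
    width = params.dynamic_range_decades / 4.0
    base[block_i] = lo + 1.5 * width + rng.uniform(-0.1, 0.1, size=len(block_i))

    log_p = (
        base[:, None]
        + slopes[:, None] * age_c[None, :]
        + noise_sd[:, None] * rng.normal(0.0, 1.0, size=(n, n_samples))
    )
    old_mask = np.array([g == "old" for g in design.age_group])
    log_p[np.ix_(block_i, old_mask)] += params.block_shift_log10

    # ---------------- miRNAome ----------------
    rng_m = streams["mirnome"]
    mirna_ids = [f"miR-{i:03d}" for i in range(1, params.n_mirnas + 1)]
    age_mirna_idx = sorted(
        rng_m.choice(params.n_mirnas, size=params.n_age_mirnas, replace=False).tolist()
    )
    mirna_base = rng_m.uniform(4.0, 10.0, size=params.n_mirnas)
    mirna_slopes = np.zeros(params.n_mirnas)
    mdirs = rng_m.choice([-1.0, 1.0], size=params.n_age_mirnas)
    mirna_slopes[age_mirna_idx] = params.mirna_slope_log2_per_decade * mdirs
    log_mir = (
        mirna_base[:, None]
        + mirna_slopes[:, None] * age_c[None, :]
        + rng_m.normal(0.0, params.mirna_noise_sd_log2, size=(params.n_mirnas, n_samples))
    )
    age_mirnas = {
        mirna_ids[i]: ("up" if mirna_slopes[i] > 0 else "down") for i in age_mirna_idx
    }

    # ---------------- target prior + repression ----------------
    rng_p = streams["prior"]
    planted_edges: set[tuple[str, str]] = set()
    decoy_edges: set[tuple[str, str]] = set()
    target_pool = list(target_i)
    rng_p.shuffle(target_pool)
    pool_iter = iter(target_pool)
    z_mir = (log_mir - log_mir.mean(axis=1, keepdims=True)) / np.where(
        log_mir.std(axis=1, keepdims=True) > 0, log_mir.std(axis=1, keepdims=True), 1.0
    )
    repress_log2 = np.zeros((n, n_samples))  # per-gene miRNA-driven component
    for mi in age_mirna_idx:
        for _ in range(params.n_prior_edges_per_mirna):
            gi = next(pool_iter)
            if params.repression_effect != 0:
                planted_edges.add((mirna_ids[mi], genes[gi]))
                repress_log2[gi] += params.repression_effect * z_mir[mi]
            else:
                decoy_edges.add((mirna_ids[mi], genes[gi]))
        # decoys: prior-only candidates drawn from planted-constant genes
        if params.n_decoy_edges_per_mirna > 0 and len(const_i) > 0:
            dec = rng_p.choice(
                const_i,
                size=min(params.n_decoy_edges_per_mirna, len(const_i)),
                replace=False,
            )
            for gi in dec:
                decoy_edges.add((mirna_ids[mi], genes[gi]))
    prior = TargetPrior.from_pairs(planted_edges | decoy_edges)

    # repression reaches the protein layer attenuated by translation
    # buffering, on the log10 scale
    log_p += repress_log2 * np.log10(2.0) * params.protein_repression_transfer

    # ---------------- peptide counts / presence ----------------
    pep = rng.geometric(params.peptide_geometric_p, size=n)
    # the planted class-shift block emulates proteins that *were* quantified
    pep[block_i] = np.maximum(pep[block_i], 2)
    q20 = np.quantile(base, 0.2)
    bmin = base.min()
    p_detect = np.full(n, 0.995)
    lowband = base < q20
    if q20 > bmin:
        p_detect[lowband] = 0.6 + 0.395 * (base[lowband] - bmin) / (q20 - bmin)
    present = rng.random((n, n_samples)) < p_detect[:, None]
    # never blank out an entire feature
    none_row = ~present.any(axis=1)
    present[none_row, 0] = True

    prot_vals = np.power(10.0, log_p)
    prot_vals[~present] = np.nan
    protein = FeatureTable(
        layer=Layer.protein,
        values=pd.DataFrame(prot_vals, index=fids, columns=list(design.donor_id)),
        meta=pd.DataFrame(
            {
                "unique_peptide_count": pep,
                "n_samples_identified": present.sum(axis=1),
                "gene_symbol": genes,
            },
            index=fids,
        ),
    )

    # ---------------- transcriptome ----------------
    rng_t = streams["transcriptome"]
    # per-gene mRNA baseline coupled to the protein baseline; the latent
    # coupling is inflated so the *observed* per-donor matched-pair
    # correlation (after peptide normalization, probe averaging and the
    # abundance-dependent filters) lands at the requested value
    z_base = (base - base.mean()) / base.std()
    eps = rng_t.normal(0.0, 1.0, size=n)
    rho = _latent_coupling(params, base, pep, p_detect, noise_sd)
    mrna_base = 8.0 + params.mrna_spread_log2 * (
        rho * z_base + np.sqrt(max(0.0, 1 - rho**2)) * eps
    )
    log_m = (
        mrna_base[:, None]
        + repress_log2
        + rng_t.normal(0.0, params.mrna_noise_sd_log2, size=(n, n_samples))
    )

    # genes with no transcript coverage (the ~2% protein-only fraction);
    # planted repressive targets always keep coverage
    n_uncov = int(round(params.frac_genes_without_mrna * n))
    coverable = sorted(set(range(n)) - set(target_i))
    uncovered = set(
        rng_t.choice(coverable, size=min(n_uncov, len(coverable)), replace=False).tolist()
    )

    probe_rows = []
    probe_meta_gene = []
    probe_vals = []
    pid = 0
    extra = params.n_extra_mrna_genes
    extra_base = rng_t.normal(
        params.background_mrna_mean_log2, params.background_mrna_sd_log2, size=extra
    )
    gene_iter = [(genes[i], log_m[i]) for i in range(n) if i not in uncovered]
    gene_iter += [
        (f"X{j:04d}", extra_base[j - 1] + rng_t.normal(0, params.mrna_noise_sd_log2, n_samples))
        for j in range(1, extra + 1)
    ]
    is_target = {genes[i] for i in target_i}
    for gname, glog in gene_iter:
        n_probes = int(rng_t.integers(1, params.max_probes_per_gene + 1))
        for _ in range(n_probes):
            pid += 1
            offset = rng_t.normal(0.0, params.probe_offset_sd_log2)
            if gname in is_target:
                offset = abs(offset)  # planted targets stay above the median filter
            noise = rng_t.normal(0.0, params.probe_noise_sd_log2, size=n_samples)
            probe_rows.append(f"PR{pid:05d}")
            mapped = rng_t.random() >= params.frac_probes_unmapped
            probe_meta_gene.append(gname if mapped else np.nan)
            probe_vals.append(np.power(2.0, glog + offset + noise))
    mrna_probe = FeatureTable(
        layer=Layer.mrna_probe,
        values=pd.DataFrame(
            np.asarray(probe_vals), index=probe_rows, columns=list(design.donor_id)
        ),
        meta=pd.DataFrame({"gene_id": probe_meta_gene}, index=probe_rows),
    )

    mirna = FeatureTable(
        layer=Layer.mirna,
        values=pd.DataFrame(
            np.power(2.0, log_mir), index=mirna_ids, columns=list(design.donor_id)
        ),
        meta=pd.DataFrame(index=mirna_ids),
    )

    # ---------------- gene sets ----------------
    rng_g = streams["gene_sets"]
    items: list[tuple[str, str, list[str]]] = []
    if block_i:
        block_members = [genes[i] for i in block_i] + [
            genes[i] for i in const_i[: max(0, 8 - len(block_i))]
        ]
        items.append(("SET_BLOCK", "planted coordinated abundance-shift block", block_members))
    if age_i:
        age_members = [genes[i] for i in age_i]
        items.append(("SET_AGE", "planted age-associated features", age_members))
    # a deliberately tiny set that the <=5-member rule must discard
    items.append(("SET_TINY", "five-member set", [genes[i] for i in const_i[8:13]]))
    universe = np.arange(n)
    for k in range(1, params.n_random_gene_sets + 1):
        size = int(rng_g.integers(8, 41))
        members = rng_g.choice(universe, size=size, replace=False)
        items.append((f"SET_R{k:03d}", f"random set {k}", [genes[i] for i in members]))
    gene_sets = GeneSetCollection.from_lists(items)

    truth = GroundTruth(
        planted_age_proteins={fids[i]: float(slopes[i]) for i in age_i},
        planted_constant_proteins={fids[i] for i in const_i},
        planted_block_proteins=[fids[i] for i in block_i],
        planted_repressive_edges=planted_edges,
        decoy_prior_edges=decoy_edges,
        age_mirnas=age_mirnas,
        base_log10={fids[i]: float(base[i]) for i in range(n)},
    )
    return design, protein, mrna_probe, mirna, prior, gene_sets, truth


def write_dataset(outdir: str | Path, params: SimulationParams) -> dict:
    """Generate and write all tables plus ``truth.json``; returns file paths."""
    from . import io as sio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design, protein, probes, mirna, prior, sets, truth = generate_dataset(params)
    paths = {
        "design": outdir / "design.tsv",
        "protein": outdir / "protein.tsv",
        "mrna_probe": outdir / "mrna_probes.tsv",
        "mirna": outdir / "mirna.tsv",
        "prior": outdir / "target_prior.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.json",
    }
    sio.write_design(design, paths["design"])
    sio.write_table(protein, paths["protein"])
    sio.write_table(probes, paths["mrna_probe"])
    sio.write_table(mirna, paths["mirna"])
    sio.write_target_prior(prior, paths["prior"])
    sio.write_gene_sets(sets, paths["gene_sets"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
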