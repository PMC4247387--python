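"""Core in-memory containers for the multi-omics cohort.

The common currency of the pipeline is the :class:`FeatureTable`, an
intensity matrix (features x samples) with layer-specific feature metadata,
always indexed against a :class:`CohortDesign` describing the donors.
Missing measurements are explicit ``NaN`` — zero is a legal measured value
and is *not* conflated with missing, because the presence-based
quantifiability filter depends on the distinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

AGE_GROUPS = ("young", "middle", "old")
DEFAULT_AGE_BANDS: dict[str, tuple[int, int]] = {
    "young": (20, 30),
    "middle": (40, 50),
    "old": (60, 70),
}


class Layer(str, Enum):
    protein = "protein"
    mrna_probe = "mrna_probe"
    mrna_gene = "mrna_gene"
    mirna = "mirna"


@dataclass(frozen=True)
class CohortDesign:
    """Donor ids, calendar ages and age-group labels for the cohort."""

    donor_id: tuple[str, ...]
    age_years: tuple[int, ...]
    age_group: tuple[str, ...]
    sex: tuple[str, ...] | None = None
    age_bands: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_BANDS)
    )

    def __post_init__(self):
        n = len(self.donor_id)
        if len(set(self.donor_id)) != n:
            raise ValidationError("donor ids must be unique")
        if len(self.age_years) != n or len(self.age_group) != n:
            raise ValidationError("design columns have unequal lengths")
        for g in self.age_group:
            if g not in self.age_bands:
                raise ValidationError(f"unknown age group {g!r}")
        for age, g in zip(self.age_years, self.age_group):
            lo, hi = self.age_bands[g]
            if not lo <= age <= hi:
                raise ValidationError(
                    f"age {age} outside configured band {lo}-{hi} for group {g!r}"
                )

    def __len__(self) -> int:
        return len(self.donor_id)

    @property
    def groups(self) -> tuple[str, ...]:
        """Age groups present, in canonical young/middle/old order."""
        present = set(self.age_group)
        return tuple(g for g in AGE_GROUPS if g in present)

    def donors_in_group(self, group: str) -> list[str]:
        return [d for d, g in zip(self.donor_id, self.age_group) if g == group]

    def ages(self) -> pd.Series:
        return pd.Series(self.age_years, index=list(self.donor_id), name="age_years")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "donor_id": self.donor_id,
                "age_years": self.age_years,
                "age_group": self.age_group,
            }
        )
        if self.sex is not None:
            out["sex"] = self.sex
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, age_bands=None) -> "CohortDesign":
        required = {"donor_id", "age_years", "age_group"}
        missing = required - set(frame.columns)
        if missing:
            raise SchemaError(f"design is missing columns: {sorted(missing)}")
        kwargs = {}
        if age_bands is not None:
            kwargs["age_bands"] = age_bands
        return cls(
            donor_id=tuple(str(d) for d in frame["donor_id"]),
            age_years=tuple(int(a) for a in frame["age_years"]),
            age_group=tuple(str(g) for g in frame["age_group"]),
            sex=tuple(str(s) for s in frame["sex"]) if "sex" in frame.columns else None,
            **kwargs,
        )


@dataclass
class FeatureTable:
    """Intensity matrix plus feature metadata for one omics layer.

    ``values`` is a features x samples DataFrame whose columns are exactly
    the cohort donor ids; ``meta`` is indexed like ``values`` and carries
    layer-specific columns (unique_peptide_count, n_samples_identified and
    gene_symbol for proteins; gene_id for mRNA probes).
    """

    layer: Layer
    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        self.layer = Layer(self.layer)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate feature ids: {list(dupes)[:5]}")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValidationError("negative intensities are not allowed")
        if not self.meta.index.equals(self.values.index):
            self.meta = self.meta.reindex(self.values.index)

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def n_features(self) -> int:
        return len(self.values)

    def check_design(self, design: CohortDesign) -> None:
        if list(self.values.columns) != list(design.donor_id):
            raise SchemaError(
                "sample columns do not match cohort donor ids: "
                f"{list(self.values.columns)} vs {list(design.donor_id)}"
            )

    def log10(self) -> pd.DataFrame:
        """log10 intensities; zeros and missing become NaN."""
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(vals > 0, np.log10(np.where(vals > 0, vals, 1.0)), np.nan)
        return pd.DataFrame(out, index=self.values.index, columns=self.values.columns)

    def log2(self) -> pd.DataFrame:
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
        return pd.DataFrame(out, index=self.values.index, columns=self.values.columns)

    def subset(self, feature_ids: Iterable[str]) -> "FeatureTable":
        ids = [f for f in feature_ids if f in self.values.index]
        return FeatureTable(
            layer=self.layer,
            values=self.values.loc[ids].copy(),
            meta=self.meta.loc[ids].copy(),
        )


def normalize_gene(symbol: str) -> str:
    """Case-fold a gene symbol to the shared upper-case namespace."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class TargetPrior:
    """Sequence-prediction candidate map: set of (mirna_id, gene_id) pairs."""

    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "TargetPrior":
        return cls(frozenset((str(m), normalize_gene(g)) for m, g in pairs))

    def __len__(self) -> int:
        return len(self.edges)

    def targets_of(self, mirna: str) -> set[str]:
        return {g for m, g in self.edges if m == mirna}

    def mirnas_targeting(self, gene: str) -> list[str]:
        gene = normalize_gene(gene)
        return sorted(m for m, g in self.edges if g == gene)

    @property
    def genes(self) -> set[str]:
        return {g for _, g in self.edges}

    @property
    def mirnas(self) -> set[str]:
        return {m for m, _ in self.edges}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.edges), columns=["mirna_id", "gene_id"])


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), members in the shared gene namespace."""

    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for sid, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {sid!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    @classmethod
    def from_lists(
        cls, items: Sequence[tuple[str, str, Iterable[str]]]
    ) -> "GeneSetCollection":
        sets: dict[str, frozenset[str]] = {}
        names: dict[str, str] = {}
        for sid, name, members in items:
            if sid in sets:
                raise ValidationError(f"duplicate gene-set id {sid!r}")
            sets[sid] = frozenset(normalize_gene(g) for g in members)
            names[sid] = name
        return cls(sets=sets, names=names)
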