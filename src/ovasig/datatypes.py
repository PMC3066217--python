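"""Shared data containers for the pipeline.

The universal currency between stages is an :class:`ExpressionMatrix` (genes x
samples, log2 scale, optional per-sample batch labels) plus a
:class:`ClinicalTable` carrying overall survival and the usual clinical
covariates.  Containers validate their invariants on construction and are
otherwise thin wrappers around numpy arrays / pandas frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "IdMap",
    "ValidationError",
]

DEBULKING_LEVELS = ("optimal", "suboptimal", "grossly_visible", "no_visible", "unknown")


class ValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


def _check_unique(ids, what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = 1
    if dups:
        raise ValidationError(f"duplicate {what} id(s): {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression intensities.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique identifiers.
    values
        2-D float array, shape ``(len(gene_ids), len(sample_ids))``; must be
        finite (missing values are rejected at I/O, not imputed).
    batch
        Optional per-sample batch label (cohort of origin).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    batch: list[str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.batch is not None:
            self.batch = [str(b) for b in self.batch]
            if len(self.batch) != len(self.sample_ids):
                raise ValidationError("batch labels length != number of samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids),
            list(self.sample_ids),
            self.values.copy(),
            None if self.batch is None else list(self.batch),
        )

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"gene(s) not present: {missing}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            [self.gene_ids[i] for i in rows],
            list(self.sample_ids),
            self.values[rows, :].copy(),
            None if self.batch is None else list(self.batch),
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"sample(s) not present: {missing}")
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(
            list(self.gene_ids),
            [self.sample_ids[i] for i in cols],
            self.values[:, cols].copy(),
            None if self.batch is None else [self.batch[i] for i in cols],
        )

    def __eq__(self, other) -> bool:  # value equality, used heavily in tests
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and self.batch == other.batch
            and np.array_equal(self.values, other.values)
        )


@dataclass
class ClinicalTable:
    """Per-sample survival outcome plus clinical covariates.

    Stored as a DataFrame indexed by ``sample_id`` with columns ``os_months``
    (non-negative float), ``event`` (0/1 int; 1 = death) and optional
    covariates ``age_years``, ``stage`` (1-4), ``grade`` (1-3), ``debulking``,
    ``histology``, ``subtype``, ``response``; missing covariates stay missing
    (NaN/None) rather than dropping the record.
    """

    data: pd.DataFrame

    COVARIATES = ("age_years", "stage", "grade", "debulking", "histology", "subtype", "response")

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise ValidationError("clinical table requires a sample_id column")
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample_id(s): {dups}")
        for col in ("os_months", "event"):
            if col not in df.columns:
                raise ValidationError(f"clinical table missing required column {col!r}")
        df["os_months"] = pd.to_numeric(df["os_months"], errors="raise").astype(float)
        if (df["os_months"] < 0).any():
            bad = df.index[df["os_months"] < 0].tolist()
            raise ValidationError(f"negative os_months for sample(s) {bad}")
        ev = pd.to_numeric(df["event"], errors="raise")
        if not ev.isin([0, 1]).all():
            bad = df.index[~ev.isin([0, 1])].tolist()
            raise ValidationError(f"event outside {{0,1}} for sample(s) {bad}")
        df["event"] = ev.astype(int)
        if "debulking" in df.columns:
            vals = df["debulking"].dropna()
            bad = sorted(set(vals) - set(DEBULKING_LEVELS))
            if bad:
                raise ValidationError(f"unknown debulking level(s): {bad}")
        for col in self.COVARIATES:
            if col not in df.columns:
                df[col] = np.nan
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def os_months(self) -> np.ndarray:
        return self.data["os_months"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    def aligned_to(self, sample_ids) -> "ClinicalTable":
        """Reorder (and subset) to the given sample ids; all must be present."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"clinical records missing for sample(s): {missing}")
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. a GMT collection), each with a description."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    systems: dict[str, str] = field(default_factory=dict)  # optional annotation system per set

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class IdMap:
    """Many-to-one mapping from platform source ids (probe sets) to gene ids."""

    mapping: dict[str, str]

    @classmethod
    def from_pairs(cls, pairs) -> "IdMap":
        mapping: dict[str, str] = {}
        for src, tgt in pairs:
            src, tgt = str(src), str(tgt)
            if src in mapping and mapping[src] != tgt:
                raise ValidationError(
                    f"ambiguous id map: {src!r} -> {mapping[src]!r} and {tgt!r}"
                )
            mapping[src] = tgt
        return cls(mapping)

    def __getitem__(self, src: str) -> str:
        return self.mapping[src]

    def __contains__(self, src: str) -> bool:
        return src in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)
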