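"""Tabular I/O: hormone concentration tables, DEG tables, pathway annotations.

All readers validate on load and raise typed errors (:mod:`hormsense.errors`)
rather than coercing. Writers emit the canonical wide CSV (hormones) or TSV
(everything else); every writer/reader pair round-trips losslessly.

File schemas
------------
hormones (wide, canonical): ``sample_id, tissue, dose_mg_L, replicate, <hormone>...``
hormones (long):            ``sample_id, tissue, dose_mg_L, replicate, hormone, concentration``
DEGs:                       ``gene_id, tissue, dose_mg_L, fold_change, p_value``
annotation:                 ``gene_id, pathway, effect_class``
qPCR:                       ``gene_id, delta_ct_control, delta_ct_treated``
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DesignError,
    DuplicateError,
    SchemaError,
    ValidationError,
)

TISSUES = ("root", "shoot")

#: The 17-hormone targeted panel: abscisic acid, salicylic acid, auxin,
#: the ethylene precursor ACC, three jasmonates, six cytokinins, three
#: gibberellins, and the brassinosteroid typhasterol.
DEFAULT_HORMONES = (
    "ABA", "SA", "IAA", "ACC",
    "JA", "JA-Ile", "OPDA",
    "iP", "iPR", "tZ", "tZR", "cZ", "cZR",
    "GA3", "GA4", "GA7",
    "TY",
)

PATHWAYS = ("ET", "JA", "CK", "GA", "BR", "ABA", "SA", "IAA")

#: Hormone -> biosynthetic pathway assignment used throughout the pipeline.
DEFAULT_HORMONE_PATHWAY_MAP: dict[str, str] = {
    "ACC": "ET",
    "JA": "JA", "JA-Ile": "JA", "OPDA": "JA",
    "iP": "CK", "iPR": "CK", "tZ": "CK", "tZR": "CK", "cZ": "CK", "cZR": "CK",
    "GA3": "GA", "GA4": "GA", "GA7": "GA",
    "TY": "BR",
    "ABA": "ABA",
    "SA": "SA",
    "IAA": "IAA",
}

EFFECT_CLASSES = ("direct", "indirect")

_DESIGN_COLS = ["sample_id", "tissue", "dose_mg_L", "replicate"]


def _delimiter_for(path: str | os.PathLike) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required column(s): {', '.join(missing)}")


@dataclass
class HormoneDataset:
    """Replicate-level hormone concentrations with design metadata.

    ``samples`` is a DataFrame with columns sample_id, tissue, dose_mg_L,
    replicate (one row per sample); ``concentrations`` is an (n_samples,
    n_hormones) array of ng/g fresh weight aligned row-wise with
    ``samples`` and column-wise with ``hormone_names``.
    """

    samples: pd.DataFrame
    concentrations: np.ndarray
    hormone_names: list[str] = field(default_factory=lambda: list(DEFAULT_HORMONES))

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.validate()

    def validate(self) -> None:
        _require_columns(self.samples, _DESIGN_COLS, "hormone sample")
        if len(self.hormone_names) != len(set(self.hormone_names)):
            raise ValidationError("hormone names are not unique")
        n, p = self.concentrations.shape
        if n != len(self.samples) or p != len(self.hormone_names):
            raise ValidationError(
                f"concentration matrix shape {self.concentrations.shape} does not match "
                f"{len(self.samples)} samples x {len(self.hormone_names)} hormones"
            )
        bad_tissue = set(self.samples["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise ValidationError(f"unknown tissue label(s): {sorted(bad_tissue)}")
        if (self.samples["dose_mg_L"] < 0).any():
            raise ValidationError("doses must be non-negative")
        if (self.samples["replicate"] < 1).any():
            raise ValidationError("replicate indices must be positive")
        if not np.isfinite(self.concentrations).all():
            ii, jj = np.argwhere(~np.isfinite(self.concentrations))[0]
            raise ValidationError(
                f"non-finite concentration for sample "
                f"{self.samples['sample_id'].iloc[ii]!r}, hormone {self.hormone_names[jj]!r}"
            )
        if (self.concentrations < 0).any():
            ii, jj = np.argwhere(self.concentrations < 0)[0]
            raise ValidationError(
                f"negative concentration for sample "
                f"{self.samples['sample_id'].iloc[ii]!r}, hormone {self.hormone_names[jj]!r}"
            )
        for tissue, sub in self.samples.groupby("tissue"):
            if 0.0 not in set(sub["dose_mg_L"].astype(float)):
                raise DesignError(
                    f"tissue {tissue!r} has no dose-0 control group; "
                    "percent-change baselines are undefined without one"
                )
        counts = self.samples.groupby(["tissue", "dose_mg_L"]).size()
        thin = counts[counts < 2]
        if len(thin):
            key = thin.index[0]
            raise DesignError(
                f"group tissue={key[0]!r} dose={key[1]} has {int(thin.iloc[0])} replicate(s); >=2 required"
            )

    @property
    def doses(self) -> list[float]:
        """Sorted unique doses, control (0) first."""
        return sorted(set(self.samples["dose_mg_L"].astype(float)))

    @property
    def treatment_doses(self) -> list[float]:
        return [d for d in self.doses if d > 0]

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: design columns followed by one column per hormone."""
        wide = self.samples[_DESIGN_COLS].copy()
        for j, h in enumerate(self.hormone_names):
            wide[h] = self.concentrations[:, j]
        return wide

    def subset(self, tissue: str, doses: list[float]) -> "HormoneDataset":
        mask = (self.samples["tissue"] == tissue) & self.samples["dose_mg_L"].isin(doses)
        return HormoneDataset(
            samples=self.samples.loc[mask],
            concentrations=self.concentrations[mask.to_numpy()],
            hormone_names=list(self.hormone_names),
        )

    def group_means(self, tissue: str) -> pd.DataFrame:
        """Per-dose mean concentration of each hormone within a tissue."""
        frame = self.to_frame()
        sub = frame[frame["tissue"] == tissue]
        return sub.groupby("dose_mg_L")[self.hormone_names].mean()

    def replicate_values(self, tissue: str, dose: float, hormone: str) -> np.ndarray:
        j = self.hormone_names.index(hormone)
        mask = (
            (self.samples["tissue"] == tissue)
            & (self.samples["dose_mg_L"].astype(float) == float(dose))
        ).to_numpy()
        return self.concentrations[mask, j]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HormoneDataset):
            return NotImplemented
        return (
            self.hormone_names == other.hormone_names
            and self.samples[_DESIGN_COLS].reset_index(drop=True).equals(
                other.samples[_DESIGN_COLS].reset_index(drop=True)
            )
            and np.allclose(self.concentrations, other.concentrations, rtol=0, atol=1e-12)
        )


def read_hormone_table(path: str | os.PathLike, dialect: str = "wide") -> HormoneDataset:
    """Read a hormone concentration table in wide or long dialect.

    Wide: one row per sample, one column per hormone (canonical).
    Long: one row per (sample, hormone) pair with columns ``hormone``
    and ``concentration``.
    """
    if dialect not in ("wide", "long"):
        raise ValueError(f"dialect must be 'wide' or 'long', got {dialect!r}")
    df = pd.read_csv(path, sep=_delimiter_for(path))
    if dialect == "long":
        _require_columns(df, _DESIGN_COLS + ["hormone", "concentration"], "long hormone")
        df = (
            df.pivot_table(
                index=_DESIGN_COLS, columns="hormone", values="concentration", sort=False
            )
            .reset_index()
        )
        df.columns.name = None
    _require_columns(df, _DESIGN_COLS, "hormone")
    hormones = [c for c in df.columns if c not in _DESIGN_COLS]
    if not hormones:
        raise SchemaError("hormone table has no hormone columns")
    samples = df[_DESIGN_COLS].copy()
    samples["dose_mg_L"] = samples["dose_mg_L"].astype(float)
    samples["replicate"] = samples["replicate"].astype(int)
    conc = df[hormones].to_numpy(dtype=float)
    return HormoneDataset(samples=samples, concentrations=conc, hormone_names=hormones)


def write_hormone_table(ds: HormoneDataset, path: str | os.PathLike) -> None:
    ds.to_frame().to_csv(path, sep=_delimiter_for(path), index=False)


@dataclass
class DegTable:
    """Differentially-tested genes: one row per (gene, tissue, dose) with the
    linear treated/control expression ratio and its p-value.

    Fold changes stay on the linear scale here; the log2 transform is applied
    only inside the pathway contribution score.
    """

    rows: pd.DataFrame

    COLUMNS = ["gene_id", "tissue", "dose_mg_L", "fold_change", "p_value"]

    def __post_init__(self) -> None:
        self.rows = self.rows.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        _require_columns(self.rows, self.COLUMNS, "DEG")
        bad_tissue = set(self.rows["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise ValidationError(f"unknown tissue label(s): {sorted(bad_tissue)}")
        if (self.rows["dose_mg_L"] <= 0).any():
            raise ValidationError("DEG doses must be positive (treated vs control contrasts)")
        if not (self.rows["fold_change"] > 0).all():
            bad = self.rows.loc[~(self.rows["fold_change"] > 0), "gene_id"].iloc[0]
            raise ValidationError(f"fold_change must be a positive ratio (gene {bad!r})")
        pv = self.rows["p_value"]
        if ((pv < 0) | (pv > 1) | pv.isna()).any():
            bad = self.rows.loc[(pv < 0) | (pv > 1) | pv.isna(), "gene_id"].iloc[0]
            raise ValidationError(f"p_value outside [0, 1] (gene {bad!r})")
        dup = self.rows.duplicated(subset=["gene_id", "tissue", "dose_mg_L"])
        if dup.any():
            bad = self.rows.loc[dup].iloc[0]
            raise DuplicateError(
                f"duplicate DEG row: gene {bad['gene_id']!r}, tissue {bad['tissue']!r}, "
                f"dose {bad['dose_mg_L']}"
            )

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DegTable):
            return NotImplemented
        a = self.rows[self.COLUMNS].reset_index(drop=True)
        b = other.rows[self.COLUMNS].reset_index(drop=True)
        if len(a) != len(b):
            return False
        return bool(
            a[["gene_id", "tissue"]].equals(b[["gene_id", "tissue"]])
            and np.allclose(
                a[["dose_mg_L", "fold_change", "p_value"]],
                b[["dose_mg_L", "fold_change", "p_value"]],
                rtol=0, atol=1e-12,
            )
        )


def read_deg_table(path: str | os.PathLike) -> DegTable:
    df = pd.read_csv(path, sep=_delimiter_for(path))
    _require_columns(df, DegTable.COLUMNS, "DEG")
    df["dose_mg_L"] = df["dose_mg_L"].astype(float)
    df["fold_change"] = df["fold_change"].astype(float)
    df["p_value"] = df["p_value"].astype(float)
    return DegTable(rows=df[DegTable.COLUMNS])


def write_deg_table(table: DegTable, path: str | os.PathLike) -> None:
    table.rows[DegTable.COLUMNS].to_csv(path, sep=_delimiter_for(path), index=False)


@dataclass
class PathwayAnnotation:
    """Gene -> hormone pathway membership with a direct/indirect effect label.

    Direct-effect genes encode biosynthetic enzymes or pathway regulators;
    indirect-effect genes influence the pathway through secondary mechanisms.
    A gene may belong to several pathways (one row each), but each
    (gene, pathway) pair appears once.
    """

    rows: pd.DataFrame
    allow_extra_pathways: bool = False

    COLUMNS = ["gene_id", "pathway", "effect_class"]

    def __post_init__(self) -> None:
        self.rows = self.rows.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        _require_columns(self.rows, self.COLUMNS, "pathway annotation")
        bad_cls = set(self.rows["effect_class"]) - set(EFFECT_CLASSES)
        if bad_cls:
            raise ValidationError(
                f"effect_class must be one of {EFFECT_CLASSES}, got {sorted(bad_cls)}"
            )
        if not self.allow_extra_pathways:
            bad_pw = set(self.rows["pathway"]) - set(PATHWAYS)
            if bad_pw:
                raise ValidationError(
                    f"unknown pathway label(s) {sorted(bad_pw)}; "
                    "pass allow_extra=True to accept additional pathways"
                )
        dup = self.rows.duplicated(subset=["gene_id", "pathway"])
        if dup.any():
            bad = self.rows.loc[dup].iloc[0]
            raise DuplicateError(
                f"gene {bad['gene_id']!r} annotated to pathway {bad['pathway']!r} twice"
            )

    def genes_for(self, pathway: str, effect_class: str) -> list[str]:
        mask = (self.rows["pathway"] == pathway) & (self.rows["effect_class"] == effect_class)
        return self.rows.loc[mask, "gene_id"].tolist()

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayAnnotation):
            return NotImplemented
        a = self.rows[self.COLUMNS].reset_index(drop=True)
        b = other.rows[self.COLUMNS].reset_index(drop=True)
        return a.equals(b)


def read_pathway_annotation(path: str | os.PathLike, allow_extra: bool = False) -> PathwayAnnotation:
    df = pd.read_csv(path, sep=_delimiter_for(path))
    _require_columns(df, PathwayAnnotation.COLUMNS, "pathway annotation")
    return PathwayAnnotation(rows=df[PathwayAnnotation.COLUMNS], allow_extra_pathways=allow_extra)


def write_pathway_annotation(ann: PathwayAnnotation, path: str | os.PathLike) -> None:
    ann.rows[PathwayAnnotation.COLUMNS].to_csv(path, sep=_delimiter_for(path), index=False)


def validate_hormone_pathway_map(
    mapping: dict[str, str], hormones: list[str] | None = None
) -> dict[str, str]:
    """Check that every hormone in the panel has a known pathway label."""
    hormones = list(hormones) if hormones is not None else list(DEFAULT_HORMONES)
    missing = [h for h in hormones if h not in mapping]
    if missing:
        raise ValidationError(f"hormone(s) missing from the pathway map: {missing}")
    bad = {h: p for h, p in mapping.items() if p not in PATHWAYS}
    if bad:
        raise ValidationError(f"unknown pathway label(s) in map: {bad}")
    return dict(mapping)


def read_qpcr_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a qPCR table with per-gene cycle-threshold differences.

    Expects columns ``gene_id, delta_ct_control, delta_ct_treated``;
    returns the frame with a ``relative_expression`` (2^-ddCT) column added.
    """
    df = pd.read_csv(path, sep=_delimiter_for(path))
    _require_columns(df, ["gene_id", "delta_ct_control", "delta_ct_treated"], "qPCR")
    ddct = df["delta_ct_treated"].astype(float) - df["delta_ct_control"].astype(float)
    if not np.isfinite(ddct).all():
        raise ValidationError("non-finite delta-CT value in qPCR table")
    df = df.copy()
    df["relative_expression"] = 2.0 ** (-ddct)
    return df
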